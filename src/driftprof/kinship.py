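"""Genetic identity analysis: IBD sharing probabilities and the PI_HAT score.

Two genomes are compared site by site.  At each biallelic site the pair
shares 0, 1 or 2 alleles identical-by-state (IBS); given population allele
frequencies, the expected IBS-class probabilities conditional on the latent
identity-by-descent state (IBD = 0, 1 or 2 alleles shared from a common
ancestor) are known in closed form.  A method-of-moments solve recovers
P(IBD=0), P(IBD=1), P(IBD=2), and the scalar relatedness score is

    PI_HAT = P(IBD=2) + 0.5 * P(IBD=1)

ranging from 0 (unrelated) to 1 (identity across the genome; monozygotic
twins or duplicate samples of one cell line score ~1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .vardata import VariantRecord


@dataclass(frozen=True)
class IdentityReport:
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    n_sites_used: int
    ibs_counts: tuple[int, int, int]  # observed sites sharing 0/1/2 alleles

    def __post_init__(self):
        total = self.p_ibd0 + self.p_ibd1 + self.p_ibd2
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"IBD probabilities sum to {total}, not 1")
        for p in (self.p_ibd0, self.p_ibd1, self.p_ibd2):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError("IBD probability outside [0,1]")
        expected = self.p_ibd2 + 0.5 * self.p_ibd1
        if abs(self.pi_hat - expected) > 1e-12:
            raise ValueError("pi_hat inconsistent with IBD probabilities")

    def to_dict(self) -> dict:
        return {"p_ibd0": self.p_ibd0, "p_ibd1": self.p_ibd1,
                "p_ibd2": self.p_ibd2, "pi_hat": self.pi_hat,
                "n_sites_used": self.n_sites_used,
                "ibs_counts": list(self.ibs_counts)}


@dataclass
class GenotypeMatrix:
    """Site x sample genotype-dosage table for a pair of genomes."""

    sites: list                 # (chrom, pos, ref, alt), sorted, unique
    dosages: np.ndarray         # shape (n_sites, 2); NaN = missing
    allele_freq: np.ndarray     # panel alt-allele frequency per site
    n_dropped: int = 0          # input sites absent from the panel

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.allele_freq = np.asarray(self.allele_freq, dtype=float)
        if self.dosages.shape != (len(self.sites), 2):
            raise ValueError("dosage matrix does not align with sites")
        if self.allele_freq.shape != (len(self.sites),):
            raise ValueError("allele_freq does not align with sites")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites in genotype matrix")


def pi_hat(p_ibd0: float, p_ibd1: float, p_ibd2: float) -> float:
    """PI_HAT = p(IBD=2) + 0.5 * p(IBD=1)."""
    probs = (p_ibd0, p_ibd1, p_ibd2)
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError(f"IBD probabilities outside [0,1]: {probs}")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"IBD probabilities sum to {sum(probs)}, not 1")
    return p_ibd2 + 0.5 * p_ibd1


def build_genotype_matrix(varset_a: Sequence[VariantRecord],
                          varset_b: Sequence[VariantRecord],
                          panel: Mapping[tuple, float | None]) -> GenotypeMatrix:
    """Join two call sets over the panel's site list.

    Sites are the union of both samples' calls and the panel; a sample with
    no call at a panel site in callable territory is hom-ref (dosage 0).
    Sites absent from the panel (or with no panel frequency) are dropped and
    counted, since the estimator needs an allele frequency at every site.
    """
    dos_a = {r.key: r.dosage for r in varset_a}
    dos_b = {r.key: r.dosage for r in varset_b}
    union = set(dos_a) | set(dos_b) | set(panel)
    sites, freqs, rows = [], [], []
    n_dropped = 0
    for key in sorted(union):
        af = panel.get(key)
        if af is None:
            n_dropped += 1
            continue
        sites.append(key)
        freqs.append(af)
        rows.append((dos_a.get(key, 0.0), dos_b.get(key, 0.0)))
    if not sites:
        raise ValueError("no informative sites: call sets share no panel sites")
    return GenotypeMatrix(sites=sites, dosages=np.array(rows),
                          allele_freq=np.array(freqs), n_dropped=n_dropped)


def estimate_ibd(matrix: GenotypeMatrix, min_sites: int = 1000) -> IdentityReport:
    """Method-of-moments IBD estimation from per-site IBS classes.

    Expected IBS-class probabilities given alt frequency p (q = 1-p):

        P(IBS=0 | IBD=0) = 2 p^2 q^2
        P(IBS=1 | IBD=0) = 4 p^3 q + 4 p q^3
        P(IBS=1 | IBD=1) = 2 p q
        P(IBS=2 | IBD=1) = p^2 + q^2
        P(IBS=2 | IBD=2) = 1

    P(IBD=0) is solved from the IBS=0 count, then P(IBD=1) from the IBS=1
    count, then P(IBD=2) from the remainder; negative estimates are
    truncated to 0 and the triple renormalized to sum to 1.
    """
    p = matrix.allele_freq
    d = matrix.dosages
    usable = (np.isfinite(d).all(axis=1)) & (p > 0.0) & (p < 1.0)
    n = int(usable.sum())
    if n < min_sites:
        raise ValueError(
            f"only {n} usable polymorphic sites; need >= {min_sites}")
    p = p[usable]
    q = 1.0 - p
    ibs = 2 - np.abs(d[usable, 0] - d[usable, 1]).astype(int)
    counts = np.bincount(ibs, minlength=3)

    e0_z0 = 2.0 * p**2 * q**2
    e1_z0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_z0 = 1.0 - e0_z0 - e1_z0
    e1_z1 = 2.0 * p * q
    e2_z1 = 1.0 - e1_z1

    p0 = counts[0] / e0_z0.sum()
    p1 = (counts[1] - p0 * e1_z0.sum()) / e1_z1.sum()
    p2 = (counts[2] - p0 * e2_z0.sum() - p1 * e2_z1.sum()) / n
    est = np.maximum([p0, p1, p2], 0.0)
    est = est / est.sum()
    p0, p1, p2 = (float(x) for x in est)
    return IdentityReport(p_ibd0=p0, p_ibd1=p1, p_ibd2=p2,
                          pi_hat=pi_hat(p0, p1, p2), n_sites_used=n,
                          ibs_counts=tuple(int(c) for c in counts))


def simulate_dosage_pair(freqs: np.ndarray, p_ibd: Sequence[float],
                         rng: np.random.Generator) -> np.ndarray:
    """Draw a dosage pair under the generative IBD model (validation utility).

    At each site an IBD state z is drawn from ``p_ibd``; z alleles are copied
    identically into both genomes, the remaining 2-z alleles per genome are
    independent Bernoulli(p) draws from the panel frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    z = rng.choice(3, size=n, p=np.asarray(p_ibd, dtype=float))
    shared = (rng.random((n, 2)) < freqs[:, None]).astype(int)
    own_a = (rng.random((n, 2)) < freqs[:, None]).astype(int)
    own_b = (rng.random((n, 2)) < freqs[:, None]).astype(int)
    dos_a = np.where(z == 2, shared.sum(1),
                     np.where(z == 1, shared[:, 0] + own_a[:, 0], own_a.sum(1)))
    dos_b = np.where(z == 2, shared.sum(1),
                     np.where(z == 1, shared[:, 0] + own_b[:, 0], own_b.sum(1)))
    return np.column_stack([dos_a, dos_b]).astype(float)
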