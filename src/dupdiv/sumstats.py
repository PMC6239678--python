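"""Neutrality and diversity statistics on haplotype and genotype samples.

The statistics are the classical frequency-spectrum summaries used to scan
for selection: average pairwise differences (π), the number of segregating
sites S, Watterson's θ_W, Tajima's D (Tajima 1989 normalization), Fay & Wu's
H in its original unnormalized form (θ_π − θ_H, Fay & Wu 2000) and Nei's
haplotype diversity dh.  π is also computed directly from unphased diploid
genotypes, and the Hardy–Weinberg exact test (Wigginton-style two-sided
conditional test) is provided for genotype-level quality auditing.

Haplotype inputs are :class:`~dupdiv.msio.HaplotypeMatrix` objects or plain
0/1 arrays with 0 = ancestral, 1 = derived (Fay & Wu's H requires the
derived coding; the other statistics are folded or coding-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msio import MISSING, GenotypeMatrix, HaplotypeMatrix

__all__ = [
    "SFSCounts",
    "StatsRecord",
    "sfs_counts",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "fay_wu_h",
    "haplotype_diversity",
    "compute_stats",
    "genotype_pi",
    "hwe_exact_test",
]


def _alleles(matrix) -> np.ndarray:
    arr = matrix.alleles if isinstance(matrix, HaplotypeMatrix) else np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError("haplotype input must be 2-D")
    return arr


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


@dataclass
class SFSCounts:
    """Unfolded site frequency spectrum: xi[i-1] sites with derived count i."""

    n: int
    xi: np.ndarray  # length n-1, index i-1 holds xi_i

    @property
    def S(self) -> int:
        return int(self.xi.sum())


@dataclass
class StatsRecord:
    """All per-replicate summaries, region-wise and per-site where sensible."""

    pi_region: float
    pi_site: float
    S: int
    watterson_theta: float
    tajimas_d: float
    fay_wu_h: float
    dh: float


def sfs_counts(matrix) -> SFSCounts:
    arr = _alleles(matrix)
    n = arr.shape[0]
    counts = arr.sum(axis=0)
    xi = np.bincount(counts, minlength=n + 1)[1:n]
    return SFSCounts(n=n, xi=xi.astype(np.int64))


def segregating_sites(matrix) -> int:
    arr = _alleles(matrix)
    n = arr.shape[0]
    counts = arr.sum(axis=0)
    return int(np.count_nonzero((counts > 0) & (counts < n)))


def nucleotide_diversity(matrix, per_site: bool = False) -> float:
    """Average pairwise differences π = Σ_sites 2 k (n−k) / (n (n−1)).

    Equals the mean Hamming distance over all sequence pairs.  With
    ``per_site=True`` the region value is divided by the matrix's
    ``block_length``.
    """
    arr = _alleles(matrix)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    k = arr.sum(axis=0, dtype=np.float64)
    pi = float(np.sum(2.0 * k * (n - k)) / (n * (n - 1)))
    if per_site:
        if not isinstance(matrix, HaplotypeMatrix):
            raise ValueError("per_site requires a HaplotypeMatrix with block_length")
        pi /= matrix.block_length
    return pi


def watterson_theta(matrix, per_site: bool = False) -> float:
    arr = _alleles(matrix)
    n = arr.shape[0]
    theta = segregating_sites(matrix) / harmonic(n - 1)
    if per_site:
        theta /= matrix.block_length
    return theta


def tajimas_d(matrix) -> float:
    """Tajima's D with the standard 1989 constants; NaN when S = 0."""
    arr = _alleles(matrix)
    n = arr.shape[0]
    S = segregating_sites(matrix)
    if S == 0:
        return math.nan
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    pi = nucleotide_diversity(matrix)
    return (pi - S / a1) / math.sqrt(var)


def fay_wu_h(matrix) -> float:
    """Unnormalized Fay & Wu's H = θ_π − θ_H; NaN when S = 0.

    θ_H = Σ_i 2 xi_i i² / (n (n−1)) weights high-frequency derived variants;
    negative H means an excess of them.  Requires derived coding (0 =
    ancestral).
    """
    sfs = sfs_counts(matrix)
    n = sfs.n
    if sfs.S == 0:
        return math.nan
    i = np.arange(1, n, dtype=float)
    theta_pi = float(np.sum(2.0 * sfs.xi * i * (n - i)) / (n * (n - 1)))
    theta_h = float(np.sum(2.0 * sfs.xi * i**2) / (n * (n - 1)))
    return theta_pi - theta_h


def haplotype_diversity(matrix) -> float:
    """Nei's dh = n/(n−1) (1 − Σ p_h²) over distinct haplotype strings."""
    arr = _alleles(matrix)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    if arr.shape[1] == 0:
        return 0.0
    _, counts = np.unique(arr, axis=0, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def compute_stats(matrix: HaplotypeMatrix) -> StatsRecord:
    pi = nucleotide_diversity(matrix)
    return StatsRecord(
        pi_region=pi,
        pi_site=pi / matrix.block_length,
        S=segregating_sites(matrix),
        watterson_theta=watterson_theta(matrix),
        tajimas_d=tajimas_d(matrix),
        fay_wu_h=fay_wu_h(matrix),
        dh=haplotype_diversity(matrix),
    )


# ---------------------------------------------------------------------------
# genotype-level statistics
# ---------------------------------------------------------------------------


def genotype_pi(genotypes, region_length: float) -> float:
    """Per-site π from unphased diploid genotypes.

    Per SNV, with m non-missing diploids and alternate-allele frequency p̂
    over the 2m alleles, the contribution is the unbiased estimator
    2m/(2m−1) · 2 p̂ (1−p̂) — identical to haplotype π over the 2m alleles.
    Missing genotypes are excluded per site.  The summed value is divided by
    ``region_length``.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    arr = genotypes.alt_counts if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    if arr.ndim != 2:
        raise ValueError("genotypes must be 2-D (sites x samples)")
    if arr.shape[0] == 0:
        return 0.0
    valid = arr != MISSING
    m = valid.sum(axis=1)
    alt = np.where(valid, arr, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * m)
        contrib = (2.0 * m) / (2.0 * m - 1) * 2.0 * p * (1.0 - p)
    contrib = np.where(m >= 1, contrib, 0.0)
    contrib = np.nan_to_num(contrib, nan=0.0)
    return float(contrib.sum() / region_length)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg test (conditional on allele counts).

    Returns the probability, under the distribution of heterozygote counts
    given the observed allele counts, of all configurations at most as
    probable as the observed one.  Monomorphic samples return 1.  Raises on
    an empty genotype table.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0

    # distribution over heterozygote counts with the parity of `rare`
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    # going down: P(h-2)/P(h) = h (h-1) / ((r_hom+1)(c_hom+1)) / 4
    het, r_hom, c_hom = mid, (rare - mid) // 2, (2 * n - rare - mid) // 2
    h, rh, ch = het, r_hom, c_hom
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (rh + 1) * (ch + 1))
        h -= 2
        rh += 1
        ch += 1
    h, rh, ch = het, r_hom, c_hom
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * rh * ch / ((h + 2.0) * (h + 1.0))
        h += 2
        rh -= 1
        ch -= 1
    probs /= probs.sum()
    obs = probs[n_het]
    p = float(probs[probs <= obs * (1.0 + 1e-9)].sum())
    return min(1.0, p)
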