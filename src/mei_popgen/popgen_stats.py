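"""Descriptive population-genetic statistics on variant tables.

Covers the frequency-based summaries used throughout the analysis: site
frequency spectra (1-D and joint), per-locus mean pairwise differences,
multi-locus Tajima's D with all of its components, per-site Weir & Cockerham
(1984) F_ST, the private / fixed / shared partition of variants between two
populations, and the exact Wilcoxon tests applied to the summary tables.

All operations take allele-dosage tables with no missing genotypes (the
filtering stage guarantees this) and treat the insertion / alternate allele
as the derived allele unless a folded spectrum is requested.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .variant_io import GenotypeTable, ValidationError


class Polarization(enum.Enum):
    DERIVED = "derived"
    MINOR_FOLDED = "minor_folded"


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """counts[k] = number of sites with allele count k among n chromosomes."""

    counts: np.ndarray
    polarization: Polarization
    n: int

    def __post_init__(self):
        if len(self.counts) != self.n + 1:
            raise ValidationError("counts must have length n + 1")
        if (np.asarray(self.counts) < 0).any():
            raise ValidationError("negative SFS entry")
        if self.polarization is Polarization.MINOR_FOLDED:
            if np.asarray(self.counts)[self.n // 2 + 1:].any():
                raise ValidationError("folded spectrum has mass above n/2")

    @property
    def n_polymorphic(self) -> int:
        return int(np.asarray(self.counts)[1:self.n].sum())


@dataclass(frozen=True)
class JointSFS:
    """2-D derived-allele spectrum; entry (k1, k2) counts sites with k1 and
    k2 derived copies in populations 1 and 2 (n1, n2 chromosomes)."""

    matrix: np.ndarray
    n1: int
    n2: int

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (self.n1 + 1, self.n2 + 1):
            raise ValidationError("joint SFS shape must be (n1+1, n2+1)")
        if (m < 0).any():
            raise ValidationError("negative joint SFS entry")

    @property
    def total(self) -> float:
        return float(np.asarray(self.matrix).sum())

    def polymorphic_mask(self) -> np.ndarray:
        """Entries polymorphic in the pooled sample (excludes both corners)."""
        mask = np.ones_like(np.asarray(self.matrix), dtype=bool)
        mask[0, 0] = False
        mask[-1, -1] = False
        return mask


@dataclass(frozen=True)
class TajimaComponents:
    n: int
    S: int
    pi_sum: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float

    @property
    def theta_w(self) -> float:
        return self.S / self.a1


@dataclass(frozen=True)
class FstResult:
    per_site: np.ndarray        # NaN where the estimate is undefined
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    mean_fst: float             # arithmetic mean over defined per-site values
    weighted_fst: float         # ratio-of-sums  sum(a) / sum(a + b + c)


@dataclass(frozen=True)
class SharingPartition:
    pct_private_pop1: float
    pct_private_pop2: float
    pct_fixed_diff: float
    pct_shared: float
    n_loci: int


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def sfs(table: GenotypeTable, population: str | None = None,
        polarization: Polarization = Polarization.DERIVED) -> SiteFrequencySpectrum:
    """Tally the site frequency spectrum for one population.

    DERIVED counts alternate/insertion dosage directly (the reference genome
    lacks the insertion, so absence is ancestral).  MINOR_FOLDED folds counts
    about n/2, the convention used when SNP ancestral states are unknown.
    """
    counts, n = table.allele_counts(population)
    return sfs_from_counts(counts, n, polarization)


def sfs_from_counts(derived_counts: np.ndarray, n: int,
                    polarization: Polarization = Polarization.DERIVED
                    ) -> SiteFrequencySpectrum:
    k = np.asarray(derived_counts)
    if ((k < 0) | (k > n)).any():
        raise ValidationError("allele count outside [0, n]")
    if polarization is Polarization.MINOR_FOLDED:
        k = np.minimum(k, n - k)
    return SiteFrequencySpectrum(np.bincount(k, minlength=n + 1),
                                 polarization, n)


def joint_sfs(table: GenotypeTable, pop1: str, pop2: str) -> JointSFS:
    k1, n1 = table.allele_counts(pop1)
    k2, n2 = table.allele_counts(pop2)
    return joint_sfs_from_counts(k1, k2, n1, n2)


def joint_sfs_from_counts(k1, k2, n1: int, n2: int) -> JointSFS:
    m = np.zeros((n1 + 1, n2 + 1))
    np.add.at(m, (np.asarray(k1), np.asarray(k2)), 1)
    return JointSFS(m, n1, n2)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def per_site_pi(derived_counts: np.ndarray, n: int) -> np.ndarray:
    """Per-site mean pairwise difference 2 k (n - k) / (n (n - 1))."""
    k = np.asarray(derived_counts, dtype=float)
    return 2.0 * k * (n - k) / (n * (n - 1))


def mean_pairwise_diff(table: GenotypeTable, population: str | None = None) -> float:
    """Average over loci of the per-locus mean pairwise difference.

    For a biallelic locus with k derived copies among n chromosomes this is
    2 k (n - k) / (n (n - 1)): the probability that two distinct chromosomes
    drawn from the sample differ at the locus.
    """
    counts, n = table.allele_counts(population)
    if counts.size == 0:
        raise ValidationError("mean_pairwise_diff undefined on an empty table")
    return float(per_site_pi(counts, n).mean())


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled chromosomes."""
    if n < 2:
        raise ValidationError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(table: GenotypeTable, population: str | None = None) -> TajimaComponents:
    counts, n = table.allele_counts(population)
    return tajimas_d_from_counts(counts, n)


def tajimas_d_from_counts(derived_counts: np.ndarray, n: int) -> TajimaComponents:
    """Multi-locus Tajima's D over all sites segregating in the sample.

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1)); sites monomorphic within the
    sample contribute to neither pi nor S.  Undefined (error) when S = 0.
    """
    if n < 4:
        raise ValidationError("Tajima's D needs n >= 4 chromosomes")
    k = np.asarray(derived_counts)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        raise ValidationError("Tajima's D undefined with no segregating sites")
    pi_sum = float(per_site_pi(k[seg], n).sum())
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    D = (pi_sum - S / c["a1"]) / np.sqrt(var)
    return TajimaComponents(n=n, S=S, pi_sum=pi_sum, D=float(D), **c)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(table: GenotypeTable, pop1: str | None = None,
                       pop2: str | None = None,
                       clamp_negative: bool = False) -> FstResult:
    """Per-site Weir & Cockerham (1984) theta-hat between two populations.

    Uses the full variance-component estimator (a, b, c) with observed
    heterozygote frequencies, so it accounts for departures from
    Hardy-Weinberg within samples.  ``mean_fst`` averages per-site estimates
    over sites where a + b + c != 0 (sites monomorphic overall are excluded);
    ``weighted_fst`` is the ratio-of-sums estimator.  Negative per-site
    estimates are retained unless ``clamp_negative``.
    """
    if table.pop_map is None:
        raise ValidationError("table has no population map attached")
    pops = table.pop_map.populations
    if pop1 is None or pop2 is None:
        if len(pops) != 2:
            raise ValidationError(
                f"need exactly two populations, map has {pops}")
        pop1, pop2 = pops
    i1 = table.sample_indices(pop1)
    i2 = table.sample_indices(pop2)
    if i1.size < 2 or i2.size < 2:
        raise ValidationError("each population needs >= 2 diploids")
    d1, d2 = table.dosage[:, i1], table.dosage[:, i2]
    if (d1 < 0).any() or (d2 < 0).any():
        raise ValidationError("missing genotypes present; filter first")
    return wc_fst_from_dosages(d1, d2, clamp_negative=clamp_negative)


def wc_fst_from_dosages(d1: np.ndarray, d2: np.ndarray,
                        clamp_negative: bool = False) -> FstResult:
    n1, n2 = d1.shape[1], d2.shape[1]           # diploid sample sizes
    p1 = d1.sum(axis=1) / (2.0 * n1)
    p2 = d2.sum(axis=1) / (2.0 * n2)
    h1 = (d1 == 1).sum(axis=1) / n1             # observed het frequencies
    h2 = (d2 == 1).sum(axis=1) / n2

    r = 2
    nbar = (n1 + n2) / 2.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2.0

    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom != 0, a / np.where(denom != 0, denom, 1), np.nan)
    if clamp_negative:
        per_site = np.where(np.isnan(per_site), np.nan, np.maximum(per_site, 0.0))
    defined = ~np.isnan(per_site)
    mean_fst = float(per_site[defined].mean()) if defined.any() else float("nan")
    wsum = float(denom[defined].sum())
    weighted = float(a[defined].sum() / wsum) if defined.any() and wsum != 0 \
        else float("nan")
    return FstResult(per_site=per_site, a=a, b=b, c=c,
                     mean_fst=mean_fst, weighted_fst=weighted)


# ---------------------------------------------------------------------------
# Allele sharing
# ---------------------------------------------------------------------------

def sharing_partition(table: GenotypeTable, pop1: str | None = None,
                      pop2: str | None = None) -> SharingPartition:
    """Class each variant locus as private, a fixed difference, or shared.

    Only loci carrying the variant allele in at least one population are
    counted.  Categories are disjoint: fixed difference (frequency 1 in one
    population and 0 in the other), private-pop1 / private-pop2 (variant
    segregating in one population only and not a fixed difference), shared
    (variant present in both populations).
    """
    if table.pop_map is None:
        raise ValidationError("table has no population map attached")
    pops = table.pop_map.populations
    if pop1 is None or pop2 is None:
        pop1, pop2 = pops[0], pops[1]
    k1, n1 = table.allele_counts(pop1)
    k2, n2 = table.allele_counts(pop2)
    present1, present2 = k1 > 0, k2 > 0
    variant = present1 | present2
    fixed_diff = ((k1 == n1) & (k2 == 0)) | ((k1 == 0) & (k2 == n2))
    private1 = present1 & ~present2 & ~fixed_diff
    private2 = present2 & ~present1 & ~fixed_diff
    shared = present1 & present2
    n_loci = int(variant.sum())
    if n_loci == 0:
        return SharingPartition(0.0, 0.0, 0.0, 0.0, 0)
    pct = lambda m: 100.0 * m.sum() / n_loci
    return SharingPartition(pct(private1), pct(private2), pct(fixed_diff),
                            pct(shared), n_loci)


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank_exact(pairs) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking (the standard exact-test
    convention); V is the sum of midranks of positive differences.  The
    two-sided p-value is exact (enumeration over sign assignments) for up to
    25 non-zero pairs and a normal approximation beyond.
    """
    diffs = np.array([float(a) - float(b) for a, b in pairs])
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValidationError("all differences are zero")
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method,
                         zero_method="wilcox")
    ranks = stats.rankdata(np.abs(diffs))
    V = float(ranks[diffs > 0].sum())
    return V, float(min(res.pvalue, 1.0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Returns the rank-sum statistic W of the first sample and the p-value
    (exact for small tie-free samples, normal approximation with tie
    correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    # rank-sum of x = U statistic of x + its minimum possible rank-sum
    W = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return W, float(res.pvalue)
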