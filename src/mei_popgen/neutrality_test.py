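"""Simulation-based tests of deviation from neutral demographic expectations.

For each LINE family the observed Tajima's D (or between-population F_ST) is
compared with a null distribution obtained by coalescent simulation under
the fitted demography, with parameters drawn from their 95% confidence
ranges and the observed number of unlinked polymorphic loci per simulation.
A SNP-block bootstrap null (random contiguous sets of 100-500 SNPs) offers a
model-free comparison distribution.

Default sidedness: D is tested in the lower tail (purifying selection against
insertions predicts an excess of rare variants, hence negative D) and F_ST
likewise in the lower tail (rare, young insertions differentiate populations
less than neutral SNPs do); a two-sided option is available.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .variant_io import GenotypeTable, ValidationError
from .popgen_stats import tajimas_d_from_counts, wc_fst_from_dosages
from . import coalescent_sim as cs


class Statistic(enum.Enum):
    TAJIMA_D = "tajima_d"
    FST = "fst"
    PI = "pi"


class Tail(enum.Enum):
    LOWER = "lower"
    UPPER = "upper"
    TWO_SIDED = "two_sided"


@dataclass
class NullDistribution:
    statistic: Statistic
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValidationError("null distribution is empty")


def _draw_params(rng, ci_ranges: dict[str, tuple[float, float]]) -> dict:
    out = {}
    for name, (lo, hi) in ci_ranges.items():
        if lo > hi:
            raise ValidationError(f"empty CI range for {name}")
        out[name] = float(rng.uniform(lo, hi))
    return out


def default_builder(base: cs.DemographicModel | None = None):
    """Builder updating a base model (default: the fitted anole model) with
    whichever free parameters a draw provides."""
    base = base or cs.TABLE5_ML
    def build(params: dict) -> cs.DemographicModel:
        return cs.DemographicModel.from_dict({**base.to_dict(), **params})
    return build


def family_null(ci_ranges: dict[str, tuple[float, float]], n_loci: int,
                n1: int = 7, n2: int = 6, n_sims: int = 5000, seed: int = 1,
                statistic: Statistic = Statistic.TAJIMA_D,
                population: int = 1, builder=None) -> NullDistribution:
    """Null distribution of a statistic for a family of ``n_loci`` insertions.

    Each of the ``n_sims`` simulations draws one parameter vector uniformly
    from ``ci_ranges`` (constant parameters may be passed as degenerate
    ranges), simulates ``n_loci`` unlinked sites conditioned on polymorphism
    in the pooled sample, and computes the statistic: Tajima's D or mean
    per-locus pairwise difference within ``population`` (1 or 2), or the mean
    per-site Weir-Cockerham F_ST between the populations.  Simulations where
    D is undefined (no sites segregating within the population) are recorded
    as NaN and excluded from the values, with a warning when they exceed 1%.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    if not ci_ranges:
        raise ValidationError("empty CI ranges")
    build = builder or default_builder()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    values = np.full(n_sims, np.nan)
    for i in range(n_sims):
        model = build(_draw_params(rng, ci_ranges))
        s = int(rng.integers(1, 2**31 - 1))
        req = cs.SimRequest(n1=n1, n2=n2, num_sites=n_loci, seed=s)
        k1, k2, hap = cs.simulate_joint_counts(model, req)
        try:
            values[i] = _statistic_value(statistic, population, k1, k2,
                                         hap, n1, n2)
        except ValidationError:
            continue
    ok = ~np.isnan(values)
    if (~ok).sum() > 0.01 * n_sims:
        warnings.warn(f"{int((~ok).sum())} of {n_sims} null simulations had an "
                      "undefined statistic (degenerate within-population data)")
    return NullDistribution(
        statistic=statistic, values=values[ok],
        provenance={"seed": seed, "n_sims": n_sims, "n_loci": n_loci,
                    "n1": n1, "n2": n2, "population": population,
                    "ci_ranges": {k: list(v) for k, v in ci_ranges.items()},
                    "n_undefined": int((~ok).sum())})


def _statistic_value(statistic, population, k1, k2, hap, n1, n2) -> float:
    k = k1 if population == 1 else k2
    n_chrom = 2 * (n1 if population == 1 else n2)
    if statistic is Statistic.TAJIMA_D:
        return tajimas_d_from_counts(k, n_chrom).D
    if statistic is Statistic.PI:
        return float((2.0 * k * (n_chrom - k)
                      / (n_chrom * (n_chrom - 1))).mean())
    # FST: pair haplotypes into the diploids msprime sampled
    d = hap.reshape(hap.shape[0], -1, 2).sum(axis=2)
    res = wc_fst_from_dosages(d[:, :n1], d[:, n1:])
    if np.isnan(res.mean_fst):
        raise ValidationError("F_ST undefined for every simulated site")
    return res.mean_fst


def empirical_p(observed: float, null: NullDistribution,
                tail: Tail = Tail.LOWER) -> float:
    """Add-one empirical p-value p = (r + 1) / (N + 1).

    ``r`` counts simulated values as or more extreme than ``observed`` in the
    chosen tail; the two-sided value doubles the smaller tail and is capped
    at 1.  The add-one rule keeps p away from 0 with finite simulations.
    """
    v = null.values
    N = v.size
    p_low = (int((v <= observed).sum()) + 1) / (N + 1)
    p_up = (int((v >= observed).sum()) + 1) / (N + 1)
    if tail is Tail.LOWER:
        return min(p_low, 1.0)
    if tail is Tail.UPPER:
        return min(p_up, 1.0)
    return min(2.0 * min(p_low, p_up), 1.0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def snp_bootstrap_null(snps: GenotypeTable, set_size_range=(100, 500),
                       n_sets: int = 1000, seed: int = 1,
                       max_retries: int = 1000
                       ) -> dict[str, NullDistribution]:
    """Block bootstrap of Tajima's D over contiguous SNP windows.

    For each set a chromosome is drawn (weighted by its SNP count), a set
    size uniform in ``set_size_range``, and a contiguous run of that many
    consecutive SNPs at a random start; Tajima's D is computed per population
    and pooled into one null distribution per population.  Chromosomes
    shorter than the drawn size trigger a redraw, up to ``max_retries``.
    """
    if snps.pop_map is None:
        raise ValidationError("SNP table has no population map attached")
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValidationError("bad set size range")
    t = snps.sorted()
    chroms = t.sites["chrom"].to_numpy()
    uniq, starts = np.unique(chroms, return_index=True)
    sizes = {c: int((chroms == c).sum()) for c in uniq}
    if max(sizes.values()) < hi:
        raise ValidationError(
            f"no chromosome has >= {hi} SNPs (largest: {max(sizes.values())})")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    pops = t.pop_map.populations
    counts = {p: t.allele_counts(p) for p in pops}
    out = {p: np.full(n_sets, np.nan) for p in pops}
    offsets = dict(zip(uniq, starts))
    weights = np.array([sizes[c] for c in uniq], dtype=float)
    weights /= weights.sum()
    for i in range(n_sets):
        for attempt in range(max_retries):
            c = rng.choice(uniq, p=weights)
            size = int(rng.integers(lo, hi + 1))
            if sizes[c] >= size:
                break
        else:
            raise ValidationError("could not place a bootstrap window")
        start = offsets[c] + int(rng.integers(0, sizes[c] - size + 1))
        sl = slice(start, start + size)
        for p in pops:
            k, n_chrom = counts[p]
            try:
                out[p][i] = tajimas_d_from_counts(k[sl], n_chrom).D
            except ValidationError:
                continue
    result = {}
    for p in pops:
        ok = ~np.isnan(out[p])
        result[p] = NullDistribution(
            statistic=Statistic.TAJIMA_D, values=out[p][ok],
            provenance={"seed": seed, "n_sets": n_sets,
                        "set_size_range": list(set_size_range),
                        "population": p, "n_undefined": int((~ok).sum())})
    return result
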