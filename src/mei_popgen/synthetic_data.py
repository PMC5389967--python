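"""Synthetic input generation and packaged worked-example tables.

Two responsibilities live here:

1. Generators producing complete, format-clean synthetic inputs (SNP tables,
   per-family MEI callsets, population maps) with the statistical structure
   the analysis assumes: neutral frequencies from the two-population
   isolation-with-migration coalescent, optional purifying-selection
   distortion of insertion frequencies, and clade-specific truncation-length
   models.  Every generator is a pure function of (configuration, seed).

2. Machine-readable transcriptions of the published summary tables (clade
   totals, per-individual insertion counts, per-group summary statistics,
   family copy numbers), used as fixtures for worked-example arithmetic.

Selection enters only through site-frequency distortion: candidate neutral
sites are rejection-sampled with acceptance weight proportional to the ratio
of the Wright-Fisher genic-selection sojourn density to its neutral limit at
the site's pooled derived frequency.  This distorts spectra the way
purifying selection does without modeling selection in the genealogy, which
is adequate for frequency-based statistics.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenotypeTable, PopulationMap, ValidationError, POP1, POP2
from . import coalescent_sim as cs


@dataclass(frozen=True)
class SelectionSpec:
    """Population-scaled genic selection coefficient; 0 = neutral,
    negative = purifying selection against the derived (insertion) allele."""

    gamma: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.gamma):
            raise ValidationError("gamma must be finite")


def sojourn_weight(q, gamma: float):
    """Relative sojourn density of a selected vs neutral derived allele.

    For genic selection with scaled coefficient gamma the diffusion sojourn
    density of a new mutation at frequency q is proportional to
    (1 - exp(-gamma (1 - q))) / (q (1 - q) (1 - exp(-gamma))); dividing by
    the neutral limit (proportional to 1/q) leaves
    w(q) = (1 - exp(-gamma (1 - q))) / ((1 - q)(1 - exp(-gamma))), which is
    1 everywhere at gamma = 0 and, for gamma < 0, decreases from 1 toward 0
    as q -> 1: high-frequency derived alleles are disfavoured.
    """
    q = np.asarray(q, dtype=float)
    if abs(gamma) < 1e-9:
        return np.ones_like(q)
    if gamma < -500.0:
        # asymptotic form, avoids expm1 overflow: exp(gamma q) / (1 - q)
        return np.exp(gamma * q) / (1.0 - q)
    if gamma > 500.0:
        return 1.0 / (1.0 - q)
    return np.expm1(-gamma * (1.0 - q)) / ((1.0 - q) * np.expm1(-gamma))


class TruncationShape(enum.Enum):
    #: truncation point uniform along the element plus a full-length class
    UNIFORM_PLUS_FULL = "uniform_plus_full"
    #: probability of truncation decreasing with distance to the 3' end:
    #: short (3'-proximal) truncates dominate, few complete copies
    LINEAR_DECREASING = "linear_decreasing"
    #: early abort (< 1 kb) or essentially complete — nothing in between
    BIMODAL = "bimodal"


@dataclass(frozen=True)
class TruncationModel:
    clade: str
    shape: TruncationShape
    full_length_bp: int
    full_fraction: float
    min_length_bp: int = 50

    def __post_init__(self):
        if not (0.0 <= self.full_fraction <= 1.0):
            raise ValidationError("full_fraction must be in [0, 1]")
        if self.full_length_bp <= 0:
            raise ValidationError("full_length_bp must be > 0")

    def sample_lengths(self, n: int, rng) -> np.ndarray:
        """Draw n insertion lengths; the complete class sits at >= 90% of
        full length so classification against the family maximum is exact."""
        full = self.full_length_bp
        cap = int(0.9 * full)  # truncated copies stay strictly below this
        is_full = rng.random(n) < self.full_fraction
        out = np.empty(n, dtype=int)
        out[is_full] = rng.integers(cap, full + 1, size=int(is_full.sum()))
        k = int((~is_full).sum())
        lo = self.min_length_bp
        if self.shape is TruncationShape.UNIFORM_PLUS_FULL:
            out[~is_full] = rng.integers(lo, cap, size=k)
        elif self.shape is TruncationShape.LINEAR_DECREASING:
            # density on [lo, cap) proportional to (cap - L): inverse-CDF
            u = rng.random(k)
            out[~is_full] = (cap - (cap - lo) * np.sqrt(u)).astype(int)
        else:  # BIMODAL
            hi = min(1000, cap)
            out[~is_full] = rng.integers(lo, hi, size=k)
        return np.clip(out, self.min_length_bp, full)


#: default per-clade truncation models; full-length fractions follow the
#: observed complete fractions per clade (RTE1 62%, L1 43%, R4 41%, CR1 9%,
#: L2 7%; RTEBovB has very few complete copies)
DEFAULT_TRUNCATION = {
    "RTE1": TruncationModel("RTE1", TruncationShape.UNIFORM_PLUS_FULL, 3900, 0.62),
    "R4": TruncationModel("R4", TruncationShape.UNIFORM_PLUS_FULL, 3800, 0.41),
    "CR1": TruncationModel("CR1", TruncationShape.LINEAR_DECREASING, 5800, 0.09),
    "L2": TruncationModel("L2", TruncationShape.LINEAR_DECREASING, 6300, 0.07),
    "L1": TruncationModel("L1", TruncationShape.BIMODAL, 6800, 0.43),
    "RTEBovB": TruncationModel("RTEBovB", TruncationShape.UNIFORM_PLUS_FULL,
                               3200, 0.04),
}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_snp_dataset(model: cs.DemographicModel | None = None,
                         n_sites: int = 5000, n1: int = 7, n2: int = 6,
                         seed: int = 1, n_chromosomes: int = 6,
                         dirty_fraction: float = 0.0
                         ) -> tuple[GenotypeTable, PopulationMap]:
    """Unlinked polymorphic SNPs under the demographic model, filter-clean.

    Sites are laid out over ``n_chromosomes`` synthetic chromosomes with
    passing DP/GQ/QUAL values so the standard filter keeps every record.
    With ``dirty_fraction > 0`` that fraction of sites is degraded (one
    genotype's depth or quality pushed below the standard thresholds) to
    exercise the filters.
    """
    model = model or cs.TABLE5_ML
    req = cs.SimRequest(n1=n1, n2=n2, num_sites=n_sites, seed=seed)
    table = cs.simulate_genotypes(model, req)
    n = table.n_sites
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    chrom_ids = np.sort(rng.integers(1, n_chromosomes + 1, size=n))
    sites = table.sites.copy()
    sites["chrom"] = [f"chr{c}" for c in chrom_ids]
    pos = np.empty(n, dtype=int)
    for c in np.unique(chrom_ids):
        m = chrom_ids == c
        pos[m] = (np.arange(1, m.sum() + 1)) * 1000
    sites["pos"] = pos
    table.sites = sites
    if dirty_fraction > 0:
        bad = rng.random(n) < dirty_fraction
        which = rng.integers(0, table.n_samples, size=n)
        kind = rng.integers(0, 2, size=n)
        for i in np.flatnonzero(bad):
            if kind[i] == 0:
                table.depth[i, which[i]] = 3     # below min depth
            else:
                table.gq[i, which[i]] = 10       # below min genotype quality
    return table.sorted(), table.pop_map


@dataclass(frozen=True)
class FamilyRequest:
    family: str
    clade: str
    n_loci: int
    truncation: TruncationModel | None = None   # default: clade model


def generate_mei_dataset(families: list[FamilyRequest],
                         model: cs.DemographicModel | None = None,
                         selection: SelectionSpec = SelectionSpec(0.0),
                         n1: int = 7, n2: int = 6, seed: int = 1,
                         locus_spacing_bp: int = 10_000,
                         inject_nearby_duplicates: int = 0,
                         max_attempt_factor: int = 2000
                         ) -> dict[str, GenotypeTable]:
    """Per-family MEI callsets with selection-distorted frequencies.

    For each family, unlinked insertion loci are simulated under the
    demographic model conditioned on polymorphism in the pooled sample, then
    rejection-sampled with acceptance weight ``sojourn_weight(q, gamma)`` at
    the pooled derived frequency q (the neutral limit gamma = 0 accepts every
    site, recovering the coalescent frequencies exactly).  Lengths follow the
    clade's truncation model; loci are spaced ``locus_spacing_bp`` apart so
    the 50 bp dedup rule fires only when ``inject_nearby_duplicates`` extra
    shorter calls are requested.  Raises when the rejection loop cannot reach
    the requested locus count within ``max_attempt_factor x n_loci`` draws
    (pathologically strong selection).
    """
    model = model or cs.TABLE5_ML
    gamma = selection.gamma
    out: dict[str, GenotypeTable] = {}
    samples = [f"FL{i+1}" for i in range(n1)] + [f"GU{i+1}" for i in range(n2)]
    pop_map = PopulationMap({s: model.pop1 for s in samples[:n1]}
                            | {s: model.pop2 for s in samples[n1:]})
    nh = 2 * (n1 + n2)
    for fi, famreq in enumerate(families):
        if famreq.n_loci < 1:
            raise ValidationError(f"n_loci must be >= 1 for {famreq.family}")
        trunc = famreq.truncation or DEFAULT_TRUNCATION.get(famreq.clade)
        if trunc is None:
            raise ValidationError(f"no truncation model for clade "
                                  f"{famreq.clade!r}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23, fi]))
        # normalize acceptance to a proper probability over attainable
        # sample frequencies (for gamma > 0 the raw weight exceeds 1)
        qgrid = np.arange(1, nh) / nh
        wmax = float(sojourn_weight(qgrid, gamma).max())
        if not np.isfinite(wmax) or wmax <= 0.0:
            raise ValidationError(
                f"rejection sampling infeasible for {famreq.family}: the "
                f"sojourn weight underflows at gamma={gamma}; use a weaker "
                "selection coefficient")
        dosages = []
        attempts = 0
        batch = max(famreq.n_loci, 200)
        while len(dosages) < famreq.n_loci:
            if attempts > max_attempt_factor * famreq.n_loci:
                raise ValidationError(
                    f"rejection sampling stalled for {famreq.family} at "
                    f"gamma={gamma}; weaken selection or raise the budget")
            s = int(rng.integers(1, 2**31 - 1))
            req = cs.SimRequest(n1=n1, n2=n2, num_sites=batch, seed=s)
            _, _, hap = cs.simulate_joint_counts(model, req)
            attempts += batch
            q = hap.sum(axis=1) / nh
            accept = rng.random(len(q)) < sojourn_weight(q, gamma) / wmax
            d = hap[accept].reshape(-1, n1 + n2, 2).sum(axis=2)
            dosages.extend(d.astype(np.int16))
        dosage = np.array(dosages[:famreq.n_loci], dtype=np.int16)
        n_loci = famreq.n_loci
        lengths = trunc.sample_lengths(n_loci, rng)
        # one synthetic chromosome per family so cross-family positions never
        # collide unless duplicates are injected deliberately
        pos = (np.arange(1, n_loci + 1)) * locus_spacing_bp
        sites = pd.DataFrame({
            "chrom": f"chr_{famreq.family}", "pos": pos, "ref": "A", "alt": "<INS:ME>",
            "qual": 60.0, "length": lengths, "family": famreq.family,
            "clade": famreq.clade, "pass_quality": True,
        })
        if inject_nearby_duplicates > 0:
            k = min(inject_nearby_duplicates, n_loci)
            pick = rng.choice(n_loci, size=k, replace=False)
            dup_sites = sites.iloc[pick].copy()
            dup_sites["pos"] = dup_sites["pos"] + rng.integers(1, 50, size=k)
            dup_sites["length"] = np.maximum(
                (dup_sites["length"] * 0.5).astype(int), 50)
            sites = pd.concat([sites, dup_sites], ignore_index=True)
            dosage = np.concatenate([dosage, dosage[pick]], axis=0)
        out[famreq.family] = GenotypeTable(
            kind="mei", samples=samples, sites=sites, dosage=dosage,
            pop_map=pop_map).sorted()
    return out


# ---------------------------------------------------------------------------
# Published-table fixtures (transcribed summary tables)
# ---------------------------------------------------------------------------

_TABLE1 = """\
clade	n_families	n_rt_hits	n_genome_copies	n_genome_full_length	full_length_range_kb	n_polymorphic	n_full_length_polymorphic
R4	2	7682	3000	994	3.8	1729	712
RTE	2	18554	3516	217	3.2-3.9	3367	1782
CR1	4	86802	1594	117	4.6-5.8	27802	2578
L2	17	38607	3800	380	4.8-6.3	11210	769
L1	20	7441	806	170	5.2-6.8	2508	1089
"""

_TABLE2 = """\
sample	population	depth	n_insertions_present	n_full_length_present
AC_36_1	GULF	15	7557	839
AC_38_4	GULF	10	6367	699
AC_8_13	GULF	9	6402	629
AC_8_8	GULF	16	7849	861
AC_27_3	GULF	10	5626	565
AC_27_4	GULF	10	5135	500
CC3	FLORIDA	16	9969	863
CC8	FLORIDA	16	11965	1130
SB3	FLORIDA	12	11839	1069
SB4	FLORIDA	8	8371	621
TV8	FLORIDA	8	8557	740
VB6	FLORIDA	10	10393	890
VB7	FLORIDA	9	10451	924
"""

# per-group summary statistics: mean pairwise differences (all / per
# population), Tajima's D per population, locus counts, the private / fixed /
# shared partition and mean F_ST.  group: All = whole set, FL = full-length
# (complete) subset, TR = truncated subset.
_TABLE3 = """\
dataset	group	pi_all	pi_florida	pi_gulf	d_florida	d_gulf	n_loci	pct_private_florida	pct_private_gulf	pct_fixed	pct_shared	mean_fst
SNPs	All	0.21	0.22	0.36	-0.62	0.47	314575	60.25	15.85	0.19	23.72	0.12
L1	All	0.15	0.22	0.31	-1.39	-0.48	2508	65.67	19.46	0	14.87	0.04
L1_AC1to16	FL	0.15	0.21	0.32	-1.46	-0.13	454	71.81	18.5	0	9.69	0.04
L1_AC1to16	TR	0.18	0.25	0.30	-0.95	-0.5	1062	59.13	15.35	0	25.52	0.04
L1_AC17to20	FL	0.11	0.17	0.28	-2.06	-0.78	635	68.82	27.09	0	4.09	0.03
L1_AC17to20	TR	0.14	0.20	0.31	-1.6	-0.24	357	71.71	19.33	0	8.96	0.04
L2	All	0.15	0.23	0.28	-1.27	-0.74	11210	61.06	23.76	0	15.18	0.05
L2	FL	0.13	0.20	0.28	-1.65	-0.75	769	67.1	25.1	0	7.80	0.04
L2	TR	0.15	0.23	0.28	-1.24	-0.74	10440	60.61	23.66	0	15.73	0.05
CR1	All	0.15	0.22	0.31	-1.31	-0.29	27802	70.35	18.02	0.02	11.62	0.05
CR1	FL	0.14	0.21	0.30	-1.51	-0.49	2578	68	23.27	0	8.73	0.05
CR1	TR	0.16	0.22	0.31	-1.29	-0.27	25224	70.59	17.48	0.02	11.91	0.05
R4	All	0.17	0.24	0.25	-1.04	-1.1	1729	49.1	20.76	0	30.13	0.03
R4	FL	0.16	0.23	0.25	-1.16	-1.21	1017	47.79	20.94	0	31.27	0.02
R4	TR	0.18	0.25	0.27	-0.87	-0.93	712	50.98	20.51	0	28.51	0.04
RTE-1	All	0.11	0.18	0.23	-1.91	-1.42	2853	62.57	33.16	0	4.28	0.02
RTE-1	FL	0.11	0.18	0.22	-2.00	-1.52	1774	61.72	35.17	0	3.10	0.02
RTE-1	TR	0.12	0.19	0.24	-1.77	-1.23	1079	63.95	29.84	0	6.21	0.02
RTEBovB	All	0.25	0.31	0.34	-0.08	0.06	514	37.74	12.84	0	49.42	0.05
RTEBovB	FL	0.27	0.38	0.33	0.76	-0.06	8	25	25	0	50.00	0.14
RTEBovB	TR	0.25	0.31	0.34	-0.1	0.06	506	37.94	12.65	0	49.41	0.05
"""

_TABLE4 = """\
clade	family	copy_number
L1	L1AC01	68
L1	L1AC02	18
L1	L1AC03	0
L1	L1AC04	43
L1	L1AC05	27
L1	L1AC06	87
L1	L1AC07	532
L1	L1AC08	95
L1	L1AC09	82
L1	L1AC10	0
L1	L1AC11	90
L1	L1AC12	52
L1	L1AC13	103
L1	L1AC14	85
L1	L1AC15	181
L1	L1AC16	53
L1	L1AC17	763
L1	L1AC18	0
L1	L1AC19	23
L1	L1AC20	206
L2	L2AC01	507
L2	L2AC02	336
L2	L2AC03	301
L2	L2AC04	504
L2	L2AC05	276
L2	L2AC06	569
L2	L2AC07	543
L2	L2AC08	1424
L2	L2AC09	1661
L2	L2AC10	131
L2	L2AC11	720
L2	L2AC12	206
L2	L2AC13	948
L2	L2AC14	256
L2	L2AC15	1177
L2	L2AC16	388
L2	L2AC17	1263
RTE	RTE-1	2853
RTE	RTEBovB	514
"""


def _parse(tsv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(tsv), sep="\t")


def table1() -> pd.DataFrame:
    """Per-clade totals: families, reference-genome copies, polymorphic and
    full-length polymorphic insertion counts."""
    return _parse(_TABLE1)


def table2() -> pd.DataFrame:
    """Per-individual polymorphic insertion counts (all / full-length)."""
    return _parse(_TABLE2)


def table3() -> pd.DataFrame:
    """Per-group summary statistics (diversity, Tajima's D, sharing, F_ST)."""
    return _parse(_TABLE3)


def table4() -> pd.DataFrame:
    """Per-family polymorphic copy numbers for the L1, L2 and RTE clades."""
    return _parse(_TABLE4)


def generate_table_fixtures(out_dir) -> dict[str, str]:
    """Write the packaged summary tables as TSV files; returns name->path."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in [("table1", table1()), ("table2", table2()),
                     ("table3", table3()), ("table4", table4())]:
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
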