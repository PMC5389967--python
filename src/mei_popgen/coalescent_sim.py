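"""Two-population isolation-with-migration coalescent simulation.

The demographic model is the one used for the anole SNP analysis: two derived
populations (Florida and Gulf-Atlantic) split from a common ancestor at a
fixed time, each undergoing a single instantaneous size change, with
continuous migration between them.  Genealogy simulation is delegated to
msprime; this module owns the model encoding, the "unlinked sites"
conditioning (one mutation per site, every site polymorphic in the pooled
sample), and the tallying of 1-D and joint site frequency spectra.

Unit conventions
----------------
* Time is in generations before present (1 generation per year when
  converting the 1.34 My divergence).
* Population sizes are numbers of diploid individuals.
* ``m12`` is the forward-in-time fraction of population 2 (Gulf) made up of
  migrants from population 1 (Florida) each generation — the "Gulf from
  Florida" orientation — which backwards in time moves lineages from Gulf to
  Florida.  ``m21`` is the reverse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import msprime

from .variant_io import GenotypeTable, PopulationMap, ValidationError, POP1, POP2
from .popgen_stats import JointSFS, SiteFrequencySpectrum, Polarization, \
    sfs_from_counts, joint_sfs_from_counts

#: fixed divergence time: 1.34 My at one generation per year
T_SPLIT_DEFAULT = 1_340_000


@dataclass(frozen=True)
class DemographicModel:
    """Isolation-with-migration model with one size change per population.

    ``n_cur_*`` are the present-day diploid sizes; ``n_anc_*`` the sizes
    before each population's size-change time (i.e. between ``t_change_*``
    and ``t_split``); ``n_anc_all`` the size of the common ancestor.
    """

    n_anc_all: float
    n_anc_p1: float
    n_anc_p2: float
    n_cur_p1: float
    n_cur_p2: float
    t_split: float = T_SPLIT_DEFAULT
    t_change_p1: float = 0.0
    t_change_p2: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    pop1: str = POP1
    pop2: str = POP2

    def validate(self) -> None:
        for name in ("n_anc_all", "n_anc_p1", "n_anc_p2", "n_cur_p1", "n_cur_p2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.t_change_p1 < self.t_split):
            raise ValidationError("need 0 <= t_change_p1 < t_split")
        if not (0 <= self.t_change_p2 < self.t_split):
            raise ValidationError("need 0 <= t_change_p2 < t_split")
        for name in ("m12", "m21"):
            m = getattr(self, name)
            if not (0 <= m < 1):
                raise ValidationError(f"{name} must be in [0, 1)")

    def to_msprime(self) -> msprime.Demography:
        self.validate()
        d = msprime.Demography()
        d.add_population(name=self.pop1, initial_size=self.n_cur_p1)
        d.add_population(name=self.pop2, initial_size=self.n_cur_p2)
        d.add_population(name="ANC", initial_size=self.n_anc_all)
        if self.t_change_p1 > 0:
            d.add_population_parameters_change(
                time=self.t_change_p1, population=self.pop1,
                initial_size=self.n_anc_p1)
        if self.t_change_p2 > 0:
            d.add_population_parameters_change(
                time=self.t_change_p2, population=self.pop2,
                initial_size=self.n_anc_p2)
        d.add_population_split(time=self.t_split,
                               derived=[self.pop1, self.pop2], ancestral="ANC")
        # forward migration pop1 -> pop2 moves lineages pop2 -> pop1 backwards
        if self.m12 > 0:
            d.set_migration_rate(source=self.pop2, dest=self.pop1, rate=self.m12)
        if self.m21 > 0:
            d.set_migration_rate(source=self.pop1, dest=self.pop2, rate=self.m21)
        d.sort_events()
        return d

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(**d)


#: maximum-likelihood demographic estimates for the Florida / Gulf-Atlantic
#: pair (diploid sizes, generations), with the single size change per
#: population and asymmetric migration described in the module docstring
TABLE5_ML = DemographicModel(
    n_anc_all=1_167_977,
    n_anc_p1=751_115,       # Florida size before its expansion
    n_anc_p2=1_422_722,     # Gulf size before its contraction
    n_cur_p1=3_316_203,
    n_cur_p2=235_789,
    t_split=T_SPLIT_DEFAULT,
    t_change_p1=802_462,
    t_change_p2=274_157,
    m12=3.94e-7,            # Gulf from Florida (forward)
    m21=3.38e-7,            # Florida from Gulf (forward)
)

#: 95% confidence ranges for the free parameters, matching TABLE5_ML
TABLE5_CI = {
    "n_anc_p2": (379_795, 8_838_592),
    "n_anc_p1": (366_002, 1_756_393),
    "n_anc_all": (564_492, 1_488_644),
    "n_cur_p1": (1_959_085, 4_603_720),
    "n_cur_p2": (101_238, 351_645),
    "t_change_p2": (57_331, 559_121),
    "t_change_p1": (275_163, 1_110_215),
    "m12": (2.96e-7, 5.51e-7),
    "m21": (2.19e-7, 9.00e-7),
}


class MutationMode(enum.Enum):
    #: exactly one mutation per site, uniform on total branch length — every
    #: site polymorphic in the pooled sample (SNP/MEI ascertainment)
    FIXED_SITES_ONE_MUTATION = "fixed_sites"
    #: Poisson mutation counts at population-scaled rate theta per site
    THETA_POISSON = "theta_poisson"


@dataclass(frozen=True)
class SimRequest:
    n1: int = 7
    n2: int = 6
    num_sites: int = 1000
    mode: MutationMode = MutationMode.FIXED_SITES_ONE_MUTATION
    theta: float = 1.0          # used by THETA_POISSON only (per site, 4*N*mu)
    seed: int = 1

    def validate(self) -> None:
        # n2 = 0 degenerates to a single-population model, useful for
        # closed-form checks; at least one diploid must be sampled overall
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 1:
            raise ValidationError("need n1, n2 >= 0 and n1 + n2 >= 1")
        if self.num_sites < 1:
            raise ValidationError("num_sites must be >= 1")


def _split_seed(seed: int, salt: int) -> int:
    """Derive an independent positive 31-bit seed from (seed, salt)."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_site_genealogy(model: DemographicModel, n1: int, n2: int,
                            seed: int):
    """Single unlinked-site genealogy as a tskit TreeSequence.

    Samples ``n1`` and ``n2`` diploids from the two populations and runs the
    structured coalescent backwards in time: pairwise coalescence at rate
    1/(2N) within each epoch's population size, migration as lineage movement
    at the model's rates, and pooling into the ancestor at the split time.
    """
    model.validate()
    return msprime.sim_ancestry(
        samples={model.pop1: n1, model.pop2: n2},
        demography=model.to_msprime(), sequence_length=1,
        ploidy=2, random_seed=_split_seed(seed, 0))


def _replicates(model: DemographicModel, n1: int, n2: int, num: int, seed: int):
    return msprime.sim_ancestry(
        samples={model.pop1: n1, model.pop2: n2},
        demography=model.to_msprime(), sequence_length=1,
        ploidy=2, num_replicates=num, random_seed=_split_seed(seed, 0))


def _node_pop_counts(tree):
    """Per non-root node: (pop1 leaves below, pop2 leaves below, branch len)."""
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    k1 = np.array([tree.num_tracked_samples(u) for u in nodes])
    k = np.array([tree.num_samples(u) for u in nodes])
    bl = np.array([tree.branch_length(u) for u in nodes])
    return nodes, k1, k - k1, bl


def simulate_joint_counts(model: DemographicModel, req: SimRequest
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate unlinked sites; return per-site derived-allele counts.

    Returns ``(k1, k2, hap1)`` where ``k1[j]``/``k2[j]`` are derived copies in
    each population at site j and ``hap1`` is the per-haplotype derived state
    matrix of population-1-then-population-2 sample chromosomes (num_sites x
    2(n1+n2)), from which diploid genotypes can be assembled.

    In FIXED_SITES_ONE_MUTATION mode each site carries exactly one mutation
    placed uniformly on total branch length, so every site is polymorphic in
    the pooled sample of 2(n1+n2) chromosomes.  In THETA_POISSON mode each
    genealogy receives a Poisson number of mutations with mean
    theta/2 x (total branch length in units of 2 N_cur_p1 generations); sites
    here are genealogies and a genealogy may yield 0 or several segregating
    mutations, so the returned arrays may be longer or shorter than
    ``num_sites`` (one row per mutation).
    """
    model.validate()
    req.validate()
    rng = np.random.default_rng(_split_seed(req.seed, 1))
    nh = 2 * (req.n1 + req.n2)
    k1_out, k2_out, rows = [], [], []
    for ts in _replicates(model, req.n1, req.n2, req.num_sites, req.seed):
        samples = np.array(list(ts.samples()))
        pops = np.array([ts.node(s).population for s in samples])
        order = np.argsort(pops, kind="stable")   # pop1 block then pop2 block
        samples = samples[order]
        tree = ts.first(tracked_samples=samples[pops[order] == 0])
        nodes, k1n, k2n, bl = _node_pop_counts(tree)
        total = bl.sum()
        if req.mode is MutationMode.FIXED_SITES_ONE_MUTATION:
            hits = [int(rng.choice(len(nodes), p=bl / total))]
        else:
            scale = 2.0 * model.n_cur_p1
            lam = req.theta / 2.0 * (total / scale)
            hits = list(rng.choice(len(nodes), p=bl / total,
                                   size=rng.poisson(lam)))
        sample_pos = {s: i for i, s in enumerate(samples)}
        for h in hits:
            below = np.zeros(nh, dtype=np.int8)
            for s in tree.samples(nodes[h]):
                below[sample_pos[s]] = 1
            k1_out.append(int(k1n[h]))
            k2_out.append(int(k2n[h]))
            rows.append(below)
    hap = np.array(rows, dtype=np.int8) if rows else np.zeros((0, nh), np.int8)
    return np.array(k1_out, dtype=int), np.array(k2_out, dtype=int), hap


def simulate_sfs(model: DemographicModel, req: SimRequest
                 ) -> tuple[JointSFS, SiteFrequencySpectrum, SiteFrequencySpectrum]:
    """Joint and per-population derived-allele spectra of simulated sites."""
    k1, k2, _ = simulate_joint_counts(model, req)
    return (joint_sfs_from_counts(k1, k2, 2 * req.n1, 2 * req.n2),
            sfs_from_counts(k1, 2 * req.n1, Polarization.DERIVED),
            sfs_from_counts(k2, 2 * req.n2, Polarization.DERIVED))


def expected_joint_sfs(model: DemographicModel, n1: int, n2: int,
                       num_trees: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of the one-mutation-per-site joint SFS law.

    Instead of sampling a single mutation per genealogy, every branch of a
    genealogy contributes its share of that genealogy's total length to the
    (k1, k2) entry of the leaves below it — the exact conditional law of a
    single uniformly placed mutation given the genealogy — and entries are
    averaged over genealogies.  This matches the generative law of
    FIXED_SITES_ONE_MUTATION data with far lower variance than sampling one
    mutation per tree.  The result sums to 1 over entries polymorphic in the
    pooled sample.
    """
    model.validate()
    m = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    for ts in _replicates(model, n1, n2, num_trees, seed):
        samples = np.array(list(ts.samples()))
        pops = np.array([ts.node(s).population for s in samples])
        tree = ts.first(tracked_samples=samples[pops == 0])
        _, k1n, k2n, bl = _node_pop_counts(tree)
        np.add.at(m, (k1n, k2n), bl / bl.sum())
    m[0, 0] = 0.0
    m[-1, -1] = 0.0
    total = m.sum()
    if total == 0:
        raise ValidationError("no branch mass tallied; model degenerate?")
    return m / total


def simulate_genotypes(model: DemographicModel, req: SimRequest,
                       chrom: str = "sim1", spacing_bp: int = 10_000
                       ) -> GenotypeTable:
    """Simulate unlinked sites and package them as a diploid SNP table.

    Haploid copies are paired into diploids within each population (msprime's
    diploid individuals, i.e. random pairing under the model); positions are
    laid out ``spacing_bp`` apart on one synthetic chromosome.  DP/GQ
    annotations are set to clean passing values so the table is accepted by
    the SNP filter unchanged.
    """
    _, _, hap = simulate_joint_counts(model, req)
    n_sites = hap.shape[0]
    dosage = hap.reshape(n_sites, -1, 2).sum(axis=2).astype(np.int16) \
        if n_sites else np.zeros((0, req.n1 + req.n2), np.int16)
    samples = [f"FL{i+1}" for i in range(req.n1)] + \
              [f"GU{i+1}" for i in range(req.n2)]
    pop_map = PopulationMap({s: model.pop1 for s in samples[:req.n1]}
                            | {s: model.pop2 for s in samples[req.n1:]})
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n_sites + 1) * spacing_bp,
        "ref": "A", "alt": "T",
        "qual": 60.0,
    })
    return GenotypeTable(
        kind="snp", samples=samples, sites=sites, dosage=dosage,
        depth=np.full((n_sites, len(samples)), 30, dtype=np.int32),
        gq=np.full((n_sites, len(samples)), 99, dtype=np.int32),
        pop_map=pop_map)
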