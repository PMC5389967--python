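import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mei_popgen import (GenotypeTable, PopulationMap)
from mei_popgen import coalescent_sim as cs


@pytest.fixture(scope="session")
def pop_map():
    return PopulationMap(
        {f"FL{i+1}": "FLORIDA" for i in range(7)}
        | {f"GU{i+1}": "GULF" for i in range(6)})


def make_snp_table(dosages, pop_map=None, depth=30, gq=99, qual=60.0,
                   ref=None, alt=None, chrom=None, pos=None):
    """Hand-built SNP table from a list of per-sample dosage rows."""
    d = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = d.shape
    samples = (list(pop_map.assignments) if pop_map is not None
               else [f"S{j+1}" for j in range(n_samples)])
    assert len(samples) == n_samples
    sites = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
        "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 100,
        "ref": ref if ref is not None else ["A"] * n_sites,
        "alt": alt if alt is not None else ["T"] * n_sites,
        "qual": np.broadcast_to(np.asarray(qual, dtype=float), n_sites).copy(),
    })
    return GenotypeTable(
        kind="snp", samples=samples, sites=sites, dosage=d,
        depth=np.broadcast_to(np.asarray(depth), d.shape).astype(np.int32).copy(),
        gq=np.broadcast_to(np.asarray(gq), d.shape).astype(np.int32).copy(),
        pop_map=pop_map)


def make_mei_table(dosages, lengths, family="FAM1", clade="L1",
                   pop_map=None, chrom=None, pos=None, pass_quality=True):
    d = np.asarray(dosages, dtype=np.int16)
    n_sites, n_samples = d.shape
    samples = (list(pop_map.assignments) if pop_map is not None
               else [f"S{j+1}" for j in range(n_samples)])
    sites = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
        "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 1000,
        "ref": ["A"] * n_sites,
        "alt": ["<INS:ME>"] * n_sites,
        "qual": [60.0] * n_sites,
        "length": np.asarray(lengths, dtype=int),
        "family": [family] * n_sites if isinstance(family, str) else family,
        "clade": [clade] * n_sites if isinstance(clade, str) else clade,
        "pass_quality": (np.broadcast_to(pass_quality, n_sites).copy()
                         if np.isscalar(pass_quality) else pass_quality),
    })
    return GenotypeTable(kind="mei", samples=samples, sites=sites, dosage=d,
                         pop_map=pop_map)


@pytest.fixture(scope="session")
def fitted_model_sim():
    """20,000 unlinked polymorphic SNPs under the fitted demographic model
    (7 + 6 diploids), shared by the simulation-versus-data checks."""
    req = cs.SimRequest(n1=7, n2=6, num_sites=20_000, seed=20260925)
    k1, k2, hap = cs.simulate_joint_counts(cs.TABLE5_ML, req)
    return k1, k2, hap
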