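"""Synthetic dataset generators: pipeline acceptance, selection distortion,
truncation-length models and the packaged summary-table fixtures."""

import numpy as np
import pytest
from scipy import integrate

from mei_popgen import (ValidationError, filter_snps, sfs,
                        merge_mei_callsets, dedup_nearby)
from mei_popgen import synthetic_data as sd
from mei_popgen.synthetic_data import (SelectionSpec, TruncationModel,
                                       TruncationShape, FamilyRequest,
                                       sojourn_weight)


class TestGenerateSnpDataset:
    def test_passes_standard_filter_unchanged(self):
        t, pm = sd.generate_snp_dataset(n_sites=400, seed=1)
        assert filter_snps(t).n_sites == 400

    def test_dirty_mode_loses_sites_to_filter(self):
        t, _ = sd.generate_snp_dataset(n_sites=400, seed=1,
                                       dirty_fraction=0.3)
        kept = filter_snps(t).n_sites
        assert kept < 400
        assert kept > 200  # only ~30% degraded

    def test_spectra_consistent_with_dosages(self):
        t, _ = sd.generate_snp_dataset(n_sites=300, seed=2)
        spec = sfs(t, "FLORIDA")
        assert spec.n_polymorphic <= 300
        assert np.asarray(spec.counts).sum() == 300

    def test_seed_stable(self):
        a, _ = sd.generate_snp_dataset(n_sites=100, seed=9)
        b, _ = sd.generate_snp_dataset(n_sites=100, seed=9)
        assert (a.dosage == b.dosage).all()
        assert (a.sites["pos"] == b.sites["pos"]).all()


class TestSelectionDistortion:
    def test_neutral_limit_matches_coalescent(self):
        """gamma = 0 accepts every simulated site, so frequencies follow the
        neutral coalescent law (same seed path, no rejection)."""
        fams = [FamilyRequest("F", "L1", 400)]
        neut = sd.generate_mei_dataset(fams, seed=4)["F"]
        w = sojourn_weight(np.linspace(0.01, 0.99, 50), 0.0)
        assert (w == 1.0).all()
        freqs = neut.dosage.sum(axis=1) / 26
        assert 0 < freqs.mean() < 0.5

    @pytest.mark.parametrize("gamma", [-5.0, -20.0])
    def test_purifying_selection_lowers_frequency(self, gamma):
        fams = [FamilyRequest("F", "CR1", 500)]
        neut = sd.generate_mei_dataset(fams, seed=6)["F"]
        sel = sd.generate_mei_dataset(fams, seed=6,
                                      selection=SelectionSpec(gamma))["F"]
        f_neut = neut.dosage.sum(axis=1).mean() / 26
        f_sel = sel.dosage.sum(axis=1).mean() / 26
        assert f_sel < f_neut
        singleton_neut = (neut.dosage.sum(axis=1) == 1).mean()
        singleton_sel = (sel.dosage.sum(axis=1) == 1).mean()
        assert singleton_sel > singleton_neut

    def test_monotone_in_gamma_magnitude(self):
        fams = [FamilyRequest("F", "L2", 400)]
        means = []
        for gamma in (0.0, -5.0, -20.0):
            t = sd.generate_mei_dataset(fams, seed=7,
                                        selection=SelectionSpec(gamma))["F"]
            means.append(t.dosage.sum(axis=1).mean())
        assert means[0] > means[1] > means[2]

    def test_sojourn_weight_against_numeric_integration(self):
        """Mean frequency under the weighted law drops as predicted by
        numerical integration of the sojourn density."""
        def mean_freq(gamma):
            dens = lambda q: sojourn_weight(q, gamma) / q
            num = integrate.quad(lambda q: q * dens(q), 1e-6, 1 - 1e-6)[0]
            den = integrate.quad(dens, 1e-6, 1 - 1e-6)[0]
            return num / den
        assert mean_freq(-20.0) < mean_freq(-5.0) < mean_freq(0.0)

    def test_extreme_gamma_still_yields_rare_alleles(self):
        """gamma = -5000 is survivable: only the least-disfavoured class
        (singletons) is ever accepted."""
        fams = [FamilyRequest("F", "L1", 30)]
        t = sd.generate_mei_dataset(fams, seed=1,
                                    selection=SelectionSpec(-5000.0))["F"]
        assert (t.dosage.sum(axis=1) == 1).all()

    def test_underflowing_gamma_raises_with_guidance(self):
        fams = [FamilyRequest("F", "L1", 50)]
        with pytest.raises(ValidationError, match="rejection"):
            sd.generate_mei_dataset(fams, seed=1,
                                    selection=SelectionSpec(-1e6))


class TestTruncationModels:
    def test_bimodal_l1_has_two_modes(self):
        model = TruncationModel("L1", TruncationShape.BIMODAL, 6800, 0.43)
        rng = np.random.default_rng(3)
        lens = model.sample_lengths(4000, rng)
        assert ((lens < 1000).mean() > 0.3)
        assert ((lens >= 0.9 * 6800).mean() == pytest.approx(0.43, abs=0.05))
        assert not ((lens >= 1000) & (lens < 0.9 * 6800)).any()

    def test_linear_decreasing_favours_short(self):
        model = TruncationModel("CR1", TruncationShape.LINEAR_DECREASING,
                                5800, 0.0)
        rng = np.random.default_rng(4)
        lens = model.sample_lengths(4000, rng)
        third = 0.9 * 5800 / 3
        assert (lens < third).mean() > (lens > 2 * third).mean()

    def test_uniform_plus_full_fraction(self):
        model = TruncationModel("RTE1", TruncationShape.UNIFORM_PLUS_FULL,
                                3900, 0.62)
        rng = np.random.default_rng(5)
        lens = model.sample_lengths(4000, rng)
        assert (lens >= 0.9 * 3900).mean() == pytest.approx(0.62, abs=0.05)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            TruncationModel("X", TruncationShape.BIMODAL, 100, 1.5)


class TestMeiDatasetPlumbing:
    def test_accepted_end_to_end_without_losses(self):
        fams = [FamilyRequest("A", "R4", 40), FamilyRequest("B", "L2", 30)]
        callsets = sd.generate_mei_dataset(fams, seed=8)
        merged = dedup_nearby(merge_mei_callsets(list(callsets.values())))
        assert merged.n_sites == 70

    def test_injected_duplicates_trigger_dedup(self):
        fams = [FamilyRequest("A", "R4", 40)]
        callsets = sd.generate_mei_dataset(fams, seed=8,
                                           inject_nearby_duplicates=10)
        t = callsets["A"]
        assert t.n_sites == 50
        assert dedup_nearby(t).n_sites == 40

    def test_pure_function_of_seed(self):
        fams = [FamilyRequest("A", "L1", 25)]
        a = sd.generate_mei_dataset(fams, seed=10)["A"]
        b = sd.generate_mei_dataset(fams, seed=10)["A"]
        assert (a.dosage == b.dosage).all()
        assert (a.sites["length"] == b.sites["length"]).all()


class TestTableFixtures:
    def test_per_individual_totals(self):
        t2 = sd.table2()
        fl = t2[t2["population"] == "FLORIDA"]
        gu = t2[t2["population"] == "GULF"]
        assert fl["n_insertions_present"].sum() == 71_545
        assert fl["n_full_length_present"].sum() == 6_237
        assert gu["n_insertions_present"].sum() == 38_936
        assert gu["n_full_length_present"].sum() == 4_093

    def test_clade_totals(self):
        t1 = sd.table1()
        assert t1["n_polymorphic"].sum() == 46_616

    def test_family_table_shape(self):
        t4 = sd.table4()
        l1 = t4[t4["clade"] == "L1"]
        assert len(l1) == 20
        assert (l1["copy_number"] == 0).sum() == 3  # three inactive families
        assert t4.loc[t4["family"] == "RTE-1", "copy_number"].iloc[0] == 2853

    def test_summary_table_consistency(self):
        t3 = sd.table3()
        assert len(t3) == 21
        snp = t3[t3["dataset"] == "SNPs"].iloc[0]
        assert snp["n_loci"] == 314_575
        assert snp["d_florida"] == pytest.approx(-0.62)
        assert snp["mean_fst"] == pytest.approx(0.12)

    def test_fixture_files_written(self, tmp_path):
        paths = sd.generate_table_fixtures(tmp_path)
        import pandas as pd
        for name, p in paths.items():
            df = pd.read_csv(p, sep="\t")
            assert len(df) > 0
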