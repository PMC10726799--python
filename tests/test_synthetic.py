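import numpy as np
import pandas as pd
import pytest

from gutage import synthetic
from gutage.assoc import bh_fdr, spearman
from gutage.clinical import QpcrMeasurement, telomere_ts
from gutage.synthetic import (
    GeneratorConfig,
    MediationChainSpec,
    age_groups,
    generate_cohort,
    generate_hit_table,
    generate_mediation_chain,
    generate_qpcr_plate,
)


class TestGenerateCohort:
    def test_identical_seed_bit_identical(self):
        cfg = GeneratorConfig(n_samples=30, n_species=6, genes_per_species=(5, 8),
                              n_metabolites=8, n_age_linked_species=3, seed=7)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.gene_abundance, c2.gene_abundance)
        pd.testing.assert_frame_equal(c1.metabolites, c2.metabolites)
        pd.testing.assert_frame_equal(c1.subjects, c2.subjects)

    def test_compositional_closure(self, small_cohort):
        np.testing.assert_allclose(
            small_cohort.gene_abundance.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            small_cohort.species_abundance.sum(axis=0), 1.0, atol=1e-9)

    def test_every_gene_maps_to_one_species(self, small_cohort):
        assert small_cohort.species_truth.index.equals(
            small_cohort.gene_abundance.index)
        assert small_cohort.species_truth.notna().all()

    def test_metabolites_align_with_subjects(self, small_cohort):
        assert list(small_cohort.metabolites.columns) == list(
            small_cohort.subjects.index)

    def test_null_slopes_give_no_age_association(self):
        cfg = GeneratorConfig(
            n_samples=120, n_species=8, genes_per_species=(5, 8),
            n_metabolites=8, n_age_linked_species=4,
            species_age_slopes=(0.0, 0.0, 0.0, 0.0),
            mediation_chains=[], seed=3,
        )
        c = generate_cohort(cfg)
        rhos = [spearman(c.species_abundance.loc[s], c.subjects.age)[0]
                for s in c.species_abundance.index]
        assert np.max(np.abs(rhos)) < 0.25
        assert abs(np.mean(rhos)) < 0.08

    def test_planted_age_species_recovered_at_bh_q05(self):
        """Oracle check: Spearman on the generating species abundances with
        BH control recovers the planted positive-slope species."""
        cfg = GeneratorConfig(
            n_samples=150, n_species=20, genes_per_species=(5, 8),
            n_metabolites=10, n_age_linked_species=4,
            species_age_slopes=(0.02, 0.02, 0.02, 0.02),
            mediation_chains=[], seed=5,
        )
        c = generate_cohort(cfg)
        planted = set(c.truth["age_slopes"].query("slope != 0").index)
        ps = {s: spearman(c.species_abundance.loc[s], c.subjects.age)[1]
              for s in c.species_abundance.index}
        names = list(ps)
        q = bh_fdr(np.clip([ps[s] for s in names], 1e-300, 1.0))
        discovered = {s for s, qv in zip(names, q) if qv < 0.05}
        assert planted <= discovered

    def test_creatinine_increases_with_age(self, small_cohort):
        rho, p = spearman(small_cohort.subjects.scr, small_cohort.subjects.age)
        assert rho > 0.2 and p < 0.01
        assert (small_cohort.subjects.scr >= 0.3).all()

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_species=0)
        with pytest.raises(ValueError):
            GeneratorConfig(age_range=(80.0, 20.0))
        with pytest.raises(ValueError):
            GeneratorConfig(dropout_prob=1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(gene_noise_sd=-0.1)


class TestMediationChain:
    @pytest.mark.parametrize("a,b", [(0.0, 0.5), (0.5, 0.0)])
    def test_null_chain_population_acme_zero(self, a, b):
        _, truth = generate_mediation_chain(100, a, b, 0.3, 1.0, 1.0, seed=0)
        assert truth["population_acme"] == 0.0

    def test_estimated_acme_near_product(self):
        d, truth = generate_mediation_chain(500, 0.5, 0.5, 0.0, 1.0, 1.0, seed=2)
        # two least-squares fits: the product-of-coefficients oracle
        a = np.polyfit(d.x, d.m, 1)[0]
        X = np.column_stack([np.ones(500), d.x, d.m])
        b = np.linalg.lstsq(X, d.y, rcond=None)[0][2]
        assert a * b == pytest.approx(truth["population_acme"], abs=0.08)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            generate_mediation_chain(5, 0.5, 0.5, 0.0, 1.0, 1.0)

    def test_cohort_chain_regressions_match_spec(self, small_cohort):
        """The planted cohort chain reproduces the chain's regression
        structure: mediator ~ exposure slope near a, and age carries the
        b-path after scaling."""
        truth = small_cohort.truth["mediation"].iloc[0]
        x = np.log(small_cohort.species_abundance.loc[truth.exposure_species])
        m = small_cohort.metabolites.loc[truth.mediator_metabolite]
        slope = np.polyfit((x - x.mean()) / x.std(), m, 1)[0]
        assert slope == pytest.approx(truth.a, abs=0.35)


class TestHitTable:
    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            generate_hit_table(pd.Series(dtype=object))

    def test_best_hits_point_to_true_species(self, small_cohort):
        hits = generate_hit_table(small_cohort.species_truth, seed=0)
        best = hits.loc[hits.groupby("gene_id").bitscore.idxmax()]
        best = best.set_index("gene_id").subject_species
        truth = small_cohort.species_truth
        assert (best.loc[truth.index] == truth).all()

    def test_identity_centered_at_requested_mean(self, small_cohort):
        hits = generate_hit_table(small_cohort.species_truth,
                                  mean_identity=80.0, seed=0)
        best = hits.loc[hits.groupby("gene_id").bitscore.idxmax()]
        assert (best.identity == 80.0).all()


class TestQpcrPlate:
    def _recover(self, table, sample):
        std = table[table.sample_id == "standard"]
        smp = table[table.sample_id == sample]
        meas = QpcrMeasurement(
            sample,
            smp[smp.target == "T"].ct.tolist(),
            smp[smp.target == "S"].ct.tolist(),
            std[std.target == "T"].ct.tolist(),
            std[std.target == "S"].ct.tolist(),
        )
        return telomere_ts(meas)

    @pytest.mark.parametrize("ts", [1.0, 2.0, 0.5])
    def test_noise_free_recovery_is_exact(self, ts):
        table = generate_qpcr_plate(3, ts, replicate_sd=0.0, seed=0)
        for s in ("S0000", "S0001", "S0002"):
            assert self._recover(table, s) == pytest.approx(ts, rel=1e-9)

    def test_three_replicates_per_target(self):
        table = generate_qpcr_plate(2, 1.0, seed=0)
        counts = table.groupby(["sample_id", "target"]).size()
        assert (counts == 3).all()

    def test_noisy_recovery_unbiased_within_5pct(self):
        """Monte-Carlo oracle: mean recovered T/S over 50 samples within 5%
        of the planted ratio at replicate SD 0.1."""
        table = generate_qpcr_plate(50, 1.5, replicate_sd=0.1, seed=1)
        recovered = [self._recover(table, f"S{i:04d}") for i in range(50)]
        assert np.mean(recovered) == pytest.approx(1.5, rel=0.05)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            generate_qpcr_plate(3, 0.0)


class TestAgeGroups:
    def test_bins_at_60_90_100(self):
        out = age_groups([25, 59.9, 60, 89.9, 90, 99.9, 100, 111])
        assert out.tolist() == ["young", "young", "elderly", "elderly",
                                "nonagenarian", "nonagenarian",
                                "centenarian", "centenarian"]


def test_write_cohort_round_trips(tmp_path, small_cohort):
    from gutage import profiles

    paths = synthetic.write_cohort(small_cohort, tmp_path)
    back = profiles.read_matrix(paths["gene_abundance"])
    np.testing.assert_allclose(back.to_numpy(),
                               small_cohort.gene_abundance.to_numpy(),
                               rtol=1e-11)
    assert (tmp_path / "manifest.json").exists()
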