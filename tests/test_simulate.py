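"""Synthetic-data generator: profiles, mixtures, reads, dilutions, betas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urometh.dmr import call_dml
from urometh.simulate import (
    BINS,
    PAPER_DILUTION_FRACTIONS,
    SimulationConfig,
    make_reference_profiles,
    simulate_beta_matrix,
    simulate_cohort,
    simulate_dilution_series,
    simulate_haplotype_counts,
    simulate_mixture,
    simulate_reads,
    write_sam,
)


class TestReferenceProfiles:
    def test_probability_vectors_normalized(self, profiles):
        for prof in profiles.values():
            sums = prof.probs.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert (prof.probs.to_numpy() >= 0).all()

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 10_000), contrast=st.floats(0.0, 4.0))
    def test_normalization_for_any_config(self, seed, contrast):
        cfg = SimulationConfig(seed=seed, entropy_contrast=contrast)
        for prof in make_reference_profiles(cfg).values():
            assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_t1_has_dominant_haplotype_per_class(self, small_config, profiles):
        types = small_config.dmr_types()
        t1_names = types.index[types == "T1"]
        for prof in profiles.values():
            assert (prof.probs.loc[t1_names].max(axis=1) >= 0.8).all()

    def test_driver_amplicons_have_elevated_hg_entropy(self):
        cfg = SimulationConfig(seed=3, n_amplicons=10, n_t1dmr=5, n_t2dmr=5,
                               entropy_contrast=2)
        profs = make_reference_profiles(cfg)
        t2 = cfg.dmr_types() == "T2"
        hg = profs["HG"].entropy()[t2]
        lg = profs["LG"].entropy()[t2]
        ur = profs["URINE"].entropy()[t2]
        assert (hg > lg).all() and (hg > ur).all()

    def test_driver_amplicons_carry_tumour_specific_haplotypes(self, small_config, profiles):
        """On every T2 amplicon the HG profile has a haplotype absent from urine."""
        t2 = small_config.dmr_types() == "T2"
        hg = profiles["HG"].probs[t2.values]
        ur = profiles["URINE"].probs[t2.values]
        tsh = (hg > 0.05) & (ur < 0.001)
        assert tsh.any(axis=1).all()

    def test_zero_contrast_collapses_all_classes(self):
        cfg = SimulationConfig(seed=5, entropy_contrast=0)
        profs = make_reference_profiles(cfg)
        assert np.allclose(profs["HG"].probs, profs["URINE"].probs)
        assert np.allclose(profs["LG"].probs, profs["URINE"].probs)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_amplicons=10, n_t1dmr=4, n_t2dmr=5)


class TestMixture:
    def test_fraction_zero_is_urine(self, profiles):
        mix = simulate_mixture(profiles["HG"], profiles["URINE"], 0.0)
        assert np.allclose(mix.probs, profiles["URINE"].probs)
        assert np.allclose(mix.entropy(), profiles["URINE"].entropy())

    def test_fraction_one_is_tumour(self, profiles):
        mix = simulate_mixture(profiles["HG"], profiles["URINE"], 1.0)
        assert np.allclose(mix.probs, profiles["HG"].probs)

    def test_hand_arithmetic(self):
        """bin with tumour 0.9 / urine 0.1 at fraction 0.3 -> 0.34."""
        assert 0.3 * 0.9 + 0.7 * 0.1 == pytest.approx(0.34)
        cfg = SimulationConfig(seed=1)
        profs = make_reference_profiles(cfg)
        mix = simulate_mixture(profs["HG"], profs["URINE"], 0.3)
        expect = 0.3 * profs["HG"].probs + 0.7 * profs["URINE"].probs
        assert np.allclose(mix.probs, expect)

    def test_out_of_range_fraction(self, profiles):
        with pytest.raises(ValueError):
            simulate_mixture(profiles["HG"], profiles["URINE"], 1.2)


class TestReads:
    def test_point_mass_profile_gives_fully_methylated_reads(self):
        cfg = SimulationConfig(seed=2, n_amplicons=2, n_t1dmr=1, n_t2dmr=1,
                               coverage=50, conversion_failure_rate=0.0,
                               low_mapq_fraction=0.0)
        profs = make_reference_profiles(cfg)
        point = profs["URINE"]
        point.probs.iloc[:, :] = 0.0
        point.probs.iloc[:, -1] = 1.0  # all mass on bin 1.0
        records, seqs, amps = simulate_reads(point, cfg, "s")
        for rec in records:
            amp = amps.set_index("name").loc[rec["rname"]]
            seq = rec["seq"]
            assert all(seq[p] == "C" for p in amp["cpg_positions"])
            assert all(seq[p] == "T" for p in amp["noncpg_c_positions"])

    def test_binomial_sampling_of_bins(self):
        cfg = SimulationConfig(seed=4, n_amplicons=2, n_t1dmr=1, n_t2dmr=1,
                               coverage=1000, conversion_failure_rate=0.0)
        profs = make_reference_profiles(cfg)
        half = profs["URINE"]
        half.probs.iloc[:, :] = 0.0
        half.probs.iloc[:, 0] = 0.5
        half.probs.iloc[:, -1] = 0.5
        records, _, amps = simulate_reads(half, cfg, "s")
        amp0 = amps.iloc[0]
        n_meth = sum(
            all(r["seq"][p] == "C" for p in amp0["cpg_positions"])
            for r in records if r["rname"] == amp0["name"]
        )
        se = np.sqrt(0.25 / 1000)
        assert abs(n_meth / 1000 - 0.5) < 3 * se

    def test_same_seed_byte_identical_sam(self, tmp_path):
        cfg = SimulationConfig(seed=9, coverage=30)
        profs = make_reference_profiles(cfg)
        paths = []
        for i in range(2):
            records, seqs, _ = simulate_reads(profs["LG"], cfg, "rep")
            p = tmp_path / f"run{i}.sam"
            write_sam(records, seqs, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_counts_converge_to_profile(self, profiles):
        """Total-variation distance between sampled haplotype frequencies and
        the generating profile shrinks with coverage."""
        prof = profiles["HG"]
        tvs = {}
        for cov in (100, 10_000):
            rng = np.random.default_rng(0)
            t = simulate_haplotype_counts(prof, cov, rng, "s")
            wide = t.pivot_table(index="amplicon", columns="bin",
                                 values="prevalence", fill_value=0.0)
            wide = wide.reindex(columns=list(BINS), fill_value=0.0)
            tvs[cov] = 0.5 * np.abs(
                wide.to_numpy() - prof.probs.to_numpy()).sum(axis=1).mean()
        assert tvs[10_000] < tvs[100]
        assert tvs[10_000] < 0.02


class TestDilutionSeries:
    def test_bookkeeping(self):
        cfg = SimulationConfig(seed=1, coverage=50,
                               dilution_fractions=(0.01, 0.0),
                               replicates_per_fraction=3)
        cohort = simulate_dilution_series(cfg)
        assert len(cohort.truth) == 6
        assert set(cohort.truth["fraction"]) == {0.01, 0.0}

    def test_default_series_has_eight_fractions_plus_blanks(self):
        cfg = SimulationConfig(seed=1, coverage=50, replicates_per_fraction=2)
        assert len(PAPER_DILUTION_FRACTIONS) == 8
        cohort = simulate_dilution_series(cfg)
        fractions = set(cohort.truth["fraction"])
        assert fractions == set(PAPER_DILUTION_FRACTIONS) | {0.0}
        assert len(cohort.truth) == 9 * 2

    def test_determinism(self):
        cfg = SimulationConfig(seed=6, coverage=100, replicates_per_fraction=2)
        a = simulate_dilution_series(cfg)
        b = simulate_dilution_series(cfg)
        pd.testing.assert_frame_equal(a.haplotype_table, b.haplotype_table)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_covers_every_sample_and_amplicon(self):
        cfg = SimulationConfig(seed=2, coverage=50, replicates_per_fraction=2)
        cohort = simulate_dilution_series(cfg)
        assert set(cohort.haplotype_table["sample"]) == set(cohort.truth.index)
        assert set(cohort.amplicon_types.index) == set(cfg.amplicon_names())


class TestBetaMatrix:
    def test_values_clipped_to_unit_interval(self):
        beta, *_ = simulate_beta_matrix(5, 100, [(10, 20)], effect=0.9, seed=0)
        vals = beta.drop(columns=["chrom", "pos"]).to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_null_effect_type_one_control(self):
        """With no effect the DML rate stays near the nominal joint level."""
        beta, labels, _, _ = simulate_beta_matrix(10, 500, [], effect=0.0, seed=1)
        dml = call_dml(beta, labels)
        # p<.01 AND |delta|>.1 jointly is rarer than 1%; allow a generous
        # binomial upper bound at the 1% level
        assert dml["is_dml"].sum() <= 500 * 0.01 + 3 * np.sqrt(500 * 0.01)

    def test_planted_loci_recovered(self):
        beta, labels, _, _ = simulate_beta_matrix(10, 100, [(30, 50)],
                                                  effect=0.3, seed=2)
        dml = call_dml(beta, labels)
        assert dml["is_dml"].iloc[30:50].mean() >= 0.9

    def test_overlapping_planted_intervals_rejected(self):
        with pytest.raises(ValueError):
            simulate_beta_matrix(5, 100, [(10, 20), (15, 30)], effect=0.3, seed=0)


def test_cohort_reproducible_under_fixed_seed():
    cfg = SimulationConfig(seed=12, coverage=100)
    a = simulate_cohort(cfg, 3, 3, 2)
    b = simulate_cohort(cfg, 3, 3, 2)
    pd.testing.assert_frame_equal(a.haplotype_table, b.haplotype_table)
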