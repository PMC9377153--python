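"""DMR discovery: DML calling, merging, seed testing, CBS, clustering,
accessibility filtering and core selection."""

import numpy as np
import pandas as pd
import pytest

from urometh.dmr import (
    DMRDiscovery,
    call_dml,
    cbs_segment,
    cluster_segments,
    filter_by_peaks,
    merge_dml,
    select_core_dmr,
)
from urometh.dmr import test_seed_dmr as seed_dmr_test  # avoid pytest collection
from urometh.simulate import simulate_beta_matrix


def _beta_frame(case, ctrl, pos=None, chrom="chr1"):
    """Beta matrix from per-locus lists of case/control values."""
    case = np.atleast_2d(case)
    ctrl = np.atleast_2d(ctrl)
    n = case.shape[0]
    df = pd.DataFrame({"chrom": [chrom] * n,
                       "pos": pos if pos is not None else np.arange(n) * 50 + 100})
    for i in range(case.shape[1]):
        df[f"case_{i}"] = case[:, i]
    for i in range(ctrl.shape[1]):
        df[f"ctrl_{i}"] = ctrl[:, i]
    labels = pd.Series(
        ["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
        index=[c for c in df.columns if c not in ("chrom", "pos")])
    return df, labels


class TestCallDml:
    def test_identical_groups_not_dml(self):
        vals = np.tile(np.linspace(0.2, 0.8, 5)[:, None], (1, 4))
        beta, labels = _beta_frame(vals, vals)
        out = call_dml(beta, labels)
        assert not out["is_dml"].any()

    def test_small_delta_with_tiny_p_rejected(self):
        """Both conditions are required: delta .05 fails the > .1 rule."""
        rng = np.random.default_rng(0)
        case = rng.normal(0.55, 0.001, size=(3, 10))
        ctrl = rng.normal(0.50, 0.001, size=(3, 10))
        beta, labels = _beta_frame(case, ctrl)
        out = call_dml(beta, labels)
        assert (out["pvalue"] < 1e-6).all()
        assert not out["is_dml"].any()

    def test_missing_heavy_loci_skipped(self):
        case = np.full((2, 4), 0.9)
        ctrl = np.full((2, 4), 0.1)
        case[0, :3] = np.nan  # 75% missing in case group
        beta, labels = _beta_frame(case, ctrl)
        out = call_dml(beta, labels)
        assert np.isnan(out["pvalue"].iloc[0])
        assert bool(out["is_dml"].iloc[1])


class TestMergeDml:
    def test_within_gap_merges(self):
        out = merge_dml(pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 100]}))
        assert len(out) == 1
        assert out.iloc[0]["start"] == 10 and out.iloc[0]["end"] == 101

    def test_beyond_gap_splits(self):
        out = merge_dml(pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [10, 200]}))
        assert len(out) == 2

    def test_chromosomes_never_merge(self):
        out = merge_dml(pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [10, 20]}))
        assert len(out) == 2

    def test_empty_input(self):
        out = merge_dml(pd.DataFrame({"chrom": [], "pos": []}))
        assert len(out) == 0


class TestSeedDmr:
    def test_flat_region_dropped_planted_kept(self):
        rng = np.random.default_rng(1)
        case = np.r_[rng.normal(0.8, 0.03, size=(5, 8)),
                     rng.normal(0.5, 0.03, size=(5, 8))]
        ctrl = np.r_[rng.normal(0.5, 0.03, size=(5, 8)),
                     rng.normal(0.5, 0.03, size=(5, 8))]
        beta, labels = _beta_frame(case, ctrl)
        initial = pd.DataFrame([
            {"chrom": "chr1", "start": 100, "end": 301},   # loci 0-4, shifted
            {"chrom": "chr1", "start": 350, "end": 551},   # loci 5-9, flat
        ])
        seeds = seed_dmr_test(initial, beta, labels)
        assert len(seeds) == 1 and seeds.iloc[0]["start"] == 100


class TestCBS:
    def test_constant_track_single_segment(self):
        segs = cbs_segment(np.zeros(60), seed=0)
        assert len(segs) == 1 and segs.iloc[0]["n"] == 60

    def test_step_function_breakpoint_localized(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 0.05, 50), rng.normal(0.4, 0.05, 50)]
        segs = cbs_segment(x, seed=3)
        cuts = sorted(set(segs["start"]) | set(segs["end"]))
        assert any(abs(c - 50) <= 2 for c in cuts)

    def test_segments_partition_input(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(0, 0.05, 30), rng.normal(0.3, 0.05, 20),
                  rng.normal(-0.2, 0.05, 30)]
        segs = cbs_segment(x, seed=5)
        assert segs.iloc[0]["start"] == 0 and segs.iloc[-1]["end"] == len(x)
        assert (segs["start"].iloc[1:].to_numpy() == segs["end"].iloc[:-1].to_numpy()).all()
        assert segs["n"].sum() == len(x)

    def test_exchangeable_track_rarely_split(self):
        """On iid noise CBS keeps a single segment in most runs."""
        rng = np.random.default_rng(6)
        single = sum(
            len(cbs_segment(rng.normal(0, 0.1, 80), alpha=0.01, n_perm=300,
                            seed=i)) == 1
            for i in range(10)
        )
        assert single >= 8

    def test_seed_required(self):
        with pytest.raises(ValueError):
            cbs_segment(np.zeros(10), seed=None)


class TestClusterSegments:
    def _segments(self):
        rows = []
        deltas = [-0.3] * 4 + [0.0] * 8 + [0.3] * 4
        for i, d in enumerate(deltas):
            rows.append({"chrom": "chr1", "start": i * 100, "end": (i + 1) * 100,
                         "mean": d + 0.001 * i})
        return pd.DataFrame(rows)

    def test_sign_structure_clusters_and_containment(self):
        segs = self._segments()
        seeds = pd.DataFrame([{"chrom": "chr1", "start": 1310, "end": 1380}])
        out = cluster_segments(segs, seeds, k=3, seed=0)
        # seed is inside a +0.3 segment: exactly the positive cluster selected
        assert (out["mean"] > 0.2).all()
        assert len(out) == 4

    def test_seed_in_neutral_segment_selects_neutral_cluster(self):
        segs = self._segments()
        seeds = pd.DataFrame([{"chrom": "chr1", "start": 610, "end": 680}])
        out = cluster_segments(segs, seeds, k=3, seed=0)
        assert np.allclose(out["mean"].abs() < 0.1, True)
        assert len(out) == 8

    def test_determinism(self):
        segs = self._segments()
        seeds = pd.DataFrame([{"chrom": "chr1", "start": 1310, "end": 1380}])
        a = cluster_segments(segs, seeds, k=3, seed=42)
        b = cluster_segments(segs, seeds, k=3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_k_exceeding_segments_errors(self):
        with pytest.raises(ValueError):
            cluster_segments(self._segments(), pd.DataFrame(), k=99, seed=0)


class TestPeakFilter:
    candidates = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])

    def test_one_bp_overlap_kept(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 199, "end": 300}])
        assert len(filter_by_peaks(self.candidates, peaks)) == 1

    def test_abutting_interval_removed(self):
        peaks = pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 300}])
        assert len(filter_by_peaks(self.candidates, peaks)) == 0

    def test_empty_peaks_remove_all(self):
        peaks = pd.DataFrame(columns=["chrom", "start", "end"])
        assert len(filter_by_peaks(self.candidates, peaks)) == 0


class TestCoreSelection:
    def test_flat_dmr_never_selected_and_planted_selected(self):
        rng = np.random.default_rng(7)
        n = 10
        # locus block 0-4: hyper in HG only; block 5-9: identical everywhere
        hg = np.r_[rng.normal(0.8, 0.03, size=(5, n)), np.full((5, n), 0.5)]
        lg = np.r_[rng.normal(0.4, 0.03, size=(5, n)), np.full((5, n), 0.5)]
        beta, labels = _beta_frame(hg, lg)
        pathology = pd.Series(np.where(labels == "case", "HG", "LG"),
                              index=labels.index)
        candidates = pd.DataFrame([
            {"chrom": "chr1", "start": 100, "end": 301},
            {"chrom": "chr1", "start": 350, "end": 551},
        ])
        core = select_core_dmr(candidates, beta, pathology)
        assert len(core) == 1 and core.iloc[0]["start"] == 100

    def test_single_class_labels_error(self):
        beta, labels = _beta_frame(np.full((3, 4), 0.5), np.full((3, 4), 0.5))
        pathology = pd.Series("HG", index=labels.index)
        with pytest.raises(ValueError):
            select_core_dmr(pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1}]),
                            beta, pathology)


class TestDiscoveryPipeline:
    def test_planted_dmrs_recovered_with_stage_monotonicity(self):
        beta, labels, truth, peaks = simulate_beta_matrix(
            10, 120, [(30, 40), (80, 90)], effect=0.3, seed=11, decoy_peaks=0)
        disc = DMRDiscovery(n_perm=300, random_state=11)
        disc.fit(beta, labels, pathology=labels, peaks=peaks)
        # every planted DMR overlapped by a filtered candidate
        for t in truth.itertuples():
            hit = ((disc.filtered_candidates_["start"] < t.end)
                   & (disc.filtered_candidates_["end"] > t.start)).any()
            assert hit
        # stage monotonicity: filtered subset of candidates subset of segments
        assert len(disc.filtered_candidates_) <= len(disc.candidates_)
        assert len(disc.candidates_) <= len(disc.segments_)
        assert len(disc.seed_dmrs_) <= len(disc.initial_dmrs_)
        # candidates stay concentrated on planted signal
        overlap = 0
        for c in disc.filtered_candidates_.itertuples():
            overlap += ((truth["start"] < c.end) & (truth["end"] > c.start)).any()
        assert overlap / max(1, len(disc.filtered_candidates_)) >= 0.95
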