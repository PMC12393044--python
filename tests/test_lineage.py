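"""Trajectory filtering, clone clustering, nesting, Muller export, coverage."""

import numpy as np
import pandas as pd
import pytest

from evoland.lineage import (
    CloneLineageInference,
    cluster_into_clones,
    detect_amplification,
    filter_trajectories,
    infer_nesting,
    muller_matrix,
)
from evoland.simulate import default_lineage_config, simulate_serial_passage

GENS = [18.0, 27.0, 31.0, 38.0]


def _table(rows: dict[str, list[float]], genes: dict[str, str] | None = None):
    genes = genes or {}
    return pd.DataFrame(
        [
            {
                "mutation_id": mid,
                "gene": genes.get(mid, mid),
                "position": i + 1,
                **dict(zip(GENS, freqs)),
            }
            for i, (mid, freqs) in enumerate(rows.items())
        ]
    )


class TestFilterTrajectories:
    def test_single_timepoint_low_frequency_dropped(self):
        table = _table({"m1": [0.0, 0.05, 0.0, 0.0]})
        kept, audit = filter_trajectories(table)
        assert kept.empty
        assert audit.loc[0, "rule"] == "dropped"

    def test_two_consecutive_above_threshold_kept(self):
        table = _table({"m1": [0.12, 0.12, 0.0, 0.0]})
        kept, audit = filter_trajectories(table)
        assert list(kept["mutation_id"]) == ["m1"]
        assert audit.loc[0, "rule"] == "direct"

    def test_low_frequency_mutation_rescued_by_gene(self):
        table = _table(
            {"m1": [0.12, 0.2, 0.3, 0.4], "m2": [0.0, 0.04, 0.0, 0.0]},
            genes={"m1": "gapA", "m2": "gapA"},
        )
        kept, audit = filter_trajectories(table)
        assert set(kept["mutation_id"]) == {"m1", "m2"}
        assert audit.set_index("mutation_id").loc["m2", "rule"] == "gene-rescue"

    def test_or_predicate_keeps_either_condition(self):
        table = _table({"m1": [0.0, 0.3, 0.0, 0.0], "m2": [0.02, 0.03, 0.0, 0.0]})
        kept_and, _ = filter_trajectories(table, predicate="and")
        kept_or, _ = filter_trajectories(table, predicate="or")
        assert kept_and.empty  # m1 seen once only; m2 never above 10%
        assert list(kept_or["mutation_id"]) == ["m1", "m2"]

    def test_filtering_is_idempotent(self):
        table = _table(
            {
                "m1": [0.12, 0.2, 0.3, 0.4],
                "m2": [0.0, 0.04, 0.0, 0.0],
                "m3": [0.0, 0.05, 0.0, 0.0],
            },
            genes={"m1": "gapA", "m2": "gapA", "m3": "pykF"},
        )
        once, _ = filter_trajectories(table)
        twice, _ = filter_trajectories(once)
        pd.testing.assert_frame_equal(once, twice)


class TestClustering:
    def test_identical_trajectories_merge_into_one_clone(self):
        table = _table({"m1": [0.0, 0.2, 0.5, 0.8], "m2": [0.0, 0.2, 0.5, 0.8]})
        labels, _ = cluster_into_clones(table)
        assert labels[0] == labels[1]

    def test_anticorrelated_trajectories_stay_separate(self):
        table = _table({"m1": [0.0, 0.5, 0.9, 0.9], "m2": [0.9, 0.5, 0.0, 0.0]})
        labels, _ = cluster_into_clones(table)
        assert labels[0] != labels[1]

    def test_correlated_but_offset_trajectories_stay_separate(self):
        # nested parent/child co-move but are vertically offset beyond max_gap
        table = _table({"m1": [0.3, 0.5, 0.7, 0.9], "m2": [0.0, 0.1, 0.3, 0.5]})
        labels, _ = cluster_into_clones(table)
        assert labels[0] != labels[1]

    def test_all_zero_trajectory_becomes_singleton_with_warning(self):
        table = _table({"m1": [0.0, 0.2, 0.5, 0.8], "m2": [0.0, 0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning, match="singleton"):
            labels, _ = cluster_into_clones(table)
        assert labels[0] != labels[1]


class TestNesting:
    def test_contained_trajectory_nested_under_parent(self):
        ab = {"A": np.array([0.2, 0.6, 0.9]), "B": np.array([0.0, 0.3, 0.85])}
        forest = infer_nesting(ab, [1, 2, 3])
        assert forest.clones["B"].parent == "A"
        assert forest.clones["A"].parent is None

    def test_two_large_clones_cannot_coexist(self):
        ab = {"A": np.array([0.1, 0.6, 0.2]), "B": np.array([0.2, 0.6, 0.1])}
        with pytest.raises(ValueError, match="conflicting|consistent"):
            infer_nesting(ab, [1, 2, 3])

    def test_single_clone_is_root_with_ancestor_residual(self):
        ab = {"A": np.array([0.1, 0.4, 0.7])}
        forest = infer_nesting(ab, [1, 2, 3])
        assert forest.roots() == ["A"]
        assert np.allclose(forest.ancestor_residual(), [0.9, 0.6, 0.3])

    def test_nesting_is_acyclic_with_unique_parents(self):
        cfg = default_lineage_config(seed=11, measurement_noise_sd=0.0)
        table, _ = simulate_serial_passage(cfg)
        model = CloneLineageInference().fit(table)
        forest = model.forest_
        for cid in forest.clones:
            seen = set()
            node = cid
            while node is not None:
                assert node not in seen  # no cycles
                seen.add(node)
                node = forest.clones[node].parent


class TestMullerMatrix:
    def test_single_sweep_gives_two_complementary_bands(self):
        ab = {"A": np.array([0.0, 0.5, 1.0])}
        forest = infer_nesting(ab, [0.0, 10.0, 20.0])
        mat = muller_matrix(forest, interpolation_points=21)
        assert list(mat.index) == ["ancestor", "A"]
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)
        assert mat.loc["A"].iloc[-1] == pytest.approx(1.0)

    def test_child_band_carved_out_of_parent(self):
        ab = {"A": np.array([0.2, 0.8, 0.9]), "B": np.array([0.0, 0.3, 0.6])}
        forest = infer_nesting(ab, [1.0, 2.0, 3.0])
        mat = muller_matrix(forest, interpolation_points=3)
        own = mat.loc["A"].iloc[-1]
        assert own == pytest.approx(0.9 - 0.6)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)

    def test_round_trip_matches_truth_derived_matrix(self):
        cfg = default_lineage_config(seed=2, measurement_noise_sd=0.0)
        table, truth = simulate_serial_passage(cfg)
        model = CloneLineageInference().fit(table)
        inferred = model.muller_
        truth_mat = muller_matrix(truth, interpolation_points=inferred.shape[1])
        assert np.allclose(inferred.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(truth_mat.sum(axis=0), 1.0, atol=1e-9)
        # align inferred bands with truth clones by their member mutations
        truth_by_members = {
            tuple(sorted(clone.mutations)): cid
            for cid, clone in truth.clones.items()
        }
        assert np.allclose(
            inferred.loc["ancestor"], truth_mat.loc["ancestor"], atol=0.02
        )
        for cid, clone in model.forest_.clones.items():
            tid = truth_by_members[tuple(sorted(clone.mutations))]
            assert np.allclose(
                inferred.loc[cid], truth_mat.loc[tid], atol=0.02
            ), (cid, tid)


class TestCoverage:
    @staticmethod
    def _track(depths, win=10_000):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(depths)) * win,
                "end": (np.arange(len(depths)) + 1) * win,
                "depth": depths,
            }
        )

    def test_large_amplification_found_with_correct_ratio_and_span(self):
        depths = [100.0] * 120
        depths[40:61] = [300.0] * 21  # ~206 kb above a 100x baseline
        out = detect_amplification(
            self._track(depths, win=9_810), ratio_threshold=1.5, min_length_bp=50_000
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert row["copy_ratio"] == pytest.approx(3.0)
        assert row["end"] - row["start"] == pytest.approx(206_010, abs=1)

    def test_uniform_coverage_yields_no_intervals(self):
        out = detect_amplification(self._track([80.0] * 50))
        assert out.empty

    def test_short_amplification_filtered_by_min_length(self):
        depths = [100.0] * 60
        depths[10:12] = [400.0, 400.0]
        out = detect_amplification(self._track(depths), min_length_bp=50_000)
        assert out.empty

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="median"):
            detect_amplification(self._track([0.0] * 30))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="20"):
            detect_amplification(self._track([100.0] * 10))
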