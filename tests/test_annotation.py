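"""Consensus annotation: argmax labels, over-clustering, MACA mapping,
certainty scores and unassigned flagging."""

import numpy as np
import pytest

from masi import (
    AnnotationConfig,
    CellTypeScoreMatrix,
    CentroidSet,
    ExpressionMatrix,
    MarkerTable,
    annotate,
    annotate_parallel,
    apply_unassigned,
    certainty_score,
    compute_centroids,
    label1_argmax,
    maca_consensus,
    overcluster,
)
from masi.annotation import AnnotationResult, ClusteringEnsemble
from masi.marker_discovery import assign_weights


def _scores(arr, types=None):
    arr = np.asarray(arr, dtype=float)
    types = types or [f"T{j}" for j in range(arr.shape[1])]
    return CellTypeScoreMatrix(arr, [f"c{i}" for i in range(arr.shape[0])], types)


class TestLabel1:
    def test_argmax_and_ties(self):
        scores = _scores([[3, 1], [2, 2], [0, 0]], types=["A", "B"])
        labels, ties = label1_argmax(scores)
        assert list(labels) == ["A", "A", "A"]  # ties -> first column
        assert list(ties) == [False, True, True]


def _blob_scores(rng, n_per=40):
    a = rng.normal([10, 0], 0.1, (n_per, 2)).clip(min=0)
    b = rng.normal([0, 10], 0.1, (n_per, 2)).clip(min=0)
    return _scores(np.vstack([a, b]), types=["A", "B"])


class TestOvercluster:
    def test_default_grid_yields_nine_full_partitions(self):
        rng = np.random.default_rng(0)
        scores = _blob_scores(rng)
        ens = overcluster(scores, seed=0)
        assert ens.n_runs == 9
        for _, _, part in ens.runs:
            assert len(part) == scores.n_cells

    def test_separated_blobs_never_merge(self):
        rng = np.random.default_rng(1)
        scores = _blob_scores(rng)
        truth = np.array([0] * 40 + [1] * 40)
        ens = overcluster(scores, seed=0)
        for _, _, part in ens.runs:
            for c in np.unique(part):
                assert len(np.unique(truth[part == c])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        scores = _blob_scores(rng)
        a = overcluster(scores, seed=5)
        b = overcluster(scores, seed=5)
        for (_, _, pa), (_, _, pb) in zip(a.runs, b.runs):
            np.testing.assert_array_equal(pa, pb)

    def test_too_few_cells_rejected(self):
        scores = _scores(np.ones((5, 2)))
        with pytest.raises(ValueError, match="at least"):
            overcluster(scores, n_neighbors=[15], seed=0)


def _brute_force_consensus(label1, runs, scores):
    """Independent majority-vote + mode oracle (plain Python loops)."""
    n = len(label1)
    types = list(scores.cell_type_names)
    mapped_all = []
    for part in runs:
        mapped = [None] * n
        for c in set(part):
            members = [i for i in range(n) if part[i] == c]
            counts = {}
            for i in members:
                counts[label1[i]] = counts.get(label1[i], 0) + 1
            top = max(counts.values())
            cands = sorted(t for t, v in counts.items() if v == top)
            if len(cands) > 1:
                means = {
                    t: np.mean([scores.scores[i, types.index(t)] for i in members])
                    for t in cands
                }
                cands = [max(cands, key=lambda t: means[t])]
            for i in members:
                mapped[i] = cands[0]
        mapped_all.append(mapped)
    final = []
    for i in range(n):
        votes = {}
        for mapped in mapped_all:
            votes[mapped[i]] = votes.get(mapped[i], 0) + 1
        top = max(votes.values())
        cands = sorted(t for t, v in votes.items() if v == top)
        if len(cands) > 1:
            cands = [max(cands, key=lambda t: scores.scores[i, types.index(t)])]
        final.append(cands[0])
    return final


class TestMacaConsensus:
    def test_hand_example(self):
        label1 = np.array(["A", "A", "B", "B", "B", "B"], dtype=object)
        scores = _scores(np.eye(2)[[0, 0, 1, 1, 1, 1]], types=["A", "B"])
        ens = ClusteringEnsemble(runs=[(3.0, 5, np.array([0, 0, 0, 1, 1, 1]))])
        final, mapped = maca_consensus(label1, ens, scores)
        assert list(final) == ["A", "A", "A", "B", "B", "B"]
        assert mapped.shape == (6, 1)

    def test_single_run_equals_mapping(self):
        rng = np.random.default_rng(3)
        scores = _scores(rng.random((20, 3)))
        label1, _ = label1_argmax(scores)
        part = rng.integers(0, 4, 20)
        ens = ClusteringEnsemble(runs=[(3.0, 5, part)])
        final, mapped = maca_consensus(label1, ens, scores)
        np.testing.assert_array_equal(final, mapped[:, 0])

    def test_identical_runs_are_idempotent(self):
        rng = np.random.default_rng(4)
        scores = _scores(rng.random((15, 2)))
        label1, _ = label1_argmax(scores)
        part = rng.integers(0, 3, 15)
        one = maca_consensus(label1, ClusteringEnsemble(runs=[(3.0, 5, part)]), scores)[0]
        three = maca_consensus(
            label1, ClusteringEnsemble(runs=[(3.0, 5, part)] * 3), scores
        )[0]
        np.testing.assert_array_equal(one, three)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = _scores(rng.random((n, 3)))
        label1, _ = label1_argmax(scores)
        runs = [rng.integers(0, rng.integers(2, 6), n) for _ in range(3)]
        ens = ClusteringEnsemble(runs=[(3.0, 5, p) for p in runs])
        final, _ = maca_consensus(label1, ens, scores)
        oracle = _brute_force_consensus(list(label1), [list(p) for p in runs], scores)
        assert list(final) == oracle


class TestCertainty:
    def _centroids(self):
        return CentroidSet(np.array([[0.0, 0.0], [4.0, 0.0]]), ["A", "B"])

    def test_at_centroid(self):
        assert certainty_score(np.array([0.0, 0.0]), self._centroids()) == pytest.approx(1.0)

    def test_equidistant(self):
        assert certainty_score(np.array([2.0, 0.0]), self._centroids()) == pytest.approx(0.0)

    def test_ratio(self):
        cents = CentroidSet(np.array([[1.0, 0.0], [-4.0, 0.0]]), ["A", "B"])
        # D_1st = 1, D_Nth = 4 -> C = 0.75
        assert certainty_score(np.array([0.0, 0.0]), cents) == pytest.approx(0.75)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        cents = rng.random((3, 4))
        cell = rng.random(4)
        shift = rng.random(4)
        a = certainty_score(cell, CentroidSet(cents, ["A", "B", "C"]))
        b = certainty_score(cell + shift, CentroidSet(cents + shift, ["A", "B", "C"]))
        assert a == pytest.approx(b, rel=1e-10)

    def test_needs_two_centroids(self):
        with pytest.raises(ValueError, match="2 centroids"):
            certainty_score(np.zeros(2), CentroidSet(np.zeros((1, 2)), ["A"]))

    def test_compute_centroids_grouping(self):
        scores = _scores([[1, 0], [3, 0], [0, 2]], types=["A", "B"])
        cents = compute_centroids(scores, ["A", "A", "B"])
        np.testing.assert_allclose(cents.centroids, [[2, 0], [0, 2]])


class TestApplyUnassigned:
    def _result(self):
        return AnnotationResult(
            cell_ids=["c1", "c2", "c3"],
            labels=["A", "B", "A"],
            certainty=[0.7, 0.3, 0.55],
        )

    def test_threshold_band(self):
        out = apply_unassigned(self._result(), 0.55)
        assert list(out.labels) == ["A", "unassigned", "A"]

    def test_zero_threshold_keeps_everything(self):
        out = apply_unassigned(self._result(), 0.0)
        assert "unassigned" not in out.labels

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            apply_unassigned(self._result(), 1.5)

    def test_requires_certainty(self):
        res = AnnotationResult(cell_ids=["c1"], labels=["A"])
        with pytest.raises(ValueError, match="certainty"):
            apply_unassigned(res, 0.5)


def _tiny_dataset(seed=0, n_per=30):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(0.5, (3 * n_per, 60))
    for t in range(3):
        counts[t * n_per : (t + 1) * n_per, 10 * t : 10 * t + 10] += rng.poisson(
            2.0, (n_per, 10)
        )
    counts[:, 0] += 1  # no zero-total cells
    expr = ExpressionMatrix(
        counts.astype(float),
        [f"c{i:03d}" for i in range(3 * n_per)],
        [f"g{j:03d}" for j in range(60)],
    )
    table = assign_weights(
        MarkerTable(
            genes={f"T{t}": [f"g{10*t+k:03d}" for k in range(10)] for t in range(3)}
        )
    )
    truth = np.repeat([f"T{t}" for t in range(3)], n_per)
    return expr, table, truth


class TestAnnotateEndToEnd:
    def test_counts_are_auto_normalized_and_types_recovered(self):
        expr, table, truth = _tiny_dataset()
        res = annotate(expr, table)
        assert np.mean(res.labels == truth) > 0.9

    def test_invariant_to_cell_permutation(self):
        expr, table, _ = _tiny_dataset()
        res = annotate(expr, table)
        rng = np.random.default_rng(8)
        perm = rng.permutation(expr.n_cells)
        permuted = expr.subset_cells(perm)
        res_p = annotate(permuted, table)
        by_id = dict(zip(res.cell_ids, res.labels))
        assert all(by_id[c] == l for c, l in zip(res_p.cell_ids, res_p.labels))

    def test_empty_marker_intersection_is_error(self):
        expr, _, _ = _tiny_dataset()
        bad = assign_weights(MarkerTable(genes={"A": ["nope1"], "B": ["nope2"]}))
        with pytest.raises(ValueError, match="marker"):
            annotate(expr, bad)

    def test_parallel_single_batch_identical_to_serial(self):
        expr, table, _ = _tiny_dataset()
        serial = annotate(expr, table)
        par = annotate_parallel(expr, table, n_batches=1)
        np.testing.assert_array_equal(serial.labels, par.labels)
        np.testing.assert_array_equal(serial.mapped_labels, par.mapped_labels)

    def test_parallel_preserves_cell_order(self):
        expr, table, _ = _tiny_dataset()
        for nb in (1, 3):
            res = annotate_parallel(expr, table, n_batches=nb)
            assert list(res.cell_ids) == list(expr.cell_ids)

    def test_too_many_batches_rejected(self):
        expr, table, _ = _tiny_dataset()
        with pytest.raises(ValueError, match="n_batches"):
            annotate_parallel(expr, table, n_batches=expr.n_cells + 1)

    def test_certainty_attached_with_centroids(self):
        expr, table, truth = _tiny_dataset()
        from masi import log_normalize, score_cells

        scores = score_cells(log_normalize(expr), table)
        cents = compute_centroids(scores, truth)
        res = annotate(expr, table, centroids=cents)
        assert res.certainty is not None
        assert res.certainty.min() >= 0 and res.certainty.max() <= 1


class TestConsensusVsLabel1:
    def test_consensus_tracks_label1_on_fixture(
        self, sim_default, scores_default, annotation_default
    ):
        """Cluster smoothing must not materially degrade the per-cell labels."""
        _, truth = sim_default
        l1, _ = label1_argmax(scores_default)
        acc_l1 = np.mean(l1 == truth.cell_types)
        acc_cons = np.mean(annotation_default.labels == truth.cell_types)
        assert acc_cons >= acc_l1 - 0.02
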