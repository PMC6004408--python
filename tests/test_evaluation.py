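"""Benchmarking protocol: folds, metrics, CV driver, KS comparison,
nearest-neighbor analysis and the applicability-domain curve."""

import numpy as np
import pandas as pd
import pytest

from moapred.dataset import TargetDataset
from moapred.evaluation import (
    ad_curve,
    compute_metrics,
    crossvalidate,
    ks_compare,
    nn_similarity_analysis,
    stratified_kfold_split,
    temporal_validate,
)
from moapred.architectures import train_stage1, train_stage2_arch2
from conftest import make_fp


def _functional_dataset(n_act, n_inh, n_bind=0, n_inact=0, seed=0):
    rng = np.random.default_rng(seed)

    def rows(n, lo):
        out = np.zeros((n, 2048), dtype=np.uint8)
        for r in range(n):
            out[r, rng.choice(np.arange(lo, lo + 200), 80, replace=False)] = 1
        return out if n else None

    return TargetDataset(
        target_id="T",
        protein_class="GPCR",
        activating_ids=[f"a{i}" for i in range(n_act)],
        inhibiting_ids=[f"i{i}" for i in range(n_inh)],
        binding_ids=[f"b{i}" for i in range(n_bind)],
        inactive_ids=[f"n{i}" for i in range(n_inact)],
        activating_fp=rows(n_act, 0),
        inhibiting_fp=rows(n_inh, 400),
        binding_fp=rows(n_bind, 800),
        inactive_fp=rows(n_inact, 1400),
        inactive_provenance=["experimental"] * n_inact,
    )


class TestStratifiedFolds:
    def test_exact_divisibility_gives_exact_per_fold_counts(self):
        ds = _functional_dataset(50, 250)
        folds = stratified_kfold_split(ds, k=5, seed=0)
        for f in folds:
            assert len(f.test["activating"]) == 10
            assert len(f.test["inhibiting"]) == 50

    def test_test_folds_partition_functional_sets(self):
        ds = _functional_dataset(23, 41, n_bind=7, n_inact=30)
        folds = stratified_kfold_split(ds, k=5, seed=1)
        for name, total in (("activating", 23), ("inhibiting", 41), ("inactive", 30)):
            seen = np.concatenate([f.test[name] for f in folds])
            assert sorted(seen) == list(range(total))  # full cover, no overlap

    def test_binding_never_in_test(self):
        ds = _functional_dataset(20, 20, n_bind=10, n_inact=20)
        folds = stratified_kfold_split(ds, k=5, seed=2)
        assert all(len(f.test["binding"]) == 0 for f in folds)
        # but partitioned across training portions
        train_counts = [len(f.train["binding"]) for f in folds]
        assert all(c >= 6 for c in train_counts)

    def test_stratification_within_rounding(self):
        ds = _functional_dataset(11, 23)
        folds = stratified_kfold_split(ds, k=5, seed=3)
        for f in folds:
            assert abs(len(f.test["activating"]) - 11 / 5) < 1
            assert abs(len(f.test["inhibiting"]) - 23 / 5) < 1

    def test_class_smaller_than_k_is_an_error(self):
        ds = _functional_dataset(4, 23)
        with pytest.raises(ValueError, match="activating"):
            stratified_kfold_split(ds, k=5, seed=0)

    def test_k_below_two_is_an_error(self):
        ds = _functional_dataset(10, 10)
        with pytest.raises(ValueError):
            stratified_kfold_split(ds, k=1, seed=0)


def _pred_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["compound_id", "target_id", "protein_class", "true_label", "pred_label"],
    )


class TestComputeMetrics:
    def test_all_correct_gives_ones(self):
        rows = [(f"c{i}", "T", "GPCR", "activating", "activating") for i in range(5)]
        rows += [(f"d{i}", "T", "GPCR", "inactive", "inactive") for i in range(5)]
        rep = compute_metrics(_pred_frame(rows))
        assert rep.target_avg == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_closed_form_confusion(self):
        # activating: TP=8, FP=2, FN=2 → P=R=F1=0.8
        rows = [(f"tp{i}", "T", "GPCR", "activating", "activating") for i in range(8)]
        rows += [(f"fp{i}", "T", "GPCR", "inhibiting", "activating") for i in range(2)]
        rows += [(f"fn{i}", "T", "GPCR", "activating", "inhibiting") for i in range(2)]
        rows += [(f"tn{i}", "T", "GPCR", "inhibiting", "inhibiting") for i in range(8)]
        rep = compute_metrics(_pred_frame(rows))
        act = rep.per_target[rep.per_target["label"] == "activating"].iloc[0]
        assert act["precision"] == pytest.approx(0.8)
        assert act["recall"] == pytest.approx(0.8)
        assert act["f1"] == pytest.approx(0.8)

    def test_matches_manual_confusion_matrices_on_toy_set(self):
        rng = np.random.default_rng(5)
        labels = ["inactive", "activating", "inhibiting"]
        rows = [
            (f"c{i}", "T", "NHR", rng.choice(labels), rng.choice(labels)) for i in range(30)
        ]
        rep = compute_metrics(_pred_frame(rows))
        df = _pred_frame(rows)
        for label in labels:
            tp = ((df.true_label == label) & (df.pred_label == label)).sum()
            fp = ((df.true_label != label) & (df.pred_label == label)).sum()
            fn = ((df.true_label == label) & (df.pred_label != label)).sum()
            if (df.true_label == label).sum() == 0:
                continue
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            cell = rep.per_target[rep.per_target["label"] == label].iloc[0]
            assert cell["precision"] == pytest.approx(p)
            assert cell["recall"] == pytest.approx(r)

    def test_f1_identity_on_every_cell(self):
        rng = np.random.default_rng(9)
        labels = ["inactive", "activating", "inhibiting"]
        rows = [
            (f"c{i}", f"T{i % 3}", "GPCR", rng.choice(labels), rng.choice(labels))
            for i in range(60)
        ]
        rep = compute_metrics(_pred_frame(rows))
        for _, cell in rep.per_target.iterrows():
            p, r = cell["precision"], cell["recall"]
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert cell["f1"] == pytest.approx(expected)
            assert 0.0 <= cell["f1"] <= 1.0

    def test_present_label_with_no_predictions_scores_zero(self):
        rows = [(f"c{i}", "T", "GPCR", "activating", "inhibiting") for i in range(4)]
        rows += [(f"d{i}", "T", "GPCR", "inhibiting", "inhibiting") for i in range(4)]
        rep = compute_metrics(_pred_frame(rows))
        act = rep.per_target[rep.per_target["label"] == "activating"].iloc[0]
        assert act["precision"] == 0.0 and act["recall"] == 0.0

    def test_conditional_report_restricted_to_gate_passers(self):
        df = _pred_frame(
            [
                ("a", "T", "GPCR", "activating", "activating"),
                ("b", "T", "GPCR", "activating", "inactive"),  # gate rejected
                ("c", "T", "GPCR", "inhibiting", "inhibiting"),
            ]
        )
        df["p_bind"] = [0.9, 0.2, 0.8]
        rep = compute_metrics(df)
        assert rep.conditional is not None
        assert rep.conditional.n_predictions == 2  # only gate passers
        assert rep.conditional.target_avg["recall"] == pytest.approx(1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics(pd.DataFrame())


class TestKSCompare:
    def test_identical_samples_statistic_zero(self):
        x = [0.1, 0.5, 0.9]
        stat, _ = ks_compare(x, x)
        assert stat == pytest.approx(0.0)

    def test_disjoint_supports_statistic_one(self):
        stat, p = ks_compare([0.1] * 20, [0.9] * 20)
        assert stat == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_ecdf_max_gap_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random(20)
        b = rng.random(20) ** 2
        stat, _ = ks_compare(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= g).mean() for g in grid])
        ecdf_b = np.array([(b <= g).mean() for g in grid])
        assert stat == pytest.approx(np.abs(ecdf_a - ecdf_b).max())

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ks_compare([], [0.5])


class TestNNSimilarityAnalysis:
    def test_subset_gives_unit_similarity(self):
        inh = np.vstack([make_fp(range(10 * i, 10 * i + 8)) for i in range(6)])
        ds = TargetDataset(
            target_id="T",
            protein_class="GPCR",
            activating_ids=["a0", "a1"],
            inhibiting_ids=[f"i{j}" for j in range(6)],
            activating_fp=inh[:2].copy(),  # activating ⊆ inhibiting
            inhibiting_fp=inh,
        )
        res = nn_similarity_analysis(ds)
        assert np.allclose(res["A-I"]["similarities"], 1.0)

    def test_orthogonal_sets_give_zero(self):
        ds = TargetDataset(
            target_id="T",
            protein_class="GPCR",
            activating_ids=["a0"],
            inhibiting_ids=["i0"],
            activating_fp=make_fp(range(10))[None, :],
            inhibiting_fp=make_fp(range(100, 110))[None, :],
        )
        res = nn_similarity_analysis(ds)
        assert res["A-I"]["median"] == 0.0

    def test_medians_match_exhaustive_row_max(self):
        rng = np.random.default_rng(3)
        A = (rng.random((5, 256)) < 0.3).astype(np.uint8)
        I = (rng.random((5, 256)) < 0.3).astype(np.uint8)
        B = (rng.random((5, 256)) < 0.3).astype(np.uint8)
        ds = TargetDataset(
            target_id="T",
            protein_class="GPCR",
            activating_ids=[f"a{j}" for j in range(5)],
            inhibiting_ids=[f"i{j}" for j in range(5)],
            binding_ids=[f"b{j}" for j in range(5)],
            activating_fp=A,
            inhibiting_fp=I,
            binding_fp=B,
        )
        from moapred.compounds import tanimoto

        res = nn_similarity_analysis(ds)
        for name, (X, Y) in {"A-I": (A, I), "B-A": (B, A), "B-I": (B, I)}.items():
            expected = [max(tanimoto(x, y) for y in Y) for x in X]
            assert res[name]["median"] == pytest.approx(float(np.median(expected)))

    def test_empty_pairing_skipped_with_warning(self):
        ds = TargetDataset(
            target_id="T",
            protein_class="GPCR",
            activating_ids=["a0"],
            inhibiting_ids=["i0"],
            activating_fp=make_fp(range(5))[None, :],
            inhibiting_fp=make_fp(range(5, 10))[None, :],
        )
        with pytest.warns(UserWarning):
            res = nn_similarity_analysis(ds)
        assert "B-A" not in res and "B-I" not in res


class TestADCurve:
    def _setup(self, sims, correct):
        """Test compounds with exact k=1 NN similarities to a single training
        fingerprint (bits shared out of 100 → Tc = shared/100)."""
        train = {"activating": make_fp(range(100))[None, :], "inhibiting": make_fp(range(200, 300))[None, :]}
        fps, true, pred = [], [], []
        for s, c in zip(sims, correct):
            shared = int(round(s * 100))
            fps.append(make_fp(range(shared)))  # subset of the activating train fp
            true.append("activating")
            pred.append("activating" if c else "inhibiting")
        return train, np.vstack(fps), np.array(true, dtype=object), np.array(pred, dtype=object)

    def test_hand_binned_example(self):
        # 12 compounds, similarities chosen to land in known 0.05-wide bins
        sims = [0.82, 0.84, 0.82, 0.67, 0.66, 0.68, 0.52, 0.53, 0.51, 0.33, 0.32, 0.31]
        correct = [1, 1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0]
        train, fps, true, pred = self._setup(sims, correct)
        with pytest.warns(UserWarning):  # k=5 exceeds the 1-member training set
            curve = ad_curve(train, fps, true, pred, k=5)
        frame = curve.as_frame().dropna()
        by_bin = {(round(r.bin_low, 2)): r.tpr for r in frame.itertuples()}
        assert by_bin[0.80] == pytest.approx(2 / 3)
        assert by_bin[0.65] == pytest.approx(1 / 3)
        assert by_bin[0.50] == pytest.approx(1 / 3)
        assert by_bin[0.30] == pytest.approx(0.0)
        # hand trapezoid over distance = 1 - bin centers
        x = 1 - np.array([0.825, 0.675, 0.525, 0.325])
        y = np.array([2 / 3, 1 / 3, 1 / 3, 0.0])
        order = np.argsort(x)
        assert curve.ad_auc == pytest.approx(np.trapezoid(y[order], x[order]))

    def test_all_correct_gives_unit_tpr_and_span_area(self):
        sims = [0.82, 0.62, 0.42, 0.22]
        train, fps, true, pred = self._setup(sims, [1, 1, 1, 1])
        with pytest.warns(UserWarning):
            curve = ad_curve(train, fps, true, pred, k=5)
        populated = curve.support > 0
        assert np.allclose(curve.tpr[populated], 1.0)
        centers = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2
        span = centers[populated].max() - centers[populated].min()
        assert curve.ad_auc == pytest.approx(span)

    def test_all_wrong_gives_zero_auc(self):
        sims = [0.82, 0.62, 0.42, 0.22]
        train, fps, true, pred = self._setup(sims, [0, 0, 0, 0])
        with pytest.warns(UserWarning):
            curve = ad_curve(train, fps, true, pred, k=5)
        assert curve.ad_auc == 0.0

    def test_no_functional_truth_is_an_error(self):
        train = {"activating": make_fp(range(10))[None, :]}
        with pytest.raises(ValueError):
            ad_curve(train, make_fp(range(5))[None, :], ["inactive"], ["inactive"], k=1)


class TestCrossValidate:
    def test_reports_are_deterministic(self, separable_universe):
        datasets, _ = separable_universe
        r1 = crossvalidate("arch1", datasets, k=5, seed=3)
        r2 = crossvalidate("arch1", datasets, k=5, seed=3)
        assert r1.theta == r2.theta
        assert r1.pooled.class_avg == r2.pooled.class_avg
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_fold_count_one_is_an_error(self, separable_universe):
        datasets, _ = separable_universe
        with pytest.raises(ValueError):
            crossvalidate("arch1", datasets, k=1, seed=0)

    def test_unknown_architecture_is_an_error(self, separable_universe):
        datasets, _ = separable_universe
        with pytest.raises(ValueError):
            crossvalidate("arch9", datasets, k=5, seed=0)

    def test_arch1_separable_class_avg_f1(self, separable_universe):
        datasets, _ = separable_universe
        rep = crossvalidate("arch1", datasets, k=5, seed=3)
        assert rep.pooled.class_avg["f1"] >= 0.9
        assert rep.theta is not None


class TestTemporalValidate:
    def _trained(self, ds, seed=0):
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            return {ds.target_id: (train_stage1(ds, seed=seed), train_stage2_arch2(ds, seed=seed))}

    def test_leaked_compound_id_is_an_error(self, toy_dataset):
        trained = self._trained(toy_dataset)
        batch = pd.DataFrame(
            {
                "compound_id": ["a0"],  # present in training
                "target_id": ["TOY"],
                "protein_class": ["GPCR"],
                "true_label": ["activating"],
            }
        )
        with pytest.raises(ValueError, match="leak"):
            temporal_validate(
                "arch2", trained, batch, toy_dataset.activating_fp[:1], {"a0"}
            )

    def test_same_distribution_batch_scores_high(self, toy_dataset):
        trained = self._trained(toy_dataset)
        rng = np.random.default_rng(1)
        fps, labels = [], []
        for lab, lo in (("activating", 0), ("inhibiting", 200)):
            for _ in range(8):
                fp = np.zeros(2048, dtype=np.uint8)
                fp[rng.choice(np.arange(lo, lo + 120), 60, replace=False)] = 1
                fps.append(fp)
                labels.append(lab)
        batch = pd.DataFrame(
            {
                "compound_id": [f"new{i}" for i in range(16)],
                "target_id": ["TOY"] * 16,
                "protein_class": ["GPCR"] * 16,
                "true_label": labels,
            }
        )
        rep = temporal_validate("arch2", trained, batch, np.vstack(fps), {"a0", "i0"})
        assert rep.class_avg["f1"] >= 0.9
        assert rep.conditional is not None
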