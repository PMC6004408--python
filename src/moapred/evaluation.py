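"""Benchmarking protocol: stratified five-fold cross-validation, temporal
validation, per-label/target/protein-class metric aggregation, conditional
Stage-1-correct metrics, Kolmogorov–Smirnov architecture comparison,
nearest-neighbor chemical-space analysis and the distance-based applicability
domain (AD) curve with its AD-AUC summary.

The common currency is a *predictions frame* with one row per evaluated
compound–target pair and columns::

    compound_id, target_id, protein_class, true_label, pred_label,
    p_bind (NaN for the single-model architecture), fold (optional)

``true_label``/``pred_label`` take values in {inactive, activating,
inhibiting}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import architectures as arch
from .architectures import (
    ACTIVATING,
    INACTIVE,
    INHIBITING,
    PREDICTION_LABELS,
    Arch1Model,
    arch1_decide,
    arch1_scores,
    cascade_predict,
    optimize_arch1_threshold,
    train_arch1,
    train_stage1,
    train_stage2_arch2,
    train_stage2_arch3,
)
from .compounds import bulk_tanimoto, knn_mean_similarity_matrix
from .dataset import TargetDataset
from ._seeds import derive_seed

logger = logging.getLogger(__name__)

ARCHITECTURES = ("arch1", "arch2", "arch3")
SET_NAMES = ("activating", "inhibiting", "binding", "inactive")
_SET_TO_LABEL = {"activating": ACTIVATING, "inhibiting": INHIBITING, "inactive": INACTIVE}


# ---------------------------------------------------------------------------
# Cross-validation folds


@dataclass
class FoldSplit:
    """One CV fold: per-set index arrays into a TargetDataset's sets.

    Binding-only compounds appear in training portions only; a fold's binding
    test portion is deliberately unused (binding data supplements Stage 1
    training and carries no functional truth to score against).
    """

    fold: int
    train: dict[str, np.ndarray]
    test: dict[str, np.ndarray]


def _set_sizes(ds: TargetDataset) -> dict[str, int]:
    return {
        "activating": len(ds.activating_ids),
        "inhibiting": len(ds.inhibiting_ids),
        "binding": len(ds.binding_ids),
        "inactive": len(ds.inactive_ids),
    }


def stratified_kfold_split(ds: TargetDataset, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Partition a target's compound sets into k stratified folds.

    Stratification is over the four set labels, so label proportions per fold
    match the global ratio within rounding. Every non-empty set must have at
    least k members.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    sizes = _set_sizes(ds)
    for name, n in sizes.items():
        if 0 < n < k:
            raise ValueError(f"{ds.target_id}: set {name!r} has {n} < k={k} members")
    y, owner = [], []
    for name in SET_NAMES:
        for i in range(sizes[name]):
            y.append(name)
            owner.append((name, i))
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32 - 1))
    folds = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = {name: [] for name in SET_NAMES}
        test = {name: [] for name in SET_NAMES}
        for j in train_idx:
            name, i = owner[j]
            train[name].append(i)
        for j in test_idx:
            name, i = owner[j]
            test[name].append(i)
        test["binding"] = []  # train-only by protocol
        folds.append(
            FoldSplit(
                fold=f,
                train={n: np.asarray(v, dtype=int) for n, v in train.items()},
                test={n: np.asarray(v, dtype=int) for n, v in test.items()},
            )
        )
    return folds


def _subset_dataset(ds: TargetDataset, idx: dict[str, np.ndarray]) -> TargetDataset:
    def pick(ids, fp, sel):
        if len(sel) == 0:
            return [], None
        return [ids[i] for i in sel], np.atleast_2d(fp)[sel]

    act_ids, act_fp = pick(ds.activating_ids, ds.activating_fp, idx["activating"])
    inh_ids, inh_fp = pick(ds.inhibiting_ids, ds.inhibiting_fp, idx["inhibiting"])
    bind_ids, bind_fp = pick(ds.binding_ids, ds.binding_fp, idx["binding"])
    ina_ids, ina_fp = pick(ds.inactive_ids, ds.inactive_fp, idx["inactive"])
    sub = TargetDataset(
        target_id=ds.target_id,
        protein_class=ds.protein_class,
        activating_ids=act_ids,
        inhibiting_ids=inh_ids,
        binding_ids=bind_ids,
        inactive_ids=ina_ids,
        activating_fp=act_fp,
        inhibiting_fp=inh_fp,
        binding_fp=bind_fp,
        inactive_fp=ina_fp,
        inactive_provenance=[ds.inactive_provenance[i] for i in idx["inactive"]],
    )
    return sub


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """Per-target, target-averaged and protein-class-averaged precision /
    recall / F1, with an optional conditional variant restricted to Stage-1
    true positives."""

    per_target: pd.DataFrame  # target_id, protein_class, label, precision, recall, f1, support
    target_avg: dict[str, float]
    target_std: dict[str, float]
    class_avg: dict[str, float]
    class_std: dict[str, float]
    label_class_avg: dict[str, dict[str, float]]  # label -> metric -> value
    conditional: "MetricsReport | None" = None
    n_predictions: int = 0

    def summary(self) -> dict:
        out = {
            "target_avg": self.target_avg,
            "target_std": self.target_std,
            "class_avg": self.class_avg,
            "class_std": self.class_std,
            "label_class_avg": self.label_class_avg,
            "n_predictions": self.n_predictions,
        }
        if self.conditional is not None:
            out["conditional"] = {
                "class_avg": self.conditional.class_avg,
                "label_class_avg": self.conditional.label_class_avg,
            }
        return out


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _per_target_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (tid, pclass), grp in df.groupby(["target_id", "protein_class"], sort=True):
        truth = grp["true_label"].values
        pred = grp["pred_label"].values
        for label in PREDICTION_LABELS:
            support = int((truth == label).sum())
            n_pred = int((pred == label).sum())
            if support == 0 and n_pred == 0:
                continue  # label plays no role for this target
            tp = int(np.sum((pred == label) & (truth == label)))
            fp = int(np.sum((pred == label) & (truth != label)))
            fn = int(np.sum((pred != label) & (truth == label)))
            if support == 0:
                # predictions exist for a label absent from truth: precision
                # is informative, recall undefined → excluded from averages
                logger.debug("%s: label %s predicted but absent from truth", tid, label)
                continue
            if n_pred == 0:
                logger.debug("%s: no predictions for present label %s (scored 0)", tid, label)
            p, r, f1 = _prf(tp, fp, fn)
            rows.append(
                {
                    "target_id": tid,
                    "protein_class": pclass,
                    "label": label,
                    "precision": p,
                    "recall": r,
                    "f1": f1,
                    "support": support,
                }
            )
    return pd.DataFrame(rows)


def _aggregate(per_target: pd.DataFrame) -> tuple[dict, dict, dict, dict, dict]:
    metrics = ("precision", "recall", "f1")
    if per_target.empty:
        z = {m: 0.0 for m in metrics}
        return z, dict(z), dict(z), dict(z), {}
    per_target_macro = per_target.groupby(["target_id", "protein_class"])[list(metrics)].mean()
    target_avg = {m: float(per_target_macro[m].mean()) for m in metrics}
    target_std = {m: float(per_target_macro[m].std(ddof=0)) for m in metrics}
    per_class = per_target_macro.groupby("protein_class").mean()
    class_avg = {m: float(per_class[m].mean()) for m in metrics}
    class_std = {m: float(per_class[m].std(ddof=0)) for m in metrics}
    label_class_avg: dict[str, dict[str, float]] = {}
    for label, grp in per_target.groupby("label"):
        per_class_label = grp.groupby("protein_class")[list(metrics)].mean()
        label_class_avg[str(label)] = {
            m: float(per_class_label[m].mean()) for m in metrics
        }
    return target_avg, target_std, class_avg, class_std, label_class_avg


def compute_metrics(predictions: pd.DataFrame, conditional: bool = True) -> MetricsReport:
    """Score a predictions frame at every aggregation level.

    Per-label one-vs-rest precision/recall/F1 per target; a present label
    with no predictions scores 0, a label absent from a target's truth is
    excluded from averages. When ``p_bind`` is available a conditional report
    restricted to functional compounds that passed the Stage 1 gate is
    attached (the cascaded architectures' Stage-2-only view).
    """
    required = {"compound_id", "target_id", "protein_class", "true_label", "pred_label"}
    if predictions.empty:
        raise ValueError("empty predictions")
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions frame missing columns {sorted(missing)}")
    per_target = _per_target_table(predictions)
    target_avg, target_std, class_avg, class_std, label_class_avg = _aggregate(per_target)
    report = MetricsReport(
        per_target=per_target,
        target_avg=target_avg,
        target_std=target_std,
        class_avg=class_avg,
        class_std=class_std,
        label_class_avg=label_class_avg,
        n_predictions=len(predictions),
    )
    if conditional and "p_bind" in predictions.columns:
        mask = (
            predictions["true_label"].isin([ACTIVATING, INHIBITING])
            & (predictions["p_bind"].astype(float) > 0.5)
        )
        sub = predictions[mask]
        if not sub.empty:
            report.conditional = compute_metrics(sub, conditional=False)
    return report


# ---------------------------------------------------------------------------
# Cross-validation driver


@dataclass
class CrossValReport:
    architecture: str
    k: int
    seed: int
    pooled: MetricsReport  # all out-of-fold predictions together
    per_fold: list[MetricsReport] = field(default_factory=list)
    fold_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    fold_std: dict[str, dict[str, float]] = field(default_factory=dict)
    theta: float | None = None  # Arch1 only
    predictions: pd.DataFrame | None = None

    def per_target_metric(self, label: str, metric: str) -> pd.Series:
        """Per-target distribution of one metric (for KS comparisons)."""
        t = self.pooled.per_target
        sub = t[t["label"] == label]
        return sub.set_index("target_id")[metric]

    def summary(self) -> dict:
        return {
            "architecture": self.architecture,
            "k": self.k,
            "seed": self.seed,
            "theta": self.theta,
            "pooled": self.pooled.summary(),
            "fold_mean": self.fold_mean,
            "fold_std": self.fold_std,
        }


def _fold_stats(reports: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict[str, dict[str, float]] = {}
    std: dict[str, dict[str, float]] = {}
    for level in ("target_avg", "class_avg"):
        vals = {
            m: np.array([getattr(r, level)[m] for r in reports])
            for m in ("precision", "recall", "f1")
        }
        mean[level] = {m: float(v.mean()) for m, v in vals.items()}
        std[level] = {m: float(v.std(ddof=0)) for m, v in vals.items()}
    return mean, std


def _test_frame_rows(ds, split):
    """Truth rows (ids, fps, labels) for one fold's test portion."""
    ids, fps, labels = [], [], []
    for name in ("activating", "inhibiting", "inactive"):
        sel = split.test[name]
        if len(sel) == 0:
            continue
        src_ids = getattr(ds, f"{name}_ids")
        src_fp = np.atleast_2d(getattr(ds, f"{name}_fp"))
        ids += [src_ids[i] for i in sel]
        fps.append(src_fp[sel])
        labels += [_SET_TO_LABEL[name]] * len(sel)
    fp = np.vstack(fps) if fps else np.zeros((0, 0))
    return ids, fp, np.asarray(labels, dtype=object)


def crossvalidate(
    architecture_id: str,
    datasets: list[TargetDataset],
    k: int = 5,
    seed: int = 0,
) -> CrossValReport:
    """Run the full k-fold CV protocol for one architecture.

    For the cascades each fold trains Stage 1 (actives incl. binding-only vs
    inactives) and Stage 2 per target and scores the fold's functional +
    inactive test compounds. For Arch1 the fold models score out-of-fold
    compounds at their annotated target; the pooled out-of-fold score
    distribution then sets θ before any metric is computed.
    """
    if architecture_id not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture_id!r}; choose from {ARCHITECTURES}")
    if not datasets:
        raise ValueError("no datasets")
    datasets = sorted(datasets, key=lambda d: d.target_id)
    folds_per_target = {
        ds.target_id: stratified_kfold_split(ds, k=k, seed=derive_seed(seed, "folds", ds.target_id))
        for ds in datasets
    }
    pclass = {ds.target_id: ds.protein_class for ds in datasets}

    rows: list[dict] = []
    theta = None
    if architecture_id == "arch1":
        for f in range(k):
            train_subs = [
                _subset_dataset(ds, folds_per_target[ds.target_id][f].train) for ds in datasets
            ]
            model = train_arch1(train_subs, seed=derive_seed(seed, "arch1", f))
            for ds in datasets:
                split = folds_per_target[ds.target_id][f]
                ids, fp, truth = _test_frame_rows(ds, split)
                if not ids:
                    continue
                sc = arch1_scores(model, fp)
                own = sc[sc["target_id"] == ds.target_id]
                for r, cid, tl in zip(own.itertuples(index=False), ids, truth):
                    rows.append(
                        {
                            "compound_id": cid,
                            "target_id": ds.target_id,
                            "protein_class": pclass[ds.target_id],
                            "true_label": tl,
                            "p_act": float(r.p_act),
                            "p_inh": float(r.p_inh),
                            "p_bind": np.nan,
                            "fold": f,
                        }
                    )
        pred_df = pd.DataFrame(rows)
        theta = optimize_arch1_threshold(pred_df[["p_act", "p_inh"]], pred_df["true_label"])
        pred_df["pred_label"] = arch1_decide(
            pred_df["p_act"].values, pred_df["p_inh"].values, theta
        )
    else:
        stage2_train = train_stage2_arch2 if architecture_id == "arch2" else train_stage2_arch3
        for ds in datasets:
            for f in range(k):
                split = folds_per_target[ds.target_id][f]
                sub = _subset_dataset(ds, split.train)
                s = derive_seed(seed, architecture_id, ds.target_id, f)
                stage1 = train_stage1(sub, seed=s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    stage2 = stage2_train(sub, seed=s + 1)
                ids, fp, truth = _test_frame_rows(ds, split)
                if not ids:
                    continue
                preds = cascade_predict(stage1, stage2, fp, compound_ids=ids)
                for p, tl in zip(preds, truth):
                    rows.append(
                        {
                            "compound_id": p.compound_id,
                            "target_id": ds.target_id,
                            "protein_class": pclass[ds.target_id],
                            "true_label": tl,
                            "p_act": p.p_act,
                            "p_inh": p.p_inh,
                            "p_bind": p.p_bind,
                            "pred_label": p.final_label,
                            "fold": f,
                        }
                    )
        pred_df = pd.DataFrame(rows)

    pooled = compute_metrics(pred_df)
    per_fold = [compute_metrics(grp) for _, grp in pred_df.groupby("fold", sort=True)]
    fold_mean, fold_std = _fold_stats(per_fold)
    return CrossValReport(
        architecture=architecture_id,
        k=k,
        seed=seed,
        pooled=pooled,
        per_fold=per_fold,
        fold_mean=fold_mean,
        fold_std=fold_std,
        theta=theta,
        predictions=pred_df,
    )


# ---------------------------------------------------------------------------
# Temporal (prospective) validation


def temporal_validate(
    architecture_id: str,
    trained,
    batch: pd.DataFrame,
    batch_fps: np.ndarray,
    training_ids: set[str],
) -> MetricsReport:
    """Score models trained on period-1 data against a later annotation batch.

    ``trained`` is either a fitted :class:`Arch1Model` (θ set) or a dict
    ``{target_id: (stage1, stage2)}``. ``batch`` needs columns compound_id,
    target_id, protein_class, true_label; rows align with ``batch_fps``.
    Any batch compound id present in the training sets is a leak and an error.
    Only class-averaged metrics are meaningful here (some targets may carry
    very few test compounds); empty per-target labels are excluded from the
    averages and logged.
    """
    overlap = set(batch["compound_id"]) & set(training_ids)
    if overlap:
        raise ValueError(
            f"temporal batch leaks {len(overlap)} training compound(s), e.g. "
            f"{sorted(overlap)[:3]}"
        )
    batch = batch.reset_index(drop=True)
    rows = []
    for tid, grp in batch.groupby("target_id", sort=True):
        fp = np.atleast_2d(batch_fps)[grp.index.values]
        if architecture_id == "arch1":
            sc = arch1_scores(trained, fp)
            own = sc[sc["target_id"] == tid]
            if own.empty:
                logger.warning("target %s unknown to the Arch1 model; skipped", tid)
                continue
            labels = arch1_decide(own["p_act"].values, own["p_inh"].values, trained.theta)
            for r, (_, b), lab in zip(own.itertuples(index=False), grp.iterrows(), labels):
                rows.append(
                    {
                        "compound_id": b["compound_id"],
                        "target_id": tid,
                        "protein_class": b["protein_class"],
                        "true_label": b["true_label"],
                        "pred_label": str(lab),
                        "p_bind": np.nan,
                    }
                )
        else:
            if tid not in trained:
                logger.warning("no trained cascade for target %s; skipped", tid)
                continue
            stage1, stage2 = trained[tid]
            preds = cascade_predict(stage1, stage2, fp, compound_ids=list(grp["compound_id"]))
            for p, (_, b) in zip(preds, grp.iterrows()):
                rows.append(
                    {
                        "compound_id": p.compound_id,
                        "target_id": tid,
                        "protein_class": b["protein_class"],
                        "true_label": b["true_label"],
                        "pred_label": p.final_label,
                        "p_bind": p.p_bind,
                    }
                )
    return compute_metrics(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Distribution comparison and chemical-space analyses


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test between per-target metric
    distributions; significance is conventionally read at 0.05."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires two non-empty samples")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def nn_similarity_analysis(ds: TargetDataset) -> dict[str, dict]:
    """Nearest-neighbor Tanimoto distributions between a target's compound
    sets: activating→inhibiting (A-I), binding-only→activating (B-A) and
    binding-only→inhibiting (B-I).

    For each compound in the first set, the most similar compound of the
    second set is retained; returns the per-compound similarities and their
    median per pairing. Pairings with an empty side are skipped with a
    warning.
    """
    pairs = {
        "A-I": (ds.activating_fp, ds.inhibiting_fp),
        "B-A": (ds.binding_fp, ds.activating_fp),
        "B-I": (ds.binding_fp, ds.inhibiting_fp),
    }
    out: dict[str, dict] = {}
    for name, (X, Y) in pairs.items():
        nx = 0 if X is None else np.atleast_2d(X).shape[0]
        ny = 0 if Y is None else np.atleast_2d(Y).shape[0]
        if nx == 0 or ny == 0:
            warnings.warn(f"{ds.target_id}: pairing {name} skipped (empty set)", stacklevel=2)
            continue
        sims = bulk_tanimoto(np.atleast_2d(X), np.atleast_2d(Y)).max(axis=1)
        out[name] = {"similarities": sims, "median": float(np.median(sims))}
    return out


# ---------------------------------------------------------------------------
# Applicability domain


@dataclass
class ADCurve:
    """Binned mean k-NN similarity vs true-positive rate.

    ``tpr`` is NaN for unpopulated bins; ``ad_auc`` is the trapezoidal area
    of TPR over the distance axis (1 − similarity) across populated bin
    centers, with the full [0,1] distance span as the reference scale.
    """

    bin_edges: np.ndarray
    tpr: np.ndarray
    support: np.ndarray
    ad_auc: float
    k: int
    similarities: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "n": self.support,
                "tpr": self.tpr,
            }
        )


def ad_curve(
    train_label_fps: dict[str, np.ndarray],
    test_fps: np.ndarray,
    true_labels,
    pred_labels,
    k: int = 5,
    bin_width: float = 0.05,
) -> ADCurve:
    """Applicability-domain curve for functional predictions.

    Each activating/inhibiting test compound is assigned the mean Tanimoto of
    its k nearest training neighbors *of its true label*; compounds are
    binned by that similarity and the per-bin TPR is the fraction predicted
    with the correct functional label (recall of the functional data points in
    the bin). AD-AUC integrates TPR over distance = 1 − similarity across
    populated bins.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    pred_labels = np.asarray(pred_labels, dtype=object)
    test_fps = np.atleast_2d(test_fps)
    mask = np.isin(true_labels, [ACTIVATING, INHIBITING])
    if not mask.any():
        raise ValueError("no functional (activating/inhibiting) truth compounds")
    sims = np.full(mask.sum(), np.nan)
    correct = (pred_labels[mask] == true_labels[mask]).astype(float)
    sub_true = true_labels[mask]
    sub_fp = test_fps[mask]
    for label in (ACTIVATING, INHIBITING):
        sel = sub_true == label
        if not sel.any():
            continue
        train = train_label_fps.get(label)
        if train is None or np.atleast_2d(train).shape[0] == 0:
            raise ValueError(f"no training fingerprints for label {label!r}")
        train = np.atleast_2d(train)
        if k > train.shape[0]:
            warnings.warn(
                f"k={k} exceeds training set size {train.shape[0]}; using all",
                stacklevel=2,
            )
        sims[sel] = knn_mean_similarity_matrix(sub_fp[sel], train, k=k)

    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    idx = np.clip((sims / bin_width).astype(int), 0, n_bins - 1)
    support = np.zeros(n_bins, dtype=int)
    tpr = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        support[b] = int(sel.sum())
        if support[b]:
            tpr[b] = float(correct[sel].mean())
    centers = (edges[:-1] + edges[1:]) / 2.0
    populated = support > 0
    if populated.sum() >= 2:
        x = 1.0 - centers[populated]
        order = np.argsort(x)
        auc = float(np.trapezoid(tpr[populated][order], x[order]))
    else:
        auc = 0.0
    return ADCurve(
        bin_edges=edges, tpr=tpr, support=support, ad_auc=auc, k=k, similarities=sims
    )
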