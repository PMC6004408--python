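"""The three functional-prediction architectures.

* **Arch1** — one multi-class random forest over every (target, function)
  label, trained on functional actives only. Probabilities are spread over
  all labels and sum to 1 per compound, so a decision threshold θ (chosen by
  F1 optimization on out-of-fold scores) converts them into calls.
* **Arch2** — per-target cascade: a Stage 1 binding gate (active vs inactive
  random forest) followed by a single Platt-calibrated activator-vs-inhibitor
  forest. Stage 2 probabilities sum to 1.
* **Arch3** — same Stage 1 gate, but Stage 2 is a pair of independent
  Platt-calibrated forests (activator-vs-inactive and inhibitor-vs-inactive)
  whose probabilities are comparable but need not sum to 1.

All forests use 100 trees with √n_features feature sampling. Arch1 uses the
explicit depth cap of 20; the per-target stage models grow unlimited-depth
trees with balanced class weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier

from .dataset import ACTIVATOR, INHIBITOR, TargetDataset

INACTIVE = "inactive"
ACTIVATING = "activating"
INHIBITING = "inhibiting"
PREDICTION_LABELS = (INACTIVE, ACTIVATING, INHIBITING)

N_TREES = 100
ARCH1_MAX_DEPTH = 20
CALIBRATION_FOLDS = 3


@dataclass
class Prediction:
    compound_id: str
    target_id: str
    p_act: float
    p_inh: float
    final_label: str
    p_bind: float | None = None


# ---------------------------------------------------------------------------
# Platt scaling primitive


def platt_fit(raw_scores, binary_labels) -> tuple[float, float]:
    """Fit Platt's sigmoid p(y=1|s) = 1 / (1 + exp(A·s + B)).

    Minimizes the calibration log-loss with Platt's smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), which regularize the fit when
    the scores separate the classes perfectly. Requires both classes present.
    """
    s = np.asarray(raw_scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if s.size == 0 or s.shape != y.shape:
        raise ValueError("scores and labels must be non-empty and aligned")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("platt_fit requires both classes present")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * s + b
        # stable log(1+exp(z)) and cross-entropy against smoothed targets
        log1pez = np.logaddexp(0.0, z)
        return float(np.sum(t * log1pez + (1.0 - t) * (log1pez - z)))

    res = minimize(nll, x0=np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))]),
                   method="BFGS")
    a, b = res.x
    return float(a), float(b)


def platt_apply(scores, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(scores, dtype=float) + b
    return 1.0 / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# Architecture 1: single multi-class forest + threshold


@dataclass
class Arch1Model:
    ensemble: RandomForestClassifier
    label_index: list[tuple[str, str]]  # ordered (target_id, functional label)
    theta: float | None = None
    seed: int = 0

    def manifest(self) -> dict:
        return {
            "architecture": "arch1",
            "n_trees": N_TREES,
            "max_depth": ARCH1_MAX_DEPTH,
            "max_features": "sqrt",
            "label_index": [list(t) for t in self.label_index],
            "theta": self.theta,
            "seed": self.seed,
        }


def train_arch1(datasets: list[TargetDataset], seed: int = 0) -> Arch1Model:
    """Train the single multi-class forest on all activating + inhibiting
    fingerprints across targets.

    Each training row is one compound–target–function annotation, so a
    promiscuous compound contributes one row per annotation and the predicted
    probabilities over all (target, function) labels sum to 1.
    """
    X_parts, y_parts, label_index = [], [], []
    for ds in datasets:
        for fp, label in ((ds.activating_fp, ACTIVATOR), (ds.inhibiting_fp, INHIBITOR)):
            if fp is None or np.atleast_2d(fp).shape[0] == 0:
                continue
            label_index.append((ds.target_id, label))
            X_parts.append(np.atleast_2d(fp))
            y_parts.append(np.full(np.atleast_2d(fp).shape[0], len(label_index) - 1))
    if not X_parts:
        raise ValueError("no functional training data")
    if len(label_index) < 2:
        raise ValueError("need at least two (target, function) labels to train")
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    clf = RandomForestClassifier(
        n_estimators=N_TREES,
        max_depth=ARCH1_MAX_DEPTH,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return Arch1Model(ensemble=clf, label_index=label_index, seed=seed)


def arch1_scores(model: Arch1Model, fps: np.ndarray) -> pd.DataFrame:
    """Per-compound per-target activation/inhibition probabilities.

    Returns a frame with one row per (compound row, target): columns
    ``row, target_id, p_act, p_inh``. Labels missing from the training data
    score 0 for that function.
    """
    fps = np.atleast_2d(fps)
    proba = model.ensemble.predict_proba(fps)  # (n, n_classes), classes = indices
    classes = model.ensemble.classes_
    targets = sorted({t for t, _ in model.label_index})
    col = {}
    for j, cls in enumerate(classes):
        t, lab = model.label_index[int(cls)]
        col[(t, lab)] = proba[:, j]
    rows = []
    zeros = np.zeros(fps.shape[0])
    for t in targets:
        rows.append(
            pd.DataFrame(
                {
                    "row": np.arange(fps.shape[0]),
                    "target_id": t,
                    "p_act": col.get((t, ACTIVATOR), zeros),
                    "p_inh": col.get((t, INHIBITOR), zeros),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def arch1_decide(p_act: np.ndarray, p_inh: np.ndarray, theta: float) -> np.ndarray:
    """Vectorized Arch1 decision rule.

    Labels whose probability reaches θ are candidate calls; when both
    functions pass, the higher probability wins and an exact tie goes to the
    inhibitor (the majority prior); when neither passes the call is inactive.
    """
    p_act = np.asarray(p_act, dtype=float)
    p_inh = np.asarray(p_inh, dtype=float)
    out = np.full(p_act.shape, INACTIVE, dtype=object)
    passed = (p_act >= theta) | (p_inh >= theta)
    # when only one label passes it is necessarily the larger one, so the
    # "higher probability wins" rule collapses to an argmax over passing rows
    act_wins = passed & (p_act > p_inh)
    out[passed] = INHIBITING
    out[act_wins] = ACTIVATING
    return out


def optimize_arch1_threshold(scores: pd.DataFrame, truth: pd.Series | np.ndarray) -> float:
    """Pick θ maximizing the mean F1 over {inactive, activating, inhibiting}.

    ``scores`` carries out-of-fold ``p_act``/``p_inh`` columns (never
    training-set scores); candidates are the 1st..100th percentiles of the
    pooled score distribution, ties broken toward the larger θ.
    """
    if len(scores) == 0:
        raise ValueError("no scores to optimize over")
    truth = np.asarray(truth, dtype=object)
    pooled = np.concatenate([scores["p_act"].values, scores["p_inh"].values])
    candidates = np.percentile(pooled, np.arange(1, 101))
    best_theta, best_f1 = None, -1.0
    p_act = scores["p_act"].values
    p_inh = scores["p_inh"].values
    for theta in candidates:
        pred = arch1_decide(p_act, p_inh, theta)
        f1 = _mean_label_f1(truth, pred)
        if f1 > best_f1 or (f1 == best_f1 and (best_theta is None or theta > best_theta)):
            best_f1, best_theta = f1, theta
    return float(best_theta)


def _mean_label_f1(truth: np.ndarray, pred: np.ndarray) -> float:
    f1s = []
    for label in PREDICTION_LABELS:
        tp = int(np.sum((pred == label) & (truth == label)))
        fp = int(np.sum((pred == label) & (truth != label)))
        fn = int(np.sum((pred != label) & (truth == label)))
        if (truth == label).sum() == 0 and (pred == label).sum() == 0:
            continue
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


def arch1_predict(
    model: Arch1Model, fps: np.ndarray, compound_ids: list[str] | None = None
) -> list[Prediction]:
    """Apply the trained Arch1 model: one prediction per compound per target."""
    if model.theta is None:
        raise ValueError("Arch1 threshold θ is unset; run optimize_arch1_threshold first")
    fps = np.atleast_2d(fps)
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(fps.shape[0])]
    sc = arch1_scores(model, fps)
    labels = arch1_decide(sc["p_act"].values, sc["p_inh"].values, model.theta)
    return [
        Prediction(
            compound_id=compound_ids[int(r.row)],
            target_id=r.target_id,
            p_act=float(r.p_act),
            p_inh=float(r.p_inh),
            final_label=str(lab),
        )
        for r, lab in zip(sc.itertuples(index=False), labels)
    ]


# ---------------------------------------------------------------------------
# Cascade stage models


@dataclass
class Stage1Model:
    target_id: str
    clf: RandomForestClassifier
    training_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def predict_bind(self, fps: np.ndarray) -> np.ndarray:
        fps = np.atleast_2d(fps)
        proba = self.clf.predict_proba(fps)
        pos = list(self.clf.classes_).index(1)
        return proba[:, pos]


def train_stage1(
    ds: TargetDataset, seed: int = 0, use_instance_weights: bool = True
) -> Stage1Model:
    """Per-target binding gate: all actives (activating ∪ inhibiting ∪
    binding-only) vs the inactive set.

    Balanced class weights plus, by default, per-instance weights giving each
    active the inactive:active ratio (and each inactive 1), as a compounded
    correction for the typically enormous inactive excess.
    """
    parts = [
        m
        for m in (ds.activating_fp, ds.inhibiting_fp, ds.binding_fp)
        if m is not None and np.atleast_2d(m).shape[0] > 0
    ]
    if not parts or ds.inactive_fp is None or np.atleast_2d(ds.inactive_fp).shape[0] == 0:
        raise ValueError(f"{ds.target_id}: both actives and inactives required for Stage 1")
    X_act = np.vstack([np.atleast_2d(p) for p in parts])
    X_inact = np.atleast_2d(ds.inactive_fp)
    X = np.vstack([X_act, X_inact])
    y = np.concatenate([np.ones(X_act.shape[0], dtype=int), np.zeros(X_inact.shape[0], dtype=int)])
    clf = RandomForestClassifier(
        n_estimators=N_TREES,
        max_depth=None,
        max_features="sqrt",
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    sample_weight = None
    if use_instance_weights:
        ratio = X_inact.shape[0] / X_act.shape[0]
        sample_weight = np.where(y == 1, ratio, 1.0)
    clf.fit(X, y, sample_weight=sample_weight)
    return Stage1Model(
        target_id=ds.target_id,
        clf=clf,
        training_counts={
            "activating": len(ds.activating_ids),
            "inhibiting": len(ds.inhibiting_ids),
            "binding_only": len(ds.binding_ids),
            "inactive": len(ds.inactive_ids),
            "n_active_rows": int(X_act.shape[0]),
        },
        seed=seed,
    )


def _check_calibration_feasible(target_id: str, *class_sizes: int) -> None:
    for n in class_sizes:
        if n < CALIBRATION_FOLDS:
            raise ValueError(
                f"{target_id}: {CALIBRATION_FOLDS}-fold Platt calibration needs at least "
                f"{CALIBRATION_FOLDS} members per class, got {n}"
            )
        if n < 10:
            warnings.warn(
                f"{target_id}: Stage 2 class with {n} members is below the "
                "recommended minimum of 10",
                stacklevel=3,
            )


def _calibrated_forest(X, y, seed):
    # the internal calibration folds are unshuffled and stratified, so rows
    # are permuted first — results must not depend on caller row order
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    base = RandomForestClassifier(
        n_estimators=N_TREES,
        max_depth=None,
        max_features="sqrt",
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    cal = CalibratedClassifierCV(base, method="sigmoid", cv=CALIBRATION_FOLDS)
    cal.fit(X[perm], y[perm])
    return cal


@dataclass
class Stage2Arch2Model:
    """Single Platt-calibrated activator-vs-inhibitor forest; p_act + p_inh = 1."""

    target_id: str
    clf: CalibratedClassifierCV
    seed: int = 0

    def predict_functional(self, fps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fps = np.atleast_2d(fps)
        proba = self.clf.predict_proba(fps)
        pos = list(self.clf.classes_).index(1)  # 1 = activator
        p_act = proba[:, pos]
        return p_act, 1.0 - p_act


def train_stage2_arch2(ds: TargetDataset, seed: int = 0) -> Stage2Arch2Model:
    act = np.atleast_2d(ds.activating_fp) if ds.activating_fp is not None else np.zeros((0, 1))
    inh = np.atleast_2d(ds.inhibiting_fp) if ds.inhibiting_fp is not None else np.zeros((0, 1))
    _check_calibration_feasible(ds.target_id, act.shape[0], inh.shape[0])
    X = np.vstack([act, inh])
    y = np.concatenate([np.ones(act.shape[0], dtype=int), np.zeros(inh.shape[0], dtype=int)])
    return Stage2Arch2Model(target_id=ds.target_id, clf=_calibrated_forest(X, y, seed), seed=seed)


@dataclass
class Stage2Arch3Model:
    """Pair of independent calibrated forests (activator-vs-inactive and
    inhibitor-vs-inactive); p_act and p_inh are each in [0,1] but their sum is
    unconstrained."""

    target_id: str
    clf_act: CalibratedClassifierCV
    clf_inh: CalibratedClassifierCV
    seed: int = 0

    def predict_functional(self, fps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fps = np.atleast_2d(fps)
        pa = self.clf_act.predict_proba(fps)[:, list(self.clf_act.classes_).index(1)]
        pi = self.clf_inh.predict_proba(fps)[:, list(self.clf_inh.classes_).index(1)]
        return pa, pi


def train_stage2_arch3(ds: TargetDataset, seed: int = 0) -> Stage2Arch3Model:
    act = np.atleast_2d(ds.activating_fp) if ds.activating_fp is not None else np.zeros((0, 1))
    inh = np.atleast_2d(ds.inhibiting_fp) if ds.inhibiting_fp is not None else np.zeros((0, 1))
    if ds.inactive_fp is None or np.atleast_2d(ds.inactive_fp).shape[0] == 0:
        raise ValueError(f"{ds.target_id}: Arch3 Stage 2 requires an inactive set")
    inact = np.atleast_2d(ds.inactive_fp)
    _check_calibration_feasible(ds.target_id, act.shape[0], inh.shape[0], inact.shape[0])
    X_a = np.vstack([act, inact])
    y_a = np.concatenate([np.ones(act.shape[0], dtype=int), np.zeros(inact.shape[0], dtype=int)])
    X_i = np.vstack([inh, inact])
    y_i = np.concatenate([np.ones(inh.shape[0], dtype=int), np.zeros(inact.shape[0], dtype=int)])
    return Stage2Arch3Model(
        target_id=ds.target_id,
        clf_act=_calibrated_forest(X_a, y_a, seed),
        clf_inh=_calibrated_forest(X_i, y_i, seed + 1),
        seed=seed,
    )


def cascade_decide(p_bind: np.ndarray, p_act: np.ndarray, p_inh: np.ndarray) -> np.ndarray:
    """Cascade decision rule.

    The gate passes only when p_bind is strictly greater than 0.5 (binding
    more likely than non-binding); gated compounds are inactive regardless of
    Stage 2. A functional label is always forced when the gate passes:
    activating iff p_act > p_inh, otherwise inhibiting (ties → inhibitor).
    """
    p_bind = np.asarray(p_bind, dtype=float)
    out = np.full(p_bind.shape, INACTIVE, dtype=object)
    passed = p_bind > 0.5
    act = passed & (np.asarray(p_act) > np.asarray(p_inh))
    out[passed] = INHIBITING
    out[act] = ACTIVATING
    return out


def cascade_predict(
    stage1: Stage1Model,
    stage2: Stage2Arch2Model | Stage2Arch3Model,
    fps: np.ndarray,
    compound_ids: list[str] | None = None,
) -> list[Prediction]:
    """Run the two-stage cascade for one target."""
    if stage1.target_id != stage2.target_id:
        raise ValueError(
            f"stage mismatch: stage1 for {stage1.target_id!r}, stage2 for {stage2.target_id!r}"
        )
    fps = np.atleast_2d(fps)
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(fps.shape[0])]
    p_bind = stage1.predict_bind(fps)
    p_act, p_inh = stage2.predict_functional(fps)
    labels = cascade_decide(p_bind, p_act, p_inh)
    return [
        Prediction(
            compound_id=cid,
            target_id=stage1.target_id,
            p_bind=float(pb),
            p_act=float(pa),
            p_inh=float(pi),
            final_label=str(lab),
        )
        for cid, pb, pa, pi, lab in zip(compound_ids, p_bind, p_act, p_inh, labels)
    ]


# ---------------------------------------------------------------------------
# Persistence


def save_models(obj, manifest: dict, path: str | Path) -> None:
    """Persist a trained model bundle: joblib archive + JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(obj, path / "models.joblib")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def load_models(path: str | Path):
    path = Path(path)
    obj = joblib.load(path / "models.joblib")
    manifest = json.loads((path / "manifest.json").read_text())
    return obj, manifest


def predictions_to_frame(preds: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                "target_id": p.target_id,
                "p_bind": p.p_bind,
                "p_act": p.p_act,
                "p_inh": p.p_inh,
                "final_label": p.final_label,
            }
            for p in preds
        ]
    )
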