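"""Assembly of per-target training sets from compound–target–assay annotations.

The pipeline turns an annotation table (compound, target, endpoint type,
potency in μM, optional BioAssay Ontology functional term) into per-target
labeled compound sets:

* ``activating`` / ``inhibiting`` — functional actives (IC50/EC50 ≤ 10 μM),
  labeled through the BAO-term mapping schema, conflicts removed;
* ``binding_only`` — compounds with affinity evidence (Ki/Kd ≤ 10 μM) but no
  functional direction;
* ``inactive`` — experimentally confirmed non-binders (> 10 μM) topped up
  with putative inactives sampled by sphere exclusion (max Tanimoto to every
  active ≤ 0.4).

Targets with fewer than 10 activating or 10 inhibiting compounds are dropped;
binding-only sets smaller than 5 are emptied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import bulk_tanimoto

ACTIVITY_THRESHOLD_UM = 10.0
SPHERE_EXCLUSION_CUTOFF = 0.4
MIN_FUNCTIONAL = 10
MIN_BINDING = 5

PROTEIN_CLASSES = ("GPCR", "NHR", "IonChannel", "Transporter")
ENDPOINT_TYPES = ("IC50", "EC50", "Ki", "Kd")

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

# BioAssay Ontology term → simplified binary functional label.
BAO_FUNCTIONAL_MAP = {
    "activation": ACTIVATOR,
    "agonism": ACTIVATOR,
    "antagonism": INHIBITOR,
    "blocking": INHIBITOR,
    "closing": INHIBITOR,
    "inhibition": INHIBITOR,
    "inverse agonism": INHIBITOR,
    "opening": ACTIVATOR,
}


class MappingError(ValueError):
    pass


def map_functional_label(bao_term: str) -> str:
    """Map a BioAssay Ontology mechanism term to ``activator``/``inhibitor``.

    Case-insensitive; unknown terms raise a :class:`MappingError` listing the
    accepted vocabulary.
    """
    key = str(bao_term).strip().lower()
    if key not in BAO_FUNCTIONAL_MAP:
        raise MappingError(
            f"unknown functional term {bao_term!r}; accepted terms: "
            + ", ".join(sorted(BAO_FUNCTIONAL_MAP))
        )
    return BAO_FUNCTIONAL_MAP[key]


@dataclass(frozen=True)
class AssayAnnotation:
    compound_id: str
    target_id: str
    endpoint_type: str
    value_um: float
    bao_term: str | None = None

    def __post_init__(self):
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ValueError(
                f"endpoint_type must be one of {ENDPOINT_TYPES}, got "
                f"{self.endpoint_type!r}"
            )
        if not self.value_um > 0:
            raise ValueError("value_um must be a positive concentration in μM")


def assign_activity_class(ann: AssayAnnotation) -> tuple[str, str | None]:
    """Classify one annotation as functional active, binder or nonbinder.

    Returns ``("functional_active", label)``, ``("binder", None)`` or
    ``("nonbinder", None)``. The 10 μM activity boundary is inclusive for
    actives. When a BAO term is present it takes precedence over the
    endpoint-unit fallback (EC50 → activator, IC50 → inhibitor).
    """
    if ann.value_um > ACTIVITY_THRESHOLD_UM:
        return ("nonbinder", None)
    if ann.bao_term:
        return ("functional_active", map_functional_label(ann.bao_term))
    if ann.endpoint_type == "EC50":
        return ("functional_active", ACTIVATOR)
    if ann.endpoint_type == "IC50":
        return ("functional_active", INHIBITOR)
    return ("binder", None)  # Ki / Kd affinity evidence only


@dataclass
class TargetDataset:
    """Per-target labeled compound sets after all assembly filters.

    Each set pairs an id list with a row-aligned fingerprint matrix.
    ``inactive_provenance`` records, per inactive compound, whether it is an
    experimental non-binder or a sphere-exclusion putative inactive.
    """

    target_id: str
    protein_class: str
    activating_ids: list[str] = field(default_factory=list)
    inhibiting_ids: list[str] = field(default_factory=list)
    binding_ids: list[str] = field(default_factory=list)
    inactive_ids: list[str] = field(default_factory=list)
    activating_fp: np.ndarray | None = None
    inhibiting_fp: np.ndarray | None = None
    binding_fp: np.ndarray | None = None
    inactive_fp: np.ndarray | None = None
    inactive_provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValueError(
                f"protein_class must be one of {PROTEIN_CLASSES}, got "
                f"{self.protein_class!r}"
            )

    def counts(self) -> dict[str, int]:
        return {
            "activating": len(self.activating_ids),
            "inhibiting": len(self.inhibiting_ids),
            "binding_only": len(self.binding_ids),
            "inactive": len(self.inactive_ids),
        }

    def validate(self) -> None:
        """Assert the type invariants (disjoint functional sets, size floors,
        row alignment)."""
        act, inh = set(self.activating_ids), set(self.inhibiting_ids)
        if act & inh:
            raise AssertionError(f"{self.target_id}: activating ∩ inhibiting ≠ ∅")
        if len(self.activating_ids) < MIN_FUNCTIONAL or len(self.inhibiting_ids) < MIN_FUNCTIONAL:
            raise AssertionError(f"{self.target_id}: functional set below minimum size")
        if self.binding_ids and len(self.binding_ids) < MIN_BINDING:
            raise AssertionError(f"{self.target_id}: non-empty binding set below minimum size")
        for ids, fp in (
            (self.activating_ids, self.activating_fp),
            (self.inhibiting_ids, self.inhibiting_fp),
            (self.binding_ids, self.binding_fp),
            (self.inactive_ids, self.inactive_fp),
        ):
            n = 0 if fp is None else np.atleast_2d(fp).shape[0]
            if ids and n != len(ids):
                raise AssertionError(f"{self.target_id}: id/fingerprint row mismatch")
        if len(self.inactive_provenance) != len(self.inactive_ids):
            raise AssertionError(f"{self.target_id}: inactive provenance mismatch")


def remove_conflicts(
    classified: pd.DataFrame,
) -> pd.DataFrame:
    """Drop per-target conflicting annotations.

    Expects a frame with columns ``compound_id, target_id, activity_class,
    functional_label``. A compound with both activator and inhibitor evidence
    at the same target is removed from that target's functional sets; a
    compound with both active (≤ 10 μM) and non-binding (> 10 μM) evidence at
    the same target is removed from the nonbinder rows. Rows are only ever
    removed, never relabeled.
    """
    df = classified.copy()
    key = ["compound_id", "target_id"]

    func = df[df["activity_class"] == "functional_active"]
    label_counts = func.groupby(key)["functional_label"].nunique()
    conflicted_func = set(label_counts[label_counts > 1].index)

    active_keys = set(
        map(tuple, df.loc[df["activity_class"].isin(["functional_active", "binder"]), key].values)
    )
    nonbind_keys = set(map(tuple, df.loc[df["activity_class"] == "nonbinder", key].values))
    conflicted_inactive = active_keys & nonbind_keys

    pairs = list(map(tuple, df[key].values))
    drop_func = np.array(
        [
            p in conflicted_func and c == "functional_active"
            for p, c in zip(pairs, df["activity_class"])
        ]
    )
    drop_inact = np.array(
        [p in conflicted_inactive and c == "nonbinder" for p, c in zip(pairs, df["activity_class"])]
    )
    return df[~(drop_func | drop_inact)].reset_index(drop=True)


def sphere_exclusion_sample(
    actives_fp: np.ndarray,
    pool_fp: np.ndarray,
    pool_ids: list[str],
    n_required: int,
    tc_cutoff: float = SPHERE_EXCLUSION_CUTOFF,
    seed: int = 0,
) -> list[int]:
    """Sample putative-inactive pool compounds outside the active similarity
    spheres.

    Iterates the pool in a seed-shuffled order (shuffling a by-id sorted view,
    so the result is invariant to the caller's pool ordering) and accepts a
    candidate iff its maximum Tanimoto to every active is ≤ ``tc_cutoff``,
    until ``n_required`` are accepted. Returns indices into the pool; fewer
    than requested with a warning when the pool is exhausted.
    """
    actives_fp = np.atleast_2d(actives_fp)
    pool_fp = np.atleast_2d(pool_fp)
    if actives_fp.shape[0] == 0:
        raise ValueError("sphere exclusion needs a non-empty active reference set")
    if pool_fp.shape[0] == 0 or n_required < 1:
        raise ValueError("pool must be non-empty and n_required >= 1")
    order = np.argsort(np.asarray(pool_ids, dtype=object))
    rng = np.random.default_rng(seed)
    order = order[rng.permutation(len(order))]
    max_tc = bulk_tanimoto(pool_fp, actives_fp).max(axis=1)
    chosen: list[int] = []
    for idx in order:
        if max_tc[idx] <= tc_cutoff:
            chosen.append(int(idx))
            if len(chosen) == n_required:
                break
    if len(chosen) < n_required:
        warnings.warn(
            f"sphere exclusion pool exhausted: {len(chosen)}/{n_required} sampled",
            stacklevel=2,
        )
    return chosen


def apply_minimum_size_filters(
    datasets: list[TargetDataset],
) -> tuple[list[TargetDataset], list[dict]]:
    """Apply the minimum-size rules and report dropped targets.

    Targets with fewer than 10 activating or 10 inhibiting compounds are
    dropped entirely; kept targets with a non-empty binding-only set smaller
    than 5 have that set emptied (too few members to survive five-fold
    cross-validation).
    """
    kept: list[TargetDataset] = []
    dropped: list[dict] = []
    for ds in datasets:
        c = ds.counts()
        if c["activating"] < MIN_FUNCTIONAL or c["inhibiting"] < MIN_FUNCTIONAL:
            dropped.append({"target_id": ds.target_id, "reason": "functional_minimum", **c})
            continue
        if 0 < c["binding_only"] < MIN_BINDING:
            ds.binding_ids = []
            ds.binding_fp = None
        kept.append(ds)
    return kept, dropped


REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "target_id",
    "protein_class",
    "endpoint_type",
    "value_um",
    "bao_term",
)


def classify_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the annotation table and add activity_class/functional_label."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {', '.join(missing)}")
    bad_class = set(df["protein_class"]) - set(PROTEIN_CLASSES)
    if bad_class:
        raise ValueError(
            f"unsupported protein classes {sorted(bad_class)}; modeled classes: "
            f"{PROTEIN_CLASSES}"
        )
    classes, labels = [], []
    for row in df.itertuples(index=False):
        bao = row.bao_term if isinstance(row.bao_term, str) and row.bao_term.strip() else None
        ann = AssayAnnotation(
            compound_id=str(row.compound_id),
            target_id=str(row.target_id),
            endpoint_type=str(row.endpoint_type),
            value_um=float(row.value_um),
            bao_term=bao,
        )
        cls, lab = assign_activity_class(ann)
        classes.append(cls)
        labels.append(lab)
    out = df.copy()
    out["activity_class"] = classes
    out["functional_label"] = labels
    return out


def build_target_datasets(
    annotations: pd.DataFrame,
    fingerprints: dict[str, np.ndarray],
    inactive_pool_ids: list[str] | None = None,
    inactive_pool_fp: np.ndarray | None = None,
    seed: int = 0,
    sphere_multiple: float = 100.0,
    tc_cutoff: float = SPHERE_EXCLUSION_CUTOFF,
) -> tuple[list[TargetDataset], list[dict]]:
    """Full assembly pipeline: classify → de-conflict → sets → sphere-exclusion
    inactives → minimum-size filters.

    ``fingerprints`` maps compound_id → bit vector for every annotated
    compound. The optional external pool supplies sphere-exclusion putative
    inactives, sampled per target up to ``sphere_multiple ×`` the active-set
    size (capped by the pool) on top of experimental non-binders.
    """
    df = classify_annotations(annotations)
    df = remove_conflicts(
        df[["compound_id", "target_id", "protein_class", "activity_class", "functional_label"]]
    )

    datasets: list[TargetDataset] = []
    for target_id, grp in df.groupby("target_id", sort=True):
        protein_class = grp["protein_class"].iloc[0]
        func = grp[grp["activity_class"] == "functional_active"]
        act = sorted(set(func.loc[func["functional_label"] == ACTIVATOR, "compound_id"]))
        inh = sorted(set(func.loc[func["functional_label"] == INHIBITOR, "compound_id"]))
        binders = sorted(
            set(grp.loc[grp["activity_class"] == "binder", "compound_id"]) - set(act) - set(inh)
        )
        exp_inact = sorted(
            set(grp.loc[grp["activity_class"] == "nonbinder", "compound_id"])
            - set(act)
            - set(inh)
            - set(binders)
        )

        def fps(ids):
            return (
                np.vstack([fingerprints[i] for i in ids]).astype(np.uint8) if ids else None
            )

        ds = TargetDataset(
            target_id=str(target_id),
            protein_class=str(protein_class),
            activating_ids=act,
            inhibiting_ids=inh,
            binding_ids=binders,
            inactive_ids=list(exp_inact),
            activating_fp=fps(act),
            inhibiting_fp=fps(inh),
            binding_fp=fps(binders),
            inactive_fp=fps(exp_inact),
            inactive_provenance=["experimental"] * len(exp_inact),
        )

        actives_all = act + inh + binders
        if (
            inactive_pool_fp is not None
            and inactive_pool_ids is not None
            and len(actives_all) > 0
        ):
            n_target = int(min(sphere_multiple * len(actives_all), len(inactive_pool_ids)))
            already = set(ds.inactive_ids) | set(actives_all)
            mask = [cid not in already for cid in inactive_pool_ids]
            cand_ids = [c for c, m in zip(inactive_pool_ids, mask) if m]
            if n_target > 0 and cand_ids:
                cand_fp = inactive_pool_fp[np.asarray(mask, dtype=bool)]
                actives_fp_all = np.vstack(
                    [m for m in (ds.activating_fp, ds.inhibiting_fp, ds.binding_fp) if m is not None]
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    idx = sphere_exclusion_sample(
                        actives_fp_all,
                        cand_fp,
                        cand_ids,
                        n_required=min(n_target, len(cand_ids)),
                        tc_cutoff=tc_cutoff,
                        seed=seed,
                    )
                ds.inactive_ids = ds.inactive_ids + [cand_ids[i] for i in idx]
                extra = cand_fp[idx]
                ds.inactive_fp = (
                    extra if ds.inactive_fp is None else np.vstack([ds.inactive_fp, extra])
                )
                ds.inactive_provenance += ["sphere_exclusion"] * len(idx)
        datasets.append(ds)

    return apply_minimum_size_filters(datasets)


# ---------------------------------------------------------------------------
# Manifest I/O


def write_manifest(
    datasets: list[TargetDataset], dropped: list[dict], out_dir: str | Path
) -> Path:
    """Persist a dataset collection: JSON manifest + per-target compound CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"targets": [], "dropped": dropped}
    for ds in datasets:
        rows = []
        for ids, fp, label in (
            (ds.activating_ids, ds.activating_fp, "activating"),
            (ds.inhibiting_ids, ds.inhibiting_fp, "inhibiting"),
            (ds.binding_ids, ds.binding_fp, "binding_only"),
            (ds.inactive_ids, ds.inactive_fp, "inactive"),
        ):
            if not ids:
                continue
            fp = np.atleast_2d(fp)
            for j, cid in enumerate(ids):
                prov = ds.inactive_provenance[j] if label == "inactive" else ""
                rows.append(
                    {
                        "compound_id": cid,
                        "set": label,
                        "provenance": prov,
                        "fingerprint": "".join(map(str, fp[j].tolist())),
                    }
                )
        csv_path = out / f"{ds.target_id}.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        manifest["targets"].append(
            {
                "target_id": ds.target_id,
                "protein_class": ds.protein_class,
                "counts": ds.counts(),
                "csv": csv_path.name,
            }
        )
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_manifest(manifest_path: str | Path) -> tuple[list[TargetDataset], list[dict]]:
    """Inverse of :func:`write_manifest`."""
    path = Path(manifest_path)
    manifest = json.loads(path.read_text())
    datasets = []
    for entry in manifest["targets"]:
        df = pd.read_csv(path.parent / entry["csv"], dtype={"fingerprint": str})
        ds = TargetDataset(target_id=entry["target_id"], protein_class=entry["protein_class"])

        def unpack(sub):
            ids = [str(c) for c in sub["compound_id"]]
            fp = (
                np.array([[int(ch) for ch in s] for s in sub["fingerprint"]], dtype=np.uint8)
                if ids
                else None
            )
            return ids, fp

        for label, attr in (
            ("activating", "activating"),
            ("inhibiting", "inhibiting"),
            ("binding_only", "binding"),
            ("inactive", "inactive"),
        ):
            sub = df[df["set"] == label]
            ids, fp = unpack(sub)
            setattr(ds, f"{attr}_ids", ids)
            setattr(ds, f"{attr}_fp", fp)
            if label == "inactive":
                ds.inactive_provenance = [str(p) for p in sub["provenance"]]
        datasets.append(ds)
    return datasets, manifest["dropped"]
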