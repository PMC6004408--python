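"""Seeded generator of benchmark chemical universes.

Real functional-bioactivity corpora are proprietary, so benchmarking relies
on synthetic universes that reproduce the *statistical* structure of such
data: per-target activator/inhibitor/binder clusters with controllable
nearest-neighbor Tanimoto separation, a configurable inhibitor:activator
imbalance, and a large diffuse inactive background.

Compounds are 2048-bit fingerprints generated directly as bit vectors. Each
functional class has a prototype bit pattern; members are noisy copies
(density-preserving bit flips). Cross-class similarity is controlled by the
fraction of prototype on-bits shared between class prototypes, calibrated by
bisection against a closed-form expectation of the Tanimoto coefficient. The
default knobs encode the structure reported for large pharma functional
panels: activator-vs-inhibitor member similarity ≈ 0.835, binder-vs-inhibitor
≈ 0.958, and a 5:1 inhibitor:activator imbalance.

An optional mode emits small-molecule SMILES from a bundled fragment grammar
so that end-to-end runs exercise standardization and fingerprinting; those
molecules are plausible drug-like structures but carry no engineered cluster
separation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .dataset import TargetDataset, PROTEIN_CLASSES

N_BITS = 2048
N_ON = 120  # prototype on-bit count; density ≈ 0.06, typical of circular FPs


# ---------------------------------------------------------------------------
# Closed-form Tanimoto expectation and knob calibration


def expected_member_tc(
    s: float, p1: float, p2: float, n: int = N_BITS, m: int = N_ON
) -> float:
    """Expected Tanimoto between members of two prototypes sharing a fraction
    ``s`` of their ``m`` on-bits.

    Each member applies density-preserving noise: an on-bit switches off with
    probability ``p`` and an off-bit switches on with probability
    ``p·m/(n−m)``, keeping the expected on-bit count at m. The expectation is
    the ratio-of-expectations approximation E|x∩y| / E|x∪y|, which is tight
    at n = 2048.
    """
    q1_off = p1 * m / (n - m)
    q2_off = p2 * m / (n - m)
    cats = [
        (s * m, 1 - p1, 1 - p2),  # on in both prototypes
        ((1 - s) * m, 1 - p1, q2_off),  # on in proto 1 only
        ((1 - s) * m, q1_off, 1 - p2),  # on in proto 2 only
        (n - (2 - s) * m, q1_off, q2_off),  # off in both
    ]
    inter = sum(c * a * b for c, a, b in cats)
    union = sum(c * (a + b - a * b) for c, a, b in cats)
    return inter / union


def solve_shared_fraction(
    target_tc: float, p1: float, p2: float, n: int = N_BITS, m: int = N_ON
) -> float:
    """Find the prototype on-bit sharing fraction giving an expected member
    Tanimoto of ``target_tc``, by bisection. Errors when the request exceeds
    what the noise level permits."""
    lo, hi = 0.0, 1.0
    t_max = expected_member_tc(1.0, p1, p2, n, m)
    t_min = expected_member_tc(0.0, p1, p2, n, m)
    if target_tc > t_max + 1e-9:
        raise ValueError(
            f"requested expected Tc {target_tc:.3f} infeasible: noise rates "
            f"({p1}, {p2}) cap the achievable expectation at {t_max:.3f}"
        )
    if target_tc <= t_min:
        return 0.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if expected_member_tc(mid, p1, p2, n, m) < target_tc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Spec and generation


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic chemical universe.

    Counts are per target and exact. When ``imbalance_ratio`` is set it
    overrides ``n_inhibiting`` as ``round(n_activating × ratio)``. Similarity
    knobs are expected member-level Tanimoto coefficients; realized
    nearest-neighbor medians sit slightly above them (a maximum over a finite
    set exceeds its mean).

    The inactive background mixes two populations, mirroring the provenance
    split of real negative data: a ``near_inactive_fraction`` of near-miss
    non-binders at ``near_inactive_similarity`` to the functional clusters
    (experimental inactive analogs) and a diffuse remainder at
    ``inactive_diffuseness`` (the sphere-exclusion-like far background).
    ``label_noise`` is the probability that a compound's recorded functional
    label is wrong; the resulting contamination of each observed set follows
    from Bayes' rule, so under strong imbalance the observed activator set is
    flooded by mislabeled inhibitors — the regime in which architectures
    differ most.
    """

    n_targets: int = 8
    n_activating: int = 40
    n_inhibiting: int = 200
    n_binding: int = 60
    n_inactive: int = 400
    imbalance_ratio: float | None = 5.0
    target_function_separation: float = 0.835
    binder_inhibitor_overlap: float = 0.958
    inactive_diffuseness: float = 0.05
    near_inactive_fraction: float = 0.5
    near_inactive_similarity: float = 0.80
    label_noise: float = 0.0
    noise_rate: float = 0.01
    n_bits: int = N_BITS
    n_on: int = N_ON
    seed: int = 0

    def __post_init__(self):
        if self.imbalance_ratio is not None:
            self.n_inhibiting = int(round(self.n_activating * self.imbalance_ratio))
        for name in ("n_targets", "n_activating", "n_inhibiting", "n_binding", "n_inactive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "target_function_separation",
            "binder_inhibitor_overlap",
            "inactive_diffuseness",
            "near_inactive_fraction",
            "near_inactive_similarity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _random_pattern(rng: np.random.Generator, n_bits: int, n_on: int) -> np.ndarray:
    fp = np.zeros(n_bits, dtype=np.uint8)
    fp[rng.choice(n_bits, size=n_on, replace=False)] = 1
    return fp


def _derived_prototype(
    rng: np.random.Generator, base: np.ndarray, shared_fraction: float, n_on: int
) -> np.ndarray:
    """Prototype keeping ``shared_fraction`` of the base's on-bits, with the
    remainder placed uniformly among the base's off-bits."""
    on = np.flatnonzero(base)
    off = np.flatnonzero(base == 0)
    n_keep = int(round(shared_fraction * n_on))
    keep = rng.choice(on, size=n_keep, replace=False)
    new = rng.choice(off, size=n_on - n_keep, replace=False)
    fp = np.zeros_like(base)
    fp[keep] = 1
    fp[new] = 1
    return fp


def _members(
    rng: np.random.Generator, proto: np.ndarray, n_members: int, p: float
) -> np.ndarray:
    """Noisy copies of a prototype with density-preserving bit flips."""
    n_bits = proto.size
    m = int(proto.sum())
    if n_members == 0:
        return np.zeros((0, n_bits), dtype=np.uint8)
    if p == 0.0:
        return np.tile(proto, (n_members, 1))
    p_off = p * m / (n_bits - m)
    flip_prob = np.where(proto == 1, p, p_off)
    flips = rng.random((n_members, n_bits)) < flip_prob
    return np.where(flips, 1 - proto, proto).astype(np.uint8)


def generate_universe(spec: SyntheticSpec) -> tuple[list[TargetDataset], dict]:
    """Generate the per-target labeled compound sets plus a ground-truth
    manifest (prototypes, calibrated fractions, id→cluster assignments).

    Deterministic: identical (spec, seed) yields byte-identical outputs.
    """
    p = spec.noise_rate
    s_ai = solve_shared_fraction(
        spec.target_function_separation, p, p, spec.n_bits, spec.n_on
    )
    # knobs for sets that are not requested are not calibrated (and hence not
    # feasibility-checked)
    s_bi = (
        solve_shared_fraction(spec.binder_inhibitor_overlap, p, p, spec.n_bits, spec.n_on)
        if spec.n_binding > 0
        else 0.0
    )
    s_inact = (
        solve_shared_fraction(spec.inactive_diffuseness, p, p, spec.n_bits, spec.n_on)
        if spec.n_inactive > 0
        else 0.0
    )
    s_near = (
        solve_shared_fraction(spec.near_inactive_similarity, p, p, spec.n_bits, spec.n_on)
        if spec.n_inactive > 0 and spec.near_inactive_fraction > 0
        else 0.0
    )
    # label contamination: spec counts are TRUE class sizes; each recorded
    # label flips with probability label_noise, so the observed sets are
    # (deterministically rounded) mixtures — under strong imbalance the
    # observed activator set is flooded by flipped inhibitors
    ln, na, ni = spec.label_noise, spec.n_activating, spec.n_inhibiting
    n_act_true = int(round((1 - ln) * na))
    n_act_fake = int(round(ln * ni))
    n_inh_true = int(round((1 - ln) * ni))
    n_inh_fake = int(round(ln * na))

    datasets: list[TargetDataset] = []
    manifest: dict = {
        "spec": asdict(spec),
        "calibrated_fractions": {
            "A-I": s_ai,
            "B-I": s_bi,
            "inactive_far": s_inact,
            "inactive_near": s_near,
        },
        "targets": {},
    }
    for t in range(spec.n_targets):
        tid = f"T{t:03d}"
        rng = np.random.default_rng(derive_seed(spec.seed, "universe", tid))
        pclass = PROTEIN_CLASSES[t % len(PROTEIN_CLASSES)]
        proto_inh = _random_pattern(rng, spec.n_bits, spec.n_on)
        proto_act = _derived_prototype(rng, proto_inh, s_ai, spec.n_on)
        proto_bind = _derived_prototype(rng, proto_inh, s_bi, spec.n_on)

        act = np.vstack(
            [
                _members(rng, proto_act, n_act_true, p),
                _members(rng, proto_inh, n_act_fake, p),
            ]
        )
        inh = np.vstack(
            [
                _members(rng, proto_inh, n_inh_true, p),
                _members(rng, proto_act, n_inh_fake, p),
            ]
        )
        bind = _members(rng, proto_bind, spec.n_binding, p)
        # inactive background: near-miss experimental analogs plus a diffuse
        # sphere-exclusion-like remainder, each compound around its own pattern
        inact_rows, provenance = [], []
        for _ in range(spec.n_inactive):
            near = rng.random() < spec.near_inactive_fraction
            base = proto_act if rng.random() < 0.5 else proto_inh
            proto_i = _derived_prototype(rng, base, s_near if near else s_inact, spec.n_on)
            inact_rows.append(_members(rng, proto_i, 1, p)[0])
            provenance.append("experimental" if near else "sphere_exclusion")
        inact = (
            np.vstack(inact_rows)
            if inact_rows
            else np.zeros((0, spec.n_bits), dtype=np.uint8)
        )

        ds = TargetDataset(
            target_id=tid,
            protein_class=pclass,
            activating_ids=[f"{tid}_act_{i:04d}" for i in range(act.shape[0])],
            inhibiting_ids=[f"{tid}_inh_{i:04d}" for i in range(inh.shape[0])],
            binding_ids=[f"{tid}_bnd_{i:04d}" for i in range(spec.n_binding)],
            inactive_ids=[f"{tid}_ina_{i:04d}" for i in range(spec.n_inactive)],
            activating_fp=act if len(act) else None,
            inhibiting_fp=inh if len(inh) else None,
            binding_fp=bind if len(bind) else None,
            inactive_fp=inact if len(inact) else None,
            inactive_provenance=provenance,
        )
        datasets.append(ds)
        manifest["targets"][tid] = {
            "protein_class": pclass,
            "prototype_on_bits": {
                "activator": np.flatnonzero(proto_act).tolist(),
                "inhibitor": np.flatnonzero(proto_inh).tolist(),
                "binder": np.flatnonzero(proto_bind).tolist(),
            },
            "counts": ds.counts(),
            "contamination": {"activating": n_act_fake, "inhibiting": n_inh_fake},
            # generating-cluster truth per functional compound (recorded label
            # may differ when label_noise > 0)
            "cluster_truth": {
                **{
                    cid: ("activator" if i < n_act_true else "inhibitor")
                    for i, cid in enumerate(ds.activating_ids)
                },
                **{
                    cid: ("inhibitor" if i < n_inh_true else "activator")
                    for i, cid in enumerate(ds.inhibiting_ids)
                },
            },
        }
    return datasets, manifest


def generate_temporal_batch(
    spec: SyntheticSpec,
    base: list[TargetDataset],
    manifest: dict,
    novelty: float,
    error_gradient: bool = False,
    n_per_class: int = 50,
    spread: float = 0.0,
    seed: int = 1,
    id_prefix: str = "new",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a later-period labeled batch at controlled distance from the
    training universe.

    ``novelty`` is the expected Tanimoto of new compounds to the training
    cluster of their class (1.0 → exact duplicates under fresh ids); with
    ``spread`` > 0 each compound's expected similarity is drawn uniformly
    from ``novelty ± spread`` (clipped to the feasible range), covering both
    similar and dissimilar chemical space. With ``error_gradient`` the
    recorded truth label flips with probability increasing with distance to
    the training set, so that prediction errors grow with dissimilarity — the
    regime applicability-domain curves are meant to expose.

    Returns an annotation frame (compound_id, target_id, protein_class,
    true_label) and the aligned fingerprint matrix.
    """
    if not 0.0 <= novelty <= 1.0:
        raise ValueError(f"novelty must be in [0,1], got {novelty}")
    p = spec.noise_rate
    t_max = expected_member_tc(1.0, p, p, spec.n_bits, spec.n_on)
    base_ids = {cid for ds in base for cid in ds.activating_ids + ds.inhibiting_ids}
    rows, fps = [], []
    for ds in sorted(base, key=lambda d: d.target_id):
        rng = np.random.default_rng(derive_seed(seed, "temporal", ds.target_id))
        protos = manifest["targets"][ds.target_id]["prototype_on_bits"]
        for label_name, proto_key, train_fp in (
            ("activating", "activator", ds.activating_fp),
            ("inhibiting", "inhibitor", ds.inhibiting_fp),
        ):
            proto = np.zeros(spec.n_bits, dtype=np.uint8)
            proto[np.asarray(protos[proto_key], dtype=int)] = 1
            for i in range(n_per_class):
                cid = f"{id_prefix}_{ds.target_id}_{label_name}_{i:04d}"
                if cid in base_ids:
                    raise ValueError(f"temporal batch id collides with base: {cid!r}")
                if novelty >= 0.999 and spread == 0.0:
                    j = int(rng.integers(np.atleast_2d(train_fp).shape[0]))
                    fp = np.atleast_2d(train_fp)[j].copy()
                else:
                    want = novelty if spread == 0.0 else float(
                        rng.uniform(max(0.0, novelty - spread), min(t_max, novelty + spread))
                    )
                    want = min(want, t_max)
                    s = solve_shared_fraction(want, p, p, spec.n_bits, spec.n_on)
                    proto_i = _derived_prototype(rng, proto, s, spec.n_on)
                    fp = _members(rng, proto_i, 1, p)[0]
                rows.append(
                    {
                        "compound_id": cid,
                        "target_id": ds.target_id,
                        "protein_class": ds.protein_class,
                        "true_label": label_name,
                    }
                )
                fps.append(fp)
    batch = pd.DataFrame(rows)
    fp_matrix = np.vstack(fps)

    if error_gradient:
        # flip truth labels with probability growing with distance to the
        # training set of the originally assigned class
        from .compounds import knn_mean_similarity_matrix

        flip = {"activating": "inhibiting", "inhibiting": "activating"}
        for label_name in ("activating", "inhibiting"):
            sel = batch["true_label"] == label_name
            if not sel.any():
                continue
            train = getattr_train(base, label_name)
            sims = knn_mean_similarity_matrix(fp_matrix[sel.values], train, k=5)
            rng = np.random.default_rng(derive_seed(seed, "gradient", label_name))
            p_flip = np.clip(1.2 * (1.0 - sims) - 0.05, 0.0, 0.95)
            do_flip = rng.random(sims.size) < p_flip
            idx = batch.index[sel][do_flip]
            batch.loc[idx, "true_label"] = flip[label_name]
    return batch, fp_matrix


def getattr_train(base: list[TargetDataset], label_name: str) -> np.ndarray:
    """Pooled training fingerprints of one functional label across targets."""
    mats = [
        np.atleast_2d(getattr(ds, f"{label_name}_fp"))
        for ds in base
        if getattr(ds, f"{label_name}_fp") is not None
    ]
    return np.vstack(mats)


# ---------------------------------------------------------------------------
# SMILES-emitting mode (fragment grammar) for end-to-end runs


_CORES = (
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCNCC1",  # piperidine
    "c1ccsc1",  # thiophene
    "C1CCOCC1",  # oxane
)
_LINKERS = ("CC(=O)N", "CCO", "COC", "CS(=O)(=O)", "C(=O)O", "CNC(=O)", "CCC")
_CAPS = ("C", "CC", "CCl", "C(F)(F)F", "OC", "N", "CBr", "CO")
# only these are chemically valid when prepended to a linker
_PREFIX_CAPS = ("C", "CC", "OC", "N", "CO")

_BAO_TERMS_ACT = ("Activation", "Agonism", "Opening")
_BAO_TERMS_INH = ("Antagonism", "Blocking", "Closing", "Inhibition", "Inverse agonism")


def sample_smiles(rng: np.random.Generator) -> str:
    """Draw a drug-like SMILES from the fragment grammar (core–linker–core
    with a terminal cap); MW falls in roughly 150–450 Da."""
    core1 = _CORES[rng.integers(len(_CORES))]
    linker = _LINKERS[rng.integers(len(_LINKERS))]
    core2 = _CORES[rng.integers(len(_CORES))]
    if rng.random() < 0.3:
        cap = _PREFIX_CAPS[rng.integers(len(_PREFIX_CAPS))]
        return f"{cap}{linker}{core1}"
    cap = _CAPS[rng.integers(len(_CAPS))]
    return f"{core1}{linker}{core2}{cap}"


def generate_annotation_table(
    n_targets: int = 2,
    n_activating: int = 12,
    n_inhibiting: int = 15,
    n_binding: int = 6,
    n_inactive: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit the annotation CSV the dataset-assembly pipeline consumes, with
    grammar-sampled SMILES.

    Molecules carry no engineered cluster structure; this mode exists to
    exercise the full standardization → fingerprint → assembly → model path
    end to end.
    """
    rng = np.random.default_rng(derive_seed(seed, "annotations"))
    rows = []
    counter = 0
    seen: set[str] = set()

    def new_compound():
        nonlocal counter
        for _ in range(200):
            smi = sample_smiles(rng)
            if smi not in seen:
                seen.add(smi)
                counter += 1
                return f"CMPD{counter:05d}", smi
        counter += 1  # grammar exhausted at tiny scale: allow a duplicate structure
        return f"CMPD{counter:05d}", smi

    for t in range(n_targets):
        tid = f"SYN{t:02d}"
        pclass = PROTEIN_CLASSES[t % len(PROTEIN_CLASSES)]
        for _ in range(n_activating):
            cid, smi = new_compound()
            rows.append(
                dict(
                    compound_id=cid,
                    smiles=smi,
                    target_id=tid,
                    protein_class=pclass,
                    endpoint_type="EC50",
                    value_um=float(np.round(rng.uniform(0.01, 9.9), 3)),
                    bao_term=_BAO_TERMS_ACT[rng.integers(len(_BAO_TERMS_ACT))],
                )
            )
        for _ in range(n_inhibiting):
            cid, smi = new_compound()
            rows.append(
                dict(
                    compound_id=cid,
                    smiles=smi,
                    target_id=tid,
                    protein_class=pclass,
                    endpoint_type="IC50",
                    value_um=float(np.round(rng.uniform(0.01, 9.9), 3)),
                    bao_term=_BAO_TERMS_INH[rng.integers(len(_BAO_TERMS_INH))],
                )
            )
        for _ in range(n_binding):
            cid, smi = new_compound()
            rows.append(
                dict(
                    compound_id=cid,
                    smiles=smi,
                    target_id=tid,
                    protein_class=pclass,
                    endpoint_type="Ki",
                    value_um=float(np.round(rng.uniform(0.01, 9.9), 3)),
                    bao_term="",
                )
            )
        for _ in range(n_inactive):
            cid, smi = new_compound()
            rows.append(
                dict(
                    compound_id=cid,
                    smiles=smi,
                    target_id=tid,
                    protein_class=pclass,
                    endpoint_type="IC50",
                    value_um=float(np.round(rng.uniform(10.01, 500.0), 2)),
                    bao_term="",
                )
            )
    return pd.DataFrame(rows)
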