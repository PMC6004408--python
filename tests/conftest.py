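import numpy as np
import pytest

from moapred.dataset import TargetDataset
from moapred.synthetic import SyntheticSpec, generate_universe


def make_fp(on_bits, n_bits=2048):
    fp = np.zeros(n_bits, dtype=np.uint8)
    fp[list(on_bits)] = 1
    return fp


@pytest.fixture(scope="session")
def small_universe():
    """Two-target universe at the default (realistic) similarity structure,
    small enough for fast model training."""
    spec = SyntheticSpec(
        n_targets=2,
        n_activating=20,
        n_inhibiting=40,
        imbalance_ratio=None,
        n_binding=10,
        n_inactive=80,
        seed=11,
    )
    return generate_universe(spec)


@pytest.fixture(scope="session")
def separable_universe():
    """Three targets with well-separated activator/inhibitor clusters."""
    spec = SyntheticSpec(
        n_targets=3,
        n_activating=25,
        n_inhibiting=50,
        imbalance_ratio=None,
        n_binding=10,
        n_inactive=100,
        target_function_separation=0.5,
        binder_inhibitor_overlap=0.7,
        seed=23,
    )
    return generate_universe(spec)


@pytest.fixture()
def toy_dataset():
    """Hand-built 4-class target dataset with orthogonal block fingerprints."""
    rng = np.random.default_rng(0)

    def block(lo, n, rows):
        out = np.zeros((rows, 2048), dtype=np.uint8)
        for r in range(rows):
            on = rng.choice(np.arange(lo, lo + 2 * n), size=n, replace=False)
            out[r, on] = 1
        return out

    act = block(0, 60, 12)
    inh = block(200, 60, 15)
    bind = block(400, 60, 6)
    inact = block(800, 60, 30)
    return TargetDataset(
        target_id="TOY",
        protein_class="GPCR",
        activating_ids=[f"a{i}" for i in range(12)],
        inhibiting_ids=[f"i{i}" for i in range(15)],
        binding_ids=[f"b{i}" for i in range(6)],
        inactive_ids=[f"n{i}" for i in range(30)],
        activating_fp=act,
        inhibiting_fp=inh,
        binding_fp=bind,
        inactive_fp=inact,
        inactive_provenance=["experimental"] * 30,
    )
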