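"""Shared chemistry substrate: standardization, drug-likeness filters,
circular fingerprints and Tanimoto similarity.

Fingerprints are plain ``numpy`` uint8 arrays of length 2048 (one element per
bit); sets of fingerprints are stacked row-wise into ``(n, 2048)`` matrices.
All similarity helpers operate on these arrays directly so that the synthetic
benchmark generator, which emits bit vectors without underlying molecules,
shares the same code path as RDKit-derived fingerprints.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

N_BITS_DEFAULT = 2048
RADIUS_DEFAULT = 2

# Atomic numbers excluded from the drug-like space: Sc..Ge, Kr..Te, and
# everything past iodine. The typical organic elements (H, B, C, N, O, F, Si,
# P, S, Cl, As, Se, Br, I and light alkali/alkaline-earth counter-ions)
# remain. Configurable per call site.
EXCLUDED_Z_DEFAULT = (
    frozenset(range(21, 33)) | frozenset(range(36, 53)) | frozenset(range(54, 119))
)

MW_RANGE_DEFAULT = (100.0, 1000.0)


@dataclass
class CompoundRecord:
    """One molecule, before/after standardization.

    ``std_smiles`` is ``None`` when the raw input could not be parsed;
    ``passed_filters`` is only meaningful after :func:`filter_druglike`.
    """

    compound_id: str
    raw_smiles: str
    std_smiles: str | None = None
    passed_filters: bool = False

    @property
    def is_valid(self) -> bool:
        return self.std_smiles is not None


_largest_fragment = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def standardize_compound(raw_smiles: str, compound_id: str = "") -> CompoundRecord:
    """Standardize a raw SMILES into a canonical parent structure.

    Pipeline: sanitize → keep the largest organic fragment (salt/solvent
    stripping) → neutralize charges where chemically valid → canonical SMILES.
    Unparsable input yields an invalid record rather than an exception; an
    empty string is an input error.
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        raise ValueError("raw_smiles must be non-empty text")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return CompoundRecord(compound_id=compound_id, raw_smiles=raw_smiles)
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = _largest_fragment.choose(mol)
        mol = _uncharger.uncharge(mol)
        std = Chem.MolToSmiles(mol)
    except Exception:  # rare RDKit sanitization corner cases
        return CompoundRecord(compound_id=compound_id, raw_smiles=raw_smiles)
    return CompoundRecord(compound_id=compound_id, raw_smiles=raw_smiles, std_smiles=std)


def filter_druglike(
    record: CompoundRecord,
    mw_range: tuple[float, float] = MW_RANGE_DEFAULT,
    excluded_z: frozenset[int] = EXCLUDED_Z_DEFAULT,
) -> bool:
    """Drug-likeness predicate: ≥1 carbon, MW within ``mw_range`` (inclusive)
    and no atom from the excluded element set."""
    if not record.is_valid:
        raise ValueError(f"cannot filter invalid record {record.compound_id!r}")
    mol = Chem.MolFromSmiles(record.std_smiles)
    if mol is None:  # invariant violation, treat as filter failure
        return False
    zs = [atom.GetAtomicNum() for atom in mol.GetAtoms()]
    if 6 not in zs:
        return False
    if any(z in excluded_z for z in zs):
        return False
    mw = Descriptors.MolWt(mol)
    return mw_range[0] <= mw <= mw_range[1]


def morgan_fingerprint(
    record: CompoundRecord | str,
    n_bits: int = N_BITS_DEFAULT,
    radius: int = RADIUS_DEFAULT,
) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint as a uint8 bit vector.

    Deterministic: the same standardized structure always maps to the same
    bits. Accepts a :class:`CompoundRecord` or a bare SMILES string.
    """
    smiles = record if isinstance(record, str) else record.std_smiles
    if smiles is None:
        raise ValueError("cannot fingerprint an invalid record")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def fingerprint_matrix(records: Iterable[CompoundRecord | str], **kw) -> np.ndarray:
    rows = [morgan_fingerprint(r, **kw) for r in records]
    if not rows:
        return np.zeros((0, kw.get("n_bits", N_BITS_DEFAULT)), dtype=np.uint8)
    return np.vstack(rows)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| between two bit vectors.

    Defined as 0.0 when both vectors are all-zero (the 0/0 case).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        return 0.0
    return inter / union


def bulk_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between row sets A (n,d) and B (m,d)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def knn_mean_similarity(
    query: np.ndarray, reference: np.ndarray, k: int = 5
) -> float:
    """Mean Tanimoto of the k most similar reference fingerprints.

    Uses all references when fewer than k are available. With k=1 this is the
    nearest-neighbor similarity.
    """
    reference = np.atleast_2d(reference)
    if reference.shape[0] == 0:
        raise ValueError("reference set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = bulk_tanimoto(np.atleast_2d(query), reference)[0]
    k_eff = min(k, sims.size)
    top = np.partition(sims, sims.size - k_eff)[sims.size - k_eff :]
    return float(top.mean())


def knn_mean_similarity_matrix(
    queries: np.ndarray, reference: np.ndarray, k: int = 5
) -> np.ndarray:
    """Vectorized :func:`knn_mean_similarity` for a matrix of queries."""
    reference = np.atleast_2d(reference)
    if reference.shape[0] == 0:
        raise ValueError("reference set is empty")
    sims = bulk_tanimoto(np.atleast_2d(queries), reference)
    k_eff = min(k, sims.shape[1])
    top = np.partition(sims, sims.shape[1] - k_eff, axis=1)[:, sims.shape[1] - k_eff :]
    return top.mean(axis=1)


# ---------------------------------------------------------------------------
# I/O: .smi line format and compound CSV


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file (``SMILES<whitespace>id`` per line) → [(smiles, id)]."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{i + 1}"
            out.append((smiles, cid))
    return out


def write_smiles_file(path, records: Sequence[CompoundRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.std_smiles or rec.raw_smiles}\t{rec.compound_id}\n")


def read_compound_csv(path) -> list[tuple[str, str]]:
    """Read a CSV with columns compound_id, smiles → [(smiles, id)]."""
    out: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"compound_id", "smiles"} <= set(
            reader.fieldnames
        ):
            raise ValueError("compound CSV requires columns: compound_id, smiles")
        for row in reader:
            out.append((row["smiles"], row["compound_id"]))
    return out
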