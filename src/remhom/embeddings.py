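"""Fixed-length protein embeddings: storage, pooling and label alignment.

Protein language models (pLMs) such as ProtT5 and ProtBERT emit one vector
per residue; a per-protein embedding is obtained by mean-pooling over
residues.  This module stores such pooled vectors keyed by domain id
(HDF5 or delimited text), aligns them with labelled domain records into a
feature matrix, and generates synthetic embeddings with controllable class
separation so every downstream component can be exercised without running a
pLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np

from .records import DomainRecord, LabelSpace, OTHER_LABEL

__all__ = [
    "EmbeddingStore",
    "FeatureMatrix",
    "SyntheticConfig",
    "pool_residue_embeddings",
    "save_store",
    "load_store",
    "align_to_labels",
    "length_features",
    "make_synthetic",
]


@dataclass
class EmbeddingStore:
    """Mapping from domain id to a fixed-length embedding vector."""

    vectors: Dict[str, np.ndarray]
    pooled: bool = True
    source_tag: str = "unknown"

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("embedding store is empty")
        dims = {v.shape[-1] for v in self.vectors.values()}
        if len(dims) != 1:
            offender = next(
                k for k, v in self.vectors.items()
                if v.shape[-1] != next(iter(dims))
            )
            raise ValueError(
                f"inconsistent embedding dimensions {sorted(dims)} "
                f"(e.g. id {offender!r})"
            )

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[-1]

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self.vectors

    def __getitem__(self, domain_id: str) -> np.ndarray:
        return self.vectors[domain_id]


@dataclass
class FeatureMatrix:
    """Row-aligned features, integer labels and ids over a label space."""

    X: np.ndarray
    y: np.ndarray
    ids: List[str]
    label_space: LabelSpace

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        n = self.X.shape[0]
        if len(self.y) != n or len(self.ids) != n:
            raise ValueError("X, y and ids must agree in length")
        if n and (self.y.min() < 0 or self.y.max() >= len(self.label_space)):
            raise ValueError("labels outside the label space")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def labels(self) -> List[str]:
        return [self.label_space.decode(i) for i in self.y]


def pool_residue_embeddings(matrix) -> np.ndarray:
    """Mean-pool a residues × dim matrix into one per-protein vector.

    Arithmetic column mean — the standard reduction for ProtT5/ProtBERT
    per-residue output; permutation-invariant over residues.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("expected a non-empty residues x dim matrix")
    return matrix.mean(axis=0)


# ---------------------------------------------------------------------------
# persistence: HDF5 (ids table + matrix) or delimited text (id, v1..vd)
# ---------------------------------------------------------------------------

def save_store(store: EmbeddingStore, path, float32: bool = False) -> None:
    """Write a store to ``.h5``/``.hdf5`` or ``.csv``/``.tsv`` by extension.

    64-bit floats by default so that load(save(s)) is exact.
    """
    path = Path(path)
    ids = sorted(store.vectors)
    X = np.stack([store.vectors[i] for i in ids])
    if float32:
        X = X.astype(np.float32)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))
            fh.create_dataset("embeddings", data=X)
            fh.attrs["pooled"] = store.pooled
            fh.attrs["source_tag"] = store.source_tag
    elif path.suffix in (".csv", ".tsv"):
        sep = "," if path.suffix == ".csv" else "\t"
        with open(path, "w") as fh:
            fh.write(f"# source_tag={store.source_tag} pooled={store.pooled}\n")
            for i, row in zip(ids, X):
                fh.write(i + sep + sep.join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unsupported store extension: {path.suffix!r}")


def load_store(path) -> EmbeddingStore:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ids = [
                i.decode() if isinstance(i, bytes) else str(i) for i in fh["ids"][:]
            ]
            X = np.asarray(fh["embeddings"][:], dtype=np.float64)
            pooled = bool(fh.attrs.get("pooled", True))
            tag = str(fh.attrs.get("source_tag", "unknown"))
        vectors = {i: X[k] for k, i in enumerate(ids)}
        return EmbeddingStore(vectors, pooled=pooled, source_tag=tag)
    sep = "," if path.suffix == ".csv" else "\t"
    vectors: Dict[str, np.ndarray] = {}
    tag, pooled = "unknown", True
    widths: Dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("source_tag="):
                        tag = token.split("=", 1)[1]
                    elif token.startswith("pooled="):
                        pooled = token.split("=", 1)[1] == "True"
                continue
            fields = line.split(sep)
            vectors[fields[0]] = np.array(fields[1:], dtype=np.float64)
            widths[fields[0]] = len(fields) - 1
    if len(set(widths.values())) > 1:
        ref = next(iter(widths.values()))
        offender = next(i for i, w in widths.items() if w != ref)
        raise ValueError(f"ragged vector lengths in {path} (e.g. id {offender!r})")
    return EmbeddingStore(vectors, pooled=pooled, source_tag=tag)


def align_to_labels(
    store: EmbeddingStore,
    records: Sequence[DomainRecord],
    label_space: LabelSpace,
    strict: bool = True,
) -> FeatureMatrix:
    """Stack embeddings in record order with labels encoded by the space.

    With ``strict=False`` records missing from the store are dropped with a
    warning instead of raising.
    """
    missing = [r.domain_id for r in records if r.domain_id not in store]
    if missing:
        if strict:
            raise KeyError(f"ids missing from embedding store: {missing}")
        warnings.warn(
            f"dropping {len(missing)} record(s) missing from store", stacklevel=2
        )
    kept = [r for r in records if r.domain_id in store]
    X = np.stack([store[r.domain_id] for r in kept]) if kept else np.empty((0, store.dim))
    y = np.array([label_space.encode(r.superfamily) for r in kept], dtype=np.int64)
    return FeatureMatrix(X, y, [r.domain_id for r in kept], label_space)


def length_features(
    records: Sequence[DomainRecord],
    label_space: LabelSpace,
    mean: Optional[float] = None,
    std: Optional[float] = None,
) -> Tuple[FeatureMatrix, float, float]:
    """Single-column z-scored sequence-length features.

    Standardisation constants default to the given records' own mean/sd
    (pass the training-set values for held-out data).  Returns the matrix
    plus the constants used; sd guard of 1 for degenerate inputs.
    """
    if not records:
        raise ValueError("no records")
    lengths = np.array([len(r.sequence) for r in records], dtype=np.float64)
    if mean is None:
        mean = float(lengths.mean())
    if std is None:
        std = float(lengths.std(ddof=0)) if len(lengths) > 1 else 1.0
        if std == 0.0:
            std = 1.0
    X = ((lengths - mean) / std)[:, None]
    y = np.array([label_space.encode(r.superfamily) for r in records], dtype=np.int64)
    return FeatureMatrix(X, y, [r.domain_id for r in records], label_space), mean, std


# ---------------------------------------------------------------------------
# synthetic embeddings
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Controls for the synthetic embedding generator.

    ``separation`` is the pairwise inter-centroid Euclidean distance in
    units of the within-class standard deviation (which is 1): 0 gives
    indistinguishable classes, ~8 gives essentially separable ones.
    ``other_fraction`` adds a diffuse mixed-bag class holding that fraction
    of the named-class total.
    """

    n_classes: int = 10
    dim: int = 64
    n_per_class: Union[int, Sequence[int]] = 50
    separation: float = 8.0
    other_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not (0.0 <= self.other_fraction <= 1.0):
            raise ValueError("other_fraction must be in [0, 1]")


_SYN_AA = "ACDEFGHIKLMNPQRSTVWY"


def _synthetic_label(k: int) -> str:
    # plausible-looking dotted CATH nodes spread over classes 1..3
    return f"{k % 3 + 1}.{10 * (k % 6 + 1)}.{k % 9 + 1}0.{k + 10}"


def class_centroids(config: SyntheticConfig) -> np.ndarray:
    """Centroids with all pairwise distances exactly ``separation``.

    Scaled-simplex construction: mutually orthonormal directions (via QR of
    a seeded Gaussian matrix) scaled by separation/sqrt(2), so every pair of
    centroids is separated by exactly ``separation`` within-class sigmas.
    Requires dim >= n_classes.
    """
    if config.n_classes > config.dim:
        raise ValueError("simplex construction needs dim >= n_classes")
    rng = np.random.default_rng(config.seed)
    G = rng.standard_normal((config.dim, config.n_classes))
    Q, _ = np.linalg.qr(G)
    return (config.separation / np.sqrt(2.0)) * Q.T


def make_synthetic(config: SyntheticConfig) -> Tuple[EmbeddingStore, List[DomainRecord]]:
    """Generate a labelled synthetic embedding store.

    Named-class members are centroid + isotropic unit Gaussian noise.  The
    optional "other" class is a broad mixture: each member sits on its own
    random centroid drawn uniformly within the centroid shell, modelling the
    heterogeneous mixed-bag class.  Matching domain records carry synthetic
    sequences whose lengths correlate with class (so length-only baselines
    have signal to find).  Fully deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    centroids = class_centroids(config)
    if isinstance(config.n_per_class, int):
        per_class = [config.n_per_class] * config.n_classes
    else:
        per_class = list(config.n_per_class)
        if len(per_class) != config.n_classes:
            raise ValueError("n_per_class list must have n_classes entries")

    vectors: Dict[str, np.ndarray] = {}
    records: List[DomainRecord] = []

    def add(domain_id: str, vec: np.ndarray, label: str, length: int) -> None:
        vectors[domain_id] = vec
        seq = "".join(rng.choice(list(_SYN_AA), size=max(length, 10)))
        records.append(DomainRecord(domain_id, seq, label, "pdb", "synthetic"))

    for k in range(config.n_classes):
        label = _synthetic_label(k)
        base_len = 80 + 15 * k
        for j in range(per_class[k]):
            vec = centroids[k] + rng.standard_normal(config.dim)
            length = base_len + int(rng.integers(-5, 6))
            add(f"syn_{k:03d}_{j:04d}", vec, label, length)

    n_other = int(round(config.other_fraction * sum(per_class)))
    radius = config.separation / np.sqrt(2.0)
    for j in range(n_other):
        direction = rng.standard_normal(config.dim)
        direction /= np.linalg.norm(direction)
        centre = rng.uniform(0.0, radius + 1e-9) * direction
        vec = centre + rng.standard_normal(config.dim)
        length = 60 + int(rng.integers(0, 120))
        add(f"syn_other_{j:04d}", vec, OTHER_LABEL, length)

    store = EmbeddingStore(vectors, pooled=True, source_tag="synthetic")
    return store, records
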