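"""Core domain records, label spaces and dataset containers.

A *domain* is a structural unit of a protein classified in the CATH
hierarchy (Class.Architecture.Topology.Homologous-superfamily, written as a
dotted node string such as ``3.40.50.300``).  Test and validation domains
come from experimentally determined structures (PDB); training domains come
from sequence-level superfamily assignments (Gene3D).  Superfamilies too
sparsely populated to be modelled individually are pooled into a single
mixed-bag ``"other"`` class.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUPERFAMILY_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
OTHER_LABEL = "other"
#: Reserved outcome for queries without any database hit; never a class label.
NO_HIT_LABEL = "no_hit"

_VALID_SOURCES = ("pdb", "gene3d")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def is_superfamily_label(label: str) -> bool:
    """True for dotted 4-field CATH node strings like ``3.40.50.300``."""
    return bool(SUPERFAMILY_PATTERN.match(label))


@dataclass(frozen=True)
class DomainRecord:
    """One protein domain with its superfamily label.

    Parameters
    ----------
    domain_id : str
        Unique identifier within a collection.
    sequence : str
        Amino-acid sequence, uppercase, 20 canonical letters plus ``X``.
    superfamily : str
        Dotted CATH node string or the literal ``"other"``.
    source : str
        ``"pdb"`` (experimental structure) or ``"gene3d"`` (sequence-level
        assignment).
    organism : str, optional
        Free-text organism tag.
    """

    domain_id: str
    sequence: str
    superfamily: str
    source: str
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.domain_id}: sequence must be non-empty")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.domain_id}: invalid sequence characters {sorted(bad)}"
            )
        if self.superfamily != OTHER_LABEL and not is_superfamily_label(self.superfamily):
            raise ValueError(
                f"{self.domain_id}: superfamily {self.superfamily!r} is neither "
                f"a dotted CATH node nor {OTHER_LABEL!r}"
            )
        if self.source not in _VALID_SOURCES:
            raise ValueError(
                f"{self.domain_id}: source must be one of {_VALID_SOURCES}, "
                f"got {self.source!r}"
            )

    def relabelled(self, superfamily: str) -> "DomainRecord":
        return DomainRecord(
            self.domain_id, self.sequence, superfamily, self.source, self.organism
        )


@dataclass(frozen=True)
class LabelSpace:
    """Ordered set of named superfamilies, optionally closed by ``"other"``.

    The integer encoding is positional; when ``has_other`` is true the
    ``"other"`` class always takes the last index.
    """

    named_superfamilies: tuple
    has_other: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "named_superfamilies", tuple(self.named_superfamilies)
        )
        labels = self.named_superfamilies
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate superfamily labels")
        for lab in labels:
            if not is_superfamily_label(lab):
                raise ValueError(f"not a CATH node string: {lab!r}")

    @property
    def labels(self) -> tuple:
        if self.has_other:
            return self.named_superfamilies + (OTHER_LABEL,)
        return self.named_superfamilies

    @property
    def index_of(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index_of

    def encode(self, label: str) -> int:
        try:
            return self.index_of[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in label space") from None

    def decode(self, index: int) -> str:
        return self.labels[index]


@dataclass(frozen=True)
class ClusterMap:
    """Member-to-representative assignment from an identity clustering."""

    assignments: Mapping[str, str]
    identity_threshold: float

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("cluster map is empty")
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        for rep in set(self.assignments.values()):
            if self.assignments.get(rep) != rep:
                raise ValueError(f"representative {rep!r} does not map to itself")

    @property
    def representatives(self) -> frozenset:
        return frozenset(self.assignments.values())

    def is_representative(self, domain_id: str) -> bool:
        return self.assignments.get(domain_id) == domain_id

    def members_of(self, representative: str) -> list:
        return sorted(
            m for m, r in self.assignments.items() if r == representative
        )


@dataclass
class DatasetConfig:
    """Knobs of the dataset build.

    ``redundancy_identity`` is the pairwise-identity ceiling enforced between
    the three sets (default 0.20, i.e. remote-homologue regime).
    ``other_undersample_target`` caps the mixed-bag training class; ``"auto"``
    uses the median per-superfamily training count.
    """

    redundancy_identity: float = 0.20
    min_pdb_members: int = 2
    other_undersample_target: object = "auto"
    top_k: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.redundancy_identity <= 1.0):
            raise ValueError("redundancy_identity must be in (0, 1]")
        if self.min_pdb_members < 2:
            raise ValueError("min_pdb_members must be >= 2")


@dataclass
class SplitDataset:
    """Train/validation/test partition over a shared label space."""

    train: list
    validation: list
    test: list
    label_space: LabelSpace
    provenance: str = ""

    def validate(self) -> None:
        ids_by_set = [
            {r.domain_id for r in part}
            for part in (self.train, self.validation, self.test)
        ]
        for part, ids in zip((self.train, self.validation, self.test), ids_by_set):
            if len(ids) != len(part):
                raise ValueError("duplicate domain_id within a set")
        if (ids_by_set[0] & ids_by_set[1]) or (ids_by_set[0] & ids_by_set[2]) or (
            ids_by_set[1] & ids_by_set[2]
        ):
            raise ValueError("train/validation/test sets are not disjoint")
        for part in (self.train, self.validation, self.test):
            for rec in part:
                if rec.superfamily not in self.label_space:
                    raise ValueError(
                        f"{rec.domain_id}: label {rec.superfamily!r} outside label space"
                    )

    def log(self, message: str) -> None:
        self.provenance += message.rstrip("\n") + "\n"


# ---------------------------------------------------------------------------
# FASTA I/O.  Header convention: >domain_id|superfamily|source[|organism]
# ---------------------------------------------------------------------------

def _record_to_seqrecord(rec: DomainRecord) -> SeqRecord:
    parts = [rec.domain_id, rec.superfamily, rec.source]
    if rec.organism:
        parts.append(rec.organism)
    header = "|".join(parts)
    return SeqRecord(Seq(rec.sequence), id=header, description="")


def write_fasta(records: Iterable[DomainRecord], path) -> None:
    SeqIO.write([_record_to_seqrecord(r) for r in records], str(path), "fasta")


def read_fasta(path) -> list:
    """Read domain records from FASTA using the pipe-separated header."""
    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        parts = sr.id.split("|")
        if len(parts) not in (3, 4):
            raise ValueError(
                f"{path}: header {sr.id!r} is not 'id|superfamily|source[|organism]'"
            )
        organism = parts[3] if len(parts) == 4 else None
        out.append(
            DomainRecord(parts[0], str(sr.seq).upper(), parts[1], parts[2], organism)
        )
    return out


def save_split(split: SplitDataset, outdir) -> None:
    """Write a split as three FASTA files plus a JSON manifest.

    The serialization is deterministic: identical splits produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, part in (
        ("train", split.train),
        ("validation", split.validation),
        ("test", split.test),
    ):
        write_fasta(part, outdir / f"{name}.fasta")
    manifest = {
        "named_superfamilies": list(split.label_space.named_superfamilies),
        "has_other": split.label_space.has_other,
        "counts": {
            "train": len(split.train),
            "validation": len(split.validation),
            "test": len(split.test),
        },
        "provenance": split.provenance,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def load_split(outdir) -> SplitDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    label_space = LabelSpace(
        tuple(manifest["named_superfamilies"]), manifest["has_other"]
    )
    split = SplitDataset(
        train=read_fasta(outdir / "train.fasta"),
        validation=read_fasta(outdir / "validation.fasta"),
        test=read_fasta(outdir / "test.fasta"),
        label_space=label_space,
        provenance=manifest.get("provenance", ""),
    )
    split.validate()
    return split
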