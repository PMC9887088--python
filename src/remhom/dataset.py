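"""Leakage-free dataset construction for remote-homology benchmarks.

The build pipeline mirrors the standard recipe for evaluating remote
homologue detection: cluster experimentally characterised (PDB) domains at a
low identity threshold, keep superfamilies with at least two non-redundant
representatives, split those representatives between test and validation,
train on sequence-level (Gene3D) assignments, then purge any cross-set pair
above the identity ceiling so that test domains share <20% identity with
anything seen in training.

The clusterer and purger here run all-pairs global alignments and are meant
for fixture-scale collections (a few hundred records); production-scale
clustering is delegated to external tools such as MMseqs2, whose cluster-TSV
output :func:`parse_cluster_tsv` consumes.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from Bio import Align

from .records import (
    ClusterMap,
    DatasetConfig,
    DomainRecord,
    LabelSpace,
    OTHER_LABEL,
    SplitDataset,
)

__all__ = [
    "parse_cluster_tsv",
    "pairwise_identity",
    "greedy_identity_cluster",
    "select_superfamilies",
    "assemble_splits",
    "purge_cross_set_homologs",
    "undersample_other",
    "select_top_k_superfamilies",
    "build_dataset",
]


def parse_cluster_tsv(path, identity_threshold: float) -> ClusterMap:
    """Parse a two-column (representative, member) cluster TSV.

    This is the MMseqs2 ``createtsv`` dialect: one tab-separated pair per
    line.  Representatives are self-assigned even when never listed as their
    own member.
    """
    assignments = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            rep, member = fields
            assignments[member] = rep
            assignments.setdefault(rep, rep)
    if not assignments:
        raise ValueError(f"{path}: empty cluster file")
    # representative self-assignment takes precedence over stray rows
    for rep in set(assignments.values()):
        assignments[rep] = rep
    return ClusterMap(assignments, identity_threshold)


# Global alignment with match +1, mismatch 0, linear gap -1.  Identity is
# counted on the first optimal path: matches / alignment columns.
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Defined as identical aligned positions divided by alignment length
    (gap columns included) on an optimal global alignment under the scoring
    match +1 / mismatch 0 / gap −1.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def greedy_identity_cluster(
    records: Sequence[DomainRecord], threshold: float, seed: int = 0
) -> ClusterMap:
    """Longest-first greedy clustering at a pairwise-identity threshold.

    Records are visited longest first (ties by id); each unassigned record
    founds a cluster and later records join the first representative they
    reach at identity >= ``threshold``.  Deterministic; quadratic, intended
    for collections of at most a few hundred records.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.domain_id))
    reps: List[DomainRecord] = []
    assignments = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            assignments[rec.domain_id] = rec.domain_id
        else:
            assignments[rec.domain_id] = home.domain_id
    return ClusterMap(assignments, threshold)


def select_superfamilies(
    pdb_records: Sequence[DomainRecord],
    cluster_map: ClusterMap,
    min_pdb_members: int = 2,
) -> Tuple[list, list]:
    """Partition superfamilies into named and mixed-bag ("other") groups.

    A superfamily is *named* (modelled as its own class) when it has at least
    ``min_pdb_members`` non-redundant PDB cluster representatives — the
    minimum needed to give both the test and the validation set one member.
    """
    for rec in pdb_records:
        if rec.source != "pdb":
            raise ValueError(f"{rec.domain_id}: expected source 'pdb'")
    rep_counts: Counter = Counter()
    for rec in pdb_records:
        if cluster_map.is_representative(rec.domain_id):
            rep_counts[rec.superfamily] += 1
    named = sorted(sf for sf, c in rep_counts.items() if c >= min_pdb_members)
    other = sorted(sf for sf, c in rep_counts.items() if c < min_pdb_members)
    return named, other


def _alternating_split(items: list, rng: np.random.Generator) -> Tuple[list, list]:
    shuffled = list(items)
    rng.shuffle(shuffled)
    return shuffled[0::2], shuffled[1::2]


def assemble_splits(
    pdb_records: Sequence[DomainRecord],
    gene3d_records: Sequence[DomainRecord],
    named: Sequence[str],
    config: DatasetConfig,
) -> SplitDataset:
    """Assemble train/validation/test sets over named superfamilies + "other".

    Per superfamily the non-redundant PDB representatives are split between
    test and validation by seeded shuffle + alternation (so a family with two
    representatives contributes one to each).  All Gene3D records of named
    superfamilies form the training set; records of every non-named
    superfamily are relabelled ``"other"`` wherever they occur.
    """
    if not named:
        raise ValueError("no named superfamilies")
    named = sorted(named)
    named_set = set(named)
    rng = np.random.default_rng(config.seed)

    by_family = defaultdict(list)
    for rec in pdb_records:
        by_family[rec.superfamily].append(rec)

    test: List[DomainRecord] = []
    validation: List[DomainRecord] = []
    for family in named:
        members = sorted(by_family.get(family, []), key=lambda r: r.domain_id)
        if len(members) < 2:
            raise ValueError(
                f"superfamily {family} has {len(members)} PDB representatives; "
                "need >= 2 to populate both test and validation"
            )
        t, v = _alternating_split(members, rng)
        test.extend(t)
        validation.extend(v)

    # non-named PDB families feed the mixed-bag class of both held-out sets
    other_pdb = sorted(
        (r for f, rs in by_family.items() if f not in named_set for r in rs),
        key=lambda r: r.domain_id,
    )
    if other_pdb:
        t, v = _alternating_split(other_pdb, rng)
        test.extend(r.relabelled(OTHER_LABEL) for r in t)
        validation.extend(r.relabelled(OTHER_LABEL) for r in v)

    train = [
        rec if rec.superfamily in named_set else rec.relabelled(OTHER_LABEL)
        for rec in gene3d_records
    ]

    split = SplitDataset(
        train=train,
        validation=validation,
        test=test,
        label_space=LabelSpace(tuple(named), has_other=True),
    )
    split.log(
        f"assembled: {len(named)} named superfamilies, "
        f"train={len(train)} val={len(validation)} test={len(test)} "
        f"seed={config.seed}"
    )
    split.validate()
    return split


def purge_cross_set_homologs(split: SplitDataset, threshold: float) -> SplitDataset:
    """Remove cross-set homologue leakage above an identity threshold.

    Training records with identity >= ``threshold`` to any test or validation
    record are dropped, then validation records likewise against the test
    set.  The test set is never reduced, keeping the held-out benchmark
    fixed.  All-pairs comparison: quadratic, fixture scale.
    """
    held_out = split.test + split.validation
    kept_train = [
        rec
        for rec in split.train
        if all(
            pairwise_identity(rec.sequence, h.sequence) < threshold
            for h in held_out
        )
    ]
    kept_val = [
        rec
        for rec in split.validation
        if all(
            pairwise_identity(rec.sequence, t.sequence) < threshold
            for t in split.test
        )
    ]
    out = SplitDataset(
        train=kept_train,
        validation=kept_val,
        test=list(split.test),
        label_space=split.label_space,
        provenance=split.provenance,
    )
    out.log(
        f"purged homologs at identity >= {threshold}: "
        f"train -{len(split.train) - len(kept_train)}, "
        f"validation -{len(split.validation) - len(kept_val)}"
    )
    out.validate()
    return out


def undersample_other(split: SplitDataset, target, seed: int = 0) -> SplitDataset:
    """Randomly under-sample the "other" training class to ``target`` records.

    ``target="auto"`` keeps the median per-named-superfamily training count.
    Only training records labelled "other" are touched.
    """
    other_train = [r for r in split.train if r.superfamily == OTHER_LABEL]
    named_train = [r for r in split.train if r.superfamily != OTHER_LABEL]
    if target == "auto":
        counts = Counter(r.superfamily for r in named_train)
        target = int(statistics.median(counts.values())) if counts else 0
    target = int(target)
    if target < 0:
        raise ValueError("target must be >= 0")
    if len(other_train) > target:
        rng = np.random.default_rng(seed)
        keep_idx = rng.choice(len(other_train), size=target, replace=False)
        kept = [other_train[i] for i in sorted(keep_idx)]
    else:
        kept = other_train
    # preserve original training order
    kept_ids = {r.domain_id for r in kept}
    train = [
        r
        for r in split.train
        if r.superfamily != OTHER_LABEL or r.domain_id in kept_ids
    ]
    out = SplitDataset(
        train, list(split.validation), list(split.test),
        split.label_space, split.provenance,
    )
    out.log(
        f"undersampled 'other' train records {len(other_train)} -> {len(kept)} "
        f"(target {target}, seed {seed})"
    )
    out.validate()
    return out


def select_top_k_superfamilies(split: SplitDataset, k: int) -> SplitDataset:
    """Restrict the dataset to the k superfamilies with most training records.

    Ties are broken lexicographically by label.  The "other" class and every
    record outside the selected superfamilies are dropped and the label space
    is rebuilt without a mixed-bag class.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    named = split.label_space.named_superfamilies
    if k > len(named):
        raise ValueError(f"k={k} exceeds {len(named)} named superfamilies")
    counts = Counter(
        r.superfamily for r in split.train if r.superfamily != OTHER_LABEL
    )
    ranked = sorted(named, key=lambda sf: (-counts.get(sf, 0), sf))
    keep = set(ranked[:k])
    out = SplitDataset(
        train=[r for r in split.train if r.superfamily in keep],
        validation=[r for r in split.validation if r.superfamily in keep],
        test=[r for r in split.test if r.superfamily in keep],
        label_space=LabelSpace(tuple(sorted(keep)), has_other=False),
        provenance=split.provenance,
    )
    out.log(f"selected top {k} superfamilies by training population")
    out.validate()
    return out


def build_dataset(
    pdb_records: Sequence[DomainRecord],
    gene3d_records: Sequence[DomainRecord],
    config: DatasetConfig,
    cluster_map: ClusterMap = None,
) -> SplitDataset:
    """Run the full fixture-scale build: cluster, select, split, purge,
    under-sample and optionally restrict to the top-k superfamilies."""
    if cluster_map is None:
        cluster_map = greedy_identity_cluster(
            pdb_records, config.redundancy_identity, config.seed
        )
    reps = [r for r in pdb_records if cluster_map.is_representative(r.domain_id)]
    named, _ = select_superfamilies(reps, cluster_map, config.min_pdb_members)
    split = assemble_splits(reps, gene3d_records, named, config)
    split = purge_cross_set_homologs(split, config.redundancy_identity)
    split = undersample_other(split, config.other_undersample_target, config.seed)
    if config.top_k:
        split = select_top_k_superfamilies(split, config.top_k)
    return split
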