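"""Structure-based validation of predicted superfamily assignments.

Two stages.  First, AlphaFold2 models are screened for quality: a domain is
*problematic* if its mean per-residue confidence (pLDDT, stored in the
coordinate file's B-factor field) is below 90, if it has fewer than three
secondary-structure elements, if its longest stretch of residues under 70
pLDDT covers more than a third of the domain, or if more than 70% of
residues are disordered (DSSP state '-').  Second, each surviving domain's
predicted structure is compared against relatives of its assigned
superfamily with SSAP (run externally); a match is validated when the SSAP
score reaches the class-specific threshold (71 mainly-alpha, 66
mainly-beta, 69 alpha-beta) and the structural overlap reaches 60%.  All
threshold comparisons are inclusive (a score exactly at the threshold
passes).
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .records import is_superfamily_label

__all__ = [
    "ResidueAnnotation",
    "QCThresholds",
    "AF2QCReport",
    "SsapRecord",
    "ValidationThresholds",
    "read_plddt",
    "read_dssp_ss",
    "count_sse",
    "longest_low_plddt_run",
    "disorder_fraction",
    "qc_af2_domain",
    "cath_class_of",
    "validate_match",
    "best_match_per_query",
    "summarize_ssap",
    "read_ssap_table",
]

DSSP_ALPHABET = frozenset("HGIEBTS-")
HELIX_STATES = frozenset("HGI")
STRAND_STATES = frozenset("EB")

MAINLY_ALPHA = "mainly_alpha"
MAINLY_BETA = "mainly_beta"
ALPHA_BETA = "alpha_beta"
OTHER_CLASS = "other_class"


@dataclass
class ResidueAnnotation:
    """Per-residue pLDDT values and DSSP secondary-structure states."""

    domain_id: str
    plddt: np.ndarray = field(default_factory=lambda: np.empty(0))
    ss: str = ""

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=np.float64)
        if self.plddt.size and (
            self.plddt.min() < 0.0 or self.plddt.max() > 100.0
        ):
            raise ValueError(f"{self.domain_id}: pLDDT values outside [0, 100]")
        if self.ss:
            bad = set(self.ss) - DSSP_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.domain_id}: invalid DSSP characters {sorted(bad)}"
                )
        if self.plddt.size and self.ss and len(self.ss) != self.plddt.size:
            raise ValueError(f"{self.domain_id}: plddt/ss length mismatch")


@dataclass
class QCThresholds:
    """Decision constants of the AlphaFold-model quality filter."""

    min_mean_plddt: float = 90.0
    min_sse_count: int = 3
    low_plddt_cutoff: float = 70.0
    max_problem_fraction: float = 1.0 / 3.0
    max_disorder: float = 0.70
    min_sse_length: int = 3


@dataclass
class AF2QCReport:
    domain_id: str
    mean_plddt: float
    sse_count: int
    longest_problem_run: int
    problem_fraction: float
    disorder_fraction: float
    failed_rules: List[str]

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def read_plddt(path, chain: Optional[str] = None) -> ResidueAnnotation:
    """Extract per-residue pLDDT from a PDB/mmCIF file's CA B-factors.

    AlphaFold stores pLDDT in the B-factor column; one value per residue is
    taken from the CA atom, in file order.  Multi-chain files require an
    explicit ``chain``; residues lacking a CA atom are skipped with a
    warning.
    """
    structure = gemmi.read_structure(str(path))
    if not structure or not len(structure[0]):
        raise ValueError(f"{path}: no chains found")
    model = structure[0]
    chains = {ch.name: ch for ch in model}
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path}: {len(chains)} chains present; specify one of "
                f"{sorted(chains)}"
            )
        target = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise ValueError(f"{path}: chain {chain!r} not found")
        target = chains[chain]
    values = []
    for residue in target:
        ca = residue.find_atom("CA", "*")
        if ca is None:
            warnings.warn(
                f"{path}: residue {residue.seqid.num} {residue.name} has no "
                "CA atom; skipped",
                stacklevel=2,
            )
            continue
        values.append(ca.b_iso)
    if not values:
        raise ValueError(f"{path}: no CA atoms in chain {target.name!r}")
    return ResidueAnnotation(domain_id=str(path), plddt=np.array(values))


def read_dssp_ss(path) -> str:
    """Extract the secondary-structure string from classic DSSP output.

    Reads the per-residue table (after the ``#  RESIDUE`` header line);
    column 17 holds the SS state, blank meaning none ('-').  Chain-break
    rows ('!') are skipped.
    """
    ss = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            state = line[16]
            ss.append("-" if state == " " else state)
    if not ss:
        raise ValueError(f"{path}: no residue records found (is this DSSP output?)")
    out = "".join(ss)
    bad = set(out) - DSSP_ALPHABET
    if bad:
        raise ValueError(f"{path}: unexpected DSSP states {sorted(bad)}")
    return out


def count_sse(ss: str, min_sse_length: int = 3) -> int:
    """Number of secondary-structure elements in a DSSP string.

    An element is a maximal run of helix states (H/G/I) or of strand states
    (E/B) of length >= ``min_sse_length``; helix and strand runs are counted
    separately (an 'HHHEEE' stretch is two elements).
    """
    bad = set(ss) - DSSP_ALPHABET
    if bad:
        raise ValueError(f"invalid DSSP characters {sorted(bad)}")

    def kind(c: str) -> Optional[str]:
        if c in HELIX_STATES:
            return "helix"
        if c in STRAND_STATES:
            return "strand"
        return None

    count = 0
    run_kind: Optional[str] = None
    run_len = 0
    for c in ss + "\0":  # sentinel flushes the final run
        k = kind(c) if c != "\0" else None
        if k == run_kind and k is not None:
            run_len += 1
        else:
            if run_kind is not None and run_len >= min_sse_length:
                count += 1
            run_kind, run_len = k, 1 if k else 0
    return count


def longest_low_plddt_run(plddt: Sequence[float], cutoff: float = 70.0) -> int:
    """Length of the longest contiguous stretch with pLDDT < ``cutoff``."""
    plddt = np.asarray(plddt, dtype=np.float64)
    if plddt.size == 0:
        raise ValueError("empty pLDDT vector")
    best = cur = 0
    for v in plddt:
        cur = cur + 1 if v < cutoff else 0
        best = max(best, cur)
    return best


def disorder_fraction(ss: str) -> float:
    """Fraction of residues with no DSSP secondary structure ('-')."""
    if not ss:
        raise ValueError("empty secondary-structure string")
    return ss.count("-") / len(ss)


RULE_LOW_MEAN_PLDDT = "mean_plddt"
RULE_FEW_SSE = "sse_count"
RULE_LONG_LOW_RUN = "low_plddt_run"
RULE_DISORDER = "disorder"


def qc_af2_domain(
    annotation: ResidueAnnotation, thresholds: QCThresholds = None
) -> AF2QCReport:
    """Apply the four problematic-domain rules to one AF2 model.

    A domain fails when any rule triggers: mean pLDDT below the floor,
    too few secondary-structure elements, the longest low-confidence
    stretch covering more than the allowed fraction of the domain, or
    excess disorder.  All intermediate quantities are reported.
    """
    thresholds = thresholds or QCThresholds()
    if annotation.plddt.size == 0 or not annotation.ss:
        raise ValueError(f"{annotation.domain_id}: need both pLDDT and ss")
    n = annotation.plddt.size
    mean_plddt = float(annotation.plddt.mean())
    sse = count_sse(annotation.ss, thresholds.min_sse_length)
    run = longest_low_plddt_run(annotation.plddt, thresholds.low_plddt_cutoff)
    prob_frac = run / n
    dis = disorder_fraction(annotation.ss)
    failed = []
    if mean_plddt < thresholds.min_mean_plddt:
        failed.append(RULE_LOW_MEAN_PLDDT)
    if sse < thresholds.min_sse_count:
        failed.append(RULE_FEW_SSE)
    if prob_frac > thresholds.max_problem_fraction:
        failed.append(RULE_LONG_LOW_RUN)
    if dis > thresholds.max_disorder:
        failed.append(RULE_DISORDER)
    return AF2QCReport(
        domain_id=annotation.domain_id,
        mean_plddt=mean_plddt,
        sse_count=sse,
        longest_problem_run=run,
        problem_fraction=prob_frac,
        disorder_fraction=dis,
        failed_rules=failed,
    )


# ---------------------------------------------------------------------------
# SSAP validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SsapRecord:
    """One SSAP structure comparison: query vs a superfamily relative."""

    query_id: str
    target_id: str
    target_superfamily: str
    ssap_score: float
    overlap: float  # fraction of the smaller domain covered, in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.ssap_score <= 100.0):
            raise ValueError("ssap_score must be in [0, 100]")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must be a fraction in [0, 1]")


@dataclass
class ValidationThresholds:
    """Class-specific SSAP score floors plus the overlap floor.

    Defaults: 71 for mainly-alpha (CATH class 1), 66 for mainly-beta
    (class 2), 69 for alpha-beta (class 3), with a 60% structural-overlap
    requirement; associated with a ~5% validation error rate.
    """

    score_by_class: Dict[str, float] = field(
        default_factory=lambda: {
            MAINLY_ALPHA: 71.0,
            MAINLY_BETA: 66.0,
            ALPHA_BETA: 69.0,
        }
    )
    min_overlap: float = 0.60


def cath_class_of(superfamily: str) -> str:
    """Map a dotted CATH node to its class: 1 mainly-alpha, 2 mainly-beta,
    3 alpha-beta; anything else is ``other_class``."""
    if not is_superfamily_label(superfamily):
        raise ValueError(f"malformed CATH node string: {superfamily!r}")
    first = superfamily.split(".")[0]
    return {"1": MAINLY_ALPHA, "2": MAINLY_BETA, "3": ALPHA_BETA}.get(
        first, OTHER_CLASS
    )


VALIDATED = "validated"
REJECTED_SCORE = "rejected_score"
REJECTED_OVERLAP = "rejected_overlap"
REJECTED_BOTH = "rejected_both"
NO_THRESHOLD = "no_threshold"


def validate_match(
    record: SsapRecord, thresholds: ValidationThresholds = None
) -> str:
    """Decide whether one SSAP comparison validates the predicted match.

    Validated iff the SSAP score reaches the class threshold AND the
    overlap reaches the floor; both comparisons are inclusive.  Classes
    without a threshold (CATH class 4+) return ``no_threshold``.
    """
    thresholds = thresholds or ValidationThresholds()
    cls = cath_class_of(record.target_superfamily)
    if cls not in thresholds.score_by_class:
        return NO_THRESHOLD
    score_ok = record.ssap_score >= thresholds.score_by_class[cls]
    overlap_ok = record.overlap >= thresholds.min_overlap
    if score_ok and overlap_ok:
        return VALIDATED
    if not score_ok and not overlap_ok:
        return REJECTED_BOTH
    return REJECTED_SCORE if not score_ok else REJECTED_OVERLAP


def best_match_per_query(records: Sequence[SsapRecord]) -> Dict[str, SsapRecord]:
    """The closest structural relative per query: maximal SSAP score, ties
    by maximal overlap then lexicographic target id."""
    best: Dict[str, SsapRecord] = {}
    for rec in records:
        cur = best.get(rec.query_id)
        if cur is None:
            best[rec.query_id] = rec
            continue
        key_new = (-rec.ssap_score, -rec.overlap, rec.target_id)
        key_cur = (-cur.ssap_score, -cur.overlap, cur.target_id)
        if key_new < key_cur:
            best[rec.query_id] = rec
    return best


@dataclass
class SsapSummary:
    mean: float
    median: float
    minimum: float
    q1: float
    q3: float
    maximum: float
    n: int


def _five_number(scores: Sequence[float]) -> SsapSummary:
    arr = np.asarray(scores, dtype=np.float64)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return SsapSummary(
        mean=float(arr.mean()),
        median=float(med),
        minimum=float(arr.min()),
        q1=float(q1),
        q3=float(q3),
        maximum=float(arr.max()),
        n=arr.size,
    )


def summarize_ssap(
    set_a: Sequence[float], set_b: Sequence[float]
) -> Dict[str, object]:
    """Five-number summaries of two best-match SSAP score sets plus the
    difference of their means (a - b)."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both score sets must be non-empty")
    sa, sb = _five_number(set_a), _five_number(set_b)
    return {"a": sa, "b": sb, "mean_difference": sa.mean - sb.mean}


def read_ssap_table(path, percent_overlap: bool = False) -> List[SsapRecord]:
    """Read SSAP results as TSV: query, target, superfamily, score, overlap.

    ``percent_overlap=True`` accepts overlap on the 0-100 scale and
    converts it to a fraction.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(f)}"
                )
            overlap = float(f[4])
            if percent_overlap:
                overlap /= 100.0
            records.append(
                SsapRecord(f[0], f[1], f[2], float(f[3]), overlap)
            )
    return records
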