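"""Curation of a viral contig database from pooled assemblies.

The curated open-reference database is built in four stages:

1. size selection (drop contigs < 1 kb);
2. circularity detection — a contig assembled from a circular genome ends
   where it began, leaving an exact terminal direct repeat; such contigs are
   flagged circular and the duplicated suffix is trimmed;
3. dereplication — of any two contigs aligning at >= 90% identity over
   >= 90% of the shorter one's length, only the longer is kept;
4. admission — a contig enters the database if it meets at least one of:
   (A) flagged viral by an external predictor, (B) similarity to a known
   reference virus (>= 50% identity over >= 90% of contig length),
   (C) circular, or (D) a rescue rule for novel viruses: > 3 kb, coverage
   >= 10x, and no long high-significance hit to a general nucleotide
   database (no alignment > 100 nt with e-value below threshold).

Every decision carries an audit trail of the criteria met.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import edlib
import pandas as pd
from Bio import Align

from .data_io import ContigRecord

__all__ = [
    "CurationThresholds",
    "ContigEvidence",
    "CurationDecision",
    "CurationSummary",
    "detect_circularity",
    "pairwise_identity",
    "dereplicate",
    "classify_contig",
    "curate",
    "read_evidence_table",
    "write_evidence_table",
    "write_decisions_table",
]

logger = logging.getLogger(__name__)

CRITERIA = ("A_prediction", "B_reference", "C_circular", "D_rescue")


@dataclass(frozen=True)
class CurationThresholds:
    """All tunable cutoffs of the curation pipeline (defaults in bp/fractions).

    ``nt_hit_evalue`` defaults to 1e-10; a 1e-5 variant is in circulation for
    the same rescue rule and can be set here.
    """

    min_contig_len: int = 1_000
    derep_identity: float = 0.90
    derep_coverage: float = 0.90
    ref_identity: float = 0.50
    ref_coverage: float = 0.90
    rescue_min_len: int = 3_000
    rescue_min_cov: float = 10.0
    nt_hit_max_len: int = 100
    nt_hit_evalue: float = 1e-10
    min_terminal_repeat: int = 20
    exact_alignment_max_len: int = 20_000

    def __post_init__(self) -> None:
        for name in ("derep_identity", "derep_coverage", "ref_identity", "ref_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_contig_len", "rescue_min_len", "nt_hit_max_len",
                     "min_terminal_repeat", "exact_alignment_max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nt_hit_evalue <= 0:
            raise ValueError("nt_hit_evalue must be > 0")
        if self.rescue_min_cov < 0:
            raise ValueError("rescue_min_cov must be >= 0")


@dataclass(frozen=True)
class ContigEvidence:
    """External evidence for one contig.

    ``ref_hit`` is ``(identity_fraction, fraction_of_contig_aligned)`` of the
    best reference-virus hit, or None. ``nt_hits`` is a list of
    ``(alignment_length_nt, e_value)`` from a general nucleotide screen.
    """

    contig_id: str
    viral_prediction: bool = False
    ref_hit: Optional[tuple[float, float]] = None
    nt_hits: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.ref_hit is not None:
            ident, cov = self.ref_hit
            if not (0.0 <= ident <= 1.0 and 0.0 <= cov <= 1.0):
                raise ValueError(
                    f"evidence for {self.contig_id!r}: ref_hit fractions must be in [0,1]"
                )
        object.__setattr__(self, "nt_hits", tuple(tuple(h) for h in self.nt_hits))
        for length, _ in self.nt_hits:
            if length < 1:
                raise ValueError(
                    f"evidence for {self.contig_id!r}: nt hit alignment length must be >= 1"
                )


@dataclass(frozen=True)
class CurationDecision:
    contig_id: str
    retained: bool
    criteria_met: frozenset[str]
    reason: str

    def __post_init__(self) -> None:
        if self.retained != bool(self.criteria_met):
            raise ValueError("retained must equal criteria_met non-empty")


@dataclass
class CurationSummary:
    """Per-stage and per-criterion counts of one curate() run."""

    n_input: int = 0
    n_after_size: int = 0
    n_circular: int = 0
    n_after_derep: int = 0
    n_retained: int = 0
    per_criterion: dict[str, int] = field(default_factory=dict)
    dropped_by_derep: dict[str, str] = field(default_factory=dict)
    missing_evidence: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Circularity


def _longest_border(seq: str) -> int:
    """Length of the longest proper prefix of ``seq`` that is also a suffix
    (KMP prefix function of the full string)."""
    n = len(seq)
    pi = [0] * n
    for i in range(1, n):
        k = pi[i - 1]
        while k > 0 and seq[i] != seq[k]:
            k = pi[k - 1]
        if seq[i] == seq[k]:
            k += 1
        pi[i] = k
    return pi[-1] if n else 0


def detect_circularity(
    record: ContigRecord, min_terminal_repeat: int = 20
) -> tuple[bool, ContigRecord]:
    """Detect an exact terminal direct repeat and trim the duplicated suffix.

    A contig is called circular iff its longest exact prefix-equals-suffix
    overlap has length k with ``min_terminal_repeat <= k < length/2``; the
    returned record then has the duplicated 3' suffix removed and
    ``circular=True``. Otherwise the input record is returned unchanged.
    Sequences shorter than twice the repeat threshold are never circular.
    """
    n = record.length
    if n < 2 * min_terminal_repeat:
        return False, record
    k = _longest_border(record.sequence)
    # a longest border >= half the length signals a tandem-repeat artefact,
    # not a circle: such contigs are left uncalled
    if min_terminal_repeat <= k < n / 2:
        trimmed = record.with_sequence(record.sequence[: n - k], circular=True)
        return True, trimmed
    return False, record


# ---------------------------------------------------------------------------
# Pairwise identity


class PairwiseIdentity(NamedTuple):
    identity: float
    aligned_fraction_of_shorter: float


_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def _exact_local_identity(a: str, b: str) -> PairwiseIdentity:
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    short_idx = 0 if len(a) <= len(b) else 1
    coords = alignment.aligned[short_idx]
    if len(coords) == 0:
        return PairwiseIdentity(0.0, 0.0)
    span = coords[-1][1] - coords[0][0]
    return PairwiseIdentity(identity, span / min(len(a), len(b)))


def _infix_identity(shorter: str, longer: str) -> PairwiseIdentity:
    """Containment alignment of the shorter contig inside the longer via
    edlib infix (HW) mode: exact edit-distance optimum, linear memory."""
    res = edlib.align(shorter, longer, mode="HW", task="path")
    if res["editDistance"] < 0:  # pragma: no cover - HW mode always aligns
        return PairwiseIdentity(0.0, 0.0)
    nice = edlib.getNiceAlignment(res, shorter, longer)
    matched = nice["matched_aligned"]
    columns = len(matched)
    identities = matched.count("|")
    identity = identities / columns if columns else 0.0
    # infix mode aligns the full shorter sequence (ends may be gapped against
    # the longer); the aligned span on the shorter is its full length
    return PairwiseIdentity(identity, 1.0)


def pairwise_identity(a: ContigRecord, b: ContigRecord,
                      exact_max_len: int = 20_000) -> PairwiseIdentity:
    """Identity and aligned fraction (of the shorter contig) for a contig pair.

    Exact local dynamic programming (match +1, mismatch -1, gap open -2,
    gap extend -1) when both contigs are <= ``exact_max_len``; above that an
    edit-distance containment alignment of the shorter contig into the longer.
    Symmetric in its arguments.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    if a.length > b.length:
        a, b = b, a
    if b.length <= exact_max_len:
        return _exact_local_identity(a.sequence, b.sequence)
    return _infix_identity(a.sequence, b.sequence)


# ---------------------------------------------------------------------------
# Dereplication


def dereplicate(
    records: Sequence[ContigRecord],
    thresholds: CurationThresholds = CurationThresholds(),
) -> tuple[list[ContigRecord], dict[str, str]]:
    """Keep-longer dereplication under the 90/90 rule.

    Greedy pass over records sorted by length descending (ties broken by
    lexicographic id): a record is dropped iff it aligns to an already
    retained record at identity >= derep_identity over an aligned fraction
    >= derep_coverage of the shorter contig. Deterministic and invariant to
    input order. Returns the retained records (in sorted order) and a map
    dropped_id -> the retained id that absorbed it.
    """
    ids = [r.contig_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in dereplication input")
    ordered = sorted(records, key=lambda r: (-r.length, r.contig_id))
    retained: list[ContigRecord] = []
    dropped: dict[str, str] = {}
    # a pair meeting identity i over coverage c of the shorter has infix edit
    # distance <= (1-i)+(1-c) of the shorter's length; pairs beyond a safety
    # margin of that bound cannot be redundant and skip the exact alignment
    screen_frac = min(
        1.0, 2.0 * ((1.0 - thresholds.derep_identity) + (1.0 - thresholds.derep_coverage))
    )
    for rec in ordered:
        absorbed_by = None
        for keeper in retained:
            max_dist = int(screen_frac * rec.length)
            quick = edlib.align(rec.sequence, keeper.sequence, mode="HW",
                                task="distance", k=max_dist)
            if quick["editDistance"] < 0:
                continue
            res = pairwise_identity(rec, keeper, thresholds.exact_alignment_max_len)
            if (
                res.identity >= thresholds.derep_identity
                and res.aligned_fraction_of_shorter >= thresholds.derep_coverage
            ):
                absorbed_by = keeper.contig_id
                break
        if absorbed_by is None:
            retained.append(rec)
        else:
            dropped[rec.contig_id] = absorbed_by
    return retained, dropped


# ---------------------------------------------------------------------------
# Admission criteria


def classify_contig(
    record: ContigRecord,
    evidence: ContigEvidence,
    thresholds: CurationThresholds = CurationThresholds(),
) -> CurationDecision:
    """Evaluate the four admission criteria independently.

    A: external viral prediction positive.
    B: reference-virus hit with identity >= ref_identity over >= ref_coverage
       of the contig length.
    C: contig flagged circular.
    D: rescue — length > rescue_min_len, coverage >= rescue_min_cov, and no
       nucleotide-screen hit longer than nt_hit_max_len with e-value below
       nt_hit_evalue.
    Retained iff at least one criterion holds.
    """
    if evidence.contig_id != record.contig_id:
        raise ValueError(
            f"evidence id {evidence.contig_id!r} does not match record "
            f"{record.contig_id!r}"
        )
    met: set[str] = set()
    if evidence.viral_prediction:
        met.add("A_prediction")
    if evidence.ref_hit is not None:
        ident, cov = evidence.ref_hit
        if ident >= thresholds.ref_identity and cov >= thresholds.ref_coverage:
            met.add("B_reference")
    if record.circular:
        met.add("C_circular")
    disqualifying = any(
        length > thresholds.nt_hit_max_len and evalue < thresholds.nt_hit_evalue
        for length, evalue in evidence.nt_hits
    )
    if (
        record.length > thresholds.rescue_min_len
        and record.coverage >= thresholds.rescue_min_cov
        and not disqualifying
    ):
        met.add("D_rescue")
    if met:
        reason = "retained via " + "+".join(sorted(met))
    else:
        reason = "no admission criterion met"
    return CurationDecision(
        contig_id=record.contig_id,
        retained=bool(met),
        criteria_met=frozenset(met),
        reason=reason,
    )


# ---------------------------------------------------------------------------
# Full pipeline


def curate(
    records: Sequence[ContigRecord],
    evidence_table: Mapping[str, ContigEvidence],
    thresholds: CurationThresholds = CurationThresholds(),
) -> tuple[list[ContigRecord], list[CurationDecision], CurationSummary]:
    """Run size filter -> circularity -> dereplication -> admission.

    Contigs with no entry in ``evidence_table`` get all-false defaults (and
    are listed in the summary). Idempotent: re-running on its own retained
    output reproduces it.
    """
    summary = CurationSummary(n_input=len(records))

    sized = [r for r in records if r.length >= thresholds.min_contig_len]
    summary.n_after_size = len(sized)

    processed: list[ContigRecord] = []
    for rec in sized:
        is_circ, trimmed = detect_circularity(rec, thresholds.min_terminal_repeat)
        # the size floor is re-applied post-trim: a boundary circle whose
        # terminal repeat is removed must not re-enter below the floor
        if trimmed.length < thresholds.min_contig_len:
            continue
        processed.append(trimmed)
        if is_circ:
            summary.n_circular += 1
    # circularity may carry over from input flags (idempotent reruns)
    summary.n_circular = sum(1 for r in processed if r.circular)

    retained_recs, dropped = dereplicate(processed, thresholds)
    summary.n_after_derep = len(retained_recs)
    summary.dropped_by_derep = dropped

    decisions: list[CurationDecision] = []
    curated: list[ContigRecord] = []
    per_criterion = {c: 0 for c in CRITERIA}
    for rec in retained_recs:
        evidence = evidence_table.get(rec.contig_id)
        if evidence is None:
            summary.missing_evidence.append(rec.contig_id)
            logger.warning("no evidence for contig %s; using all-false defaults", rec.contig_id)
            evidence = ContigEvidence(contig_id=rec.contig_id)
        decision = classify_contig(rec, evidence, thresholds)
        decisions.append(decision)
        for c in decision.criteria_met:
            per_criterion[c] += 1
        if decision.retained:
            curated.append(rec)
    summary.per_criterion = per_criterion
    summary.n_retained = len(curated)
    return curated, decisions, summary


# ---------------------------------------------------------------------------
# Evidence / decision tables

_EVIDENCE_COLUMNS = ["contig_id", "viral_prediction", "ref_identity", "ref_cov", "nt_hits"]


def read_evidence_table(path) -> dict[str, ContigEvidence]:
    """Read the per-contig evidence TSV.

    Columns: contig_id, viral_prediction (0/1), ref_identity, ref_cov (empty
    when no reference hit), nt_hits (semicolon-separated ``len:evalue`` pairs,
    a reduction of tabular nucleotide-screen output).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table {path} missing columns {sorted(missing)}")
    out: dict[str, ContigEvidence] = {}
    for row in df.itertuples(index=False):
        cid = str(row.contig_id)
        if cid in out:
            raise ValueError(f"duplicate contig id {cid!r} in evidence table")
        ref_hit = None
        if not _blank(row.ref_identity) and not _blank(row.ref_cov):
            ref_hit = (float(row.ref_identity), float(row.ref_cov))
        nt_hits: list[tuple[int, float]] = []
        if not _blank(row.nt_hits):
            for part in str(row.nt_hits).split(";"):
                length_s, _, evalue_s = part.partition(":")
                nt_hits.append((int(length_s), float(evalue_s)))
        out[cid] = ContigEvidence(
            contig_id=cid,
            viral_prediction=str(row.viral_prediction) in ("1", "true", "True"),
            ref_hit=ref_hit,
            nt_hits=tuple(nt_hits),
        )
    return out


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value) == "" or str(value) == "nan"


def write_evidence_table(evidence: Iterable[ContigEvidence], path) -> None:
    rows = []
    for ev in evidence:
        rows.append(
            {
                "contig_id": ev.contig_id,
                "viral_prediction": int(ev.viral_prediction),
                "ref_identity": "" if ev.ref_hit is None else repr(ev.ref_hit[0]),
                "ref_cov": "" if ev.ref_hit is None else repr(ev.ref_hit[1]),
                "nt_hits": ";".join(f"{l}:{e!r}" for l, e in ev.nt_hits),
            }
        )
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_decisions_table(decisions: Iterable[CurationDecision], path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": d.contig_id,
                "retained": int(d.retained),
                "criteria_met": "+".join(sorted(d.criteria_met)),
                "reason": d.reason,
            }
            for d in decisions
        ]
    ).to_csv(path, sep="\t", index=False)
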