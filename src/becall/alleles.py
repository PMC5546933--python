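"""Allele calling: align subcloned sequences to the amplicon and classify edits.

Each Sanger subclone is globally aligned to its reference amplicon; every
difference becomes an :class:`EditEvent` with a deamination category and a
strand call, and the event list determines the allele class and a canonical
pattern key used for clone tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .locus import (
    DOWNSTREAM,
    PAM,
    PROTOSPACER,
    UPSTREAM,
    WINDOW,
    RelPosition,
    TargetLocus,
    complement,
    normalize_seq,
    revcomp,
)

# Event kinds
SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

# Event categories
WINDOW_DEAMINATION = "window_deamination"
ON_TARGET_DEAMINATION = "on_target_deamination"
TARGET_STRAND_DEAMINATION = "target_strand_deamination"
NONCANONICAL_CONVERSION = "noncanonical_conversion"
PROXIMAL_SITE_DEAMINATION = "proximal_site_deamination"
OTHER_SUBSTITUTION = "other_substitution"
INDEL = "indel"

DEAMINATION_CATEGORIES = frozenset(
    {
        WINDOW_DEAMINATION,
        ON_TARGET_DEAMINATION,
        TARGET_STRAND_DEAMINATION,
        NONCANONICAL_CONVERSION,
        PROXIMAL_SITE_DEAMINATION,
    }
)

# Strand calls
NON_TARGET = "non_target"
TARGET = "target"
NA = "n/a"

# Allele classes
WILD_TYPE = "wild_type"
EDITED = "edited"
INDEL_ALLELE = "indel_allele"

WT_PATTERN = "WT"

# Alignment scoring: Sanger subclones are near-identical to the reference,
# so a heavy gap-open suppresses spurious indels.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0

#: Equal-length clones within this Hamming distance are called directly as
#: substitutions: any gapped alternative needs one insertion plus one
#: deletion (score <= -10), strictly worse than <= 4 mismatches (-8).
_FAST_PATH_MAX_MISMATCHES = 4


class InputError(ValueError):
    """A clone sequence violates the input contract (alphabet, length)."""


class AlignmentQualityError(RuntimeError):
    """Alignment identity fell below the configured floor; clone excluded."""

    def __init__(self, clone_id: str, identity: float, floor: float):
        self.clone_id = clone_id
        self.identity = identity
        self.floor = floor
        super().__init__(
            f"clone {clone_id!r}: alignment identity {identity:.2f} below floor {floor:.2f}"
        )


@dataclass(frozen=True)
class EditEvent:
    """One substitution or indel, in protospacer-relative coordinates.

    ``ref``/``alt`` are single bases for substitutions and the deleted /
    inserted sequence for indels, always expressed in non-target-strand
    (guide) sense. Indel coordinates are left-normalized against the
    reference amplicon; ``rel`` is the relative position of the
    reference-leftmost affected base.
    """

    rel: RelPosition
    ref: str
    alt: str
    kind: str
    category: str
    strand_call: str

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    @property
    def token(self) -> str:
        if self.kind == SUBSTITUTION:
            return f"{self.rel.value}{self.ref}>{self.alt}"
        if self.kind == DELETION:
            return f"{self.rel.value}del{self.ref}"
        return f"{self.rel.value}ins{self.alt}"


@dataclass(frozen=True)
class AlleleCall:
    """The classified outcome of one subcloned allele sequence."""

    clone_id: str
    events: tuple[EditEvent, ...]
    allele_class: str
    pattern_key: str

    @property
    def is_wild_type(self) -> bool:
        return self.allele_class == WILD_TYPE

    @property
    def has_indel(self) -> bool:
        return any(e.is_indel for e in self.events)

    @property
    def has_proximal(self) -> bool:
        return any(e.category == PROXIMAL_SITE_DEAMINATION for e in self.events)

    @property
    def has_substitution(self) -> bool:
        return any(e.kind == SUBSTITUTION for e in self.events)


def pattern_key(events: Iterable[EditEvent]) -> str:
    """Canonical text encoding of an event list (``WT`` when empty).

    Tokens are ordered by relative position (guide orientation), so the key
    is invariant to which physical strand the locus was defined on.
    """
    ordered = sorted(events, key=lambda e: (e.rel.value, e.kind, e.alt))
    tokens = [e.token for e in ordered]
    return ";".join(tokens) if tokens else WT_PATTERN


def categorize_event(
    kind: str, ref: str, alt: str, rel: RelPosition
) -> tuple[str, str]:
    """Assign (category, strand_call) to a raw event in non-target-strand sense.

    Rules: indels are ``indel``. C>T is deamination of the non-target strand
    and G>A deamination of the target strand (a target-strand C>T read in
    protospacer sense); C>G/A and G>T/C are the rarer non-canonical
    deamination outcomes with the same strand logic. Any
    deamination-consistent change outside the protospacer (upstream,
    downstream or PAM) is proximal-site deamination; inside the window it is
    window deamination; elsewhere in the protospacer, on-target (non-target
    strand) or target-strand deamination for the canonical outcomes and
    noncanonical_conversion otherwise. Everything else is
    other_substitution.
    """
    if kind != SUBSTITUTION:
        return INDEL, NA
    if ref == "C" and alt == "T":
        strand, canonical = NON_TARGET, True
    elif ref == "G" and alt == "A":
        strand, canonical = TARGET, True
    elif ref == "C" and alt in ("G", "A"):
        strand, canonical = NON_TARGET, False
    elif ref == "G" and alt in ("T", "C"):
        strand, canonical = TARGET, False
    else:
        return OTHER_SUBSTITUTION, NA
    if rel.region in (UPSTREAM, DOWNSTREAM, PAM):
        return PROXIMAL_SITE_DEAMINATION, strand
    if not canonical:
        return NONCANONICAL_CONVERSION, strand
    if rel.region == WINDOW:
        return WINDOW_DEAMINATION, strand
    assert rel.region == PROTOSPACER
    return (ON_TARGET_DEAMINATION if strand == NON_TARGET else TARGET_STRAND_DEAMINATION), strand


def _make_event(locus: TargetLocus, kind: str, offset: int, ref: str, alt: str) -> EditEvent:
    """Build an EditEvent from an amplicon-coordinate raw difference."""
    if locus.strand == "-":
        if kind == SUBSTITUTION:
            ref, alt = complement(ref), complement(alt)
        else:
            ref, alt = revcomp(ref), revcomp(alt)
    rel = locus.to_relative(offset)
    category, strand_call = categorize_event(kind, ref, alt, rel)
    return EditEvent(rel=rel, ref=ref, alt=alt, kind=kind, category=category, strand_call=strand_call)


def left_normalize_deletion(ref: str, offset: int, length: int) -> int:
    """Shift a deletion of ``length`` ref bases at ``offset`` to its leftmost
    equivalent placement (VCF convention)."""
    while offset > 0 and ref[offset - 1] == ref[offset + length - 1]:
        offset -= 1
    return offset

def left_normalize_insertion(ref: str, offset: int, seq: str) -> tuple[int, str]:
    """Left-normalize an insertion of ``seq`` before ref ``offset``."""
    while offset > 0 and seq and seq[-1] == ref[offset - 1]:
        seq = ref[offset - 1] + seq[:-1]
        offset -= 1
    return offset, seq


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = MATCH_SCORE if a == b else MISMATCH_SCORE
        matrix[a, "N"] = 0.0
        matrix["N", a] = 0.0
    matrix["N", "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _raw_diffs_from_alignment(ref: str, query: str) -> tuple[list[tuple], float]:
    """Globally align query to ref; return raw diffs and alignment identity.

    Raw diffs are tuples ``(kind, ref_offset, ref_seq, alt_seq)`` in
    reference order. N bases in the query are masked (never called).
    """
    alignment = _aligner().align(ref, query)[0]
    ref_blocks, query_blocks = alignment.aligned
    diffs: list[tuple] = []
    matches = 0
    columns = 0
    prev_r = prev_q = 0
    blocks = list(zip(ref_blocks, query_blocks)) + [
        ((len(ref), len(ref)), (len(query), len(query)))
    ]
    for (r0, r1), (q0, q1) in blocks:
        if r0 > prev_r:  # deletion from the reference
            diffs.append((DELETION, prev_r, ref[prev_r:r0], ""))
            columns += r0 - prev_r
        if q0 > prev_q:  # insertion of query sequence
            ins = query[prev_q:q0]
            if "N" not in ins:
                diffs.append((INSERTION, r0, "", ins))
            columns += q0 - prev_q
        for i in range(r1 - r0):
            rb, qb = ref[r0 + i], query[q0 + i]
            columns += 1
            if qb == "N":
                matches += 1  # masked: not a difference, not a penalty
            elif rb == qb:
                matches += 1
            else:
                diffs.append((SUBSTITUTION, r0 + i, rb, qb))
        prev_r, prev_q = r1, q1
    identity = matches / columns if columns else 0.0
    return diffs, identity


def align_allele(
    locus: TargetLocus,
    clone_seq: str,
    *,
    min_identity: float = 0.6,
    clone_id: str = "?",
) -> list[EditEvent]:
    """Globally align a clone sequence to the amplicon and call edit events.

    Events come back in amplicon order with indels left-normalized. Raises
    :class:`InputError` for empty / non-nucleotide input or a length more
    than 30% away from the amplicon, :class:`AlignmentQualityError` when the
    alignment identity falls below ``min_identity``.
    """
    ref = locus.amplicon
    seq = normalize_seq(clone_seq)
    if not seq:
        raise InputError(f"clone {clone_id!r}: empty sequence")
    if set(seq) - set("ACGTN"):
        raise InputError(f"clone {clone_id!r}: non-nucleotide characters in sequence")
    if abs(len(seq) - len(ref)) > 0.3 * len(ref):
        raise InputError(
            f"clone {clone_id!r}: length {len(seq)} more than 30% from amplicon {len(ref)}"
        )

    diffs: list[tuple] | None = None
    if len(seq) == len(ref):
        mismatch_offsets = [
            i for i, (a, b) in enumerate(zip(ref, seq)) if a != b and b != "N"
        ]
        if len(mismatch_offsets) <= _FAST_PATH_MAX_MISMATCHES:
            diffs = [(SUBSTITUTION, i, ref[i], seq[i]) for i in mismatch_offsets]
    if diffs is None:
        diffs, identity = _raw_diffs_from_alignment(ref, seq)
        if identity < min_identity:
            raise AlignmentQualityError(clone_id, identity, min_identity)

    events: list[tuple[int, EditEvent]] = []
    for diff in diffs:
        kind = diff[0]
        if kind == SUBSTITUTION:
            _, off, rb, qb = diff
            events.append((off, _make_event(locus, SUBSTITUTION, off, rb, qb)))
        elif kind == DELETION:
            _, off, deleted, _alt = diff
            off = left_normalize_deletion(ref, off, len(deleted))
            deleted = ref[off : off + len(deleted)]
            events.append((off, _make_event(locus, DELETION, off, deleted, "")))
        else:
            _, off, _ref, inserted = diff
            off, inserted = left_normalize_insertion(ref, off, inserted)
            anchor = min(off, len(ref) - 1)
            events.append((anchor, _make_event(locus, INSERTION, anchor, "", inserted)))
    events.sort(key=lambda pair: pair[0])
    return [e for _, e in events]


def call_allele(
    locus: TargetLocus,
    clone_id: str,
    clone_seq: str,
    *,
    min_identity: float = 0.6,
) -> AlleleCall:
    """Align one clone and wrap the result as an :class:`AlleleCall`."""
    events = tuple(
        align_allele(locus, clone_seq, min_identity=min_identity, clone_id=clone_id)
    )
    if not events:
        allele_class = WILD_TYPE
    elif any(e.is_indel for e in events):
        allele_class = INDEL_ALLELE
    else:
        allele_class = EDITED
    return AlleleCall(
        clone_id=clone_id,
        events=events,
        allele_class=allele_class,
        pattern_key=pattern_key(events),
    )


def classify_pool(
    locus: TargetLocus,
    clones: Mapping[str, str],
    *,
    min_identity: float = 0.6,
) -> tuple[list[AlleleCall], dict[str, str]]:
    """Classify a pool of clones; low-quality clones are excluded, not fatal.

    Returns the calls in input order plus a map of excluded clone id ->
    reason. Identical sequences are classified once and reused.
    """
    calls: list[AlleleCall] = []
    excluded: dict[str, str] = {}
    cache: dict[str, AlleleCall] = {}
    for clone_id, seq in clones.items():
        key = normalize_seq(seq)
        cached = cache.get(key)
        if cached is not None:
            calls.append(
                AlleleCall(clone_id, cached.events, cached.allele_class, cached.pattern_key)
            )
            continue
        try:
            call = call_allele(locus, clone_id, seq, min_identity=min_identity)
        except AlignmentQualityError as err:
            excluded[clone_id] = f"low_identity:{err.identity:.2f}"
            continue
        cache[key] = call
        calls.append(call)
    return calls, excluded
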