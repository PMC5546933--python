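"""Off-target candidate triage for whole-genome variant lists.

Starting from called variants (the hand-off point after alignment and
variant calling), candidates are screened by quality, known-variant
membership, low-complexity overlap and a flank homopolymer rule, and the
flanks of the survivors are scanned for guide-like sites: protospacer-length
windows followed by an NGG PAM that either stay within a mismatch budget or
match the guide's 3' seed exactly. Variants that survive every filter and
sit near such a site are flagged as potential off-target-associated.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .locus import GuideRNA, revcomp

SNV = "snv"
INDEL = "indel"

# Filter names (verdict keys)
F_QUALITY = "quality"
F_KNOWN = "known_variant"
F_LOW_COMPLEXITY = "low_complexity"
F_HOMOPOLYMER = "flank_homopolymer"
ALL_FILTERS = (F_QUALITY, F_KNOWN, F_LOW_COMPLEXITY, F_HOMOPOLYMER)

PASS = "pass"

# Match rules
RULE_FULL = "full_mismatch_budget"
RULE_SEED = "seed_10nt"

NO_OFFTARGET_OUTCOME = "no potential off-target site indel or SNV"


class ConfigurationError(ValueError):
    """Inconsistent inputs (e.g. VCF contigs missing from the genome)."""


@dataclass(frozen=True)
class GuideSiteMatch:
    """One guide-like site: protospacer-length window with an NGG PAM.

    ``start`` is the 0-based plus-strand coordinate of the leftmost
    protospacer base; ``matched_seq`` and ``pam`` are in site (guide) sense.
    """

    chrom: str
    start: int
    strand: str
    matched_seq: str
    pam: str
    mismatches: int
    rule: str
    distance_to_variant: int | None = None


@dataclass
class VariantCandidate:
    """One SNV/indel candidate moving through the triage filter chain."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float | None = None
    verdicts: dict[str, str] = field(default_factory=dict)
    site_hits: list[GuideSiteMatch] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span covered by the REF allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    @property
    def passes_filters(self) -> bool:
        return all(v == PASS for v in self.verdicts.values())

    @property
    def is_potential_offtarget(self) -> bool:
        return self.passes_filters and bool(self.site_hits)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# -- filters (pure per-candidate predicates; evaluation order is irrelevant) --

def filter_quality(candidate: VariantCandidate, min_qual: float = 30.0) -> None:
    """Fail candidates below the quality threshold; missing QUAL passes."""
    if candidate.qual is None or candidate.qual >= min_qual:
        candidate.verdicts[F_QUALITY] = PASS
    else:
        candidate.verdicts[F_QUALITY] = "fail:low_quality"


def filter_known(
    candidate: VariantCandidate,
    known: set,
    *,
    match_mode: str = "exact",
) -> None:
    """Fail candidates present in the known-variant set.

    ``match_mode`` 'exact' matches chrom+pos+ref+alt; 'position' matches
    chrom+pos only.
    """
    if match_mode == "exact":
        hit = candidate.key in known
    elif match_mode == "position":
        hit = (candidate.chrom, candidate.pos) in known
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    candidate.verdicts[F_KNOWN] = "fail:known_variant" if hit else PASS


def known_key_set(
    candidates: Iterable[VariantCandidate], *, match_mode: str = "exact"
) -> set:
    """Build the lookup set for :func:`filter_known` from known records."""
    if match_mode == "exact":
        return {c.key for c in candidates}
    return {(c.chrom, c.pos) for c in candidates}


def filter_low_complexity(
    candidate: VariantCandidate,
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> None:
    """Fail candidates whose reference span intersects a masked interval.

    ``intervals`` maps contig -> sorted, merged, 0-based half-open tuples.
    """
    start, end = candidate.span
    chrom_ivs = intervals.get(candidate.chrom, ())
    starts = [iv[0] for iv in chrom_ivs]
    idx = bisect_right(starts, end - 1) - 1
    hit = False
    while idx >= 0:
        iv_start, iv_end = chrom_ivs[idx]
        if iv_end <= start:
            break
        if iv_start < end:
            hit = True
            break
        idx -= 1
    candidate.verdicts[F_LOW_COMPLEXITY] = "fail:low_complexity" if hit else PASS


def longest_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def filter_flank_homopolymer(
    candidate: VariantCandidate,
    genome: Mapping[str, str],
    *,
    radius: int = 100,
    min_run: int = 8,
) -> None:
    """Fail candidates with a homopolymer run >= ``min_run`` within +/-``radius``.

    The window is anchored on the variant's POS base and clipped at contig
    ends; only bases inside the window count toward a run.
    """
    seq = genome[candidate.chrom]
    p = candidate.pos - 1
    if not 0 <= p < len(seq):
        raise IndexError(
            f"variant {candidate.chrom}:{candidate.pos} beyond contig end ({len(seq)} bp)"
        )
    window = seq[max(0, p - radius) : min(len(seq), p + radius + 1)]
    fail = longest_homopolymer(window) >= min_run
    candidate.verdicts[F_HOMOPOLYMER] = "fail:flank_homopolymer" if fail else PASS


# -- guide-like site scanning -------------------------------------------------

def _scan_one_strand(
    seq: str, spacer: str, max_mm: int, seed_len: int
) -> list[tuple[int, str, str, int, str]]:
    """Scan one orientation of ``seq``; yields (offset, window, pam, mm, rule)."""
    L = len(spacer)
    seed = spacer[-seed_len:]
    out = []
    for i in range(len(seq) - L - 3 + 1):
        pam = seq[i + L : i + L + 3]
        if pam[1] != "G" or pam[2] != "G":
            continue
        window = seq[i : i + L]
        if "N" in window or "N" in pam:
            continue
        mm = sum(a != b for a, b in zip(window, spacer))
        if mm <= max_mm:
            rule = RULE_FULL
        elif window[-seed_len:] == seed:
            rule = RULE_SEED
        else:
            continue
        out.append((i, window, pam, mm, rule))
    return out


def scan_guide_sites(
    flank_seq: str,
    flank_origin: int,
    guide: GuideRNA,
    *,
    chrom: str = "",
    max_mm: int = 5,
    seed_len: int = 10,
) -> list[GuideSiteMatch]:
    """Exhaustively scan a flank for guide-like sites on both strands.

    A window qualifies when it is immediately followed (3', same strand) by
    an NGG PAM and either its Hamming distance to the spacer is <= ``max_mm``
    or its 3'-most ``seed_len`` bases match the spacer seed exactly. When
    both rules hold the site is reported once under the mismatch-budget rule.
    A flank shorter than guide + PAM yields no matches.
    """
    seq = flank_seq.upper()
    L = len(guide)
    matches: list[GuideSiteMatch] = []
    for i, window, pam, mm, rule in _scan_one_strand(seq, guide.spacer, max_mm, seed_len):
        matches.append(
            GuideSiteMatch(
                chrom=chrom,
                start=flank_origin + i,
                strand="+",
                matched_seq=window,
                pam=pam,
                mismatches=mm,
                rule=rule,
            )
        )
    rc = revcomp(seq)
    for i, window, pam, mm, rule in _scan_one_strand(rc, guide.spacer, max_mm, seed_len):
        # window occupies rc[i:i+L] -> plus-strand [origin+len-i-L, origin+len-i)
        matches.append(
            GuideSiteMatch(
                chrom=chrom,
                start=flank_origin + len(seq) - i - L,
                strand="-",
                matched_seq=window,
                pam=pam,
                mismatches=mm,
                rule=rule,
            )
        )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def _site_span(match: GuideSiteMatch, guide_len: int) -> tuple[int, int]:
    """Plus-strand half-open span of protospacer plus PAM."""
    if match.strand == "+":
        return match.start, match.start + guide_len + 3
    return match.start - 3, match.start + guide_len


@dataclass
class TriageReport:
    """All candidates with verdicts/site hits plus per-filter tallies."""

    candidates: list[VariantCandidate]
    guide: GuideRNA
    params: dict

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def surviving(self) -> list[VariantCandidate]:
        return [c for c in self.candidates if c.passes_filters]

    @property
    def potential_offtargets(self) -> list[VariantCandidate]:
        return [c for c in self.candidates if c.is_potential_offtarget]

    @property
    def outcome(self) -> str:
        n = len(self.potential_offtargets)
        if n == 0:
            return NO_OFFTARGET_OUTCOME
        return f"{n} potential off-target-associated variant(s) found"

    def filter_fail_counts(self) -> dict[str, int]:
        return {
            name: sum(c.verdicts.get(name, PASS) != PASS for c in self.candidates)
            for name in ALL_FILTERS
        }

    def summary(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_snv": sum(c.kind == SNV for c in self.candidates),
            "n_indel": sum(c.kind == INDEL for c in self.candidates),
            "filter_fail_counts": self.filter_fail_counts(),
            "n_surviving": len(self.surviving),
            "n_potential_offtarget": len(self.potential_offtargets),
            "outcome": self.outcome,
            "params": self.params,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            best = min(
                (h for h in c.site_hits),
                key=lambda h: (h.distance_to_variant or 0, h.mismatches),
                default=None,
            )
            rows.append(
                {
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "kind": c.kind,
                    "qual": c.qual,
                    **{f"filter_{k}": c.verdicts.get(k, "") for k in ALL_FILTERS},
                    "n_site_hits": len(c.site_hits),
                    "site_start": best.start if best else "",
                    "site_strand": best.strand if best else "",
                    "site_mismatches": best.mismatches if best else "",
                    "site_rule": best.rule if best else "",
                    "site_distance": best.distance_to_variant if best else "",
                    "potential_offtarget": c.is_potential_offtarget,
                }
            )
        return pd.DataFrame(rows)


def triage(
    candidates: Sequence[VariantCandidate],
    genome: Mapping[str, str],
    known: set,
    lc_intervals: Mapping[str, Sequence[tuple[int, int]]],
    guide: GuideRNA,
    *,
    flank: int = 100,
    max_mm: int = 5,
    seed_len: int = 10,
    min_run: int = 8,
    min_qual: float = 30.0,
    known_match_mode: str = "exact",
) -> TriageReport:
    """Run the full candidate triage: independent filters, then site scan.

    Every candidate receives all four verdicts; guide-site hits are computed
    only for filter-surviving candidates (matching the staged workflow the
    triage reproduces). Raises :class:`ConfigurationError` when candidate
    contigs are absent from the genome.
    """
    missing = sorted({c.chrom for c in candidates} - set(genome))
    if missing:
        raise ConfigurationError(f"contigs in VCF but not in genome: {missing}")
    genome = {k: v.upper() for k, v in genome.items()}
    for c in candidates:
        c.verdicts.clear()
        c.site_hits.clear()
        filter_quality(c, min_qual)
        filter_known(c, known, match_mode=known_match_mode)
        filter_low_complexity(c, lc_intervals)
        filter_flank_homopolymer(c, genome, radius=flank, min_run=min_run)
    for c in candidates:
        if not c.passes_filters:
            continue
        seq = genome[c.chrom]
        p = c.pos - 1
        origin = max(0, p - flank)
        flank_seq = seq[origin : min(len(seq), p + flank + 1)]
        hits = scan_guide_sites(
            flank_seq, origin, guide, chrom=c.chrom, max_mm=max_mm, seed_len=seed_len
        )
        for h in hits:
            s0, s1 = _site_span(h, len(guide))
            distance = max(0, s0 - p, p - (s1 - 1))
            c.site_hits.append(
                GuideSiteMatch(
                    chrom=h.chrom,
                    start=h.start,
                    strand=h.strand,
                    matched_seq=h.matched_seq,
                    pam=h.pam,
                    mismatches=h.mismatches,
                    rule=h.rule,
                    distance_to_variant=distance,
                )
            )
    params = {
        "flank": flank,
        "max_mm": max_mm,
        "seed_len": seed_len,
        "min_run": min_run,
        "min_qual": min_qual,
        "known_match_mode": known_match_mode,
        "guide": guide.name,
    }
    return TriageReport(candidates=list(candidates), guide=guide, params=params)
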