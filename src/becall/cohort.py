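"""Embryo genotyping and per-group editing statistics.

Aggregates per-clone allele calls into embryo genotype classes
(wild-type / heterozygous / homozygous / biallelic / mosaic), then into
group summaries carrying the three printed percentages used to compare
editing efficiency and proximal-site deamination between experimental
groups, plus founder-mouse (pup) summaries and the pairwise chi-square
comparisons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

from scipy import stats

from .alleles import AlleleCall, WT_PATTERN

# Genotype classes
WILD_TYPE = "wild_type"
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
BIALLELIC = "biallelic"
MOSAIC = "mosaic"

BIALLELIC_CLASSES = frozenset({HOMOZYGOUS, BIALLELIC})

# Coat colors for founder records
COAT_BLACK = "black"
COAT_ALBINO = "albino"
COAT_MOSAIC = "mosaic"


def round_pct(numerator: float, denominator: float) -> float | None:
    """Percentage rounded half-even to one decimal; None for a 0 denominator."""
    if denominator == 0:
        return None
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN
    )
    return float(q)


@dataclass
class EmbryoGenotype:
    """Per-embryo aggregation of clone allele patterns."""

    embryo_id: str
    clone_calls: tuple[AlleleCall, ...]
    distinct_patterns: dict[str, int]
    supported_patterns: dict[str, int]
    genotype_class: str
    is_mutant: bool
    has_proximal: bool
    has_indel: bool

    @property
    def is_biallelic(self) -> bool:
        """Both alleles edited (homozygous mutants included)."""
        return self.genotype_class in BIALLELIC_CLASSES

    @property
    def n_clones(self) -> int:
        return len(self.clone_calls)


def _classify_patterns(
    supported: dict[str, int],
) -> str:
    """Genotype class from the supported pattern tally.

    All wild-type -> wild_type; WT plus one edited pattern -> heterozygous;
    WT plus two or more -> mosaic; no WT with one edited pattern ->
    homozygous; with exactly two -> biallelic; with more -> mosaic.
    """
    edited = [k for k in supported if k != WT_PATTERN]
    has_wt = WT_PATTERN in supported
    if not edited:
        return WILD_TYPE
    if has_wt:
        return HETEROZYGOUS if len(edited) == 1 else MOSAIC
    if len(edited) == 1:
        return HOMOZYGOUS
    if len(edited) == 2:
        return BIALLELIC
    return MOSAIC


def genotype_embryo(
    embryo_id: str,
    clone_calls: Sequence[AlleleCall],
    *,
    min_support: float = 1,
    indel_only_is_mutant: bool = True,
) -> EmbryoGenotype:
    """Genotype one embryo from its subclone calls.

    ``min_support`` is the minimum clone count per allele pattern (a value
    in (0, 1) is taken as a fraction of the pool size, rounded up).
    ``indel_only_is_mutant`` controls whether a pattern whose only events
    are indels counts toward the mutant flag.
    """
    if not clone_calls:
        raise ValueError(f"embryo {embryo_id!r}: no clone calls")
    n = len(clone_calls)
    if 0 < min_support < 1:
        threshold = math.ceil(min_support * n)
    else:
        threshold = max(1, int(min_support))
    tally = Counter(call.pattern_key for call in clone_calls)
    supported = {k: c for k, c in tally.items() if c >= threshold}
    representative = {}
    for call in clone_calls:
        representative.setdefault(call.pattern_key, call)

    genotype_class = _classify_patterns(supported) if supported else WILD_TYPE
    mutant_patterns = []
    for key in supported:
        if key == WT_PATTERN:
            continue
        call = representative[key]
        if not indel_only_is_mutant and not call.has_substitution:
            continue
        mutant_patterns.append(key)
    has_proximal = any(
        representative[k].has_proximal for k in supported if k != WT_PATTERN
    )
    has_indel = any(
        representative[k].has_indel for k in supported if k != WT_PATTERN
    )
    return EmbryoGenotype(
        embryo_id=embryo_id,
        clone_calls=tuple(clone_calls),
        distinct_patterns=dict(tally),
        supported_patterns=supported,
        genotype_class=genotype_class,
        is_mutant=bool(mutant_patterns),
        has_proximal=has_proximal,
        has_indel=has_indel,
    )


@dataclass
class GroupSummary:
    """Per-experimental-group counts and the three printed percentages."""

    group_name: str
    n_total: int
    n_mutant: int
    n_proximal: int
    pct_mutant: float | None
    ratio_proximal_over_mutant: float | None
    ratio_proximal_over_total: float | None


def summarize_group(group_name: str, genotypes: Iterable[EmbryoGenotype]) -> GroupSummary:
    """Tally embryo genotypes into a group summary.

    Proximal-deaminated embryos are counted among mutants (a proximal edit
    is an edit, so every proximal-deaminated embryo is mutant by
    construction). Percentages round half-even to one decimal; ratios over
    an empty denominator are reported as blank (None).
    """
    genotypes = list(genotypes)
    n_total = len(genotypes)
    n_mutant = sum(g.is_mutant for g in genotypes)
    n_proximal = sum(g.is_mutant and g.has_proximal for g in genotypes)
    return GroupSummary(
        group_name=group_name,
        n_total=n_total,
        n_mutant=n_mutant,
        n_proximal=n_proximal,
        pct_mutant=round_pct(n_mutant, n_total),
        ratio_proximal_over_mutant=round_pct(n_proximal, n_mutant),
        ratio_proximal_over_total=round_pct(n_proximal, n_total),
    )


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Rows are groups, columns outcomes: ``[[a, b], [c, d]]``. Raises
    ValueError when any margin is zero (the test is undefined).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    result = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class PupRecord:
    """One genotyped founder pup with its coat-color annotation."""

    pup_id: str
    coat: str  # black | albino | mosaic (coat mosaicism is metadata, not inferred)
    genotype_class: str

    @property
    def is_mutant(self) -> bool:
        return self.genotype_class != WILD_TYPE

    @property
    def is_biallelic(self) -> bool:
        return self.genotype_class in BIALLELIC_CLASSES


@dataclass
class PupSummary:
    """Founder-mouse summary for one injection group.

    ``n_pups`` is pups born; percentages for genotype columns use the
    genotyped pups as denominator (pups lost before genotyping are counted
    as born but not genotyped).
    """

    group_name: str
    n_injected: int
    n_survived: int
    n_transferred: int
    n_pups: int
    n_genotyped: int
    n_albino: int
    n_mosaic_coat: int
    n_mutant_black: int
    n_mutant: int
    n_biallelic: int
    pct_survived: float | None
    pct_pups_per_transferred: float | None
    pct_albino: float | None
    pct_mosaic_coat: float | None
    pct_mutant_black: float | None
    pct_mutant: float | None
    pct_biallelic: float | None


def summarize_pups(
    group_name: str,
    *,
    n_injected: int,
    n_survived: int,
    n_transferred: int,
    n_pups: int,
    records: Sequence[PupRecord],
) -> PupSummary:
    """Summarize one founder group (survival, litter and genotype columns)."""
    n_genotyped = len(records)
    n_albino = sum(r.coat == COAT_ALBINO for r in records)
    n_mosaic_coat = sum(r.coat == COAT_MOSAIC for r in records)
    n_mutant_black = sum(r.coat == COAT_BLACK and r.is_mutant for r in records)
    n_mutant = sum(r.is_mutant for r in records)
    n_biallelic = sum(r.is_biallelic for r in records)
    return PupSummary(
        group_name=group_name,
        n_injected=n_injected,
        n_survived=n_survived,
        n_transferred=n_transferred,
        n_pups=n_pups,
        n_genotyped=n_genotyped,
        n_albino=n_albino,
        n_mosaic_coat=n_mosaic_coat,
        n_mutant_black=n_mutant_black,
        n_mutant=n_mutant,
        n_biallelic=n_biallelic,
        pct_survived=round_pct(n_survived, n_injected),
        pct_pups_per_transferred=round_pct(n_pups, n_transferred),
        pct_albino=round_pct(n_albino, n_genotyped),
        pct_mosaic_coat=round_pct(n_mosaic_coat, n_genotyped),
        pct_mutant_black=round_pct(n_mutant_black, n_genotyped),
        pct_mutant=round_pct(n_mutant, n_genotyped),
        pct_biallelic=round_pct(n_biallelic, n_genotyped),
    )


def pairwise_chi2(
    summaries: Sequence[GroupSummary],
) -> list[dict]:
    """Pairwise chi-square comparisons between group summaries.

    For every group pair, tests (a) mutant vs non-mutant composition over
    all embryos and (b) proximal vs non-proximal composition among mutant
    embryos. Pairs with a degenerate margin are skipped.
    """
    rows: list[dict] = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            g1, g2 = summaries[i], summaries[j]
            comparisons = [
                (
                    "mutant_rate",
                    (g1.n_mutant, g1.n_total - g1.n_mutant),
                    (g2.n_mutant, g2.n_total - g2.n_mutant),
                ),
                (
                    "proximal_over_mutant",
                    (g1.n_proximal, g1.n_mutant - g1.n_proximal),
                    (g2.n_proximal, g2.n_mutant - g2.n_proximal),
                ),
            ]
            for name, row1, row2 in comparisons:
                try:
                    statistic, pvalue = chi2_2x2(*row1, *row2)
                except ValueError:
                    continue
                rows.append(
                    {
                        "comparison": name,
                        "group_a": g1.group_name,
                        "group_b": g2.group_name,
                        "a": row1[0],
                        "b": row1[1],
                        "c": row2[0],
                        "d": row2[1],
                        "statistic": statistic,
                        "p_value": pvalue,
                    }
                )
    return rows
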