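"""Synthetic data: edited-embryo clone pools and toy genomes with planted truth.

Two generators cover the pipeline's inputs end to end.

``simulate_cohort`` draws embryos under a stochastic editing model: each
embryo carries 2 (zygote-stage editing) or 4 (post-division editing,
emulating mosaicism) allele lineages, each lineage is edited independently
per position — cytidines in the canonical window at a high rate, elsewhere
in the protospacer at a low rate, and outside the protospacer at an
exponentially decaying rate with distance — with the rarer C->G/A outcomes,
a target-strand multiplier for Gs, and rare 1-3 bp indels; subclones are
then drawn with replacement from the lineages.

``simulate_genome`` builds a toy genome with planted guide-like sites (at
chosen mismatch counts, seed integrity, PAM validity and strand),
homopolymer runs, low-complexity intervals and variant candidates, emitting
FASTA/VCF/BED plus a per-variant truth table of expected triage verdicts.

A deterministic cohort builder (``build_group_pools``) constructs clone
pools realizing exact per-group embryo counts, for reproducing printed
summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as bio
from .alleles import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    EditEvent,
    _make_event,
    left_normalize_deletion,
    left_normalize_insertion,
    pattern_key,
)
from .cohort import _classify_patterns, WILD_TYPE
from .locus import GuideRNA, TargetLocus, complement
from .triage import VariantCandidate

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# demo locus (synthetic)
# ---------------------------------------------------------------------------

def demo_guide(length: int = 20, name: str | None = None) -> GuideRNA:
    """The synthetic demo guide (full-length or 5'-truncated to 16/17 nt).

    Synthetic stand-in sequence: the window holds Cs at protospacer
    positions 4 and 5 and a G (target-strand C) at position 7.
    """
    spacer = "GTACCAGTGATCGATTGATG"
    if name is None:
        name = {20: "gRNA-2", 17: "gRNA-2-T1", 16: "gRNA-2-T2"}.get(length, f"guide-{length}")
    return GuideRNA(name=name, spacer=spacer[20 - length :])


def demo_locus(guide_length: int = 20, strand: str = "+") -> TargetLocus:
    """A synthetic 143-bp demo amplicon with the feature set the pipeline exercises.

    Deterministically generated; carries cytidines at protospacer-relative
    -38, -10 and -2 (proximal-site positions), window Cs at 4-5, a
    target-strand G at 7, a protospacer C at 12 outside the window, a TGG
    PAM and a C 42 bp downstream of the PAM. Truncated-guide variants share
    the same amplicon with the protospacer start shifted so the 3' end and
    PAM stay fixed.
    """
    rng = np.random.default_rng(20170605)
    up = list(rng.choice(list("ACGT"), size=60))
    down = list(rng.choice(list("ACGT"), size=60))
    # planted proximal-site cytidines (guide-sense positions -38, -10, -2)
    up[22] = "C"   # rel -38
    up[50] = "C"   # rel -10
    up[58] = "C"   # rel -2
    down[41] = "C"  # rel +65 = 42 bp past the PAM's 3' end
    # keep the PAM junction unambiguous and homopolymers short
    up_s, down_s = "".join(up), "".join(down)
    spacer = demo_guide(20).spacer
    amplicon = up_s + spacer + "TGG" + down_s
    guide = demo_guide(guide_length)
    start = 60 + (20 - guide_length)
    locus = TargetLocus(
        name=f"demo_{guide.name}",
        amplicon=amplicon,
        protospacer_start=start,
        strand="+",
        guide=guide,
    )
    if strand == "-":
        from .locus import revcomp

        locus = TargetLocus(
            name=locus.name + "_minus",
            amplicon=revcomp(amplicon),
            protospacer_start=len(amplicon) - (start + guide_length),
            strand="-",
            guide=guide,
        )
    return locus


# ---------------------------------------------------------------------------
# editing model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditingModel:
    """Per-position stochastic deamination model for one allele lineage.

    Probabilities are per non-target-strand C (Gs, i.e. target-strand Cs,
    use the same positional rate scaled by ``p_target_strand_factor``).
    Outside the protospacer the rate decays exponentially with distance
    (``p_proximal_amp * exp(-d / proximal_scale)``), truncated at
    ``proximal_max`` bp — a modelling invention for test realism; no
    analysis stage depends on its form.
    """

    p_window: float = 0.12
    p_protospacer_out: float = 0.01
    p_proximal_amp: float = 0.012
    proximal_scale: float = 20.0
    proximal_max: int = 100
    outcome_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)  # T, G, A
    p_target_strand_factor: float = 0.5
    p_indel: float = 0.02
    indel_max_len: int = 3
    n_lineages: int = 2
    clones_per_embryo: int = 15

    def __post_init__(self) -> None:
        for p in (
            self.p_window,
            self.p_protospacer_out,
            self.p_proximal_amp,
            self.p_indel,
            self.p_target_strand_factor,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.outcome_probs) - 1.0) > 1e-9:
            raise ValueError("outcome_probs must sum to 1")
        if self.n_lineages not in (2, 4):
            raise ValueError("n_lineages must be 2 (zygote) or 4 (post-division)")
        if self.clones_per_embryo < 1:
            raise ValueError("clones_per_embryo must be positive")

    def positional_rate(self, locus: TargetLocus, offset: int) -> float:
        """Edit probability for the amplicon base at ``offset`` (0 for A/T)."""
        base = locus.amplicon[offset]
        sense = base if locus.strand == "+" else complement(base)
        if sense == "C":
            factor = 1.0
        elif sense == "G":
            factor = self.p_target_strand_factor
        else:
            return 0.0
        rel = locus.to_relative(offset)
        if rel.region == "window":
            rate = self.p_window
        elif rel.region == "protospacer":
            rate = self.p_protospacer_out
        else:
            d = locus.proximal_distance(rel.value)
            if d > self.proximal_max:
                return 0.0
            rate = self.p_proximal_amp * math.exp(-d / self.proximal_scale)
        return rate * factor

    def allele_edit_prob(self, locus: TargetLocus) -> float:
        """Closed-form probability that one lineage carries >= 1 edit."""
        p_no_sub = 1.0
        for offset in range(len(locus.amplicon)):
            p_no_sub *= 1.0 - self.positional_rate(locus, offset)
        return 1.0 - p_no_sub * (1.0 - self.p_indel)

    def embryo_mutant_prob(self, locus: TargetLocus) -> float:
        """Closed-form probability that an embryo has >= 1 edited lineage."""
        q = self.allele_edit_prob(locus)
        return 1.0 - (1.0 - q) ** self.n_lineages


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class LineageTruth:
    """One simulated allele lineage with its true event list."""

    sequence: str
    events: tuple[EditEvent, ...]
    pattern: str


@dataclass
class EmbryoSim:
    """Simulated embryo: lineages, sampled clones, and expected genotype."""

    embryo_id: str
    lineages: list[LineageTruth]
    clone_lineages: list[int]
    clones: dict[str, str]
    expected_genotype: str
    expected_mutant: bool
    expected_proximal: bool
    expected_indel: bool


@dataclass
class CohortSim:
    locus: TargetLocus
    model: EditingModel
    embryos: list[EmbryoSim]

    def clone_pools(self) -> dict[str, dict[str, str]]:
        return {e.embryo_id: dict(e.clones) for e in self.embryos}

    def write_fasta(self, path: str | Path) -> None:
        """Write all clones as one multi-FASTA with embryoID/cloneID headers."""
        records = {
            f"{e.embryo_id}/{clone_id}": seq
            for e in self.embryos
            for clone_id, seq in e.clones.items()
        }
        bio.write_fasta(records, path)

    def truth_rows(self) -> list[dict]:
        return [
            {
                "embryo_id": e.embryo_id,
                "n_lineages": len(e.lineages),
                "lineage_patterns": "|".join(l.pattern for l in e.lineages),
                "expected_genotype": e.expected_genotype,
                "expected_mutant": e.expected_mutant,
                "expected_proximal": e.expected_proximal,
                "expected_indel": e.expected_indel,
            }
            for e in self.embryos
        ]


def _positional_rates(locus: TargetLocus, model: EditingModel) -> np.ndarray:
    return np.array(
        [model.positional_rate(locus, off) for off in range(len(locus.amplicon))]
    )


def _edit_lineage(
    locus: TargetLocus,
    model: EditingModel,
    rng: np.random.Generator,
    rates: np.ndarray,
) -> LineageTruth:
    ref = locus.amplicon
    raw: list[tuple] = []  # (kind, offset, ref, alt) amplicon sense
    seq = list(ref)
    outcomes = "TGA"
    probs = np.asarray(model.outcome_probs)
    edited = np.nonzero(rng.random(len(rates)) < rates)[0]
    for offset in (int(o) for o in edited):
        base = ref[offset]
        # outcome drawn for the deaminated C on its own strand
        out = outcomes[rng.choice(3, p=probs)]
        sense = base if locus.strand == "+" else complement(base)
        if sense == "C":
            new_sense = out
        else:  # sense G: target-strand C -> out, read back on non-target strand
            new_sense = complement(out)
        new_base = new_sense if locus.strand == "+" else complement(new_sense)
        if new_base == base:
            continue
        seq[offset] = new_base
        raw.append((SUBSTITUTION, offset, base, new_base))

    indel: tuple | None = None
    if rng.random() < model.p_indel:
        w_lo = locus.from_relative(locus.window[0])
        w_hi = locus.from_relative(locus.window[1])
        lo, hi = min(w_lo, w_hi), max(w_lo, w_hi)
        length = int(rng.integers(1, model.indel_max_len + 1))
        pos = int(rng.integers(max(1, lo - 3), min(len(ref) - length, hi + 4)))
        # apply at the left-normalized placement, and revert substitutions
        # near the indel: an edit adjacent to a gap would make co-optimal
        # alignment representations ambiguous and the truth ill-defined
        if rng.random() < 0.5:
            norm = left_normalize_deletion(ref, pos, length)
            guard = range(norm - 4, norm + length + 4)
            indel = (DELETION, norm, ref[norm : norm + length], "")
        else:
            ins = "".join(rng.choice(list(_BASES), size=length))
            norm, ins_norm = left_normalize_insertion(ref, pos, ins)
            guard = range(norm - 4, norm + 4)
            indel = (INSERTION, min(norm, len(ref) - 1), "", ins_norm)
        kept = []
        for r in raw:
            if r[0] == SUBSTITUTION and r[1] in guard:
                seq[r[1]] = ref[r[1]]
            else:
                kept.append(r)
        raw = kept
        if indel[0] == DELETION:
            del seq[norm : norm + length]
        else:
            seq.insert(norm, ins_norm)
    if indel is not None:
        raw.append(indel)
        raw.sort(key=lambda r: r[1])

    # seq edits applied in list space: the insertion branch adds one list
    # entry holding a multi-character string; joining flattens it
    sequence = "".join(seq)
    events = tuple(_make_event(locus, k, off, r, a) for k, off, r, a in raw)
    return LineageTruth(sequence=sequence, events=events, pattern=pattern_key(events))


def _expected_genotype(patterns: Sequence[str]) -> str:
    support = {}
    for p in patterns:
        support[p] = support.get(p, 0) + 1
    return _classify_patterns(support) if support else WILD_TYPE


def simulate_cohort(
    locus: TargetLocus,
    model: EditingModel,
    n_embryos: int,
    seed: int,
    *,
    prefix: str = "E",
) -> CohortSim:
    """Simulate a cohort of edited embryos with full per-lineage truth.

    The expected genotype is derived from the lineage patterns actually
    represented among the sampled clones, by the same classification rules
    the genotyper applies, so pipeline output on noise-free data must
    reproduce it exactly.
    """
    rng = np.random.default_rng(seed)
    rates = _positional_rates(locus, model)
    width = max(2, len(str(n_embryos)))
    embryos = []
    for i in range(n_embryos):
        lineages = [
            _edit_lineage(locus, model, rng, rates) for _ in range(model.n_lineages)
        ]
        clone_lineages = [
            int(rng.integers(model.n_lineages)) for _ in range(model.clones_per_embryo)
        ]
        clones = {
            f"c{j + 1:02d}": lineages[k].sequence for j, k in enumerate(clone_lineages)
        }
        sampled = [lineages[k] for k in sorted(set(clone_lineages))]
        patterns = [lineages[k].pattern for k in clone_lineages]
        sampled_edits = [l for l in sampled if l.events]
        embryos.append(
            EmbryoSim(
                embryo_id=f"{prefix}{i + 1:0{width}d}",
                lineages=lineages,
                clone_lineages=clone_lineages,
                clones=clones,
                expected_genotype=_expected_genotype(patterns),
                expected_mutant=bool(sampled_edits),
                expected_proximal=any(
                    ev.category == "proximal_site_deamination"
                    for l in sampled_edits
                    for ev in l.events
                ),
                expected_indel=any(
                    ev.is_indel for l in sampled_edits for ev in l.events
                ),
            )
        )
    return CohortSim(locus=locus, model=model, embryos=embryos)


# ---------------------------------------------------------------------------
# deterministic cohort builders (printed-table fixtures)
# ---------------------------------------------------------------------------

def _apply_subs(locus: TargetLocus, subs: Sequence[tuple[int, str]]) -> str:
    """Apply (relative position, non-target-sense alt base) substitutions."""
    seq = list(locus.amplicon)
    for rel_value, alt in subs:
        off = locus.from_relative(rel_value)
        seq[off] = alt if locus.strand == "+" else complement(alt)
    return "".join(seq)


def _window_deamination_subs(locus: TargetLocus) -> list[tuple[int, str]]:
    """Canonical deamination edits available in the window, 5' to 3'.

    Each entry is (relative position, non-target-sense alt): C>T for
    non-target-strand Cs, G>A for target-strand Cs.
    """
    subs = []
    for rel_value in range(locus.window[0], locus.window[1] + 1):
        sense = locus.guide.spacer[rel_value - 1]
        if sense == "C":
            subs.append((rel_value, "T"))
        elif sense == "G":
            subs.append((rel_value, "A"))
    if not subs:
        raise ValueError(f"locus {locus.name!r}: no editable C/G in the window")
    return subs


def window_edit_allele(locus: TargetLocus) -> str:
    """Allele with one canonical deamination at the 5'-most editable window base."""
    return _apply_subs(locus, [_window_deamination_subs(locus)[0]])


def proximal_edit_allele(locus: TargetLocus) -> str:
    """Allele with the window edit plus a proximal C>T 10 bp upstream."""
    return _apply_subs(locus, [_window_deamination_subs(locus)[0], (-10, "T")])


def second_pattern_allele(locus: TargetLocus) -> str:
    """A distinct edited pattern (next editable window base) for biallelic fixtures."""
    subs = _window_deamination_subs(locus)
    if len(subs) > 1:
        return _apply_subs(locus, [subs[1]])
    rel_value, alt = subs[0]
    # same position, rarer non-canonical outcome
    return _apply_subs(locus, [(rel_value, "A" if alt == "T" else "T")])


def build_group_pools(
    locus: TargetLocus,
    n_total: int,
    n_mutant: int,
    n_proximal: int,
    *,
    clones_per_embryo: int = 8,
    prefix: str = "E",
) -> dict[str, dict[str, str]]:
    """Deterministic clone pools realizing exact group counts.

    The first ``n_proximal`` embryos are heterozygous for the
    window+proximal pattern, the next ``n_mutant - n_proximal`` heterozygous
    for the window-only pattern, the rest wild-type. Half of each mutant
    pool carries the edited allele.
    """
    if not 0 <= n_proximal <= n_mutant <= n_total:
        raise ValueError("need 0 <= n_proximal <= n_mutant <= n_total")
    wt = locus.amplicon
    half = clones_per_embryo // 2
    pools: dict[str, dict[str, str]] = {}
    width = max(2, len(str(n_total)))
    for i in range(n_total):
        embryo_id = f"{prefix}{i + 1:0{width}d}"
        if i < n_proximal:
            edited = proximal_edit_allele(locus)
        elif i < n_mutant:
            edited = window_edit_allele(locus)
        else:
            edited = None
        clones = {}
        for j in range(clones_per_embryo):
            seq = wt if (edited is None or j >= half) else edited
            clones[f"c{j + 1:02d}"] = seq
        pools[embryo_id] = clones
    return pools


def build_founder_pools(locus: TargetLocus) -> dict[str, tuple[str, dict[str, str]]]:
    """Clone pools + coat colors for the 11 genotyped full-length-guide founders.

    Synthetic stand-in litter: 4 wild-type black pups, 2 heterozygous black
    mutants, 4 coat mosaics (2 heterozygous, 2 biallelic) and 1 albino
    biallelic — the composition behind 63.6% mutants, 27.3% biallelic,
    36.4% coat mosaics and 9.1% albino among 11 genotyped pups.
    """
    wt = locus.amplicon
    a = window_edit_allele(locus)
    b = second_pattern_allele(locus)

    def pool(*alleles: str) -> dict[str, str]:
        seqs = []
        for allele in alleles:
            seqs.extend([allele] * (8 // len(alleles)))
        return {f"c{j + 1:02d}": s for j, s in enumerate(seqs)}

    return {
        "P1": ("mosaic", pool(wt, a)),
        "P2": ("black", pool(wt)),
        "P3": ("mosaic", pool(a, b)),
        "P4": ("black", pool(wt)),
        "P5": ("mosaic", pool(wt, a)),
        "P6": ("albino", pool(a, b)),
        "P7": ("black", pool(wt)),
        "P8": ("black", pool(wt, a)),
        "P9": ("black", pool(wt, a)),
        "P10": ("black", pool(wt)),
        "P11": ("mosaic", pool(a, b)),
    }


def build_founder_pools_grna1(locus: TargetLocus) -> dict[str, tuple[str, dict[str, str]]]:
    """The 11 genotyped short-efficiency-group founders: 2 heterozygous mutants."""
    wt = locus.amplicon
    a = window_edit_allele(locus)
    pools: dict[str, tuple[str, dict[str, str]]] = {}
    for i in range(1, 12):
        if i in (8, 9):
            clones = {f"c{j + 1:02d}": (wt if j < 4 else a) for j in range(8)}
        else:
            clones = {f"c{j + 1:02d}": wt for j in range(8)}
        pools[f"P{i}"] = ("black", clones)
    return pools


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """A guide-like site to plant: mismatch count, seed/PAM integrity, strand."""

    mismatches: int = 0
    seed_intact: bool = True
    pam_ok: bool = True
    strand: str = "+"
    pos: int | None = None  # leftmost plus-strand coordinate of the footprint


@dataclass(frozen=True)
class HomopolymerSpec:
    base: str = "A"
    run: int = 8
    pos: int | None = None


@dataclass(frozen=True)
class VariantSpec:
    """A candidate variant to plant, optionally anchored near a planted site."""

    kind: str = "snv"  # snv | del | ins
    qual: float = 50.0
    known: bool = False
    near_site: int | None = None  # index into the sites list
    offset: int = 20  # bp from the site's protospacer start (when near_site set)
    pos: int | None = None  # explicit 1-based position otherwise


@dataclass
class PlantedSite:
    spec: SiteSpec
    footprint_start: int  # leftmost plus-strand coordinate incl. PAM
    protospacer_start: int
    site_seq: str  # guide-sense protospacer
    pam: str

    @property
    def qualifies(self) -> bool:
        """Whether the scanner's acceptance rules admit this site (defaults)."""
        return self.spec.pam_ok and (self.spec.mismatches <= 5 or self.spec.seed_intact)


@dataclass
class GenomeSim:
    chrom: str
    sequence: str
    guide: GuideRNA
    sites: list[PlantedSite]
    homopolymers: list[tuple[str, int, int]]  # (base, run, start)
    lc_intervals: list[tuple[int, int]]
    candidates: list[VariantCandidate]
    known: list[VariantCandidate]
    truth: list[dict]

    @property
    def genome(self) -> dict[str, str]:
        return {self.chrom: self.sequence}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "candidates": outdir / "candidates.vcf",
            "known": outdir / "known.vcf",
            "bed": outdir / "lowcomplexity.bed",
            "truth": outdir / "truth.tsv",
        }
        bio.write_fasta({self.chrom: self.sequence}, paths["genome"])
        contigs = {self.chrom: len(self.sequence)}
        bio.write_vcf(self.candidates, contigs, paths["candidates"])
        bio.write_vcf(self.known, contigs, paths["known"])
        bio.write_bed({self.chrom: self.lc_intervals}, paths["bed"])
        import pandas as pd

        pd.DataFrame(self.truth).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _background(length: int, rng: np.random.Generator) -> list[str]:
    """Random sequence with single-base runs capped at 3 (no chance homopolymers)."""
    seq: list[str] = []
    for _ in range(length):
        if len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3]:
            choices = [b for b in _BASES if b != seq[-1]]
        else:
            choices = list(_BASES)
        seq.append(choices[int(rng.integers(len(choices)))])
    return seq


def _site_segment(guide: GuideRNA, spec: SiteSpec, rng: np.random.Generator, seed_len: int = 10) -> tuple[str, str]:
    """Build (protospacer, pam) in guide sense for a planted site."""
    spacer = list(guide.spacer)
    L = len(spacer)
    if spec.seed_intact:
        allowed = list(range(0, L - seed_len))
        if spec.mismatches > len(allowed):
            raise ValueError("too many mismatches for an intact seed")
        positions = rng.choice(allowed, size=spec.mismatches, replace=False)
    elif spec.mismatches > 0:
        seed_positions = list(range(L - seed_len, L))
        first = int(rng.choice(seed_positions))
        rest_pool = [i for i in range(L) if i != first]
        rest = rng.choice(rest_pool, size=spec.mismatches - 1, replace=False)
        positions = np.concatenate([[first], rest]).astype(int)
    else:
        positions = np.array([], dtype=int)
    for p in positions:
        spacer[int(p)] = rng.choice([b for b in _BASES if b != spacer[int(p)]])
    first_pam = str(rng.choice(list(_BASES)))
    if spec.pam_ok:
        pam = first_pam + "GG"
    else:
        while True:
            tail = "".join(rng.choice(list(_BASES), size=2))
            if tail != "GG":
                break
        pam = first_pam + tail
    return "".join(spacer), pam


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    size: int,
    length: int,
    margin: int = 120,
    attempts: int = 1000,
) -> int:
    for _ in range(attempts):
        pos = int(rng.integers(margin, length - margin - size))
        if all(pos + size + 5 <= s or e + 5 <= pos for s, e in occupied):
            occupied.append((pos, pos + size))
            return pos
    raise RuntimeError("infeasible packing: could not place all planted features")


def simulate_genome(
    guide: GuideRNA,
    *,
    length: int = 5000,
    sites: Sequence[SiteSpec] = (),
    homopolymers: Sequence[HomopolymerSpec] = (),
    lc_intervals: Sequence[tuple[int, int]] = (),
    variants: Sequence[VariantSpec] = (),
    seed: int = 0,
    chrom: str = "chrSim",
    flank: int = 100,
    min_qual: float = 30.0,
    min_run: int = 8,
) -> GenomeSim:
    """Build a toy genome with planted features and a per-variant truth table.

    The background sequence carries no homopolymer runs longer than 3 bp, so
    planted runs are the only ones the flank filter can see. The truth table
    is constructed from the planting plan alone (never by running the triage
    code) and records, per variant, the expected verdict of every filter and
    whether a qualifying guide-like site lies fully within its flank.
    """
    from .locus import revcomp

    rng = np.random.default_rng(seed)
    seq = _background(length, rng)
    occupied: list[tuple[int, int]] = []
    L = len(guide)

    planted_sites: list[PlantedSite] = []
    for spec in sites:
        site_seq, pam = _site_segment(guide, spec, rng)
        segment = site_seq + pam if spec.strand == "+" else revcomp(site_seq + pam)
        size = L + 3
        if spec.pos is not None:
            pos = spec.pos
            occupied.append((pos, pos + size))
        else:
            pos = _place(rng, occupied, size, length)
        seq[pos : pos + size] = list(segment)
        # break any run continuing across the junctions
        for edge, inside in ((pos - 1, segment[0]), (pos + size, segment[-1])):
            if 0 <= edge < length and seq[edge] == inside:
                seq[edge] = next(b for b in _BASES if b != inside and b != seq[edge - 1 if edge else 0])
        ps_start = pos if spec.strand == "+" else pos + 3
        planted_sites.append(
            PlantedSite(
                spec=spec,
                footprint_start=pos,
                protospacer_start=ps_start,
                site_seq=site_seq,
                pam=pam,
            )
        )

    planted_runs: list[tuple[str, int, int]] = []
    for spec in homopolymers:
        size = spec.run
        pos = spec.pos if spec.pos is not None else _place(rng, occupied, size, length)
        if spec.pos is not None:
            occupied.append((pos, pos + size))
        seq[pos : pos + size] = [spec.base] * size
        for edge in (pos - 1, pos + size):
            if 0 <= edge < length and seq[edge] == spec.base:
                seq[edge] = next(b for b in _BASES if b != spec.base)
        planted_runs.append((spec.base, spec.run, pos))

    sequence = "".join(seq)

    merged_lc = sorted((int(s), int(e)) for s, e in lc_intervals)
    candidates: list[VariantCandidate] = []
    known_records: list[VariantCandidate] = []
    truth: list[dict] = []
    for idx, vspec in enumerate(variants):
        if vspec.near_site is not None:
            site = planted_sites[vspec.near_site]
            p0 = site.protospacer_start + vspec.offset  # 0-based
        elif vspec.pos is not None:
            p0 = vspec.pos - 1
        else:
            p0 = _place(rng, occupied, 4, length)
        if vspec.kind == "snv":
            ref = sequence[p0]
            alt = next(b for b in _BASES if b != ref)
        elif vspec.kind == "del":
            ref = sequence[p0 : p0 + 3]
            alt = sequence[p0]
        elif vspec.kind == "ins":
            ref = sequence[p0]
            alt = ref + "TAC"
        else:
            raise ValueError(f"unknown variant kind {vspec.kind!r}")
        cand = VariantCandidate(chrom=chrom, pos=p0 + 1, ref=ref, alt=alt, qual=vspec.qual)
        candidates.append(cand)
        if vspec.known:
            known_records.append(
                VariantCandidate(chrom=chrom, pos=p0 + 1, ref=ref, alt=alt, qual=None)
            )

        span0, span1 = cand.span
        exp_quality = vspec.qual >= min_qual
        exp_lc = any(s < span1 and span0 < e for s, e in merged_lc)
        win0, win1 = max(0, p0 - flank), min(length, p0 + flank + 1)
        exp_homopolymer = any(
            min(r_pos + r_run, win1) - max(r_pos, win0) >= min_run
            for _, r_run, r_pos in planted_runs
        )
        exp_site = False
        for site in planted_sites:
            f0 = site.footprint_start
            f1 = f0 + L + 3
            if win0 <= f0 and f1 <= win1 and site.qualifies:
                exp_site = True
        passes = exp_quality and not vspec.known and not exp_lc and not exp_homopolymer
        truth.append(
            {
                "variant_index": idx,
                "chrom": chrom,
                "pos": p0 + 1,
                "ref": ref,
                "alt": alt,
                "kind": cand.kind,
                "expect_quality_pass": exp_quality,
                "expect_known_fail": vspec.known,
                "expect_lc_fail": exp_lc,
                "expect_homopolymer_fail": exp_homopolymer,
                "expect_site_hit": exp_site,
                "expect_potential_offtarget": passes and exp_site,
            }
        )

    return GenomeSim(
        chrom=chrom,
        sequence=sequence,
        guide=guide,
        sites=planted_sites,
        homopolymers=planted_runs,
        lc_intervals=merged_lc,
        candidates=candidates,
        known=known_records,
        truth=truth,
    )
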