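"""Readers/writers for FASTA, VCF and BED, run configuration and the pipeline.

VCF positions are 1-based only at the file boundary; everything internal is
0-based half-open. BED intervals are 0-based half-open and merged on read
(touching intervals merge — this affects reporting granularity only, never
an overlap verdict).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from . import __version__
from .alleles import classify_pool
from .cohort import (
    EmbryoGenotype,
    genotype_embryo,
    pairwise_chi2,
    summarize_group,
)
from .locus import GuideRNA, TargetLocus, normalize_seq
from .triage import VariantCandidate

logger = logging.getLogger("becall")


class FormatError(ValueError):
    """A standard-format file violates its contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving {id: sequence} mapping.

    Sequences are uppercased with U mapped to T; duplicate or empty record
    ids raise :class:`FormatError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_seq(str(rec.seq))
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantCandidate]:
    """Read a VCF 4.x into candidates, splitting multi-allelic records.

    1-based positions are preserved; a missing QUAL (".") becomes None.
    """
    candidates: list[VariantCandidate] = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    candidates.append(
                        VariantCandidate(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=str(alt).upper(),
                            qual=None if rec.qual is None else float(rec.qual),
                        )
                    )
    except (ValueError, OSError) as err:
        raise FormatError(f"{path}: malformed VCF ({err})") from err
    return candidates


def write_vcf(
    records: Iterable[VariantCandidate],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write candidates as a minimal uncompressed VCF 4.2."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=becall {__version__}\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            qual = "." if rec.qual is None else f"{rec.qual:g}"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t{qual}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3+ into {contig: sorted merged 0-based half-open intervals}.

    Unsorted input is sorted internally; touching intervals merge. A start
    >= end raises :class:`FormatError`.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with < 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from err
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            raw.setdefault(chrom, []).append((start, end))
    return {chrom: merge_intervals(ivs) for chrom, ivs in raw.items()}


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge intervals; touching intervals ([0,10) + [10,20)) merge."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def write_bed(intervals: Mapping[str, Sequence[tuple[int, int]]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom in intervals:
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    """Config-file description of one target locus."""

    name: str
    amplicon_fasta: str
    protospacer_start: int
    strand: str
    guide_name: str
    guide_spacer: str | None = None  # inline spacer, or
    guide_fasta: str | None = None  # FASTA holding the spacer under guide_name
    amplicon_id: str | None = None  # defaults to the first record
    window: tuple[int, int] = (4, 8)


@dataclass
class GroupSpec:
    """One experimental group: a locus name plus clone-pool FASTA paths.

    Pool FASTA headers may be ``embryoID/cloneID``; headers without a slash
    put every record of the file into one embryo named after the file stem.
    """

    name: str
    locus: str
    pools: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    """Full pipeline configuration (serializes round-trip through YAML)."""

    loci: list[LocusSpec] = field(default_factory=list)
    groups: list[GroupSpec] = field(default_factory=list)
    min_support: float = 1
    min_identity: float = 0.6
    min_qual: float = 30.0
    flank: int = 100
    max_mm: int = 5
    seed_len: int = 10
    min_run: int = 8
    seed: int = 0
    output_dir: str = "becall_out"

    def to_dict(self) -> dict:
        return {
            "loci": [
                {**vars(l), "window": list(l.window)} for l in self.loci
            ],
            "groups": [vars(g) for g in self.groups],
            "min_support": self.min_support,
            "min_identity": self.min_identity,
            "min_qual": self.min_qual,
            "flank": self.flank,
            "max_mm": self.max_mm,
            "seed_len": self.seed_len,
            "min_run": self.min_run,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        loci = [
            LocusSpec(**{**spec, "window": tuple(spec.get("window", (4, 8)))})
            for spec in data.get("loci", [])
        ]
        groups = [GroupSpec(**spec) for spec in data.get("groups", [])]
        keys = (
            "min_support",
            "min_identity",
            "min_qual",
            "flank",
            "max_mm",
            "seed_len",
            "min_run",
            "seed",
            "output_dir",
        )
        kwargs = {k: data[k] for k in keys if k in data}
        return cls(loci=loci, groups=groups, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_locus(spec: LocusSpec, base_dir: str | Path = ".") -> TargetLocus:
    """Materialize a TargetLocus from its config spec (paths relative to base_dir)."""
    base = Path(base_dir)
    amplicons = read_fasta(base / spec.amplicon_fasta)
    if spec.amplicon_id is not None:
        try:
            amplicon = amplicons[spec.amplicon_id]
        except KeyError:
            raise FormatError(
                f"locus {spec.name!r}: amplicon id {spec.amplicon_id!r} not in FASTA"
            ) from None
    else:
        amplicon = next(iter(amplicons.values()))
    if spec.guide_spacer is not None:
        spacer = spec.guide_spacer
    elif spec.guide_fasta is not None:
        guides = read_fasta(base / spec.guide_fasta)
        try:
            spacer = guides[spec.guide_name]
        except KeyError:
            raise FormatError(
                f"locus {spec.name!r}: guide {spec.guide_name!r} not in FASTA"
            ) from None
    else:
        raise FormatError(f"locus {spec.name!r}: need guide_spacer or guide_fasta")
    return TargetLocus(
        name=spec.name,
        amplicon=amplicon,
        protospacer_start=spec.protospacer_start,
        strand=spec.strand,
        guide=GuideRNA(name=spec.guide_name, spacer=spacer),
        window=spec.window,
    )


def read_clone_pools(
    paths: Sequence[str | Path], base_dir: str | Path = "."
) -> dict[str, dict[str, str]]:
    """Read clone pools: multi-FASTA with embryoID/cloneID headers, or one
    file per embryo (headers without a slash, embryo named after the file)."""
    pools: dict[str, dict[str, str]] = {}
    base = Path(base_dir)
    for raw_path in paths:
        path = base / raw_path
        records = read_fasta(path)
        for header, seq in records.items():
            if "/" in header:
                embryo_id, clone_id = header.split("/", 1)
            else:
                embryo_id, clone_id = path.stem, header
            pool = pools.setdefault(embryo_id, {})
            if clone_id in pool:
                raise FormatError(f"{path}: duplicate clone {clone_id!r} in {embryo_id!r}")
            pool[clone_id] = seq
    return pools


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    config: RunConfig
    genotypes: dict[str, list[EmbryoGenotype]]  # group -> embryos
    summaries: list
    chi2_rows: list[dict]
    outputs: dict[str, Path]
    stage_counts: dict


GROUP_TSV_COLUMNS = [
    "group",
    "n_total",
    "n_mutant",
    "pct_mutant",
    "n_proximal",
    "ratio_proximal_over_mutant",
    "ratio_proximal_over_total",
]


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> PipelineReport:
    """Classify every clone pool, genotype embryos, and write the report bundle.

    Outputs (TSV column order mirrors the summary-table layout so diffs
    against expected fixtures stay stable): per-clone events, per-embryo
    genotypes, per-group summary, pairwise chi-square table, and a JSON
    run summary with the package version, config hash and per-stage counts.
    """
    base = Path(base_dir)
    outdir = base / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    loci = {spec.name: load_locus(spec, base) for spec in config.loci}

    event_rows: list[dict] = []
    embryo_rows: list[dict] = []
    genotypes: dict[str, list[EmbryoGenotype]] = {}
    n_clones = n_excluded = 0
    for group in config.groups:
        try:
            locus = loci[group.locus]
        except KeyError:
            raise FormatError(
                f"group {group.name!r}: unknown locus {group.locus!r}"
            ) from None
        pools = read_clone_pools(group.pools, base)
        group_genotypes: list[EmbryoGenotype] = []
        for embryo_id in sorted(pools):
            calls, excluded = classify_pool(
                locus, pools[embryo_id], min_identity=config.min_identity
            )
            n_clones += len(pools[embryo_id])
            n_excluded += len(excluded)
            for clone_id, reason in excluded.items():
                logger.warning("excluded clone %s/%s: %s", embryo_id, clone_id, reason)
            genotype = genotype_embryo(embryo_id, calls, min_support=config.min_support)
            group_genotypes.append(genotype)
            for call in calls:
                for event in call.events:
                    event_rows.append(
                        {
                            "group": group.name,
                            "embryo_id": embryo_id,
                            "clone_id": call.clone_id,
                            "rel_position": event.rel.value,
                            "region": event.rel.region,
                            "kind": event.kind,
                            "ref": event.ref,
                            "alt": event.alt,
                            "category": event.category,
                            "strand_call": event.strand_call,
                        }
                    )
            embryo_rows.append(
                {
                    "group": group.name,
                    "embryo_id": embryo_id,
                    "n_clones": genotype.n_clones,
                    "genotype_class": genotype.genotype_class,
                    "is_mutant": genotype.is_mutant,
                    "has_proximal": genotype.has_proximal,
                    "has_indel": genotype.has_indel,
                    "patterns": "|".join(
                        f"{k}:{v}" for k, v in sorted(genotype.distinct_patterns.items())
                    ),
                }
            )
        genotypes[group.name] = group_genotypes

    summaries = [
        summarize_group(name, group_genotypes)
        for name, group_genotypes in genotypes.items()
    ]
    chi2_rows = pairwise_chi2(summaries)

    group_rows = [
        {
            "group": s.group_name,
            "n_total": s.n_total,
            "n_mutant": s.n_mutant,
            "pct_mutant": _blank(s.pct_mutant),
            "n_proximal": s.n_proximal,
            "ratio_proximal_over_mutant": _blank(s.ratio_proximal_over_mutant),
            "ratio_proximal_over_total": _blank(s.ratio_proximal_over_total),
        }
        for s in summaries
    ]

    outputs = {
        "events": outdir / "clone_events.tsv",
        "embryos": outdir / "embryo_genotypes.tsv",
        "groups": outdir / "group_summary.tsv",
        "chi2": outdir / "pairwise_chi2.tsv",
        "summary": outdir / "run_summary.json",
    }
    pd.DataFrame(event_rows).to_csv(outputs["events"], sep="\t", index=False)
    pd.DataFrame(embryo_rows).to_csv(outputs["embryos"], sep="\t", index=False)
    pd.DataFrame(group_rows, columns=GROUP_TSV_COLUMNS).to_csv(
        outputs["groups"], sep="\t", index=False
    )
    pd.DataFrame(chi2_rows).to_csv(outputs["chi2"], sep="\t", index=False)

    stage_counts = {
        "n_loci": len(loci),
        "n_groups": len(config.groups),
        "n_embryos": sum(len(v) for v in genotypes.values()),
        "n_clones": n_clones,
        "n_clones_excluded": n_excluded,
        "n_events": len(event_rows),
    }
    run_summary = {
        "tool": "becall",
        "version": __version__,
        "config_hash": config.config_hash(),
        "stage_counts": stage_counts,
        "groups": group_rows,
    }
    with open(outputs["summary"], "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineReport(
        config=config,
        genotypes=genotypes,
        summaries=summaries,
        chi2_rows=chi2_rows,
        outputs=outputs,
        stage_counts=stage_counts,
    )


def _blank(value: float | None) -> float | str:
    return "" if value is None else value
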