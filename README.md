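# becall

Analysis toolkit for cytidine base-editor experiments in zygotes.

Base editors (a cytidine deaminase fused to a catalytically dead or nicking
Cas9 plus a uracil-glycosylase inhibitor) convert C·G to T·A at
guide-RNA-directed sites, concentrated in a deamination window at
protospacer positions 4–8. In embryo experiments the outcomes are read out
by PCR-amplifying the target locus, subcloning, and Sanger-sequencing
individual clones; off-target activity is assessed by whole-genome
sequencing followed by variant triage. `becall` implements the computational
side of that workflow for people running or reviewing such experiments:

- **Allele classification** — global alignment of each subcloned allele to
  its reference amplicon; every difference becomes an event with a
  deamination category (window, on-target, target-strand, non-canonical,
  proximal-site, other substitution, indel) and a strand call, in
  protospacer-relative coordinates (position 1 = PAM-distal end, PAM at
  L+1..L+3, negative positions upstream).
- **Genotyping and cohort statistics** — clone tallies per allele pattern;
  embryo genotype classes (wild type / heterozygous / homozygous /
  biallelic / mosaic); per-group summaries with mutant %, proximal-site
  deaminated/mutant % and proximal/total % (half-even rounding to one
  decimal); founder-litter summaries; pairwise Pearson χ² (df = 1, no
  continuity correction) between groups.
- **Off-target variant triage** — from a called-variant VCF: quality,
  known-variant, low-complexity (BED) and flank-homopolymer (runs > 7 bp
  within ±100 bp) filters, then an exhaustive both-strand scan of each
  survivor's ±100 bp flank for guide-like sites: protospacer-length windows
  with an NGG PAM, accepted at ≤ 5 mismatches or an exact 3' 10-nt seed
  match.
- **Synthetic data** — a per-lineage stochastic editing model that
  generates clone pools with exact ground truth, and a toy-genome generator
  that plants guide-like sites, homopolymers, repeat intervals and variant
  candidates with a per-variant truth table, so the whole pipeline is
  testable without any external data.

## Worked example

```python
from becall import call_allele, chi2_2x2, genotype_embryo, summarize_group
from becall.alleles import classify_pool
from becall.simulate import demo_locus, EditingModel, simulate_cohort

locus = demo_locus()          # synthetic 143-bp amplicon, 20-nt guide, TGG PAM

# one clone carrying a window edit and a proximal-site edit
clone = locus.amplicon
for rel, alt in [(5, "T"), (-10, "T")]:
    off = locus.from_relative(rel)
    clone = clone[:off] + alt + clone[off + 1:]
call = call_allele(locus, "clone1", clone)
print(call.pattern_key)
for e in call.events:
    print(e.rel.value, e.ref, ">", e.alt, e.category, e.strand_call)
```

prints

```
-10C>T;5C>T
-10 C > T proximal_site_deamination non_target
5 C > T window_deamination non_target
```

the allele pattern key and its two events: the C>T at protospacer position
5 is canonical window deamination on the non-target strand, while the C>T
at −10 lies 10 bp upstream of the protospacer — proximal-site deamination.

```python
sim = simulate_cohort(locus, EditingModel(), n_embryos=50, seed=7)
genotypes = []
for embryo in sim.embryos:
    calls, _ = classify_pool(locus, embryo.clones)
    genotypes.append(genotype_embryo(embryo.embryo_id, calls))
s = summarize_group("demo", genotypes)
print(s.n_total, s.n_mutant, s.pct_mutant, s.ratio_proximal_over_mutant)
```

prints

```
50 28 56.0 46.4
```

50 simulated embryos of which 28 carry at least one supported edited allele
pattern (56.0% mutant), and 46.4% of those mutants also carry a
proximal-site edit. A χ² comparison between two groups'
proximal-composition, `chi2_2x2(3, 3, 15, 11)`, returns
`(0.117, 0.732)` — no significant difference.

The same stages are available from the shell:

```bash
becall simulate cohort --seed 7 --n-embryos 24 --out sim/
becall run -c run.yaml
becall simulate genome --seed 3 --out gsim/
becall triage --vcf gsim/candidates.vcf --genome gsim/genome.fa \
    --known gsim/known.vcf --bed gsim/lowcomplexity.bed \
    --guide-seq GTACCAGTGATCGATTGATG --out triage/
```

`becall run` reads a YAML config (loci, group manifests, thresholds) and
writes per-clone event, per-embryo genotype, per-group summary and pairwise
χ² tables plus a JSON run summary; `becall triage` writes an annotated
candidate table and a summary that ends in either a count of potential
off-target-associated variants or the "no potential off-target site indel
or SNV" outcome.

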