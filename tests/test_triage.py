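"""Variant triage filters and the guide-like site scanner."""

import random

import pytest

from becall.locus import revcomp
from becall.simulate import (
    HomopolymerSpec,
    SiteSpec,
    VariantSpec,
    demo_locus,
    simulate_genome,
)
from becall.triage import (
    ALL_FILTERS,
    ConfigurationError,
    NO_OFFTARGET_OUTCOME,
    PASS,
    RULE_FULL,
    RULE_SEED,
    VariantCandidate,
    filter_flank_homopolymer,
    filter_known,
    filter_low_complexity,
    filter_quality,
    longest_homopolymer,
    scan_guide_sites,
    triage,
)

from _oracles import brute_scan


@pytest.fixture(scope="module")
def guide():
    return demo_locus().guide


def snv(pos, chrom="chr1", ref="A", alt="T", qual=50.0):
    return VariantCandidate(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "qual, verdict_pass", [(50.0, True), (10.0, False), (30.0, True), (None, True)]
    )
    def test_threshold_and_missing_qual(self, qual, verdict_pass):
        c = snv(100, qual=qual)
        filter_quality(c, 30.0)
        assert (c.verdicts["quality"] == PASS) is verdict_pass


class TestKnownFilter:
    def test_exact_match_fails(self):
        c = snv(100)
        filter_known(c, {("chr1", 100, "A", "T")})
        assert c.verdicts["known_variant"] == "fail:known_variant"

    def test_same_position_different_alt_passes_exact_mode(self):
        c = snv(100, alt="G")
        filter_known(c, {("chr1", 100, "A", "T")})
        assert c.verdicts["known_variant"] == PASS

    def test_position_mode(self):
        c = snv(100, alt="G")
        filter_known(c, {("chr1", 100)}, match_mode="position")
        assert c.verdicts["known_variant"] == "fail:known_variant"

    def test_planted_overlap_counts(self):
        known = {("chr1", p, "A", "T") for p in range(1, 201)}
        candidates = [snv(p) for p in range(1, 1001)]
        for c in candidates:
            filter_known(c, known)
        n_fail = sum(c.verdicts["known_variant"] != PASS for c in candidates)
        assert n_fail == 200


class TestLowComplexityFilter:
    IVS = {"chr1": [(99, 200)]}  # 0-based half-open

    def test_snv_inside_fails(self):
        c = snv(150)
        filter_low_complexity(c, self.IVS)
        assert c.verdicts["low_complexity"] == "fail:low_complexity"

    def test_half_open_boundary(self):
        # 1-based pos 200 -> 0-based 199, last covered base: fails
        c = snv(200)
        filter_low_complexity(c, self.IVS)
        assert c.verdicts["low_complexity"] == "fail:low_complexity"
        # 1-based pos 201 -> 0-based 200, first base outside: passes
        c = snv(201)
        filter_low_complexity(c, self.IVS)
        assert c.verdicts["low_complexity"] == PASS

    def test_deletion_straddling_interval_edge_fails(self):
        c = VariantCandidate(chrom="chr1", pos=196, ref="AAAAA", alt="A", qual=50.0)
        filter_low_complexity(c, self.IVS)
        assert c.verdicts["low_complexity"] == "fail:low_complexity"

    def test_deletion_entirely_outside_passes(self):
        c = VariantCandidate(chrom="chr1", pos=201, ref="AAAAA", alt="A", qual=50.0)
        filter_low_complexity(c, self.IVS)
        assert c.verdicts["low_complexity"] == PASS


class TestHomopolymerFilter:
    def _genome(self, run_base, run_len, at, length=400):
        """Run-free background with one guarded homopolymer run planted."""
        rng = random.Random(0)
        bases = []
        for _ in range(length):
            prev = bases[-3:]
            pool = [b for b in "ACGT" if not (len(prev) == 3 and all(p == b for p in prev))]
            bases.append(rng.choice(pool))
        seq = "".join(bases)
        guard = "T" if run_base != "T" else "A"
        insert = guard + run_base * run_len + guard
        return {"chr1": seq[:at] + insert + seq[at + len(insert):]}

    def test_eight_base_run_fails(self):
        genome = self._genome("A", 8, 150)
        c = snv(120, ref=genome["chr1"][119])
        filter_flank_homopolymer(c, genome)
        assert c.verdicts["flank_homopolymer"] == "fail:flank_homopolymer"

    def test_seven_base_run_passes(self):
        genome = self._genome("C", 7, 150)
        c = snv(120, ref=genome["chr1"][119])
        filter_flank_homopolymer(c, genome)
        assert c.verdicts["flank_homopolymer"] == PASS

    def test_run_split_by_window_edge_passes(self):
        # run of 8 starting 98 bp after the variant: only 3 bases inside +/-100
        genome = self._genome("G", 8, 219)
        c = snv(122)
        filter_flank_homopolymer(c, genome)
        assert c.verdicts["flank_homopolymer"] == PASS

    def test_window_clipped_at_contig_start(self):
        genome = self._genome("T", 8, 0)
        c = snv(5)
        filter_flank_homopolymer(c, genome)
        assert c.verdicts["flank_homopolymer"] == "fail:flank_homopolymer"

    def test_variant_beyond_contig_raises(self):
        genome = {"chr1": "ACGT" * 50}
        with pytest.raises(IndexError):
            filter_flank_homopolymer(snv(10_000), genome)

    def test_longest_run_helper(self):
        assert longest_homopolymer("AAACCCCCGT") == 5
        assert longest_homopolymer("") == 0


class TestScanner:
    def test_exact_site_with_agg_pam(self, guide):
        flank = "TTAC" + guide.spacer + "AGG" + "CATT"
        hits = scan_guide_sites(flank, 1000, guide)
        exact = [h for h in hits if h.start == 1004 and h.strand == "+"]
        assert len(exact) == 1
        assert exact[0].mismatches == 0 and exact[0].rule == RULE_FULL

    def test_seed_only_site_reported_under_seed_rule(self, guide):
        window = "ACCAAC" + guide.spacer[6:]  # 6 mismatches, all 5' of the seed
        assert sum(a != b for a, b in zip(window, guide.spacer)) == 6
        flank = "AC" + window + "TGG" + "GTTA"
        hits = scan_guide_sites(flank, 0, guide)
        seed_hits = [h for h in hits if h.start == 2 and h.strand == "+"]
        assert len(seed_hits) == 1
        assert seed_hits[0].rule == RULE_SEED and seed_hits[0].mismatches == 6

    def test_pam_violation_rejects_even_perfect_window(self, guide):
        flank = "TTAC" + guide.spacer + "ATT" + "CATT"
        assert scan_guide_sites(flank, 0, guide) == []

    def test_both_rules_reported_once_as_full_budget(self, guide):
        window = "T" + guide.spacer[1:]  # 1 mismatch, seed intact
        flank = "AC" + window + "CGG"
        hits = [h for h in scan_guide_sites(flank, 0, guide) if h.start == 2]
        assert len(hits) == 1 and hits[0].rule == RULE_FULL

    def test_short_flank_yields_nothing(self, guide):
        assert scan_guide_sites(guide.spacer[:10], 0, guide) == []

    def test_agreement_with_brute_force_on_planted_genome(self, guide):
        site_specs = []
        for mm in range(0, 8):
            for seed_intact in (True, False):
                if seed_intact and mm > 10:
                    continue
                site_specs.append(SiteSpec(mismatches=mm, seed_intact=seed_intact))
                site_specs.append(
                    SiteSpec(mismatches=mm, seed_intact=seed_intact, strand="-")
                )
        # PAM-violating decoys
        site_specs += [SiteSpec(mismatches=0, pam_ok=False), SiteSpec(mismatches=2, pam_ok=False, strand="-")]
        sim = simulate_genome(guide, length=6000, sites=site_specs, seed=5)
        got = {
            (h.start, h.strand): (h.mismatches, h.rule)
            for h in scan_guide_sites(sim.sequence, 0, guide)
        }
        assert got == brute_scan(sim.sequence, guide.spacer)
        # every qualifying planted site recovered; every decoy absent
        for site in sim.sites:
            key = (site.protospacer_start, site.spec.strand)
            assert (key in got) == site.qualifies, site.spec

    def test_strand_symmetry_mirrors_matches(self, guide):
        sim = simulate_genome(
            guide, length=2000, sites=[SiteSpec(mismatches=2), SiteSpec(mismatches=4, strand="-")], seed=9
        )
        n = len(sim.sequence)
        fwd = scan_guide_sites(sim.sequence, 0, guide)
        rev = scan_guide_sites(revcomp(sim.sequence), 0, guide)
        mirrored = {
            (n - h.start - len(guide), {"+": "-", "-": "+"}[h.strand], h.mismatches)
            for h in rev
        }
        assert {(h.start, h.strand, h.mismatches) for h in fwd} == mirrored

    def test_truncated_guide_seed_is_its_three_prime_end(self):
        guide = demo_locus(guide_length=16).guide
        window = "AAAA" + guide.spacer[4:]
        flank = "AT" + window + "AGG" + "TT"
        hits = scan_guide_sites(flank, 0, guide)
        assert any(h.rule == RULE_FULL and h.mismatches <= 5 for h in hits) or any(
            h.rule == RULE_SEED for h in hits
        )


class TestTriagePipeline:
    def test_empty_candidate_list(self, guide):
        sim = simulate_genome(guide, length=1500, seed=3)
        report = triage([], sim.genome, set(), {}, guide)
        assert report.n_candidates == 0
        assert report.outcome == NO_OFFTARGET_OUTCOME

    def test_planted_truth_fixture(self, guide):
        sim = simulate_genome(
            guide,
            length=6000,
            sites=[
                SiteSpec(mismatches=3),
                SiteSpec(mismatches=6, seed_intact=True, strand="-"),
                SiteSpec(mismatches=5, seed_intact=False, pam_ok=False),
                SiteSpec(mismatches=7, seed_intact=False),
            ],
            homopolymers=[HomopolymerSpec("A", 8), HomopolymerSpec("T", 7)],
            lc_intervals=[(2400, 2460)],
            variants=[
                VariantSpec(near_site=0, offset=25),
                VariantSpec(near_site=1, offset=-40),
                VariantSpec(near_site=2, offset=15),
                VariantSpec(near_site=3, offset=10),
                VariantSpec(kind="del"),
                VariantSpec(kind="ins"),
                VariantSpec(known=True),
                VariantSpec(qual=10.0),
                VariantSpec(pos=2430),
            ],
            seed=11,
        )
        known = {c.key for c in sim.known}
        report = triage(
            sim.candidates, sim.genome, known, {sim.chrom: sim.lc_intervals}, guide
        )
        for row, cand in zip(sim.truth, report.candidates):
            assert (cand.verdicts["quality"] == PASS) == row["expect_quality_pass"]
            assert (cand.verdicts["known_variant"] != PASS) == row["expect_known_fail"]
            assert (cand.verdicts["low_complexity"] != PASS) == row["expect_lc_fail"]
            assert (cand.verdicts["flank_homopolymer"] != PASS) == row["expect_homopolymer_fail"]
            assert cand.is_potential_offtarget == row["expect_potential_offtarget"]
        n_expected = sum(row["expect_potential_offtarget"] for row in sim.truth)
        assert len(report.potential_offtargets) == n_expected >= 2
        for cand in report.potential_offtargets:
            assert all(h.distance_to_variant <= 100 for h in cand.site_hits)

    def test_clean_fixture_reports_no_offtarget_outcome(self, guide):
        sim = simulate_genome(
            guide,
            length=4000,
            sites=[SiteSpec(mismatches=7, seed_intact=False)],  # non-qualifying
            variants=[VariantSpec(), VariantSpec(kind="del"), VariantSpec(known=True)],
            seed=21,
        )
        known = {c.key for c in sim.known}
        report = triage(sim.candidates, sim.genome, known, {}, guide)
        assert report.potential_offtargets == []
        assert report.outcome == NO_OFFTARGET_OUTCOME
        assert report.summary()["n_potential_offtarget"] == 0

    def test_filter_order_independence(self, guide):
        sim = simulate_genome(
            guide,
            length=3000,
            homopolymers=[HomopolymerSpec("A", 9)],
            variants=[VariantSpec(qual=10.0), VariantSpec(known=True), VariantSpec()],
            seed=13,
        )
        known = {c.key for c in sim.known}
        genome = sim.genome
        orders = [
            (filter_quality, filter_known, filter_low_complexity, filter_flank_homopolymer),
            (filter_flank_homopolymer, filter_low_complexity, filter_known, filter_quality),
        ]
        verdict_sets = []
        for order in orders:
            verdicts = []
            for c in sim.candidates:
                c.verdicts.clear()
                for f in order:
                    if f is filter_quality:
                        f(c, 30.0)
                    elif f is filter_known:
                        f(c, known)
                    elif f is filter_low_complexity:
                        f(c, {})
                    else:
                        f(c, genome)
                verdicts.append(dict(c.verdicts))
            verdict_sets.append(verdicts)
        assert verdict_sets[0] == verdict_sets[1]

    def test_contig_mismatch_raises(self, guide):
        with pytest.raises(ConfigurationError, match="chrMissing"):
            triage([snv(5, chrom="chrMissing")], {"chr1": "ACGT" * 100}, set(), {}, guide)

    def test_every_candidate_gets_all_verdicts(self, guide):
        sim = simulate_genome(
            guide, length=2000, variants=[VariantSpec(qual=5.0), VariantSpec()], seed=2
        )
        report = triage(sim.candidates, sim.genome, set(), {}, guide)
        for c in report.candidates:
            assert set(c.verdicts) == set(ALL_FILTERS)
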