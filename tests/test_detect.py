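"""The detection cascade: extraction, filters, silence, causes, ORFs."""

import numpy as np
import pandas as pd
import pytest

from protoscan.detect import (
    CandidateRegion,
    CoverageTracks,
    DetectionParams,
    ProtoGeneDetection,
    ancestral_silence_check,
    classify_cause,
    cross_condition_filter,
    dedup_regions,
    extract_downstream_regions,
    filter_candidate_overlaps,
    find_orfs,
    orfs_for_candidate,
    survey_is_downstream,
)
from protoscan.engineering import MutationRecord, apply_mutations
from protoscan.genome import Feature, GenomeRecord
from protoscan.quantify import CountMatrix


def make_genome(rng, n=10_000, feats=()):
    return GenomeRecord(
        name="g", sequence="".join(rng.choice(list("ACGT"), size=n)), features=list(feats)
    )


class TestExtraction:
    def test_snp_yields_four_regions(self, rng):
        g = make_genome(rng)
        m = MutationRecord(id="s", type="SNP", position=5000, new_base="A")
        _, cmap = apply_mutations(g, [m])
        regions = extract_downstream_regions([m], cmap)
        assert len(regions) == 4
        assert {(r.strand, r.length) for r in regions} == {("+", 100), ("+", 200), ("-", 100), ("-", 200)}
        plus100 = next(r for r in regions if r.strand == "+" and r.length == 100)
        assert (plus100.evo_start, plus100.evo_end) == (5000, 5100)
        minus100 = next(r for r in regions if r.strand == "-" and r.length == 100)
        assert (minus100.evo_start, minus100.evo_end) == (4899, 4999)

    def test_mob_yields_two_regions_single_strand(self, rng):
        g = make_genome(rng)
        elements = {"IS150": "".join(rng.choice(list("ACGT"), size=1443))}
        m = MutationRecord(
            id="mob", type="MOB", position=4000, element="IS150",
            element_length=1443, strand="+", duplication_size=3,
        )
        _, cmap = apply_mutations(g, [m], elements)
        regions = extract_downstream_regions([m], cmap)
        assert len(regions) == 2
        assert {r.strand for r in regions} == {"+"}
        # inserted material spans evolved [4002, 4002+1446); region starts after
        for r in regions:
            assert r.evo_start == 3999 + 3 + 1446

    def test_mob_minus_strand_reads_into_left_flank(self, rng):
        g = make_genome(rng)
        elements = {"IS150": "".join(rng.choice(list("ACGT"), size=1443))}
        m = MutationRecord(
            id="mob", type="MOB", position=4000, element="IS150",
            element_length=1443, strand="-", duplication_size=3,
        )
        _, cmap = apply_mutations(g, [m], elements)
        regions = extract_downstream_regions([m], cmap)
        assert {r.strand for r in regions} == {"-"}
        for r in regions:
            assert r.evo_end == 4002  # inserted material starts here
            assert r.evo_start == 4002 - r.length

    def test_deletion_region_abuts_evolved_junction(self, rng):
        """The + strand region downstream of a deletion starts at the
        junction, whose evolved coordinate the liftover oracle confirms."""
        g = make_genome(rng, n=20_000)
        m = MutationRecord(id="d", type="DEL", position=5001, size=7849 // 2)
        evolved, cmap = apply_mutations(g, [m])
        regions = extract_downstream_regions([m], cmap)
        plus = [r for r in regions if r.strand == "+"]
        junction = cmap.lift_interval(5000 + m.size, 5000 + m.size + 1).start
        for r in plus:
            assert r.evo_start == junction == 5000
            # evolved sequence downstream equals ancestral sequence past the deletion
            assert evolved[r.evo_start : r.evo_end] == g.sequence[5000 + m.size : 5000 + m.size + r.length]
        assert plus[0].anc_start == 5000 + m.size

    def test_region_at_genome_end_truncated(self, rng):
        g = make_genome(rng, n=5000)
        m = MutationRecord(id="s", type="SNP", position=4950, new_base="A")
        _, cmap = apply_mutations(g, [m])
        regions = extract_downstream_regions([m], cmap)
        plus200 = next(r for r in regions if r.strand == "+" and r.length == 200)
        assert plus200.truncated and plus200.evo_end == 5000

    def test_ins_region_excludes_inserted_bases(self, rng):
        g = make_genome(rng)
        m = MutationRecord(id="i", type="INS", position=3000, sequence="ACGTAC")
        evolved, cmap = apply_mutations(g, [m])
        regions = extract_downstream_regions([m], cmap)
        plus100 = next(r for r in regions if r.strand == "+" and r.length == 100)
        assert evolved[plus100.evo_start : plus100.evo_end] == g.sequence[3000:3100]


class TestOverlapFilter:
    def region(self, start, end, strand="+"):
        r = CandidateRegion(
            mutation_id="m", clone="c", strand=strand, length=end - start,
            evo_start=start, evo_end=end, anc_start=start, anc_end=end,
        )
        return r

    @pytest.mark.parametrize(
        "kind", ["gene", "rna", "pseudogene", "repeat"]
    )
    def test_11bp_same_strand_overlap_excludes(self, kind):
        feats = [Feature("f", 0, 111, "+", kind)]
        r = self.region(100, 300)
        filter_candidate_overlaps([r], feats)
        assert r.excluded and r.excluded_by == "overlap-filter"

    def test_10bp_overlap_retained(self):
        feats = [Feature("f", 0, 110, "+", "gene")]
        r = self.region(100, 300)
        filter_candidate_overlaps([r], feats)
        assert not r.excluded

    def test_opposite_strand_gene_ignored(self):
        feats = [Feature("f", 0, 300, "-", "gene")]
        r = self.region(100, 300)
        filter_candidate_overlaps([r], feats)
        assert not r.excluded

    def test_opposite_strand_repeat_removed_at_dedup(self):
        feats = [Feature("rep", 150, 260, "-", "repeat")]
        r = self.region(100, 300)
        filter_candidate_overlaps([r], feats)
        assert not r.excluded
        dedup_regions([r], feats)
        assert r.excluded and r.excluded_by == "dedup"

    def test_duplicate_regions_keep_first_in_genome_order(self):
        a = self.region(100, 300)
        b = self.region(100, 300)
        b.mutation_id = "m2"
        dedup_regions([b, a], [])
        kept = [r for r in (a, b) if not r.excluded]
        assert len(kept) == 1


class TestSilence:
    def cov(self, plus):
        return CoverageTracks(plus=np.asarray(plus, float), minus=np.zeros_like(np.asarray(plus, float)))

    def region(self, start=100, end=300):
        return CandidateRegion(
            mutation_id="m", clone="c", strand="+", length=end - start,
            evo_start=start, evo_end=end, anc_start=start, anc_end=end,
        )

    def test_all_zero_coverage_silent(self):
        cov = self.cov(np.zeros((2, 1000)))
        assert ancestral_silence_check(self.region(), cov) == "silent"

    def test_uniform_high_coverage_expressed(self):
        cov = self.cov(np.full((2, 1000), 50.0))
        assert ancestral_silence_check(self.region(), cov) == "expressed"

    def test_contiguous_run_breaks_silence(self):
        base = np.zeros((2, 1000))
        base[0, 150:180] = 3.0  # 30-bp run at depth 3, region mean still low
        cov = self.cov(base)
        assert ancestral_silence_check(self.region(), cov) == "ambiguous"

    def test_verdict_stable_under_replicate_ordering(self):
        base = np.zeros((2, 1000))
        base[1, 150:180] = 3.0
        assert ancestral_silence_check(self.region(), self.cov(base)) == "ambiguous"
        assert ancestral_silence_check(self.region(), self.cov(base[::-1])) == "ambiguous"

    def test_missing_coverage_errors(self):
        cov = self.cov(np.zeros((2, 50)))
        with pytest.raises(ValueError):
            ancestral_silence_check(self.region(100, 300), cov)


class TestConditionFilter:
    def counts(self, rows):
        df = pd.DataFrame(rows, index=["m|+|200"])
        return CountMatrix(counts=df, lengths=pd.Series([200], index=df.index))

    def region(self):
        return CandidateRegion(
            mutation_id="m", clone="c", strand="+", length=200,
            evo_start=0, evo_end=200, anc_start=0, anc_end=200,
        )

    def test_zero_everywhere_unseen(self):
        cm = self.counts({f"c{i}": [0] for i in range(34)})
        assert cross_condition_filter(self.region(), cm) == "unseen"

    def test_three_reads_in_one_condition_seen(self):
        cols = {f"c{i}": [0] for i in range(33)}
        cols["c33"] = [3]
        assert cross_condition_filter(self.region(), self.counts(cols)) == "seen"

    def test_two_reads_everywhere_unseen_no_pooling(self):
        cm = self.counts({f"c{i}": [2] for i in range(34)})
        assert cross_condition_filter(self.region(), cm) == "unseen"


class TestClassifyCause:
    def test_mob_is_promoter_recruitment(self, rng):
        g = make_genome(rng)
        m = MutationRecord(id="m", type="MOB", position=100, element="IS150",
                           element_length=1443, strand="+", duplication_size=3)
        assert classify_cause(m, g, "+") == "promoter in insertion sequence"

    def test_large_deletion_with_upstream_gene_is_translocation(self, rng):
        gene = Feature("gA", 3500, 4400, "+", "gene")
        g = make_genome(rng, feats=[gene])
        m = MutationRecord(id="d", type="DEL", position=4501, size=2000)
        assert classify_cause(m, g, "+") == "translocation to existing promoter"

    def test_large_deletion_without_gene(self, rng):
        g = make_genome(rng)
        m = MutationRecord(id="d", type="DEL", position=4501, size=2000)
        assert "no upstream promoter" in classify_cause(m, g, "+")

    def test_snp_is_unknown_promoter_status(self, rng):
        g = make_genome(rng)
        m = MutationRecord(id="s", type="SNP", position=100, new_base="A")
        assert "unknown" in classify_cause(m, g, "+")


class TestOrfs:
    def test_no_start_no_stop_empty(self):
        assert find_orfs("CCC" * 50) == []

    def test_constructed_orf_length(self):
        """ATG + 32 codons + TAA spans 34 codons = 102 bp."""
        rng = np.random.default_rng(0)
        body = "".join(rng.choice(["GCT", "GAA", "CAT", "CGT"], size=32))
        seq = "CCCCC" + "ATG" + body + "TAA" + "CCCCC"
        orfs = find_orfs(seq)
        assert any(o.length == 102 for o in orfs)

    def test_117aa_orf_reports_354_bp(self):
        rng = np.random.default_rng(1)
        body = "".join(rng.choice(["GCT", "GAA", "CAT", "CGT"], size=116))
        seq = "ATG" + body + "TGA"
        assert len(seq) == 354
        orfs = find_orfs(seq)
        assert max(o.length for o in orfs) == 354

    def test_min_length_strictly_greater_than_30(self):
        # 30 bp: start + 8 codons + stop -> excluded; 33 bp -> included
        seq30 = "ATG" + "GCT" * 8 + "TAA"
        seq33 = "ATG" + "GCT" * 9 + "TAA"
        assert find_orfs(seq30, min_len=30) == []
        assert len(find_orfs(seq33, min_len=30)) == 1

    def test_all_three_frames_scanned(self):
        inner = "ATG" + "GCT" * 12 + "TAA"
        for shift in ("", "C", "CC"):
            orfs = find_orfs(shift + inner + "GG")
            assert any(o.length == len(inner) for o in orfs)

    def test_candidate_scan_discards_upstream_only_orfs(self):
        up = "ATG" + "GCT" * 12 + "TAA"          # entirely upstream of anchor
        seq = ("C" * (200 - len(up))) + up + ("G" * 500)
        orfs = orfs_for_candidate(200, seq, "+", DetectionParams(orf_upstream=200, orf_downstream=500))
        assert all(o.end > 200 for o in orfs)
        assert not any(o.length == len(up) for o in orfs)


class TestCascade:
    def test_recovers_planted_events(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        truth = scenario.truth
        eligible = set(truth[~truth.condition_expressed].mutation_id)
        detected = set(res.report.proto_gene_id.str.split("_").str[1])
        assert eligible <= detected | set()
        assert not (detected - set(truth.mutation_id))  # no false positives here

    def test_condition_expressed_plant_excluded_with_reason(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        cond = scenario.truth[scenario.truth.condition_expressed]
        for _, r in cond.iterrows():
            row = res.candidates[
                (res.candidates.mutation_id == r.mutation_id)
                & (res.candidates.strand == r.strand)
            ].iloc[0]
            assert row.status == "excluded"
            assert row.reason == "seen in condition library"

    def test_rerun_same_seed_identical_report(self, default_config):
        from protoscan.detect import run_detection

        a = run_detection(default_config)
        b = run_detection(default_config)
        assert a.report.equals(b.report)
        assert a.candidates.equals(b.candidates)

    def test_trail_completeness(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        for r in res.regions:
            assert r.trail, r.feature_id
            excl = [s for s, v, _ in r.trail if v == "excluded"]
            if r.excluded:
                assert r.excluded_by == excl[0]
            else:
                assert not excl

    def test_no_orphan_protogenes(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        muts = {m.id: m for m in scenario.mutations}
        for _, row in res.report.iterrows():
            mid = row.proto_gene_id.split("_")[1]
            assert mid in muts
            assert muts[mid].position == row.start_position_ancestral

    def test_tightening_alpha_never_adds_protogenes(self, scenario):
        loose = ProtoGeneDetection.from_scenario(scenario, DetectionParams(alpha=0.05)).fit()
        tight = ProtoGeneDetection.from_scenario(scenario, DetectionParams(alpha=0.001)).fit()
        assert set(tight.report.proto_gene_id) <= set(loose.report.proto_gene_id)

    def test_mob_causes_labelled_promoter_recruitment(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        mob = res.report[res.report.mutation_type == "MOB"]
        assert (mob.cause == "promoter in insertion sequence").all()

    def test_ribo_cascade_runs(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        assert res.ribo_report is not None
        assert "novel_translation" in res.report.columns


class TestSurvey:
    def test_counts_mob_insertions(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        table, summary = survey_is_downstream(
            "IS150", res, scenario.mutations, scenario.ancestral_coverage
        )
        n_mob = sum(m.type == "MOB" for m in scenario.mutations)
        assert summary["total"] == len(table) == n_mob
        planted_mobs = set(
            scenario.truth[scenario.truth.mutation_type == "MOB"].mutation_id
        )
        sig = set(table[table.significant].mutation_id)
        assert planted_mobs <= sig
        assert summary["significant"] >= summary["significant_and_silent"]

    def test_no_mob_mutations_empty_table(self, scenario):
        res = ProtoGeneDetection.from_scenario(scenario).fit()
        table, summary = survey_is_downstream("IS999", res, scenario.mutations)
        assert len(table) == 0 and summary["total"] == 0
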