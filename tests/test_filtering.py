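"""Variant exclusion ledger, epigenetic annotation, intergenic selection."""

import numpy as np
import pandas as pd
import pytest

from imaps.filtering import (
    GenomeMask,
    apply_filters,
    annotate_epigenetics,
    select_intergenic_regions,
)


def make_variants(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "pass_flag"])


@pytest.fixture
def toy_genome():
    # 60 bp contig; CpG at 30-31
    seq = "ACGTT" * 5 + "AACGT" + "TTGCA" * 6
    return {"chr1": seq}


class TestApplyFilters:
    def test_strand_ag_rule_counts(self, toy_genome):
        # 12 SNVs of which exactly 3 are A>G or T>C on either strand
        rows = []
        seq = toy_genome["chr1"]
        payload = [
            (10, "G"), (11, "C"), (12, "A"),   # T>G? depends on ref base
        ]
        # construct explicitly: positions with known ref bases
        picks = [
            (6, "C"),   # C>? seq[6]='G'? -- fill below
        ]
        rows = []
        ag = 0
        pos_cycle = [i for i in range(6, 54)]
        for p in pos_cycle:
            refb = seq[p]
            if refb == "A" and ag < 2:
                rows.append(("chr1", p, "A", "G", 1, True)); ag += 1
            elif refb == "T" and ag < 3:
                rows.append(("chr1", p, "T", "C", 2, True)); ag += 1
            elif refb in "ACGT" and len(rows) - ag < 9:
                alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[refb]
                rows.append(("chr1", p, refb, alt, 1, True))
            if len(rows) == 12:
                break
        v = make_variants(rows)
        out, report = apply_filters(v, toy_genome, toy_genome, {})
        assert report.exclusions["strand_ag"] == 3
        assert report.check()

    def test_reference_not_ancestral_excluded(self, toy_genome):
        anc = {"chr1": toy_genome["chr1"][:20] + "T" + toy_genome["chr1"][21:]}
        refb = toy_genome["chr1"][20]
        assert refb != "T"
        v = make_variants([("chr1", 20, refb, "C" if refb != "C" else "G", 1, True)])
        out, report = apply_filters(v, toy_genome, anc, {})
        assert len(out) == 0 and report.exclusions["ancestral"] == 1

    def test_empty_input(self, toy_genome):
        v = make_variants([])
        out, report = apply_filters(v, toy_genome, toy_genome, {})
        assert len(out) == 0
        assert report.check() and all(c == 0 for c in report.exclusions.values())

    def test_quality_and_non_snv(self, toy_genome):
        v = make_variants(
            [("chr1", 10, "T", "C", 1, False), ("chr1", 12, "GT", "G", 1, True)]
        )
        out, report = apply_filters(v, toy_genome, toy_genome, {})
        assert report.exclusions["quality"] == 1
        assert report.exclusions["snv"] == 1

    def test_sex_chromosomes_excluded(self, toy_genome):
        genomes = {"chr1": toy_genome["chr1"], "chrX": toy_genome["chr1"]}
        v = make_variants([("chrX", 10, "T", "A", 1, True)])
        out, report = apply_filters(v, genomes, genomes, {})
        assert report.exclusions["chrom"] == 1

    def test_cpg_without_methylation_excluded(self, toy_genome):
        # CpG at 26-27 ("AACGT" block): C at 26, G at 27
        seq = toy_genome["chr1"]
        assert seq[27:29] == "CG"
        v = make_variants([("chr1", 27, "C", "A", 1, True), ("chr1", 28, "G", "T", 1, True)])
        out, report = apply_filters(v, toy_genome, toy_genome, {})
        assert report.exclusions["cpg_methylation"] == 2
        # with methylation present both survive
        meth = {("chr1", 27): 50.0, ("chr1", 28): 50.0}
        out, report = apply_filters(v, toy_genome, toy_genome, meth)
        assert len(out) == 2

    def test_masks_and_first_match_attribution(self, toy_genome):
        v = make_variants([("chr1", 10, "T", "A", 1, True)])
        lcr = GenomeMask([("chr1", 8, 12)])
        cov = GenomeMask([("chr1", 0, 5)])  # keep-set excludes pos 10
        out, report = apply_filters(
            v, toy_genome, toy_genome, {}, lcr=lcr, coverage_keep=cov
        )
        # LCR precedes coverage in the attribution order
        assert report.exclusions["lcr"] == 1
        assert report.exclusions["coverage"] == 0

    def test_retained_violate_no_predicate(self, toy_genome, rng):
        seq = toy_genome["chr1"]
        rows = []
        for _ in range(50):
            p = int(rng.integers(5, 55))
            refb = seq[p]
            alt = str(rng.choice([b for b in "ACGT" if b != refb]))
            rows.append(("chr1", p, refb, alt, int(rng.integers(1, 4)), bool(rng.random() < 0.9)))
        v = make_variants(rows)
        lcr = GenomeMask([("chr1", 0, 8)])
        out, report = apply_filters(v, toy_genome, toy_genome,
                                    {(("chr1"), i): 50.0 for i in range(60)}, lcr=lcr)
        assert report.check()
        # re-check pass: no survivor violates any single predicate
        for r in out.itertuples():
            assert r.pass_flag
            assert len(r.ref) == 1 and len(r.alt) == 1
            assert (r.ref, r.alt) not in {("A", "G"), ("T", "C")}
            assert not lcr.contains([r.chrom], [r.pos])[0]
            assert all(b in "ACGT" for b in r.window11)

    def test_singleton_flag_matches_allele_count(self, toy_genome):
        v = make_variants(
            [("chr1", 13, "T", "G", 1, True), ("chr1", 14, "T", "A", 7, True)]
        )
        out, _ = apply_filters(v, toy_genome, toy_genome, {})
        assert out["is_singleton"].tolist() == [True, False]

    def test_missing_contig_raises(self, toy_genome):
        v = make_variants([("chr9", 10, "T", "A", 1, True)])
        with pytest.raises(KeyError):
            apply_filters(v, {"chr9": toy_genome["chr1"]}, toy_genome, {})


class TestAnnotate:
    def test_flags_and_meth_bins(self, toy_genome):
        v = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [10, 40],
                "alt": ["A", "C"],
                "window11": ["ACGTTACGTTA", "GCATTGCATTG"],
            }
        )
        dnase = GenomeMask([("chr1", 0, 20)])
        out = annotate_epigenetics(v, dnase, None, {("chr1", 10): 45.0})
        assert out["dnase"].tolist() == [True, False]
        assert not out["h3k9me3"].any()
        assert out["meth"].iloc[0] == 45.0

    def test_cpg_transition_missing_meth_marked(self):
        v = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [5],
                "alt": ["T"],
                "window11": ["AAAAACGAAAA"],
            }
        )
        out = annotate_epigenetics(v, None, None, {})
        assert out["exclude_missing_meth"].iloc[0]


class TestIntergenicSelection:
    def test_single_gene_flanks_end_at_buffer(self):
        regions = select_intergenic_regions(
            [("chr1", 400_000, 500_000)], {"chr1": 1_000_000}
        )
        assert regions == [("chr1", 0, 375_000), ("chr1", 525_000, 1_000_000)]

    def test_percentile_cap_by_hand_example(self):
        # region lengths 10/20/30/100 kb; with the nearest-rank (lower)
        # convention the 75th percentile is 30 kb -> cap 45 kb
        chroms = {"c1": 10_000, "c2": 20_000, "c3": 30_000, "c4": 100_000}
        regions = select_intergenic_regions([], chroms, percentile_method="lower")
        lens = sorted(e - s for _, s, e in regions)
        assert lens == [10_000, 20_000, 30_000, 45_000]

    def test_linear_interpolation_default(self):
        chroms = {"c1": 10_000, "c2": 20_000, "c3": 30_000, "c4": 100_000}
        regions = select_intergenic_regions([], chroms)
        lens = sorted(e - s for _, s, e in regions)
        # np.percentile linear: 47.5 kb -> cap 71.25 kb
        assert lens == [10_000, 20_000, 30_000, 71_250]

    def test_no_annotations_whole_chromosome_minus_gaps(self):
        regions = select_intergenic_regions(
            [], {"chr1": 50_000}, gaps=[("chr1", 10_000, 12_000)], cap_factor=100.0
        )
        assert regions == [("chr1", 0, 10_000), ("chr1", 12_000, 50_000)]

    def test_gap_and_centromere_subtracted(self):
        regions = select_intergenic_regions(
            [("chr1", 0, 1_000)],
            {"chr1": 100_000},
            centromeres=[("chr1", 50_000, 60_000)],
            cap_factor=100.0,
        )
        assert regions == [("chr1", 26_000, 50_000), ("chr1", 60_000, 100_000)]


class TestGenomeMask:
    def test_membership_and_merge(self):
        m = GenomeMask([("c", 10, 20), ("c", 15, 30), ("d", 0, 5)])
        assert m.intervals() == [("c", 10, 30), ("d", 0, 5)]
        hits = m.contains(["c", "c", "c", "d", "e"], [9, 10, 29, 4, 0])
        assert hits.tolist() == [False, True, True, True, False]
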