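"""ReP site calling, positional permutation test, controls, sharing."""

import numpy as np
import pytest

from imaps.psam import PSAM, scan
from imaps.rep_sites import (
    Peak,
    RepSite,
    call_rep_sites,
    control_sites,
    conservation_enrichment,
    positional_enrichment_test,
    rep_site_offsets,
    sample_control_regions,
    shared_across_cell_lines,
)
from imaps.simulate import SimConfig, gen_psam_and_peaks, gen_reference


@pytest.fixture(scope="module")
def planted():
    ref = gen_reference(SimConfig(seed=5))
    psam, peaks, truth, genome = gen_psam_and_peaks(
        ref, "RBP1", 11, 30, seed=7, planted_offset=20
    )
    return psam, peaks, truth, genome


class TestCalling:
    def test_planted_motif_found_at_offset(self, planted):
        psam, peaks, truth, genome = planted
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        assert len(sites) == len(peaks)
        assert all(s.offset == 20 for s in sites)
        got = {(s.chrom, s.start, s.end) for s in sites}
        want = {(r.chrom, r.start, r.end) for r in truth.itertuples()}
        assert got == want

    def test_affinity_is_max_over_window(self, planted):
        psam, peaks, truth, genome = planted
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        k = psam.k
        for s, peak in zip(sorted(sites, key=lambda x: x.start), peaks):
            fp = peak.five_prime
            lo = max(0, fp - 75)
            seq = genome[s.chrom][lo : fp + 75 + k]
            prof = scan(psam, seq).affinities
            assert s.affinity == pytest.approx(prof.max())

    def test_uniform_psam_tie_breaks_to_zero_offset(self, planted):
        _, peaks, _, genome = planted
        uniform = PSAM("U", np.ones((11, 4)))
        sites = call_rep_sites(peaks[:5], {"U": PSAM("RBP1", np.ones((11, 4)))}, genome)
        # every window scores 1.0; smallest |offset| is 0
        assert all(s.offset == 0 for s in sites)

    def test_minus_strand_mirrored(self):
        ref = gen_reference(SimConfig(seed=6))
        psam, peaks, truth, genome = gen_psam_and_peaks(
            ref, "RBP1", 10, 10, seed=8, planted_offset=-35, strand="-"
        )
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        assert all(s.offset == -35 for s in sites)
        got = {(s.start, s.end) for s in sites}
        assert got == {(r.start, r.end) for r in truth.itertuples()}

    def test_cross_cell_line_dedup(self, planted):
        psam, peaks, _, genome = planted
        twice = peaks[:3] + [
            Peak(p.chrom, p.start, p.end, p.strand, p.rbp, "HepG2") for p in peaks[:3]
        ]
        sites = call_rep_sites(twice, {"RBP1": psam}, genome)
        assert len(sites) == 3
        assert all(s.cell_lines == frozenset({"K562", "HepG2"}) for s in sites)


class TestPositionalTest:
    def test_concentrated_offsets_small_p(self, planted):
        psam, peaks, _, genome = planted
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        offs = rep_site_offsets(sites)["RBP1"]
        p = positional_enrichment_test(offs, n_sims=2000, seed=3)
        assert p == pytest.approx(1 / 2001)

    def test_uniform_null_large_p(self):
        ref = gen_reference(SimConfig(seed=9))
        psam, peaks, _, genome = gen_psam_and_peaks(
            ref, "RBP1", 11, 30, seed=10, planted_offset=None
        )
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        p = positional_enrichment_test([s.offset for s in sites], n_sims=2000, seed=3)
        assert p >= 0.01

    def test_p_valid_under_null(self, rng):
        # P(p <= alpha) <= alpha + simulation tolerance for uniform offsets
        hits = 0
        reps = 40
        for i in range(reps):
            offs = rng.integers(-75, 76, size=25)
            p = positional_enrichment_test(offs, n_sims=400, seed=int(i))
            if p <= 0.1:
                hits += 1
        assert hits / reps <= 0.1 + 2 * np.sqrt(0.1 * 0.9 / reps)

    def test_seed_reproducibility(self):
        offs = [3, 3, 3, 10, -20, 5]
        p1 = positional_enrichment_test(offs, n_sims=500, seed=11)
        p2 = positional_enrichment_test(offs, n_sims=500, seed=11)
        assert p1 == p2

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            positional_enrichment_test([])


class TestControls:
    def make_psam(self):
        m = np.full((5, 4), 0.05)
        for i, b in enumerate("ACGUA"):
            m[i, "ACGU".index(b)] = 1.0
        return PSAM("R", m)

    def test_closest_affinity_decoy_selected(self):
        psam = self.make_psam()
        # UTR: ideal site at 10, decoy with one mismatch at 30
        utr = "G" * 10 + "ACGTA" + "G" * 15 + "ACGTC" + "G" * 10
        rep = RepSite("u", 10, 15, "+", "R", 1.0, 0)
        mapping = control_sites(
            [rep], {"u": utr}, {"u": [rep]}, {0: "u"}, {"R": psam}
        )
        start, end, aff = mapping[0]
        assert (start, end) == (30, 35)
        assert aff == pytest.approx(0.05)

    def test_tie_prefers_five_prime(self):
        psam = self.make_psam()
        utr = "G" * 10 + "ACGTA" + "G" * 10 + "ACGTC" + "G" * 10 + "ACGTC" + "G" * 5
        rep = RepSite("u", 10, 15, "+", "R", 1.0, 0)
        mapping = control_sites([rep], {"u": utr}, {"u": [rep]}, {0: "u"}, {"R": psam})
        assert mapping[0][0] == 25  # first of the two equal-affinity decoys

    def test_all_masked_yields_none(self):
        psam = self.make_psam()
        utr = "ACGTAAC"  # too short to have unmasked windows once masked
        rep = RepSite("u", 0, 5, "+", "R", 1.0, 0)
        mapping = control_sites([rep], {"u": utr}, {"u": [rep]}, {0: "u"}, {"R": psam})
        assert mapping[0] is None

    def test_control_never_overlaps_rep_site(self, rng):
        psam = self.make_psam()
        bases = np.array(list("ACGT"))
        for trial in range(10):
            utr = "".join(bases[rng.integers(0, 4, 120)])
            prof = scan(psam, utr).affinities
            j = int(prof.argmax())
            rep = RepSite("u", j, j + 5, "+", "R", float(prof[j]), 0)
            mapping = control_sites([rep], {"u": utr}, {"u": [rep]}, {0: "u"}, {"R": psam})
            if mapping[0] is None:
                continue
            c0, c1, _ = mapping[0]
            assert c1 <= rep.start or c0 >= rep.end


class TestSharing:
    def s(self, start, lines, rbp="R"):
        return RepSite("c", start, start + 11, "+", rbp, 0.9, 0, frozenset(lines))

    def test_identical_site_both_lines_shared(self):
        sites = [self.s(100, {"K562", "HepG2"})]
        out = shared_across_cell_lines(sites, {0: "geneA"})
        assert out["shared"] == [0]

    def test_offset_by_one_is_positional_control(self):
        sites = [self.s(100, {"K562"}), self.s(101, {"HepG2"})]
        out = shared_across_cell_lines(sites, {0: "geneA", 1: "geneA"})
        assert out["shared"] == []
        assert set(out["positional_control"]) == {0, 1}

    def test_single_line_gene_absent_elsewhere(self):
        sites = [self.s(100, {"K562"})]
        out = shared_across_cell_lines(sites, {0: "geneA"})
        assert out["single"] == [0]


class TestConservation:
    def test_identical_distributions_or_near_one(self, rng):
        scores = rng.normal(1.0, 1.0, 2000)
        out = conservation_enrichment(scores, scores, thresholds=(2,))
        assert out[2].odds_ratio == pytest.approx(1.0)

    def test_planted_high_scores_enriched(self):
        site_scores = [5.0] * 30 + [0.0] * 10
        ctrl_scores = [5.0] * 10 + [0.0] * 30
        out = conservation_enrichment(site_scores, ctrl_scores, thresholds=(2,))
        assert out[2].odds_ratio == pytest.approx((30 / 10) / (10 / 30))

    def test_control_region_sampling_reproducible_and_disjoint(self):
        # needs a spread of offsets to sample from (a degenerate offset pool
        # admits no non-overlapping draw, matching the redraw-until rule)
        ref = gen_reference(SimConfig(seed=9))
        psam, peaks, _, genome = gen_psam_and_peaks(
            ref, "RBP1", 11, 30, seed=10, planted_offset=None
        )
        sites = call_rep_sites(peaks, {"RBP1": psam}, genome)
        r1 = sample_control_regions(sites, seed=4)
        r2 = sample_control_regions(sites, seed=4)
        assert r1 == r2
        for s, (c0, c1) in zip(sites, r1):
            assert c1 <= s.start or c0 >= s.end
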