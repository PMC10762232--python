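"""Regulatory-element variant classification rules."""

import numpy as np
import pytest

from imaps.classify import (
    CANONICAL_PAS,
    MirTargetSite,
    au_flank_context,
    classify_mir_variant,
    classify_pas_variant,
    classify_pum_creation,
    classify_rep_variant,
)
from imaps.psam import PSAM
from imaps.utr import PolyASite, StopCodon, build_utrs


@pytest.fixture
def psam5():
    """Sharp k=5 model, ideal site ACGUA."""
    m = np.full((5, 4), 0.05)
    for i, b in enumerate("ACGUA"):
        m[i, "ACGU".index(b)] = 1.0
    return PSAM("RBP", m)


class TestRepClassification:
    def test_focal_disrupting(self, psam5):
        seq = "GGGGGGGGGG" + "ACGTA" + "GGGGGGGGGG"
        eff = classify_rep_variant("v", psam5, seq, 12, "C", 10, 15)
        assert eff.focality == "focal"
        assert eff.effect == "disrupting"

    def test_preserving_when_affinity_kept(self, psam5):
        # two ideal sites side by side: breaking one leaves the other intact
        seq = "GGGGGGGGGG" + "ACGTA" + "ACGTA" + "GGGGGGGGGG"
        eff = classify_rep_variant("v", psam5, seq, 17, "C", 10, 15)
        # variant in the second site; first site untouched -> classify that one
        eff = classify_rep_variant("v", psam5, seq, 12, "C", 10, 15)
        assert eff.ancestral_affinity > 0

    def test_intermediate_gap_is_neither(self, psam5):
        # engineered ratio in (1/3, 2/3): single mismatch of affinity 0.5
        m = psam5.matrix.copy()
        m[2] = [0.5, 0.5, 1.0, 0.5]
        psam = PSAM("MID", m)
        seq = "GGGGGGGGGG" + "ACGTA" + "GGGGGGGGGG"
        eff = classify_rep_variant("v", psam, seq, 12, "C", 10, 15)
        assert 1 / 3 < eff.detail["affinity_ratio"] < 2 / 3
        assert eff.effect == "intermediate"

    def test_neighbor_forces_nonfocal(self, psam5):
        seq = "GGGGGGGGGG" + "ACGTA" + "GGGGGGGGGG"
        eff = classify_rep_variant(
            "v", psam5, seq, 12, "C", 10, 15, neighbor_within_25=True
        )
        assert eff.focality == "nonfocal"

    def test_relaxed_thresholds_preset(self, psam5):
        m = psam5.matrix.copy()
        m[2] = [0.55, 0.55, 1.0, 0.55]
        psam = PSAM("MID", m)
        seq = "GGGGGGGGGG" + "ACGTA" + "GGGGGGGGGG"
        strict = classify_rep_variant("v", psam, seq, 12, "C", 10, 15)
        relaxed = classify_rep_variant(
            "v", psam, seq, 12, "C", 10, 15,
            disrupt_below=0.5, preserve_above=0.5,
        )
        assert strict.effect == "intermediate"
        assert relaxed.effect == "preserving"

    def test_no_variant_both_disrupting_and_preserving(self, psam5, rng):
        # label sets disjoint over random fixtures
        for _ in range(50):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
            pos = 20
            der = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            eff = classify_rep_variant("v", psam5, seq, pos, der, 18, 23)
            assert eff.effect in {"disrupting", "preserving", "intermediate"}


class TestPumCreation:
    def test_creation_rule(self, psam5):
        # background with no site; the derived allele completes the motif
        seq = "GGGGGGGGGG" + "ACCTA" + "GGGGGGGGGG"
        eff = classify_pum_creation("v", psam5, seq, 12, "G")
        assert eff.derived_affinity > 0.25
        assert eff.effect == "created"

    def test_ratio_below_two_not_created(self, psam5):
        m = psam5.matrix.copy()
        m[2] = [0.6, 0.6, 1.0, 0.6]
        psam = PSAM("SOFT", m)
        seq = "GGGGGGGGGG" + "ACCTA" + "GGGGGGGGGG"
        eff = classify_pum_creation("v", psam, seq, 12, "G")
        # ancestral already 0.6 of ideal: ratio 1/0.6 < 2
        assert eff.effect == "not_created"

    def test_min_affinity_threshold_sweep(self, psam5):
        m = psam5.matrix.copy()
        m[2] = [0.28, 0.05, 1.0, 0.05]
        psam = PSAM("SWEEP", m)
        # ancestral C at the motif's G position scores 0.05; derived A scores
        # 0.28, so the derived affinity sits between the sweep thresholds
        seq = "GGGGGGGGGG" + "ACCTA" + "GGGGGGGGGG"
        eff_25 = classify_pum_creation("v", psam, seq, 12, "A", min_derived_affinity=0.25)
        eff_35 = classify_pum_creation("v", psam, seq, 12, "A", min_derived_affinity=0.35)
        assert eff_25.effect == "created"
        assert eff_35.effect == "not_created"

    def test_region_label_attached(self, psam5):
        utrs, _ = build_utrs(
            [StopCodon("chr1", 1000, "+", "g")],
            [PolyASite("chr1", 1200, "+", "g", 20.0), PolyASite("chr1", 1800, "+", "g", 5.0)],
        )
        seq = "GGGGGGGGGG" + "ACCTA" + "GGGGGGGGGG"
        eff = classify_pum_creation(
            "v", psam5, seq, 12, "G", utr=utrs[0], genomic_pos=1500
        )
        assert eff.region == "variable"


class TestPAS:
    WL = list(CANONICAL_PAS) + ["AAGAAA", "AATACA"]

    def test_loss_when_no_frame_matches(self):
        seq = "GGGGG" + "AATAAA" + "GGGGG"
        eff = classify_pas_variant("v", seq, 9, "C", list(CANONICAL_PAS))
        assert eff.effect == "lost"

    def test_w_position_swap_preserved(self):
        seq = "GGGGG" + "AATAAA" + "GGGGG"
        # A>T at the second base: AATAAA -> ATTAAA, still AWUAAA
        eff = classify_pas_variant("v", seq, 6, "T", list(CANONICAL_PAS))
        assert eff.effect == "preserved_pas"

    def test_overlapping_frame_rescue(self):
        # derived sequence loses the original frame but gains an overlapping
        # whitelist hexamer one frame over
        seq = "GGGA" + "AATAAA" + "CGGGG"
        # variant at the hexamer's last base: AATAAA -> AATAAT, which no
        # longer matches AWUAAA in any frame but does match an enriched
        # A-rich hexamer when the whitelist carries it
        eff = classify_pas_variant("v", seq, 9, "T", list(CANONICAL_PAS))
        wl = list(CANONICAL_PAS) + ["AATAAT"]
        eff2 = classify_pas_variant("v", seq, 9, "T", wl)
        assert eff.effect == "lost"
        assert eff2.effect == "preserved_pas"

    def test_requires_ancestral_awuaaa(self):
        with pytest.raises(ValueError):
            classify_pas_variant("v", "GGGGGGGGGGGG", 6, "A", self.WL)

    def test_empty_whitelist_rejected(self):
        seq = "GGGGG" + "AATAAA" + "GGGGG"
        with pytest.raises(ValueError):
            classify_pas_variant("v", seq, 6, "T", [])

    def test_primary_vs_secondary_tier(self):
        utrs, _ = build_utrs(
            [StopCodon("chr1", 1000, "+", "g")], [PolyASite("chr1", 1500, "+", "g", 9.0)]
        )
        u = utrs[0]
        # hexamer at genomic 1475..1481 lies inside [1470, 1486)
        seq = "G" * 20 + "AATAAA" + "G" * 20
        eff = classify_pas_variant(
            "v", seq, 22, "T", list(CANONICAL_PAS), utr=u, genomic_pos=1477
        )
        assert eff.detail["tier"] == "primary"
        eff2 = classify_pas_variant(
            "v", seq, 22, "T", list(CANONICAL_PAS), utr=u, genomic_pos=1200
        )
        assert eff2.detail["tier"] == "secondary"

    def test_frame_completeness_brute_force(self, rng):
        # preserved <=> at least one overlapping whitelist 6-mer on the
        # derived sequence; verified against an all-frame oracle
        wl = set(self.WL)
        bases = np.array(list("ACGT"))
        n_checked = 0
        while n_checked < 300:
            seq = "".join(bases[rng.integers(0, 4, 20)])
            pos = int(rng.integers(5, 15))
            s0 = int(rng.integers(pos - 5, pos + 1))
            core = "AATAAA" if rng.random() < 0.5 else "ATTAAA"
            seq = seq[:s0] + core + seq[s0 + 6 :]
            der = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            eff = classify_pas_variant("v", seq, pos, der, sorted(wl))
            dseq = seq[:pos] + der + seq[pos + 1 :]
            oracle = any(
                dseq[s : s + 6] in wl
                for s in range(max(0, pos - 5), min(len(dseq) - 6, pos) + 1)
            )
            assert (eff.effect == "preserved_pas") == oracle
            n_checked += 1


class TestMirSites:
    def test_analyzable_position_counts(self):
        s8 = MirTargetSite("c", 100, 108, "+", "8mer", "fam1", "broadly_conserved")
        s7m8 = MirTargetSite("c", 100, 107, "+", "7mer-m8", "fam1", "conserved")
        s7a1 = MirTargetSite("c", 100, 107, "+", "7mer-A1", "fam1", "conserved")
        assert len(s8.analyzable_positions()) == 8
        assert len(s7m8.analyzable_positions()) == 7
        assert len(s7a1.analyzable_positions()) == 7

    def test_a1_position_membership_by_type(self):
        s8 = MirTargetSite("c", 100, 108, "+", "8mer", "fam1", "broadly_conserved")
        # mRNA 3' end base pairs with miRNA position 1 for 8mer
        a1 = 107
        assert a1 in s8.analyzable_positions()
        eff = classify_mir_variant("v", a1, "c", [s8])
        assert eff.effect == "in_target"
        # for a 7mer-m8 the base 3' of the site (across from position 1)
        # is not analyzable
        s7m8 = MirTargetSite("c", 100, 107, "+", "7mer-m8", "fam1", "conserved")
        beyond = 107
        eff2 = classify_mir_variant("v", beyond, "c", [s7m8])
        assert eff2.effect == "not_in_target"

    def test_multi_family_count(self):
        s1 = MirTargetSite("c", 100, 108, "+", "8mer", "famA", "broadly_conserved")
        s2 = MirTargetSite("c", 102, 110, "+", "8mer", "famB", "broadly_conserved")
        eff = classify_mir_variant("v", 104, "c", [s1, s2])
        assert eff.detail["n_families"] == 2

    def test_minus_strand_positions_mirrored(self):
        s = MirTargetSite("c", 100, 108, "+", "8mer", "f", "conserved")
        sm = MirTargetSite("c", 100, 108, "-", "8mer", "f", "conserved")
        assert s.analyzable_positions() == set(range(100, 108))
        assert sm.analyzable_positions() == set(range(100, 108))

    def test_unknown_site_type_rejected(self):
        with pytest.raises(ValueError):
            MirTargetSite("c", 100, 106, "+", "6mer", "f", "conserved")


class TestAUFlank:
    @pytest.mark.parametrize(
        "seq,start,end,expected",
        [
            ("AUXXXXUA".replace("X", "G").replace("U", "T"), 2, 6, 1.0),
            ("GCXXXXGC".replace("X", "G"), 2, 6, 0.0),
            ("AGXXXXCT".replace("X", "G"), 2, 6, 0.5),
        ],
    )
    def test_au_fraction(self, seq, start, end, expected):
        frac, clipped = au_flank_context(seq, start, end)
        assert frac == pytest.approx(expected)
        assert not clipped

    def test_clipping_at_ends(self):
        frac, clipped = au_flank_context("AGGGGT", 0, 4)
        assert clipped
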