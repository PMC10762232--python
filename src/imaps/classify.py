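"""Variant effects on 3'UTR regulatory elements.

Four element families are classified:

* ReP (RBP binding) sites — variants are labeled focal/non-focal by how
  much of the local (+/-25 nt) summed affinity the site accounts for, and
  disrupting/preserving by the derived-to-ancestral affinity ratio.  Both
  axes use a two-threshold design (1/3 and 2/3); the gap in between is an
  explicit "intermediate" label analyzed in neither class.
* Pumilio site creation — derived alleles that more than double the
  PUM1/PUM2 affinity and exceed a minimum derived affinity create a site.
* Polyadenylation signals — a variant in an ancestral AWUAAA hexamer
  loses the PAS if no hexamer overlapping the variant on the derived
  sequence matches the PAS whitelist in any frame; otherwise preserved.
* miRNA target sites — a variant is "in target" when it hits an
  analyzable seed-pairing position for the site type (8mer, 7mer-m8,
  7mer-A1), and the number of distinct targeting families is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .psam import PSAM, variant_affinities
from .utr import UTRModel

# ratio thresholds of the two-threshold design
FOCAL_HI = 2 / 3
FOCAL_LO = 1 / 3
DISRUPT_BELOW = 1 / 3
PRESERVE_ABOVE = 2 / 3
# relaxed preset used when statistical power is limiting (e.g. eQTL sets)
RELAXED_DISRUPT_BELOW = 1 / 2
RELAXED_PRESERVE_ABOVE = 1 / 2

#: default PAS hexamers: the canonical AWUAAA pair in DNA alphabet
CANONICAL_PAS = ("AATAAA", "ATTAAA")


@dataclass
class SiteEffect:
    variant_id: str
    kind: str  # rep | pum_created | pas | mir
    focality: Optional[str] = None  # focal | nonfocal | intermediate
    effect: Optional[str] = None
    ancestral_affinity: Optional[float] = None
    derived_affinity: Optional[float] = None
    local_affinity: Optional[float] = None
    region: str = "none"  # core | variable | none
    flags: list = field(default_factory=list)
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ReP sites
# ---------------------------------------------------------------------------


def classify_rep_variant(
    variant_id: str,
    psam: PSAM,
    sequence: str,
    pos: int,
    derived_base: str,
    site_start: int,
    site_end: int,
    neighbor_within_25: bool = False,
    disrupt_below: float = DISRUPT_BELOW,
    preserve_above: float = PRESERVE_ABOVE,
    region: str = "none",
) -> SiteEffect:
    """Focality and disruption labels for a variant in a ReP site.

    ``sequence`` is the UTR sense-strand ancestral sequence, ``pos`` the
    variant position and [site_start, site_end) the ReP site, all in the
    same local coordinates.  ``neighbor_within_25`` marks another ReP site
    of the same RBP within 25 bases, which forces non-focality.
    """
    a_anc, a_der, a_local = variant_affinities(
        psam, sequence, pos, derived_base, site_start, site_end
    )
    eff = SiteEffect(
        variant_id,
        "rep",
        ancestral_affinity=a_anc,
        derived_affinity=a_der,
        local_affinity=a_local,
        region=region,
    )
    if a_local and a_local > 0:
        frac = a_anc / a_local
        if neighbor_within_25 or frac < FOCAL_LO:
            eff.focality = "nonfocal"
        elif frac > FOCAL_HI:
            eff.focality = "focal"
        else:
            eff.focality = "intermediate"
    else:
        eff.focality = "intermediate"
        eff.flags.append("zero_local_affinity")
    if a_anc > 0:
        ratio = a_der / a_anc
        if ratio < disrupt_below:
            eff.effect = "disrupting"
        elif ratio > preserve_above:
            eff.effect = "preserving"
        else:
            eff.effect = "intermediate"
        eff.detail["affinity_ratio"] = ratio
    else:
        eff.effect = "intermediate"
        eff.flags.append("zero_ancestral_affinity")
    return eff


def classify_pum_creation(
    variant_id: str,
    psam_pum: PSAM,
    sequence: str,
    pos: int,
    derived_base: str,
    utr: Optional[UTRModel] = None,
    genomic_pos: Optional[int] = None,
    min_derived_affinity: float = 0.25,
    min_ratio: float = 2.0,
) -> SiteEffect:
    """Does the derived allele create a Pumilio binding site?

    Created iff derived/ancestral affinity ratio exceeds ``min_ratio``
    (default 2) and the derived affinity exceeds ``min_derived_affinity``
    (sweepable; 0.25 by default).  The core/variable region label is
    attached when a UTR model and genomic position are supplied.
    """
    a_anc, a_der, _ = variant_affinities(psam_pum, sequence, pos, derived_base)
    created = a_der > min_derived_affinity and (
        a_anc == 0 or a_der / a_anc > min_ratio
    )
    region = "none"
    if utr is not None and genomic_pos is not None:
        region = utr.classify_region(genomic_pos)
    return SiteEffect(
        variant_id,
        "pum_created",
        effect="created" if created else "not_created",
        ancestral_affinity=a_anc,
        derived_affinity=a_der,
        region=region,
    )


# ---------------------------------------------------------------------------
# Polyadenylation signals
# ---------------------------------------------------------------------------


def is_awuaaa(hexamer: str) -> bool:
    return hexamer in CANONICAL_PAS


def classify_pas_variant(
    variant_id: str,
    sequence: str,
    pos: int,
    derived_base: str,
    hexamer_whitelist: Sequence[str],
    utr: Optional[UTRModel] = None,
    genomic_pos: Optional[int] = None,
) -> SiteEffect:
    """Lost/preserved call for a variant overlapping an ancestral PAS.

    The variant must overlap an ancestral AWUAAA hexamer.  On the derived
    sequence every 6-mer frame overlapping the variant position is checked
    against the whitelist (AWUAAA plus the additional A-rich hexamers
    supplied by the caller); the PAS is lost iff no frame matches.  The
    PAS is "primary" when its ancestral hexamer lies wholly inside the
    15-30 nt window upstream of the UTR's primary poly(A) site, else
    "secondary".
    """
    wl = {h.upper().replace("U", "T") for h in hexamer_whitelist}
    if not wl:
        raise ValueError("PAS hexamer whitelist is empty")
    anc_frames = _overlapping_hexamers(sequence, pos)
    anc_hits = [(s, h) for s, h in anc_frames if is_awuaaa(h)]
    if not anc_hits:
        raise ValueError(
            f"variant {variant_id} does not overlap an ancestral AWUAAA hexamer"
        )
    derived_seq = sequence[:pos] + derived_base + sequence[pos + 1 :]
    der_frames = _overlapping_hexamers(derived_seq, pos)
    preserved = any(h in wl for _, h in der_frames)
    tier = "secondary"
    if utr is not None and genomic_pos is not None:
        lo, hi, _ = utr.primary_pas_window()
        for s, _h in anc_hits:
            g0 = genomic_pos - (pos - s)  # genomic start of the hexamer
            if utr.strand == "-":
                g0 = genomic_pos + (pos - s) - 5
            if g0 >= lo and g0 + 6 <= hi:
                tier = "primary"
                break
    return SiteEffect(
        variant_id,
        "pas",
        effect="preserved_pas" if preserved else "lost",
        detail={"tier": tier, "ancestral_hexamers": [h for _, h in anc_hits]},
    )


def _overlapping_hexamers(sequence: str, pos: int) -> list[tuple[int, str]]:
    out = []
    for s in range(pos - 5, pos + 1):
        if s < 0 or s + 6 > len(sequence):
            continue
        out.append((s, sequence[s : s + 6].upper().replace("U", "T")))
    return out


# ---------------------------------------------------------------------------
# miRNA target sites
# ---------------------------------------------------------------------------

MIR_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

#: miRNA positions covered by each site type (position 1 = the A across
#: from miRNA position 1, at the site's mRNA 3' end)
_SITE_SPAN = {"8mer": (1, 8), "7mer-m8": (2, 8), "7mer-A1": (1, 7)}
#: positions analyzable for variant effects: seed 2-7 for all types, the
#: A1 base for 8mer/7mer-A1, the position-8 base for 8mer/7mer-m8
_ANALYZABLE = {
    "8mer": frozenset(range(1, 9)),
    "7mer-m8": frozenset(range(2, 9)),
    "7mer-A1": frozenset(range(1, 8)),
}


@dataclass(frozen=True)
class MirTargetSite:
    chrom: str
    start: int
    end: int
    strand: str
    site_type: str
    family: str
    conservation_class: str  # broadly_conserved | conserved

    def __post_init__(self):
        if self.site_type not in MIR_SITE_TYPES:
            raise ValueError(f"unknown miRNA site type {self.site_type!r}")
        span = _SITE_SPAN[self.site_type]
        if self.end - self.start != span[1] - span[0] + 1:
            raise ValueError(
                f"{self.site_type} site must span {span[1] - span[0] + 1} bases"
            )

    def analyzable_positions(self) -> set[int]:
        """Genomic positions whose variants are analyzable for this site.

        The mRNA 3' end of the site pairs with the 5'-most covered miRNA
        position; on the + strand this is ``end - 1``.
        """
        lo_p, _hi_p = _SITE_SPAN[self.site_type]
        out = set()
        for p in _ANALYZABLE[self.site_type]:
            i = p - lo_p  # 0-based distance from the site's mRNA 3' end
            out.add(self.end - 1 - i if self.strand == "+" else self.start + i)
        return out


def classify_mir_variant(
    variant_id: str,
    genomic_pos: int,
    chrom: str,
    target_sites: Iterable[MirTargetSite],
) -> SiteEffect:
    """Membership of a variant in analyzable miRNA target positions.

    Returns in_target with the number of distinct miRNA families whose
    analyzable positions cover the variant ("multi-family" targeting).
    """
    families = set()
    hit_types = []
    for site in target_sites:
        if site.chrom != chrom:
            continue
        if genomic_pos in site.analyzable_positions():
            families.add(site.family)
            hit_types.append(site.site_type)
    eff = SiteEffect(
        variant_id,
        "mir",
        effect="in_target" if families else "not_in_target",
        detail={"n_families": len(families), "site_types": hit_types},
    )
    return eff


def au_flank_context(sequence: str, site_start: int, site_end: int) -> tuple[float, bool]:
    """AU fraction of the dinucleotides flanking a target site.

    Considers up to two bases on each side of [site_start, site_end),
    clipped at the sequence ends (flag True when clipped); returns the
    fraction of A/U (T) among the available flanking bases.
    """
    left = sequence[max(0, site_start - 2) : site_start]
    right = sequence[site_end : site_end + 2]
    clipped = len(left) < 2 or len(right) < 2
    flanks = (left + right).upper().replace("U", "T")
    if not flanks:
        return 0.0, True
    au = sum(1 for b in flanks if b in "AT")
    return au / len(flanks), clipped
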