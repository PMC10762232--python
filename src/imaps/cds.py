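"""Coding consequence calls for benchmark variant classes.

Synonymous, missense and stop-gain variants provide the reference points
against which non-coding singleton-excess values are benchmarked.  Codons
are reconstructed across exon junctions using the annotated phase of each
CDS exon; variants in frame-conflicted exons (overlapping another CDS
exon in a different frame), within three bases of a splice site, or whose
ancestral codon is already a stop, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

SEVERITY = {"stop_gain": 3, "missense": 2, "synonymous": 1, "excluded": 0}


@dataclass(frozen=True)
class CDSExon:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    phase: int  # bases to skip before the first complete codon of this exon
    transcript: str
    gene: str

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError(f"invalid phase {self.phase}")
        if self.end <= self.start:
            raise ValueError("exon end must exceed start")


class PhaseError(ValueError):
    pass


@dataclass
class Transcript:
    """Ordered CDS exons of one transcript with a spliced coding sequence."""

    transcript: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[CDSExon, ...]  # transcript (5'->3') order

    @classmethod
    def from_exons(cls, exons: Sequence[CDSExon]) -> "Transcript":
        exons = sorted(exons, key=lambda e: e.start, reverse=exons[0].strand == "-")
        first = exons[0]
        # verify the annotated phases agree with cumulative coding length
        cum = 0
        for e in exons:
            expected = (3 - cum % 3) % 3
            if e.phase != expected:
                raise PhaseError(
                    f"transcript {first.transcript}: exon at {e.start} has phase "
                    f"{e.phase}, expected {expected} from cumulative length"
                )
            cum += e.end - e.start
        return cls(first.transcript, first.gene, first.chrom, first.strand, tuple(exons))

    def coding_sequence(self, genome) -> str:
        parts = []
        for e in self.exons:
            seq = _fetch(genome, self.chrom, e.start, e.end)
            parts.append(seq.translate(_RC)[::-1] if self.strand == "-" else seq)
        return "".join(parts)

    def cds_index(self, genomic_pos: int) -> int | None:
        """0-based position within the spliced CDS, or None if intronic."""
        off = 0
        for e in self.exons:
            if e.start <= genomic_pos < e.end:
                within = (
                    genomic_pos - e.start if self.strand == "+" else e.end - 1 - genomic_pos
                )
                return off + within
            off += e.end - e.start
        return None

    def splice_proximal(self, genomic_pos: int, margin: int = 3) -> bool:
        """Within ``margin`` bases of an exon edge that adjoins an intron."""
        g_sorted = sorted(self.exons, key=lambda e: e.start)
        for i, e in enumerate(g_sorted):
            if not e.start <= genomic_pos < e.end:
                continue
            near_left = genomic_pos - e.start < margin
            near_right = e.end - 1 - genomic_pos < margin
            has_left_intron = i > 0
            has_right_intron = i < len(g_sorted) - 1
            return (near_left and has_left_intron) or (near_right and has_right_intron)
        return False


def _fetch(genome, chrom, start, end) -> str:
    seq = genome[chrom]
    if not isinstance(seq, str):
        seq = str(seq[start:end])
        return seq.upper()
    return seq[start:end].upper()


def frame_conflicted_exons(exons: Iterable[CDSExon]) -> set[tuple[str, int, int]]:
    """CDS exons overlapping another CDS exon annotation in a different frame.

    Frame is compared as the genomic phase of codon boundaries: two
    overlapping exons conflict when their first complete codons are not in
    register on the genome.
    """
    exs = list(exons)
    conflicted: set[tuple[str, int, int]] = set()
    for i, a in enumerate(exs):
        for b in exs[i + 1 :]:
            if a.chrom != b.chrom or a.end <= b.start or b.end <= a.start:
                continue
            if _genomic_frame(a) != _genomic_frame(b) or a.strand != b.strand:
                conflicted.add((a.chrom, a.start, a.end))
                conflicted.add((b.chrom, b.start, b.end))
    return conflicted


def _genomic_frame(e: CDSExon) -> int:
    # genomic residue class of positions that start a codon
    if e.strand == "+":
        return (e.start + e.phase) % 3
    return (e.end - 1 - e.phase) % 3


def call_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcript: Transcript,
    genome,
    conflicted: set | None = None,
) -> str:
    """synonymous / missense / stop_gain / excluded for one SNV.

    ``ref`` must be the ancestral allele on the forward genomic strand;
    orientation to the coding strand is handled internally.
    """
    if conflicted is None:
        conflicted = set()
    exon = next(
        (e for e in transcript.exons if e.start <= pos < e.end and e.chrom == chrom),
        None,
    )
    if exon is None:
        return "excluded"
    if (exon.chrom, exon.start, exon.end) in conflicted:
        return "excluded"
    if transcript.splice_proximal(pos):
        return "excluded"
    cds = transcript.coding_sequence(genome)
    i = transcript.cds_index(pos)
    if i is None or i >= len(cds) - len(cds) % 3:
        return "excluded"
    ref_c, alt_c = ref.upper(), alt.upper()
    if transcript.strand == "-":
        ref_c = ref_c.translate(_RC)
        alt_c = alt_c.translate(_RC)
    if cds[i] != ref_c:
        raise ValueError(
            f"{transcript.transcript}: reference mismatch at {chrom}:{pos} "
            f"(CDS has {cds[i]}, variant ref implies {ref_c})"
        )
    codon_start = 3 * (i // 3)
    anc_codon = cds[codon_start : codon_start + 3]
    der_codon = (
        anc_codon[: i - codon_start] + alt_c + anc_codon[i - codon_start + 1 :]
    )
    anc_aa = str(Seq(anc_codon).translate())
    der_aa = str(Seq(der_codon).translate())
    if anc_aa == "*":
        return "excluded"  # ancestral allele codes for a stop
    if der_aa == "*":
        return "stop_gain"
    return "synonymous" if der_aa == anc_aa else "missense"


def most_severe(consequences: Iterable[str]) -> str:
    """Collision rule across isoforms: stop_gain > missense > synonymous."""
    best = "excluded"
    for c in consequences:
        if SEVERITY[c] > SEVERITY[best]:
            best = c
    return best
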