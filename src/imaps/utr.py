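"""3'UTR models built from stop codons and poly(A)-site usage.

Each poly(A) site is attached to the closest upstream (5') stop codon;
the sites sharing a stop codon define one 3'UTR.  The primary poly(A)
site is the most utilized one (highest mean reads-per-million across
tissues), which need not be the most distal.  Every position between the
stop codon and the primary site is "core", regardless of intervening
secondary sites; positions between the primary and the most distal site
are "variable" (present only in longer isoforms).  UTRs longer than 50 kb
are dropped, as are pairs of UTRs where a poly(A) site falls within 100
bases of a downstream UTR start (ambiguous assignment without long reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

MAX_UTR_LENGTH = 50_000
STOP_PROXIMITY = 100


@dataclass(frozen=True)
class PolyASite:
    chrom: str
    pos: int  # 0-based cleavage position
    strand: str
    gene: str
    mean_rpm: float
    conserved: bool = False  # active homologous site in mouse or rat

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.mean_rpm >= 0:
            raise ValueError("mean_rpm must be finite and nonnegative")


@dataclass(frozen=True)
class StopCodon:
    chrom: str
    pos: int  # 0-based position of the stop codon's last (3'-most) base
    strand: str
    gene: str


@dataclass
class UTRModel:
    gene: str
    chrom: str
    strand: str
    stop_pos: int
    sites: tuple[PolyASite, ...]  # ordered 5'->3'
    primary: PolyASite = field(init=False)

    def __post_init__(self):
        if not self.sites:
            raise ValueError("a UTR needs at least one poly(A) site")
        best_rpm = max(s.mean_rpm for s in self.sites)
        # RPM tie: most proximal (5'-most) site wins; sites are 5'->3'
        self.primary = next(s for s in self.sites if s.mean_rpm == best_rpm)

    def _downstream_of_stop(self, pos: int) -> int:
        """Transcript-direction distance from the stop (positive = 3')."""
        return pos - self.stop_pos if self.strand == "+" else self.stop_pos - pos

    @property
    def distal(self) -> PolyASite:
        return self.sites[-1]

    @property
    def length(self) -> int:
        return self._downstream_of_stop(self.distal.pos)

    @property
    def has_variable_region(self) -> bool:
        return self.primary is not self.distal

    def core_interval(self) -> tuple[int, int]:
        """Genomic half-open interval of the core region (stop -> primary)."""
        if self.strand == "+":
            return (self.stop_pos, self.primary.pos + 1)
        return (self.primary.pos, self.stop_pos + 1)

    def variable_interval(self) -> Optional[tuple[int, int]]:
        if not self.has_variable_region:
            return None
        if self.strand == "+":
            return (self.primary.pos + 1, self.distal.pos + 1)
        return (self.distal.pos, self.primary.pos)

    def classify_region(self, pos: int) -> str:
        """'core', 'variable' or 'outside' for a genomic position.

        Intervening secondary poly(A) sites never interrupt the core:
        everything from the stop codon to the primary site is core.
        """
        d = self._downstream_of_stop(pos)
        d_primary = self._downstream_of_stop(self.primary.pos)
        d_distal = self._downstream_of_stop(self.distal.pos)
        if 0 < d <= d_primary:
            return "core"
        if d_primary < d <= d_distal:
            return "variable"
        return "outside"

    def primary_pas_window(self) -> tuple[int, int, bool]:
        """Genomic span where a primary PAS hexamer may lie, plus a clip flag.

        The canonical polyadenylation signal sits 15-30 bases (inclusive)
        upstream of the cleavage site; the returned half-open interval
        covers the bases at upstream distances 15..30, so a hexamer is
        "primary" iff it lies entirely inside it.  The window is clipped
        at the stop codon when the UTR is very short (flag True).
        """
        x = self.primary.pos
        if self.strand == "+":
            lo, hi = x - 30, x - 14
            clipped = lo < self.stop_pos
            lo = max(lo, self.stop_pos)
        else:
            lo, hi = x + 15, x + 31
            clipped = hi > self.stop_pos + 1
            hi = min(hi, self.stop_pos + 1)
        return lo, hi, clipped


@dataclass
class UTRBuildReport:
    n_built: int = 0
    n_dropped_long: int = 0
    n_dropped_proximal_pair: int = 0
    unassigned_sites: list = field(default_factory=list)


def build_utrs(
    stop_codons: Iterable[StopCodon],
    polya_sites: Iterable[PolyASite],
    max_length: int = MAX_UTR_LENGTH,
    stop_proximity: int = STOP_PROXIMITY,
) -> tuple[list[UTRModel], UTRBuildReport]:
    """Assemble UTR models chromosome/strand-wise.

    Each site goes to the closest upstream stop codon on the same
    chromosome and strand.  UTRs longer than ``max_length`` are dropped.
    If any poly(A) site of one UTR lies within ``stop_proximity`` bases of
    the next (downstream) UTR's stop codon, both UTRs of the pair are
    dropped.
    """
    report = UTRBuildReport()
    stops_by_cs: dict[tuple[str, str], list[StopCodon]] = {}
    for sc in stop_codons:
        stops_by_cs.setdefault((sc.chrom, sc.strand), []).append(sc)
    for lst in stops_by_cs.values():
        lst.sort(key=lambda s: s.pos)

    assigned: dict[tuple[str, str, int], list[PolyASite]] = {}
    stop_lookup: dict[tuple[str, str, int], StopCodon] = {}
    for site in polya_sites:
        stops = stops_by_cs.get((site.chrom, site.strand), [])
        upstream = [
            sc
            for sc in stops
            if (site.pos > sc.pos if site.strand == "+" else site.pos < sc.pos)
        ]
        if not upstream:
            report.unassigned_sites.append(site)
            continue
        sc = (
            max(upstream, key=lambda s: s.pos)
            if site.strand == "+"
            else min(upstream, key=lambda s: s.pos)
        )
        key = (sc.chrom, sc.strand, sc.pos)
        assigned.setdefault(key, []).append(site)
        stop_lookup[key] = sc

    utrs: list[UTRModel] = []
    for key, sites in assigned.items():
        sc = stop_lookup[key]
        sites.sort(key=lambda s: s.pos, reverse=(sc.strand == "-"))
        utr = UTRModel(sc.gene, sc.chrom, sc.strand, sc.pos, tuple(sites))
        if utr.length > max_length:
            report.n_dropped_long += 1
            continue
        utrs.append(utr)

    # drop pairs where a site crowds the downstream UTR's start
    drop: set[int] = set()
    by_cs: dict[tuple[str, str], list[int]] = {}
    for i, u in enumerate(utrs):
        by_cs.setdefault((u.chrom, u.strand), []).append(i)
    for idxs in by_cs.values():
        idxs.sort(key=lambda i: utrs[i].stop_pos)
        for a_i, b_i in zip(idxs, idxs[1:]):
            up, down = (a_i, b_i) if utrs[a_i].strand == "+" else (b_i, a_i)
            down_stop = utrs[down].stop_pos
            for site in utrs[up].sites:
                if abs(site.pos - down_stop) <= stop_proximity:
                    drop.update((up, down))
                    report.n_dropped_proximal_pair += 2
                    break
    utrs = [u for i, u in enumerate(utrs) if i not in drop]
    report.n_built = len(utrs)
    return utrs, report
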