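"""Pre-analysis variant exclusion rules and annotation of survivors.

Variants entering singleton-excess analyses are filtered to reduce
non-selective biases in the allele frequency spectrum: quality fails,
non-SNVs, sex/mitochondrial chromosomes, low-complexity regions, sites
with median sequencing coverage outside [25, 42], the C of CpG
dinucleotides lacking methylation data, CpG islands, sites where the
reference allele is not the ancestral allele, A>G changes on either
strand (transcription-associated mutability), any N within five bases,
and — for 3'UTR cohorts — overlap with CDS exons on either strand.

The rules are pure predicates, so the retained set is order-independent;
only the per-rule attribution of exclusions in the report follows the
fixed documented order (first matching rule wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

RULE_ORDER = (
    "quality",
    "snv",
    "chrom",
    "lcr",
    "coverage",
    "cpg_methylation",
    "cpg_island",
    "ancestral",
    "strand_ag",
    "n_flank",
    "cds_overlap",
)

SEX_MITO_CHROMS = {"X", "Y", "M", "MT", "chrX", "chrY", "chrM", "chrMT"}

VALID = frozenset("ACGT")


class GenomeMask:
    """Merged per-chromosome intervals with vectorized point membership."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end > start:
                raw.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in raw.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.array([s for s, _ in merged])
            self._ends[chrom] = np.array([e for _, e in merged])

    def contains(self, chrom: Sequence[str], pos: Sequence[int]) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            sel = chrom == c
            starts = self._starts.get(c)
            if starts is None:
                continue
            ends = self._ends[c]
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = pos[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class FilterReport:
    input_count: int = 0
    retained_count: int = 0
    exclusions: dict = field(default_factory=dict)

    def check(self) -> bool:
        return self.input_count == self.retained_count + sum(self.exclusions.values())


def _window11(genome, chrom: str, pos: int) -> str:
    seq = genome[chrom]
    contig = seq if isinstance(seq, str) else None
    lo, hi = pos - 5, pos + 6
    if contig is not None:
        if lo < 0 or hi > len(contig):
            return ""
        return contig[lo:hi].upper()
    if lo < 0 or hi > len(seq):
        return ""
    return str(seq[lo:hi]).upper()


def apply_filters(
    variants: pd.DataFrame,
    observed_genome,
    ancestral_genome,
    methylation: Mapping[tuple[str, int], float],
    *,
    lcr: Optional[GenomeMask] = None,
    coverage_keep: Optional[GenomeMask] = None,
    cpg_islands: Optional[GenomeMask] = None,
    cds_exons: Optional[GenomeMask] = None,
    chrom_blacklist: frozenset = frozenset(SEX_MITO_CHROMS),
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion ledger; annotate and return survivors.

    ``variants`` needs columns chrom, pos (0-based), ref, alt, ac and
    pass_flag; multi-allelic records must already be split into biallelic
    rows (see :func:`imaps.io.read_vcf`).  ``coverage_keep`` holds the
    *keep* intervals (median coverage within [25, 42]).  ``cds_exons`` is
    only supplied for 3'UTR cohorts.  Survivors gain window11,
    is_singleton, meth and anc columns.
    """
    v = variants.reset_index(drop=True)
    n = len(v)
    report = FilterReport(input_count=n)
    if n == 0:
        report.exclusions = {r: 0 for r in RULE_ORDER}
        return v.assign(window11="", is_singleton=False, meth=np.nan), report

    chrom = v["chrom"].to_numpy(object)
    pos = v["pos"].to_numpy(np.int64)
    ref = v["ref"].astype(str).str.upper().to_numpy(object)
    alt = v["alt"].astype(str).str.upper().to_numpy(object)

    fails: dict[str, np.ndarray] = {}
    fails["quality"] = ~v["pass_flag"].to_numpy(bool)
    is_snv = np.array([len(r) == 1 and len(a) == 1 and r in VALID and a in VALID
                       for r, a in zip(ref, alt)])
    fails["snv"] = ~is_snv
    fails["chrom"] = np.array([c in chrom_blacklist for c in chrom])
    fails["lcr"] = lcr.contains(chrom, pos) if lcr else np.zeros(n, bool)
    fails["coverage"] = (
        ~coverage_keep.contains(chrom, pos) if coverage_keep else np.zeros(n, bool)
    )

    windows = np.array(
        [_window11(observed_genome, c, p) for c, p in zip(chrom, pos)], dtype=object
    )
    has_window = np.array([len(w) == 11 for w in windows])
    clean_window = np.array(
        [len(w) == 11 and all(b in VALID for b in w) for w in windows]
    )
    fails["n_flank"] = ~clean_window

    prev_b = np.array([w[4] if len(w) == 11 else "N" for w in windows], dtype=object)
    next_b = np.array([w[6] if len(w) == 11 else "N" for w in windows], dtype=object)
    is_cpg_c = is_snv & (((ref == "C") & (next_b == "G")) | ((ref == "G") & (prev_b == "C")))
    meth = np.array(
        [methylation.get((c, int(p)), np.nan) for c, p in zip(chrom, pos)], dtype=float
    )
    fails["cpg_methylation"] = is_cpg_c & np.isnan(meth)
    fails["cpg_island"] = cpg_islands.contains(chrom, pos) if cpg_islands else np.zeros(n, bool)

    anc = np.empty(n, dtype=object)
    for i in range(n):
        contig = ancestral_genome.get(chrom[i]) if isinstance(
            ancestral_genome, Mapping
        ) else (ancestral_genome[chrom[i]] if chrom[i] in ancestral_genome else None)
        if contig is None:
            raise KeyError(
                f"ancestral sequence missing for contig {chrom[i]!r}"
            )
        base = contig[pos[i]]
        anc[i] = (base if isinstance(base, str) else str(base)).upper()
    fails["ancestral"] = is_snv & (anc != ref)

    fails["strand_ag"] = ((ref == "A") & (alt == "G")) | ((ref == "T") & (alt == "C"))
    fails["cds_overlap"] = (
        cds_exons.contains(chrom, pos) if cds_exons else np.zeros(n, bool)
    )

    attributed = np.full(n, "", dtype=object)
    excluded = np.zeros(n, dtype=bool)
    for rule in RULE_ORDER:
        f = fails.get(rule, np.zeros(n, bool))
        newly = f & ~excluded
        attributed[newly] = rule
        excluded |= f
        report.exclusions[rule] = int(newly.sum())

    keep = ~excluded
    out = v.loc[keep].copy()
    out["window11"] = windows[keep]
    out["is_singleton"] = (out["ac"].to_numpy(int) == 1)
    out["meth"] = meth[keep]
    out["anc"] = anc[keep]
    report.retained_count = int(keep.sum())
    return out.reset_index(drop=True), report


def annotate_epigenetics(
    variants: pd.DataFrame,
    dnase: Optional[GenomeMask],
    h3k9me3: Optional[GenomeMask],
    methylation: Optional[Mapping[tuple[str, int], float]] = None,
) -> pd.DataFrame:
    """Attach dnase/h3k9me3 flags (and meth, if not already present).

    CpG-transition variants lacking methylation data are marked with
    ``exclude_missing_meth`` so the caller can drop them.
    """
    v = variants.copy()
    chrom = v["chrom"].to_numpy(object)
    pos = v["pos"].to_numpy(np.int64)
    v["dnase"] = dnase.contains(chrom, pos) if dnase else False
    v["h3k9me3"] = h3k9me3.contains(chrom, pos) if h3k9me3 else False
    if "meth" not in v.columns:
        if methylation is None:
            raise ValueError("methylation table required when meth column absent")
        v["meth"] = [methylation.get((c, int(p)), np.nan) for c, p in zip(chrom, pos)]
    if {"window11", "alt"} <= set(v.columns):
        w = v["window11"].astype(str)
        cpg_transition = (
            (w.str[5] == "C") & (v["alt"] == "T") & (w.str[6] == "G")
        ) | ((w.str[5] == "G") & (v["alt"] == "A") & (w.str[4] == "C"))
        v["exclude_missing_meth"] = cpg_transition & v["meth"].isna()
    return v


def select_intergenic_regions(
    annotation_spans: Iterable[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
    gaps: Iterable[tuple[str, int, int]] = (),
    centromeres: Iterable[tuple[str, int, int]] = (),
    buffer: int = 25_000,
    cap_factor: float = 1.5,
    trim_keep: str = "5prime",
    percentile_method: str = "linear",
) -> list[tuple[str, int, int]]:
    """Neutral calibration regions far from any annotated feature.

    Keeps regions at least ``buffer`` bases from every annotation span,
    subtracts assembly gaps and centromeres, then caps region lengths at
    ``cap_factor`` times the 75th percentile length (linear interpolation)
    to stop very long intergenic stretches from dominating; trimming keeps
    the 5'-most (left) span by default.
    """
    expanded = GenomeMask(
        [(c, max(0, s - buffer), e + buffer) for c, s, e in annotation_spans]
    )
    exclude = GenomeMask(list(gaps) + list(centromeres))
    regions: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        blocked = merge_intervals(
            [
                (max(0, s), min(length, e))
                for c, s, e in expanded.intervals() + exclude.intervals()
                if c == chrom
            ]
        )
        cursor = 0
        for s, e in blocked:
            if s > cursor:
                regions.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            regions.append((chrom, cursor, length))
    if not regions:
        return regions
    lengths = np.array([e - s for _, s, e in regions], dtype=float)
    cap = cap_factor * float(np.percentile(lengths, 75, method=percentile_method))
    cap_i = int(cap)
    out = []
    for chrom, s, e in regions:
        if e - s > cap_i:
            if trim_keep == "5prime":
                e = s + cap_i
            else:
                s = e - cap_i
        out.append((chrom, s, e))
    return out
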