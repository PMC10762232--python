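"""Synthetic genomes, annotations and variant cohorts at toy scale.

Every input the pipeline reads — reference and ancestral FASTA, gene
annotations with phased CDS, poly(A)-site usage, chromatin peaks,
methylation, PSAMs, eCLIP-like peaks and VCF cohorts — can be generated
here, reproducibly from a seed, so the full pipeline is testable without
any external download.

The statistical model mirrors what the singleton-excess statistic
consumes: each variant's singleton status is an independent Bernoulli
draw with probability baseline(parent context) [+ extended-context
deviation] [+ planted selection bump per class].  Baselines are fixed
per parent context by the seed; a full population simulation would add
nothing the statistic can see, since only the singleton indicator and
allele count enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import contexts
from .filtering import GenomeMask
from .psam import PSAM
from .rep_sites import Peak

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Baseline singleton proportions per parent context are drawn once from
    ``baseline_range`` (anchored around the intergenic proportion-singleton
    scale of large human cohorts); planted deviations and selection bumps
    are supplied per call.
    """

    seed: int = 0
    intergenic_length: int = 200_000
    gene_contig_length: int = 400_000
    n_genes: int = 3
    baseline_range: tuple[float, float] = (0.35, 0.65)
    extended_deviations: dict = field(default_factory=dict)  # hexa code -> delta
    planted_window: Optional[str] = None  # 11-mer to embed in the intergenic contig
    planted_derived: str = "T"
    n_planted: int = 0
    #: positions sharing the planted window's inner trinucleotide (hence its
    #: parent context) but with randomized outer flanks, giving the parent
    #: complement statistical weight when testing the planted deep context
    n_planted_background: int = 0
    methylation_fraction: float = 1.0  # fraction of CpGs with methylation data

    def __post_init__(self):
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("baseline_range must be within [0, 1]")
        if self.planted_window is not None and len(self.planted_window) != 11:
            raise ValueError("planted_window must be an 11-mer")


def parent_baselines(config: SimConfig) -> dict[str, float]:
    """Deterministic baseline proportion singleton per parent context."""
    rng = np.random.default_rng((config.seed, 0xBA5E))
    lo, hi = config.baseline_range
    codes = sorted(k.code() for k in contexts.enumerate_parent_contexts())
    draws = rng.uniform(lo, hi, size=len(codes))
    return dict(zip(codes, draws))


@dataclass
class SimReference:
    """A generated toy genome with all side annotations."""

    config: SimConfig
    observed: dict[str, str]
    ancestral: dict[str, str]
    gene_spans: list[tuple[str, int, int]]
    cds_exons: list  # imaps.cds.CDSExon
    stop_codons: list  # imaps.utr.StopCodon
    polya_sites: list  # imaps.utr.PolyASite
    methylation: dict[tuple[str, int], float]
    dnase: GenomeMask
    h3k9me3: GenomeMask
    cpg_islands: GenomeMask
    lcr: GenomeMask
    coverage_keep: GenomeMask
    intergenic_regions: list[tuple[str, int, int]]
    planted_positions: list[tuple[str, int]]
    background_positions: list[tuple[str, int]]
    baselines: dict[str, float]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.observed.items()}


def _random_seq(rng, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def gen_reference(config: SimConfig) -> SimReference:
    """Generate the toy genome: an annotation-free intergenic contig and a
    gene contig with phased CDS, stop codons and poly(A) sites."""
    from .cds import CDSExon
    from .utr import PolyASite, StopCodon

    rng = np.random.default_rng((config.seed, 0x9E0))
    inter = list(_random_seq(rng, config.intergenic_length))

    planted_positions: list[tuple[str, int]] = []
    background_positions: list[tuple[str, int]] = []
    if config.planted_window and (config.n_planted or config.n_planted_background):
        span = 15  # spacing between planted copies
        start0 = 1000
        total = config.n_planted + config.n_planted_background
        needed = start0 + total * span + 1000
        if needed > config.intergenic_length:
            raise ValueError("intergenic contig too short for requested plantings")
        inner3 = config.planted_window[4:7]
        for i in range(total):
            p = start0 + i * span
            if i < config.n_planted:
                inter[p : p + 11] = list(config.planted_window)
                planted_positions.append(("chrI", p + 5))
            else:
                w = _random_seq(rng, 4) + inner3 + _random_seq(rng, 4)
                inter[p : p + 11] = list(w)
                background_positions.append(("chrI", p + 5))
    inter_seq = "".join(inter)

    gl = config.gene_contig_length
    gene_seq = list(_random_seq(rng, gl))
    gene_spans = []
    cds_exons = []
    stop_codons = []
    polya_sites = []
    spacing = gl // max(config.n_genes, 1)
    if spacing < 70_000:
        raise ValueError("gene contig too short for the requested gene count")
    for g in range(config.n_genes):
        strand = "-" if g % 3 == 2 else "+"
        gstart = g * spacing + 5_000
        gene = f"gene{g}"
        if strand == "+":
            # two CDS exons; exon2 length chosen so the CDS ends with a stop
            e1 = (gstart, gstart + 100)  # phase 0
            e2 = (gstart + 200, gstart + 200 + 101)  # 100+101=201 codons*67
            # force a clean ORF: no internal stops, terminal TAA
            _write_orf(gene_seq, [e1, e2], "+", rng)
            stop_pos = e2[1] - 1
            utr_len = 3_000
            sites = [
                PolyASite("chrG", stop_pos + 800, "+", gene, 20.0, True),
                PolyASite("chrG", stop_pos + utr_len, "+", gene, 5.0, False),
            ]
            gene_spans.append(("chrG", gstart, stop_pos + utr_len + 1))
            cds_exons.append(CDSExon("chrG", e1[0], e1[1], "+", 0, f"tx{g}", gene))
            cds_exons.append(CDSExon("chrG", e2[0], e2[1], "+", (3 - 100 % 3) % 3, f"tx{g}", gene))
            stop_codons.append(StopCodon("chrG", stop_pos, "+", gene))
        else:
            e2 = (gstart + 3_000 + 200, gstart + 3_000 + 200 + 101)
            e1 = (gstart + 3_000 + 400, gstart + 3_000 + 500)
            _write_orf(gene_seq, [e1, e2], "-", rng)
            stop_pos = e2[0]
            utr_len = 3_000
            sites = [
                PolyASite("chrG", stop_pos - 800, "-", gene, 20.0, True),
                PolyASite("chrG", stop_pos - utr_len, "-", gene, 5.0, False),
            ]
            gene_spans.append(("chrG", stop_pos - utr_len, e1[1]))
            cds_exons.append(CDSExon("chrG", e1[0], e1[1], "-", 0, f"tx{g}", gene))
            cds_exons.append(CDSExon("chrG", e2[0], e2[1], "-", (3 - 100 % 3) % 3, f"tx{g}", gene))
            stop_codons.append(StopCodon("chrG", stop_pos, "-", gene))
        polya_sites.extend(sites)
    gene_seq = "".join(gene_seq)

    observed = {"chrI": inter_seq, "chrG": gene_seq}
    # ancestral genome equals the reference except at sparse disagreement
    # sites (filter-rule targets), kept off the intergenic contig
    anc_gene = list(gene_seq)
    n_anc_mismatch = 5
    for p in rng.integers(0, gl, size=n_anc_mismatch):
        cur = anc_gene[p]
        anc_gene[p] = str(rng.choice([b for b in "ACGT" if b != cur]))
    ancestral = {"chrI": inter_seq, "chrG": "".join(anc_gene)}

    methylation: dict[tuple[str, int], float] = {}
    for chrom, seq in observed.items():
        meth_rng = np.random.default_rng((config.seed, 0x3E7, hash(chrom) & 0xFFFF))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        for p in cg:
            if meth_rng.random() > config.methylation_fraction:
                continue
            m = float(meth_rng.uniform(0, 100))
            methylation[(chrom, int(p))] = m
            methylation[(chrom, int(p) + 1)] = m

    mask_rng = np.random.default_rng((config.seed, 0x10AD))
    dnase = _random_mask(mask_rng, observed, frac=0.3, mean_len=600)
    h3k = _random_mask(mask_rng, observed, frac=0.1, mean_len=900)
    if planted_positions or background_positions:
        # the planted stretch is a designed fixture: keep the chromatin
        # strata there fixed (negative) so its context is fully determined
        # by the planted sequence
        all_p = [p for _, p in planted_positions + background_positions]
        span = (min(all_p) - 10, max(all_p) + 11)
        dnase = _subtract_span(dnase, "chrI", *span)
        h3k = _subtract_span(h3k, "chrI", *span)
    cpg_islands = GenomeMask([("chrG", 1_000, 1_600)])
    lcr = GenomeMask([("chrI", 0, 500)])
    coverage_keep = GenomeMask(
        [("chrI", 500, config.intergenic_length), ("chrG", 0, gl)]
    )

    from .filtering import select_intergenic_regions

    intergenic = select_intergenic_regions(
        gene_spans,
        {c: len(s) for c, s in observed.items()},
        buffer=25_000,
    )

    return SimReference(
        config=config,
        observed=observed,
        ancestral=ancestral,
        gene_spans=gene_spans,
        cds_exons=cds_exons,
        stop_codons=stop_codons,
        polya_sites=polya_sites,
        methylation=methylation,
        dnase=dnase,
        h3k9me3=h3k,
        cpg_islands=cpg_islands,
        lcr=lcr,
        coverage_keep=coverage_keep,
        intergenic_regions=intergenic,
        planted_positions=planted_positions,
        background_positions=background_positions,
        baselines=parent_baselines(config),
    )


def _write_orf(seq: list, exons: Sequence[tuple[int, int]], strand: str, rng) -> None:
    """Overwrite exon sequence with a stop-free ORF ending in TAA."""
    total = sum(e - s for s, e in exons)
    n_codons = total // 3
    safe = ["GCT", "GGA", "TCC", "CTG", "AAA", "GAT", "TTC"]
    middle = [safe[i] for i in rng.integers(0, len(safe), size=max(n_codons - 2, 0))]
    cds = ("ATG" + "".join(middle) + "TAA")[:total]
    if strand == "-":
        cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        # exons given in transcript order for -, genomic write order reversed
        exons = sorted(exons)
        offset = 0
        for s, e in exons:
            seq[s:e] = list(cds[offset : offset + (e - s)])
            offset += e - s
    else:
        offset = 0
        for s, e in sorted(exons):
            seq[s:e] = list(cds[offset : offset + (e - s)])
            offset += e - s


def _subtract_span(mask: GenomeMask, chrom: str, lo: int, hi: int) -> GenomeMask:
    ivs = []
    for c, s, e in mask.intervals():
        if c != chrom or e <= lo or s >= hi:
            ivs.append((c, s, e))
        else:
            if s < lo:
                ivs.append((c, s, lo))
            if e > hi:
                ivs.append((c, hi, e))
    return GenomeMask(ivs)


def _random_mask(rng, observed: dict[str, str], frac: float, mean_len: int) -> GenomeMask:
    ivs = []
    for chrom, seq in observed.items():
        covered = 0
        target = frac * len(seq)
        while covered < target:
            start = int(rng.integers(0, len(seq) - mean_len))
            length = int(rng.integers(mean_len // 2, mean_len * 2))
            ivs.append((chrom, start, min(start + length, len(seq))))
            covered += length
    return GenomeMask(ivs)


# ---------------------------------------------------------------------------
# Variant cohorts
# ---------------------------------------------------------------------------


def candidate_sites(
    ref: SimReference,
    regions: Sequence[tuple[str, int, int]],
    rng,
    n: int,
    include_strand_ag: bool = False,
    positions: Optional[Sequence[tuple[str, int]]] = None,
    derived: Optional[str] = None,
) -> pd.DataFrame:
    """Sample variant sites (position + derived allele) inside regions.

    Sites keep 5 clean flanking bases; CpG transitions are only sampled
    where methylation data exists.  A>G / T>C changes are excluded unless
    requested (they are filtered from real cohorts, and deliberately
    included only to give the filter rules targets).
    """
    rows = []
    if positions is not None:
        pool = list(positions)
        idx = rng.integers(0, len(pool), size=n)
        chosen = [pool[i] for i in idx]
    else:
        spans = [(c, s, e) for c, s, e in regions if e - s > 12]
        weights = np.array([e - s - 10 for _, s, e in spans], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(spans), size=n, p=weights)
        chosen = []
        for i in which:
            c, s, e = spans[i]
            chosen.append((c, int(rng.integers(s + 5, e - 5))))
    for chrom, pos in chosen:
        seq = ref.observed[chrom]
        w = seq[pos - 5 : pos + 6]
        anc = w[5]
        if derived is not None:
            der = derived
        else:
            opts = [b for b in "ACGT" if b != anc]
            if not include_strand_ag:
                opts = [
                    b
                    for b in opts
                    if (anc, b) not in (("A", "G"), ("T", "C"))
                ]
            der = opts[int(rng.integers(0, len(opts)))]
        is_cpg_tr = (anc == "C" and der == "T" and w[6] == "G") or (
            anc == "G" and der == "A" and w[4] == "C"
        )
        meth = ref.methylation.get((chrom, pos), np.nan)
        if is_cpg_tr and np.isnan(meth):
            continue
        rows.append((chrom, pos, anc, der, w, meth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "window11", "meth"])
    if len(df):
        df["dnase"] = ref.dnase.contains(df["chrom"].to_numpy(object), df["pos"].to_numpy())
        df["h3k9me3"] = ref.h3k9me3.contains(df["chrom"].to_numpy(object), df["pos"].to_numpy())
        df["derived"] = df["alt"]
    return df


def singleton_probability(
    ref: SimReference, sites: pd.DataFrame, class_delta: float = 0.0
) -> np.ndarray:
    """Generative singleton probability per site: parent baseline plus any
    planted extended-context deviation plus the class selection bump."""
    parent_codes = contexts.assign_context_codes(
        sites["window11"].to_numpy(),
        sites["derived"].to_numpy(),
        sites["meth"].to_numpy(dtype=float),
        sites["dnase"].to_numpy(),
        sites["h3k9me3"].to_numpy(),
        "di",
    )
    p = pd.Series(parent_codes).map(ref.baselines).to_numpy(dtype=float)
    if ref.config.extended_deviations:
        hexa_codes = contexts.assign_context_codes(
            sites["window11"].to_numpy(),
            sites["derived"].to_numpy(),
            sites["meth"].to_numpy(dtype=float),
            sites["dnase"].to_numpy(),
            sites["h3k9me3"].to_numpy(),
            "hexa",
        )
        dev = pd.Series(hexa_codes).map(ref.config.extended_deviations).fillna(0.0)
        p = p + dev.to_numpy()
    p = p + class_delta
    if np.any((p < 0) | (p > 1)):
        raise ValueError("singleton probability left [0, 1]; adjust deltas")
    return p


def gen_variant_cohort(
    ref: SimReference,
    regions: Sequence[tuple[str, int, int]],
    n: int,
    seed: int,
    class_delta: float = 0.0,
    include_strand_ag: bool = False,
    positions: Optional[Sequence[tuple[str, int]]] = None,
    derived: Optional[str] = None,
) -> pd.DataFrame:
    """A ready-annotated cohort with Bernoulli singleton status.

    Returns a table usable both as calibration input (window11, derived,
    meth, dnase, h3k9me3, is_singleton) and as VCF-writable rows (chrom,
    pos, ref, alt, ac, pass_flag).
    """
    rng = np.random.default_rng((seed, 0xC040))
    sites = candidate_sites(
        ref, regions, rng, n,
        include_strand_ag=include_strand_ag,
        positions=positions,
        derived=derived,
    )
    p = singleton_probability(ref, sites, class_delta)
    singleton = rng.random(len(sites)) < p
    ac = np.where(singleton, 1, 2 + rng.geometric(0.05, size=len(sites)))
    out = sites.assign(
        is_singleton=singleton,
        ac=ac,
        an=100_000,
        pass_flag=True,
        p_singleton=p,
    )
    return out


# ---------------------------------------------------------------------------
# PSAMs, peaks and planted motifs
# ---------------------------------------------------------------------------


def gen_psam(
    rbp: str,
    k: int,
    seed: int,
    off_affinity: float = 0.05,
) -> PSAM:
    """A PSAM with controllable information content.

    ``off_affinity`` is the relative affinity of non-ideal bases; 1.0
    yields the degenerate uniform matrix (every window scores 1).
    """
    rng = np.random.default_rng((seed, 0x95A3))
    ideal = rng.integers(0, 4, size=k)
    m = np.full((k, 4), off_affinity, dtype=float)
    m[np.arange(k), ideal] = 1.0
    return PSAM(rbp, m)


def gen_psam_and_peaks(
    ref: SimReference,
    rbp: str,
    k: int,
    n_peaks: int,
    seed: int,
    planted_offset: Optional[int] = 20,
    off_affinity: float = 0.05,
    chrom: str = "chrI",
    cell_line: str = "K562",
    strand: str = "+",
) -> tuple[PSAM, list[Peak], pd.DataFrame, dict[str, str]]:
    """Peaks with the PSAM's ideal site planted at a known offset.

    When ``planted_offset`` is None the offsets are drawn uniformly from
    [-75, 75] (the positional null).  Returns the PSAM, the peaks, a truth
    table (peak index, planted genomic start, offset) and the modified
    genome sequences.
    """
    rng = np.random.default_rng((seed, 0x9EA5))
    psam = gen_psam(rbp, k, seed, off_affinity)
    ideal = psam.ideal_site.replace("U", "T")
    genome = {c: list(s) for c, s in ref.observed.items()}
    peaks = []
    truth = []
    contig_len = len(genome[chrom])
    spacing = max(400, 2 * 75 + k + 50)
    first = 200
    if first + n_peaks * spacing + 400 > contig_len:
        raise ValueError("contig too short for the requested peak count")
    for i in range(n_peaks):
        p_start = first + i * spacing
        p_end = p_start + 120
        peak = Peak(chrom, p_start, p_end, strand, rbp, cell_line)
        offset = (
            int(planted_offset)
            if planted_offset is not None
            else int(rng.integers(-75, 76))
        )
        fp = peak.five_prime
        if strand == "+":
            g0 = fp + offset
            genome[chrom][g0 : g0 + k] = list(ideal)
        else:
            g1 = fp - offset + 1
            g0 = g1 - k
            rc = ideal.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            genome[chrom][g0 : g0 + k] = list(rc)
        peaks.append(peak)
        truth.append((i, chrom, g0, g0 + k, offset))
    truth_df = pd.DataFrame(
        truth, columns=["peak", "chrom", "start", "end", "offset"]
    )
    return psam, peaks, truth_df, {c: "".join(s) for c, s in genome.items()}
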