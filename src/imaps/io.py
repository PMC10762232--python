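"""Readers and writers for the standard formats the pipeline consumes.

Coordinates are 0-based half-open internally; VCF positions are converted
at this boundary.  All writers emit plain text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .filtering import GenomeMask
from .rep_sites import Peak
from .utr import PolyASite, StopCodon
from .cds import CDSExon
from .classify import MirTargetSite


# -- VCF -------------------------------------------------------------------


def read_vcf(path) -> pd.DataFrame:
    """SNV table from a VCF: chrom, pos (0-based), ref, alt, ac, pass_flag.

    Multi-allelic records are split into independent biallelic rows.
    Non-SNV alleles are kept (the filter step attributes their exclusion).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = set(rec.filter.keys())
            pass_flag = filters in (set(), {"PASS"})
            acs = rec.info.get("AC", ())
            if not isinstance(acs, (tuple, list)):
                acs = (acs,)
            for i, alt in enumerate(rec.alts or ()):
                ac = int(acs[i]) if i < len(acs) else 1
                rows.append((rec.chrom, rec.start, rec.ref, alt, ac, pass_flag))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ac", "pass_flag"])


def write_vcf(path, variants: pd.DataFrame, contigs: Mapping[str, int]) -> None:
    """Minimal VCF 4.2 writer for synthetic cohorts (AC/AN in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.iterrows():
            flt = "PASS" if r.get("pass_flag", True) else "lowq"
            an = int(r["an"]) if "an" in r else 100000
            fh.write(
                f"{r['chrom']}\t{int(r['pos']) + 1}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"{flt}\tAC={int(r['ac'])};AN={an}\n"
            )


# -- FASTA -----------------------------------------------------------------


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        out[name] = "".join(chunks)
    return out


# -- BED / interval masks ---------------------------------------------------


def read_bed(path) -> list[tuple]:
    """BED rows as tuples (chrom, start, end, *extra columns)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def read_mask(path) -> GenomeMask:
    return GenomeMask((c, s, e) for c, s, e, *_ in read_bed(path))


def write_bed(path, rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_peaks(path) -> list[Peak]:
    """BED6 + rbp + cell_line columns."""
    peaks = []
    for row in read_bed(path):
        chrom, start, end = row[0], row[1], row[2]
        strand = row[5] if len(row) > 5 else "+"
        rbp = row[6] if len(row) > 6 else row[3]
        cell = row[7] if len(row) > 7 else ""
        peaks.append(Peak(chrom, start, end, strand, rbp, cell))
    return peaks


def read_mir_sites(path) -> list[MirTargetSite]:
    """BED6 + site_type + family + conservation_class columns."""
    sites = []
    for row in read_bed(path):
        chrom, start, end = row[0], row[1], row[2]
        strand = row[5] if len(row) > 5 else "+"
        sites.append(MirTargetSite(chrom, start, end, strand, row[6], row[7], row[8]))
    return sites


# -- TSV tables -------------------------------------------------------------


def read_methylation(path) -> dict[tuple[str, int], float]:
    """TSV (chrom, pos, mean_methylation 0-100), 0-based positions."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(c), int(p)): float(m)
        for c, p, m in zip(df["chrom"], df["pos"], df["mean_methylation"])
    }


def write_methylation(path, table: Mapping[tuple[str, int], float]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmean_methylation\n")
        for (chrom, pos), m in sorted(table.items()):
            fh.write(f"{chrom}\t{pos}\t{m:g}\n")


def read_polya_sites(path) -> list[PolyASite]:
    """TSV (chrom, pos, strand, gene, mean_rpm, conserved)."""
    df = pd.read_csv(path, sep="\t")
    return [
        PolyASite(str(r.chrom), int(r.pos), str(r.strand), str(r.gene),
                  float(r.mean_rpm), bool(r.conserved))
        for r in df.itertuples()
    ]


def write_polya_sites(path, sites: Iterable[PolyASite]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tgene\tmean_rpm\tconserved\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.gene}\t{s.mean_rpm:g}\t"
                f"{int(s.conserved)}\n"
            )


def read_pas_whitelist(path) -> list[str]:
    """One hexamer per line; '#' comments allowed; U accepted for T."""
    out = []
    with open(path) as fh:
        for line in fh:
            h = line.split("#")[0].strip().upper().replace("U", "T")
            if h:
                if len(h) != 6 or any(b not in "ACGT" for b in h):
                    raise ValueError(f"invalid PAS hexamer {h!r}")
                out.append(h)
    return out


# -- GFF3 (genes, CDS with phase, stop codons) ------------------------------


def read_gff3(path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(f)
    df = pd.DataFrame(rows, columns=cols)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def _attr(attributes: str, key: str) -> str:
    for kv in attributes.split(";"):
        k, _, v = kv.partition("=")
        if k.strip() == key:
            return v
    return ""


def read_cds_exons(path) -> list[CDSExon]:
    df = read_gff3(path)
    out = []
    for r in df[df["type"] == "CDS"].itertuples():
        out.append(
            CDSExon(
                r.seqid,
                r.start - 1,
                r.end,
                r.strand,
                int(r.phase),
                _attr(r.attributes, "transcript_id"),
                _attr(r.attributes, "gene_id"),
            )
        )
    return out


def read_stop_codons(path) -> list[StopCodon]:
    df = read_gff3(path)
    out = []
    for r in df[df["type"] == "stop_codon"].itertuples():
        pos = r.end - 1 if r.strand == "+" else r.start - 1
        out.append(StopCodon(r.seqid, pos, r.strand, _attr(r.attributes, "gene_id")))
    return out


def read_gene_spans(path) -> list[tuple[str, int, int]]:
    df = read_gff3(path)
    return [
        (r.seqid, r.start - 1, r.end) for r in df[df["type"] == "gene"].itertuples()
    ]


# -- run manifests ----------------------------------------------------------


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
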