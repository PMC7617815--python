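"""Readers and writers for the pipeline's text interchange formats.

FASTA/FASTQ via Biopython-compatible plain text (buffered, Phred+33), a
minimal VCF v4.2 dialect with GT:AD:DP, tab-separated pedigree / marker /
hit / truth tables, BED and BEDGRAPH tracks. Internal coordinates are
0-based half-open; all text formats are 1-based inclusive where the format
prescribes it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simcross import BASES, CrossResult, codes_to_seq

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

_COMP = str.maketrans("ACGTN", "TACGN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_cross_fastq(cross: CrossResult, outdir, quality: int = 35) -> list[Path]:
    """Write paired FASTQ per sample; mate 2 is reverse-complemented."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(cross.pedigree["sample_id"])
    paths = []
    for sid in samples:
        p1, p2 = outdir / f"{sid}_R1.fastq", outdir / f"{sid}_R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for gid, gc in cross.genes.items():
                rs = gc.reads.get(sid)
                if rs is None:
                    continue
                q = chr(quality + 33) * rs.bases1.shape[1]
                for k in range(rs.n_pairs):
                    rid = f"{sid}|{gid}|{k}"
                    f1.write(f"@{rid}/1\n{codes_to_seq(rs.bases1[k])}\n+\n{q}\n")
                    f2.write(f"@{rid}/2\n{revcomp(codes_to_seq(rs.bases2[k]))}\n+\n{q}\n")
        paths.extend([p1, p2])
    return paths


# ---------------------------------------------------------------------------
# VCF (minimal v4.2, GT:AD:DP)


def write_vcf(path, cross: CrossResult, min_allele_reads: int = 2) -> None:
    """Write called-style genotypes at every variant site of the cross.

    Genotypes are naive depth-based calls: alleles with at least
    ``min_allele_reads`` supporting reads are genotyped; AD reports depths
    over REF and the listed ALTs.
    """
    samples = list(cross.pedigree["sample_id"])
    obs = cross.observations.set_index(["chrom", "pos", "sample_id"])
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
    ]
    for gid, gc in cross.genes.items():
        lines.append(f"##contig=<ID={gid},length={gc.length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for gid, gc in cross.genes.items():
        ref_seq = gc.haplotypes["X_ref"]
        for pos in gc.var_positions:
            ref = BASES[int(ref_seq[pos])]
            depths = {}
            alt_counts = np.zeros(4, dtype=np.int64)
            for sid in samples:
                try:
                    row = obs.loc[(gid, pos, sid)]
                    d = np.array([row[b] for b in BASES], dtype=np.int64)
                except KeyError:
                    d = np.zeros(4, dtype=np.int64)
                depths[sid] = d
                alt_counts += d
            alts = [b for i, b in enumerate(BASES)
                    if b != ref and alt_counts[i] >= min_allele_reads]
            if not alts:
                continue
            alleles = [ref] + alts
            allele_idx = {b: i for i, b in enumerate(alleles)}
            fields = []
            for sid in samples:
                d = depths[sid]
                ad = [int(d[BASES.index(b)]) for b in alleles]
                dp = int(d.sum())
                carried = [allele_idx[b] for b in alleles
                           if d[BASES.index(b)] >= min_allele_reads]
                if not carried:
                    gt = "./."
                elif len(carried) == 1:
                    gt = f"{carried[0]}/{carried[0]}"
                else:
                    gt = f"{carried[0]}/{carried[1]}"
                fields.append(f"{gt}:{','.join(map(str, ad))}:{dp}")
            lines.append(
                f"{gid}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT:AD:DP\t"
                + "\t".join(fields)
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_observations_from_vcf(path) -> pd.DataFrame:
    """Per-sample allele-depth table (chrom, pos, sample_id, A, C, G, T) from VCF AD."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alleles = rec.alleles
            for sid in samples:
                ad = rec.samples[sid].get("AD")
                if ad is None:
                    continue
                counts = dict.fromkeys(BASES, 0)
                for allele, d in zip(alleles, ad):
                    if allele in counts and d is not None:
                        counts[allele] = int(d)
                rows.append({"chrom": rec.chrom, "pos": rec.pos - 1, "sample_id": sid,
                             **counts})
    df = pd.DataFrame(rows, columns=["chrom", "pos", "sample_id", *BASES])
    df["depth"] = df[list(BASES)].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# tabular formats


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_hits(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment hit table (-outfmt 6 dialect)."""
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")


def write_bed(path, intervals: list[tuple[int, int, str]], chrom: str) -> None:
    with open(path, "w") as fh:
        for start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "name"],
                       usecols=[0, 1, 2, 3])


def write_bedgraph(path, windows: pd.DataFrame, chrom: str, value_col: str = "rate") -> None:
    with open(path, "w") as fh:
        for _, row in windows.iterrows():
            v = row[value_col]
            if pd.isna(v):
                continue
            fh.write(f"{chrom}\t{int(row['start'])}\t{int(row['end'])}\t{v:.6g}\n")


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
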