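"""Readers and writers for the pipeline's text formats.

Conventions: VCF, pileup and SV coordinates are 1-based; BED and bin tables
are 0-based half-open. FASTQ may be plain or gzip (detected by suffix).
"""

from __future__ import annotations

import gzip
import json
import sys
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import ReadPair
from .svkat import SVCall

SV_COLUMNS = ["sample", "caller", "svtype", "chrom1", "pos1", "chrom2", "pos2",
              "strand1", "strand2", "tier_flag"]


def _open_text(path, mode: str = "rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality-string) records."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), quals


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality-string) records; lengths must match."""
    with _open_text(path, "wt") as fh:
        for i, (rid, seq, qual) in enumerate(records):
            if len(seq) != len(qual):
                raise ValueError(f"record {i} ({rid}): seq/qual length mismatch")
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            SeqIO.write(rec, fh, "fastq")


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    for (id1, s1, q1), (id2, s2, q2) in zip(
        read_fastq(path1), read_fastq(path2), strict=True
    ):
        if id1.split("/")[0] != id2.split("/")[0]:
            raise ValueError(f"read id mismatch: {id1} vs {id2}")
        yield ReadPair(read_id=id1.split("/")[0], seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    pairs = list(pairs)
    write_fastq(((p.read_id, p.seq1, p.qual1) for p in pairs), path1)
    write_fastq(((p.read_id, p.seq2, p.qual2) for p in pairs), path2)


def read_vcf_min(path, sample_id: str | None = None,
                 caller_id: str | None = None) -> pd.DataFrame:
    """Read a minimal single-ALT SNV VCF into a call table.

    Multi-allelic or indel records are rejected with a pointer to
    pre-splitting; a missing header is an error (pysam enforces it).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}:{rec.chrom}:{rec.pos}: multi-allelic record; "
                    "pre-split variants before loading"
                )
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(
                    f"{path}:{rec.chrom}:{rec.pos}: indel record not supported"
                )
            rows.append({
                "sample_id": sample_id or "sample",
                "caller_id": caller_id or "caller",
                "chrom": rec.chrom, "pos": rec.pos, "ref": ref, "alt": alt,
                "qual": rec.qual, "filter": ";".join(rec.filter.keys()) or ".",
            })
    return pd.DataFrame(rows, columns=["sample_id", "caller_id", "chrom", "pos",
                                       "ref", "alt", "qual", "filter"])


def write_vcf_min(calls: pd.DataFrame, path) -> None:
    """Write SNV calls (columns chrom, pos, ref, alt [, qual, filter]) as VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=barcodewga\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            qual = getattr(row, "qual", None)
            qual = "." if qual is None or pd.isna(qual) else f"{qual:g}"
            filt = getattr(row, "filter", ".") or "."
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{qual}\t{filt}\t.\n")


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"}
    if not need <= set(df.columns):
        raise ValueError(f"pileup TSV must have columns {sorted(need)}")
    return df


def write_pileup_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sv_tsv(path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SV TSV missing columns: {sorted(missing)}")
    return [
        SVCall(sample_id=r.sample, caller_id=r.caller, svtype=r.svtype,
               chrom1=r.chrom1, pos1=int(r.pos1), chrom2=r.chrom2,
               pos2=int(r.pos2), strand1=r.strand1, strand2=r.strand2,
               tier_flag=r.tier_flag)
        for r in df.itertuples(index=False)
    ]


def write_sv_tsv(calls: Iterable[SVCall], path) -> None:
    rows = [{
        "sample": c.sample_id, "caller": c.caller_id, "svtype": c.svtype,
        "chrom1": c.chrom1, "pos1": c.pos1, "chrom2": c.chrom2, "pos2": c.pos2,
        "strand1": c.strand1, "strand2": c.strand2, "tier_flag": c.tier_flag,
    } for c in calls]
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, *_ = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end)))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Samples x sites matrix with 0/1/NA entries."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def write_run_manifest(path, params: dict, seed: int | None = None) -> None:
    """Machine-readable record of a CLI run: parameters, seed, versions."""
    import barcodewga
    manifest = {
        "package": "barcodewga",
        "version": barcodewga.__version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "params": params,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
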