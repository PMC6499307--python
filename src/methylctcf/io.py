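"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; 1-based coordinates
appear only at the methylation-TSV boundary (methratio dialect) and are
converted on read/write.  Readers raise on malformed lines with the line
number; the methylation reader strand-collapses symmetric CpG measurements
into one dinucleotide record (coverage-weighted).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, IntervalSet
from .methylome import MethylationTrack
from .nucleosomes import FragmentSet, SignalTrack


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not genome:
        raise ValueError(f"no sequences in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


# -- BED / BEDPE ------------------------------------------------------------

def read_intervals(path: str, fmt: str = "BED") -> IntervalSet:
    """Read BED3/BED6 (``fmt='BED'``) or BEDPE (paired anchors flattened)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            try:
                if fmt == "BEDPE":
                    if len(f) < 6:
                        raise ValueError("BEDPE needs >= 6 columns")
                    name = f[6] if len(f) > 6 else None
                    ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name=name))
                    ivs.append(GenomicInterval(f[3], int(f[4]), int(f[5]), name=name))
                else:
                    if len(f) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    name = f[3] if len(f) > 3 and f[3] != "." else None
                    score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                    strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                    ivs.append(
                        GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name, score)
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
    return IntervalSet(ivs)


def write_intervals(intervals: IntervalSet, path: str, bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name if iv.name is not None else '.'}\t"
                    f"{iv.score if iv.score is not None else 0}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedpe(pairs: Sequence[tuple[GenomicInterval, GenomicInterval]], path: str) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


# -- fragments --------------------------------------------------------------

def read_fragments(path: str, replicate: str = "", condition: str = "") -> FragmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end"],
        usecols=[0, 1, 2], dtype={0: str, 1: np.int64, 2: np.int64},
    )
    if df.empty:
        raise ValueError(f"no fragments in {path}")
    return FragmentSet(df, replicate=replicate, condition=condition)


def write_fragments(frags: FragmentSet, path: str) -> None:
    frags.data[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# -- methylation TSV (methratio dialect) ------------------------------------

def read_methylation(path: str, condition: str = "") -> MethylationTrack:
    """Read a methratio-style TSV: chrom, pos (1-based), strand, context, ratio, coverage.

    Positions are converted to 0-based.  Symmetric +/- CpG rows are collapsed
    coverage-weighted into one record at the + strand C; non-CpG contexts are
    dropped (the count is recorded in ``track.data.attrs['n_non_cpg']``).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "pos", "strand", "context", "ratio", "coverage"],
    )
    if df.empty:
        raise ValueError(f"no methylation records in {path}")
    if ((df["ratio"] < 0) | (df["ratio"] > 1)).any():
        bad = df[(df["ratio"] < 0) | (df["ratio"] > 1)].index[0]
        raise ValueError(f"{path}: ratio outside [0,1] at data row {bad + 1}")
    n_non_cpg = int((df["context"] != "CG").sum())
    df = df[df["context"] == "CG"].copy()
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    # collapse the - strand G onto the + strand C of the same dinucleotide
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] -= 1
    df["meth_reads"] = df["ratio"] * df["coverage"]
    grouped = (
        df.groupby(["chrom", "pos"], as_index=False)
        .agg(meth_reads=("meth_reads", "sum"), coverage=("coverage", "sum"))
    )
    grouped["ratio"] = np.where(
        grouped["coverage"] > 0, grouped["meth_reads"] / grouped["coverage"].clip(lower=1), 0.0
    )
    out = grouped[["chrom", "pos", "ratio", "coverage"]]
    track = MethylationTrack(out, condition=condition)
    track.data.attrs["n_non_cpg"] = n_non_cpg
    return track


def write_methylation(track: MethylationTrack, path: str) -> None:
    """Write the strand-collapsed track back out in methratio dialect (+ strand rows)."""
    with open(path, "w") as fh:
        for row in track.data.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t+\tCG\t{row.ratio:.6g}\t{int(row.coverage)}\n"
            )


# -- bedGraph ---------------------------------------------------------------

def write_bedgraph(track: SignalTrack | pd.DataFrame, path: str) -> None:
    """Write a SignalTrack (run-length encoded) or a (chrom,start,end,value) frame."""
    with open(path, "w") as fh:
        if isinstance(track, pd.DataFrame):
            for row in track.itertuples(index=False):
                fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.6g}\n")
            return
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str, chrom_lengths: dict[str, int]) -> SignalTrack:
    values = {c: np.zeros(l) for c, l in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            values[chrom][s:e] = v
    return SignalTrack(values)


# -- transcripts ------------------------------------------------------------

TRANSCRIPT_COLUMNS = ["transcript_id", "chrom", "start", "end", "strand", "log2fc", "signif"]


def read_transcripts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing transcript columns {sorted(missing)}")
    bad = ~df["signif"].isin(["up", "down", "ns"])
    if bad.any():
        raise ValueError(f"{path}: signif must be up/down/ns")
    return df


def write_transcripts(df: pd.DataFrame, path: str) -> None:
    df[TRANSCRIPT_COLUMNS].to_csv(path, sep="\t", index=False)
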