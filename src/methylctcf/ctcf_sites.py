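"""Replicate-consensus CTCF site categories, motif scanning, CpG composition.

A site is *common* when a peak is present in every WT and every DKO replicate,
*lost* when present in every WT replicate and no DKO replicate, and *gained*
when present in every DKO replicate and no WT replicate; anything else is left
uncategorized.  Motif-level sites are PWM log-odds matches inside peaks and
inherit the peak's category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .trap import MotifModel, encode_sequence

DEFAULT_RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class SiteCall:
    interval: GenomicInterval
    category: str  # common / lost / gained / uncategorized
    level: str  # "peak" or "motif"
    motif_score: Optional[float] = None
    contains_cpg: Optional[bool] = None
    flank_cpg_density: Optional[float] = None


def consensus_sites(
    wt_replicates: Sequence[IntervalSet],
    dko_replicates: Sequence[IntervalSet],
    min_reciprocal: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> list[SiteCall]:
    """Categorize candidate CTCF sites by their replicate support.

    Candidates are single-linkage overlap clusters of the pooled peaks of all
    replicates (insensitive to replicate ordering).  A replicate supports a
    candidate when it contributes a peak whose reciprocal overlap with the
    cluster span is >= ``min_reciprocal``.  The representative interval is the
    intersection of the supporting peaks.
    """
    if not wt_replicates or not dko_replicates:
        raise ValueError("need at least one replicate per condition")
    import warnings

    if len(wt_replicates) < 2 or len(dko_replicates) < 2:
        warnings.warn("fewer than 2 replicates in a condition; consensus is weak")

    tagged: list[tuple[GenomicInterval, str, int]] = []
    for r, peaks in enumerate(wt_replicates):
        tagged.extend((iv, "WT", r) for iv in peaks)
    for r, peaks in enumerate(dko_replicates):
        tagged.extend((iv, "DKO", r) for iv in peaks)

    clusters = IntervalSet([iv for iv, _, _ in tagged]).merged(gap=0)
    calls: list[SiteCall] = []
    for cluster in clusters:
        members = [
            (iv, cond, r)
            for iv, cond, r in tagged
            if iv.overlaps(cluster) and iv.reciprocal_overlap(cluster) >= min_reciprocal
        ]
        wt_reps = {r for _, cond, r in members if cond == "WT"}
        dko_reps = {r for _, cond, r in members if cond == "DKO"}
        all_wt = len(wt_reps) == len(wt_replicates)
        all_dko = len(dko_reps) == len(dko_replicates)
        if all_wt and all_dko:
            category = "common"
        elif all_wt and not dko_reps:
            category = "lost"
        elif all_dko and not wt_reps:
            category = "gained"
        else:
            category = "uncategorized"
        if members:
            start = max(iv.start for iv, _, _ in members)
            end = min(iv.end for iv, _, _ in members)
            rep = (
                GenomicInterval(cluster.chrom, start, end, name=category)
                if end > start
                else cluster
            )
        else:
            rep = cluster
        calls.append(SiteCall(interval=rep, category=category, level="peak"))
    return calls


def scan_motifs(
    peaks: Sequence[SiteCall] | IntervalSet,
    genome: dict[str, str],
    motif: MotifModel,
    score_threshold: Optional[float] = None,
    threshold_fraction: float = 0.6,
) -> list[SiteCall]:
    """Report every PWM match inside each peak as a motif-level site.

    Scores are log2 odds against a uniform background; the default threshold
    is ``threshold_fraction`` of the maximum attainable score.  Both strands
    are scanned; a match is reported on its better-scoring orientation (ties
    go to +) and inherits the parent peak's category.
    """
    lo = motif.log_odds()
    lo_rc = lo[::-1][:, [3, 2, 1, 0]]
    max_score = lo.max(axis=1).sum()
    if score_threshold is None:
        score_threshold = threshold_fraction * max_score
    w = motif.width
    out: list[SiteCall] = []
    items = (
        peaks
        if peaks and isinstance(next(iter(peaks)), SiteCall)
        else [SiteCall(iv, "uncategorized", "peak") for iv in peaks]
    )
    for call in items:
        iv = call.interval
        seq = genome[iv.chrom][iv.start : iv.end]
        codes = encode_sequence(seq)
        n_win = len(codes) - w + 1
        for s in range(max(n_win, 0)):
            win = codes[s : s + w]
            if (win < 0).any():
                continue
            idx = np.arange(w)
            fwd = float(lo[idx, win].sum())
            rev = float(lo_rc[idx, win].sum())
            score, strand = (fwd, "+") if fwd >= rev else (rev, "-")
            if score >= score_threshold:
                out.append(
                    SiteCall(
                        interval=GenomicInterval(
                            iv.chrom, iv.start + s, iv.start + s + w, strand=strand,
                            name=call.category,
                        ),
                        category=call.category,
                        level="motif",
                        motif_score=score,
                    )
                )
    return out


def motifs_per_peak(
    peaks: Sequence[SiteCall], motif_sites: Sequence[SiteCall]
) -> pd.DataFrame:
    """Per-peak motif copy count."""
    motif_set = IntervalSet([m.interval for m in motif_sites])
    rows = []
    for p in peaks:
        n = len(motif_set.overlapping(p.interval))
        rows.append((p.interval.chrom, p.interval.start, p.interval.end, p.category, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "n_motifs"])


def site_cpg_composition(
    sites: Sequence[SiteCall],
    genome: dict[str, str],
    flank: int = 500,
    freq_flank: int = 2000,
) -> dict[str, dict]:
    """Per-category CpG/GC composition of motif-level sites.

    For each category: the fraction of motifs containing a CG dinucleotide,
    the mean CpG density (CpGs per kb) in the +/-``flank`` region, and the
    per-position A/C/G/T frequency matrix over +/-``freq_flank`` bp oriented
    by motif strand.
    """
    by_cat: dict[str, dict] = {}
    width = 2 * freq_flank + 1
    for site in sites:
        iv = site.interval
        chrom_seq = genome[iv.chrom]
        motif_seq = chrom_seq[iv.start : iv.end]
        contains = "CG" in motif_seq.upper()
        f_lo = max(iv.start - flank, 0)
        f_hi = min(iv.end + flank, len(chrom_seq))
        flank_seq = chrom_seq[f_lo:f_hi].upper()
        density = flank_seq.count("CG") / max(len(flank_seq), 1) * 1000.0

        c = iv.center
        lo_, hi_ = c - freq_flank, c + freq_flank + 1
        s_lo, s_hi = max(lo_, 0), min(hi_, len(chrom_seq))
        codes = np.full(width, -1, dtype=np.int8)
        codes[s_lo - lo_ : s_hi - lo_] = encode_sequence(chrom_seq[s_lo:s_hi])
        if iv.strand == "-":
            codes = np.where(codes >= 0, 3 - codes, -1)[::-1]

        entry = by_cat.setdefault(
            site.category,
            {
                "n": 0,
                "n_with_cpg": 0,
                "flank_densities": [],
                "base_counts": np.zeros((width, 4), dtype=np.int64),
                "valid_counts": np.zeros(width, dtype=np.int64),
            },
        )
        entry["n"] += 1
        entry["n_with_cpg"] += int(contains)
        entry["flank_densities"].append(density)
        valid = codes >= 0
        entry["base_counts"][np.arange(width)[valid], codes[valid]] += 1
        entry["valid_counts"] += valid

    result = {}
    for cat, e in by_cat.items():
        with np.errstate(invalid="ignore"):
            freq = e["base_counts"] / np.maximum(e["valid_counts"][:, None], 1)
        freq[e["valid_counts"] == 0] = np.nan
        result[cat] = {
            "n_sites": e["n"],
            "fraction_with_cpg": e["n_with_cpg"] / e["n"],
            "mean_flank_cpg_density": float(np.mean(e["flank_densities"])),
            "base_frequencies": freq,
            "gc_profile": freq[:, 1] + freq[:, 2],
        }
    return result
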