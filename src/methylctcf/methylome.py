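"""Per-CpG methylation handling: classes, smoothing, DMR calling, metaplots.

A :class:`MethylationTrack` holds strand-collapsed CpG dinucleotide records
(position of the C on the + strand, 0-based) with a bisulfite methylation
ratio and read coverage.  The four CpG classes compare the WT and DKO ratios
against fixed thresholds (>=0.8 commonly methylated in both; <0.2 WT with
>0.5 DKO gained; >0.5 WT with <0.2 DKO lost; <0.2 in both unmethylated).
Differentially methylated regions (DMRs) are sliding 1000-bp windows whose
mean methylation deviates between conditions by more than 10%, merged by
direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet


class CpGClass(enum.Enum):
    COMMON_METHYLATED = "common_methylated"
    GAINED = "gained"
    LOST = "lost"
    UNMETHYLATED = "unmethylated"
    OTHER = "other"


# class thresholds; boundary semantics follow the printed definitions:
# ">=0.8" inclusive, "<0.2" and ">0.5" strict
T_LOW = 0.2
T_MID = 0.5
T_HIGH_COMMON = 0.8


@dataclass
class MethylationTrack:
    """Strand-collapsed per-CpG methylation ratios for one condition."""

    data: pd.DataFrame  # columns: chrom, pos, ratio, coverage
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ratio", "coverage"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        df = self.data.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate CpG positions")
        covered = df["coverage"] > 0
        r = df.loc[covered, "ratio"]
        if ((r < 0) | (r > 1)).any():
            raise ValueError("methylation ratio outside [0, 1]")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def chrom_subset(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def covered(self) -> pd.DataFrame:
        return self.data[self.data["coverage"] > 0]

    def dense_arrays(self, chrom: str, length: int) -> np.ndarray:
        """Ratio per bp over ``[0, length)``; NaN away from covered CpGs."""
        arr = np.full(length, np.nan)
        sub = self.chrom_subset(chrom)
        sub = sub[(sub["coverage"] > 0) & (sub["pos"] < length)]
        arr[sub["pos"].to_numpy()] = sub["ratio"].to_numpy()
        return arr


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    direction: str  # "gain" (DKO higher) or "loss"
    mean_wt: float
    mean_dko: float
    n_cpgs: int

    @property
    def delta(self) -> float:
        return self.mean_dko - self.mean_wt


def classify_cpg(m_wt: float, m_dko: float) -> CpGClass:
    """Assign one WT/DKO ratio pair to a methylation-change class."""
    if np.isnan(m_wt) or np.isnan(m_dko):
        raise ValueError("classify_cpg requires covered ratios in both conditions")
    if m_wt >= T_HIGH_COMMON and m_dko >= T_HIGH_COMMON:
        return CpGClass.COMMON_METHYLATED
    if m_wt < T_LOW and m_dko > T_MID:
        return CpGClass.GAINED
    if m_wt > T_MID and m_dko < T_LOW:
        return CpGClass.LOST
    if m_wt < T_LOW and m_dko < T_LOW:
        return CpGClass.UNMETHYLATED
    return CpGClass.OTHER


def classify_cpgs(wt: MethylationTrack, dko: MethylationTrack) -> pd.DataFrame:
    """Vectorized class assignment on CpGs covered in both conditions."""
    merged = pd.merge(
        wt.covered()[["chrom", "pos", "ratio"]],
        dko.covered()[["chrom", "pos", "ratio"]],
        on=["chrom", "pos"],
        suffixes=("_wt", "_dko"),
    )
    mw = merged["ratio_wt"].to_numpy()
    md = merged["ratio_dko"].to_numpy()
    cls = np.full(len(merged), CpGClass.OTHER.value, dtype=object)
    cls[(mw < T_LOW) & (md < T_LOW)] = CpGClass.UNMETHYLATED.value
    cls[(mw > T_MID) & (md < T_LOW)] = CpGClass.LOST.value
    cls[(mw < T_LOW) & (md > T_MID)] = CpGClass.GAINED.value
    cls[(mw >= T_HIGH_COMMON) & (md >= T_HIGH_COMMON)] = CpGClass.COMMON_METHYLATED.value
    merged["cpg_class"] = cls
    return merged


def smooth_methylation(
    track: MethylationTrack,
    window: int = 500,
    step: int = 100,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window mean methylation landscape.

    Returns a bedGraph-shaped frame (chrom, start, end, value); windows with no
    covered CpG are omitted.  The per-window value is the unweighted mean of
    the per-CpG ratios.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    rows = []
    for chrom, sub in track.covered().groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        ratio = sub["ratio"].to_numpy()
        limit = chrom_lengths[chrom] if chrom_lengths else int(pos.max()) + 1
        starts = np.arange(0, max(limit - window, 0) + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        csum = np.concatenate([[0.0], np.cumsum(ratio)])
        n = hi - lo
        with np.errstate(invalid="ignore"):
            means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        keep = n > 0
        for s, m in zip(starts[keep], means[keep]):
            rows.append((chrom, int(s), int(s + window), float(m)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def call_dmrs(
    wt: MethylationTrack,
    dko: MethylationTrack,
    window: int = 1000,
    step: int = 100,
    delta: float = 0.10,
    min_cpgs: int = 4,
    min_cov: int = 4,
    chrom_lengths: dict[str, int] | None = None,
) -> list[DMR]:
    """Call differentially methylated regions between two conditions.

    A window qualifies when both conditions have >= ``min_cpgs`` CpGs covered
    at >= ``min_cov`` reads inside it and the window means deviate by strictly
    more than ``delta``.  Overlapping or bookended qualified windows of the
    same direction merge into one DMR whose means are recomputed over the
    merged interval.
    """
    if window < step:
        raise ValueError("window must be >= step")
    qualified: list[tuple[str, int, int, str]] = []
    wt_cov = wt.data[(wt.data["coverage"] >= min_cov)]
    dko_cov = dko.data[(dko.data["coverage"] >= min_cov)]
    chroms = sorted(set(wt_cov["chrom"]) & set(dko_cov["chrom"]))
    per_chrom: dict[str, tuple] = {}
    for chrom in chroms:
        w_sub = wt_cov[wt_cov["chrom"] == chrom]
        d_sub = dko_cov[dko_cov["chrom"] == chrom]
        wp, wr = w_sub["pos"].to_numpy(), w_sub["ratio"].to_numpy()
        dp, dr = d_sub["pos"].to_numpy(), d_sub["ratio"].to_numpy()
        per_chrom[chrom] = (wp, wr, dp, dr)
        limit = (
            chrom_lengths[chrom]
            if chrom_lengths
            else int(max(wp.max(), dp.max())) + 1
        )
        starts = np.arange(0, max(limit - window, 0) + 1, step)
        wm, wn = _window_means(wp, wr, starts, window)
        dm, dn = _window_means(dp, dr, starts, window)
        ok = (wn >= min_cpgs) & (dn >= min_cpgs)
        diff = dm - wm
        # strict ">" with a guard against float accumulation at the boundary
        called = ok & (np.abs(diff) > delta + 1e-9)
        for s in np.nonzero(called)[0]:
            direction = "gain" if diff[s] > 0 else "loss"
            qualified.append((chrom, int(starts[s]), int(starts[s] + window), direction))

    # merge same-direction overlapping/adjacent windows
    dmrs: list[DMR] = []
    for direction in ("gain", "loss"):
        sub = IntervalSet(
            GenomicInterval(c, s, e) for c, s, e, d in qualified if d == direction
        )
        if len(sub) == 0:
            continue
        for iv in sub.merged(gap=0):
            wp, wr, dp, dr = per_chrom[iv.chrom]
            wmask = (wp >= iv.start) & (wp < iv.end)
            dmask = (dp >= iv.start) & (dp < iv.end)
            dmrs.append(
                DMR(
                    interval=GenomicInterval(iv.chrom, iv.start, iv.end, name=direction),
                    direction=direction,
                    mean_wt=float(wr[wmask].mean()),
                    mean_dko=float(dr[dmask].mean()),
                    n_cpgs=int(min(wmask.sum(), dmask.sum())),
                )
            )
    dmrs.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return dmrs


def _window_means(pos: np.ndarray, ratio: np.ndarray, starts: np.ndarray, window: int):
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    csum = np.concatenate([[0.0], np.cumsum(ratio)])
    n = hi - lo
    means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return means, n


def methylation_profile(
    track: MethylationTrack,
    anchors: IntervalSet,
    flank: int,
    chrom_lengths: dict[str, int],
    mode: str = "absolute",
) -> pd.DataFrame:
    """Mean methylation as a function of distance from anchor centers.

    ``relative`` mode divides by the mean over the full +/-flank window so two
    conditions plotted together are normalized in the same way.  Stranded
    anchors are orientation-flipped.  Returns columns (d, mean, n).
    """
    if len(anchors) == 0:
        raise ValueError("no anchors")
    if mode not in ("absolute", "relative"):
        raise ValueError(f"bad mode {mode!r}")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    dense: dict[str, np.ndarray] = {}
    for iv in anchors:
        if iv.chrom not in dense:
            dense[iv.chrom] = track.dense_arrays(iv.chrom, chrom_lengths[iv.chrom])
        arr = dense[iv.chrom]
        c = iv.center
        lo, hi = c - flank, c + flank + 1
        s_lo, s_hi = max(lo, 0), min(hi, len(arr))
        seg = np.full(width, np.nan)
        seg[s_lo - lo : s_hi - lo] = arr[s_lo:s_hi]
        if iv.strand == "-":
            seg = seg[::-1]
        valid = ~np.isnan(seg)
        total[valid] += seg[valid]
        count += valid
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    if mode == "relative":
        overall = np.nanmean(mean)
        if not np.isfinite(overall) or overall == 0:
            raise ValueError("cannot normalize: zero/empty profile mean")
        mean = mean / overall
    return pd.DataFrame({"d": np.arange(-flank, flank + 1), "mean": mean, "n": count})
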