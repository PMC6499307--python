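"""Anchor-centered average profiles, normalization, periodicity, clustering.

A :class:`Profile` is the unit of every metaplot: per-replicate mean signal as
a function of signed distance from anchor centers, then averaged across
replicates with a cross-replicate standard deviation (sample SD, n-1
denominator — the shaded band of the figures is the SD of the replicate
averaging, not of the anchors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .intervals import IntervalSet
from .nucleosomes import NRLResult, SignalTrack, band_periodogram


@dataclass
class Profile:
    positions: np.ndarray  # relative coordinate d in [-flank, flank]
    replicate_means: np.ndarray  # (n_replicates, len(positions))
    n_anchors: int
    signal_label: str = ""
    anchor_label: str = ""
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.replicate_means = np.atleast_2d(np.asarray(self.replicate_means, dtype=float))
        self.mean = np.nanmean(self.replicate_means, axis=0)
        if self.replicate_means.shape[0] > 1:
            self.sd = np.nanstd(self.replicate_means, axis=0, ddof=1)
        else:
            self.sd = np.zeros_like(self.mean)

    @property
    def flank(self) -> int:
        return int(self.positions.max())

    def scaled(self, factor: float) -> "Profile":
        return Profile(
            self.positions,
            self.replicate_means * factor,
            self.n_anchors,
            self.signal_label,
            self.anchor_label,
        )


def _dense_lookup(signal, chrom: str) -> Optional[np.ndarray]:
    """Per-bp value array for one chromosome from any supported signal type."""
    if isinstance(signal, SignalTrack):
        return signal.values.get(chrom)
    if hasattr(signal, "values") and hasattr(signal, "chrom"):  # AffinityTrack
        if signal.chrom != chrom:
            return None
        if signal.start == 0:
            return signal.values
        out = np.full(signal.start + len(signal.values), np.nan)
        out[signal.start :] = signal.values
        return out
    raise TypeError(f"unsupported signal type {type(signal)!r}")


def anchor_profile(
    signals: Sequence | object,
    anchors: IntervalSet,
    flank: int,
    signal_label: str = "",
    anchor_label: str = "",
) -> Profile:
    """Average signal around anchor centers, replicate-wise then pooled.

    ``signals`` is one signal object or a list of per-replicate signal objects
    (:class:`~methylctcf.nucleosomes.SignalTrack` or
    :class:`~methylctcf.trap.AffinityTrack`).  Stranded anchors are flipped so
    that positive d points in the anchor's 3' direction.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if len(anchors) == 0:
        raise ValueError("no anchors")
    if not isinstance(signals, (list, tuple)):
        signals = [signals]
    width = 2 * flank + 1
    rep_means = []
    for signal in signals:
        total = np.zeros(width)
        count = np.zeros(width, dtype=np.int64)
        cache: dict[str, Optional[np.ndarray]] = {}
        for iv in anchors:
            if iv.chrom not in cache:
                cache[iv.chrom] = _dense_lookup(signal, iv.chrom)
            arr = cache[iv.chrom]
            if arr is None:
                continue
            c = iv.center
            lo, hi = c - flank, c + flank + 1
            s_lo, s_hi = max(lo, 0), min(hi, len(arr))
            seg = np.full(width, np.nan)
            if s_hi > s_lo:
                seg[s_lo - lo : s_hi - lo] = arr[s_lo:s_hi]
            if iv.strand == "-":
                seg = seg[::-1]
            valid = ~np.isnan(seg)
            total[valid] += seg[valid]
            count += valid
        with np.errstate(invalid="ignore"):
            rep_means.append(np.where(count > 0, total / np.maximum(count, 1), np.nan))
    return Profile(
        positions=np.arange(-flank, flank + 1),
        replicate_means=np.vstack(rep_means),
        n_anchors=len(anchors),
        signal_label=signal_label,
        anchor_label=anchor_label,
    )


def normalize_to_common(
    profiles: dict[tuple[str, str], Profile], reference_category: str = "common"
) -> dict[tuple[str, str], Profile]:
    """Scale DKO profiles so WT and DKO agree at the reference category.

    ``profiles`` maps (condition, category) -> Profile for conditions WT/DKO
    and categories including the reference.  The scalar
    s = mean(WT reference) / mean(DKO reference) multiplies every DKO profile;
    WT profiles are untouched.  Idempotent.
    """
    wt_ref = profiles[("WT", reference_category)]
    dko_ref = profiles[("DKO", reference_category)]
    dko_mean = float(np.nanmean(dko_ref.mean))
    if dko_mean == 0 or not np.isfinite(dko_mean):
        raise ValueError("zero-mean reference profile; cannot normalize")
    s = float(np.nanmean(wt_ref.mean)) / dko_mean
    out = {}
    for (cond, cat), prof in profiles.items():
        out[(cond, cat)] = prof.scaled(s) if cond == "DKO" else prof
    return out


def estimate_profile_periodicity(
    profile: Profile,
    period_range: tuple[int, int] = (100, 400),
    detrend_window: int = 300,
    snr_threshold: float = 25.0,
) -> NRLResult:
    """Dominant oscillation period of a profile (e.g. an affinity landscape).

    The profile is detrended by a running mean of ``detrend_window`` bp and
    analyzed with the same band periodogram as the dyad-based NRL estimator
    (peak-to-median significance, parabolic frequency refinement) — robust
    both for smooth oscillations and for sparse periodic combs such as
    motif-echo affinity landscapes.  Missing positions are treated as the
    local trend (zero after detrending).
    """
    y = profile.mean.copy()
    x = profile.positions.astype(float)
    valid = np.isfinite(y)
    if valid.sum() < 3 * period_range[0]:
        raise ValueError("too few defined positions")
    half = detrend_window // 2
    detrended = np.zeros(len(y))
    xv, yv = x[valid], y[valid]
    trend = np.array([yv[(xv >= xi - half) & (xv <= xi + half)].mean() for xi in xv])
    detrended[valid] = yv - trend
    if np.allclose(detrended, 0):
        return NRLResult(None, None, False)
    return band_periodogram(detrended, period_range, snr_threshold)


@dataclass
class ClusterResult:
    centroids: np.ndarray  # (k, profile_length)
    assignments: np.ndarray
    asymmetry: np.ndarray  # per-centroid |left - right| / pooled SD
    n_profiles: int
    control: Optional["ClusterResult"] = None


def cluster_profiles(
    matrix: np.ndarray,
    k: int = 6,
    sample_cap: int = 200_000,
    seed: int = 1,
    control_matrix: Optional[np.ndarray] = None,
) -> ClusterResult:
    """k-means clustering of per-anchor (log-)affinity profiles.

    Rows beyond ``sample_cap`` are subsampled with the given seed.  The
    asymmetry of each centroid is |mean(left flank) - mean(right flank)|
    divided by the pooled SD of the centroid.  When ``control_matrix`` (random
    genomic regions) is given, it is clustered with identical settings and
    attached for comparison.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (profiles x positions)")
    if k > matrix.shape[0]:
        raise ValueError("k exceeds the number of profiles")
    rng = np.random.default_rng(seed)
    if matrix.shape[0] > sample_cap:
        idx = rng.choice(matrix.shape[0], size=sample_cap, replace=False)
        matrix = matrix[idx]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignments = km.fit_predict(matrix)
    centroids = km.cluster_centers_
    asym = centroid_asymmetry(centroids)
    control = None
    if control_matrix is not None:
        control = cluster_profiles(control_matrix, k=k, sample_cap=sample_cap, seed=seed)
    return ClusterResult(centroids, assignments, asym, matrix.shape[0], control)


def centroid_asymmetry(centroids: np.ndarray) -> np.ndarray:
    """|mean left half - mean right half| / pooled SD, per centroid."""
    m = centroids.shape[1]
    half = m // 2
    left = centroids[:, :half].mean(axis=1)
    right = centroids[:, m - half :].mean(axis=1)
    sd = centroids.std(axis=1, ddof=0)
    return np.abs(left - right) / np.where(sd > 0, sd, 1.0)
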