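"""Enrichment, ROC/AUC predictor comparison, and expression linkage.

The predictor table compares four per-site features for discriminating lost
from common CTCF sites: motif log-odds score, change of nucleosome occupancy
(DKO - WT), methylation level, and CpG density of the 1000-bp region around
the site.  AUC is the Mann-Whitney statistic (ties counted half), reported
as-is (no forced >= 0.5 orientation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, rankdata

from .intervals import GenomicInterval, IntervalSet
from .methylome import MethylationTrack
from .nucleosomes import SignalTrack
from .ctcf_sites import SiteCall


@dataclass(frozen=True)
class EnrichmentResult:
    query_label: str
    feature_label: str
    observed: int
    expected: float
    fold: float
    percent_overlap: float
    p_value: Optional[float] = None


def fold_enrichment(
    query: IntervalSet,
    feature: IntervalSet,
    genome_size: int,
    method: str = "analytic",
    n_perm: int = 1000,
    seed: int = 0,
    chrom_lengths: Optional[dict[str, int]] = None,
    query_label: str = "query",
    feature_label: str = "feature",
) -> EnrichmentResult:
    """Fold enrichment of query elements overlapping a feature set.

    Observed = number of query elements overlapping the feature by >= 1 bp.
    Analytic expectation places each element uniformly: n_query x (feature
    coverage / genome size).  The permutation method redraws length-preserving
    uniform placements (chromosome-matched) ``n_perm`` times and reports the
    empirical mean and p-value.
    """
    feat_cov = feature.coverage_bp()
    if genome_size <= feat_cov:
        raise ValueError("genome_size must exceed feature coverage")
    if len(query) == 0:
        raise ValueError("empty query set")
    observed = query.count_overlapping(feature)
    percent = 100.0 * observed / len(query)
    if method == "analytic":
        expected = len(query) * feat_cov / genome_size
        return EnrichmentResult(
            query_label, feature_label, observed, expected, observed / expected, percent
        )
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if chrom_lengths is None:
        raise ValueError("permutation method needs chrom_lengths")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm)
    by_chrom: dict[str, list[int]] = {}
    for iv in query:
        by_chrom.setdefault(iv.chrom, []).append(len(iv))
    for p in range(n_perm):
        n_hit = 0
        for chrom, lens in by_chrom.items():
            L = chrom_lengths[chrom]
            for length in lens:
                s = int(rng.integers(0, max(L - length, 1)))
                if feature.any_overlap(GenomicInterval(chrom, s, s + length)):
                    n_hit += 1
        counts[p] = n_hit
    expected = float(counts.mean())
    if expected == 0:
        expected = 0.5 / n_perm  # continuity guard for empty permutation overlap
    more_extreme = np.sum(counts >= observed) if observed >= expected else np.sum(counts <= observed)
    p_value = float((more_extreme + 1) / (n_perm + 1))
    return EnrichmentResult(
        query_label, feature_label, observed, expected, observed / expected, percent, p_value
    )


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, direction: str = "greater"
) -> tuple[float, pd.DataFrame]:
    """AUC and ROC points for a scalar score against binary labels.

    AUC is computed as the Mann-Whitney U statistic divided by n1*n0 with ties
    counted half, i.e. the probability that a random positive outscores a
    random negative.  ``direction='less'`` negates the scores first (lower
    score predicts the positive class); the result is reported as-is, which
    can be below 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    if direction == "less":
        scores = -scores
    elif direction != "greater":
        raise ValueError(f"bad direction {direction!r}")
    ranks = rankdata(scores)  # average ranks: ties counted half
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # one ROC point per distinct threshold
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate([distinct, [len(sorted_scores) - 1]])
    roc = pd.DataFrame(
        {
            "fpr": np.concatenate([[0.0], fps[idx] / n0]),
            "tpr": np.concatenate([[0.0], tps[idx] / n1]),
            "threshold": np.concatenate([[np.inf], sorted_scores[idx]]),
        }
    )
    return float(auc), roc


def build_predictor_table(
    sites: Sequence[SiteCall],
    occupancy_wt: SignalTrack,
    occupancy_dko: SignalTrack,
    methylation_wt: MethylationTrack,
    genome: dict[str, str],
    occupancy_window: int = 100,
    meth_flank: int = 500,
    cpg_flank: int = 500,
) -> pd.DataFrame:
    """One row per categorized motif site with the four loss predictors.

    flank_cpg_density covers the 1000-bp region around the site (+/-500 bp) in
    CpGs per kb; delta_nuc_occupancy is the DKO - WT mean occupancy over the
    site +/- ``occupancy_window``; methylation_level is the WT mean ratio over
    +/- ``meth_flank``.  Label: lost=1, common=0; other categories dropped.
    """
    rows = []
    meth_by_chrom = {
        chrom: sub for chrom, sub in methylation_wt.covered().groupby("chrom")
    }
    for site in sites:
        if site.category not in ("common", "lost"):
            continue
        iv = site.interval
        occ_iv = GenomicInterval(
            iv.chrom, max(iv.start - occupancy_window, 0), iv.end + occupancy_window
        )
        d_occ = occupancy_dko.region_mean(occ_iv) - occupancy_wt.region_mean(occ_iv)
        sub = meth_by_chrom.get(iv.chrom)
        if sub is not None:
            m = sub[(sub["pos"] >= iv.start - meth_flank) & (sub["pos"] < iv.end + meth_flank)]
            meth = float(m["ratio"].mean()) if len(m) else np.nan
        else:
            meth = np.nan
        chrom_seq = genome[iv.chrom]
        lo = max(iv.start - cpg_flank, 0)
        hi = min(iv.end + cpg_flank, len(chrom_seq))
        flank_seq = chrom_seq[lo:hi].upper()
        density = flank_seq.count("CG") / max(hi - lo, 1) * 1000.0
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "motif_score": site.motif_score,
                "delta_nuc_occupancy": d_occ,
                "methylation_level": meth,
                "flank_cpg_density": density,
                "label": 1 if site.category == "lost" else 0,
            }
        )
    return pd.DataFrame(rows)


EXPRESSION_CATEGORIES = [
    "genome_wide",
    "inside_tads",
    "near_loop_boundary",
    "near_tad_boundary",
    "in_tad_with_lost_boundary",
    "near_lost_loop_boundary",
    "near_lost_tad_boundary",
    "lost_ctcf_at_promoter",
]


def _boundaries(tads: IntervalSet) -> list[tuple[str, int]]:
    pts = []
    for iv in tads:
        pts.append((iv.chrom, iv.start))
        pts.append((iv.chrom, iv.end))
    return pts


def _near_any(chrom: str, start: int, end: int, points: list[tuple[str, int]], dist: int) -> bool:
    for c, p in points:
        if c == chrom and start - dist <= p <= end + dist:
            return True
    return False


def expression_linkage(
    transcripts: pd.DataFrame,
    tads: IntervalSet,
    loop_anchors: IntervalSet,
    lost_sites: IntervalSet,
    promoter_flank: int = 1000,
    dist: int = 10_000,
) -> pd.DataFrame:
    """Up/down-regulation statistics across boundary-defined categories.

    ``transcripts`` columns: transcript_id, chrom, start, end, strand, signif
    (up/down/ns).  A TAD or loop boundary counts as *lost* when at least one
    lost CTCF site lies within ``dist`` of it.  A transcript "lost CTCF at its
    promoter" when a lost site overlaps TSS +/- ``promoter_flank``.  For each
    category the down/up ratio and a chi-square (no continuity correction) of
    (up, down) against the genome-wide counts are reported.
    """
    required = {"chrom", "start", "end", "signif"}
    if not required <= set(transcripts.columns):
        raise ValueError(f"transcripts need columns {sorted(required)}")
    n_skipped = transcripts[["chrom", "start", "end"]].isna().any(axis=1).sum()
    tx = transcripts.dropna(subset=["chrom", "start", "end"]).copy()

    tad_pts = _boundaries(tads)
    loop_pts = [(iv.chrom, iv.center) for iv in loop_anchors]

    def is_lost_point(chrom: str, p: int) -> bool:
        return lost_sites.nearest_distance(chrom, p) <= dist

    lost_tad_pts = [(c, p) for c, p in tad_pts if is_lost_point(c, p)]
    lost_loop_pts = [(c, p) for c, p in loop_pts if is_lost_point(c, p)]
    lost_tads = IntervalSet(
        iv
        for iv in tads
        if is_lost_point(iv.chrom, iv.start) or is_lost_point(iv.chrom, iv.end)
    )

    membership: dict[str, list[bool]] = {c: [] for c in EXPRESSION_CATEGORIES}
    for row in tx.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        tx_iv = GenomicInterval(chrom, start, end)
        membership["genome_wide"].append(True)
        membership["inside_tads"].append(tads.any_overlap(tx_iv))
        membership["near_loop_boundary"].append(_near_any(chrom, start, end, loop_pts, dist))
        membership["near_tad_boundary"].append(_near_any(chrom, start, end, tad_pts, dist))
        membership["in_tad_with_lost_boundary"].append(lost_tads.any_overlap(tx_iv))
        membership["near_lost_loop_boundary"].append(
            _near_any(chrom, start, end, lost_loop_pts, dist)
        )
        membership["near_lost_tad_boundary"].append(
            _near_any(chrom, start, end, lost_tad_pts, dist)
        )
        strand = str(getattr(row, "strand", "+"))
        tss = start if strand != "-" else end - 1
        promoter = GenomicInterval(chrom, max(tss - promoter_flank, 0), tss + promoter_flank + 1)
        membership["lost_ctcf_at_promoter"].append(lost_sites.any_overlap(promoter))

    signif = tx["signif"].to_numpy()
    gw_up = int((signif == "up").sum())
    gw_down = int((signif == "down").sum())
    rows = []
    for cat in EXPRESSION_CATEGORIES:
        mask = np.asarray(membership[cat], dtype=bool)
        n_up = int(((signif == "up") & mask).sum())
        n_down = int(((signif == "down") & mask).sum())
        n_total = int(mask.sum())
        ratio = n_down / n_up if n_up > 0 else np.nan
        if cat == "genome_wide" or n_up + n_down == 0:
            chi2, p = np.nan, np.nan
        else:
            table = np.array([[gw_up, gw_down], [n_up, n_down]])
            if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                chi2, p, _, _ = chi2_contingency(table, correction=False)
            else:
                chi2, p = np.nan, np.nan
        rows.append(
            {
                "category": cat,
                "n_total": n_total,
                "n_up": n_up,
                "n_down": n_down,
                "down_up_ratio": ratio,
                "chi2": chi2,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = int(n_skipped)
    return out
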