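"""Synthetic two-condition epigenome generator with planted ground truth.

The generator emits a miniature genome carrying the statistical structure the
analysis assumes: CpG islands on a CpG-poor background, planted CTCF motifs of
two affinity tiers, WT/DKO methylomes with condition-specific differences and
distance-decaying methylation spreading around lost CTCF sites, phased
nucleosome fragment sets with a configurable repeat length, replicate peak
sets with condition-dependent site loss, and transcripts whose down-regulation
probability rises near lost boundaries.  Ground truth is returned as a
separate :class:`TruthManifest`, never encoded in the analysis inputs.

All parameter defaults are artifact choices of this package (the study the
structures emulate reports no generative model); they are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .methylome import MethylationTrack
from .nucleosomes import FragmentSet
from .trap import load_ctcf_motif, reverse_complement


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic epigenome.

    Rates are per-bp, methylation levels are ratios in [0, 1], lengths in bp.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    island_count: int = 40
    island_length: int = 2000
    island_cpg_rate: float = 0.10
    background_cpg_rate: float = 0.01
    n_sites_island: int = 40
    n_sites_outside: int = 80
    weak_tier_mismatches: int = 2
    site_spacing: int = 400  # min center-to-center distance; keeps peaks disjoint
    # methylome
    meth_island_wt: float = 0.05
    meth_background_wt: float = 0.60
    meth_background_dko: float = 0.62
    spreading_amplitude: float = 0.25
    spreading_decay_length: float = 500.0
    n_planted_dmrs: int = 20
    dmr_length: int = 2000
    dmr_delta: float = 0.35
    coverage: int = 20
    # nucleosomes
    nrl: int = 176
    phasing_sd: float = 20.0
    phasing_fraction: float = 0.7
    phasing_max_order: int = 5
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 15.0
    fragments_per_replicate: int = 150_000
    # peaks
    replicates_per_condition: int = 2
    n_gained_sites: int = 3
    p_fn: float = 0.0
    peak_halfwidth: int = 150
    # site loss model: logistic in local CpG density (dominant) and motif tier
    # p_loss = sigmoid(intercept - density_coef * density/kb - strong_penalty * 1[strong])
    loss_intercept: float = 2.9
    loss_density_coef: float = 0.25
    loss_strong_penalty: float = 1.4
    # expression
    tad_size: int = 100_000
    n_transcripts: int = 500
    base_up_prob: float = 0.10
    base_down_prob: float = 0.10
    expression_downreg_boost: float = 0.35
    boundary_dist: int = 10_000
    promoter_flank: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.island_cpg_rate, self.background_cpg_rate, self.meth_island_wt,
            self.meth_background_wt, self.meth_background_dko, self.spreading_amplitude,
            self.phasing_fraction, self.p_fn,
            self.base_up_prob, self.base_down_prob, self.expression_downreg_boost,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all rates/probabilities must lie in [0, 1]")
        if self.island_length * self.island_count >= self.genome_length:
            raise ValueError("islands cannot fit: island_length * island_count >= genome_length")
        if self.nrl < 147:
            raise ValueError("nrl must be >= 147 (nucleosome footprint)")
        if self.spreading_decay_length <= 0:
            raise ValueError("spreading decay length must be > 0")

    def loss_probability(self, tier: str, density_per_kb: float) -> float:
        """Site loss probability given motif tier and local 1-kb CpG density.

        Logistic with the density term dominant: CpG-island sites (density
        ~100/kb) essentially never lose CTCF, CpG-poor background sites lose
        it often, and within the background a denser flank still protects;
        a strong motif gives additional, smaller protection.
        """
        z = (
            self.loss_intercept
            - self.loss_density_coef * density_per_kb
            - (self.loss_strong_penalty if tier == "strong" else 0.0)
        )
        return float(1.0 / (1.0 + np.exp(-z)))

    @classmethod
    def dmr_benchmark(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Conditions for validating DMR recovery in isolation.

        A 2-Mb genome with 50 planted DMR blocks of |delta| = 0.35 at 20x
        coverage, equal background baselines and no methylation spreading, on
        a CpG background dense enough (~50 CpGs per 1-kb window) that the
        window mean-deviation rule is essentially deterministic: the window
        difference SD is sqrt(2 p(1-p) / (coverage n)) ~ 0.022, putting the
        0.10 threshold at ~4.5 sigma of counting noise.
        """
        kwargs = dict(
            genome_length=2_000_000,
            background_cpg_rate=0.05,
            meth_background_wt=0.60,
            meth_background_dko=0.60,
            spreading_amplitude=0.0,
            n_planted_dmrs=50,
            dmr_delta=0.35,
            coverage=20,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TruthManifest:
    """Machine-readable ground truth of one synthetic epigenome."""

    planted_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    nrl_true: Optional[int] = None
    boundary_losses: pd.DataFrame = field(default_factory=pd.DataFrame)
    downregulated_transcripts: list[str] = field(default_factory=list)
    gained_sites: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self) -> str:
        def df_records(df: pd.DataFrame) -> list[dict]:
            return df.to_dict(orient="records") if len(df) else []

        return json.dumps(
            {
                "planted_sites": df_records(self.planted_sites),
                "planted_dmrs": df_records(self.planted_dmrs),
                "nrl_true": self.nrl_true,
                "boundary_losses": df_records(self.boundary_losses),
                "downregulated_transcripts": self.downregulated_transcripts,
                "gained_sites": df_records(self.gained_sites),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            planted_sites=pd.DataFrame(d["planted_sites"]),
            planted_dmrs=pd.DataFrame(d["planted_dmrs"]),
            nrl_true=d["nrl_true"],
            boundary_losses=pd.DataFrame(d["boundary_losses"]),
            downregulated_transcripts=list(d["downregulated_transcripts"]),
            gained_sites=pd.DataFrame(d["gained_sites"]),
        )


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    islands: IntervalSet
    sites: pd.DataFrame  # chrom, start, end, strand, tier, flank_density, lost, spread_side
    gained_sites: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def site_intervals(self, lost: Optional[bool] = None) -> IntervalSet:
        df = self.sites
        if lost is not None:
            df = df[df["lost"] == lost]
        return IntervalSet.from_dataframe(df.assign(name=df["tier"]))


def _sample_sequence(rng: np.random.Generator, length: int, cpg_rate: np.ndarray) -> str:
    """Sequence with a position-dependent target CpG dinucleotide rate.

    At each emit step a CG dinucleotide is planted with probability
    p = r / (1 - r) (so the realized CpG-per-bp rate is p / (1 + p) = r);
    otherwise a single base is drawn, never a G directly after a C, so planted
    CGs are the only CpGs.
    """
    p_plant = cpg_rate / (1.0 - cpg_rate)
    u = rng.random(length)
    picks4 = rng.integers(0, 4, length)
    picks3 = rng.integers(0, 3, length)
    bases4 = "ACGT"
    bases3 = "ACT"
    out = []
    i = 0
    prev = ""
    while i < length:
        if u[i] < p_plant[i] and i + 1 < length:
            out.append("CG")
            prev = "G"
            i += 2
        else:
            b = bases3[picks3[i]] if prev == "C" else bases4[picks4[i]]
            out.append(b)
            prev = b
            i += 1
    return "".join(out)[:length]


def _weak_variant(consensus: str, motif_prob: np.ndarray, n_mut: int, rng: np.random.Generator) -> str:
    """Consensus with ``n_mut`` columns flipped to their second-best base.

    A weaker-but-genuine match: the site still scores as the motif but below
    the consensus, the way lost CTCF sites match the canonical motif less
    well than retained ones.
    """
    cols = rng.choice(len(consensus), size=n_mut, replace=False)
    seq = list(consensus)
    for j in cols:
        order = np.argsort(motif_prob[j])
        seq[j] = "ACGT"[int(order[-2])]
    return "".join(seq)


def generate_genome(config: SyntheticConfig) -> GenomeBundle:
    """Genome sequence with CpG islands, planted CTCF motifs and site fates.

    Site loss is drawn from the configured loss model (tier and local 1-kb CpG
    density measured on the emitted sequence), so islands retain CTCF while
    CpG-poor background sites lose it preferentially.
    """
    rng = np.random.default_rng(config.seed)
    motif = load_ctcf_motif()
    consensus = motif.consensus
    w = motif.width

    sequences: dict[str, str] = {}
    island_rows = []
    site_rows = []
    gained_rows = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.genome_length
        # non-overlapping islands: one per equal slot, random offset inside
        islands = []
        if config.island_count > 0:
            slot = L // config.island_count
            if slot <= config.island_length:
                raise ValueError("island placement overflow: islands cannot fit without overlap")
            for k in range(config.island_count):
                off = int(rng.integers(0, slot - config.island_length))
                start = k * slot + off
                islands.append((start, start + config.island_length))
        rate = np.full(L, config.background_cpg_rate)
        for s, e in islands:
            rate[s:e] = config.island_cpg_rate
        seq = list(_sample_sequence(rng, L, rate))

        # plant motifs: inside islands and in the background, non-overlapping
        taken: list[tuple[int, int]] = []

        def place(n: int, inside: bool) -> list[tuple[int, str, str]]:
            placed = []
            attempts = 0
            while len(placed) < n and attempts < 50 * n + 100:
                attempts += 1
                if inside:
                    s_isl, e_isl = islands[int(rng.integers(0, len(islands)))]
                    start = int(rng.integers(s_isl + 50, e_isl - 50 - w))
                else:
                    start = int(rng.integers(0, L - w))
                    if any(s - 500 <= start <= e + 500 for s, e in islands):
                        continue
                if any(abs(start - s) < config.site_spacing for s, e in taken):
                    continue
                tier = "strong" if rng.random() < 0.5 else "weak"
                strand = "+" if rng.random() < 0.5 else "-"
                taken.append((start, start + w))
                placed.append((start, tier, strand))
            if len(placed) < n:
                raise ValueError("could not place all requested motif sites")
            return placed

        for start, tier, strand in place(config.n_sites_island, True) + place(
            config.n_sites_outside, False
        ):
            site_seq = (
                consensus
                if tier == "strong"
                else _weak_variant(consensus, motif.prob, config.weak_tier_mismatches, rng)
            )
            if strand == "-":
                site_seq = reverse_complement(site_seq)
            seq[start : start + w] = list(site_seq)
            site_rows.append((chrom, start, start + w, strand, tier))

        sequences[chrom] = "".join(seq)
        island_rows.extend((chrom, s, e) for s, e in islands)

        # gained sites: DKO-only peaks at motif-free background positions,
        # kept clear of planted sites so peak clusters stay condition-pure
        n_placed, attempts = 0, 0
        while n_placed < config.n_gained_sites and attempts < 1000:
            attempts += 1
            start = int(rng.integers(0, L - w))
            if any(abs(start - s) < config.site_spacing for s, e in taken):
                continue
            taken.append((start, start + w))
            gained_rows.append((chrom, start, start + w))
            n_placed += 1

    sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "strand", "tier"])
    # local 1-kb CpG density (measured on the emitted sequence) drives loss
    densities = []
    for row in sites.itertuples(index=False):
        c = (row.start + row.end) // 2
        lo, hi = max(c - 500, 0), min(c + 500, len(sequences[row.chrom]))
        densities.append(sequences[row.chrom][lo:hi].count("CG") / (hi - lo) * 1000.0)
    sites["flank_density"] = densities
    p_loss = np.array(
        [config.loss_probability(t, d) for t, d in zip(sites["tier"], sites["flank_density"])]
    )
    sites["lost"] = rng.random(len(sites)) < p_loss
    # side on which methylation spreads from each lost site (recorded as truth)
    sides = np.array(["left", "right", "both"])[rng.integers(0, 3, len(sites))]
    sites["spread_side"] = np.where(sites["lost"], sides, "none")

    islands_set = IntervalSet(GenomicInterval(c, s, e) for c, s, e in island_rows)
    gained = pd.DataFrame(gained_rows, columns=["chrom", "start", "end"])
    return GenomeBundle(sequences, islands_set, sites, gained)


def cpg_positions(sequence: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    return np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]


def simulate_methylomes(
    bundle: GenomeBundle, config: SyntheticConfig
) -> tuple[MethylationTrack, MethylationTrack, pd.DataFrame]:
    """WT/DKO methylomes with planted DMR blocks and spreading at lost sites.

    True per-CpG levels: islands at ``meth_island_wt`` in both conditions,
    background at the condition baselines; around each lost CTCF site the DKO
    level gains ``spreading_amplitude * exp(-d / spreading_decay_length)`` on
    the recorded side(s); planted DMR blocks shift the DKO level by
    +/- ``dmr_delta``.  Observed ratios are Binomial(coverage, true)/coverage.
    Returns (WT track, DKO track, planted-DMR table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dmr_rows = []
    wt_frames, dko_frames = [], []
    for chrom, seq in bundle.sequences.items():
        L = len(seq)
        pos = cpg_positions(seq)
        in_island = np.zeros(L, dtype=bool)
        for iv in bundle.islands:
            if iv.chrom == chrom:
                in_island[iv.start : iv.end] = True
        true_wt = np.where(in_island[pos], config.meth_island_wt, config.meth_background_wt)
        true_dko = np.where(in_island[pos], config.meth_island_wt, config.meth_background_dko)

        # spreading around lost sites
        lost = bundle.sites[(bundle.sites["chrom"] == chrom) & bundle.sites["lost"]]
        for row in lost.itertuples(index=False):
            c = (row.start + row.end) // 2
            d = pos - c
            decay = config.spreading_amplitude * np.exp(
                -np.abs(d) / config.spreading_decay_length
            )
            if row.spread_side == "left":
                decay[d > 0] = 0.0
            elif row.spread_side == "right":
                decay[d < 0] = 0.0
            true_dko = true_dko + decay

        # planted DMR blocks in motif- and island-free background
        occupied = in_island.copy()
        for row in bundle.sites.itertuples(index=False):
            if row.chrom == chrom:
                c = (row.start + row.end) // 2
                lo = max(c - 4 * int(config.spreading_decay_length), 0)
                occupied[lo : c + 4 * int(config.spreading_decay_length)] = True
        n_placed, attempts = 0, 0
        while n_placed < config.n_planted_dmrs and attempts < 100 * config.n_planted_dmrs:
            attempts += 1
            start = int(rng.integers(0, L - config.dmr_length))
            if occupied[start : start + config.dmr_length].any():
                continue
            occupied[max(start - 2000, 0) : start + config.dmr_length + 2000] = True
            direction = "gain" if n_placed % 2 == 0 else "loss"
            delta = config.dmr_delta if direction == "gain" else -config.dmr_delta
            mask = (pos >= start) & (pos < start + config.dmr_length)
            true_dko[mask] = np.clip(true_dko[mask] + delta, 0.0, 1.0)
            realized = float(
                np.mean(np.clip(true_dko[mask], 0, 1) - np.clip(true_wt[mask], 0, 1))
            ) if mask.any() else delta
            dmr_rows.append(
                (chrom, start, start + config.dmr_length, direction, realized)
            )
            n_placed += 1
        if n_placed < config.n_planted_dmrs:
            raise ValueError("could not place all requested DMR blocks")

        true_wt = np.clip(true_wt, 0.0, 1.0)
        true_dko = np.clip(true_dko, 0.0, 1.0)
        cov = config.coverage
        obs_wt = rng.binomial(cov, true_wt) / cov
        obs_dko = rng.binomial(cov, true_dko) / cov
        wt_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "ratio": obs_wt, "coverage": cov})
        )
        dko_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "ratio": obs_dko, "coverage": cov})
        )
    dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "direction", "delta"])
    wt = MethylationTrack(pd.concat(wt_frames, ignore_index=True), condition="WT")
    dko = MethylationTrack(pd.concat(dko_frames, ignore_index=True), condition="DKO")
    return wt, dko, dmrs


def _bound_mask(bundle: GenomeBundle, condition: str) -> np.ndarray:
    """Which planted sites are CTCF-bound in a condition (lost sites unbind in DKO)."""
    if condition == "WT":
        return np.ones(len(bundle.sites), dtype=bool)
    if condition == "DKO":
        return ~bundle.sites["lost"].to_numpy()
    raise ValueError(f"unknown condition {condition!r}")


def simulate_nucleosome_fragments(
    bundle: GenomeBundle,
    config: SyntheticConfig,
    condition: str,
    replicate: int = 0,
) -> FragmentSet:
    """Phased mononucleosome fragments for one replicate of one condition.

    A fraction ``phasing_fraction`` of fragments belongs to phased arrays
    around planted sites: dyads at +/- k * NRL (k = 1..phasing_max_order) from
    the site center with SD ``phasing_sd``, leaving a depleted region over a
    CTCF-bound motif; at sites not bound in this condition the k = 0 position
    is also available, restoring occupancy over the motif.  The rest is
    uniform background.  Fragment lengths are Normal(mean, sd) truncated to
    [100, 200].
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, 0 if condition == "WT" else 1, replicate])
    )
    n = config.fragments_per_replicate
    if n == 0:
        return FragmentSet(
            pd.DataFrame(columns=["chrom", "start", "end"]), str(replicate), condition
        )
    bound = _bound_mask(bundle, condition)
    sites = bundle.sites
    chroms = list(bundle.sequences)
    lengths = np.array([len(bundle.sequences[c]) for c in chroms], dtype=np.int64)

    phased = rng.random(n) < config.phasing_fraction
    n_ph = int(phased.sum())
    dyads = np.empty(n, dtype=np.int64)
    chrom_idx = np.empty(n, dtype=np.int64)

    # background: uniform over the genome (length-weighted chromosome choice)
    n_bg = n - n_ph
    bg_chrom = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
    dyads[~phased] = (rng.random(n_bg) * lengths[bg_chrom]).astype(np.int64)
    chrom_idx[~phased] = bg_chrom

    if n_ph and len(sites):
        s_idx = rng.integers(0, len(sites), n_ph)
        centers = ((sites["start"] + sites["end"]) // 2).to_numpy()[s_idx]
        kmax = config.phasing_max_order
        ks_nonzero = np.concatenate([np.arange(-kmax, 0), np.arange(1, kmax + 1)])
        ks = rng.choice(ks_nonzero, size=n_ph)
        unbound = ~bound[s_idx]
        # at unbound sites the central (k=0) position carries its uniform share
        take_center = unbound & (rng.random(n_ph) < 1.0 / (2 * kmax + 1))
        ks[take_center] = 0
        jitter = rng.normal(0.0, config.phasing_sd, n_ph)
        site_chrom = sites["chrom"].to_numpy()[s_idx]
        c_map = {c: i for i, c in enumerate(chroms)}
        chrom_idx[phased] = [c_map[c] for c in site_chrom]
        dyads[phased] = (centers + ks * config.nrl + jitter).astype(np.int64)

    frag_len = rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    bad = (frag_len < 100) | (frag_len > 200)
    while bad.any():  # resample outside the truncation bounds
        frag_len[bad] = rng.normal(
            config.fragment_length_mean, config.fragment_length_sd, int(bad.sum())
        )
        bad = (frag_len < 100) | (frag_len > 200)
    frag_len = frag_len.astype(np.int64)
    starts = dyads - frag_len // 2
    chrom_len = lengths[chrom_idx]
    starts = np.clip(starts, 0, chrom_len - frag_len)
    df = pd.DataFrame(
        {
            "chrom": np.array(chroms)[chrom_idx],
            "start": starts,
            "end": starts + frag_len,
        }
    ).sort_values(["chrom", "start"], kind="stable")
    return FragmentSet(df.reset_index(drop=True), replicate=str(replicate), condition=condition)


def simulate_ctcf_peaks(
    bundle: GenomeBundle, config: SyntheticConfig
) -> dict[tuple[str, int], IntervalSet]:
    """Replicate peak sets: lost sites peak in all WT and no DKO replicates.

    Peak intervals are site center +/- ``peak_halfwidth`` with a small
    per-replicate boundary jitter; each peak is independently dropped with the
    false-negative probability ``p_fn`` (0 by default).  Gained sites peak in
    every DKO replicate only.
    """
    if config.replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    out: dict[tuple[str, int], IntervalSet] = {}
    for condition in ("WT", "DKO"):
        bound = _bound_mask(bundle, condition)
        for r in range(config.replicates_per_condition):
            ivs = []
            for (row, b) in zip(bundle.sites.itertuples(index=False), bound):
                if not b:
                    continue
                if config.p_fn > 0 and rng.random() < config.p_fn:
                    continue
                c = (row.start + row.end) // 2
                j1, j2 = rng.integers(-10, 11, 2)
                ivs.append(
                    GenomicInterval(
                        row.chrom,
                        max(c - config.peak_halfwidth + int(j1), 0),
                        c + config.peak_halfwidth + int(j2),
                    )
                )
            if condition == "DKO":
                for row in bundle.gained_sites.itertuples(index=False):
                    c = (row.start + row.end) // 2
                    j1, j2 = rng.integers(-10, 11, 2)
                    ivs.append(
                        GenomicInterval(
                            row.chrom,
                            max(c - config.peak_halfwidth + int(j1), 0),
                            c + config.peak_halfwidth + int(j2),
                        )
                    )
            out[(condition, r)] = IntervalSet(ivs)
    return out


def simulate_expression(
    bundle: GenomeBundle, config: SyntheticConfig
) -> tuple[pd.DataFrame, IntervalSet, IntervalSet, pd.DataFrame]:
    """Transcripts with boundary-linked down-regulation, plus TADs and loops.

    TADs tile each chromosome without overlap; loop anchors sit at a subset of
    TAD boundaries.  A transcript's down-regulation probability is the
    baseline plus ``expression_downreg_boost`` weighted by proximity to the
    nearest lost boundary (exp(-d / boundary_dist)), and maximal for
    transcripts with a lost CTCF site at their promoter.

    Returns (transcript table, TAD set, loop-anchor set, lost-boundary table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    tads = []
    loop_anchor_rows = []
    for chrom, L in bundle.chrom_lengths.items():
        edges = list(range(0, L + 1, config.tad_size))
        if edges[-1] != L:
            edges.append(L)
        for s, e in zip(edges[:-1], edges[1:]):
            tads.append(GenomicInterval(chrom, s, e))
        # loops: anchors at every other interior boundary
        for b in edges[1:-1:2]:
            loop_anchor_rows.append((chrom, b))
    tad_set = IntervalSet(tads)
    loop_set = IntervalSet(
        GenomicInterval(c, max(b - 1, 0), b + 1) for c, b in loop_anchor_rows
    )

    lost_sites = bundle.site_intervals(lost=True)
    boundary_rows = []
    lost_boundaries: list[tuple[str, int]] = []
    seen = set()
    for iv in tads:
        for b in (iv.start, iv.end):
            if (iv.chrom, b) in seen:
                continue
            seen.add((iv.chrom, b))
            if lost_sites.nearest_distance(iv.chrom, b) <= config.boundary_dist:
                lost_boundaries.append((iv.chrom, b))
                boundary_rows.append((iv.chrom, b, "tad"))
    for c, b in loop_anchor_rows:
        if lost_sites.nearest_distance(c, b) <= config.boundary_dist:
            boundary_rows.append((c, b, "loop"))

    chroms = list(bundle.sequences)
    lengths = np.array([bundle.chrom_lengths[c] for c in chroms], dtype=np.int64)
    rows = []
    down_ids = []
    for i in range(config.n_transcripts):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        length = int(rng.integers(2000, 20001))
        start = int(rng.integers(0, max(lengths[ci] - length, 1)))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        promoter = GenomicInterval(
            chrom, max(tss - config.promoter_flank, 0), tss + config.promoter_flank + 1
        )
        if lost_sites.any_overlap(promoter):
            weight = 1.0
        else:
            d_min = min(
                (
                    abs(tss_b - p)
                    for c, p in lost_boundaries
                    if c == chrom
                    for tss_b in (start, end)
                ),
                default=np.inf,
            )
            weight = float(np.exp(-d_min / config.boundary_dist)) if np.isfinite(d_min) else 0.0
            if weight < 1e-3:
                weight = 0.0
        p_down = min(config.base_down_prob + config.expression_downreg_boost * weight, 0.95)
        p_up = config.base_up_prob
        u = rng.random()
        if u < p_down:
            signif = "down"
        elif u < p_down + p_up:
            signif = "up"
        else:
            signif = "ns"
        log2fc = {
            "down": float(rng.normal(-1.5, 0.5)),
            "up": float(rng.normal(1.5, 0.5)),
            "ns": float(rng.normal(0.0, 0.2)),
        }[signif]
        tid = f"tx{i:05d}"
        if signif == "down":
            down_ids.append(tid)
        rows.append((tid, chrom, start, end, strand, log2fc, signif))
    transcripts = pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "strand", "log2fc", "signif"]
    )
    boundaries = pd.DataFrame(boundary_rows, columns=["chrom", "pos", "kind"])
    transcripts.attrs["downregulated"] = down_ids
    return transcripts, tad_set, loop_set, boundaries


@dataclass
class SimulationResult:
    config: SyntheticConfig
    bundle: GenomeBundle
    meth_wt: MethylationTrack
    meth_dko: MethylationTrack
    fragments: dict[tuple[str, int], FragmentSet]
    peaks: dict[tuple[str, int], IntervalSet]
    transcripts: pd.DataFrame
    tads: IntervalSet
    loops: IntervalSet
    manifest: TruthManifest


def simulate_all(config: SyntheticConfig) -> SimulationResult:
    """Run every generator stage and assemble the truth manifest."""
    bundle = generate_genome(config)
    meth_wt, meth_dko, dmrs = simulate_methylomes(bundle, config)
    fragments = {
        (cond, r): simulate_nucleosome_fragments(bundle, config, cond, r)
        for cond in ("WT", "DKO")
        for r in range(config.replicates_per_condition)
    }
    peaks = simulate_ctcf_peaks(bundle, config)
    transcripts, tads, loops, boundaries = simulate_expression(bundle, config)
    manifest = TruthManifest(
        planted_sites=bundle.sites.copy(),
        planted_dmrs=dmrs,
        nrl_true=config.nrl,
        boundary_losses=boundaries,
        downregulated_transcripts=list(transcripts.attrs.get("downregulated", [])),
        gained_sites=bundle.gained_sites.copy(),
    )
    return SimulationResult(
        config, bundle, meth_wt, meth_dko, fragments, peaks, transcripts, tads, loops, manifest
    )
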