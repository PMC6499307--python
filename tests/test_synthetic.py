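"""Synthetic epigenome generator: determinism, planted structure, manifest."""

import dataclasses

import numpy as np
import pytest

import methylctcf as m
from methylctcf.intervals import GenomicInterval, IntervalSet
from methylctcf.synthetic import cpg_positions

SMALL = dict(
    genome_length=300_000,
    island_count=8,
    n_sites_island=8,
    n_sites_outside=16,
    fragments_per_replicate=30_000,
    n_planted_dmrs=4,
    n_transcripts=80,
)


class TestConfigValidation:
    def test_islands_must_fit(self):
        with pytest.raises(ValueError):
            m.SyntheticConfig(genome_length=10_000, island_count=10, island_length=2000)

    def test_nrl_floor(self):
        with pytest.raises(ValueError):
            m.SyntheticConfig(nrl=120)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            m.SyntheticConfig(island_cpg_rate=1.5)

    def test_decay_length_positive(self):
        with pytest.raises(ValueError):
            m.SyntheticConfig(spreading_decay_length=0)


class TestGenerateGenome:
    def test_island_cpg_rate_within_tolerance(self):
        cfg = m.SyntheticConfig(seed=5, **SMALL)
        bundle = m.generate_genome(cfg)
        rates = []
        for iv in bundle.islands:
            seq = bundle.sequences[iv.chrom][iv.start : iv.end]
            rates.append(seq.count("CG") / len(seq))
        assert 0.08 <= np.mean(rates) <= 0.12
        bg = bundle.sequences["chr1"][:5000]
        assert bg.count("CG") / len(bg) < 0.03

    def test_no_islands_degenerate_config(self):
        cfg = m.SyntheticConfig(seed=5, island_count=0, n_sites_island=0, **{
            k: v for k, v in SMALL.items() if k not in ("island_count", "n_sites_island")
        })
        bundle = m.generate_genome(cfg)
        assert len(bundle.islands) == 0
        seq = bundle.sequences["chr1"]
        assert seq.count("CG") / len(seq) == pytest.approx(cfg.background_cpg_rate, rel=0.25)

    def test_same_seed_identical_output(self):
        cfg = m.SyntheticConfig(seed=11, **SMALL)
        b1, b2 = m.generate_genome(cfg), m.generate_genome(cfg)
        assert b1.sequences == b2.sequences
        assert b1.sites.equals(b2.sites)

    def test_planted_motifs_match_tier_by_construction(self, ctcf_motif):
        from methylctcf.trap import reverse_complement

        cfg = m.SyntheticConfig(seed=5, **SMALL)
        bundle = m.generate_genome(cfg)
        for row in bundle.sites.itertuples(index=False):
            site_seq = bundle.sequences[row.chrom][row.start : row.end]
            if row.strand == "-":
                site_seq = reverse_complement(site_seq)
            n_diff = sum(a != b for a, b in zip(site_seq, ctcf_motif.consensus))
            if row.tier == "strong":
                assert n_diff == 0
            else:
                assert n_diff == cfg.weak_tier_mismatches

    def test_island_overflow_raises(self):
        with pytest.raises(ValueError):
            m.generate_genome(
                m.SyntheticConfig(genome_length=100_000, island_count=45, island_length=2000)
            )


class TestSimulateMethylomes:
    def test_spreading_decay_closed_form(self):
        """DKO-WT at distance d from a lost site: baseline delta + A exp(-d/L)."""
        cfg = m.SyntheticConfig(
            seed=9,
            meth_background_wt=0.2,
            meth_background_dko=0.7,
            spreading_amplitude=0.5,
            spreading_decay_length=500.0,
            coverage=4000,  # crush counting noise to expose the mean structure
            n_planted_dmrs=0,
            **{k: v for k, v in SMALL.items() if k != "n_planted_dmrs"},
        )
        bundle = m.generate_genome(cfg)
        wt, dko, _ = m.simulate_methylomes(bundle, cfg)
        lost = bundle.sites[bundle.sites["lost"] & (bundle.sites["spread_side"] == "both")]
        if len(lost) == 0:
            lost = bundle.sites[bundle.sites["lost"]]
        row = lost.iloc[0]
        center = (row.start + row.end) // 2
        sign = -1 if row.spread_side == "left" else 1
        d = int(cfg.spreading_decay_length)
        target = center + sign * d
        merged = wt.data.merge(dko.data, on=["chrom", "pos"], suffixes=("_wt", "_dko"))
        sub = merged[(merged["chrom"] == row.chrom) & (abs(merged["pos"] - target) < 100)]
        observed = (sub["ratio_dko"] - sub["ratio_wt"]).mean()
        expected = (0.7 - 0.2) + 0.5 * np.exp(-1.0)
        assert observed == pytest.approx(expected, abs=0.05)

    def test_null_spreading_no_dmrs_beyond_planted(self):
        cfg = m.SyntheticConfig.dmr_benchmark(seed=4, n_planted_dmrs=0, genome_length=500_000)
        bundle = m.generate_genome(cfg)
        wt, dko, dmrs = m.simulate_methylomes(bundle, cfg)
        assert len(dmrs) == 0
        called = m.call_dmrs(wt, dko, chrom_lengths=bundle.chrom_lengths)
        assert called == []

    def test_manifest_lists_planted_dmrs(self):
        cfg = m.SyntheticConfig(seed=5, **SMALL)
        bundle = m.generate_genome(cfg)
        _, _, dmrs = m.simulate_methylomes(bundle, cfg)
        assert len(dmrs) == cfg.n_planted_dmrs
        assert set(dmrs["direction"]) <= {"gain", "loss"}
        assert (dmrs["end"] - dmrs["start"] == cfg.dmr_length).all()

    def test_ratios_in_unit_interval(self, default_sim):
        for track in (default_sim.meth_wt, default_sim.meth_dko):
            r = track.data["ratio"]
            assert r.between(0, 1).all()


class TestSimulateFragments:
    def test_dyad_autocorrelation_peaks_at_nrl(self, default_sim):
        dyads = default_sim.fragments[("WT", 0)].dyads()["pos"].to_numpy()
        res = m.estimate_nrl(dyads)
        assert res.periodic
        assert res.nrl == pytest.approx(default_sim.config.nrl, abs=2)

    def test_dko_occupancy_restored_at_lost_sites(self, default_sim, default_occupancy):
        occ_wt, occ_dko = default_occupancy
        lost = default_sim.bundle.sites[default_sim.bundle.sites["lost"]]
        wt_means, dko_means = [], []
        for row in lost.itertuples(index=False):
            iv = GenomicInterval(row.chrom, row.start, row.end)
            wt_means.append(occ_wt.region_mean(iv))
            dko_means.append(occ_dko.region_mean(iv))
        assert np.mean(dko_means) > np.mean(wt_means)

    def test_phasing_zero_uniform_coverage(self):
        cfg = m.SyntheticConfig(seed=5, phasing_fraction=0.0, **SMALL)
        bundle = m.generate_genome(cfg)
        frags = m.simulate_nucleosome_fragments(bundle, cfg, "WT", 0)
        track = m.occupancy_track(frags, bundle.chrom_lengths, normalization="raw")
        arr = track.values["chr1"]
        inner = arr[1000:-1000]  # away from edge effects
        assert inner.std() / inner.mean() < 0.5
        assert not m.estimate_nrl(frags.dyads()["pos"].to_numpy()).periodic

    def test_zero_fragments_empty_set(self):
        cfg = m.SyntheticConfig(seed=5, **{**SMALL, "fragments_per_replicate": 0})
        bundle = m.generate_genome(cfg)
        frags = m.simulate_nucleosome_fragments(bundle, cfg, "WT", 0)
        assert len(frags) == 0

    def test_fragment_lengths_truncated(self, default_sim):
        lengths = (
            default_sim.fragments[("DKO", 1)].data["end"]
            - default_sim.fragments[("DKO", 1)].data["start"]
        )
        assert lengths.between(100, 200).all()


class TestSimulatePeaks:
    def test_lost_sites_peak_only_in_wt(self, default_sim):
        truth = default_sim.bundle.sites
        n_rep = default_sim.config.replicates_per_condition
        for row in truth[truth["lost"]].itertuples(index=False):
            center = (row.start + row.end) // 2
            probe = GenomicInterval(row.chrom, center, center + 1)
            for r in range(n_rep):
                assert default_sim.peaks[("WT", r)].any_overlap(probe)
                assert not default_sim.peaks[("DKO", r)].any_overlap(probe)

    def test_no_loss_probability_no_lost_sites(self):
        cfg = m.SyntheticConfig(seed=5, loss_intercept=-50.0, **SMALL)
        bundle = m.generate_genome(cfg)
        assert not bundle.sites["lost"].any()

    def test_single_replicate_rejected(self):
        cfg = m.SyntheticConfig(seed=5, replicates_per_condition=1, **SMALL)
        bundle = m.generate_genome(cfg)
        with pytest.raises(ValueError):
            m.simulate_ctcf_peaks(bundle, cfg)


class TestSimulateExpression:
    def test_tads_tile_without_overlap(self, default_sim):
        tads = sorted(default_sim.tads, key=lambda t: (t.chrom, t.start))
        for a, b in zip(tads, tads[1:]):
            if a.chrom == b.chrom:
                assert a.end == b.start
        assert tads[0].start == 0

    def test_transcript_table_schema(self, default_sim):
        tx = default_sim.transcripts
        assert set(tx["signif"]) <= {"up", "down", "ns"}
        assert (tx["end"] > tx["start"]).all()

    def test_determinism_of_full_simulation(self):
        cfg = m.SyntheticConfig(seed=21, **SMALL)
        s1, s2 = m.simulate_all(cfg), m.simulate_all(cfg)
        assert s1.bundle.sequences == s2.bundle.sequences
        assert s1.transcripts.equals(s2.transcripts)
        assert s1.meth_wt.data.equals(s2.meth_wt.data)
        assert s1.fragments[("DKO", 1)].data.equals(s2.fragments[("DKO", 1)].data)
        assert s1.manifest.to_json() == s2.manifest.to_json()


class TestManifest:
    def test_round_trip_json(self, default_sim):
        text = default_sim.manifest.to_json()
        back = m.TruthManifest.from_json(text)
        assert back.nrl_true == default_sim.manifest.nrl_true
        assert back.planted_sites.shape == default_sim.manifest.planted_sites.shape
        assert back.downregulated_transcripts == default_sim.manifest.downregulated_transcripts

    def test_lost_flags_match_peak_emission(self, default_sim):
        """Manifest truth and emitted peaks agree on every planted site."""
        truth = default_sim.manifest.planted_sites
        n_rep = default_sim.config.replicates_per_condition
        for row in truth.itertuples(index=False):
            center = (row.start + row.end) // 2
            probe = GenomicInterval(row.chrom, center, center + 1)
            in_dko = any(
                default_sim.peaks[("DKO", r)].any_overlap(probe) for r in range(n_rep)
            )
            assert in_dko == (not row.lost)
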