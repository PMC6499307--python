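"""TRAP affinity model: PFM parsing, mismatch energies, binding isotherm."""

import math

import numpy as np
import pytest

from methylctcf.intervals import GenomicInterval
from methylctcf.trap import (
    MotifModel,
    TrapParams,
    affinity_profile,
    load_ctcf_motif,
    load_pfm,
    mismatch_energy,
    region_affinity,
    reverse_complement,
    window_binding_prob,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_profile(sequence, motif, params):
    """Independent reference: explicit per-window, per-strand loops."""
    w = motif.width
    prob = motif.prob
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    values = [float("nan")] * len(sequence)
    for s in range(len(sequence) - w + 1):
        window = sequence[s : s + w].upper()
        if any(b not in base_idx for b in window):
            continue
        total = 0.0
        for oriented in (window, "".join(COMPLEMENT[b] for b in reversed(window))):
            energy = 0.0
            for j, b in enumerate(oriented):
                col = prob[j]
                energy += math.log(max(col) / col[base_idx[b]])
            energy /= params.lam
            x = params.R0 * math.exp(-energy)
            total += x / (1.0 + x)
        values[s + w // 2] = min(total, 1.0)
    return values


class TestLoadPfm:
    def test_pseudocount_normalization(self):
        # counts [[8,0],[0,8],[0,0],[0,0]] + pseudocount 1 -> p(1,A)=9/12
        text = "A 8 0\nC 0 8\nG 0 0\nT 0 0\n"
        motif = load_pfm(text, pseudocount=1.0)
        assert motif.width == 2
        assert motif.prob[0, 0] == pytest.approx(9 / 12)
        assert motif.prob[1, 1] == pytest.approx(9 / 12)
        assert np.allclose(motif.prob.sum(axis=1), 1.0)

    def test_uniform_counts(self):
        motif = load_pfm("A 3 3\nC 3 3\nG 3 3\nT 3 3\n")
        assert np.allclose(motif.prob, 0.25)
        assert np.allclose(motif.max_prob, 0.25)

    def test_packaged_ctcf_width_is_19(self):
        assert load_ctcf_motif().width == 19

    @pytest.mark.parametrize(
        "text",
        [
            "A 1 2\nC 1\nG 1 2\nT 1 2\n",  # ragged
            "A 1 -2\nC 1 2\nG 1 2\nT 1 2\n",  # negative
            "A 1 2\nC 1 2\nG 1 2\nX 1 2\n",  # unknown base
        ],
    )
    def test_malformed_pfm_rejected(self, text):
        with pytest.raises(ValueError):
            load_pfm(text)


class TestMismatchEnergy:
    def test_consensus_energy_zero(self, ctcf_motif):
        params = TrapParams()
        assert mismatch_energy(ctcf_motif.consensus, ctcf_motif, params) == 0.0

    def test_single_mismatch_arithmetic(self):
        # one column p_max=0.9 / p_obs=0.1, lambda=1.5 -> ln(9)/1.5
        prob = np.array([[0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3]] * 3)
        prob /= prob.sum(axis=1, keepdims=True)
        motif = MotifModel(prob)
        params = TrapParams(lam=1.5)
        # mutate middle column to a base with p = 0.1/3... use explicit probs
        prob2 = np.array([[0.9, 0.1, 0.0, 0.0]] * 3) + 1e-12
        prob2 /= prob2.sum(axis=1, keepdims=True)
        motif2 = MotifModel(prob2)
        e = mismatch_energy("ACA", motif2, params)
        assert e == pytest.approx(math.log(9) / 1.5, rel=1e-6)
        assert math.log(9) / 1.5 == pytest.approx(1.4648, abs=1e-4)

    def test_lambda_scaling_halves_energy(self, ctcf_motif, rng):
        window = "".join(rng.choice(list("ACGT"), size=ctcf_motif.width))
        e1 = mismatch_energy(window, ctcf_motif, TrapParams(lam=1.5))
        e2 = mismatch_energy(window, ctcf_motif, TrapParams(lam=3.0))
        assert e2 == pytest.approx(e1 / 2)

    def test_minus_strand_uses_reverse_complement(self, ctcf_motif):
        rc = reverse_complement(ctcf_motif.consensus)
        assert mismatch_energy(rc, ctcf_motif, TrapParams(), strand="-") == 0.0

    def test_ambiguous_base_is_nan(self, ctcf_motif):
        window = "N" + ctcf_motif.consensus[1:]
        assert math.isnan(mismatch_energy(window, ctcf_motif, TrapParams()))


class TestBindingProb:
    def test_consensus_saturates(self):
        p = window_binding_prob(0.0, TrapParams(R0=1e9))
        assert p == pytest.approx(1e9 / (1e9 + 1))

    def test_midpoint_identity(self):
        p = window_binding_prob(math.log(1e9), TrapParams(R0=1e9))
        assert p == pytest.approx(0.5)

    def test_high_energy_value(self):
        x = 1e9 * math.exp(-25)
        assert window_binding_prob(25.0, TrapParams(R0=1e9)) == pytest.approx(
            x / (1 + x)
        )
        assert window_binding_prob(25.0, TrapParams(R0=1e9)) == pytest.approx(
            0.0134, abs=2e-3
        )

    def test_monotone_decreasing(self):
        params = TrapParams()
        energies = np.linspace(0, 40, 50)
        probs = [window_binding_prob(e, params) for e in energies]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestAffinityProfile:
    def test_matches_brute_force_on_random_sequences(self, ctcf_motif, rng):
        """Oracle equivalence on random 200-bp sequences at <= 1e-9 relative."""
        params = TrapParams()
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            track = affinity_profile(seq, ctcf_motif, params)
            expected = brute_force_profile(seq, ctcf_motif, params)
            for got, want in zip(track.values, expected):
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-9)

    def test_planted_consensus_is_global_maximum(self, ctcf_motif, rng):
        seq = list("".join(rng.choice(list("ACGT"), size=400)))
        start = 190
        seq[start : start + 19] = list(ctcf_motif.consensus)
        # R0=1 keeps windows out of saturation so the maximum is unique
        track = affinity_profile("".join(seq), ctcf_motif, TrapParams(R0=1.0))
        assert np.nanargmax(track.values) == start + 19 // 2
        # at the default R0 the planted center still attains the capped maximum
        track9 = affinity_profile("".join(seq), ctcf_motif, TrapParams())
        assert track9.values[start + 9] == pytest.approx(np.nanmax(track9.values))

    def test_n_windows_are_missing_not_zero(self, ctcf_motif):
        seq = ctcf_motif.consensus + "N" * 19 + ctcf_motif.consensus
        track = affinity_profile(seq, ctcf_motif, TrapParams())
        # the N bleeds into every overlapping window
        assert np.isnan(track.values[19 + 9])
        assert track.values[9] > 0.99

    def test_single_worsening_substitution_never_increases_p(self, ctcf_motif, rng):
        params = TrapParams(R0=1.0)  # mid-range so changes are visible
        seq = "".join(rng.choice(list("ACGT"), size=19))
        e0 = mismatch_energy(seq, ctcf_motif, params)
        p0 = window_binding_prob(e0, params)
        for j in range(19):
            for b in "ACGT":
                if b == seq[j]:
                    continue
                mutated = seq[:j] + b + seq[j + 1 :]
                e1 = mismatch_energy(mutated, ctcf_motif, params)
                if e1 >= e0:  # worsening or neutral substitution
                    assert window_binding_prob(e1, params) <= p0 + 1e-12

    def test_r0_limits(self, ctcf_motif, rng):
        seq = "".join(rng.choice(list("ACGT"), size=19))
        e = mismatch_energy(seq, ctcf_motif, TrapParams())
        assert window_binding_prob(e, TrapParams(R0=1e30)) == pytest.approx(1.0)
        tiny = TrapParams(R0=1e-12)
        assert window_binding_prob(e, tiny) == pytest.approx(
            tiny.R0 * math.exp(-e), rel=1e-6
        )

    def test_sequence_shorter_than_motif_rejected(self, ctcf_motif):
        with pytest.raises(ValueError):
            affinity_profile("ACGT", ctcf_motif, TrapParams())


class TestRegionAffinity:
    def test_additive_over_split(self, ctcf_motif, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        track = affinity_profile(seq, ctcf_motif, TrapParams())
        whole = region_affinity(track, GenomicInterval("chr1", 50, 450))
        left = region_affinity(track, GenomicInterval("chr1", 50, 250))
        right = region_affinity(track, GenomicInterval("chr1", 250, 450))
        assert whole == pytest.approx(left + right)

    def test_consensus_region_value(self, ctcf_motif, rng):
        seq = list("A" * 200)
        seq[90:109] = list(ctcf_motif.consensus)
        track = affinity_profile("".join(seq), ctcf_motif, TrapParams())
        # the planted consensus window saturates and is capped at 1
        val = region_affinity(track, GenomicInterval("chr1", 95, 105))
        assert val >= 0.999
        assert val <= 10.0

    def test_outside_track_is_zero(self, ctcf_motif):
        track = affinity_profile("ACGT" * 10, ctcf_motif, TrapParams())
        assert region_affinity(track, GenomicInterval("chr1", 1000, 2000)) == 0.0
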