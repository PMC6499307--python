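"""Biophysical prediction of TF-DNA binding affinity (TRAP model).

The TRAP model converts a position frequency matrix into an expected binding
occupancy for every sequence window.  A window's mismatch energy is the
lambda-scaled sum of log-ratios between the per-column best base and the base
actually observed,

    beta*E(w) = (1/lambda) * sum_j ln( p(j, b_max) / p(j, w_j) ),

which is zero exactly for the per-column consensus.  The occupancy of the
window then follows the two-state binding isotherm

    p = R0 * exp(-beta*E) / (1 + R0 * exp(-beta*E)),

where ``R0`` plays the role of a dimensionless protein-concentration /
association constant.  Defaults ``R0 = 1e9`` and ``lambda = 1.5`` are the
values used throughout this analysis for the 19-bp CTCF motif.

Per-window probabilities are computed on both strands, summed and capped at 1
(a site carries the motif on one orientation only, but either strand may carry
it); the sum is assigned to the window-center coordinate.  Windows containing
ambiguous bases are reported missing (NaN) rather than zero, so assembly gaps
do not produce spurious affinity valleys.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass(frozen=True)
class TrapParams:
    """TRAP binding parameters: association constant ``R0`` and energy scale ``lam``."""

    R0: float = 1e9
    lam: float = 1.5

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass(frozen=True)
class MotifModel:
    """Position probability matrix with per-column maxima.

    ``prob`` has shape (width, 4) in A,C,G,T order; every column sums to 1 and
    all entries are strictly positive (a pseudocount is applied before
    normalization, so mismatch energies are always finite).
    """

    prob: np.ndarray
    name: str = "motif"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.prob, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("prob must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif columns must sum to 1")
        if not (p > 0).all():
            raise ValueError("motif probabilities must be strictly positive")
        object.__setattr__(self, "prob", p)

    @property
    def width(self) -> int:
        return self.prob.shape[0]

    @property
    def max_prob(self) -> np.ndarray:
        return self.prob.max(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.prob.argmax(axis=1))

    def log_mismatch(self) -> np.ndarray:
        """ln(p_max / p) per (column, base); zero at the consensus base."""
        return np.log(self.max_prob[:, None] / self.prob)

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        """log2(p / background) per (column, base), for motif scanning."""
        return np.log2(self.prob / background)


@dataclass
class AffinityTrack:
    """Per-position predicted binding probability along one chromosome.

    ``values[i]`` is the strand-summed, capped window probability assigned to
    genomic position ``start + i``; NaN where no complete window covers the
    position or the window contains an ambiguous base.
    """

    chrom: str
    start: int
    values: np.ndarray
    motif_name: str = "motif"
    log_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.log_values = np.log(self.values)

    @property
    def end(self) -> int:
        return self.start + len(self.values)


def load_pfm(text: str, pseudocount: float = 1.0, name: str | None = None) -> MotifModel:
    """Parse a JASPAR-dialect PFM into a normalized :class:`MotifModel`.

    Accepts both the bracketed form (``A  [ 87 167 ... ]``) and plain
    whitespace-separated count rows in A,C,G,T order; a ``>`` header line
    supplies the motif name.
    """
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    motif_name = name
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if motif_name is None:
                motif_name = line[1:].strip() or "motif"
            continue
        base = None
        body = line
        if line[0].upper() in _BASE_INDEX and (len(line) == 1 or not line[1].isdigit()):
            base = line[0].upper()
            body = line[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            counts = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise ValueError(f"PFM parse error at line {lineno}: {exc}") from None
        if not counts:
            continue
        if any(c < 0 for c in counts):
            raise ValueError(f"PFM parse error at line {lineno}: negative count")
        if base is None:
            base = _BASES[len(order)] if len(order) < 4 else None
        if base is None or base in rows:
            raise ValueError(f"PFM parse error at line {lineno}: unexpected row")
        rows[base] = counts
        order.append(base)
    if set(rows) != set(_BASES):
        raise ValueError(f"PFM must have A,C,G,T rows; got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError(f"ragged PFM rows: widths {sorted(widths)}")
    counts = np.array([rows[b] for b in _BASES], dtype=float).T  # (width, 4)
    counts += pseudocount
    prob = counts / counts.sum(axis=1, keepdims=True)
    return MotifModel(prob, name=motif_name or "motif", pseudocount=pseudocount)


def load_ctcf_motif(pseudocount: float = 1.0) -> MotifModel:
    """The packaged 19-bp JASPAR CTCF matrix (MA0139.1)."""
    text = (
        importlib.resources.files("methylctcf.data")
        .joinpath("ctcf_jaspar.pfm")
        .read_text()
    )
    return load_pfm(text, pseudocount=pseudocount)


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any other symbol (N, gaps) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def mismatch_energy(
    window: str, motif: MotifModel, params: TrapParams, strand: str = "+"
) -> float:
    """Dimensionless mismatch energy beta*E of one window on one strand.

    Returns NaN if the window contains a base outside A,C,G,T.
    """
    if len(window) != motif.width:
        raise ValueError(f"window length {len(window)} != motif width {motif.width}")
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    codes = encode_sequence(window)
    if (codes < 0).any():
        return float("nan")
    lm = motif.log_mismatch()
    return float(lm[np.arange(motif.width), codes].sum() / params.lam)


def window_binding_prob(energy: float, params: TrapParams) -> float:
    """Binding isotherm p = R0 e^-E / (1 + R0 e^-E); decreasing in the energy."""
    x = params.R0 * np.exp(-energy)
    return float(x / (1.0 + x))


def _windowed_energies(codes: np.ndarray, log_mismatch: np.ndarray, lam: float) -> np.ndarray:
    """Per-window beta*E for every window start; NaN where a window has an N."""
    w = log_mismatch.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        raise ValueError("sequence shorter than motif")
    energies = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(w):
        col_codes = codes[j : j + n_win]
        valid = col_codes >= 0
        vals = np.zeros(n_win)
        vals[valid] = log_mismatch[j, col_codes[valid]]
        energies += vals
        bad |= ~valid
    energies /= lam
    energies[bad] = np.nan
    return energies


def affinity_profile(
    sequence: str,
    motif: MotifModel,
    params: TrapParams = TrapParams(),
    chrom: str = "chr1",
    start: int = 0,
) -> AffinityTrack:
    """Strand-summed TRAP binding-probability landscape of a sequence.

    The probability of the window starting at ``s`` (forward) plus the window
    probability of its reverse complement is capped at 1 and assigned to the
    center position ``s + width//2``.  Positions whose window would run off
    either end are NaN.
    """
    w = motif.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than motif width")
    codes = encode_sequence(sequence)
    lm = motif.log_mismatch()
    # reverse-complement scoring matrix: column j reads complement base at
    # mirrored column, so the same forward window indexes both strands
    lm_rc = lm[::-1][:, _COMPLEMENT_IDX]
    e_fwd = _windowed_energies(codes, lm, params.lam)
    e_rev = _windowed_energies(codes, lm_rc, params.lam)
    with np.errstate(invalid="ignore"):
        p = _isotherm(e_fwd, params.R0) + _isotherm(e_rev, params.R0)
        p = np.minimum(p, 1.0)
    values = np.full(len(sequence), np.nan)
    centers = np.arange(len(p)) + w // 2
    values[centers] = p
    return AffinityTrack(chrom, start, values, motif_name=motif.name)


def _isotherm(energies: np.ndarray, R0: float) -> np.ndarray:
    x = R0 * np.exp(-energies)
    return x / (1.0 + x)


def region_affinity(track: AffinityTrack, region: GenomicInterval) -> float:
    """Sum of window binding probabilities over a region (additive; NaN-skipped)."""
    if region.chrom != track.chrom:
        raise ValueError("region on a different chromosome than the track")
    lo = max(region.start, track.start) - track.start
    hi = min(region.end, track.end) - track.start
    if hi <= lo:
        return 0.0
    seg = track.values[lo:hi]
    return float(np.nansum(seg))
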