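"""Mallat-pyramid discrete wavelet decomposition with subband bookkeeping.

A single analysis level splits a signal through a quadrature-mirror
high-/low-pass filter pair followed by dyadic downsampling, yielding the
detail (high-band) and approximation (low-band) coefficient series.
Cascading the split on successive approximations gives the familiar
three-level pyramid A1/D1 .. A3/D3; with Nyquist frequency fN = fs/2 the
level-j approximation occupies (0, fN/2^j) Hz and the level-j detail
(fN/2^j, fN/2^(j-1)) Hz, so {D1, D2, D3, A3} tile (0, fN).

Filtering and downsampling are delegated to PyWavelets; this module owns
the level bookkeeping, band-edge arithmetic, and reconstruction cascade.
The default boundary rule is half-point symmetric padding; "periodization"
is available when exact subband energy conservation is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

DEFAULT_WAVELET = "db4"

#: Subband labels of a three-level pyramid in cascade order.
LEVEL_LABELS = ("A1", "D1", "A2", "D2", "A3", "D3")


@dataclass
class FilterBank:
    """Analysis/synthesis tap sets of a two-channel quadrature-mirror bank."""

    name: str
    lo_a: np.ndarray
    hi_a: np.ndarray
    lo_s: np.ndarray
    hi_s: np.ndarray

    def __post_init__(self) -> None:
        self.lo_a = np.asarray(self.lo_a, dtype=float)
        self.hi_a = np.asarray(self.hi_a, dtype=float)
        self.lo_s = np.asarray(self.lo_s, dtype=float)
        self.hi_s = np.asarray(self.hi_s, dtype=float)
        lens = {len(self.lo_a), len(self.hi_a), len(self.lo_s), len(self.hi_s)}
        if len(lens) != 1:
            raise ValueError("all four filter tap sequences must have equal length")
        if self.taps % 2 != 0:
            raise ValueError("filter length must be even")

    @property
    def taps(self) -> int:
        return len(self.lo_a)

    def _pywt(self) -> pywt.Wavelet:
        return pywt.Wavelet(
            self.name,
            filter_bank=[self.lo_a, self.hi_a, self.lo_s, self.hi_s],
        )


def filter_bank(name: str = DEFAULT_WAVELET) -> FilterBank:
    """Look up a standard orthogonal wavelet filter bank by name.

    Any discrete PyWavelets name works ("haar", "db2".."db10", "sym4",
    "coif1", ...). db4 is the default: a standard compromise between
    frequency selectivity and time localization for EEG subband work.
    """
    try:
        w = pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet name {name!r}") from exc
    return FilterBank(
        name=name,
        lo_a=w.dec_lo,
        hi_a=w.dec_hi,
        lo_s=w.rec_lo,
        hi_s=w.rec_hi,
    )


@dataclass
class WaveletDecomposition:
    """Coefficients of a multi-level pyramid plus reconstruction metadata.

    ``coeffs`` maps labels A1..A{levels}, D1..D{levels} to coefficient
    arrays; ``level_lens`` records the input length at each cascade stage
    so the synthesis cascade can trim to the exact original lengths.
    """

    levels: int
    coeffs: dict[str, np.ndarray]
    fs: float
    orig_len: int
    wavelet: str = DEFAULT_WAVELET
    mode: str = "symmetric"
    level_lens: tuple[int, ...] = field(default_factory=tuple)

    def approx(self, level: int | None = None) -> np.ndarray:
        level = self.levels if level is None else level
        return self.coeffs[f"A{level}"]

    def detail(self, level: int) -> np.ndarray:
        return self.coeffs[f"D{level}"]


def dwt_level(x, fb: FilterBank, mode: str = "symmetric"):
    """One analysis level: filter with the LP/HP pair and downsample by 2.

    Returns
    -------
    (approx, detail) : pair of ndarray
        Equal-length low-band and high-band coefficient series. Under
        symmetric padding both have length floor((N + taps - 1) / 2).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_level expects a 1-D signal")
    if x.size < fb.taps:
        raise ValueError(
            f"signal of length {x.size} is shorter than the {fb.taps}-tap "
            "filter; reduce the number of decomposition levels"
        )
    approx, detail = pywt.dwt(x, fb._pywt(), mode=mode)
    return approx, detail


def idwt_level(approx, detail, fb: FilterBank, out_len: int, mode: str = "symmetric"):
    """One synthesis level, trimmed to ``out_len`` samples.

    Inverse of :func:`dwt_level`: upsample, filter with the synthesis
    pair, and sum the branches. ``out_len`` disambiguates the one-sample
    length ambiguity of the downsampled representation.
    """
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape:
        raise ValueError(
            f"approx and detail lengths differ: {approx.size} vs {detail.size}"
        )
    rec = pywt.idwt(approx, detail, fb._pywt(), mode=mode)
    if out_len > rec.size or out_len < rec.size - 1:
        raise ValueError(
            f"out_len {out_len} inconsistent with coefficient length "
            f"{approx.size} (reconstruction yields {rec.size} samples)"
        )
    return rec[:out_len]


def decompose3(x, fb: FilterBank | None = None, levels: int = 3,
               fs: float = 250.0, mode: str = "symmetric") -> WaveletDecomposition:
    """Cascade :func:`dwt_level` on successive approximations.

    The level-1 split is applied to the signal, the level-2 split to A1,
    and so on; all intermediate approximations and details are kept.
    """
    fb = fb if fb is not None else filter_bank()
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    coeffs: dict[str, np.ndarray] = {}
    lens = []
    current = x
    for j in range(1, levels + 1):
        lens.append(current.size)
        try:
            approx, detail = dwt_level(current, fb, mode=mode)
        except ValueError as exc:
            raise ValueError(f"level {j}: {exc}") from None
        coeffs[f"A{j}"] = approx
        coeffs[f"D{j}"] = detail
        current = approx
    return WaveletDecomposition(
        levels=levels,
        coeffs=coeffs,
        fs=fs,
        orig_len=x.size,
        wavelet=fb.name,
        mode=mode,
        level_lens=tuple(lens),
    )


def reconstruct(dec: WaveletDecomposition, fb: FilterBank | None = None):
    """Invert :func:`decompose3` from {A_L, D_L, ..., D_1}."""
    fb = fb if fb is not None else filter_bank(dec.wavelet)
    current = dec.coeffs[f"A{dec.levels}"]
    for j in range(dec.levels, 0, -1):
        current = idwt_level(
            current, dec.coeffs[f"D{j}"], fb, dec.level_lens[j - 1], mode=dec.mode
        )
    return current


def band_edges(level: int, kind: str, fs: float) -> tuple[float, float]:
    """Nominal frequency band of a subband, in Hz.

    With Nyquist fN = fs/2: approximation level j covers (0, fN/2^j);
    detail level j covers (fN/2^j, fN/2^(j-1)). Bands are stated
    relative to the Nyquist frequency, the physically attainable range
    of a sampled signal.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if not (fs > 0):
        raise ValueError("fs must be positive")
    nyquist = fs / 2.0
    if kind == "approx":
        return (0.0, nyquist / 2**level)
    if kind == "detail":
        return (nyquist / 2**level, nyquist / 2 ** (level - 1))
    raise ValueError(f"kind must be 'approx' or 'detail', got {kind!r}")
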