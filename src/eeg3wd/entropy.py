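"""Approximate entropy, sample entropy, and per-channel feature extraction.

Both estimators embed the series x(1..N) into overlapping templates
u_m(i) = [x(i), ..., x(i+m-1)] and compare templates under the Chebyshev
(maximum-component) distance against a tolerance r.

ApEn (Pincus) averages, over all N-m+1 templates, the log of each
template's match *frequency* (self-matches included) and reports the
drop Phi^m(r) - Phi^(m+1)(r) when the template grows by one sample.

SampEn (Richman-Moorman) excludes self-matches and works with the first
N-m templates at both lengths: B counts matched pairs at length m, A at
length m+1, and SampEn = -ln(A/B). Lower values mean more regular
(self-similar) signals; a pure periodic signal gives 0.

The tolerance is conventionally a fraction of the analyzed series'
standard deviation (default r = 0.2 * SD, m = 2), which makes both
estimators invariant under affine amplitude transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eeg3wd.eeg_io import CANONICAL_CHANNELS, EEGRecording
from eeg3wd.wavelet import FilterBank, decompose3, filter_bank

#: Token an abstaining classifier emits in place of a class label.
BOUNDARY = "boundary"

# row-block size for the pairwise template comparison; bounds peak memory
# at roughly _BLOCK * N floats regardless of series length
_BLOCK = 512


class DegenerateToleranceError(ValueError):
    """Tolerance r is zero (e.g. SD-relative r on a constant series)."""


class UndefinedEntropyError(ValueError):
    """No template pairs matched, so the entropy ratio is undefined."""


class FeatureExtractionError(ValueError):
    """A channel produced no valid entropy feature; names the channel."""


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension m and SD-relative tolerance fraction.

    The effective tolerance is ``r_frac * SD(series)`` where SD is the
    population standard deviation of the series actually analyzed.
    """

    m: int = 2
    r_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not (self.r_frac > 0):
            raise ValueError("r_frac must be positive")


@dataclass
class FeatureVector:
    """Per-channel SampEn values of one subject, in canonical channel order."""

    subject_id: str
    values: np.ndarray
    label: int | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(CANONICAL_CHANNELS),):
            raise ValueError(
                f"expected {len(CANONICAL_CHANNELS)} feature values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must all be finite")


def cheb_dist(u, v) -> float:
    """Chebyshev distance max_k |u_k - v_k| between equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    # (N - m + 1, m) view of overlapping length-m templates
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _match_counts_with_self(emb: np.ndarray, r: float) -> np.ndarray:
    """Per-template counts of templates within r, self included."""
    n = emb.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, _BLOCK):
        block = emb[start:start + _BLOCK]
        d = np.abs(block[:, None, 0] - emb[None, :, 0])
        for k in range(1, emb.shape[1]):
            np.maximum(d, np.abs(block[:, None, k] - emb[None, :, k]), out=d)
        counts[start:start + _BLOCK] = (d <= r).sum(axis=1)
    return counts


def _pair_count(emb: np.ndarray, r: float) -> int:
    """Number of unordered template pairs (i < j) within distance r."""
    # counts include the self-match once per template; remove and halve
    counts = _match_counts_with_self(emb, r)
    return int((counts.sum() - emb.shape[0]) // 2)


def _check_series(x: np.ndarray, m: int) -> None:
    if x.ndim != 1:
        raise ValueError("entropy estimators expect a 1-D series")
    if x.size < m + 2:
        raise ValueError(
            f"series of length {x.size} too short for m={m} (need >= {m + 2})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")


def _resolve_r(x: np.ndarray, p: EntropyParams, r: float | None) -> float:
    if r is None:
        r = p.r_frac * float(np.std(x))
    if not (r > 0):
        raise DegenerateToleranceError(
            "tolerance r is not positive (constant series with SD-relative r?)"
        )
    return float(r)


def apen(x, p: EntropyParams = EntropyParams(), r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r, N) of a series.

    Phi^m(r) is the mean over templates of log(C_i^m(r)), where C_i^m is
    the fraction of templates (self included) within Chebyshev distance
    r of template i; ApEn = Phi^m - Phi^(m+1). Each template length
    normalizes by its own template count.
    """
    x = np.asarray(x, dtype=float)
    _check_series(x, p.m)
    r = _resolve_r(x, p, r)

    def phi(m: int) -> float:
        emb = _embed(x, m)
        counts = _match_counts_with_self(emb, r)
        return float(np.mean(np.log(counts / emb.shape[0])))

    return phi(p.m) - phi(p.m + 1)


def sampen(x, p: EntropyParams = EntropyParams(), r: float | None = None) -> float:
    """Sample entropy SampEn(m, r, N) of a series.

    B counts unordered pairs of length-m templates within r, A the same
    for length m+1; both range over the first N-m templates so the two
    template sets have equal size. Self-matches are excluded. Returns
    -ln(A/B), which is >= 0 whenever defined because every (m+1)-match
    is also an m-match.

    Raises
    ------
    UndefinedEntropyError
        If A or B is zero: the conditional probability is undefined and
        no finite value is returned.
    """
    x = np.asarray(x, dtype=float)
    _check_series(x, p.m)
    r = _resolve_r(x, p, r)
    n_templates = x.size - p.m
    emb_m = _embed(x, p.m)[:n_templates]
    emb_m1 = _embed(x, p.m + 1)
    b = _pair_count(emb_m, r)
    a = _pair_count(emb_m1, r)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            f"no template matches at tolerance r={r:.6g} (B={b}, A={a}); "
            "SampEn is undefined for this series"
        )
    return float(-np.log(a / b))


def extract_features(
    rec: EEGRecording,
    use_dwt: bool = True,
    fb: FilterBank | None = None,
    p: EntropyParams = EntropyParams(),
    approx_level: int = 3,
    levels: int = 3,
    mode: str = "symmetric",
) -> FeatureVector:
    """SampEn feature vector of a canonical 10-channel recording.

    Per channel: optionally decompose with the wavelet pyramid and keep
    the level-``approx_level`` approximation (the low-frequency band,
    which discards high-frequency noise), else analyze the raw channel;
    then compute SampEn with tolerance ``r_frac * SD`` of that analyzed
    series. Output order matches the canonical channel order.
    """
    if rec.channels != CANONICAL_CHANNELS:
        raise ValueError(
            "feature extraction requires the canonical 10-channel layout "
            f"{list(CANONICAL_CHANNELS)}"
        )
    if approx_level > levels:
        raise ValueError(
            f"approx_level {approx_level} exceeds decomposition levels {levels}"
        )
    fb = fb if fb is not None else filter_bank()
    values = np.empty(len(rec.channels))
    for i, name in enumerate(rec.channels):
        series = rec.data[i]
        if use_dwt:
            dec = decompose3(series, fb, levels=levels, fs=rec.fs, mode=mode)
            series = dec.approx(approx_level)
        try:
            values[i] = sampen(series, p)
        except (DegenerateToleranceError, UndefinedEntropyError, ValueError) as exc:
            raise FeatureExtractionError(
                f"channel {name}: {exc}"
            ) from exc
    return FeatureVector(subject_id=rec.subject_id, values=values, label=rec.label)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table: subject_id, F3..O2, label."""
    rows = [
        {"subject_id": f.subject_id,
         **dict(zip(CANONICAL_CHANNELS, f.values)),
         "label": f.label}
        for f in features
    ]
    return pd.DataFrame(rows, columns=["subject_id", *CANONICAL_CHANNELS, "label"])


def write_feature_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = ["subject_id", *CANONICAL_CHANNELS, "label"]
    if list(frame.columns) != expected:
        raise ValueError(
            f"feature table columns {list(frame.columns)} do not match "
            f"{expected}"
        )
    return frame
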