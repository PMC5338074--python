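"""Synthetic two-class EEG cohorts and feature-table fixtures.

The generator emulates the statistical structure the analysis pipeline
assumes rather than physiological detail: a broadband pink-noise
background (the 1/f character of resting EEG) mixed with narrowband
alpha (10 Hz) and beta (20 Hz) oscillations. The two classes differ
only in how much of the signal is oscillatory: the PD-like class gets a
larger oscillatory weight, making its channels more rhythmic and
regular and hence lower in sample entropy, while the normal-like class
stays broadband and irregular. Every channel is standardized to zero
mean and unit variance so amplitude carries no class information — only
regularity does, which is exactly the quantity SampEn measures.

All generators are deterministic given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eeg3wd.eeg_io import (
    CANONICAL_CHANNELS,
    EEGRecording,
    LABEL_NORMAL,
    LABEL_PD,
)

#: Oscillatory frequencies mixed into every channel, in Hz. Alpha and
#: beta rhythms, the dominant awake resting bands.
OSC_FREQS_HZ = (10.0, 20.0)

#: Baseline oscillatory weight shared by both classes. Sample entropy of
#: the low-frequency approximation band is non-monotonic in the mixing
#: weight: adding a mid-band tone to slow-drifting pink noise first
#: *raises* SampEn (large sample-to-sample increments, poor template
#: matching) and only past ~0.5 does extra oscillatory weight make the
#: series more regular. The baseline therefore sits at 0.5, the start of
#: the monotone-decreasing branch, so that any positive regularity gap
#: lowers the PD-like class's SampEn as intended.
BASE_OSC_WEIGHT = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    Defaults mirror the clinical recording format this pipeline targets:
    25 normal + 17 PD-like subjects, 10 channels at 250 Hz for 40 s
    (10000 samples per channel). ``regularity_gap`` is the extra
    oscillatory-power weight given to the PD-like class; at 0 the two
    classes are distributionally identical. ``noise_exponent`` is the
    spectral slope of the background (1 = pink noise).
    """

    n_normal: int = 25
    n_pd: int = 17
    fs: float = 250.0
    duration_s: float = 40.0
    regularity_gap: float = 0.4
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_pd < 0:
            raise ValueError("cohort sizes must be nonnegative")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"fs * duration_s must be a positive integer sample count, "
                f"got {n}"
            )
        if not (0 <= self.regularity_gap <= 1):
            raise ValueError("regularity_gap must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^exponent noise via frequency-domain amplitude shaping.

    White Gaussian noise is transformed to the frequency domain, its
    amplitudes scaled by f^(-exponent/2) (power slope -exponent), and
    transformed back. The DC bin keeps zero weight so the series is
    mean-free in expectation.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n)
    return shaped


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return x / sd


def synth_recording(cls: str, spec: CohortSpec, subject_seed: int,
                    subject_id: str | None = None) -> EEGRecording:
    """One synthetic 10-channel recording of class "normal" or "pd".

    Each channel mixes standardized pink noise with two random-phase
    sinusoids: ``(1 - w) * noise + w * (sin(2*pi*10*t + p1) +
    sin(2*pi*20*t + p2))`` with oscillatory weight ``w = 0.5`` for the
    normal class and ``w = 0.5 + 0.5 * regularity_gap`` for the PD-like
    class (see :data:`BASE_OSC_WEIGHT` for why the baseline sits at the
    start of the monotone branch); the mixed series is then
    standardized. Channels are independent; the recording is
    deterministic given ``(spec, subject_seed)``.
    """
    if cls not in ("normal", "pd"):
        raise ValueError(f"class must be 'normal' or 'pd', got {cls!r}")
    # pd weight spans the headroom above baseline: gap=1 -> pure tones
    w = BASE_OSC_WEIGHT
    if cls == "pd":
        w += (1.0 - BASE_OSC_WEIGHT) * spec.regularity_gap
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(np.random.SeedSequence(subject_seed))
    data = np.empty((len(CANONICAL_CHANNELS), n))
    for i in range(len(CANONICAL_CHANNELS)):
        noise = _standardize(pink_noise(n, spec.noise_exponent, rng))
        osc = np.zeros(n)
        for f in OSC_FREQS_HZ:
            phase = rng.uniform(0, 2 * np.pi)
            osc += np.sin(2 * np.pi * f * t + phase)
        data[i] = _standardize((1.0 - w) * noise + w * osc)
    return EEGRecording(
        subject_id=subject_id or f"{cls}-{subject_seed}",
        label=LABEL_PD if cls == "pd" else LABEL_NORMAL,
        fs=spec.fs,
        channels=CANONICAL_CHANNELS,
        data=data,
        canonical=True,
    )


def subject_seeds(spec: CohortSpec) -> list[int]:
    """Per-subject integer seeds derived deterministically from the spec."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_normal + spec.n_pd)
    return [int(c.generate_state(1, dtype=np.uint32)[0]) for c in children]


def synth_cohort(spec: CohortSpec) -> tuple[list[EEGRecording], np.ndarray]:
    """Full synthetic cohort: normal subjects first, then PD-like.

    Returns the recordings and a matching 0/1 label vector. Distinct
    subjects get distinct seeds spawned from ``spec.seed``, so the
    cohort is reproducible yet subjects are independent.
    """
    seeds = subject_seeds(spec)
    recordings: list[EEGRecording] = []
    labels = []
    for i in range(spec.n_normal):
        recordings.append(
            synth_recording("normal", spec, seeds[i], subject_id=f"N{i + 1:02d}")
        )
        labels.append(LABEL_NORMAL)
    for i in range(spec.n_pd):
        recordings.append(
            synth_recording(
                "pd", spec, seeds[spec.n_normal + i], subject_id=f"P{i + 1:02d}"
            )
        )
        labels.append(LABEL_PD)
    return recordings, np.array(labels, dtype=int)


def synth_feature_table(n_per_class: int, dim: int, separation: float,
                        seed: int) -> pd.DataFrame:
    """Two spherical Gaussian clusters as a labelled feature table.

    Cluster centers are ``separation`` apart (Euclidean, in units of the
    within-class standard deviation, which is 1). Columns are f1..f<dim>
    plus ``label``; class 0 rows come first. Intended as a controllable
    fixture for the covering classifier.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    offset = np.full(dim, separation / np.sqrt(dim))
    x0 = rng.standard_normal((n_per_class, dim))
    x1 = rng.standard_normal((n_per_class, dim)) + offset
    table = pd.DataFrame(
        np.vstack([x0, x1]), columns=[f"f{i + 1}" for i in range(dim)]
    )
    table["label"] = np.repeat([0, 1], n_per_class)
    return table
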