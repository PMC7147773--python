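"""Vestibular stimulus construction and psychophysical threshold procedures.

Three current waveforms are used in subthreshold stochastic vestibular
stimulation (SVS) experiments:

* the SVS stimulus itself — zero-mean, Gaussian-distributed white noise
  band-limited to 0–30 Hz;
* a sham control — a 1 s linear ramp up to the matched intensity followed by
  a 1 s ramp back to zero (perceptually similar onset, no sustained current);
* a 1 Hz sinusoidal probe used to find each participant's vestibular motion
  threshold.

Stimulation intensity is individualized by one of two threshold techniques:
the *sinusoidal* technique presents 10 s sinusoidal probes at a randomized,
fixed list of peak amplitudes and takes the lowest perceived level, scaled by
50%; the *cutaneous* technique ramps the stochastic stimulus up from 50 µA in
25 µA increments until a skin sensation is reported (lowest level over two
repeats), scaled by 80%.

All currents are in microamperes (µA); rates in samples per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import DegenerateVarianceError, InvalidArgumentError, ThresholdNotFoundError

#: Peak-amplitude list (µA) for the sinusoidal motion-threshold procedure.
#: 50 µA steps up to 1000 µA, then 100 µA steps (thresholds above 1000 µA are rare).
SINUSOIDAL_LEVELS_UA: tuple[float, ...] = tuple(
    float(x) for x in list(range(50, 1001, 50)) + [1100, 1200]
)

#: Familiarization pulse shown once before the sinusoidal procedure (µA). It is
#: not part of threshold classification.
FAMILIARIZATION_PEAK_UA = 1500.0

#: Band edge of the stochastic stimulus (Hz).
SVS_BAND_HZ = 30.0

#: Default stimulus duration (s) for SVS, sham and sinusoidal probes.
DEFAULT_DURATION_S = 10.0

SINUSOIDAL_FRACTION = 0.5
CUTANEOUS_FRACTION = 0.8


@dataclass(frozen=True)
class StimulusWaveform:
    """A current-vs-time signal.

    Attributes
    ----------
    samples : np.ndarray
        Current in µA per sample.
    rate : float
        Samples per second.
    kind : str
        One of ``{"svs", "sham", "sinusoidal"}``.
    nominal_amplitude : float
        The amplitude (µA) the waveform was constructed for; peak convention.
    seed : int | None
        RNG seed for stochastic kinds; ``None`` for deterministic kinds.
    """

    samples: np.ndarray
    rate: float
    kind: str
    nominal_amplitude: float
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def to_csv(self, path) -> None:
        """Write a two-column CSV ``time_s,current_uA`` with a one-line header."""
        arr = np.column_stack([self.times, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,current_uA", comments="")


@dataclass(frozen=True)
class ThresholdProfile:
    """Per-participant thresholds and the stimulation amplitudes derived from them."""

    participant_id: int
    sinusoidal_threshold: float
    cutaneous_threshold: float
    sinusoidal_amplitude: float = field(default=0.0)
    cutaneous_amplitude: float = field(default=0.0)

    def __post_init__(self):
        if self.sinusoidal_threshold <= 0 or self.cutaneous_threshold <= 0:
            raise InvalidArgumentError("thresholds must be positive")
        if self.sinusoidal_amplitude == 0.0:
            object.__setattr__(
                self,
                "sinusoidal_amplitude",
                scale_amplitude(self.sinusoidal_threshold, SINUSOIDAL_FRACTION),
            )
        if self.cutaneous_amplitude == 0.0:
            object.__setattr__(
                self,
                "cutaneous_amplitude",
                scale_amplitude(self.cutaneous_threshold, CUTANEOUS_FRACTION),
            )


@dataclass(frozen=True)
class PerceptualObserver:
    """Stand-in for the human participant during simulated threshold runs.

    With ``response_noise_sd == 0`` the observer is a deterministic step: a
    probe is perceived iff its amplitude reaches the latent threshold. A
    positive value gives a logistic psychometric function with that scale.
    """

    motion_latent_threshold: float
    cutaneous_latent_threshold: float
    response_noise_sd: float = 0.0

    def perceives_motion(self, level: float, rng: np.random.Generator | None = None) -> bool:
        return self._perceives(level, self.motion_latent_threshold, rng)

    def perceives_cutaneous(self, level: float, rng: np.random.Generator | None = None) -> bool:
        return self._perceives(level, self.cutaneous_latent_threshold, rng)

    def _perceives(self, level, latent, rng):
        if self.response_noise_sd <= 0:
            return level >= latent
        if rng is None:
            rng = np.random.default_rng()
        p = special.expit((level - latent) / self.response_noise_sd)
        return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------


def _check_rate_duration(rate: float, duration: float) -> int:
    if duration <= 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration}")
    if rate <= 0:
        raise InvalidArgumentError(f"rate must be positive, got {rate}")
    return int(round(rate * duration))


def generate_svs_waveform(
    amplitude: float,
    duration: float = DEFAULT_DURATION_S,
    rate: float = 1000.0,
    seed: int | None = None,
    band_hz: float = SVS_BAND_HZ,
    scaling: str = "peak",
) -> StimulusWaveform:
    """Zero-mean Gaussian white noise band-limited to 0–``band_hz`` Hz.

    White Gaussian samples are low-passed with an ideal (frequency-domain)
    cutoff at ``band_hz``, re-zeroed in mean, and rescaled.  ``scaling="peak"``
    (default) makes ``max |sample|`` equal ``amplitude``, matching the peak
    convention of the sinusoidal probe; ``scaling="sd"`` makes the sample
    standard deviation equal ``amplitude``.
    """
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be non-negative")
    if rate < 4 * band_hz:
        raise InvalidArgumentError(
            f"rate {rate} too low to resolve the {band_hz} Hz band with margin"
        )
    if scaling not in ("peak", "sd"):
        raise InvalidArgumentError(f"unknown scaling {scaling!r}")
    n = _check_rate_duration(rate, duration)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[freqs > band_hz] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    if amplitude == 0:
        x = np.zeros(n)
    else:
        norm = np.max(np.abs(x)) if scaling == "peak" else x.std()
        x = x * (amplitude / norm)
    return StimulusWaveform(x, rate, "svs", amplitude, seed)


def generate_sham_waveform(
    amplitude: float, duration: float = DEFAULT_DURATION_S, rate: float = 1000.0
) -> StimulusWaveform:
    """Linear 1 s ramp up to ``amplitude``, linear 1 s ramp down, zero thereafter."""
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be non-negative")
    if duration < 2.0:
        raise InvalidArgumentError("sham waveform needs at least 2 s for the ramps")
    n = _check_rate_duration(rate, duration)
    t = np.arange(n) / rate
    x = amplitude * np.interp(t, [0.0, 1.0, 2.0], [0.0, 1.0, 0.0], right=0.0)
    # Grid ends one sample before the down-ramp's zero when duration == 2 s;
    # the waveform ends at zero by contract.
    x[-1] = 0.0
    return StimulusWaveform(x, rate, "sham", amplitude)


def generate_sinusoidal_probe(
    peak: float,
    duration: float = DEFAULT_DURATION_S,
    frequency: float = 1.0,
    rate: float = 1000.0,
) -> StimulusWaveform:
    """``peak × sin(2π·frequency·t)`` — the motion-threshold probe."""
    if peak < 0:
        raise InvalidArgumentError("peak must be non-negative")
    n = _check_rate_duration(rate, duration)
    t = np.arange(n) / rate
    x = peak * np.sin(2 * math.pi * frequency * t)
    return StimulusWaveform(x, rate, "sinusoidal", peak)


# ---------------------------------------------------------------------------
# Threshold procedures
# ---------------------------------------------------------------------------


def run_sinusoidal_threshold(
    observer: PerceptualObserver,
    levels=SINUSOIDAL_LEVELS_UA,
    seed: int | None = None,
) -> float:
    """Randomized-order presentation of every level; lowest perceived level wins.

    Raises :class:`ThresholdNotFoundError` if no level is perceived (latent
    threshold above the top of the list).
    """
    levels = list(levels)
    if not levels:
        raise InvalidArgumentError("level list must be non-empty")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise InvalidArgumentError("level list must be strictly increasing")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(levels))
    perceived = [levels[i] for i in order if observer.perceives_motion(levels[i], rng)]
    if not perceived:
        raise ThresholdNotFoundError(
            f"no motion perceived up to {levels[-1]} µA"
        )
    return float(min(perceived))


def run_cutaneous_threshold(
    observer: PerceptualObserver,
    start: float = 50.0,
    step: float = 25.0,
    repeats: int = 2,
    seed: int | None = None,
    ceiling: float = 2000.0,
) -> float:
    """Ascending staircase from ``start`` in ``step`` increments, lowest over repeats."""
    if start <= 0 or step <= 0:
        raise InvalidArgumentError("start and step must be positive")
    if repeats < 1:
        raise InvalidArgumentError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    found = []
    for _ in range(repeats):
        level = start
        while not observer.perceives_cutaneous(level, rng):
            level += step
            if level > ceiling:
                raise ThresholdNotFoundError(
                    f"no cutaneous sensation up to the {ceiling} µA ceiling"
                )
        found.append(level)
    return float(min(found))


def scale_amplitude(threshold: float, fraction: float) -> float:
    """Stimulation amplitude as a fraction of a perceptual threshold."""
    if threshold < 0:
        raise InvalidArgumentError("threshold must be non-negative")
    if not 0 < fraction <= 1:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    return threshold * fraction


def compare_techniques(profiles) -> tuple[float, int, float]:
    """Two-tailed paired t test of cutaneous − sinusoidal stimulation amplitudes.

    Returns ``(t, df, p)`` with ``df = n − 1``.  The sign convention
    (cutaneous minus sinusoidal) makes the statistic negative when the
    sinusoidal technique yields the larger amplitudes.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InvalidArgumentError("need at least 2 profiles for a paired test")
    cut = np.array([p.cutaneous_amplitude for p in profiles], dtype=float)
    sin = np.array([p.sinusoidal_amplitude for p in profiles], dtype=float)
    diffs = cut - sin
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateVarianceError("paired differences have zero variance")
    res = stats.ttest_rel(cut, sin)
    return float(res.statistic), len(profiles) - 1, float(res.pvalue)


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Paired t test of ``x − y`` (thin wrapper, same conventions as above)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if len(d) < 2:
        raise InvalidArgumentError("need at least 2 pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateVarianceError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(d) - 1, float(res.pvalue)
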