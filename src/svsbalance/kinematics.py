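"""Balance and gait measures from 3-D marker trajectories.

The pipeline turns 120 Hz marker positions into five outcome measures:

* medial-lateral (ML) and anterior-posterior (AP) trunk velocity RMS from the
  chest marker — a sway/stability index;
* minimum distance of the trunk (chest marker, a centre-of-mass proxy) to the
  edge of the base of support, standing trials only (AP edge: right toe
  marker; ML edge: right fifth-metatarsal marker);
* gait speed over a fixed central distance, walking trials only;
* step widths and step-width variability from mid-foot marker ML positions at
  foot contact, walking trials only.

Foot contact is defined as a local minimum of the mid-foot marker's vertical
velocity. All velocity-based measures share one fixed preprocessing order:
fill marker gaps → zero-phase low-pass filter positions → differentiate.

Coordinate convention: X = anterior-posterior (+ forward), Y = vertical
(+ up), Z = medial-lateral (+ to the participant's right); positions in
meters, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDistanceError,
    InsufficientStepsError,
    InvalidArgumentError,
    InvalidTaskError,
    SequenceError,
    TrialRejectedError,
)

MARKER_NAMES = (
    "head",
    "chest",
    "heel_L",
    "heel_R",
    "midfoot_L",
    "midfoot_R",
    "fifthmet_L",
    "fifthmet_R",
    "toe_L",
    "toe_R",
)

AXIS_INDEX = {"AP": 0, "UP": 1, "ML": 2}

#: Fixed preprocessing order applied before every velocity-based measure.
PIPELINE_STAGES = ("fill_gaps", "lowpass_filter", "differentiate", "measure")


@dataclass
class MeasurementParams:
    """Tunable measurement parameters (defaults follow the standard protocol)."""

    cutoff_hz: float = 6.0
    filter_order: int = 4
    contact_prominence: float = 0.05  # m/s, minimum vertical-velocity dip
    contact_min_separation_s: float = 0.4  # same-foot refractory period
    walkway_midpoint_m: float = 3.0
    gait_distance_m: float = 3.0
    max_gap_s: float = 0.1


@dataclass
class MarkerTrial:
    """One recorded trial: marker positions over time plus condition metadata."""

    participant_id: int
    task: str  # {"standing", "walking"}
    balance: str  # {"unchallenged", "challenged"}
    stimulation: str  # {"svs", "sham"}
    technique: str  # {"sinusoidal", "cutaneous"}
    trial_index: int
    rate: float
    markers: dict  # name -> (n_frames, 3) array, columns (AP, UP, ML)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def positions(self, marker: str, axis: str) -> np.ndarray:
        return self.markers[marker][:, AXIS_INDEX[axis]]

    def validate(self) -> None:
        if self.rate <= 0:
            raise TrialRejectedError("rate must be positive")
        n = self.n_frames
        if n < 2:
            raise TrialRejectedError("trial needs at least 2 frames")
        for name in MARKER_NAMES:
            if name not in self.markers:
                raise TrialRejectedError(f"missing marker {name}")
            arr = self.markers[name]
            if arr.shape != (n, 3):
                raise TrialRejectedError(f"marker {name} has shape {arr.shape}")
            if np.isnan(arr).any():
                raise TrialRejectedError(f"marker {name} has unfilled gaps")
        if self.task == "standing" and abs(self.duration - 5.0) > 2.0 / self.rate:
            raise TrialRejectedError(
                f"standing trial spans {self.duration:.3f} s, expected 5 s"
            )

    def metadata(self) -> dict:
        return {
            "participant": self.participant_id,
            "task": self.task,
            "balance": self.balance,
            "stimulation": self.stimulation,
            "technique": self.technique,
            "trial": self.trial_index,
        }


@dataclass(frozen=True)
class FootContact:
    """A detected foot-contact event."""

    frame_index: int
    time: float
    side: str  # {"left", "right"}
    ap_position: float | None = None  # mid-foot AP position at contact (m)


@dataclass
class TrialMeasures:
    """Per-trial outcome measures; walking-only fields are None for standing."""

    ml_trunk_velocity_rms: float
    ap_trunk_velocity_rms: float
    min_dist_com_ml_bos: float | None = None
    min_dist_com_ap_bos: float | None = None
    gait_speed: float | None = None
    step_widths: list | None = None
    step_width_sd: float | None = None
    audit: tuple = field(default=PIPELINE_STAGES)

    def to_dict(self) -> dict:
        d = {
            "ml_trunk_velocity_rms": self.ml_trunk_velocity_rms,
            "ap_trunk_velocity_rms": self.ap_trunk_velocity_rms,
            "min_dist_com_ml_bos": self.min_dist_com_ml_bos,
            "min_dist_com_ap_bos": self.min_dist_com_ap_bos,
            "gait_speed": self.gait_speed,
            "step_width_sd": self.step_width_sd,
        }
        if self.step_widths is not None:
            for i, w in enumerate(self.step_widths, 1):
                d[f"step_width_{i}"] = w
        return d


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------


def lowpass_filter(series, rate: float, cutoff: float = 6.0, order: int = 4):
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward as a pair of second-order
    passes so the net magnitude response is of order ``order`` with zero
    phase; the per-pass cutoff is pre-warped by the standard dual-pass
    correction ``(2**(1/2) - 1) ** (1/(2*order_per_pass))`` so the *net*
    −3 dB point sits at ``cutoff``.
    """
    series = np.asarray(series, dtype=float)
    if rate <= 2 * cutoff:
        raise InvalidArgumentError("rate must exceed twice the cutoff")
    if order < 2 or order % 2:
        raise InvalidArgumentError("order must be an even integer >= 2")
    if series.shape[0] < 3 * order:
        raise InvalidArgumentError(
            f"series too short ({series.shape[0]} samples) for order-{order} filtering"
        )
    per_pass = order // 2
    correction = (2 ** (1 / 2) - 1) ** (1 / (2 * per_pass))
    wn = (cutoff / correction) / (rate / 2)
    sos = signal.butter(per_pass, wn, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def differentiate(positions, rate: float):
    """Central-difference velocities (one-sided at the endpoints)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 frames to differentiate")
    return np.gradient(positions, 1.0 / rate, axis=0)


def fill_gaps(trial: MarkerTrial, max_gap_s: float = 0.1) -> MarkerTrial:
    """Linearly interpolate NaN runs up to ``max_gap_s``; longer runs reject the trial."""
    max_run = int(round(max_gap_s * trial.rate))
    filled = {}
    n = trial.n_frames
    idx = np.arange(n)
    for name, arr in trial.markers.items():
        out = arr.astype(float).copy()
        for col in range(3):
            x = out[:, col]
            bad = np.isnan(x)
            if not bad.any():
                continue
            if bad[0] or bad[-1]:
                raise TrialRejectedError(f"marker {name}: gap at trial boundary")
            # longest NaN run
            runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0])))))
            if runs[::2].max() > max_run:
                raise TrialRejectedError(
                    f"marker {name}: gap longer than {max_gap_s} s"
                )
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
        filled[name] = out
    return replace(trial, markers=filled)


def _velocity(trial, marker, axis, params):
    pos = lowpass_filter(
        trial.positions(marker, axis), trial.rate, params.cutoff_hz, params.filter_order
    )
    return differentiate(pos, trial.rate)


# ---------------------------------------------------------------------------
# Outcome measures
# ---------------------------------------------------------------------------


def trunk_velocity_rms(
    trial: MarkerTrial,
    axis: str,
    window: tuple | None = None,
    params: MeasurementParams | None = None,
) -> float:
    """RMS of filtered chest-marker velocity on ``axis`` over ``window`` frames."""
    params = params or MeasurementParams()
    if axis not in ("ML", "AP"):
        raise InvalidArgumentError(f"axis must be 'ML' or 'AP', got {axis!r}")
    v = _velocity(trial, "chest", axis, params)
    if window is None:
        window = (0, trial.n_frames)
    lo, hi = window
    seg = v[lo:hi]
    if seg.size == 0:
        raise InvalidArgumentError("empty window")
    return float(np.sqrt(np.mean(seg**2)))


def min_com_bos_distance(
    trial: MarkerTrial, axis: str, params: MeasurementParams | None = None
) -> float:
    """Minimum |base-of-support edge − chest| distance on ``axis`` (standing only).

    The AP edge is the right toe marker; the ML edge is the right
    fifth-metatarsal marker.
    """
    params = params or MeasurementParams()
    if trial.task != "standing":
        raise InvalidTaskError("base-of-support distance is a standing measure")
    ref = {"AP": "toe_R", "ML": "fifthmet_R"}
    if axis not in ref:
        raise InvalidArgumentError(f"axis must be 'ML' or 'AP', got {axis!r}")
    chest = lowpass_filter(
        trial.positions("chest", axis), trial.rate, params.cutoff_hz, params.filter_order
    )
    edge = lowpass_filter(
        trial.positions(ref[axis], axis), trial.rate, params.cutoff_hz, params.filter_order
    )
    return float(np.min(np.abs(edge - chest)))


def detect_foot_contacts(
    trial: MarkerTrial, side: str, params: MeasurementParams | None = None
) -> list:
    """Foot contacts as local minima of the mid-foot vertical velocity.

    Minima must exceed ``contact_prominence`` (m/s) and be separated by at
    least ``contact_min_separation_s`` for the same foot.
    """
    params = params or MeasurementParams()
    if side not in ("left", "right"):
        raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")
    marker = "midfoot_L" if side == "left" else "midfoot_R"
    vy = _velocity(trial, marker, "UP", params)
    distance = max(1, int(round(params.contact_min_separation_s * trial.rate)))
    idx, _ = signal.find_peaks(-vy, prominence=params.contact_prominence, distance=distance)
    ap = lowpass_filter(
        trial.positions(marker, "AP"), trial.rate, params.cutoff_hz, params.filter_order
    )
    return [
        FootContact(int(i), i / trial.rate, side, float(ap[i])) for i in idx
    ]


def _merge_contacts(contacts_left, contacts_right):
    merged = sorted(
        list(contacts_left) + list(contacts_right), key=lambda c: c.frame_index
    )
    for a, b in zip(merged, merged[1:]):
        if a.side == b.side:
            raise SequenceError(
                f"consecutive contacts on the same side at frames "
                f"{a.frame_index} and {b.frame_index}"
            )
    return merged


def select_stride_window(
    contacts_left, contacts_right, walkway_midpoint: float = 3.0
) -> list:
    """Four consecutive alternating contacts centred on the walkway midpoint.

    Picks the window whose mean contacting-foot AP position is closest to
    ``walkway_midpoint``, avoiding gait initiation and termination.
    """
    merged = _merge_contacts(contacts_left, contacts_right)
    if len(merged) < 4:
        raise InsufficientStepsError(
            f"need >= 4 foot contacts, found {len(merged)}"
        )
    centers = [
        np.mean([c.ap_position for c in merged[i : i + 4]])
        for i in range(len(merged) - 3)
    ]
    best = int(np.argmin(np.abs(np.asarray(centers) - walkway_midpoint)))
    return merged[best : best + 4]


def step_widths(
    trial: MarkerTrial, window, params: MeasurementParams | None = None
) -> list:
    """Three step widths from four alternating contacts.

    Width i is the |ML| distance between the leading foot's mid-foot marker at
    its contact and the trailing foot's mid-foot marker at its own preceding
    contact.
    """
    params = params or MeasurementParams()
    window = list(window)
    if len(window) != 4:
        raise SequenceError(f"stride window must hold 4 contacts, got {len(window)}")
    for a, b in zip(window, window[1:]):
        if a.side == b.side or b.frame_index <= a.frame_index:
            raise SequenceError("stride window must alternate sides in time order")
    ml = {
        side: lowpass_filter(
            trial.positions(marker, "ML"), trial.rate, params.cutoff_hz, params.filter_order
        )
        for side, marker in (("left", "midfoot_L"), ("right", "midfoot_R"))
    }
    widths = []
    for trail, lead in zip(window, window[1:]):
        widths.append(
            float(abs(ml[lead.side][lead.frame_index] - ml[trail.side][trail.frame_index]))
        )
    return widths


def step_width_variability(widths) -> float:
    """Sample standard deviation (n − 1) of three consecutive step widths."""
    widths = np.asarray(widths, dtype=float)
    if widths.shape != (3,):
        raise InvalidArgumentError(f"expected exactly 3 widths, got {widths.shape}")
    return float(np.std(widths, ddof=1))


def gait_speed(
    trial: MarkerTrial,
    distance: float = 3.0,
    params: MeasurementParams | None = None,
) -> float:
    """Speed over the central ``distance`` of the chest marker's AP excursion.

    Crossing times of the window edges are linearly interpolated between
    frames.
    """
    params = params or MeasurementParams()
    x = lowpass_filter(
        trial.positions("chest", "AP"), trial.rate, params.cutoff_hz, params.filter_order
    )
    lo_x, hi_x = float(np.min(x)), float(np.max(x))
    if hi_x - lo_x < distance:
        raise InsufficientDistanceError(
            f"chest AP excursion {hi_x - lo_x:.3f} m < required {distance} m"
        )
    if x[-1] < x[0]:  # walking in the -AP direction
        x = -x
        lo_x, hi_x = -hi_x, -lo_x
    center = 0.5 * (lo_x + hi_x)
    t_enter = _crossing_time(x, center - distance / 2, trial.rate)
    t_exit = _crossing_time(x, center + distance / 2, trial.rate)
    return float(distance / (t_exit - t_enter))


def _crossing_time(x, level, rate):
    above = np.flatnonzero(x >= level)
    k = int(above[0])
    if k == 0:
        return 0.0
    frac = (level - x[k - 1]) / (x[k] - x[k - 1])
    return (k - 1 + frac) / rate


def measure_trial(
    trial: MarkerTrial, params: MeasurementParams | None = None
) -> TrialMeasures:
    """All outcome measures for one trial.

    Standing: trunk velocity RMS (ML, AP) over the whole trial plus both
    base-of-support distances. Walking: trunk velocity RMS over the central
    four-contact stride window, gait speed, step widths, and step-width
    variability.
    """
    params = params or MeasurementParams()
    trial = fill_gaps(trial, params.max_gap_s)
    trial.validate()
    if trial.task == "standing":
        return TrialMeasures(
            ml_trunk_velocity_rms=trunk_velocity_rms(trial, "ML", params=params),
            ap_trunk_velocity_rms=trunk_velocity_rms(trial, "AP", params=params),
            min_dist_com_ml_bos=min_com_bos_distance(trial, "ML", params),
            min_dist_com_ap_bos=min_com_bos_distance(trial, "AP", params),
        )
    if trial.task != "walking":
        raise InvalidTaskError(f"unknown task {trial.task!r}")
    left = detect_foot_contacts(trial, "left", params)
    right = detect_foot_contacts(trial, "right", params)
    window = select_stride_window(left, right, params.walkway_midpoint_m)
    frames = (window[0].frame_index, window[-1].frame_index + 1)
    widths = step_widths(trial, window, params)
    return TrialMeasures(
        ml_trunk_velocity_rms=trunk_velocity_rms(trial, "ML", frames, params),
        ap_trunk_velocity_rms=trunk_velocity_rms(trial, "AP", frames, params),
        gait_speed=gait_speed(trial, params.gait_distance_m, params),
        step_widths=widths,
        step_width_sd=step_width_variability(widths),
    )
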