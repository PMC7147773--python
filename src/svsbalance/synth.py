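"""Synthetic marker-trajectory cohorts with known ground truth.

The generator emulates a 13-participant crossed design: 2 tasks (standing,
walking) × 2 balance conditions (unchallenged, challenged by compliant
hemispheres under the shoes) × 2 stimulation conditions (SVS, sham) × 2
threshold techniques (sinusoidal, cutaneous), 5 trials per cell.

Standing trunk sway is a stationary first-order autoregressive (discretized
Ornstein–Uhlenbeck) *velocity* process with correlation time ``sway_tau_s``,
so the stationary velocity RMS — the pipeline's headline measure — has a
closed form equal to the cell's target. Walking is built from per-step foot
placements with raised-cosine swing arcs; each swing's vertical-velocity
profile has a single unambiguous local minimum (at 75% of swing), which the
generator records as the ground-truth contact instant — the same operational
event definition the measurement pipeline uses.

Condition effects enter as multiplicative factors on the cell targets
(see :class:`CohortSpec`); participants get a multiplicative log-normal
random factor so a random-intercept ANOVA is meaningful. Ground truth is
emitted alongside every trial and is never read by the measurement pipeline.

The swing arc uses a ``sin⁴`` vertical profile: it is twice continuously
differentiable at the stance boundaries (no filter ringing that could mimic
a contact) and its vertical velocity has a single smooth minimum at 2/3 of
swing — the ground-truth contact instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InvalidArgumentError
from .kinematics import MarkerTrial
from .stimulus import SINUSOIDAL_LEVELS_UA, ThresholdProfile

STANDING_CELLS = [
    ("standing", b, s, t)
    for b in ("unchallenged", "challenged")
    for s in ("svs", "sham")
    for t in ("sinusoidal", "cutaneous")
]
WALKING_CELLS = [
    ("walking", b, s, t)
    for b in ("unchallenged", "challenged")
    for s in ("svs", "sham")
    for t in ("sinusoidal", "cutaneous")
]
ALL_CELLS = STANDING_CELLS + WALKING_CELLS


@dataclass
class CohortSpec:
    """Design and effect parameters of a synthetic cohort.

    The default effect multipliers encode the experimental effects the
    generator is built to reproduce: SVS reduces challenged-standing ML trunk
    velocity RMS by 24% (× 0.76); the balance challenge raises standing AP
    trunk velocity RMS 232% (× 3.32); walking with challenged balance raises
    ML trunk RMS 30% (× 1.30), lowers AP oscillation slightly (× 0.92) and
    raises step-width variability 31% (× 1.31); SVS while walking raises gait
    speed 3% (× 1.03) and lowers step-width variability 11% (× 0.89) in both
    balance conditions. The challenged-walking speed factor (× 0.85) and the
    challenged-standing ML factor (× 2.5) are generator choices, not
    empirical values — only their directions are empirically anchored.
    """

    n_participants: int = 13
    trials_per_cell: int = 5
    seed: int = 0
    rate: float = 120.0

    # --- standing sway (stationary velocity RMS baselines, m/s) ---
    standing_ml_rms: float = 0.015
    standing_ap_rms: float = 0.020
    sway_tau_s: float = 1.0
    standing_duration_s: float = 5.0

    # --- walking gait ---
    gait_speed: float = 1.3  # m/s baseline
    step_length: float = 0.70  # m
    n_steps: int = 10
    swing_fraction: float = 0.8  # swing time / step time
    step_height: float = 0.05  # m, swing arc height
    mean_step_width: float = 0.10  # m
    step_width_sd: float = 0.015  # m, SD across steps
    chest_ml_osc: float = 0.02  # m, lateral trunk oscillation amplitude
    chest_ap_osc_frac: float = 0.05  # within-stride speed oscillation fraction
    chest_bounce: float = 0.01  # m, vertical bounce amplitude
    walking_ml_sway_rms: float = 0.012  # m/s, OU sway added to chest ML
    walking_ap_sway_rms: float = 0.010  # m/s, OU sway around the speed trend

    # --- condition effect multipliers ---
    challenged_standing_ml: float = 2.5  # placeholder magnitude (direction only)
    challenged_standing_ap: float = 3.32  # +232%
    svs_standing_ml_challenged: float = 0.76  # -24%, challenged cells only
    challenged_walking_ml: float = 1.30  # +30%
    challenged_walking_ap: float = 0.92  # -8% (oscillatory component)
    challenged_step_width_sd: float = 1.31  # +31%
    challenged_gait_speed: float = 0.85  # placeholder magnitude (direction only)
    svs_gait_speed: float = 1.03  # +3%, both balance conditions
    svs_step_width_sd: float = 0.89  # -11%, both balance conditions

    # --- participant/trial stochastics ---
    participant_factor_sd: float = 0.15  # log-normal sigma
    marker_noise_rms: float = 0.00015  # m, additive white positional noise
    threshold_sinusoidal_mean: float = 608.0  # µA
    threshold_sinusoidal_sd: float = 162.0
    threshold_cutaneous_mean: float = 312.0
    threshold_cutaneous_sd: float = 104.0

    # --- geometry (m) ---
    foot_half_separation: float = 0.06  # standing, unchallenged
    foot_half_separation_challenged: float = 0.11  # ~10 cm wider stance
    chest_height: float = 1.40
    head_offset: float = 0.30

    # --- trial-to-trial dispersion of the measures (measure-level mode) ---
    trial_cv_rms: float = 0.45
    trial_cv_speed: float = 0.06
    trial_cv_step_width_sd: float = 0.52

    def standing_sway_targets(self, balance: str, stimulation: str) -> dict:
        """Target stationary velocity RMS (m/s) per axis for a standing cell."""
        ml, ap = self.standing_ml_rms, self.standing_ap_rms
        if balance == "challenged":
            ml *= self.challenged_standing_ml
            ap *= self.challenged_standing_ap
            if stimulation == "svs":
                ml *= self.svs_standing_ml_challenged
        return {"ML": ml, "AP": ap}

    def walking_targets(self, balance: str, stimulation: str) -> dict:
        """Target gait parameters for a walking cell."""
        speed = self.gait_speed
        sw_sd = self.step_width_sd
        ml_mult = 1.0
        ap_mult = 1.0
        if balance == "challenged":
            speed *= self.challenged_gait_speed
            sw_sd *= self.challenged_step_width_sd
            ml_mult = self.challenged_walking_ml
            ap_mult = self.challenged_walking_ap
        if stimulation == "svs":
            speed *= self.svs_gait_speed
            sw_sd *= self.svs_step_width_sd
        # Lateral oscillation velocity scales with amplitude × cadence; divide
        # the amplitude by the cell's speed factor so the injected ML
        # multiplier acts on trunk ML *velocity*, the measured quantity.
        ml_amp = self.chest_ml_osc * ml_mult / (speed / self.gait_speed)
        return {
            "speed": speed,
            "step_width_sd": sw_sd,
            "ml_mult": ml_mult,
            "ap_mult": ap_mult,
            "ml_amp": ml_amp,
        }


@dataclass
class GroundTruth:
    """Per-trial truth emitted alongside each generated trial (never read by the pipeline)."""

    contact_times: list = field(default_factory=list)  # (time_s, side)
    step_widths: list = field(default_factory=list)  # m, per consecutive step pair
    chest_speed: float | None = None  # m/s, constant forward speed component
    sway_rms: dict = field(default_factory=dict)  # axis -> stationary velocity RMS


# ---------------------------------------------------------------------------
# Primitive processes
# ---------------------------------------------------------------------------


def ou_velocity(n: int, dt: float, rms: float, tau: float, rng) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein–Uhlenbeck) velocity series.

    ``v[k] = a v[k-1] + rms * sqrt(1-a²) ε_k`` with ``a = exp(-dt/tau)``; the
    stationary standard deviation is exactly ``rms``.
    """
    if rms == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    e = rms * math.sqrt(1 - a * a) * rng.standard_normal(n)
    v0 = rms * rng.standard_normal()
    v, _ = sp_signal.lfilter([1.0], [1.0, -a], e, zi=np.array([a * v0]))
    return v


def _smoothstep(s):
    return 3 * s**2 - 2 * s**3


def _snap_nearest(value: float, grid: np.ndarray) -> float:
    return float(grid[np.argmin(np.abs(grid - value))])


def _draw_thresholds(spec: CohortSpec, rng) -> tuple[float, float]:
    """Thresholds from the cohort distribution, snapped to the legal grids."""
    sin_grid = np.asarray(SINUSOIDAL_LEVELS_UA)
    cut_grid = 50.0 + 25.0 * np.arange(0, 79)  # 50..2000 µA
    while True:
        sin = rng.normal(spec.threshold_sinusoidal_mean, spec.threshold_sinusoidal_sd)
        if sin > 0:
            break
    while True:
        cut = rng.normal(spec.threshold_cutaneous_mean, spec.threshold_cutaneous_sd)
        if cut > 0:
            break
    return _snap_nearest(sin, sin_grid), _snap_nearest(cut, cut_grid)


# ---------------------------------------------------------------------------
# Trial generators
# ---------------------------------------------------------------------------

_FOOT_MARKER_OFFSETS = {
    # (dx, dy, dz_outward) relative to the mid-foot marker
    "heel": (-0.13, -0.01, 0.0),
    "midfoot": (0.0, 0.0, 0.0),
    "fifthmet": (0.02, 0.0, 0.025),
    "toe": (0.08, -0.01, 0.0),
}


def _add_foot_markers(markers, side, x, y, z):
    suffix = "_L" if side == "left" else "_R"
    out_sign = -1.0 if side == "left" else 1.0
    for name, (dx, dy, dz) in _FOOT_MARKER_OFFSETS.items():
        markers[name + suffix] = np.column_stack(
            [x + dx, np.maximum(y + dy, 0.0), z + out_sign * dz]
        )


def simulate_standing_trial(
    profile: ThresholdProfile,
    cell,
    seed: int,
    spec: CohortSpec | None = None,
    participant_factor: float = 1.0,
) -> tuple[MarkerTrial, GroundTruth]:
    """A 5 s standing trial with OU trunk sway and static feet."""
    spec = spec or CohortSpec()
    task, balance, stimulation, technique = cell
    if task != "standing":
        raise InvalidArgumentError(f"not a standing cell: {cell}")
    rng = np.random.default_rng(seed)
    rate, dt = spec.rate, 1.0 / spec.rate
    n = int(round(spec.standing_duration_s * rate)) + 1
    targets = spec.standing_sway_targets(balance, stimulation)
    s_ml = targets["ML"] * participant_factor
    s_ap = targets["AP"] * participant_factor

    chest_x = np.cumsum(ou_velocity(n, dt, s_ap, spec.sway_tau_s, rng)) * dt
    chest_z = np.cumsum(ou_velocity(n, dt, s_ml, spec.sway_tau_s, rng)) * dt
    chest_y = spec.chest_height + np.cumsum(ou_velocity(n, dt, 0.003, spec.sway_tau_s, rng)) * dt

    markers = {
        "chest": np.column_stack([chest_x, chest_y, chest_z]),
        "head": np.column_stack([chest_x, chest_y + spec.head_offset, chest_z]),
    }
    half = (
        spec.foot_half_separation_challenged
        if balance == "challenged"
        else spec.foot_half_separation
    )
    for side, zc in (("left", -half), ("right", half)):
        _add_foot_markers(
            markers, side, np.zeros(n), np.full(n, 0.03), np.full(n, zc)
        )
    if spec.marker_noise_rms > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, spec.marker_noise_rms, markers[name].shape
            )
    trial = MarkerTrial(
        participant_id=profile.participant_id,
        task=task,
        balance=balance,
        stimulation=stimulation,
        technique=technique,
        trial_index=0,
        rate=rate,
        markers=markers,
    )
    truth = GroundTruth(sway_rms={"ML": s_ml, "AP": s_ap})
    return trial, truth


def simulate_walking_trial(
    profile: ThresholdProfile,
    cell,
    seed: int,
    spec: CohortSpec | None = None,
    participant_factor: float = 1.0,
) -> tuple[MarkerTrial, GroundTruth]:
    """A straight-path walking trial of ``spec.n_steps`` alternating steps."""
    spec = spec or CohortSpec()
    task, balance, stimulation, technique = cell
    if task != "walking":
        raise InvalidArgumentError(f"not a walking cell: {cell}")
    rng = np.random.default_rng(seed)
    rate, dt = spec.rate, 1.0 / spec.rate
    targets = spec.walking_targets(balance, stimulation)
    speed = targets["speed"] * participant_factor
    sw_sd = targets["step_width_sd"]
    ml_mult, ap_mult = targets["ml_mult"], targets["ap_mult"]

    n_steps = spec.n_steps
    step_t = spec.step_length / speed
    swing_t = spec.swing_fraction * step_t
    duration = (n_steps + 0.5) * step_t
    n = int(round(duration * rate)) + 1
    t = np.arange(n) * dt

    # Per-step foot placements: step i lands at x = i*L at time i*step_t;
    # odd steps are the right foot. ML placements are drawn around ±w/2 with
    # SD sw_sd/sqrt(2) so consecutive-placement differences have SD sw_sd.
    sides = ["right" if i % 2 == 1 else "left" for i in range(1, n_steps + 1)]
    z_sd = sw_sd / math.sqrt(2)
    place_z = np.array(
        [
            rng.normal(
                (spec.mean_step_width / 2) * (1 if s == "right" else -1), z_sd
            )
            for s in sides
        ]
    )
    place_x = spec.step_length * np.arange(1, n_steps + 1)
    land_times = step_t * np.arange(1, n_steps + 1)
    init_z = {
        "right": rng.normal(spec.mean_step_width / 2, z_sd),
        "left": rng.normal(-spec.mean_step_width / 2, z_sd),
    }

    for side in ("left", "right"):
        steps = [
            (land_times[i], place_x[i], place_z[i])
            for i in range(n_steps)
            if sides[i] == side
        ]
        x = np.zeros(n)
        y = np.zeros(n)
        z = np.full(n, init_z[side])
        x_prev, z_prev = 0.0, init_z[side]
        for t_land, x_next, z_next in steps:
            t0 = t_land - swing_t
            sw = (t >= t0) & (t < t_land)
            s = (t[sw] - t0) / swing_t
            x[sw] = x_prev + (x_next - x_prev) * (1 - np.cos(math.pi * s)) / 2
            y[sw] = spec.step_height * np.sin(math.pi * s) ** 4
            z[sw] = z_prev + (z_next - z_prev) * _smoothstep(np.minimum(s / 0.6, 1.0))
            after = t >= t_land
            x[after], z[after] = x_next, z_next
            y[after] = 0.0
            x_prev, z_prev = x_next, z_next
        if side == "left":
            foot_l = (x, y, z)
        else:
            foot_r = (x, y, z)

    # Chest: constant forward speed + within-stride oscillation + OU sway.
    v_ap = speed * (
        1 + spec.chest_ap_osc_frac * ap_mult * np.sin(2 * math.pi * t / step_t)
    ) + ou_velocity(n, dt, spec.walking_ap_sway_rms * ap_mult, spec.sway_tau_s, rng)
    chest_x = np.cumsum(v_ap) * dt
    chest_z = targets["ml_amp"] * np.sin(
        math.pi * t / step_t
    ) + np.cumsum(
        ou_velocity(n, dt, spec.walking_ml_sway_rms * ml_mult, spec.sway_tau_s, rng)
    ) * dt
    chest_y = spec.chest_height + spec.chest_bounce * np.cos(2 * math.pi * t / step_t)

    markers = {
        "chest": np.column_stack([chest_x, chest_y, chest_z]),
        "head": np.column_stack([chest_x, chest_y + spec.head_offset, chest_z]),
    }
    _add_foot_markers(markers, "left", *foot_l)
    _add_foot_markers(markers, "right", *foot_r)
    if spec.marker_noise_rms > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, spec.marker_noise_rms, markers[name].shape
            )
    trial = MarkerTrial(
        participant_id=profile.participant_id,
        task=task,
        balance=balance,
        stimulation=stimulation,
        technique=technique,
        trial_index=0,
        rate=rate,
        markers=markers,
    )
    # Ground-truth contact instant: the swing arc's vertical-velocity minimum,
    # at 2/3 of swing — the pipeline's own operational definition of contact.
    contact_times = [
        (land_times[i] - swing_t / 3.0, sides[i]) for i in range(n_steps)
    ]
    true_widths = [abs(place_z[i + 1] - place_z[i]) for i in range(n_steps - 1)]
    truth = GroundTruth(
        contact_times=contact_times,
        step_widths=true_widths,
        chest_speed=speed,
        sway_rms={
            "ML": spec.walking_ml_sway_rms * ml_mult,
            "AP": spec.walking_ap_sway_rms * ap_mult,
        },
    )
    return trial, truth


def simulate_trial(profile, cell, seed, spec=None, participant_factor=1.0):
    """Dispatch to the standing or walking generator based on the cell's task."""
    if cell[0] == "standing":
        return simulate_standing_trial(profile, cell, seed, spec, participant_factor)
    return simulate_walking_trial(profile, cell, seed, spec, participant_factor)


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------


def simulate_cohort(spec: CohortSpec | None = None):
    """Threshold profiles, participant factors, and a per-trial manifest.

    Returns ``(profiles, factors, manifest)``: 13 profiles with thresholds
    drawn from the cohort distribution and snapped to the procedure grids, a
    log-normal random factor per participant, and a manifest DataFrame of
    ``n_participants × 16 cells × trials_per_cell`` trial records with
    per-trial seeds.
    """
    spec = spec or CohortSpec()
    if spec.n_participants < 1 or spec.trials_per_cell < 1:
        raise InvalidArgumentError("participants and trials per cell must be positive")
    rng = np.random.default_rng(spec.seed)
    profiles, factors = [], {}
    for pid in range(1, spec.n_participants + 1):
        sin, cut = _draw_thresholds(spec, rng)
        profiles.append(ThresholdProfile(pid, sin, cut))
        factors[pid] = float(
            np.exp(rng.normal(0.0, spec.participant_factor_sd))
        )
    rows = []
    for profile in profiles:
        for cell in ALL_CELLS:
            for k in range(spec.trials_per_cell):
                rows.append(
                    {
                        "participant": profile.participant_id,
                        "task": cell[0],
                        "balance": cell[1],
                        "stimulation": cell[2],
                        "technique": cell[3],
                        "trial": k + 1,
                        "seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
    return profiles, factors, pd.DataFrame(rows)


def simulate_measures(
    spec: CohortSpec | None = None, seed: int | None = None, null: bool = False
) -> pd.DataFrame:
    """Trial-level outcome measures sampled directly from the cohort's statistical model.

    This is the generator's measure-level mode: each trial's measure is
    ``baseline × cell multiplier × participant factor × log-normal trial
    noise``, with per-measure trial CVs chosen to match the dispersion of the
    kinematic synthesis (RMS over a 5 s OU window, an SD over three steps,
    and a timed 3 m speed). With ``null=True`` all condition multipliers are
    1 and only participant and trial variability remain — the calibration
    null of the downstream ANOVA.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    def ln_noise(cv, size):
        sigma = math.sqrt(math.log(1 + cv * cv))
        return np.exp(rng.normal(-sigma * sigma / 2, sigma, size))

    rows = []
    for pid in range(1, spec.n_participants + 1):
        f = float(np.exp(rng.normal(0.0, spec.participant_factor_sd)))
        for cell in ALL_CELLS:
            task, balance, stimulation, technique = cell
            if task == "standing":
                tg = (
                    {"ML": spec.standing_ml_rms, "AP": spec.standing_ap_rms}
                    if null
                    else spec.standing_sway_targets(balance, stimulation)
                )
                values = {
                    "ml_trunk_velocity_rms": (tg["ML"], spec.trial_cv_rms),
                    "ap_trunk_velocity_rms": (tg["AP"], spec.trial_cv_rms),
                }
            else:
                tg = (
                    {"speed": spec.gait_speed, "step_width_sd": spec.step_width_sd}
                    if null
                    else spec.walking_targets(balance, stimulation)
                )
                values = {
                    "gait_speed": (tg["speed"], spec.trial_cv_speed),
                    "step_width_sd": (tg["step_width_sd"], spec.trial_cv_step_width_sd),
                }
            for name, (mean, cv) in values.items():
                draws = mean * f * ln_noise(cv, spec.trials_per_cell)
                for k, v in enumerate(draws, 1):
                    rows.append(
                        {
                            "participant": pid,
                            "task": task,
                            "balance": balance,
                            "stimulation": stimulation,
                            "technique": technique,
                            "trial": k,
                            "measure": name,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)


def write_fixture_dataset(path, spec: CohortSpec | None = None, seed: int | None = None):
    """Write a trial dataset (trajectory CSVs + manifest + ground truth) to ``path``.

    Returns the manifest with a ``file`` column. Ground truth goes under
    ``path/truth/`` so the measurement pipeline can be pointed at the trial
    files alone.
    """
    from . import io as svs_io

    spec = spec or CohortSpec()
    if seed is not None:
        spec = CohortSpec(**{**asdict(spec), "seed": seed})
    path = Path(path)
    (path / "trials").mkdir(parents=True, exist_ok=True)
    (path / "truth").mkdir(parents=True, exist_ok=True)
    profiles, factors, manifest = simulate_cohort(spec)
    by_id = {p.participant_id: p for p in profiles}
    files = []
    for row in manifest.itertuples(index=False):
        cell = (row.task, row.balance, row.stimulation, row.technique)
        trial, truth = simulate_trial(
            by_id[row.participant], cell, row.seed, spec, factors[row.participant]
        )
        trial.trial_index = row.trial
        stem = (
            f"p{row.participant:02d}_{row.task}_{row.balance}_"
            f"{row.stimulation}_{row.technique}_t{row.trial}"
        )
        svs_io.write_trial_csv(trial, path / "trials" / f"{stem}.csv")
        svs_io.write_ground_truth_csv(truth, path / "truth" / f"{stem}.csv")
        files.append(f"trials/{stem}.csv")
    manifest = manifest.assign(file=files)
    manifest.to_csv(path / "manifest.csv", index=False)
    svs_io.write_thresholds_csv(profiles, path / "thresholds.csv")
    return manifest
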