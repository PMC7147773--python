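"""CSV readers and writers for trials, thresholds, and ground truth.

Trajectory CSV schema (one file per trial): two comment header lines
``# rate_hz=<rate>`` and ``# axes=AP,UP,ML``, then columns
``frame,t_s,<marker>_x,<marker>_y,<marker>_z`` for the 10 canonical markers
(x = AP, y = vertical, z = ML, meters). The trial manifest is a sidecar CSV
with the participant/task/condition fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrialRejectedError
from .kinematics import MARKER_NAMES, MarkerTrial

_AXES_LABEL = "AP,UP,ML"


def write_trial_csv(trial: MarkerTrial, path) -> None:
    path = Path(path)
    n = trial.n_frames
    cols = {"frame": np.arange(n), "t_s": np.arange(n) / trial.rate}
    for name in MARKER_NAMES:
        arr = trial.markers[name]
        cols[f"{name}_x"] = arr[:, 0]
        cols[f"{name}_y"] = arr[:, 1]
        cols[f"{name}_z"] = arr[:, 2]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={trial.rate:g}\n")
        fh.write(f"# axes={_AXES_LABEL}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_trial_csv(path, metadata: dict | None = None) -> MarkerTrial:
    """Read a trajectory CSV; ``metadata`` supplies the condition fields."""
    path = Path(path)
    rate = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "rate_hz":
                rate = float(val)
            elif key == "axes" and val.strip() != _AXES_LABEL:
                raise TrialRejectedError(
                    f"{path.name}: unexpected axes header {val.strip()!r}"
                )
    if rate is None:
        raise TrialRejectedError(f"{path.name}: missing '# rate_hz=' header")
    df = pd.read_csv(path, comment="#")
    markers = {}
    for name in MARKER_NAMES:
        try:
            markers[name] = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(float)
        except KeyError as exc:
            raise TrialRejectedError(f"{path.name}: missing column {exc}") from None
    meta = metadata or {}
    return MarkerTrial(
        participant_id=int(meta.get("participant", 0)),
        task=str(meta.get("task", "standing")),
        balance=str(meta.get("balance", "unchallenged")),
        stimulation=str(meta.get("stimulation", "sham")),
        technique=str(meta.get("technique", "sinusoidal")),
        trial_index=int(meta.get("trial", 0)),
        rate=rate,
        markers=markers,
    )


def write_thresholds_csv(profiles, path) -> None:
    """Threshold table in canonical column order."""
    rows = [
        {
            "participant": p.participant_id,
            "sinusoidal_threshold_uA": p.sinusoidal_threshold,
            "cutaneous_threshold_uA": p.cutaneous_threshold,
            "sinusoidal_amplitude_uA": p.sinusoidal_amplitude,
            "cutaneous_amplitude_uA": p.cutaneous_amplitude,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thresholds_csv(path):
    from .stimulus import ThresholdProfile

    df = pd.read_csv(path)
    return [
        ThresholdProfile(
            int(r.participant),
            float(r.sinusoidal_threshold_uA),
            float(r.cutaneous_threshold_uA),
        )
        for r in df.itertuples(index=False)
    ]


def write_ground_truth_csv(truth, path) -> None:
    """Flatten a GroundTruth record to a small long-format CSV."""
    rows = []
    for t, side in truth.contact_times:
        rows.append({"field": "contact", "key": side, "value": t})
    for i, w in enumerate(truth.step_widths, 1):
        rows.append({"field": "step_width", "key": str(i), "value": w})
    if truth.chest_speed is not None:
        rows.append({"field": "chest_speed", "key": "", "value": truth.chest_speed})
    for axis, rms in truth.sway_rms.items():
        rows.append({"field": "sway_rms", "key": axis, "value": rms})
    pd.DataFrame(rows, columns=["field", "key", "value"]).to_csv(path, index=False)


def read_measures_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measures_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
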