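"""Bundled reference data.

``reference_thresholds()`` returns the per-participant vestibular thresholds
of a published 13-adult SVS cohort (sinusoidal motion threshold and cutaneous
threshold, both in µA), which serve as the package's worked example and as the
empirical anchor for the synthetic-cohort threshold distributions
(sinusoidal: mean 608, SD 162 µA; cutaneous: mean 312, SD 104 µA).
"""

from __future__ import annotations

import pandas as pd

from .stimulus import (
    CUTANEOUS_FRACTION,
    SINUSOIDAL_FRACTION,
    ThresholdProfile,
    scale_amplitude,
)

# (participant, sinusoidal threshold µA, cutaneous threshold µA)
_REFERENCE_THRESHOLDS = (
    (1, 750, 375),
    (2, 800, 375),
    (3, 650, 300),
    (4, 800, 375),
    (5, 400, 150),
    (6, 500, 175),
    (7, 700, 350),
    (8, 700, 400),
    (9, 550, 325),
    (10, 250, 150),
    (11, 550, 475),
    (12, 550, 225),
    (13, 700, 375),
)


def reference_profiles() -> list[ThresholdProfile]:
    """The 13 reference participants as :class:`ThresholdProfile` objects."""
    return [
        ThresholdProfile(pid, float(sin), float(cut))
        for pid, sin, cut in _REFERENCE_THRESHOLDS
    ]


def reference_thresholds() -> pd.DataFrame:
    """Reference cohort as a DataFrame in canonical column order."""
    rows = []
    for pid, sin, cut in _REFERENCE_THRESHOLDS:
        rows.append(
            {
                "participant": pid,
                "sinusoidal_threshold_uA": float(sin),
                "cutaneous_threshold_uA": float(cut),
                "sinusoidal_amplitude_uA": scale_amplitude(sin, SINUSOIDAL_FRACTION),
                "cutaneous_amplitude_uA": scale_amplitude(cut, CUTANEOUS_FRACTION),
            }
        )
    return pd.DataFrame(rows)
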