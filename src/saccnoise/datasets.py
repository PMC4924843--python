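"""Reference dataset: per-monkey saccade statistics and fitted noise-model
parameters from five rhesus macaques recorded before and during unilateral
muscimol inactivation of the caudal fastigial nucleus (cFN).

These group-level values serve two purposes: they parameterize the condition
presets of the synthetic generator, and they are the inputs to the reporting
utilities (condition contrasts, paired t statistics, group means) that
summarize inactivation effects.  Conditions: ``control`` (pre-injection),
``ipsiversive`` and ``contraversive`` (saccades toward / away from the
inactivated side).  All trial statistics refer to the 10-deg motor-error
class (errors between 8.5 and 12.5 deg).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "fitted_parameters",
    "trial_statistics",
    "kinematics_at_10deg",
]

# fitted parameters of the 3-parameter noise model without ON noise
# (k_ON = 0): accumulating-noise coefficient k_A, PBN noise coefficient
# k_PBN, internal feedback gain g (1/s), and the fit's R^2
_FITTED = [
    # subject, condition, k_A, k_PBN, g, r2
    (1, "control", 0.102, 0.032, 280.0, 0.986),
    (2, "control", 0.046, 0.020, 204.0, 0.992),
    (3, "control", 0.170, 0.028, 317.0, 0.997),
    (4, "control", 0.134, 0.040, 227.0, 0.989),
    (5, "control", 0.080, 0.022, 171.0, 0.994),
    (1, "ipsiversive", 0.142, 0.024, 92.0, 0.996),
    (2, "ipsiversive", 0.223, 0.015, 35.0, 0.998),
    (3, "ipsiversive", 0.144, 0.049, 168.0, 0.998),
    (4, "ipsiversive", 0.183, 0.035, 93.0, 0.999),
    (5, "ipsiversive", 0.184, 0.023, 84.0, 0.999),
    (1, "contraversive", 0.094, 0.034, 199.0, 0.897),
    (2, "contraversive", 0.201, 0.034, 286.0, 0.999),
    (3, "contraversive", 0.199, 0.060, 110.0, 0.940),
    (4, "contraversive", 0.164, 0.039, 282.0, 0.994),
    (5, "contraversive", 0.259, 0.043, 165.0, 0.997),
]

# inter-trial statistics of duration and amplitude in the 10-deg class:
# var of total duration (ms^2), main-sequence slope alpha (deg/ms),
# alpha^2*var_TDur (deg^2), var of amplitude (deg^2), Pearson r(dur, amp)
_TRIAL_STATS = [
    (1, "control", 23.5, 0.58, 7.8, 1.5, 0.44),
    (2, "control", 8.2, 0.57, 2.7, 0.2, 0.28),
    (3, "control", 58.5, 0.72, 30.1, 3.0, 0.02),
    (4, "control", 75.8, 0.75, 43.0, 2.5, 0.12),
    (5, "control", 3.9, 0.66, 1.7, 0.7, 0.00),
    (1, "ipsiversive", 41.3, 0.60, 14.7, 3.3, 0.66),
    (2, "ipsiversive", 197.3, 0.43, 36.3, 10.9, 0.83),
    (3, "ipsiversive", 703.8, 0.47, 156.2, 8.8, 0.72),
    (4, "ipsiversive", 130.6, 0.65, 55.4, 13.7, 0.31),
    (5, "ipsiversive", 244.5, 0.64, 100.0, 19.9, 0.77),
    (1, "contraversive", 51.4, 0.40, 8.3, 0.7, -0.54),
    (2, "contraversive", 167.4, 0.52, 45.0, 2.7, -0.72),
    (3, "contraversive", 843.5, 0.13, 15.0, 1.0, -0.58),
    (4, "contraversive", 229.8, 0.52, 61.3, 4.8, -0.51),
    (5, "contraversive", 267.9, 0.28, 20.6, 1.9, -0.60),
]

# main-sequence parameters: amplitude (deg) of saccades with 10-deg motor
# error; peak velocity (deg/s), total duration (ms) and deceleration
# duration (ms) of saccades with 10-deg amplitude
_KINEMATICS = [
    (1, "control", 10.3, 468.9, 36.5, 19.7),
    (2, "control", 10.1, 417.0, 38.6, 20.7),
    (3, "control", 9.9, 434.2, 40.9, 22.9),
    (4, "control", 10.3, 402.8, 42.9, 24.0),
    (5, "control", 10.0, 425.1, 41.2, 22.5),
    (1, "ipsiversive", 12.9, 357.2, 48.4, 29.2),
    (2, "ipsiversive", 14.0, 319.2, 53.4, 33.7),
    (3, "ipsiversive", 20.8, 356.4, 52.7, 34.6),
    (4, "ipsiversive", 17.7, 309.2, 61.8, 42.2),
    (5, "ipsiversive", 25.4, 375.8, 47.0, 27.9),
    (1, "contraversive", 8.4, 403.4, 44.6, 27.1),
    (2, "contraversive", 8.3, 285.9, 60.1, 40.7),
    (3, "contraversive", 5.1, 204.8, 91.4, 61.8),
    (4, "contraversive", 10.0, 289.9, 62.1, 40.9),
    (5, "contraversive", 5.6, 270.0, 67.0, 43.3),
]


def fitted_parameters() -> pd.DataFrame:
    """Per-subject fitted [k_A, k_PBN, g] and R² of the no-ON-noise model."""
    return pd.DataFrame(
        _FITTED, columns=["subject", "condition", "k_A", "k_PBN", "g", "r2"]
    )


def trial_statistics() -> pd.DataFrame:
    """Per-subject inter-trial duration/amplitude statistics (10-deg class)."""
    return pd.DataFrame(
        _TRIAL_STATS,
        columns=["subject", "condition", "var_tdur_ms2", "alpha",
                 "alpha2_var_tdur", "var_amp", "cc_tdur_amp"],
    )


def kinematics_at_10deg() -> pd.DataFrame:
    """Per-subject main-sequence parameters at 10-deg amplitude."""
    return pd.DataFrame(
        _KINEMATICS,
        columns=["subject", "condition", "amplitude", "peak_velocity",
                 "total_duration_ms", "decel_duration_ms"],
    )
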