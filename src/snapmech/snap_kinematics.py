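"""Snap kinematics from ultrahigh-speed angular measurements.

Given the peak angular velocity ω_A of the anterior mandible part and the
time t_A to reach it, the chain is:

    V_MT = L_A·ω_A              tip linear velocity
    α_A  = ω_A / t_A            mean angular acceleration
    F_A  = M_A·L_A·α_A / 3      snap force (uniform-rod lever arm)
    E_A  = I_A·ω_A² / 2         snap (rotational kinetic) energy

``t_A`` defaults to 8.68 μs — four inter-frame intervals at 460,830 fps,
the timing at which peak tip velocity is observed in ultrahigh-speed
footage — and can be overridden per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import units
from .errors import InsufficientDataError, InvalidDurationError, SchemaError

#: Default time from snap initiation to peak angular velocity, s.
DEFAULT_T_A = 8.68e-6


@dataclass(frozen=True)
class SnapEvent:
    """One snap: peak angular velocity, timing, optional full series (SI)."""

    omega_a: float
    t_a: float = DEFAULT_T_A
    omega_series: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.omega_a > 0:
            raise InvalidDurationError(f"omega_a must be positive, got {self.omega_a!r}")
        if not self.t_a > 0:
            raise InvalidDurationError(f"t_a must be positive, got {self.t_a!r}")


@dataclass(frozen=True)
class SnapPerformance:
    """Derived per-event performance figures (SI)."""

    v_mt: float
    alpha_a: float
    f_a: float
    e_a: float
    f_bw: float


def tip_velocity(l_a: float, omega_a: float) -> float:
    """Linear velocity of the mandible tip: L_A·ω_A (m/s)."""
    return l_a * omega_a


def angular_acceleration(omega_a: float, t_a: float) -> float:
    """Mean angular acceleration ω_A/t_A (rad/s²)."""
    if not t_a > 0:
        raise InvalidDurationError(f"t_a must be positive, got {t_a!r}")
    return omega_a / t_a


def snap_force(m_a: float, l_a: float, alpha_a: float) -> float:
    """Snap force M_A·L_A·α_A/3 (N)."""
    return m_a * l_a * alpha_a / 3.0


def snap_energy(i_a: float, omega_a: float) -> float:
    """Rotational kinetic energy ½·I_A·ω_A² (J)."""
    return 0.5 * i_a * omega_a**2


def force_to_bodyweight(f_a: float, m_t: float) -> float:
    """Force divided by body weight M_T·g (dimensionless)."""
    return f_a / (m_t * units.G)


def peak_from_series(
    omega_series: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Peak angular velocity and its time from an ordered (t, ω) series.

    Ties are broken by the earliest time.  Times must be strictly
    increasing and start at or after 0.
    """
    if len(omega_series) == 0:
        raise InsufficientDataError("omega series is empty")
    times = [t for t, _ in omega_series]
    if any(b <= a for a, b in zip(times, times[1:])) or times[0] < 0:
        raise InvalidDurationError("series times must be strictly increasing from 0")
    best_t, best_w = omega_series[0]
    for t, w in omega_series[1:]:
        if w > best_w:
            best_t, best_w = t, w
    return best_w, best_t


def performance(
    event: SnapEvent, m_a: float, l_a: float, i_a: float, m_t: float
) -> SnapPerformance:
    """Full kinematic chain for one event against one morphometry."""
    alpha = angular_acceleration(event.omega_a, event.t_a)
    f = snap_force(m_a, l_a, alpha)
    return SnapPerformance(
        v_mt=tip_velocity(l_a, event.omega_a),
        alpha_a=alpha,
        f_a=f,
        e_a=snap_energy(i_a, event.omega_a),
        f_bw=force_to_bodyweight(f, m_t),
    )


SNAP_COLUMNS = ["individual_id", "omega_a_rad_s"]


def read_snap_events_csv(path) -> pd.DataFrame:
    """Read a snap-event table (individual_id, omega_a_rad_s[, t_a_us]).

    Returns individual_id plus SI columns omega_a and t_a (seconds;
    missing t_a_us falls back to the 8.68 μs default).
    """
    df = pd.read_csv(path)
    missing = [c for c in SNAP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing snap-event column(s): {', '.join(missing)}")
    if "t_a_us" in df.columns:
        t_a = df["t_a_us"].map(units.us_to_s).fillna(DEFAULT_T_A)
    else:
        t_a = pd.Series(DEFAULT_T_A, index=df.index)
    return pd.DataFrame({
        "individual_id": df["individual_id"],
        "omega_a": df["omega_a_rad_s"].astype(float),
        "t_a": t_a,
    })
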