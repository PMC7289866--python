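"""Energy-conservation inversion of ball-strike events.

A small metal ball (2.25 mg, 0.7 mm) is placed in front of the soldier;
after the mandible strikes it, ball and termite move apart.  Assuming no
loss to air resistance or ball rotation, the snap energy equals the
post-impact kinetic energy:

    E_A = ½·M_B·V_B² + ½·M_T·V_T² + ½·I_T·ω_T²

from which the mandible tip velocity at impact is recovered as

    V_MT = sqrt(2·E_A / (M_A·K)),

and the impact force follows from the kinematic chain with the fixed
time-to-peak t_A:

    F_A = M_A·V_MT / (3·t_A).

Strike precision is summarised from the ball's deviation angles relative
to the body axis: mean, sd, range and a Shapiro–Wilk normality test on
the raw (non-circular) angles.  Angles are summarised as absolute
deviations in [0°, 180°]; signed values are retained on the event for
plotting and side-of-axis questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .errors import InsufficientDataError, InvalidDurationError, SchemaError
from .snap_kinematics import DEFAULT_T_A

#: Default metal-ball mass, kg (2.25 mg ballpoint-pen ball).
DEFAULT_M_B = 2.25e-6


@dataclass(frozen=True)
class BallStrikeEvent:
    """Post-impact motion of ball and termite for one strike (SI units)."""

    v_b: float
    m_t: float
    v_t: float
    i_t: float
    omega_t: float
    m_b: float = DEFAULT_M_B
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.m_b > 0 or not self.m_t > 0:
            raise ValueError("masses must be positive")
        if self.v_b < 0 or self.v_t < 0 or self.omega_t < 0:
            raise ValueError("speeds must be non-negative")
        if self.i_t < 0:
            raise ValueError("i_t must be non-negative")
        if self.angle_deg is not None and not -180.0 <= self.angle_deg <= 180.0:
            raise ValueError(f"angle_deg must be in [-180, 180], got {self.angle_deg!r}")


@dataclass(frozen=True)
class StrikeAngleSummary:
    """Summary statistics and normality test for strike angles (degrees)."""

    n: int
    mean_deg: float
    sd_deg: float
    min_deg: float
    max_deg: float
    w: float
    p: float


def event_kinetic_energy(
    e: BallStrikeEvent, include_ball_rotation: bool = False, r_b: float = 0.35e-3
) -> float:
    """Total post-impact kinetic energy of ball and termite (J).

    ``include_ball_rotation`` adds a solid-sphere rolling term
    (2/5·M_B·r_B²·(V_B/r_B)²/2 = M_B·V_B²/5) for sensitivity analysis;
    the default matches the stated no-ball-rotation assumption.
    """
    e_kin = (
        0.5 * e.m_b * e.v_b**2
        + 0.5 * e.m_t * e.v_t**2
        + 0.5 * e.i_t * e.omega_t**2
    )
    if include_ball_rotation:
        e_kin += 0.2 * e.m_b * e.v_b**2
    return e_kin


def invert_tip_velocity(e_a: float, m_a: float, k: float) -> float:
    """Tip velocity from snap energy: sqrt(2·E_A/(M_A·K)) (m/s)."""
    if e_a < 0:
        raise ValueError(f"e_a must be non-negative, got {e_a!r}")
    if not m_a > 0 or not k > 0:
        raise ValueError("m_a and k must be positive")
    return float(np.sqrt(2.0 * e_a / (m_a * k)))


def strike_force_from_event(
    v_mt: float, m_a: float, t_a: float = DEFAULT_T_A, l_a: float | None = None
) -> float:
    """Impact force assuming the ball was struck at peak tip velocity.

    Chains ω_A = V_MT/L_A, α_A = ω_A/t_A and F_A = M_A·L_A·α_A/3, in which
    L_A cancels: F_A = M_A·V_MT/(3·t_A).  ``l_a`` is accepted for interface
    symmetry but does not influence the result.
    """
    if not t_a > 0:
        raise InvalidDurationError(f"t_a must be positive, got {t_a!r}")
    return m_a * v_mt / (3.0 * t_a)


def strike_angle_summary(angles_deg) -> StrikeAngleSummary:
    """Mean/sd/range and Shapiro–Wilk normality for strike angles.

    Angles are folded to absolute deviation from the body axis before
    summarising.  Requires at least 3 finite angles.
    """
    a = np.abs(np.asarray(angles_deg, dtype=float))
    if a.size < 3:
        raise InsufficientDataError(
            f"normality test needs at least 3 angles, got {a.size}"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    w, p = stats.shapiro(a)
    return StrikeAngleSummary(
        n=int(a.size),
        mean_deg=float(a.mean()),
        sd_deg=float(a.std(ddof=1)),
        min_deg=float(a.min()),
        max_deg=float(a.max()),
        w=float(w),
        p=float(p),
    )


BALL_STRIKE_COLUMNS = ["individual_id", "event_id", "v_b_m_s", "v_t_m_s", "omega_t_rad_s"]


def read_ball_strike_csv(path) -> pd.DataFrame:
    """Read a ball-strike event table into SI columns.

    Required columns: individual_id, event_id, v_b_m_s, v_t_m_s,
    omega_t_rad_s.  Optional: angle_deg, m_b_mg (default 2.25).
    """
    df = pd.read_csv(path)
    missing = [c for c in BALL_STRIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing ball-strike column(s): {', '.join(missing)}")
    out = pd.DataFrame({
        "individual_id": df["individual_id"],
        "event_id": df["event_id"],
        "v_b": df["v_b_m_s"].astype(float),
        "v_t": df["v_t_m_s"].astype(float),
        "omega_t": df["omega_t_rad_s"].astype(float),
    })
    out["m_b"] = (
        df["m_b_mg"].map(units.mg_to_kg) if "m_b_mg" in df.columns else DEFAULT_M_B
    )
    out["angle_deg"] = df["angle_deg"].astype(float) if "angle_deg" in df.columns else np.nan
    return out


def analyze_events(
    events: pd.DataFrame,
    body: pd.DataFrame,
    m_a: float,
    k: float,
    t_a: float = DEFAULT_T_A,
) -> pd.DataFrame:
    """Invert a table of ball-strike events into E_A, V_MT, F_A.

    ``events`` follows :func:`read_ball_strike_csv` output; ``body`` maps
    individual_id to SI m_t and l_t (for I_T).  ``m_a`` and ``k`` are the
    cohort-level mandible mass and inertia constant.
    """
    from .morphometry import compute_it

    body = body.set_index("individual_id")
    rows = []
    for rec in events.itertuples(index=False):
        b = body.loc[rec.individual_id]
        i_t = compute_it(float(b["m_t"]), float(b["l_t"]))
        ev = BallStrikeEvent(
            v_b=float(rec.v_b),
            m_t=float(b["m_t"]),
            v_t=float(rec.v_t),
            i_t=i_t,
            omega_t=float(rec.omega_t),
            m_b=float(rec.m_b),
            angle_deg=None if pd.isna(rec.angle_deg) else float(rec.angle_deg),
        )
        e_a = event_kinetic_energy(ev)
        v_mt = invert_tip_velocity(e_a, m_a, k)
        rows.append({
            "individual_id": rec.individual_id,
            "event_id": rec.event_id,
            "e_a": e_a,
            "v_mt": v_mt,
            "f_a": strike_force_from_event(v_mt, m_a, t_a),
            "angle_deg": rec.angle_deg,
        })
    return pd.DataFrame(rows)
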