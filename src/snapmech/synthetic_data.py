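"""Forward simulation of every input table with known ground truth.

No raw recordings are redistributable, so each input kind — morphometry,
ultrahigh-speed snap events, ball-strike events (with digitized tracks)
and defence trials — is simulated here from a :class:`SimulationConfig`
with explicit ground truth, letting every downstream stage be tested for
exact round trips (zero noise) and statistical recovery (noisy case).

Randomness comes exclusively from :func:`numpy.random.default_rng`
(PCG64) seeded from the config; each generator op derives its own stream
from ``(seed, op_tag)`` so tables are reproducible independently of call
order.  Measurement noise is multiplicative Gaussian (a coefficient of
variation) on tracked velocities only — masses are weighed, velocities
are tracked, and tracking dominates the error budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import units
from .errors import ConfigError
from .morphometry import MandibleMorphometry, inertia_model, compute_it
from .snap_kinematics import DEFAULT_T_A

# per-op stream tags (keep stable: changing one reshuffles that table only)
_TAG_MORPH, _TAG_SNAP, _TAG_STRIKE, _TAG_DEFENCE = 1, 2, 3, 4


@dataclass(frozen=True)
class SpeciesRates:
    """True per-species probabilities driving the defence simulation."""

    attack: float
    snap: float
    hit: float
    kill: float
    immobilise: float = 0.0
    encounters_per_trial: float = 16.0

    def __post_init__(self) -> None:
        for name in ("attack", "snap", "hit", "kill", "immobilise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} rate must be in [0, 1], got {v!r}")
        if self.encounters_per_trial < 0:
            raise ConfigError("encounters_per_trial must be non-negative")


def _default_species() -> dict[str, SpeciesRates]:
    # four predator species spanning generalist/specialist contrasts
    return {
        "generalist_A": SpeciesRates(0.09, 0.5, 0.83, 0.95, 0.0, 15.5),
        "generalist_B": SpeciesRates(0.17, 0.5, 0.13, 0.90, 0.0, 17.8),
        "specialist_A": SpeciesRates(0.34, 0.5, 0.30, 0.0, 0.083, 50.0),
        "specialist_B": SpeciesRates(0.23, 0.5, 0.41, 0.0, 0.0, 23.8),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward simulation (reporting units, like the CSVs)."""

    seed: int = 0
    n_individuals: int = 17
    n_events: int = 92
    n_snap_events: int = 2
    # morphometry truncated-normal (mean, sd) in reporting units
    body_mass_mg: tuple[float, float] = (3.22, 0.12)
    body_length_mm: tuple[float, float] = (6.06, 0.08)
    m_a1_ug: tuple[float, float] = (8.6, 0.9)
    m_a2_ug: tuple[float, float] = (19.4, 1.8)
    l_a_mm: tuple[float, float] = (1.06, 0.04)
    # peak angular velocity: lognormal, median and log-sd
    omega_median_rad_s: float = 1.28e5
    omega_sigma_log: float = 0.10
    t_a_us: float = DEFAULT_T_A * 1e6
    ball_mass_mg: float = 2.25
    # energy partition across (ball, termite translation, termite rotation)
    partition_weights: tuple[float, float, float] = (0.62, 0.36, 0.02)
    partition_concentration: float = 50.0
    noise_cv: float = 0.05
    angle_mean_deg: float = 52.9
    angle_sd_deg: float = 22.7
    n_trials: int = 6
    ants_per_trial: int = 4
    species: dict[str, SpeciesRates] = field(default_factory=_default_species)

    def __post_init__(self) -> None:
        for name in ("body_mass_mg", "body_length_mm", "m_a1_ug", "m_a2_ug", "l_a_mm"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigError(f"{name}: sd must be non-negative, got {sd!r}")
            if mean <= 0:
                raise ConfigError(f"{name}: mean must be positive, got {mean!r}")
        w = np.asarray(self.partition_weights, dtype=float)
        if w.size != 3 or (w < 0).any():
            raise ConfigError("partition_weights must be 3 non-negative values")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ConfigError(f"partition_weights must sum to 1, got {w.sum()!r}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if self.partition_concentration <= 0:
            raise ConfigError("partition_concentration must be positive")


def _rng(cfg: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int,
    lower: float = 0.0, upper: float = np.inf,
) -> np.ndarray:
    """Positive truncated-normal draws; sd = 0 degenerates to the mean."""
    if sd == 0:
        return np.full(n, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_morphometry(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate the morphometry CSV (reporting units, validated dialect)."""
    rng = _rng(cfg, _TAG_MORPH)
    n = cfg.n_individuals
    return pd.DataFrame({
        "individual_id": [f"T{i + 1:02d}" for i in range(n)],
        "m_t_mg": _trunc_normal(rng, *cfg.body_mass_mg, n),
        "l_t_mm": _trunc_normal(rng, *cfg.body_length_mm, n),
        "m_a1_ug": _trunc_normal(rng, *cfg.m_a1_ug, n),
        "m_a2_ug": _trunc_normal(rng, *cfg.m_a2_ug, n),
        "l_a_mm": _trunc_normal(rng, *cfg.l_a_mm, n),
    })


def morphometry_si(morph: pd.DataFrame) -> pd.DataFrame:
    """Convert a generated morphometry table to the SI frame readers emit."""
    return pd.DataFrame({
        "individual_id": morph["individual_id"],
        "m_t": morph["m_t_mg"].map(units.mg_to_kg),
        "l_t": morph["l_t_mm"].map(units.mm_to_m),
        "m_a1": morph["m_a1_ug"].map(units.ug_to_kg),
        "m_a2": morph["m_a2_ug"].map(units.ug_to_kg),
        "l_a": morph["l_a_mm"].map(units.mm_to_m),
    })


def cohort_mandible(morph_si: pd.DataFrame) -> MandibleMorphometry:
    """Cohort-mean mandible (subsection masses pooled across specimens)."""
    return MandibleMorphometry(
        m_a1=float(morph_si["m_a1"].mean()),
        m_a2=float(morph_si["m_a2"].mean()),
        l_a=float(morph_si["l_a"].mean()),
        provenance="cohort-mean",
    )


def gen_snap_events(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate the ultrahigh-speed snap-event CSV (ω_A draws, fixed t_A)."""
    rng = _rng(cfg, _TAG_SNAP)
    n = cfg.n_snap_events
    omega = rng.lognormal(math.log(cfg.omega_median_rad_s), cfg.omega_sigma_log, n)
    return pd.DataFrame({
        "individual_id": [f"U{i + 1:02d}" for i in range(n)],
        "omega_a_rad_s": omega,
        "t_a_us": np.full(n, cfg.t_a_us),
    })


def _dirichlet_partition(
    rng: np.random.Generator, weights: np.ndarray, conc: float, n: int
) -> np.ndarray:
    """Dirichlet draws with mean ``weights``; zero-weight parts stay exactly 0."""
    pos = weights > 0
    out = np.zeros((n, weights.size))
    if pos.sum() == 1:
        out[:, pos] = 1.0
        return out
    out[:, pos] = rng.dirichlet(weights[pos] * conc, size=n)
    return out


def gen_ball_strike_events(
    cfg: SimulationConfig, morph: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ball-strike events plus the hidden truth table.

    Per event: draw true ω_A, compute the true snap energy from the
    cohort-mean mandible inertia model and the individual's L_A, partition
    it across ball / termite translation / termite rotation, convert each
    share into the implied speed, then corrupt the three measured speeds
    with multiplicative Gaussian noise of coefficient ``noise_cv``.

    Returns (events, truth); events follow the ball-strike CSV dialect,
    truth carries event_id, individual_id, omega, E_A (μJ), V_MT (m/s)
    and the drawn partition weights.
    """
    rng = _rng(cfg, _TAG_STRIKE)
    msi = morphometry_si(morph)
    mandible = cohort_mandible(msi)
    im = inertia_model(mandible)
    weights = np.asarray(cfg.partition_weights, dtype=float)
    m_b = units.mg_to_kg(cfg.ball_mass_mg)
    n = cfg.n_events

    idx = np.arange(n) % len(msi)
    omega = rng.lognormal(math.log(cfg.omega_median_rad_s), cfg.omega_sigma_log, n)
    parts = _dirichlet_partition(rng, weights, cfg.partition_concentration, n)
    angles = _trunc_normal(rng, cfg.angle_mean_deg, cfg.angle_sd_deg, n, 0.0, 180.0)
    noise = 1.0 + cfg.noise_cv * rng.standard_normal((n, 3))

    ev_rows, truth_rows = [], []
    for i in range(n):
        ind = msi.iloc[int(idx[i])]
        l_a = float(ind["l_a"])
        m_t = float(ind["m_t"])
        i_t = compute_it(m_t, float(ind["l_t"]))
        v_mt = l_a * omega[i]
        # E_A from the cohort mandible's K and M_A with this individual's L_A:
        # ½·K·M_A·V_MT², so inversion does not depend on L_A
        e_a = 0.5 * im.k * mandible.m_a * v_mt**2
        e_ball, e_trans, e_rot = e_a * parts[i]
        v_b = math.sqrt(2.0 * e_ball / m_b)
        v_t = math.sqrt(2.0 * e_trans / m_t)
        omega_t = math.sqrt(2.0 * e_rot / i_t)
        ev_rows.append({
            "individual_id": ind["individual_id"],
            "event_id": f"E{i + 1:03d}",
            "v_b_m_s": max(0.0, v_b * noise[i, 0]),
            "v_t_m_s": max(0.0, v_t * noise[i, 1]),
            "omega_t_rad_s": max(0.0, omega_t * noise[i, 2]),
            "angle_deg": angles[i],
            "m_b_mg": cfg.ball_mass_mg,
        })
        truth_rows.append({
            "event_id": f"E{i + 1:03d}",
            "individual_id": ind["individual_id"],
            "omega_a_rad_s": omega[i],
            "e_a_uj": units.j_to_uj(e_a),
            "v_mt_m_s": v_mt,
            "w_ball": parts[i, 0],
            "w_translation": parts[i, 1],
            "w_rotation": parts[i, 2],
        })
    return pd.DataFrame(ev_rows), pd.DataFrame(truth_rows)


#: calibration used for generated tracks (90 mm dish spanning 450 px at 1 kfps)
TRACK_CONFIG = {"frame_rate": 1000.0, "reference_px": 450.0, "reference_mm": 90.0,
                "body_axis": [1.0, 0.0]}


def gen_tracks(cfg: SimulationConfig, events: pd.DataFrame) -> pd.DataFrame:
    """Digitized two-frame tracks reproducing each event's stated speeds.

    Ball displacement points along the event's angle (left of the body
    axis, image y-down coordinates); the termite recoils opposite.
    Feeding these through track_processing returns the event's v_b / v_t
    and |angle| exactly (float pixel coordinates, no quantisation).
    """
    scale = (TRACK_CONFIG["reference_mm"] * 1e-3) / TRACK_CONFIG["reference_px"]
    fps = TRACK_CONFIG["frame_rate"]
    rows = []
    for rec in events.itertuples(index=False):
        theta = math.radians(rec.angle_deg)
        # left-positive in math convention -> flip y for image coordinates
        direction = np.array([math.cos(theta), -math.sin(theta)])
        for subject, speed, origin, sgn in (
            ("ball", rec.v_b_m_s, (100.0, 100.0), 1.0),
            ("termite", rec.v_t_m_s, (80.0, 100.0), -1.0),
        ):
            step = sgn * direction * speed / (scale * fps)
            rows.append({"event_id": rec.event_id, "subject": subject, "frame": 0,
                         "x_px": origin[0], "y_px": origin[1]})
            rows.append({"event_id": rec.event_id, "subject": subject, "frame": 1,
                         "x_px": origin[0] + step[0], "y_px": origin[1] + step[1]})
    return pd.DataFrame(rows)


def gen_defence_trials(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate the per-trial defence CSV by Bernoulli thinning.

    Per trial: encounters ~ Poisson, attacks ~ Binomial(encounters,
    attack), snaps ~ Binomial(encounters, snap), hits ~ Binomial(snaps,
    hit), kills ~ Binomial(hits, kill), immobilised ~ Binomial(ants,
    immobilise) — so the count invariants hold by construction.
    """
    rng = _rng(cfg, _TAG_DEFENCE)
    rows = []
    for species, r in cfg.species.items():
        for trial in range(1, cfg.n_trials + 1):
            enc = int(rng.poisson(r.encounters_per_trial))
            attacks = int(rng.binomial(enc, r.attack)) if enc else 0
            snaps = int(rng.binomial(enc, r.snap)) if enc else 0
            hits = int(rng.binomial(snaps, r.hit)) if snaps else 0
            kills = int(rng.binomial(hits, r.kill)) if hits else 0
            immobilised = int(rng.binomial(cfg.ants_per_trial, r.immobilise))
            rows.append({
                "species": species, "trial_id": trial, "encounters": enc,
                "attacks": attacks, "snaps": snaps, "hits": hits, "kills": kills,
                "immobilised": immobilised, "ants": cfg.ants_per_trial,
            })
    return pd.DataFrame(rows)
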