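"""Cohort report: ties all stages into one summary table plus output files.

The report mirrors the conventional comparative table: mean ± sd and
min–max per metric, in reporting units, one decimal, round-half-up.  For
force and energy it prints both the mean of per-event values and the
value computed at mean inputs — these differ whenever inputs covary
(mean-of-products ≠ product-of-means), so both are shown with a caveat
rather than silently choosing one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, units
from . import ball_strike, defence_assay, morphometry, snap_kinematics, synthetic_data
from .errors import ConfigError, InsufficientDataError

log = logging.getLogger("snapmech")

RECONCILIATION_CAVEAT = (
    "Mean of per-event F_A/E_A differs from F_A/E_A at mean inputs whenever "
    "inputs covary (mean of products != product of means); both are reported."
)


def summarize(values, unit: str, ndigits: int = 1) -> dict:
    """mean/sd/min/max of SI values converted to ``unit`` and rounded.

    Sample sd (n−1); sd is None for a single value.  Raw (unrounded)
    converted values are kept under ``raw`` for downstream use.
    """
    conv = units.REPORT_CONVERTERS[unit]
    x = np.asarray([conv(v) for v in values], dtype=float)
    if x.size == 0:
        raise InsufficientDataError("cannot summarize an empty sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else None
    out = {
        "unit": unit,
        "n": int(x.size),
        "mean": units.round_half_up(float(x.mean()), ndigits),
        "sd": None if sd is None else units.round_half_up(sd, ndigits),
        "min": units.round_half_up(float(x.min()), ndigits),
        "max": units.round_half_up(float(x.max()), ndigits),
        "raw": {
            "mean": float(x.mean()),
            "sd": sd,
            "min": float(x.min()),
            "max": float(x.max()),
        },
    }
    return out


def summarize_durations(durations_ms) -> tuple[float, float]:
    """Sample mean and sd of behavioural phase durations, in ms."""
    x = np.asarray(durations_ms, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 durations, got {x.size}")
    return float(x.mean()), float(x.std(ddof=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: dict, base_dir: Path) -> dict:
    """Resolve input tables from files or from the simulation block."""
    data: dict = {"file_hashes": {}, "seed": None}
    if "simulate" in config:
        sim = dict(config["simulate"])
        species = sim.pop("species", None)
        if species is not None:
            sim["species"] = {
                name: synthetic_data.SpeciesRates(**rates) for name, rates in species.items()
            }
        cfg = synthetic_data.SimulationConfig(**sim)
        data["seed"] = cfg.seed
        morph = synthetic_data.gen_morphometry(cfg)
        data["morph_si"] = synthetic_data.morphometry_si(morph)
        snaps = synthetic_data.gen_snap_events(cfg)
        data["snap_events"] = pd.DataFrame({
            "individual_id": snaps["individual_id"],
            "omega_a": snaps["omega_a_rad_s"],
            "t_a": snaps["t_a_us"].map(units.us_to_s),
        })
        events, truth = synthetic_data.gen_ball_strike_events(cfg, morph)
        data["strike_events"] = pd.DataFrame({
            "individual_id": events["individual_id"],
            "event_id": events["event_id"],
            "v_b": events["v_b_m_s"],
            "v_t": events["v_t_m_s"],
            "omega_t": events["omega_t_rad_s"],
            "m_b": events["m_b_mg"].map(units.mg_to_kg),
            "angle_deg": events["angle_deg"],
        })
        data["strike_truth"] = truth
        data["defence"] = synthetic_data.gen_defence_trials(cfg)
    elif "inputs" in config:
        paths = {k: base_dir / v for k, v in config["inputs"].items()}
        for k, p in paths.items():
            if not p.exists():
                raise ConfigError(f"input file not found: {p}")
            data["file_hashes"][k] = _sha256(p)
        data["morph_si"] = morphometry.read_morphometry_csv(paths["morphometry"])
        if "snap_events" in paths:
            data["snap_events"] = snap_kinematics.read_snap_events_csv(paths["snap_events"])
        if "ball_strike" in paths:
            data["strike_events"] = ball_strike.read_ball_strike_csv(paths["ball_strike"])
        if "defence" in paths:
            data["defence"] = defence_assay.read_defence_csv(paths["defence"])
    else:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")
    return data


def build_report(config: dict, base_dir: Path | str = ".") -> dict:
    """Execute the full analysis and return the report as a plain dict."""
    base_dir = Path(base_dir)
    data = _load_inputs(config, base_dir)
    morph_si = data["morph_si"]

    mandible = synthetic_data.cohort_mandible(morph_si)
    im = morphometry.inertia_model(mandible)
    m_t_mean = float(morph_si["m_t"].mean())

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": data["seed"],
            "config": config,
            "file_hashes": data["file_hashes"],
        },
        "cohort_mandible": {
            "m_a_ug": units.kg_to_ug(mandible.m_a),
            "l_a_mm": units.m_to_mm(mandible.l_a),
            "l_com_mm": units.m_to_mm(im.l_com),
            "k": im.k,
            "i_a_1e14": units.kgm2_to_1e14(im.i_a),
        },
        "body": {
            "M_T": summarize(morph_si["m_t"], "mg", 2),
            "L_T": summarize(morph_si["l_t"], "mm", 2),
            "M_A": summarize(morph_si["m_a1"] + morph_si["m_a2"], "μg", 1),
            "L_A": summarize(morph_si["l_a"], "mm", 2),
        },
        "caveat": RECONCILIATION_CAVEAT,
    }

    if "snap_events" in data:
        ev = data["snap_events"]
        perfs = [
            snap_kinematics.performance(
                snap_kinematics.SnapEvent(omega_a=float(r.omega_a), t_a=float(r.t_a)),
                m_a=mandible.m_a, l_a=mandible.l_a, i_a=im.i_a, m_t=m_t_mean,
            )
            for r in ev.itertuples(index=False)
        ]
        omega_mean = float(ev["omega_a"].mean())
        t_a_mean = float(ev["t_a"].mean())
        at_mean = snap_kinematics.performance(
            snap_kinematics.SnapEvent(omega_a=omega_mean, t_a=t_a_mean),
            m_a=mandible.m_a, l_a=mandible.l_a, i_a=im.i_a, m_t=m_t_mean,
        )
        report["ultrahigh_speed"] = {
            "omega_A": summarize([p for p in ev["omega_a"]], "×10⁴ rad/s", 1),
            "V_MT": summarize([p.v_mt for p in perfs], "m/s", 1),
            "alpha_A": summarize([p.alpha_a for p in perfs], "×10⁹ rad/s²", 1),
            "E_A": summarize([p.e_a for p in perfs], "μJ", 1),
            "F_A": summarize([p.f_a for p in perfs], "mN", 1),
            "F_A_per_BW": summarize([p.f_bw for p in perfs], "×10³ BW", 1),
            "at_mean_inputs": {
                "E_A_uJ": units.j_to_uj(at_mean.e_a),
                "F_A_mN": units.n_to_mn(at_mean.f_a),
            },
        }

    if "strike_events" in data:
        analyzed = ball_strike.analyze_events(
            data["strike_events"], morph_si, m_a=mandible.m_a, k=im.k,
        )
        report["ball_strike"] = {
            "E_A": summarize(analyzed["e_a"], "μJ", 1),
            "V_MT": summarize(analyzed["v_mt"], "m/s", 1),
            "F_A": summarize(analyzed["f_a"], "mN", 1),
        }
        angles = analyzed["angle_deg"].dropna()
        if len(angles) >= 3:
            s = ball_strike.strike_angle_summary(angles)
            report["strike_angles"] = {
                "n": s.n,
                "mean_deg": units.round_half_up(s.mean_deg, 1),
                "sd_deg": units.round_half_up(s.sd_deg, 1),
                "min_deg": units.round_half_up(s.min_deg, 1),
                "max_deg": units.round_half_up(s.max_deg, 1),
                "shapiro_w": units.round_half_up(s.w, 2),
                "shapiro_p": units.round_half_up(s.p, 2),
            }
        report["_events_table"] = analyzed  # consumed by write_outputs, not JSON

    if "defence" in data:
        counts = defence_assay.aggregate_trials(data["defence"])
        species_block = {}
        for c in counts:
            hit_p, kill_p = defence_assay.hit_kill_probabilities(c)
            row = {
                "encounters": c.encounters, "attacks": c.attacks, "snaps": c.snaps,
                "hits": c.hits, "kills": c.kills,
                "attack_rate_pct": units.round_half_up(100 * defence_assay.attack_rate(c), 1)
                if c.encounters else None,
                "hit_probability_pct": None if hit_p is None else units.round_half_up(100 * hit_p, 1),
                "kill_probability_pct": None if kill_p is None else units.round_half_up(100 * kill_p, 1),
            }
            if c.immobilised is not None and c.ants:
                row["immobilised_pct"] = units.round_half_up(
                    100 * defence_assay.immobilised_rate(c), 1
                )
            species_block[c.species] = row
        tests = {}
        for outcome in ("hit", "kill"):
            pairs = defence_assay.pairwise_fisher(counts, outcome)
            letters = defence_assay.compact_letter_display(counts, pairs, outcome)
            tests[outcome] = {
                "pairs": pairs.to_dict(orient="records"),
                "letters": letters,
            }
        report["defence"] = {"species": species_block, "pairwise": tests}

    return report


def render_text(report: dict) -> str:
    """Human-readable fixed-width rendering of the report."""
    lines = ["Cohort snap-performance report", "=" * 60]
    for section in ("body", "ultrahigh_speed", "ball_strike"):
        if section not in report:
            continue
        lines.append(f"\n[{section}]")
        for metric, s in report[section].items():
            if not isinstance(s, dict) or "mean" not in s:
                continue
            sd = "—" if s["sd"] is None else s["sd"]
            lines.append(
                f"  {metric:<12} {s['mean']} ± {sd} ({s['min']}–{s['max']}) {s['unit']}"
            )
    if "ultrahigh_speed" in report:
        am = report["ultrahigh_speed"]["at_mean_inputs"]
        lines.append(
            f"  at mean inputs: E_A={am['E_A_uJ']:.1f} μJ, F_A={am['F_A_mN']:.1f} mN"
        )
        lines.append(f"  note: {report['caveat']}")
    if "strike_angles" in report:
        a = report["strike_angles"]
        lines.append(
            f"\n[strike_angles] n={a['n']}, {a['mean_deg']} ± {a['sd_deg']} deg "
            f"({a['min_deg']}–{a['max_deg']}), Shapiro–Wilk W={a['shapiro_w']}, "
            f"p={a['shapiro_p']}"
        )
    if "defence" in report:
        lines.append("\n[defence]")
        for sp, row in report["defence"]["species"].items():
            lines.append(
                f"  {sp:<16} attack {row['attack_rate_pct']}%  "
                f"hit {row['hit_probability_pct']}%  kill {row['kill_probability_pct']}%"
            )
        for outcome, block in report["defence"]["pairwise"].items():
            lines.append(f"  letters ({outcome}): " + ", ".join(
                f"{sp}={ltr}" for sp, ltr in block["letters"].items()
            ))
    return "\n".join(lines) + "\n"


def run_pipeline(config: dict, out_dir: Path | str, base_dir: Path | str = ".") -> dict:
    """Execute the pipeline and write report.json/report.txt plus CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = build_report(config, base_dir)
    events = report.pop("_events_table", None)
    if events is not None:
        ev = pd.DataFrame({
            "individual_id": events["individual_id"],
            "event_id": events["event_id"],
            "e_a_uj": events["e_a"].map(units.j_to_uj),
            "v_mt_m_s": events["v_mt"],
            "f_a_mn": events["f_a"].map(units.n_to_mn),
            "angle_deg": events["angle_deg"],
        })
        ev.to_csv(out_dir / "events.csv", index=False)
        log.info("wrote %s", out_dir / "events.csv")
    if "defence" in report:
        rows = [
            {"species": sp, **row} for sp, row in report["defence"]["species"].items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / "defence.csv", index=False)
        log.info("wrote %s", out_dir / "defence.csv")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "report.txt").write_text(render_text(report))
    log.info("wrote report.json and report.txt to %s", out_dir)
    return report


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg
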