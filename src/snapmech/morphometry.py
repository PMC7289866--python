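"""Inertia estimation for the rotating anterior part of the left mandible.

The anterior part of the twisted left mandible rotates about a functional
pivot.  Its moment of inertia about that pivot is modelled as

    I_A = K · M_A · L_A²

where the dimensionless constant ``K`` corrects the point-mass formula for
the inhomogeneous mass distribution, estimated from two cut subsections:
A1 (distal half) and A2 (proximal half).  The centre of mass of the
anterior part is placed from the subsection masses at their midpoints,

    L_COM = (¼·L_A·M_A2 + ¾·L_A·M_A1) / M_A,

and K places subsection masses at L_COM/2 and (L_COM + L_A)/2:

    K = (M_A2/M_A)·(L_COM/(2·L_A))² + (M_A1/M_A)·((L_COM + L_A)/(2·L_A))².

Note the two-point-mass locations used by K are halves of the COM-based
lever arms, not the subsection midpoints L_A/4 and 3·L_A/4; the formula is
implemented exactly as published, without "correcting" this.

The whole termite body is modelled as a uniform cylinder rotating about
its centre of mass: I_T = M_T·L_T²/12.

All quantities are strict SI (kg, m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from . import units
from .errors import InvalidGeometryError, InvalidMorphometryError, SchemaError

Provenance = Literal["individual", "cohort-mean"]

#: Exact bounds of K over all non-negative mass splits: (1/8)² at all-proximal
#: mass and (7/8)² at all-distal mass.
K_MIN = 1.0 / 64.0
K_MAX = 49.0 / 64.0


@dataclass(frozen=True)
class MandibleMorphometry:
    """Masses and length of the rotating anterior left-mandible part (SI).

    Parameters
    ----------
    m_a1 : float
        Mass of the distal subsection A1, kg.
    m_a2 : float
        Mass of the proximal subsection A2, kg.
    l_a : float
        Length of the anterior rotating part, m.
    provenance : {"individual", "cohort-mean"}
        Whether subsection masses are per-individual measurements or
        cohort means (subsection masses are routinely pooled across
        specimens to suppress weighing error).
    """

    m_a1: float
    m_a2: float
    l_a: float
    provenance: Provenance = "individual"

    def __post_init__(self) -> None:
        if self.m_a1 < 0 or self.m_a2 < 0:
            raise InvalidMorphometryError(
                f"subsection masses must be non-negative, got "
                f"m_a1={self.m_a1!r}, m_a2={self.m_a2!r}"
            )
        if self.m_a1 + self.m_a2 <= 0:
            raise InvalidMorphometryError("total anterior mass must be positive")
        if not self.l_a > 0:
            raise InvalidMorphometryError(f"l_a must be positive, got {self.l_a!r}")

    @property
    def m_a(self) -> float:
        """Total anterior mass M_A = M_A1 + M_A2, kg."""
        return self.m_a1 + self.m_a2


@dataclass(frozen=True)
class InertiaModel:
    """Derived inertia quantities for one mandible: L_COM, K, I_A."""

    l_com: float
    k: float
    i_a: float


@dataclass(frozen=True)
class TermiteBody:
    """Whole-body mass/length with cylinder moment of inertia (SI)."""

    m_t: float
    l_t: float

    def __post_init__(self) -> None:
        if not self.m_t > 0 or not self.l_t > 0:
            raise InvalidMorphometryError(
                f"body mass and length must be positive, got "
                f"m_t={self.m_t!r}, l_t={self.l_t!r}"
            )

    @property
    def i_t(self) -> float:
        """Moment of inertia about the centre of mass, kg·m²."""
        return compute_it(self.m_t, self.l_t)


def compute_lcom(m: MandibleMorphometry) -> float:
    """Centre of mass of the anterior part measured from the pivot, m.

    Subsection masses act at their midpoints L_A/4 (A2, proximal) and
    3·L_A/4 (A1, distal).  The result lies strictly inside
    (L_A/4, 3·L_A/4) except at degenerate single-subsection splits,
    where the bound is attained.
    """
    return (0.25 * m.l_a * m.m_a2 + 0.75 * m.l_a * m.m_a1) / m.m_a


def compute_k(m: MandibleMorphometry, l_com: float | None = None) -> float:
    """Dimensionless inertia-adjustment constant K.

    If ``l_com`` is omitted it is derived via :func:`compute_lcom`.
    """
    if l_com is None:
        l_com = compute_lcom(m)
    if not 0 < l_com < m.l_a:
        raise InvalidGeometryError(
            f"l_com must lie in (0, l_a), got l_com={l_com!r} with l_a={m.l_a!r}"
        )
    w2 = m.m_a2 / m.m_a
    w1 = m.m_a1 / m.m_a
    return w2 * (l_com / (2.0 * m.l_a)) ** 2 + w1 * ((l_com + m.l_a) / (2.0 * m.l_a)) ** 2


def compute_ia(m: MandibleMorphometry, k: float | None = None) -> float:
    """Moment of inertia of the anterior part about the pivot: K·M_A·L_A²."""
    if k is None:
        k = compute_k(m)
    if k < 0:
        raise InvalidGeometryError(f"k must be non-negative, got {k!r}")
    return k * m.m_a * m.l_a**2


def compute_it(m_t: float, l_t: float) -> float:
    """Whole-body moment of inertia of a uniform cylinder: M_T·L_T²/12."""
    if not m_t > 0 or not l_t > 0:
        raise InvalidMorphometryError(
            f"m_t and l_t must be positive, got m_t={m_t!r}, l_t={l_t!r}"
        )
    return m_t * l_t**2 / 12.0


def inertia_model(m: MandibleMorphometry) -> InertiaModel:
    """Full derived chain L_COM -> K -> I_A for one morphometry."""
    l_com = compute_lcom(m)
    k = compute_k(m, l_com)
    return InertiaModel(l_com=l_com, k=k, i_a=compute_ia(m, k))


MORPHOMETRY_COLUMNS = ["individual_id", "m_t_mg", "l_t_mm", "m_a1_ug", "m_a2_ug", "l_a_mm"]


def read_morphometry_csv(path) -> pd.DataFrame:
    """Read a morphometry table and convert to SI columns.

    Input columns (header required): individual_id, m_t_mg, l_t_mm,
    m_a1_ug, m_a2_ug, l_a_mm.  Returns a frame with individual_id plus
    SI columns m_t, l_t, m_a1, m_a2, l_a (kg / m).
    """
    df = pd.read_csv(path)
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing morphometry column(s): {', '.join(missing)}")
    out = pd.DataFrame({
        "individual_id": df["individual_id"],
        "m_t": df["m_t_mg"].map(units.mg_to_kg),
        "l_t": df["l_t_mm"].map(units.mm_to_m),
        "m_a1": df["m_a1_ug"].map(units.ug_to_kg),
        "m_a2": df["m_a2_ug"].map(units.ug_to_kg),
        "l_a": df["l_a_mm"].map(units.mm_to_m),
    })
    bad = out[(out[["m_t", "l_t", "l_a"]] <= 0).any(axis=1) | (out[["m_a1", "m_a2"]] < 0).any(axis=1)]
    if not bad.empty:
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad.index)
        raise SchemaError(f"{path}: non-positive measurement(s) at line(s) {lines}")
    return out


def two_point_inertia(m: MandibleMorphometry, l_com: float | None = None) -> float:
    """I_A written directly as the two-point-mass sum (algebraic mirror).

    Equals ``compute_ia(m, compute_k(m))`` identically:
    M_A2·(L_COM/2)² + M_A1·((L_COM + L_A)/2)².  Exposed so callers can
    sanity-check the K-based route without re-deriving the algebra.
    """
    if l_com is None:
        l_com = compute_lcom(m)
    return m.m_a2 * (l_com / 2.0) ** 2 + m.m_a1 * ((l_com + m.l_a) / 2.0) ** 2


def distal_mass_fraction(m: MandibleMorphometry) -> float:
    """m_a1 / m_a — K is strictly increasing in this fraction."""
    return m.m_a1 / m.m_a


def check_k_bounds(k: float, rel_tol: float = 1e-12) -> bool:
    """True iff K lies in [1/64, 49/64] up to floating slack."""
    return K_MIN * (1 - rel_tol) <= k <= K_MAX * (1 + rel_tol)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def describe(m: MandibleMorphometry) -> str:
    """One-line human-readable summary (report plumbing)."""
    im = inertia_model(m)
    return (
        f"M_A={units.kg_to_ug(m.m_a):.6g} ug, L_A={units.m_to_mm(m.l_a):.6g} mm, "
        f"L_COM={units.m_to_mm(im.l_com):.6g} mm, K={_fmt(im.k)}, "
        f"I_A={units.kgm2_to_1e14(im.i_a):.6g} x1e-14 kg.m2"
    )
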