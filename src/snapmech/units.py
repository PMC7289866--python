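"""Unit conversion helpers.

All internal computation is strict SI (kg, m, s, J, N, rad/s).  Reporting
uses the mixed scales conventional in the comparative-biomechanics
literature (mg, mm, μg, μs, μJ, mN, ×10⁴ rad/s, ×10⁹ rad/s², ×10⁻¹⁴
kg·m², ×10³ body weights).  Every conversion crossing that boundary goes
through a named converter below so that report units stay auditable.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: standard gravity, m/s² (used for force-to-body-weight ratios)
G = 9.81

# ---- input converters: paper/report units -> SI ----------------------------


def ug_to_kg(x: float) -> float:
    """Micrograms to kilograms."""
    return x * 1e-9


def mg_to_kg(x: float) -> float:
    """Milligrams to kilograms."""
    return x * 1e-6


def mm_to_m(x: float) -> float:
    """Millimetres to metres."""
    return x * 1e-3


def us_to_s(x: float) -> float:
    """Microseconds to seconds."""
    return x * 1e-6


def ms_to_s(x: float) -> float:
    """Milliseconds to seconds."""
    return x * 1e-3


# ---- output converters: SI -> paper/report units ---------------------------


def kg_to_mg(x: float) -> float:
    return x * 1e6


def kg_to_ug(x: float) -> float:
    return x * 1e9


def m_to_mm(x: float) -> float:
    return x * 1e3


def s_to_us(x: float) -> float:
    return x * 1e6


def s_to_ms(x: float) -> float:
    return x * 1e3


def j_to_uj(x: float) -> float:
    return x * 1e6


def n_to_mn(x: float) -> float:
    return x * 1e3


def kgm2_to_1e14(x: float) -> float:
    """kg·m² to units of 10⁻¹⁴ kg·m² (inertia reporting scale)."""
    return x * 1e14


def rad_s_to_1e4(x: float) -> float:
    """rad/s to units of 10⁴ rad/s (angular-velocity reporting scale)."""
    return x * 1e-4


def rad_s2_to_1e9(x: float) -> float:
    """rad/s² to units of 10⁹ rad/s² (angular-acceleration reporting scale)."""
    return x * 1e-9


def ratio_to_1e3(x: float) -> float:
    """Dimensionless ratio to units of 10³ (body-weight reporting scale)."""
    return x * 1e-3


def identity(x: float) -> float:
    return x


#: Registry mapping report unit labels to the SI->report converter used.
#: The unit-audit test walks report rows and checks each label resolves here
#: and that the converter round-trips against its inverse factor.
REPORT_CONVERTERS = {
    "mg": kg_to_mg,
    "μg": kg_to_ug,
    "mm": m_to_mm,
    "μs": s_to_us,
    "ms": s_to_ms,
    "μJ": j_to_uj,
    "mN": n_to_mn,
    "×10⁻¹⁴ kg·m²": kgm2_to_1e14,
    "×10⁴ rad/s": rad_s_to_1e4,
    "×10⁹ rad/s²": rad_s2_to_1e9,
    "×10³ BW": ratio_to_1e3,
    "m/s": identity,
    "deg": identity,
    "%": identity,
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention).

    Python's built-in ``round`` is banker's rounding; report tables use
    ordinary half-up instead so e.g. 111.05 -> 111.1.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> float:
    """Plain percentage, no rounding."""
    return 100.0 * numerator / denominator
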