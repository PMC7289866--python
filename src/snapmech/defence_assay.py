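"""Defence-assay statistics: attack/hit/kill rates and pairwise exact tests.

Counts are pooled across fight trials per ant species.  Rates are simple
ratios (attacks/encounters, hits/snaps, kills/hits).  Species are compared
pairwise with two-sided Fisher's exact tests using the point-probability
definition (sum of hypergeometric probabilities not exceeding the observed
table's), Bonferroni-adjusted within one outcome family, and labelled with
a compact letter display at α = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import SchemaError, UndefinedRateError

#: Relative slack when comparing floating hypergeometric probabilities to the
#: observed table's probability (handles symmetric exact ties).
_TIE_REL_TOL = 1e-9


@dataclass(frozen=True)
class DefenceCounts:
    """Pooled per-species counts from fight trials.

    ``ants`` is the number of ant individuals exposed (trials × ants per
    trial), the denominator for the immobilisation proportion.
    """

    species: str
    encounters: int
    attacks: int
    snaps: int
    hits: int
    kills: int
    immobilised: int | None = None
    ants: int | None = None

    def __post_init__(self) -> None:
        if min(self.encounters, self.attacks, self.snaps, self.hits, self.kills) < 0:
            raise ValueError("counts must be non-negative")
        if self.attacks > self.encounters:
            raise ValueError(
                f"{self.species}: attacks ({self.attacks}) exceed encounters "
                f"({self.encounters})"
            )
        if self.hits > self.snaps:
            raise ValueError(f"{self.species}: hits ({self.hits}) exceed snaps ({self.snaps})")
        if self.kills > self.hits:
            raise ValueError(f"{self.species}: kills ({self.kills}) exceed hits ({self.hits})")


def attack_rate(c: DefenceCounts) -> float:
    """Attacks per encounter, as a proportion in [0, 1]."""
    if c.encounters == 0:
        raise UndefinedRateError(f"{c.species}: no encounters recorded")
    return c.attacks / c.encounters


def hit_kill_probabilities(c: DefenceCounts) -> tuple[float | None, float | None]:
    """(hits/snaps, kills/hits); a ratio is None when its denominator is 0."""
    hit_p = c.hits / c.snaps if c.snaps > 0 else None
    kill_p = c.kills / c.hits if c.hits > 0 else None
    return hit_p, kill_p


def immobilised_rate(c: DefenceCounts) -> float:
    """Immobilised ants per ant individual exposed."""
    if c.immobilised is None or c.ants is None:
        raise UndefinedRateError(f"{c.species}: immobilised/ants counts not recorded")
    if c.ants == 0:
        raise UndefinedRateError(f"{c.species}: zero ants exposed")
    return c.immobilised / c.ants


def two_sided_p_values(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p for every table with margins (r1, r2) × (c1, ·).

    For fixed margins the table is determined by its top-left cell ``a``,
    ranging over max(0, c1-r2)..min(r1, c1).  Returns the p-value for each
    ``a`` in that order: the sum of hypergeometric probabilities that do
    not exceed the probability of the observed table (with a small
    relative slack for exact ties).
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    # sort-and-cumsum: p(a) = sum of pmf values <= pmf(a)·(1+tol)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    thresholds = pmf * (1.0 + _TIE_REL_TOL)
    idx = np.searchsorted(pmf[order], thresholds, side="right") - 1
    return np.minimum(csum[idx], 1.0)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table [[a, b], [c, d]]."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"table entries must be non-negative integers, got {table!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    return float(two_sided_p_values(r1, r2, c1)[a - lo])


def bonferroni(p: float, m: int) -> float:
    """min(1, m·p)."""
    return min(1.0, m * p)


_OUTCOME_FIELDS = {
    "attack": ("attacks", "encounters"),
    "hit": ("hits", "snaps"),
    "kill": ("kills", "hits"),
}


def pairwise_fisher(counts: list[DefenceCounts], outcome: str) -> pd.DataFrame:
    """All pairwise two-sided Fisher tests for one outcome, Bonferroni-adjusted.

    ``outcome`` is one of "attack" (attacks/encounters), "hit" (hits/snaps)
    or "kill" (kills/hits).  Pairs where either species has a zero
    denominator are skipped (recorded with NaN p-values).  The Bonferroni
    family is the set of all pairs within this one outcome.
    """
    if outcome not in _OUTCOME_FIELDS:
        raise ValueError(f"outcome must be one of {sorted(_OUTCOME_FIELDS)}, got {outcome!r}")
    if len(counts) < 2:
        raise ValueError("need at least 2 species to compare")
    num_field, den_field = _OUTCOME_FIELDS[outcome]
    m = len(counts) * (len(counts) - 1) // 2
    rows = []
    for ca, cb in itertools.combinations(counts, 2):
        na, da = getattr(ca, num_field), getattr(ca, den_field)
        nb, db = getattr(cb, num_field), getattr(cb, den_field)
        if da == 0 or db == 0:
            rows.append({
                "species_a": ca.species, "species_b": cb.species,
                "p_raw": np.nan, "p_adj": np.nan, "skipped": True,
            })
            continue
        p = fisher_exact_two_sided([[na, da - na], [nb, db - nb]])
        rows.append({
            "species_a": ca.species, "species_b": cb.species,
            "p_raw": p, "p_adj": bonferroni(p, m), "skipped": False,
        })
    return pd.DataFrame(rows)


def compact_letter_display(
    counts: list[DefenceCounts], pairs: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> dict[str, str]:
    """Letter groupings: species sharing a letter are not significantly
    different at ``alpha`` on the adjusted p-values (insert-and-absorb)."""
    num_field, den_field = _OUTCOME_FIELDS[outcome]

    def rate(c: DefenceCounts) -> float:
        d = getattr(c, den_field)
        return getattr(c, num_field) / d if d > 0 else -1.0

    species = [c.species for c in sorted(counts, key=rate, reverse=True)]
    differ = [
        (rec.species_a, rec.species_b)
        for rec in pairs.itertuples(index=False)
        if not rec.skipped and rec.p_adj < alpha
    ]

    def absorb(groups: list[set[str]]) -> list[set[str]]:
        return [
            g for i, g in enumerate(groups)
            if not any(i != j and g <= h for j, h in enumerate(groups) if not (j < i and h == g))
        ]

    # insert-and-absorb: split every group that joins a significant pair
    groups: list[set[str]] = [set(species)]
    for a, b in differ:
        nxt: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        groups = absorb(nxt)
    groups.sort(key=lambda g: min(species.index(sp) for sp in g))
    letters = {sp: "" for sp in species}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for sp in sorted(g, key=species.index):
            letters[sp] += letter
    return {sp: "".join(sorted(letters[sp])) for sp in species}


DEFENCE_COLUMNS = ["species", "trial_id", "encounters", "attacks", "snaps", "hits", "kills"]


def read_defence_csv(path) -> pd.DataFrame:
    """Read a per-trial defence table; immobilised and ants are optional."""
    df = pd.read_csv(path)
    missing = [c for c in DEFENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing defence column(s): {', '.join(missing)}")
    return df


def aggregate_trials(df: pd.DataFrame) -> list[DefenceCounts]:
    """Pool per-trial counts into one DefenceCounts per species."""
    out = []
    for species, grp in df.groupby("species", sort=False):
        out.append(DefenceCounts(
            species=str(species),
            encounters=int(grp["encounters"].sum()),
            attacks=int(grp["attacks"].sum()),
            snaps=int(grp["snaps"].sum()),
            hits=int(grp["hits"].sum()),
            kills=int(grp["kills"].sum()),
            immobilised=int(grp["immobilised"].sum()) if "immobilised" in grp.columns else None,
            ants=int(grp["ants"].sum()) if "ants" in grp.columns else None,
        ))
    return out
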