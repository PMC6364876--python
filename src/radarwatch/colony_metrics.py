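"""Colony-level condition and diet summaries.

Body condition of an adult is mass over wing length (g/mm), a standard
size-corrected condition index for gannets. Chick growth rate is the mean of
per-interval mass changes (g/day) over consecutive measurements during the
linear growth phase. Diet composition is percent frequency of occurrence: the
share of regurgitation samples containing each prey taxon (columns can sum to
more than 100% when samples hold several taxa).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError


@dataclass
class AdultMeasure:
    bird_id: str
    mass_g: float  # +/- 10 g field precision
    wing_mm: float  # +/- 1 mm

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.wing_mm <= 0:
            raise ValueError("wing_mm must be > 0")


@dataclass
class ChickSeries:
    chick_id: str
    dates: list  # date-like, strictly increasing
    masses_g: list

    def __post_init__(self) -> None:
        d = pd.to_datetime(pd.Series(self.dates))
        if len(d) != len(self.masses_g):
            raise ValueError("dates and masses must align")
        if len(d) > 1 and not d.is_monotonic_increasing or d.duplicated().any():
            raise ValueError("measurement dates must be strictly increasing")


@dataclass
class DietSample:
    sample_id: str
    date: object
    species: list[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("diet sample must contain >=1 identified taxon")


def body_condition(mass_g, wing_mm):
    """Condition index mass/wing in g/mm; scalar or vectorised."""
    mass = np.asarray(mass_g, dtype=float)
    wing = np.asarray(wing_mm, dtype=float)
    if np.any(wing <= 0) or np.any(mass <= 0):
        raise ValueError("mass and wing length must be > 0")
    out = mass / wing
    return float(out) if out.ndim == 0 else out


def growth_rate(c: ChickSeries) -> float:
    """Mean of per-interval (delta mass / delta days) over consecutive pairs.

    Note this average weights each interval equally, not by its length —
    with unequal intervals it is not the overall slope.
    """
    if len(c.masses_g) < 2:
        raise InsufficientDataError(f"chick {c.chick_id}: need >=2 measurements")
    d = pd.to_datetime(pd.Series(c.dates))
    days = d.diff().dt.total_seconds().to_numpy()[1:] / 86400.0
    dm = np.diff(np.asarray(c.masses_g, dtype=float))
    return float(np.mean(dm / days))


def growth_rate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-chick growth rates from a long table (chick_id, date, mass_g)."""
    rows = []
    for cid, g in df.sort_values("date").groupby("chick_id"):
        if len(g) < 2:
            continue
        rows.append(
            {
                "chick_id": cid,
                "n_measurements": len(g),
                "growth_g_per_day": growth_rate(
                    ChickSeries(str(cid), list(g["date"]), list(g["mass_g"]))
                ),
            }
        )
    return pd.DataFrame(rows)


def diet_composition(samples: list[DietSample] | pd.DataFrame) -> pd.Series:
    """Percent frequency of occurrence per prey taxon.

    Accepts a list of :class:`DietSample` or a long DataFrame with columns
    (sample_id, species). Occurrence is per sample: a taxon listed twice in
    one sample counts once.
    """
    if isinstance(samples, pd.DataFrame):
        if len(samples) == 0:
            raise InsufficientDataError("no diet samples")
        n = samples["sample_id"].nunique()
        occ = samples.drop_duplicates(["sample_id", "species"]).groupby("species").size()
    else:
        if not samples:
            raise InsufficientDataError("no diet samples")
        n = len(samples)
        occ = pd.Series(
            [sp for s in samples for sp in set(s.species)], dtype=object
        ).value_counts()
        occ.index.name = "species"
    return (100.0 * occ / n).sort_values(ascending=False).rename("percent_occurrence")
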