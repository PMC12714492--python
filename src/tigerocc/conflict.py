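"""Rescue-conflict association analysis on 2x2 km buffer subgrids.

Subgrids in the buffer zone are classified high/low on posterior tiger use,
prey use and (log-floored) human population density by strict comparison
against fixed thresholds (defaults are the buffer-wide means: tiger use
0.54, prey use 0.80, 141 persons/km^2).  Rescue *presence* per subgrid
(>= 1 rescue counts once) is cross-tabulated against each classification in
2x2 contingency tables; association is tested with the one-sided Z-test on
the log odds ratio, and homogeneity of odds ratios across strata with
Woolf's inverse-variance chi-square test (Breslow-Day available as an
option via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "Thresholds", "TwoByTwo", "StratifiedTables", "classify_subgrids",
    "build_table", "rescue_presence", "odds_ratio", "log_or_test",
    "homogeneity_test", "marginal_association", "naive_occupancy",
    "thresholds_from_data", "OddsRatioTest", "HomogeneityResult",
]


@dataclass(frozen=True)
class Thresholds:
    """High/low cutpoints; a cell is "high" when strictly above the cut."""

    tiger_use_cut: float = 0.54
    prey_use_cut: float = 0.80
    pop_cut: float = 141.0

    def __post_init__(self) -> None:
        for name in ("tiger_use_cut", "prey_use_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.pop_cut <= 0:
            raise ValueError("pop_cut must be positive")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: a = exposed & event, b = unexposed & event,
    c = exposed & no event, d = unexposed & no event."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def continuity_corrected(self) -> "TwoByTwo":
        """Haldane-Anscombe correction: 0.5 added to every cell."""
        return TwoByTwo(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def swap_exposure(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


StratifiedTables = Sequence[tuple[str, TwoByTwo]]


@dataclass(frozen=True)
class OddsRatioTest:
    odds_ratio: float
    log_or: float
    se: float
    z: float
    p: float
    alternative: str


@dataclass(frozen=True)
class HomogeneityResult:
    chi2: float
    df: int
    p: float
    method: str
    stratum_ors: dict[str, float]
    pooled_log_or: float | None = None


def _checked(table: TwoByTwo, continuity: bool) -> TwoByTwo:
    if table.has_zero_cell:
        if not continuity:
            raise ValueError(
                "table has a zero cell; pass continuity=True to apply the "
                "0.5 correction")
        return table.continuity_corrected()
    return table


def odds_ratio(table: TwoByTwo, continuity: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c)."""
    t = _checked(table, continuity)
    return (t.a * t.d) / (t.b * t.c)


def log_or_test(table: TwoByTwo, alternative: str = "greater",
                continuity: bool = False) -> OddsRatioTest:
    """Z-test for the log odds ratio with the asymptotic SE
    sqrt(1/a + 1/b + 1/c + 1/d)."""
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    t = _checked(table, continuity)
    log_or = float(np.log((t.a * t.d) / (t.b * t.c)))
    se = float(np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d))
    z = log_or / se
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2 * norm.sf(abs(z)))
    return OddsRatioTest(float(np.exp(log_or)), log_or, se, z, p, alternative)


def homogeneity_test(strata: StratifiedTables, method: str = "woolf",
                     continuity: bool = False) -> HomogeneityResult:
    """Test whether the odds ratio is constant across strata.

    ``woolf`` (default): inverse-variance weights w_k = 1/(1/a+1/b+1/c+1/d),
    pooled log-OR the weighted mean, chi-square sum of weighted squared
    deviations on (K-1) df.  ``breslow-day``: delegated to statsmodels.
    """
    strata = list(strata)
    if len(strata) < 2:
        raise ValueError("homogeneity testing needs at least 2 strata")
    tables = [(label, _checked(t, continuity)) for label, t in strata]
    ors = {label: (t.a * t.d) / (t.b * t.c) for label, t in tables}
    if method == "woolf":
        log_ors = np.array([np.log(o) for o in ors.values()])
        w = np.array([1 / (1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
                      for _, t in tables])
        pooled = float((w * log_ors).sum() / w.sum())
        stat = float((w * (log_ors - pooled) ** 2).sum())
        df = len(tables) - 1
        return HomogeneityResult(stat, df, float(chi2_dist.sf(stat, df)),
                                 "woolf", ors, pooled)
    if method == "breslow-day":
        from statsmodels.stats.contingency_tables import StratifiedTable
        st = StratifiedTable([t.to_array() for _, t in tables])
        res = st.test_equal_odds()
        return HomogeneityResult(float(res.statistic), len(tables) - 1,
                                 float(res.pvalue), "breslow-day", ors)
    raise ValueError(f"unknown method {method!r}")


def marginal_association(strata: StratifiedTables) -> tuple[TwoByTwo, float]:
    """Collapse the event dimension to the exposure-by-stratum 2x2.

    For two strata this yields the table of exposure level against stratum
    membership (e.g. prey use against population level) and its odds ratio.
    """
    strata = list(strata)
    if len(strata) != 2:
        raise ValueError("marginal exposure-by-stratum table needs exactly "
                         f"2 strata, got {len(strata)}")
    (_, t1), (_, t2) = strata
    for label, t in strata:
        if t.total <= 0:
            raise ValueError(f"stratum {label!r} is empty")
    table = TwoByTwo(a=t1.a + t1.c, b=t2.a + t2.c,
                     c=t1.b + t1.d, d=t2.b + t2.d)
    return table, odds_ratio(table)


def naive_occupancy(detected_grids: int, surveyed_grids: int) -> float:
    """Fraction of surveyed grids with >= 1 detection (no detection
    correction)."""
    if surveyed_grids <= 0:
        raise ValueError("surveyed_grids must be positive")
    if not 0 <= detected_grids <= surveyed_grids:
        raise ValueError("detected_grids must be in [0, surveyed_grids]")
    return detected_grids / surveyed_grids


def classify_subgrids(
    use_map: pd.DataFrame,
    population: pd.Series,
    thresholds: Thresholds = Thresholds(),
    buffer_only: bool = True,
    buffer_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """High/low labels per subgrid for tiger use, prey use and population.

    ``use_map`` needs columns ``p_tiger_use, p_prey_use`` (and
    ``in_buffer`` unless ``buffer_flags`` is supplied) indexed by
    subgrid_id; ``population`` is raw persons/km^2 on the same index.
    Labels use strict ``>`` so a value exactly at a cut is "low".
    """
    missing = set(use_map.index).symmetric_difference(population.index)
    if missing:
        raise ValueError(
            f"use map and population cover different cells: {sorted(missing)[:10]}")
    df = use_map.copy()
    df["population"] = population.loc[df.index]
    if buffer_only:
        flags = buffer_flags if buffer_flags is not None else df.get("in_buffer")
        if flags is None:
            raise ValueError("buffer_only=True requires an in_buffer column "
                             "or buffer_flags")
        df = df.loc[flags.loc[df.index].astype(bool)]
    return pd.DataFrame({
        "high_tiger": df["p_tiger_use"] > thresholds.tiger_use_cut,
        "high_prey": df["p_prey_use"] > thresholds.prey_use_cut,
        "high_pop": df["population"] > thresholds.pop_cut,
    }, index=df.index)


def thresholds_from_data(use_map: pd.DataFrame,
                         population: pd.Series,
                         buffer_flags: pd.Series | None = None) -> Thresholds:
    """Recompute the cutpoints as means over the (buffer) cells."""
    df = use_map.copy()
    df["population"] = population.loc[df.index]
    if buffer_flags is not None:
        df = df.loc[buffer_flags.loc[df.index].astype(bool)]
    return Thresholds(float(df["p_tiger_use"].mean()),
                      float(df["p_prey_use"].mean()),
                      float(df["population"].mean()))


def rescue_presence(rescues: pd.DataFrame, cells: pd.Index) -> pd.Series:
    """Presence indicator per cell: True where >= 1 rescue was recorded.

    Rescues with missing subgrid ids, or in cells outside ``cells``, are
    ignored.
    """
    hit = set(rescues["subgrid_id"].dropna().astype(str))
    return pd.Series([c in hit for c in cells], index=cells, name="rescue")


def build_table(exposure: pd.Series, events: pd.Series) -> TwoByTwo:
    """Cross-tabulate a binary exposure against event presence per cell."""
    if not exposure.index.equals(events.index):
        if set(exposure.index) != set(events.index):
            raise ValueError("exposure and event series cover different cells")
        events = events.loc[exposure.index]
    e = exposure.astype(bool).to_numpy()
    v = events.astype(bool).to_numpy()
    return TwoByTwo(
        a=int(np.sum(e & v)), b=int(np.sum(~e & v)),
        c=int(np.sum(e & ~v)), d=int(np.sum(~e & ~v)),
    )
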