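"""Published rescue-association summary tables for the Chitwan-Parsa buffer.

These constants encode the reported 2020-2024 rescue contingency tables for
the 407 buffer-zone subgrids — cell counts of subgrids with/without tiger
rescues, cross-classified against high/low tiger use, prey use and human
population density, plus the prey-use-by-population stratification and the
rescued-tiger demographics.  They let the conflict analysis run and be
demonstrated with no external downloads.

``write_conflict_fixture`` additionally materialises a *synthetic*
cell-level reconstruction whose marginal tables equal the published ones
(the joint arrangement across classifications is not published and is
assigned arbitrarily), for exercising the classify/tabulate pipeline end
to end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .conflict import Thresholds, TwoByTwo

__all__ = [
    "TIGER_USE_TABLE", "POPULATION_TABLE", "PREY_USE_TABLE",
    "PREY_BY_POPULATION_STRATA", "RESCUE_DEMOGRAPHICS",
    "DEFAULT_THRESHOLDS", "TOTAL_GRIDS", "SURVEYED_GRIDS",
    "GRIDS_WITH_TIGER_DETECTIONS", "N_BUFFER_SUBGRIDS",
    "write_conflict_fixture",
]

# subgrids with / without rescues, by high/low classification
TIGER_USE_TABLE = TwoByTwo(a=11, b=5, c=197, d=194)
POPULATION_TABLE = TwoByTwo(a=10, b=6, c=236, d=155)
PREY_USE_TABLE = TwoByTwo(a=13, b=3, c=208, d=183)

# prey-use tables within population-density strata
PREY_BY_POPULATION_STRATA = (
    ("low_population", TwoByTwo(a=5, b=1, c=145, d=10)),
    ("high_population", TwoByTwo(a=8, b=2, c=63, d=173)),
)

# age class x sex of the 32 rescued tigers (four males of unknown age)
RESCUE_DEMOGRAPHICS = pd.DataFrame(
    {"adult": [7, 17], "cub": [2, 1], "subadult": [0, 1], "unknown": [0, 4]},
    index=pd.Index(["female", "male"], name="sex"),
)

DEFAULT_THRESHOLDS = Thresholds(tiger_use_cut=0.54, prey_use_cut=0.80,
                                pop_cut=141.0)

TOTAL_GRIDS = 62
SURVEYED_GRIDS = 57
GRIDS_WITH_TIGER_DETECTIONS = 36
N_BUFFER_SUBGRIDS = 407


def _cells_from_strata() -> pd.DataFrame:
    """Synthetic cell-level reconstruction of the buffer subgrids.

    Prey use, population level and rescue presence come jointly from the
    stratified tables; the tiger-use labels are assigned independently to
    match the tiger-use marginal table only (the published data do not
    constrain the joint distribution).
    """
    rows = []
    for label, t in PREY_BY_POPULATION_STRATA:
        high_pop = label == "high_population"
        for prey, rescue, count in (
                (True, True, t.a), (False, True, t.b),
                (True, False, t.c), (False, False, t.d)):
            rows.extend({"high_pop": high_pop, "high_prey": prey,
                         "rescue": rescue} for _ in range(int(count)))
    df = pd.DataFrame(rows)
    # tiger-use labels: 11 of the 16 rescue cells and 197 of the 391
    # non-rescue cells are high tiger use, matching the marginal table
    df["high_tiger"] = False
    df.loc[df.index[df["rescue"]][:TIGER_USE_TABLE.a], "high_tiger"] = True
    df.loc[df.index[~df["rescue"]][:TIGER_USE_TABLE.c], "high_tiger"] = True
    df.index = pd.Index([f"B{i:03d}" for i in range(len(df))],
                        name="subgrid_id")
    return df


def write_conflict_fixture(directory: str | Path,
                           seed: int = 0) -> dict[str, Path]:
    """Write synthetic per-subgrid CSVs consistent with the published tables.

    Produces ``use_map.csv`` (posterior-style use probabilities placed on
    either side of the default thresholds), ``population.csv`` (raw
    persons/km^2) and ``rescues.csv`` (one dated rescue event per rescue
    cell).  Values within the high/low classes are arbitrary; only the
    classifications are meaningful.
    """
    rng = np.random.default_rng(seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells = _cells_from_strata()
    th = DEFAULT_THRESHOLDS

    def place(high: pd.Series, cut: float, lo: float, hi: float) -> np.ndarray:
        v = np.where(high, rng.uniform(cut + 1e-6, hi, len(high)),
                     rng.uniform(lo, cut, len(high)))
        return v

    use_map = pd.DataFrame({
        "p_tiger_use": place(cells["high_tiger"], th.tiger_use_cut, 0.05, 0.99),
        "p_prey_use": place(cells["high_prey"], th.prey_use_cut, 0.05, 0.99),
        "in_buffer": True,
    }, index=cells.index)
    population = pd.Series(
        place(cells["high_pop"], th.pop_cut, 11.0, 2000.0),
        index=cells.index, name="population")

    rescue_cells = cells.index[cells["rescue"]]
    dates = pd.to_datetime("2020-01-15") + pd.to_timedelta(
        rng.integers(0, 4 * 365, len(rescue_cells)), unit="D")
    rescues = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "subgrid_id": rescue_cells,
        "sex": rng.choice(["female", "male"], len(rescue_cells)),
        "age_class": rng.choice(["adult", "subadult", "cub"], len(rescue_cells)),
    })

    paths = {
        "use_map": directory / "use_map.csv",
        "population": directory / "population.csv",
        "rescues": directory / "rescues.csv",
    }
    use_map.reset_index().to_csv(paths["use_map"], index=False)
    population.reset_index().to_csv(paths["population"], index=False)
    rescues.to_csv(paths["rescues"], index=False)
    return paths
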