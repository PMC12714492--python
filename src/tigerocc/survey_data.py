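"""Sign-survey data containers, readers/writers and covariate preparation.

The survey design partitions the landscape into large 10 km x 10 km grids,
each divided into up to 25 subgrids of 2 km x 2 km.  Survey teams walk up to
40 km of trail per grid, recording tiger and prey sign every 100 m, so a
subgrid's *effort* is the number of 100-m segments walked within it (at most
400 per grid) and its detections are counts bounded by effort.

Covariate preparation mirrors standard occupancy-analysis practice:

* human population density is floored at the minimum observed nonzero
  density (11 persons/km^2) and log10-transformed;
* prey for unvisited grids is imputed as the mean over adjacent visited
  grids (adjacency supplied explicitly, conventionally 8-neighbour);
* every covariate is centred and scaled (sample sd) separately at the grid
  and subgrid scale, with the scaling recorded so it can be inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = (
    "grid_id", "subgrid_id", "effort", "tiger_det", "prey_det",
    "ndvi", "hpd", "elev", "in_buffer",
)
GRID_COLUMNS = ("grid_id", "prey_km", "ndvi", "hpd", "elev", "surveyed")
RESCUE_COLUMNS = ("date", "subgrid_id", "sex", "age_class")

GRID_COVARIATES = ("prey_km", "ndvi", "hpd", "elev")
SUBGRID_COVARIATES = ("ndvi", "hpd", "elev")

MAX_SUBGRIDS_PER_GRID = 25      # 2-km cells tiling a 10-km cell
MAX_EFFORT_PER_GRID = 400       # 40 km of trail at 100-m recording intervals

SEXES = ("female", "male", "unknown")
AGE_CLASSES = ("adult", "subadult", "cub", "unknown")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """Rows violate a dataset invariant."""


@dataclass
class SurveyDataset:
    """Grid- and subgrid-level survey tables plus the covariate scaling record.

    ``grids`` is indexed by ``grid_id`` with columns ``prey_km, ndvi, hpd,
    elev, surveyed``; ``subgrids`` is indexed by ``subgrid_id`` with columns
    ``grid_id, effort, tiger_det, prey_det, ndvi, hpd, elev, in_buffer``.
    ``scaling`` maps ``"<scale>:<field>"`` to the ``(mean, sd)`` removed by
    :func:`standardize_covariates`; it is ``None`` until standardization.
    """

    grids: pd.DataFrame
    subgrids: pd.DataFrame
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def n_grids(self) -> int:
        return len(self.grids)

    @property
    def n_subgrids(self) -> int:
        return len(self.subgrids)

    @property
    def standardized(self) -> bool:
        return self.scaling is not None

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            self.grids.copy(), self.subgrids.copy(),
            dict(self.scaling) if self.scaling is not None else None,
        )

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        problems: list[str] = []
        g, s = self.grids, self.subgrids
        if g.index.has_duplicates:
            dup = g.index[g.index.duplicated()].unique().tolist()
            problems.append(f"duplicate grid_id values: {dup}")
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()].unique().tolist()
            problems.append(f"duplicate subgrid_id values: {dup}")
        for row, (sid, rec) in enumerate(s.iterrows()):
            if rec["grid_id"] not in g.index:
                problems.append(
                    f"row {row} (subgrid {sid}): unknown grid_id {rec['grid_id']!r}")
            if rec["effort"] < 0:
                problems.append(f"row {row} (subgrid {sid}): negative effort")
            for col in ("tiger_det", "prey_det"):
                if rec[col] < 0:
                    problems.append(f"row {row} (subgrid {sid}): negative {col}")
                elif rec[col] > rec["effort"]:
                    problems.append(
                        f"row {row} (subgrid {sid}): {col}={rec[col]} exceeds "
                        f"effort={rec['effort']}")
        counts = s.groupby("grid_id").size()
        for gid, n in counts.items():
            if n > MAX_SUBGRIDS_PER_GRID:
                problems.append(
                    f"grid {gid}: {n} subgrids exceeds {MAX_SUBGRIDS_PER_GRID}")
        tot = s.groupby("grid_id")["effort"].sum()
        for gid, e in tot.items():
            if e > MAX_EFFORT_PER_GRID:
                problems.append(
                    f"grid {gid}: total effort {e} exceeds {MAX_EFFORT_PER_GRID} "
                    "segments (40 km at 100 m)")
        if problems:
            raise ValidationError(
                "survey dataset failed validation:\n  " + "\n  ".join(problems))


def _require_columns(df: pd.DataFrame, required: Sequence[str], origin: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{origin}: missing column(s) {missing}")


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names (schema maps canonical -> file)."""
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def load_survey(
    survey_path: str | Path,
    grids_path: str | Path,
    schema: Mapping[str, str] | None = None,
    scaling_path: str | Path | None = None,
    validate: bool = True,
) -> SurveyDataset:
    """Load and validate the subgrid survey table and grid covariate table.

    ``schema`` maps canonical column names to the names used in the files.
    If ``scaling_path`` is given (or a ``scaling.csv`` sits beside the survey
    file), the recorded covariate scaling is attached.
    """
    sub = _apply_schema(pd.read_csv(survey_path), schema)
    _require_columns(sub, SURVEY_COLUMNS, str(survey_path))
    grids = _apply_schema(pd.read_csv(grids_path), schema)
    _require_columns(grids, GRID_COLUMNS, str(grids_path))

    sub = sub.astype({
        "grid_id": str, "subgrid_id": str, "effort": int,
        "tiger_det": int, "prey_det": int,
        "ndvi": float, "hpd": float, "elev": float, "in_buffer": bool,
    }).set_index("subgrid_id")
    grids = grids.astype({
        "grid_id": str, "prey_km": float, "ndvi": float, "hpd": float,
        "elev": float, "surveyed": bool,
    }).set_index("grid_id")

    scaling = None
    if scaling_path is None:
        candidate = Path(survey_path).parent / "scaling.csv"
        if candidate.exists():
            scaling_path = candidate
    if scaling_path is not None:
        scaling = _read_scaling(scaling_path)

    ds = SurveyDataset(grids, sub, scaling)
    if validate:
        ds.validate()
    return ds


def _read_scaling(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    _require_columns(df, ("key", "mean", "sd"), str(path))
    return {r["key"]: (float(r["mean"]), float(r["sd"])) for _, r in df.iterrows()}


def write_dataset(ds: SurveyDataset, directory: str | Path) -> dict[str, Path]:
    """Write ``survey.csv``, ``grids.csv`` and (if present) ``scaling.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": directory / "survey.csv",
        "grids": directory / "grids.csv",
    }
    sub = ds.subgrids.reset_index()[list(SURVEY_COLUMNS)]
    sub.to_csv(paths["survey"], index=False, float_format="%.17g")
    ds.grids.reset_index()[list(GRID_COLUMNS)].to_csv(
        paths["grids"], index=False, float_format="%.17g")
    if ds.scaling is not None:
        rows = [{"key": k, "mean": m, "sd": s} for k, (m, s) in ds.scaling.items()]
        paths["scaling"] = directory / "scaling.csv"
        pd.DataFrame(rows).to_csv(paths["scaling"], index=False,
                                  float_format="%.17g")
    return paths


def load_dataset(directory: str | Path, validate: bool = True) -> SurveyDataset:
    """Load a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    return load_survey(directory / "survey.csv", directory / "grids.csv",
                       validate=validate)


def floor_and_log_population(raw_density, floor: float = 11.0):
    """Floor population density at the minimum observed nonzero value and log10.

    The floor (default 11 persons/km^2) replaces zero densities inside park
    cores so that the log10 transform is defined everywhere.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    arr = np.asarray(raw_density, dtype=float)
    if np.any(arr < 0):
        raise ValueError("population density must be non-negative")
    out = np.log10(np.maximum(arr, floor))
    return float(out) if np.isscalar(raw_density) or arr.ndim == 0 else out


def standardize_covariates(
    ds: SurveyDataset,
    grid_fields: Sequence[str] = GRID_COVARIATES,
    subgrid_fields: Sequence[str] = SUBGRID_COVARIATES,
) -> SurveyDataset:
    """Centre and scale covariates to mean 0, sample sd 1 at each scale.

    Scaling statistics are composed with any prior record so a second
    application is a numerical no-op and un-standardization always recovers
    the original values.
    """
    out = ds.copy()
    scaling = dict(ds.scaling) if ds.scaling is not None else {}
    for scale, df, fields in (("grid", out.grids, grid_fields),
                              ("subgrid", out.subgrids, subgrid_fields)):
        for f in fields:
            if f not in df.columns:
                raise SchemaError(f"{scale} table has no covariate {f!r}")
            v = df[f].to_numpy(dtype=float)
            m = float(np.nanmean(v))
            s = float(np.nanstd(v, ddof=1))
            if not np.isfinite(s) or s == 0.0:
                raise ValidationError(
                    f"{scale} covariate {f!r} is constant; cannot standardize")
            df[f] = (v - m) / s
            key = f"{scale}:{f}"
            if key in scaling:
                m0, s0 = scaling[key]
                scaling[key] = (m0 + s0 * m, s0 * s)
            else:
                scaling[key] = (m, s)
    out.scaling = scaling
    return out


def unstandardize_covariates(ds: SurveyDataset) -> SurveyDataset:
    """Invert :func:`standardize_covariates` using the stored scaling record."""
    if ds.scaling is None:
        raise ValidationError("dataset has no scaling record to invert")
    out = ds.copy()
    for key, (m, s) in ds.scaling.items():
        scale, f = key.split(":", 1)
        df = out.grids if scale == "grid" else out.subgrids
        df[f] = df[f].to_numpy(dtype=float) * s + m
    out.scaling = None
    return out


def load_adjacency(path: str | Path) -> list[tuple[str, str]]:
    """Read the grid adjacency table (columns ``grid_id, neighbor_id``)."""
    df = pd.read_csv(path)
    _require_columns(df, ("grid_id", "neighbor_id"), str(path))
    return [(str(a), str(b)) for a, b in zip(df["grid_id"], df["neighbor_id"])]


def write_adjacency(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["grid_id", "neighbor_id"]).to_csv(path, index=False)


def impute_missing_prey(
    grids: pd.DataFrame,
    adjacency: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Fill prey for unvisited grids with the mean over adjacent visited grids.

    A grid is imputed when it is flagged unsurveyed or its ``prey_km`` is
    missing.  Only directly observed (surveyed, non-missing) neighbours
    donate; an unsurveyed grid with no such neighbour raises.  Returns the
    updated table and the list of imputed grid ids.
    """
    neighbours: dict[str, set[str]] = {}
    for a, b in adjacency:
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)

    out = grids.copy()
    observed = out["surveyed"].astype(bool) & out["prey_km"].notna()
    to_impute = [gid for gid in out.index if not observed.loc[gid]]
    imputed: list[str] = []
    for gid in to_impute:
        donors = [n for n in neighbours.get(gid, ())
                  if n in out.index and observed.loc[n]]
        if not donors:
            raise ValidationError(
                f"unsurveyed grid {gid!r} has no surveyed neighbour to impute from")
        out.loc[gid, "prey_km"] = float(np.mean(
            [out.loc[n, "prey_km"] for n in donors]))
        imputed.append(gid)
        logger.info("imputed prey_km for grid %s from neighbours %s", gid, donors)
    return out, imputed


def correlation_matrix(
    ds: SurveyDataset,
    scale: str,
    fields: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between covariates at one scale (report-only).

    Correlations are reported for screening; no covariate is dropped
    automatically regardless of magnitude.
    """
    if scale == "grid":
        df, default = ds.grids, GRID_COVARIATES
    elif scale == "subgrid":
        df, default = ds.subgrids, SUBGRID_COVARIATES
    else:
        raise ValueError(f"scale must be 'grid' or 'subgrid', got {scale!r}")
    if len(df) < 3:
        raise ValidationError(
            f"need at least 3 {scale} cells for correlations, have {len(df)}")
    fields = list(fields) if fields is not None else list(default)
    return df[fields].corr(method="pearson")


def load_rescues(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the rescue-event table (``date, subgrid_id, sex, age_class``)."""
    df = _apply_schema(pd.read_csv(path), schema)
    _require_columns(df, RESCUE_COLUMNS, str(path))
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["subgrid_id"] = df["subgrid_id"].astype("string")
    for col, allowed in (("sex", SEXES), ("age_class", AGE_CLASSES)):
        df[col] = df[col].astype(str).str.lower()
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValidationError(f"invalid {col} value(s) {bad}; allowed: {allowed}")
    return df


def filter_window(
    rescues: pd.DataFrame,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
) -> tuple[pd.DataFrame, int]:
    """Keep rescues inside [start, end]; report how many were excluded."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    keep = (rescues["date"] >= start) & (rescues["date"] <= end)
    excluded = int((~keep).sum())
    if excluded:
        logger.info("excluded %d rescue(s) outside %s..%s", excluded,
                    start.date(), end.date())
    return rescues.loc[keep].copy(), excluded
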