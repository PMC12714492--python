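"""Posterior summaries: coefficient tables, probabilities at mean
covariates, and per-cell use maps.

Credible intervals are equal-tailed empirical quantiles (2.5%/97.5% by
default), pooled over chains, matching the usual "estimate (CI: a, b)"
reporting convention.  "At mean covariates" means all standardized
covariates at 0, i.e. the inverse-logit of the intercept draws; for tiger
use the prey-use indicator is not a covariate with a mean of zero, so the
quantity is reported both with and without prey use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import inv_logit
from .sampler import PosteriorDraws
from .survey_data import SurveyDataset

__all__ = ["summarize", "quantity_at_mean_covariates", "use_probability_map",
           "UseMap"]

MIN_DRAWS = 100

QUANTITIES = ("grid_occupancy", "tiger_use", "prey_use",
              "tiger_detection", "prey_detection")


def _interval(v: np.ndarray, mass: float) -> tuple[float, float]:
    a = (1 - mass) / 2
    lo, hi = np.quantile(v, [a, 1 - a])
    return float(lo), float(hi)


def summarize(draws: PosteriorDraws, ci_mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, equal-tailed CI and a CI-excludes-zero flag per
    coefficient."""
    if draws.n_draws < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} retained draws, have {draws.n_draws}")
    pooled = draws.pooled()
    rows = {}
    for name in pooled.columns:
        v = pooled[name].to_numpy()
        lo, hi = _interval(v, ci_mass)
        rows[name] = {"mean": float(v.mean()), "ci_lower": lo, "ci_upper": hi,
                      "excludes_zero": bool(lo > 0 or hi < 0)}
    return pd.DataFrame.from_dict(rows, orient="index")


def quantity_at_mean_covariates(
    draws: PosteriorDraws,
    quantity: str,
    ci_mass: float = 0.95,
) -> pd.DataFrame:
    """Posterior of a probability evaluated at mean (standardized = 0)
    covariates.

    Applies the inverse logit to the relevant intercept draws.  For
    ``tiger_use``, rows ``prey_used`` (z_x = 1, adds the prey-use
    coefficient) and ``prey_unused`` (z_x = 0) are both reported; other
    quantities return a single ``estimate`` row.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; one of {QUANTITIES}")
    if draws.n_draws < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} retained draws, have {draws.n_draws}")
    intercept = {"grid_occupancy": "b0", "tiger_use": "beta0y",
                 "prey_use": "beta0x", "tiger_detection": "d0y",
                 "prey_detection": "d0x"}[quantity]
    base = draws.get(intercept)
    variants = {"estimate": base}
    if quantity == "tiger_use":
        variants = {"prey_used": base + draws.get("beta1y"),
                    "prey_unused": base}
    rows = {}
    for label, eta in variants.items():
        p = inv_logit(eta)
        lo, hi = _interval(p, ci_mass)
        rows[label] = {"mean": float(p.mean()), "ci_lower": lo, "ci_upper": hi}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class UseMap:
    """Posterior use/occupancy probabilities per cell.

    ``subgrid`` has columns ``p_tiger_use, p_prey_use`` indexed by
    subgrid_id; ``grid`` has ``p_occupancy`` indexed by grid_id.  Values are
    means of the retained latent indicators, so cells with positive gated
    detections are exactly 1.
    """

    subgrid: pd.DataFrame
    grid: pd.DataFrame

    def to_csv(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"subgrid": directory / "use_map_subgrid.csv",
                 "grid": directory / "use_map_grid.csv"}
        self.subgrid.reset_index().to_csv(paths["subgrid"], index=False,
                                          float_format="%.17g")
        self.grid.reset_index().to_csv(paths["grid"], index=False,
                                       float_format="%.17g")
        return paths

    def to_geojson(self, geometries: dict, path: str | Path) -> Path:
        """Export subgrid probabilities as a GeoJSON FeatureCollection.

        ``geometries`` maps subgrid_id to a GeoJSON geometry dict; cells
        without geometry are skipped.
        """
        features = []
        for sid, row in self.subgrid.iterrows():
            geom = geometries.get(sid)
            if geom is None:
                continue
            features.append({
                "type": "Feature", "geometry": geom,
                "properties": {"subgrid_id": sid,
                               "p_tiger_use": float(row["p_tiger_use"]),
                               "p_prey_use": float(row["p_prey_use"])},
            })
        path = Path(path)
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))
        return path


def use_probability_map(draws: PosteriorDraws,
                        data: SurveyDataset | None = None) -> UseMap:
    """Build the per-cell posterior use map from retained latent frequencies.

    ``data`` (optional) is only used to carry the buffer flags through to
    the subgrid table for downstream conflict analysis.
    """
    if draws.p_tiger_use is None or len(draws.p_tiger_use) == 0:
        raise ValueError(
            "no latent-state summaries retained; re-run the sampler to "
            "produce a use map")
    sub = pd.DataFrame({
        "p_tiger_use": draws.p_tiger_use,
        "p_prey_use": draws.p_prey_use,
    }, index=pd.Index(draws.subgrid_ids, name="subgrid_id"))
    if data is not None:
        sub["in_buffer"] = data.subgrids.loc[sub.index, "in_buffer"].to_numpy()
    grid = pd.DataFrame({"p_occupancy": draws.p_occupancy},
                        index=pd.Index(draws.grid_ids, name="grid_id"))
    bad = [
        name for name, df in (("subgrid", sub), ("grid", grid))
        if not df.select_dtypes("number").apply(
            lambda c: c.between(0, 1).all()).all()
    ]
    if bad:
        raise ValueError(f"use-map probabilities outside [0, 1] at scale {bad}")
    return UseMap(sub, grid)
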