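"""Two-scale occupancy/use/detection model with logit links.

The hierarchy has three latent Bernoulli layers and two binomial
observation layers:

* ``Z_i`` — tiger occupancy of large grid *i*,
  ``logit(psi_i) = b0 + b1*Prey_i + b2*NDVI_i + b3*HPD_i + b4*Elev_i``;
* ``z^x_ij`` — prey use of subgrid *j* of grid *i*,
  ``logit(psix_ij) = beta0x + beta2x*NDVI_ij + beta3x*HPD_ij + beta4x*Elev_ij``;
* ``z^y_ij`` — tiger use,
  ``logit(psiy_ij) = beta0y + beta1y*z^x_ij + beta2y*NDVI_ij
  + beta3y*HPD_ij + beta4y*Elev_ij``;
* detections ``x_ij ~ Binomial(n_ij, p^x_ij * gate_x)`` and
  ``y_ij ~ Binomial(n_ij, p^y_ij * gate_y)`` over the ``n_ij`` 100-m
  segments walked in the subgrid, with
  ``logit(p_ij) = d0 + d1*NDVI_ij + d2*Elev_ij`` per species.

The *gates* multiply a detection probability by latent indicators so that
sign is impossible where the relevant states are 0.  :class:`GatingMode`
selects which binomial carries the grid-level ``Z_i``:

* ``tiger_gated`` (default): ``gate_y = Z_i * z^y_ij`` and ``gate_x =
  z^x_ij`` — subgrid tiger use is "use within an occupied home range";
* ``as_printed``: ``gate_x = Z_i * z^x_ij`` and ``gate_y = z^y_ij`` — kept
  for exact replication of the published equation block, whose placement of
  ``Z_i`` on the prey binomial is ecologically inverted;
* ``both_gated``: ``Z_i`` gates both binomials (sensitivity analysis).

Use-state priors are *not* conditioned on ``Z_i``; gating acts only through
detection.  All arithmetic is in the log domain; impossible observations
yield ``-inf``, never NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy.special import expit, gammaln

from .survey_data import SurveyDataset

__all__ = [
    "GatingMode", "ModelParameters", "LatentState", "ModelArrays",
    "PARAM_NAMES", "inv_logit", "grid_occupancy_prob", "subgrid_use_prob",
    "detection_prob", "complete_data_loglik", "marginal_loglik_bruteforce",
    "enumerate_latent_posterior",
]

PARAM_NAMES = (
    "b0", "b1", "b2", "b3", "b4",
    "beta0x", "beta2x", "beta3x", "beta4x",
    "beta0y", "beta1y", "beta2y", "beta3y", "beta4y",
    "d0y", "d1y", "d2y",
    "d0x", "d1x", "d2x",
)

BLOCKS = {
    "grid_occupancy": slice(0, 5),
    "prey_use": slice(5, 9),
    "tiger_use": slice(9, 14),
    "tiger_detection": slice(14, 17),
    "prey_detection": slice(17, 20),
}

_ENUMERATION_GUARD = 20  # max latent bits for brute-force enumeration


class GatingMode(str, Enum):
    TIGER_GATED = "tiger_gated"
    AS_PRINTED = "as_printed"
    BOTH_GATED = "both_gated"

    @property
    def z_gates_tiger(self) -> bool:
        return self in (GatingMode.TIGER_GATED, GatingMode.BOTH_GATED)

    @property
    def z_gates_prey(self) -> bool:
        return self in (GatingMode.AS_PRINTED, GatingMode.BOTH_GATED)


@dataclass
class ModelParameters:
    """All regression coefficients of the four logistic predictors.

    ``b``: grid occupancy (intercept, Prey, NDVI, HPD, Elev);
    ``beta_x``: prey use (intercept, NDVI, HPD, Elev);
    ``beta_y``: tiger use (intercept, prey-use indicator, NDVI, HPD, Elev);
    ``d_y`` / ``d_x``: tiger / prey detection (intercept, NDVI, Elev).
    """

    b: np.ndarray
    beta_x: np.ndarray
    beta_y: np.ndarray
    d_y: np.ndarray
    d_x: np.ndarray

    def __post_init__(self) -> None:
        for name, size in (("b", 5), ("beta_x", 4), ("beta_y", 5),
                           ("d_y", 3), ("d_x", 3)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (size,):
                raise ValueError(f"{name} must have shape ({size},), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @classmethod
    def zeros(cls) -> "ModelParameters":
        return cls(np.zeros(5), np.zeros(4), np.zeros(5), np.zeros(3), np.zeros(3))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.b, self.beta_x, self.beta_y, self.d_y, self.d_x])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelParameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected vector of length {len(PARAM_NAMES)}")
        return cls(v[0:5], v[5:9], v[9:14], v[14:17], v[17:20])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_vector()))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        missing = [k for k in PARAM_NAMES if k not in d]
        if missing:
            raise ValueError(f"missing parameter(s) {missing}")
        return cls.from_vector(np.array([d[k] for k in PARAM_NAMES]))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k} = {float(v)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        d: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            d[k.strip()] = float(v)
        return cls.from_dict(d)


@dataclass
class ModelArrays:
    """Design matrices and observations in sampler-ready form.

    Subgrids are ordered by grid; ``grid_index`` maps each subgrid to its
    grid's position.  ``X_grid`` columns are (1, Prey, NDVI, HPD, Elev);
    ``X_use`` columns (1, NDVI, HPD, Elev); ``X_det`` columns (1, NDVI,
    Elev).
    """

    grid_ids: np.ndarray
    subgrid_ids: np.ndarray
    grid_index: np.ndarray
    X_grid: np.ndarray
    X_use: np.ndarray
    X_det: np.ndarray
    n: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def n_grids(self) -> int:
        return len(self.grid_ids)

    @property
    def n_subgrids(self) -> int:
        return len(self.subgrid_ids)

    @property
    def n_latent_bits(self) -> int:
        return self.n_grids + 2 * self.n_subgrids

    @classmethod
    def from_dataset(cls, ds: SurveyDataset) -> "ModelArrays":
        grids = ds.grids
        order = np.argsort(
            np.searchsorted(grids.index.to_numpy(),
                            ds.subgrids["grid_id"].to_numpy()),
            kind="stable")
        sub = ds.subgrids.iloc[order]
        gid_pos = {g: i for i, g in enumerate(grids.index)}
        grid_index = np.array([gid_pos[g] for g in sub["grid_id"]], dtype=np.intp)

        Xg = np.column_stack([
            np.ones(len(grids)),
            grids["prey_km"].to_numpy(float),
            grids["ndvi"].to_numpy(float),
            grids["hpd"].to_numpy(float),
            grids["elev"].to_numpy(float),
        ])
        Xu = np.column_stack([
            np.ones(len(sub)),
            sub["ndvi"].to_numpy(float),
            sub["hpd"].to_numpy(float),
            sub["elev"].to_numpy(float),
        ])
        Xd = np.column_stack([
            np.ones(len(sub)),
            sub["ndvi"].to_numpy(float),
            sub["elev"].to_numpy(float),
        ])
        if not (np.all(np.isfinite(Xg)) and np.all(np.isfinite(Xu))):
            raise ValueError("covariates contain non-finite values "
                             "(impute prey before building model arrays)")
        return cls(
            grid_ids=grids.index.to_numpy(),
            subgrid_ids=sub.index.to_numpy(),
            grid_index=grid_index,
            X_grid=Xg, X_use=Xu, X_det=Xd,
            n=sub["effort"].to_numpy(int),
            x=sub["prey_det"].to_numpy(int),
            y=sub["tiger_det"].to_numpy(int),
        )


@dataclass
class LatentState:
    """Binary occupancy/use indicators: ``Z`` per grid, ``z_x``/``z_y`` per subgrid."""

    Z: np.ndarray
    z_x: np.ndarray
    z_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Z", "z_x", "z_y"):
            arr = np.asarray(getattr(self, name), dtype=np.int8)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
            setattr(self, name, arr)

    def check_dims(self, arrays: ModelArrays) -> None:
        if self.Z.shape != (arrays.n_grids,) or \
           self.z_x.shape != (arrays.n_subgrids,) or \
           self.z_y.shape != (arrays.n_subgrids,):
            raise ValueError("latent state dimensions do not match the dataset")

    @classmethod
    def ones(cls, arrays: ModelArrays) -> "LatentState":
        return cls(np.ones(arrays.n_grids, np.int8),
                   np.ones(arrays.n_subgrids, np.int8),
                   np.ones(arrays.n_subgrids, np.int8))


def inv_logit(x):
    """Overflow-safe logistic function 1/(1+exp(-x))."""
    return expit(x)


def _as_covariates(rec, keys) -> np.ndarray:
    vals = np.array([float(rec[k]) for k in keys])
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite covariate among {keys}")
    return vals


def grid_occupancy_prob(params: ModelParameters, grid) -> float:
    """psi_i for one grid record (mapping with prey_km, ndvi, hpd, elev)."""
    cov = _as_covariates(grid, ("prey_km", "ndvi", "hpd", "elev"))
    return float(expit(params.b[0] + params.b[1:] @ cov))


def subgrid_use_prob(params: ModelParameters, subgrid, species: str,
                     prey_use_state: int | None = None) -> float:
    """Use probability of one subgrid for ``species`` in {'prey', 'tiger'}.

    Tiger use depends on the prey-use indicator of the same subgrid, so
    ``prey_use_state`` is required for tigers and ignored for prey.
    """
    cov = _as_covariates(subgrid, ("ndvi", "hpd", "elev"))
    if species == "prey":
        return float(expit(params.beta_x[0] + params.beta_x[1:] @ cov))
    if species == "tiger":
        if prey_use_state is None:
            raise ValueError("tiger use requires prey_use_state (0 or 1)")
        eta = (params.beta_y[0] + params.beta_y[1] * prey_use_state
               + params.beta_y[2:] @ cov)
        return float(expit(eta))
    raise ValueError(f"species must be 'prey' or 'tiger', got {species!r}")


def detection_prob(params: ModelParameters, subgrid, species: str) -> float:
    """Per-100-m-segment detection probability; effort is the binomial size,
    not a predictor."""
    cov = _as_covariates(subgrid, ("ndvi", "elev"))
    d = {"tiger": params.d_y, "prey": params.d_x}.get(species)
    if d is None:
        raise ValueError(f"species must be 'prey' or 'tiger', got {species!r}")
    return float(expit(d[0] + d[1:] @ cov))


def _bernoulli_loglik(z: np.ndarray, eta: np.ndarray) -> float:
    # log Bern(z | expit(eta)) summed; z*eta - log(1+e^eta) is exact for z in {0,1}
    return float(np.sum(z * eta - np.logaddexp(0.0, eta)))


def _gated_binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray,
                        gate: np.ndarray) -> float:
    """Sum of log Binomial(k | n, p*gate) with gate in {0,1}; -inf if impossible."""
    gate = np.asarray(gate, bool)
    if np.any(k[~gate] > 0):
        return -np.inf
    if not gate.any():
        return 0.0
    k, n, p = k[gate], n[gate], np.clip(p[gate], 1e-300, np.nextafter(1.0, 0.0))
    terms = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
             + k * np.log(p) + (n - k) * np.log1p(-p))
    return float(terms.sum())


def _predictors(params: ModelParameters, arrays: ModelArrays,
                z_x: np.ndarray | None = None):
    eta_g = arrays.X_grid @ params.b
    eta_x = arrays.X_use @ params.beta_x
    eta_y0 = (arrays.X_use @ params.beta_y[[0, 2, 3, 4]])
    eta_y = eta_y0 if z_x is None else eta_y0 + params.beta_y[1] * z_x
    p_x = expit(arrays.X_det @ params.d_x)
    p_y = expit(arrays.X_det @ params.d_y)
    return eta_g, eta_x, eta_y, p_x, p_y


def _gates(latent: LatentState, arrays: ModelArrays, gating: GatingMode):
    Zg = latent.Z[arrays.grid_index]
    gate_x = latent.z_x * (Zg if gating.z_gates_prey else 1)
    gate_y = latent.z_y * (Zg if gating.z_gates_tiger else 1)
    return gate_x, gate_y


def complete_data_loglik(
    params: ModelParameters,
    latent: LatentState,
    data: SurveyDataset | ModelArrays,
    gating: GatingMode = GatingMode.TIGER_GATED,
) -> float:
    """Joint log-density of latent states and detections given parameters.

    Sum of the three Bernoulli layers plus the two gated binomial layers;
    ``-inf`` when any observed detection is impossible under the latent
    state.
    """
    arrays = data if isinstance(data, ModelArrays) else ModelArrays.from_dataset(data)
    latent.check_dims(arrays)
    gating = GatingMode(gating)
    if arrays.n_grids == 0 and arrays.n_subgrids == 0:
        return 0.0
    eta_g, eta_x, eta_y, p_x, p_y = _predictors(params, arrays, latent.z_x)
    ll = _bernoulli_loglik(latent.Z, eta_g)
    ll += _bernoulli_loglik(latent.z_x, eta_x)
    ll += _bernoulli_loglik(latent.z_y, eta_y)
    gate_x, gate_y = _gates(latent, arrays, gating)
    ll += _gated_binom_loglik(arrays.x, arrays.n, p_x, gate_x)
    ll += _gated_binom_loglik(arrays.y, arrays.n, p_y, gate_y)
    return ll


def _enumerate_states(arrays: ModelArrays) -> Iterator[LatentState]:
    G, M = arrays.n_grids, arrays.n_subgrids
    for bits in itertools.product((0, 1), repeat=G + 2 * M):
        yield LatentState(np.array(bits[:G], np.int8),
                          np.array(bits[G:G + M], np.int8),
                          np.array(bits[G + M:], np.int8))


def _check_enumeration_size(arrays: ModelArrays) -> None:
    if arrays.n_latent_bits > _ENUMERATION_GUARD:
        raise ValueError(
            f"instance has {arrays.n_latent_bits} latent bits; enumeration is "
            f"guarded at {_ENUMERATION_GUARD}")


def marginal_loglik_bruteforce(
    params: ModelParameters,
    data: SurveyDataset | ModelArrays,
    gating: GatingMode = GatingMode.TIGER_GATED,
) -> float:
    """log sum over all 2^k latent configurations of exp(complete-data loglik).

    Exact enumeration oracle for validating the sampler on tiny instances
    (guarded at 20 latent bits).
    """
    arrays = data if isinstance(data, ModelArrays) else ModelArrays.from_dataset(data)
    _check_enumeration_size(arrays)
    lls = np.array([complete_data_loglik(params, st, arrays, gating)
                    for st in _enumerate_states(arrays)])
    finite = lls[np.isfinite(lls)]
    if finite.size == 0:
        return -np.inf
    m = finite.max()
    return float(m + np.log(np.sum(np.exp(finite - m))))


def enumerate_latent_posterior(
    params: ModelParameters,
    data: SurveyDataset | ModelArrays,
    gating: GatingMode = GatingMode.TIGER_GATED,
) -> dict[str, np.ndarray]:
    """Exact posterior marginals P(Z_i=1|data), P(z_x=1|data), P(z_y=1|data)
    at fixed parameters, by enumeration (guarded at 20 latent bits)."""
    arrays = data if isinstance(data, ModelArrays) else ModelArrays.from_dataset(data)
    _check_enumeration_size(arrays)
    states = list(_enumerate_states(arrays))
    lls = np.array([complete_data_loglik(params, st, arrays, gating)
                    for st in states])
    m = np.max(lls[np.isfinite(lls)])
    w = np.exp(np.where(np.isfinite(lls), lls - m, -np.inf))
    w /= w.sum()
    Z = np.array([st.Z for st in states], float)
    zx = np.array([st.z_x for st in states], float)
    zy = np.array([st.z_y for st in states], float)
    return {name: np.clip(w @ mat, 0.0, 1.0)
            for name, mat in (("Z", Z), ("z_x", zx), ("z_y", zy))}
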