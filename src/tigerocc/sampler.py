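"""Metropolis-within-Gibbs sampler for the two-scale occupancy model.

Data augmentation: the latent grid-occupancy and subgrid-use indicators are
drawn from their exact Bernoulli full conditionals each iteration, then the
five coefficient blocks (grid occupancy, prey use, tiger use, tiger
detection, prey detection) are updated with blockwise random-walk
Metropolis steps under independent uniform priors on
[-prior_bound, prior_bound].  Proposal scales adapt toward a 0.2-0.5
acceptance band during burn-in only, so the post-burn-in kernel is a fixed,
detailed-balance-preserving Metropolis kernel.

The run configuration mirrors a standard generic-engine setup: 10,000
iterations, three chains, burn-in 2,500 (within the 10,000), thinning 10.
Convergence is assessed with the split-chain Gelman-Rubin potential scale
reduction factor (threshold 1.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    BLOCKS, PARAM_NAMES, GatingMode, LatentState, ModelArrays,
    ModelParameters,
)
from .survey_data import SurveyDataset

__all__ = [
    "SamplerConfig", "PosteriorDraws", "ConvergenceReport",
    "run_mcmc", "gelman_rubin", "full_conditional_Z", "full_conditional_use",
    "metropolis_update",
]


@dataclass
class SamplerConfig:
    """MCMC run configuration.

    ``proposal_sd`` is the initial random-walk scale per coefficient block;
    it adapts during burn-in.  Coefficient priors are uniform on
    [-``prior_bound``, ``prior_bound``] (default 10, spanning essentially
    the whole probability scale through the logit link).
    """

    iterations: int = 10_000
    chains: int = 3
    thin: int = 10
    burn_in: int = 2_500
    prior_bound: float = 10.0
    proposal_sd: float = 0.2
    seed: int = 0
    gating: GatingMode = GatingMode.TIGER_GATED
    adapt_interval: int = 50
    metropolis_sweeps: int = 3

    def __post_init__(self) -> None:
        self.gating = GatingMode(self.gating)
        if self.iterations <= 0 or self.chains <= 0 or self.thin <= 0:
            raise ValueError("iterations, chains and thin must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.prior_bound <= 0 or self.proposal_sd <= 0:
            raise ValueError("prior_bound and proposal_sd must be positive")
        if self.metropolis_sweeps < 1:
            raise ValueError("metropolis_sweeps must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gating"] = self.gating.value
        return d


@dataclass
class ConvergenceReport:
    """Per-parameter split-chain R-hat and the overall verdict."""

    r_hat: pd.Series
    threshold: float
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_hat": self.r_hat,
                             "below_threshold": self.r_hat < self.threshold})


@dataclass
class PosteriorDraws:
    """Retained coefficient draws plus latent-state posterior frequencies.

    ``draws`` has shape (chains, draws_per_chain, n_parameters) in
    :data:`~tigerocc.model.PARAM_NAMES` order.  Latent frequencies are means
    of the retained latent indicators, pooled over chains.
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    grid_ids: np.ndarray
    subgrid_ids: np.ndarray
    p_occupancy: np.ndarray
    p_prey_use: np.ndarray
    p_tiger_use: np.ndarray
    accept_rates: dict
    config: SamplerConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str, chain: int | None = None) -> np.ndarray:
        """Draws of one parameter, pooled over chains unless ``chain`` given."""
        j = self.param_names.index(name)
        if chain is None:
            return self.draws[:, :, j].ravel()
        return self.draws[chain, :, j]

    def pooled(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws.reshape(-1, len(self.param_names)),
                            columns=list(self.param_names))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        C, N, P = self.draws.shape
        flat = self.draws.reshape(C * N, P)
        df = pd.DataFrame(flat, columns=list(self.param_names))
        df.insert(0, "chain", np.repeat(np.arange(C), N))
        df.insert(1, "draw", np.tile(np.arange(N), C))
        df.to_csv(directory / "draws.csv", index=False, float_format="%.17g")
        pd.DataFrame({"grid_id": self.grid_ids,
                      "p_occupancy": self.p_occupancy}).to_csv(
            directory / "latent_grid.csv", index=False, float_format="%.17g")
        pd.DataFrame({"subgrid_id": self.subgrid_ids,
                      "p_prey_use": self.p_prey_use,
                      "p_tiger_use": self.p_tiger_use}).to_csv(
            directory / "latent_subgrid.csv", index=False, float_format="%.17g")
        with open(directory / "run.json", "w") as fh:
            json.dump({"config": self.config.to_dict(),
                       "accept_rates": self.accept_rates}, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        df = pd.read_csv(directory / "draws.csv")
        names = tuple(c for c in df.columns if c not in ("chain", "draw"))
        C = int(df["chain"].max()) + 1
        N = len(df) // C
        draws = df[list(names)].to_numpy().reshape(C, N, len(names))
        lg = pd.read_csv(directory / "latent_grid.csv")
        ls = pd.read_csv(directory / "latent_subgrid.csv")
        with open(directory / "run.json") as fh:
            run = json.load(fh)
        return cls(
            draws=draws, param_names=names,
            grid_ids=lg["grid_id"].astype(str).to_numpy(),
            subgrid_ids=ls["subgrid_id"].astype(str).to_numpy(),
            p_occupancy=lg["p_occupancy"].to_numpy(),
            p_prey_use=ls["p_prey_use"].to_numpy(),
            p_tiger_use=ls["p_tiger_use"].to_numpy(),
            accept_rates=run["accept_rates"],
            config=SamplerConfig(**run["config"]),
        )


# ---------------------------------------------------------------------------
# Latent full conditionals (vectorized)

def _clip_p(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-300, np.nextafter(1.0, 0.0))


def _open_gate_delta(k: np.ndarray, n: np.ndarray, p: np.ndarray,
                     open_: np.ndarray) -> np.ndarray:
    """Log-likelihood difference of a subgrid's binomial between its own
    gate bit being 1 vs 0, given the *other* gate factor ``open_``.

    +inf forces the bit to 1 wherever detections occurred and the other
    factor is open; 0 where the other factor is closed (the bit is then
    likelihood-free).
    """
    log_miss = n * np.log1p(-_clip_p(p))
    return np.where(open_ == 1, np.where(k > 0, np.inf, log_miss), 0.0)


def _update_z_x(rng, arrays, gating, Z, z_y, eta_x, eta_y0, beta1y, p_x):
    Zg = Z[arrays.grid_index]
    other = Zg if gating.z_gates_prey else np.ones_like(Zg)
    delta_det = _open_gate_delta(arrays.x, arrays.n, p_x, other)
    # prey use feeds the tiger-use prior, so the z_y prior term enters
    eta_y1 = eta_y0 + beta1y
    prior_y = ((z_y * eta_y1 - np.logaddexp(0.0, eta_y1))
               - (z_y * eta_y0 - np.logaddexp(0.0, eta_y0)))
    logodds = eta_x + delta_det + prior_y
    return (rng.random(arrays.n_subgrids) < expit(logodds)).astype(np.int8)


def _update_z_y(rng, arrays, gating, Z, z_x, eta_y0, beta1y, p_y):
    Zg = Z[arrays.grid_index]
    other = Zg if gating.z_gates_tiger else np.ones_like(Zg)
    delta_det = _open_gate_delta(arrays.y, arrays.n, p_y, other)
    logodds = eta_y0 + beta1y * z_x + delta_det
    return (rng.random(arrays.n_subgrids) < expit(logodds)).astype(np.int8)


def _grid_delta(k, n, p, z_bit, grid_index, n_grids):
    """Per-grid log-likelihood difference of the gated binomials between
    Z_i=1 and Z_i=0 (cells whose own use bit is 0 contribute 0)."""
    log_miss = n * np.log1p(-_clip_p(p))
    per_cell = np.where(k > 0,
                        np.where(z_bit == 1, np.inf, 0.0),
                        np.where(z_bit == 1, log_miss, 0.0))
    return np.bincount(grid_index, weights=per_cell, minlength=n_grids)


def _update_Z(rng, arrays, gating, z_x, z_y, eta_g, p_x, p_y):
    delta = np.zeros(arrays.n_grids)
    if gating.z_gates_tiger:
        delta += _grid_delta(arrays.y, arrays.n, p_y, z_y,
                             arrays.grid_index, arrays.n_grids)
    if gating.z_gates_prey:
        delta += _grid_delta(arrays.x, arrays.n, p_x, z_x,
                             arrays.grid_index, arrays.n_grids)
    logodds = eta_g + delta
    return (rng.random(arrays.n_grids) < expit(logodds)).astype(np.int8)


def full_conditional_Z(
    params: ModelParameters,
    latent: LatentState,
    data: SurveyDataset | ModelArrays,
    gating: GatingMode = GatingMode.TIGER_GATED,
) -> np.ndarray:
    """P(Z_i = 1 | everything else) for every grid."""
    arrays = data if isinstance(data, ModelArrays) else ModelArrays.from_dataset(data)
    latent.check_dims(arrays)
    gating = GatingMode(gating)
    eta_g = arrays.X_grid @ params.b
    p_x = expit(arrays.X_det @ params.d_x)
    p_y = expit(arrays.X_det @ params.d_y)
    delta = np.zeros(arrays.n_grids)
    if gating.z_gates_tiger:
        delta += _grid_delta(arrays.y, arrays.n, p_y, latent.z_y,
                             arrays.grid_index, arrays.n_grids)
    if gating.z_gates_prey:
        delta += _grid_delta(arrays.x, arrays.n, p_x, latent.z_x,
                             arrays.grid_index, arrays.n_grids)
    return expit(eta_g + delta)


def full_conditional_use(
    params: ModelParameters,
    latent: LatentState,
    data: SurveyDataset | ModelArrays,
    species: str,
    gating: GatingMode = GatingMode.TIGER_GATED,
) -> np.ndarray:
    """P(z_ij = 1 | everything else) for every subgrid, for one species.

    For prey the conditional includes the tiger-use prior factor, because
    the tiger-use probability depends on the prey-use indicator.
    """
    arrays = data if isinstance(data, ModelArrays) else ModelArrays.from_dataset(data)
    latent.check_dims(arrays)
    gating = GatingMode(gating)
    eta_x = arrays.X_use @ params.beta_x
    eta_y0 = arrays.X_use @ params.beta_y[[0, 2, 3, 4]]
    p_x = expit(arrays.X_det @ params.d_x)
    p_y = expit(arrays.X_det @ params.d_y)
    Zg = latent.Z[arrays.grid_index]
    if species == "prey":
        other = Zg if gating.z_gates_prey else np.ones_like(Zg)
        delta = _open_gate_delta(arrays.x, arrays.n, p_x, other)
        eta_y1 = eta_y0 + params.beta_y[1]
        prior_y = ((latent.z_y * eta_y1 - np.logaddexp(0.0, eta_y1))
                   - (latent.z_y * eta_y0 - np.logaddexp(0.0, eta_y0)))
        return expit(eta_x + delta + prior_y)
    if species == "tiger":
        other = Zg if gating.z_gates_tiger else np.ones_like(Zg)
        delta = _open_gate_delta(arrays.y, arrays.n, p_y, other)
        return expit(eta_y0 + params.beta_y[1] * latent.z_x + delta)
    raise ValueError(f"species must be 'prey' or 'tiger', got {species!r}")


# ---------------------------------------------------------------------------
# Coefficient blocks

def _block_loglik(block: str, theta_block: np.ndarray, arrays: ModelArrays,
                  Z, z_x, z_y, gate_x_open, gate_y_open) -> float:
    """Complete-data log-likelihood terms that involve one coefficient block.

    Detection blocks only see open-gate cells: closed cells have zero
    detections (else the state would be impossible) and contribute a
    constant.
    """
    if block == "grid_occupancy":
        eta = arrays.X_grid @ theta_block
        return float(np.sum(Z * eta - np.logaddexp(0.0, eta)))
    if block == "prey_use":
        eta = arrays.X_use @ theta_block
        return float(np.sum(z_x * eta - np.logaddexp(0.0, eta)))
    if block == "tiger_use":
        eta = arrays.X_use @ theta_block[[0, 2, 3, 4]] + theta_block[1] * z_x
        return float(np.sum(z_y * eta - np.logaddexp(0.0, eta)))
    if block == "tiger_detection":
        k, n, mask = arrays.y, arrays.n, gate_y_open
    elif block == "prey_detection":
        k, n, mask = arrays.x, arrays.n, gate_x_open
    else:
        raise ValueError(f"unknown block {block!r}")
    p = _clip_p(expit(arrays.X_det[mask] @ theta_block))
    return float(np.sum(k[mask] * np.log(p) + (n - k)[mask] * np.log1p(-p)))


def metropolis_update(
    block: str,
    theta: np.ndarray,
    arrays: ModelArrays,
    latent: LatentState,
    gating: GatingMode,
    scale: float,
    prior_bound: float,
    rng: np.random.Generator,
    chol: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """One symmetric random-walk Metropolis step on a coefficient block.

    The step is ``scale * N(0, I)`` or, when a Cholesky factor of the
    adapted block covariance is supplied, ``scale * L @ N(0, I)`` — still a
    symmetric proposal.  Proposals outside the uniform prior bounds are
    rejected outright; a zero log-likelihood difference is always accepted
    (ratio 1).  Returns the (possibly updated) full parameter vector and
    the accept flag.
    """
    sl = BLOCKS[block]
    Zg = latent.Z[arrays.grid_index]
    gate_x_open = (latent.z_x * (Zg if gating.z_gates_prey else 1)).astype(bool)
    gate_y_open = (latent.z_y * (Zg if gating.z_gates_tiger else 1)).astype(bool)
    current = theta[sl]
    step = rng.standard_normal(current.shape)
    if chol is not None:
        step = chol @ step
    proposal = current + scale * step
    if np.any(np.abs(proposal) > prior_bound):
        return theta, False
    ll_cur = _block_loglik(block, current, arrays, latent.Z, latent.z_x,
                           latent.z_y, gate_x_open, gate_y_open)
    ll_prop = _block_loglik(block, proposal, arrays, latent.Z, latent.z_x,
                            latent.z_y, gate_x_open, gate_y_open)
    if np.log(rng.random()) < ll_prop - ll_cur:
        theta = theta.copy()
        theta[sl] = proposal
        return theta, True
    return theta, False


def _init_latent(arrays: ModelArrays, gating: GatingMode,
                 rng: np.random.Generator) -> LatentState:
    """Latent init compatible with detections: bits forced to 1 wherever the
    corresponding gated detections are positive, Bernoulli(0.5) elsewhere."""
    z_x = (rng.random(arrays.n_subgrids) < 0.5).astype(np.int8)
    z_y = (rng.random(arrays.n_subgrids) < 0.5).astype(np.int8)
    Z = (rng.random(arrays.n_grids) < 0.5).astype(np.int8)
    z_x[arrays.x > 0] = 1
    z_y[arrays.y > 0] = 1
    if gating.z_gates_tiger:
        Z[np.bincount(arrays.grid_index, weights=arrays.y,
                      minlength=arrays.n_grids) > 0] = 1
    if gating.z_gates_prey:
        Z[np.bincount(arrays.grid_index, weights=arrays.x,
                      minlength=arrays.n_grids) > 0] = 1
    return LatentState(Z, z_x, z_y)


def _init_theta(config: SamplerConfig, rng: np.random.Generator) -> np.ndarray:
    # overdispersed relative to the posterior, but inside the prior bounds
    theta = rng.normal(0.0, 1.5, size=len(PARAM_NAMES))
    return np.clip(theta, -config.prior_bound, config.prior_bound)


def _run_chain(arrays: ModelArrays, config: SamplerConfig,
               rng: np.random.Generator,
               fixed_params: ModelParameters | None):
    gating = config.gating
    P = len(PARAM_NAMES)
    if fixed_params is not None:
        theta = fixed_params.to_vector()
    else:
        theta = _init_theta(config, rng)
    latent = _init_latent(arrays, gating, rng)
    Z, z_x, z_y = latent.Z, latent.z_x, latent.z_y

    scales = {b: config.proposal_sd for b in BLOCKS}
    chols: dict[str, np.ndarray | None] = {b: None for b in BLOCKS}
    window = {b: [0, 0] for b in BLOCKS}      # [accepts, attempts] in window
    totals = {b: [0, 0] for b in BLOCKS}      # post-burn-in accept bookkeeping
    history = np.empty((config.burn_in, P)) if fixed_params is None else None
    cov_start = max(10 * config.adapt_interval, config.burn_in // 5)

    n_keep = config.draws_per_chain
    kept = np.empty((n_keep, P))
    Z_sum = np.zeros(arrays.n_grids)
    zx_sum = np.zeros(arrays.n_subgrids)
    zy_sum = np.zeros(arrays.n_subgrids)
    k = 0

    for t in range(1, config.iterations + 1):
        params = ModelParameters.from_vector(theta)
        eta_g = arrays.X_grid @ params.b
        eta_x = arrays.X_use @ params.beta_x
        eta_y0 = arrays.X_use @ params.beta_y[[0, 2, 3, 4]]
        p_x = expit(arrays.X_det @ params.d_x)
        p_y = expit(arrays.X_det @ params.d_y)

        z_x = _update_z_x(rng, arrays, gating, Z, z_y, eta_x, eta_y0,
                          params.beta_y[1], p_x)
        z_y = _update_z_y(rng, arrays, gating, Z, z_x, eta_y0,
                          params.beta_y[1], p_y)
        Z = _update_Z(rng, arrays, gating, z_x, z_y, eta_g, p_x, p_y)
        latent = LatentState(Z, z_x, z_y)

        if fixed_params is None:
            # several cheap coefficient sweeps per (expensive) latent sweep
            for _ in range(config.metropolis_sweeps):
                for block in BLOCKS:
                    theta, accepted = metropolis_update(
                        block, theta, arrays, latent, gating,
                        scales[block], config.prior_bound, rng,
                        chol=chols[block])
                    window[block][0] += accepted
                    window[block][1] += 1
                    if t > config.burn_in:
                        totals[block][0] += accepted
                        totals[block][1] += 1
            if t <= config.burn_in:
                history[t - 1] = theta
                if t % config.adapt_interval == 0:
                    for block in BLOCKS:
                        acc, att = window[block]
                        rate = acc / att if att else 0.0
                        if rate < 0.2:
                            scales[block] = max(scales[block] * 0.7, 1e-3)
                        elif rate > 0.5:
                            scales[block] = min(scales[block] * 1.4, 5.0)
                        window[block] = [0, 0]
                        # Haario-style covariance adaptation: shape the
                        # proposal with the empirical covariance of the
                        # recent burn-in history (frozen after burn-in)
                        if t >= cov_start:
                            sl = BLOCKS[block]
                            seg = history[t // 2:t, sl]
                            dim = sl.stop - sl.start
                            cov = np.cov(seg.T) + 1e-6 * np.eye(dim)
                            if chols[block] is None:
                                scales[block] = 2.38 / np.sqrt(dim)
                            chols[block] = np.linalg.cholesky(cov)

        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            kept[k] = theta
            Z_sum += Z
            zx_sum += z_x
            zy_sum += z_y
            k += 1

    accept = {b: (totals[b][0] / totals[b][1] if totals[b][1] else None)
              for b in BLOCKS}
    return kept[:k], Z_sum / max(k, 1), zx_sum / max(k, 1), zy_sum / max(k, 1), accept


def run_mcmc(
    data: SurveyDataset | ModelArrays,
    config: SamplerConfig,
    fixed_params: ModelParameters | None = None,
) -> PosteriorDraws:
    """Fit the model, returning retained draws and latent-state frequencies.

    ``fixed_params`` freezes the coefficients at the given values and runs
    the latent Gibbs updates only (used for validating the augmentation
    against the enumeration oracle).

    The dataset must carry a covariate scaling record (i.e. have been
    standardized); refuse otherwise, because coefficient priors and the
    reporting conventions assume standardized covariates.
    """
    if isinstance(data, SurveyDataset):
        if not data.standardized:
            raise ValueError(
                "covariates are not standardized; run standardize_covariates "
                "(and impute prey) before fitting")
        arrays = ModelArrays.from_dataset(data)
    else:
        arrays = data

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    per_chain = [
        _run_chain(arrays, config, np.random.default_rng(s), fixed_params)
        for s in seeds
    ]
    draws = np.stack([c[0] for c in per_chain])
    p_occ = np.mean([c[1] for c in per_chain], axis=0)
    p_zx = np.mean([c[2] for c in per_chain], axis=0)
    p_zy = np.mean([c[3] for c in per_chain], axis=0)
    accept = {f"chain_{i}": c[4] for i, c in enumerate(per_chain)}
    return PosteriorDraws(
        draws=draws, param_names=PARAM_NAMES,
        grid_ids=arrays.grid_ids, subgrid_ids=arrays.subgrid_ids,
        p_occupancy=p_occ, p_prey_use=p_zx, p_tiger_use=p_zy,
        accept_rates=accept, config=config,
    )


def gelman_rubin(draws: PosteriorDraws | np.ndarray,
                 threshold: float = 1.1,
                 param_names: tuple[str, ...] | None = None) -> ConvergenceReport:
    """Split-chain Gelman-Rubin potential scale reduction factor per parameter.

    Each chain is split in half; R-hat = sqrt(((n-1)/n * W + B/n) / W) over
    the 2C half-chains.  Requires >= 2 chains and >= 10 retained draws per
    chain.  Chains that are identical constants give R-hat 1; chains stuck
    at different constants give +inf.
    """
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.draws, draws.param_names
    else:
        arr = np.asarray(draws, dtype=float)
        names = param_names or tuple(f"p{i}" for i in range(arr.shape[2]))
    if arr.ndim != 3:
        raise ValueError("draws must have shape (chains, n_draws, n_params)")
    C, N, P = arr.shape
    if C < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if N < 10:
        raise ValueError("R-hat requires at least 10 retained draws per chain")
    half = N // 2
    split = np.concatenate([arr[:, :half, :], arr[:, half:2 * half, :]], axis=0)
    n = half
    means = split.mean(axis=1)                      # (2C, P)
    W = split.var(axis=1, ddof=1).mean(axis=0)      # (P,)
    B_over_n = means.var(axis=0, ddof=1)            # B/n
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    r = np.where((W == 0) & (B_over_n == 0), 1.0,
                 np.where(W == 0, np.inf, r))
    series = pd.Series(r, index=list(names), name="r_hat")
    return ConvergenceReport(series, threshold, bool((series < threshold).all()))
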