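"""Component-wise adaptive random-walk Metropolis (Metropolis-within-Gibbs).

The sampler sweeps the parameter vector once per iteration, proposing a
Gaussian random-walk move for each component and accepting it by the
Metropolis rule against the joint posterior.  Proposal scales are
adapted toward a target acceptance rate (0.44, the 1-D optimum) during
burn-in only, by a decaying Robbins-Monro update on the log scale, so
the post-burn-in chain is a valid time-homogeneous Markov chain.

Models plug in through a small state protocol (see
:class:`ModelStateProtocol`): ``propose`` returns the change in log
posterior for a single-component move and ``accept`` commits it.  This
lets each model supply an O(affected observations) incremental update
instead of a full posterior evaluation per component, which is what
makes full-size runs (tens of thousands of iterations, hundreds of
parameters) tractable in pure Python.  A state may additionally expose
``gibbs_sweep(rng)``, an exact draw from a parameter's full
conditional run once per iteration; the models use this for their
scale (SD) parameters, whose random-walk mixing is otherwise throttled
by the narrow conditional relative to the marginal posterior.

Chain ``c`` is seeded with ``seed + c``; identical model, config and
seed reproduce identical draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["MCMCConfig", "PosteriorDraws", "run_mcmc"]


class ModelStateProtocol(Protocol):
    """Incremental single-component update interface used by the sampler."""

    def propose(self, index: int, delta: float) -> float:
        """Log-posterior change if component ``index`` moves by ``delta``."""

    def accept(self) -> None:
        """Commit the last proposed move."""

    def reject(self) -> None:
        """Discard the last proposed move."""

    def params_array(self) -> np.ndarray:
        """Copy of the current parameter vector."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule.

    Defaults follow the analysis protocol this package reproduces: three
    simultaneous chains of 20,000 iterations with a 5,000-iteration
    burn-in.  ``thin`` retains every ``thin``-th post-burn-in draw;
    convergence diagnostics may recommend increasing it after the fact.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt_during_burn_in: bool = True
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ConfigError("n_chains must be >= 2")
        if not (0 <= self.burn_in < self.n_iter):
            raise ConfigError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if not (0 < self.target_accept < 1):
            raise ConfigError("target_accept must be in (0, 1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC output: chains x retained iterations x parameters."""

    param_names: list[str]
    array: np.ndarray  # shape (n_chains, n_retained, n_params)
    acceptance: np.ndarray  # post-burn-in acceptance rate, (n_chains, n_params)
    config: MCMCConfig
    proposal_scales: np.ndarray | None = None  # final adapted scales per chain
    extra_thin: int = 1  # post-hoc thinning applied on top of config.thin

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_retained(self) -> int:
        return self.array.shape[1]

    @property
    def n_params(self) -> int:
        return self.array.shape[2]

    @property
    def total_thin(self) -> int:
        return self.config.thin * self.extra_thin

    def flat(self) -> np.ndarray:
        """All chains concatenated: (n_chains * n_retained, n_params)."""
        return self.array.reshape(-1, self.array.shape[2])

    def get(self, name: str) -> np.ndarray:
        """Draws of one named parameter, shape (n_chains, n_retained)."""
        return self.array[:, :, self.param_names.index(name)]

    def thin_by(self, factor: int) -> "PosteriorDraws":
        """Keep every ``factor``-th retained draw (post-hoc thinning)."""
        if factor < 1:
            raise ValueError("thin factor must be >= 1")
        if factor == 1:
            return self
        return replace(
            self,
            array=self.array[:, factor - 1 :: factor].copy(),
            extra_thin=self.extra_thin * factor,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: chain, iteration, parameter, value."""
        c, k, p = self.array.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), k * p),
                "iteration": np.tile(np.repeat(np.arange(k), p), c),
                "parameter": np.tile(np.asarray(self.param_names, dtype=object), c * k),
                "value": self.array.reshape(-1),
            }
        )


def run_mcmc(model, config: MCMCConfig) -> PosteriorDraws:
    """Sample the model's posterior by component-wise adaptive Metropolis.

    ``model`` must expose ``n_params``, ``param_names``,
    ``init_params(rng, chain)`` (deterministically overdispersed in the
    chain index), ``initial_scales()`` and ``make_state(params)``
    returning a :class:`ModelStateProtocol` implementation.
    """
    n_params = model.n_params
    n_keep = config.n_retained
    if n_keep < 1:
        raise ConfigError("schedule retains no draws; reduce burn_in or thin")
    out = np.empty((config.n_chains, n_keep, n_params))
    acc_post = np.zeros((config.n_chains, n_params))
    final_scales = np.empty((config.n_chains, n_params))
    window = config.adapt_window
    target = config.target_accept
    # models may request extra within-iteration scans of some components
    order = list(getattr(model, "sweep_order", range(n_params)))
    n_moves = len(order)
    visits = np.bincount(order, minlength=n_params).astype(float)

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + chain)
        params = np.asarray(model.init_params(rng, chain), dtype=float)
        state = model.make_state(params)
        gibbs_sweep = getattr(state, "gibbs_sweep", None)
        scales = [float(s) for s in model.initial_scales()]
        log_scales = [math.log(s) for s in scales]
        batch_acc = [0] * n_params
        n_batches = 0
        kept = 0

        post_acc = [0] * n_params

        for it in range(config.n_iter):
            zs = rng.standard_normal(n_moves).tolist()
            lus = np.log(rng.random(n_moves)).tolist()
            in_burn = it < config.burn_in
            adapting = in_burn and config.adapt_during_burn_in
            if gibbs_sweep is not None:
                gibbs_sweep(rng, adapting)
            if in_burn:
                for j, p in enumerate(order):
                    dlp = state.propose(p, zs[j] * scales[p])
                    if dlp >= 0.0 or lus[j] < dlp:
                        state.accept()
                        batch_acc[p] += 1
                    else:
                        state.reject()
                    # interleave the extra kernel between component scans
                    if gibbs_sweep is not None and (j + 1) % n_params == 0:
                        gibbs_sweep(rng, adapting)
                if config.adapt_during_burn_in and (it + 1) % window == 0:
                    n_batches += 1
                    step = 1.0 / math.sqrt(n_batches)
                    for p in range(n_params):
                        rate = batch_acc[p] / (window * visits[p])
                        ls = log_scales[p] + step * (rate - target)
                        log_scales[p] = min(5.0, max(-13.0, ls))
                        scales[p] = math.exp(log_scales[p])
                        batch_acc[p] = 0
            else:
                for j, p in enumerate(order):
                    dlp = state.propose(p, zs[j] * scales[p])
                    if dlp >= 0.0 or lus[j] < dlp:
                        state.accept()
                        post_acc[p] += 1
                    else:
                        state.reject()
                    if gibbs_sweep is not None and (j + 1) % n_params == 0:
                        gibbs_sweep(rng, False)
                if (it - config.burn_in + 1) % config.thin == 0 and kept < n_keep:
                    out[chain, kept] = state.params_array()
                    kept += 1

        denom = max(1, config.n_iter - config.burn_in)
        acc_post[chain] = np.asarray(post_acc, dtype=float) / (denom * visits)
        final_scales[chain] = scales

    return PosteriorDraws(
        param_names=list(model.param_names),
        array=out,
        acceptance=acc_post,
        config=config,
        proposal_scales=final_scales,
    )
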