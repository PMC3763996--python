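"""Bayesian models of screening activity and their posterior summaries.

Two model tiers mirror the two-stage analysis protocol:

**Hierarchical tier** — a mixed-effects logistic model of the per-sample
category-level active indicator:

    y_i ~ Bernoulli(p_i),   logit(p_i) = mu + a[taxon(i)] + b[region(i)] + u[cell(i)]

with sum-to-zero fixed taxon and bioregion effects, a Normal(0, sigma)
random effect per (taxon, bioregion) data cell, vague Normal(0, 100)
priors on all coefficients and a Uniform(0, 100] prior on sigma.
Because samples within a cell share one linear predictor, the Bernoulli
likelihood collapses to cell-level binomial sufficient statistics, which
the sampler exploits.

**Main-effects tier** — a Normal model of the observed cell
percent-active values with a single fixed factor (taxon or bioregion):

    pct_c ~ Normal(mu + e[level(c)], sigma_resid)

with the same prior structure.

Posterior marginal means per factor level are predicted from the draws:
for the hierarchical tier the inverse-logit linear predictor is averaged
over the observed levels of the other factor with the cell random effect
at zero (predicting the typical cell; a noise-integrated variant is
available), then scaled to percent.  Equal-tailed 95% credible
intervals come straight from the 2.5/97.5 posterior percentiles.  The
grand mean is the per-draw average over the factor's levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammainc, gammaincinv
from sklearn.base import BaseEstimator

from .errors import ConfigError
from .lineage import LineageScheme, default_scheme
from .sampler import MCMCConfig, PosteriorDraws, run_mcmc

__all__ = [
    "ModelSpec",
    "build_model",
    "log_posterior",
    "marginal_means",
    "lineage_marginal_means",
    "HierarchicalActivityModel",
    "CellMeansModel",
]

HIERARCHICAL = "hierarchical"
MAIN_EFFECTS = "main_effects"

GRAND_MEAN_LABEL = "GRAND_MEAN"

_LOG_2PI = math.log(2.0 * math.pi)


def _softplus(x: float) -> float:
    # log(1 + e^x), overflow-safe for the scalar incremental updates
    if x > 35.0:
        return x
    if x < -35.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


def _draw_sigma_conditional(
    rng: np.random.Generator, n_terms: int, sum_sq: float, upper: float
) -> float | None:
    """Exact draw of a scale parameter from its full conditional.

    With a Uniform(0, upper] prior on sigma and ``n_terms`` Normal(0,
    sigma) terms with summed squares ``sum_sq``, the conditional of
    tau = sigma^-2 is Gamma((n_terms - 1)/2, rate sum_sq/2) truncated to
    tau >= upper^-2; inverse-CDF sampling is exact and mixes the scale
    parameter independently of its random-walk history.  Returns None
    when the conditional is degenerate (too few terms or zero sums).
    """
    shape = 0.5 * (n_terms - 1)
    if shape <= 0 or sum_sq <= 0:
        return None
    rate = 0.5 * sum_sq
    lo = float(gammainc(shape, rate * upper**-2))  # regularized lower P
    u = lo + rng.random() * (1.0 - lo)
    if u >= 1.0:
        u = 1.0 - 1e-16
    tau = float(gammaincinv(shape, u)) / rate
    if not math.isfinite(tau) or tau <= 0:
        return None
    # guard the truncation against CDF round-off when the in-support
    # tail mass underflows (otherwise sigma could escape its prior)
    tau = max(tau, upper**-2)
    return float(tau**-0.5)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model tier.

    ``sigma_fixed`` pins the residual SD of the main-effects tier to a
    known value (used by conjugate validation scenarios); ``None`` (the
    default) samples it under the uniform prior.
    """

    tier: str
    response: str
    factors: tuple[str, ...]
    random_terms: tuple[str, ...] = ()
    prior_coef_sd: float = 100.0
    prior_sd_upper: float = 100.0
    link: str = "logit"
    sigma_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.tier == HIERARCHICAL:
            if self.response != "per_sample_active" or self.link != "logit":
                raise ConfigError(
                    "hierarchical tier models per-sample active indicators "
                    "on the logit link"
                )
            if tuple(self.factors) != ("taxon", "bioregion"):
                raise ConfigError(
                    "hierarchical tier uses factors ('taxon', 'bioregion')"
                )
            if tuple(self.random_terms) != ("cell",):
                raise ConfigError("hierarchical tier requires the cell random term")
        elif self.tier == MAIN_EFFECTS:
            if self.response != "cell_percent" or self.link != "identity":
                raise ConfigError(
                    "main-effects tier models cell percentages on the identity link"
                )
            if len(self.factors) != 1:
                raise ConfigError("main-effects tier takes exactly one factor")
            if self.random_terms:
                raise ConfigError("main-effects tier has no random terms")
        else:
            raise ConfigError(f"unknown tier {self.tier!r}")
        if self.prior_coef_sd <= 0 or self.prior_sd_upper <= 0:
            raise ConfigError("prior scales must be positive")

    @classmethod
    def hierarchical(cls, **kw) -> "ModelSpec":
        return cls(
            tier=HIERARCHICAL,
            response="per_sample_active",
            factors=("taxon", "bioregion"),
            random_terms=("cell",),
            link="logit",
            **kw,
        )

    @classmethod
    def main_effects(cls, factor: str, **kw) -> "ModelSpec":
        return cls(
            tier=MAIN_EFFECTS,
            response="cell_percent",
            factors=(factor,),
            link="identity",
            **kw,
        )


# ---------------------------------------------------------------------------
# Hierarchical tier
# ---------------------------------------------------------------------------


class HierarchicalLogitModel:
    """Design structure and posterior of the hierarchical Bernoulli tier."""

    def __init__(self, calls: pd.DataFrame, spec: ModelSpec):
        if len(calls) == 0:
            raise ConfigError("empty data")
        taxon_col = "taxon" if "taxon" in calls.columns else "phylum"
        needed = {taxon_col, "bioregion", "active"}
        missing = needed - set(calls.columns)
        if missing:
            raise ConfigError(f"calls table missing columns: {sorted(missing)}")
        self.spec = spec
        grouped = calls.groupby([taxon_col, "bioregion"], sort=True)["active"]
        cells = grouped.agg(n="size", k="sum").reset_index()
        self.taxon_levels = sorted(calls[taxon_col].unique())
        self.region_levels = sorted(calls["bioregion"].unique())
        if len(self.taxon_levels) < 2 or len(self.region_levels) < 2:
            raise ConfigError("each factor needs at least 2 observed levels")
        t_pos = {t: i for i, t in enumerate(self.taxon_levels)}
        r_pos = {r: i for i, r in enumerate(self.region_levels)}
        self.t_idx = [t_pos[t] for t in cells[taxon_col]]
        self.r_idx = [r_pos[r] for r in cells["bioregion"]]
        self.n = [int(v) for v in cells["n"]]
        self.k = [int(v) for v in cells["k"]]
        self.cell_labels = [
            f"{t}:{r}" for t, r in zip(cells[taxon_col], cells["bioregion"])
        ]

        T, R, C = len(self.taxon_levels), len(self.region_levels), len(self.n)
        self.n_cells = C
        self.param_names = (
            ["intercept"]
            + [f"taxon[{t}]" for t in self.taxon_levels[:-1]]
            + [f"bioregion[{r}]" for r in self.region_levels[:-1]]
            + [f"cell[{c}]" for c in self.cell_labels]
            + ["sigma_cell"]
        )
        self.n_params = len(self.param_names)
        self._taxon_off = 1
        self._region_off = 1 + (T - 1)
        self._cell_off = self._region_off + (R - 1)
        self._sigma_idx = self.n_params - 1

        # affected cells per coefficient parameter: (cell index, sign)
        aff: list[list[tuple[int, int]] | None] = [None] * self.n_params
        aff[0] = [(c, +1) for c in range(C)]
        for j in range(T - 1):
            lst = []
            for c in range(C):
                if self.t_idx[c] == j:
                    lst.append((c, +1))
                elif self.t_idx[c] == T - 1:
                    lst.append((c, -1))
            aff[self._taxon_off + j] = lst
        for j in range(R - 1):
            lst = []
            for c in range(C):
                if self.r_idx[c] == j:
                    lst.append((c, +1))
                elif self.r_idx[c] == R - 1:
                    lst.append((c, -1))
            aff[self._region_off + j] = lst
        self._affected = aff
        # per-iteration update schedule: three full component scans.
        # The sweep kernel's composition is a sampler design choice;
        # richer scans cut the per-iteration autocorrelation that the
        # post-hoc thinning rule must absorb.
        self.sweep_order = list(range(self.n_params)) * 3

    # -- parameter helpers ------------------------------------------------

    def split(self, params: np.ndarray):
        """(mu, full taxon effects, full region effects, cell effects, sigma)."""
        params = np.asarray(params, dtype=float)
        mu = params[..., 0]
        at = params[..., self._taxon_off : self._region_off]
        br = params[..., self._region_off : self._cell_off]
        u = params[..., self._cell_off : self._sigma_idx]
        sigma = params[..., self._sigma_idx]
        a_full = np.concatenate([at, -at.sum(axis=-1, keepdims=True)], axis=-1)
        b_full = np.concatenate([br, -br.sum(axis=-1, keepdims=True)], axis=-1)
        return mu, a_full, b_full, u, sigma

    def log_posterior(self, params: np.ndarray) -> float:
        """Full vectorized log posterior (reference path; the sampler uses
        the incremental state below, which must agree with this)."""
        mu, a, b, u, sigma = self.split(np.asarray(params, dtype=float))
        if sigma <= 0 or sigma > self.spec.prior_sd_upper:
            return -math.inf
        t = np.asarray(self.t_idx)
        r = np.asarray(self.r_idx)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        eta = mu + a[t] + b[r] + u
        ll = float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))
        s2 = self.spec.prior_coef_sd**2
        coefs = np.concatenate([[mu], a[:-1], b[:-1]])
        lp_coef = float(
            -0.5 * len(coefs) * (_LOG_2PI + math.log(s2))
            - np.sum(coefs**2) / (2.0 * s2)
        )
        lp_cell = float(
            -0.5 * len(u) * (_LOG_2PI + 2.0 * math.log(sigma))
            - np.sum(u**2) / (2.0 * sigma**2)
        )
        lp_sigma = -math.log(self.spec.prior_sd_upper)
        return ll + lp_coef + lp_cell + lp_sigma

    # -- sampler interface -------------------------------------------------

    def init_params(self, rng: np.random.Generator, chain: int) -> np.ndarray:
        k_tot = sum(self.k)
        n_tot = sum(self.n)
        p0 = (k_tot + 1.0) / (n_tot + 2.0)
        params = np.zeros(self.n_params)
        params[0] = math.log(p0 / (1 - p0)) + rng.normal(0.0, 1.0)
        params[1 : self._cell_off] = rng.normal(0.0, 0.5, self._cell_off - 1)
        params[self._cell_off : self._sigma_idx] = rng.normal(
            0.0, 0.3, self.n_cells
        )
        params[self._sigma_idx] = rng.uniform(0.2, 2.0)
        return params

    def initial_scales(self) -> np.ndarray:
        scales = np.full(self.n_params, 0.3)
        scales[self._sigma_idx] = 0.2
        return scales

    def make_state(self, params: np.ndarray) -> "_HierState":
        return _HierState(self, params)


class _HierState:
    """Incremental log-posterior state for :class:`HierarchicalLogitModel`."""

    __slots__ = (
        "m", "params", "eta", "ll", "sum_u2", "sigma", "pending", "_prior_s2",
        "_eps_scale", "_eps_acc", "_eps_calls", "_eps_batches",
    )

    def __init__(self, model: HierarchicalLogitModel, params: np.ndarray):
        self.m = model
        self.params = [float(v) for v in params]
        mu, a, b, u, sigma = model.split(np.asarray(params, dtype=float))
        self.sigma = float(sigma)
        self._prior_s2 = model.spec.prior_coef_sd**2
        self.eta = [
            float(mu + a[model.t_idx[c]] + b[model.r_idx[c]] + u[c])
            for c in range(model.n_cells)
        ]
        self.ll = [
            model.k[c] * self.eta[c] - model.n[c] * _softplus(self.eta[c])
            for c in range(model.n_cells)
        ]
        self.sum_u2 = float(np.sum(u * u))
        self.pending = None
        self._eps_scale = 0.2  # log-scale step of the joint (u, sigma) rescale
        self._eps_acc = 0
        self._eps_calls = 0
        self._eps_batches = 0

    def propose(self, i: int, d: float) -> float:
        m = self.m
        if i == m._sigma_idx:
            s0 = self.sigma
            s1 = s0 + d
            if s1 <= 0.0 or s1 > m.spec.prior_sd_upper:
                self.pending = None
                return -math.inf
            self.pending = ("s", i, d)
            return -m.n_cells * (math.log(s1) - math.log(s0)) - 0.5 * self.sum_u2 * (
                1.0 / (s1 * s1) - 1.0 / (s0 * s0)
            )
        if i >= m._cell_off:
            c = i - m._cell_off
            u = self.params[i]
            ne = self.eta[c] + d
            nll = m.k[c] * ne - m.n[c] * _softplus(ne)
            self.pending = ("u", i, d, c, ne, nll)
            dlp = -d * (2.0 * u + d) / (2.0 * self.sigma * self.sigma)
            return dlp + nll - self.ll[c]
        # fixed-effect coefficient (intercept / taxon / bioregion)
        x = self.params[i]
        dlp = -d * (2.0 * x + d) / (2.0 * self._prior_s2)
        dll = 0.0
        pend = []
        eta = self.eta
        ll = self.ll
        k = m.k
        n = m.n
        for c, s in m._affected[i]:
            ne = eta[c] + d if s > 0 else eta[c] - d
            nll = k[c] * ne - n[c] * _softplus(ne)
            dll += nll - ll[c]
            pend.append((c, ne, nll))
        self.pending = ("b", i, d, pend)
        return dlp + dll

    def accept(self) -> None:
        pend = self.pending
        kind = pend[0]
        if kind == "b":
            _, i, d, cells = pend
            self.params[i] += d
            eta = self.eta
            ll = self.ll
            for c, ne, nll in cells:
                eta[c] = ne
                ll[c] = nll
        elif kind == "u":
            _, i, d, c, ne, nll = pend
            u = self.params[i]
            self.params[i] = u + d
            self.eta[c] = ne
            self.ll[c] = nll
            self.sum_u2 += d * (2.0 * u + d)
        else:
            _, i, d = pend
            self.params[i] += d
            self.sigma = self.params[i]
        self.pending = None

    def reject(self) -> None:
        self.pending = None

    def gibbs_sweep(self, rng: np.random.Generator, adapt: bool = False) -> None:
        """Extra per-iteration moves for the variance component.

        (1) A joint rescale of all cell effects and sigma by a common
        factor c = e^eps — the direction along which component-wise
        moves are slowest (the scale funnel).  The Normal prior's
        quadratic term is invariant under the joint rescale, so the MH
        log-ratio is the likelihood change plus eps (the net of prior
        and Jacobian terms).  Its step size self-adapts during burn-in.
        (2) An exact draw of sigma from its full conditional (truncated
        inverse-gamma under the uniform prior).
        """
        m = self.m
        # refresh the running sum of squared cell effects from scratch:
        # the incremental updates are exact in expectation but can lose
        # all precision during large joint rescales, and sigma's moves
        # key off this quantity
        off = m._cell_off
        self.sum_u2 = math.fsum(
            self.params[off + c] ** 2 for c in range(m.n_cells)
        )
        for _ in range(6):  # a few rescale attempts per call
            eps = rng.normal(0.0, self._eps_scale)
            c = math.exp(eps)
            s1 = self.sigma * c
            self._eps_calls += 1
            if s1 <= m.spec.prior_sd_upper:
                params = self.params
                eta = self.eta
                ll = self.ll
                k = m.k
                n = m.n
                dll = 0.0
                new_vals = []
                for cell in range(m.n_cells):
                    u = params[off + cell]
                    ne = eta[cell] + (c - 1.0) * u
                    nll = k[cell] * ne - n[cell] * _softplus(ne)
                    dll += nll - ll[cell]
                    new_vals.append((ne, nll))
                if dll + eps >= 0.0 or math.log(rng.random()) < dll + eps:
                    for cell, (ne, nll) in enumerate(new_vals):
                        params[off + cell] *= c
                        eta[cell] = ne
                        ll[cell] = nll
                    self.sum_u2 *= c * c
                    self.sigma = s1
                    params[m._sigma_idx] = s1
                    self._eps_acc += 1
            if adapt and self._eps_calls % 50 == 0:
                self._eps_batches += 1
                rate = self._eps_acc / 50.0
                step = 1.0 / math.sqrt(self._eps_batches)
                self._eps_scale = float(
                    np.clip(self._eps_scale * math.exp(step * (rate - 0.44)),
                            1e-4, 1.0)
                )
                self._eps_acc = 0
            s = _draw_sigma_conditional(
                rng, m.n_cells, self.sum_u2, m.spec.prior_sd_upper
            )
            if s is not None:
                self.sigma = s
                self.params[m._sigma_idx] = s

    def params_array(self) -> np.ndarray:
        return np.asarray(self.params, dtype=float)


# ---------------------------------------------------------------------------
# Main-effects tier
# ---------------------------------------------------------------------------


class MainEffectsModel:
    """Normal model of cell percentages with one sum-to-zero fixed factor."""

    def __init__(self, cells: pd.DataFrame, spec: ModelSpec,
                 response_col: str = "pct_active"):
        if len(cells) == 0:
            raise ConfigError("empty data")
        factor = spec.factors[0]
        if factor not in cells.columns:
            raise ConfigError(f"data has no column {factor!r}")
        if response_col not in cells.columns:
            raise ConfigError(f"data has no column {response_col!r}")
        self.spec = spec
        self.factor = factor
        self.levels = sorted(cells[factor].unique())
        if len(self.levels) < 2 and spec.sigma_fixed is None:
            raise ConfigError(f"factor {factor!r} has fewer than 2 levels")
        pos = {lv: i for i, lv in enumerate(self.levels)}
        y = cells[response_col].to_numpy(dtype=float)
        lvl = cells[factor].map(pos).to_numpy()
        L = len(self.levels)
        self.m = [int(np.sum(lvl == j)) for j in range(L)]
        self.sy = [float(np.sum(y[lvl == j])) for j in range(L)]
        self.syy = [float(np.sum(y[lvl == j] ** 2)) for j in range(L)]
        self.M_total = int(len(y))
        self._y = y
        self._lvl = lvl

        self.param_names = ["intercept"] + [
            f"{factor}[{lv}]" for lv in self.levels[:-1]
        ]
        self._free = L - 1
        if spec.sigma_fixed is None:
            self.param_names.append("sigma_resid")
            self._sigma_idx: int | None = len(self.param_names) - 1
        else:
            self._sigma_idx = None
        self.n_params = len(self.param_names)

        aff: list[list[tuple[int, int]]] = [[(j, +1) for j in range(L)]]
        for j in range(self._free):
            aff.append([(j, +1), (L - 1, -1)])
        self._affected = aff

    def split(self, params: np.ndarray):
        """(theta per level, sigma)."""
        params = np.asarray(params, dtype=float)
        mu = params[..., 0]
        e = params[..., 1 : 1 + self._free]
        e_full = np.concatenate([e, -e.sum(axis=-1, keepdims=True)], axis=-1)
        theta = mu[..., None] + e_full
        if self._sigma_idx is None:
            sigma = np.broadcast_to(
                np.asarray(self.spec.sigma_fixed, dtype=float), mu.shape
            )
        else:
            sigma = params[..., self._sigma_idx]
        return theta, sigma

    def log_posterior(self, params: np.ndarray) -> float:
        theta, sigma = self.split(np.asarray(params, dtype=float))
        sigma = float(sigma)
        if sigma <= 0 or (
            self._sigma_idx is not None and sigma > self.spec.prior_sd_upper
        ):
            return -math.inf
        resid = self._y - theta[self._lvl]
        ll = float(
            -0.5 * self.M_total * (_LOG_2PI + 2.0 * math.log(sigma))
            - np.sum(resid**2) / (2.0 * sigma**2)
        )
        params = np.asarray(params, dtype=float)
        coefs = params[: 1 + self._free]
        s2 = self.spec.prior_coef_sd**2
        lp = float(
            -0.5 * len(coefs) * (_LOG_2PI + math.log(s2))
            - np.sum(coefs**2) / (2.0 * s2)
        )
        if self._sigma_idx is not None:
            lp += -math.log(self.spec.prior_sd_upper)
        return ll + lp

    def init_params(self, rng: np.random.Generator, chain: int) -> np.ndarray:
        ybar = float(np.mean(self._y))
        ysd = float(np.std(self._y)) or 1.0
        params = np.zeros(self.n_params)
        params[0] = ybar + rng.normal(0.0, ysd + 1.0)
        params[1 : 1 + self._free] = rng.normal(0.0, 0.5 * ysd, self._free)
        if self._sigma_idx is not None:
            upper = self.spec.prior_sd_upper
            params[self._sigma_idx] = min(
                upper, max(1e-3, ysd * rng.uniform(0.5, 2.0))
            )
        return params

    def initial_scales(self) -> np.ndarray:
        ysd = float(np.std(self._y)) or 1.0
        scales = np.full(self.n_params, ysd / math.sqrt(max(2, self.M_total / 4)))
        if self._sigma_idx is not None:
            scales[self._sigma_idx] = ysd / 2.0 or 1.0
        return scales

    def make_state(self, params: np.ndarray) -> "_MainState":
        return _MainState(self, params)


class _MainState:
    """Incremental log-posterior state for :class:`MainEffectsModel`."""

    __slots__ = ("m", "params", "theta", "sse", "total_sse", "sigma", "pending",
                 "_prior_s2")

    def __init__(self, model: MainEffectsModel, params: np.ndarray):
        self.m = model
        self.params = [float(v) for v in params]
        theta, sigma = model.split(np.asarray(params, dtype=float))
        self.sigma = float(sigma)
        self._prior_s2 = model.spec.prior_coef_sd**2
        self.theta = [float(t) for t in theta]
        self.sse = [
            model.syy[j] - 2.0 * self.theta[j] * model.sy[j]
            + model.m[j] * self.theta[j] ** 2
            for j in range(len(model.levels))
        ]
        self.total_sse = sum(self.sse)
        self.pending = None

    def propose(self, i: int, d: float) -> float:
        m = self.m
        if m._sigma_idx is not None and i == m._sigma_idx:
            s0 = self.sigma
            s1 = s0 + d
            if s1 <= 0.0 or s1 > m.spec.prior_sd_upper:
                self.pending = None
                return -math.inf
            self.pending = ("s", i, d)
            return -m.M_total * (math.log(s1) - math.log(s0)) - 0.5 * self.total_sse * (
                1.0 / (s1 * s1) - 1.0 / (s0 * s0)
            )
        x = self.params[i]
        dlp = -d * (2.0 * x + d) / (2.0 * self._prior_s2)
        inv2s2 = 1.0 / (2.0 * self.sigma * self.sigma)
        dll = 0.0
        pend = []
        for j, s in m._affected[i]:
            tn = self.theta[j] + d if s > 0 else self.theta[j] - d
            ssen = m.syy[j] - 2.0 * tn * m.sy[j] + m.m[j] * tn * tn
            dll -= (ssen - self.sse[j]) * inv2s2
            pend.append((j, tn, ssen))
        self.pending = ("b", i, d, pend)
        return dlp + dll

    def accept(self) -> None:
        pend = self.pending
        if pend[0] == "b":
            _, i, d, levels = pend
            self.params[i] += d
            for j, tn, ssen in levels:
                self.total_sse += ssen - self.sse[j]
                self.theta[j] = tn
                self.sse[j] = ssen
        else:
            _, i, d = pend
            self.params[i] += d
            self.sigma = self.params[i]
        self.pending = None

    def reject(self) -> None:
        self.pending = None

    def gibbs_sweep(self, rng: np.random.Generator, adapt: bool = False) -> None:
        """Exact conditional draw of the residual SD (when not fixed)."""
        if self.m._sigma_idx is None:
            return
        s = _draw_sigma_conditional(
            rng, self.m.M_total, self.total_sse, self.m.spec.prior_sd_upper
        )
        if s is not None:
            self.sigma = s
            self.params[self.m._sigma_idx] = s

    def params_array(self) -> np.ndarray:
        return np.asarray(self.params, dtype=float)


# ---------------------------------------------------------------------------
# Construction and posterior summaries
# ---------------------------------------------------------------------------


def build_model(data: pd.DataFrame, spec: ModelSpec):
    """Build the design structure + parameter index for one model tier.

    ``data`` is a calls table (hierarchical tier: one row per sample x
    category with an ``active`` column) or a cell-summary table
    (main-effects tier: one row per cell with ``pct_active``).
    """
    if spec.tier == HIERARCHICAL:
        return HierarchicalLogitModel(data, spec)
    return MainEffectsModel(data, spec)


def log_posterior(model, params) -> float:
    """Joint log posterior of ``params`` under ``model``."""
    return model.log_posterior(np.asarray(params, dtype=float))


def _hier_level_values(
    model: HierarchicalLogitModel,
    flat: np.ndarray,
    factor: str,
    integrate_cell_noise: bool,
    chunk: int = 4000,
) -> tuple[np.ndarray, list[str]]:
    """Per-draw marginal mean (in %) for each level of ``factor``."""
    if factor == "taxon":
        levels = model.taxon_levels
    elif factor == "bioregion":
        levels = model.region_levels
    else:
        raise ValueError(f"unknown factor {factor!r}")
    N = flat.shape[0]
    out = np.empty((N, len(levels)))
    if integrate_cell_noise:
        nodes, weights = np.polynomial.hermite_e.hermegauss(21)
        weights = weights / weights.sum()
    for start in range(0, N, chunk):
        block = flat[start : start + chunk]
        mu, a, b, _, sigma = model.split(block)
        eta = mu[:, None, None] + a[:, :, None] + b[:, None, :]
        if factor == "bioregion":
            eta = np.swapaxes(eta, 1, 2)
        if integrate_cell_noise:
            probs = np.zeros_like(eta)
            for z, w in zip(nodes, weights):
                probs += w * expit(eta + sigma[:, None, None] * z)
        else:
            probs = expit(eta)
        out[start : start + chunk] = 100.0 * probs.mean(axis=2)
    return out, [str(lv) for lv in levels]


def _summarize_levels(
    values: np.ndarray, levels: list[str], truncate: bool = True
) -> pd.DataFrame:
    """Mean and equal-tailed 95% CI per level, plus the grand-mean row."""
    grand = values.mean(axis=1, keepdims=True)
    mat = np.concatenate([values, grand], axis=1)
    names = levels + [GRAND_MEAN_LABEL]
    mean = mat.mean(axis=0)
    lo, hi = np.percentile(mat, [2.5, 97.5], axis=0)
    df = pd.DataFrame(
        {
            "level": names,
            "mean": mean,
            "ci_lower": np.clip(lo, 0.0, 100.0) if truncate else lo,
            "ci_upper": np.clip(hi, 0.0, 100.0) if truncate else hi,
            "mean_raw": mean,
            "ci_lower_raw": lo,
            "ci_upper_raw": hi,
            "n_draws": mat.shape[0],
        }
    )
    if truncate:
        df["mean"] = np.clip(df["mean"], 0.0, 100.0)
    return df


def marginal_means(
    draws: PosteriorDraws,
    model,
    factor: str,
    integrate_cell_noise: bool = False,
    diagnostics=None,
    allow_unconverged: bool = False,
) -> pd.DataFrame:
    """Posterior predicted marginal mean percent-active per factor level.

    Hierarchical tier: per draw the inverse-logit linear predictor is
    averaged over the observed levels of the other factor with cell
    random effects at zero (or integrated over Normal(0, sigma) when
    ``integrate_cell_noise``), x100.  Main-effects tier: the level mean
    ``mu + e_level`` directly.  A ``GRAND_MEAN`` row holds the per-draw
    average over levels.  Reported percentages are truncated to
    [0, 100]; the untruncated values stay in the ``*_raw`` columns.

    If a :class:`~phyloscreen.diagnostics.DiagnosticsReport` is passed
    and failed, a ``RuntimeError`` is raised unless
    ``allow_unconverged`` is set.
    """
    if diagnostics is not None and not diagnostics.passed and not allow_unconverged:
        raise RuntimeError(
            "convergence diagnostics failed "
            f"({'; '.join(diagnostics.reasons)}); pass allow_unconverged=True "
            "to summarize anyway"
        )
    flat = draws.flat()
    if isinstance(model, HierarchicalLogitModel):
        values, levels = _hier_level_values(
            model, flat, factor, integrate_cell_noise
        )
    elif isinstance(model, MainEffectsModel):
        if factor != model.factor:
            raise ValueError(
                f"model was built for factor {model.factor!r}, not {factor!r}"
            )
        theta, _ = model.split(flat)
        values, levels = theta, [str(lv) for lv in model.levels]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    df = _summarize_levels(values, levels)
    df.insert(0, "factor", factor)
    return df


def lineage_marginal_means(
    draws: PosteriorDraws,
    model: HierarchicalLogitModel,
    scheme: LineageScheme | None = None,
    method: str = "mean_of_phyla",
    phylum_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Roll taxon marginal means up to phylogenetic lineages.

    ``method="mean_of_phyla"`` (default) averages the member taxa's
    per-draw marginal means with equal weight, propagating the full
    posterior; ``method="pooled"`` weights each taxon by its number of
    tested samples.  ``phylum_of`` maps genus-level taxon labels to
    phyla when the model was fitted at genus aggregation.
    """
    scheme = scheme or default_scheme()
    values, levels = _hier_level_values(model, draws.flat(), "taxon", False)
    weights = {}
    if method == "pooled":
        for t_i, n in zip(model.t_idx, model.n):
            weights[levels[t_i]] = weights.get(levels[t_i], 0) + n
    elif method != "mean_of_phyla":
        raise ValueError(f"unknown method {method!r}")
    groups: dict[str, list[int]] = {}
    for i, taxon in enumerate(levels):
        phylum = phylum_of.get(taxon, taxon) if phylum_of else taxon
        lin = scheme.lineage[phylum] if phylum in scheme.lineage else None
        if lin is None:
            raise KeyError(f"phylum {phylum!r} is not in the lineage scheme")
        groups.setdefault(lin, []).append(i)
    rows = []
    per_lineage = []
    names = []
    for lin in sorted(groups):
        idx = groups[lin]
        if method == "pooled":
            w = np.asarray([weights.get(levels[i], 0) for i in idx], dtype=float)
            w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
            agg = values[:, idx] @ w
        else:
            agg = values[:, idx].mean(axis=1)
        per_lineage.append(agg[:, None])
        names.append(lin)
    mat = np.concatenate(per_lineage, axis=1)
    df = _summarize_levels(mat, names)
    df.insert(0, "factor", "lineage")
    df.attrs["method"] = method
    return df


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class _BayesEstimatorMixin:
    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=int(self.random_state or 0),
            target_accept=self.target_accept,
        )

    def _run(self, model) -> None:
        from .diagnostics import auto_thin, diagnose

        self.model_ = model
        draws = run_mcmc(model, self._mcmc_config())
        report = diagnose(draws)
        if self.auto_thin and not report.passed:
            draws, report = auto_thin(draws, report)
        self.draws_ = draws
        self.diagnostics_ = report

    def marginal_means(
        self,
        factor: str | None = None,
        integrate_cell_noise: bool = False,
        allow_unconverged: bool = False,
    ) -> pd.DataFrame:
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted")
        if factor is None:
            factor = getattr(self.model_, "factor", "taxon")
        return marginal_means(
            self.draws_,
            self.model_,
            factor,
            integrate_cell_noise=integrate_cell_noise,
            diagnostics=self.diagnostics_,
            allow_unconverged=allow_unconverged,
        )


class HierarchicalActivityModel(_BayesEstimatorMixin, BaseEstimator):
    """Hierarchical Bernoulli-logit model of per-sample activity calls.

    Fit on a calls table (columns ``taxon`` — or ``phylum`` —,
    ``bioregion``, ``active``); fitted attributes are ``model_``,
    ``draws_`` and ``diagnostics_``.  ``auto_thin`` applies the smallest
    post-hoc thinning factor in {2, 5, 10, 20} that brings every
    parameter's lag-1 autocorrelation under 0.1 when the unthinned
    chains fail that rule.
    """

    def __init__(
        self,
        prior_coef_sd: float = 100.0,
        prior_sd_upper: float = 100.0,
        n_chains: int = 3,
        n_iter: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 1,
        target_accept: float = 0.44,
        auto_thin: bool = True,
        random_state: int = 0,
    ):
        self.prior_coef_sd = prior_coef_sd
        self.prior_sd_upper = prior_sd_upper
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.target_accept = target_accept
        self.auto_thin = auto_thin
        self.random_state = random_state

    def fit(self, calls: pd.DataFrame, y=None):
        spec = ModelSpec.hierarchical(
            prior_coef_sd=self.prior_coef_sd, prior_sd_upper=self.prior_sd_upper
        )
        self._run(build_model(calls, spec))
        return self

    def lineage_means(
        self,
        scheme: LineageScheme | None = None,
        method: str = "mean_of_phyla",
        phylum_of: dict[str, str] | None = None,
    ) -> pd.DataFrame:
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted")
        return lineage_marginal_means(
            self.draws_, self.model_, scheme, method, phylum_of
        )


class CellMeansModel(_BayesEstimatorMixin, BaseEstimator):
    """Main-effects Normal model of cell percent-active values.

    Fit on a cell-summary table; one fixed factor (``taxon`` or
    ``bioregion``) with sum-to-zero effects, shared residual SD under a
    Uniform(0, prior_sd_upper] prior (or pinned via ``sigma_fixed``).
    """

    def __init__(
        self,
        factor: str = "bioregion",
        prior_coef_sd: float = 100.0,
        prior_sd_upper: float = 100.0,
        sigma_fixed: float | None = None,
        n_chains: int = 3,
        n_iter: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 1,
        target_accept: float = 0.44,
        auto_thin: bool = True,
        random_state: int = 0,
    ):
        self.factor = factor
        self.prior_coef_sd = prior_coef_sd
        self.prior_sd_upper = prior_sd_upper
        self.sigma_fixed = sigma_fixed
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.target_accept = target_accept
        self.auto_thin = auto_thin
        self.random_state = random_state

    def fit(self, cells: pd.DataFrame, y=None):
        spec = ModelSpec.main_effects(
            self.factor,
            prior_coef_sd=self.prior_coef_sd,
            prior_sd_upper=self.prior_sd_upper,
            sigma_fixed=self.sigma_fixed,
        )
        self._run(build_model(cells, spec))
        return self
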