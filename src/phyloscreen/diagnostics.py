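"""MCMC convergence diagnostics: lag-1 autocorrelation, split R-hat, ESS.

The independence rule follows the analysis protocol this package
reproduces — every parameter's post-thinning lag-1 autocorrelation must
be below 0.1 — augmented with a programmatic convergence check (split
R-hat < 1.05, replacing the protocol's visual assessment) and bulk
effective sample sizes.  When the autocorrelation rule fails, the
smallest post-hoc thinning factor in {2, 5, 10, 20} that restores it is
recommended (and optionally applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from .sampler import PosteriorDraws

__all__ = ["DiagnosticsReport", "diagnose", "auto_thin"]

DEFAULT_THIN_CANDIDATES = (2, 5, 10, 20)


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary for one set of posterior draws."""

    param_names: list[str]
    lag1_autocorr: np.ndarray  # worst (max |acf|) across chains, per parameter
    rhat: np.ndarray
    ess: np.ndarray
    passed: bool
    reasons: list[str] = field(default_factory=list)
    autocorr_limit: float = 0.1
    rhat_limit: float = 1.05
    recommended_thin: int | None = None  # extra post-hoc thinning, if needed
    thin_applied: int = 1

    @property
    def max_lag1(self) -> float:
        return float(np.nanmax(self.lag1_autocorr))

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(self.ess))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "lag1_autocorr": self.lag1_autocorr,
                "rhat": self.rhat,
                "ess": self.ess,
            }
        )


def _lag1_autocorr(array: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation magnitude per parameter.

    Computed on the concatenated post-burn-in (thinned) chains after
    removing each chain's own mean, so between-chain location
    differences do not masquerade as autocorrelation; the chain seams
    contribute nothing.  A zero-variance parameter yields NaN.
    """
    centered = array - array.mean(axis=1, keepdims=True)
    var = (centered**2).mean(axis=(0, 1))
    # within-chain lag-1 products pooled across chains (no seam terms)
    cov = (centered[:, :-1] * centered[:, 1:]).sum(axis=(0, 1)) / (
        array.shape[0] * array.shape[1]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        acf = np.where(var > 0, cov / var, np.nan)
    return np.abs(acf)


def _to_dataset(draws: PosteriorDraws) -> xr.Dataset:
    return xr.Dataset(
        {"theta": (("chain", "draw", "param"), draws.array)},
        coords={"param": draws.param_names},
    )


def diagnose(
    draws: PosteriorDraws,
    autocorr_limit: float = 0.1,
    rhat_limit: float = 1.05,
    thin_candidates: tuple[int, ...] = DEFAULT_THIN_CANDIDATES,
) -> DiagnosticsReport:
    """Check sample independence and convergence of retained draws.

    Passes iff every parameter's lag-1 autocorrelation (worst chain) is
    below ``autocorr_limit`` and every split R-hat is below
    ``rhat_limit``.  Zero-variance (constant) parameter chains and
    completely rejecting chains are reported as failures with an
    explicit reason.  If only the autocorrelation rule fails, the
    smallest candidate thinning factor that would restore it is stored
    in ``recommended_thin``.
    """
    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    if draws.n_retained < 100:
        raise ValueError(
            f"diagnostics require >= 100 retained draws, got {draws.n_retained}"
        )
    lag1 = _lag1_autocorr(draws.array)
    ds = _to_dataset(draws)
    rhat = az.rhat(ds)["theta"].to_numpy()
    ess = az.ess(ds)["theta"].to_numpy()

    reasons: list[str] = []
    constant = np.isnan(lag1)
    if constant.any():
        bad = [draws.param_names[i] for i in np.nonzero(constant)[0][:5]]
        reasons.append(
            f"zero variance (constant chain) for parameter(s) {bad}"
        )
    if draws.acceptance is not None and np.any(draws.acceptance == 0.0):
        n_dead = int(np.sum(np.all(draws.acceptance == 0.0, axis=1)))
        if n_dead:
            reasons.append(f"{n_dead} chain(s) accepted no post-burn-in moves")
        else:
            reasons.append("some parameters accepted no post-burn-in moves")
    acf_fail = bool(np.any(lag1[~constant] >= autocorr_limit))
    if acf_fail:
        worst = draws.param_names[int(np.nanargmax(lag1))]
        reasons.append(
            f"lag-1 autocorrelation >= {autocorr_limit} "
            f"(worst {np.nanmax(lag1):.3f} at {worst!r})"
        )
    if np.any(np.nan_to_num(rhat, nan=np.inf) >= rhat_limit):
        worst = draws.param_names[int(np.nanargmax(rhat))]
        reasons.append(
            f"split R-hat >= {rhat_limit} (worst {np.nanmax(rhat):.3f} at {worst!r})"
        )

    recommended = None
    if acf_fail and not constant.any():
        for t in thin_candidates:
            if draws.n_retained // t < 100:
                break
            thinned = draws.thin_by(t)
            lag_t = _lag1_autocorr(thinned.array)
            if np.all(np.nan_to_num(lag_t, nan=np.inf) < autocorr_limit):
                recommended = t
                break

    return DiagnosticsReport(
        param_names=list(draws.param_names),
        lag1_autocorr=lag1,
        rhat=np.asarray(rhat, dtype=float),
        ess=np.asarray(ess, dtype=float),
        passed=not reasons,
        reasons=reasons,
        autocorr_limit=autocorr_limit,
        rhat_limit=rhat_limit,
        recommended_thin=recommended,
        thin_applied=draws.extra_thin,
    )


def auto_thin(
    draws: PosteriorDraws,
    report: DiagnosticsReport | None = None,
    autocorr_limit: float = 0.1,
    rhat_limit: float = 1.05,
    thin_candidates: tuple[int, ...] = DEFAULT_THIN_CANDIDATES,
) -> tuple[PosteriorDraws, DiagnosticsReport]:
    """Apply the smallest thinning factor that restores sample independence.

    Returns the (possibly thinned) draws and their fresh diagnostics; if
    no candidate factor helps, the original draws and failing report are
    returned unchanged.
    """
    if report is None:
        report = diagnose(draws, autocorr_limit, rhat_limit, thin_candidates)
    if report.passed or report.recommended_thin is None:
        return draws, report
    thinned = draws.thin_by(report.recommended_thin)
    new_report = diagnose(thinned, autocorr_limit, rhat_limit, thin_candidates)
    return thinned, new_report
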