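"""Model evaluation: WAIC, model comparison, posterior spatial structure.

WAIC is computed pointwise from the posterior log-likelihood matrix:
lppd_i = log mean_d exp(loglik_di), p_waic_i = Var_d(loglik_di) with the
unbiased (n-1) variance, WAIC = -2 * sum_i (lppd_i - p_waic_i).  Models are
ranked by WAIC with Akaike weights w_m = exp(-Delta_m/2) / sum_k exp(-Delta_k/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geo import DistanceMatrix
from .model import DiscoveryCountResults, gp_covariance


@dataclass
class WAICResult:
    acronym: str | None
    period: int | None
    lppd: float
    p_waic: float
    waic: float
    se: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray


@dataclass
class WAICComparison:
    """Models of one period ranked ascending by WAIC."""

    period: int | None
    table: pd.DataFrame  # columns acronym, waic, delta, weight


@dataclass
class IslandCorrelation:
    islands: list[str]
    R: np.ndarray
    period: int | None = None

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for a, ca in enumerate(self.islands):
            for b, cb in enumerate(self.islands):
                rows.append({"i": ca, "j": cb, "R": self.R[a, b]})
        return pd.DataFrame(rows)


@dataclass
class PredictiveCurve:
    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    harbor_value: int
    interval: float

    def to_frame(self) -> pd.DataFrame:
        lo = int(round(100 * (1 - self.interval) / 2))
        hi = 100 - lo
        return pd.DataFrame({"grid": self.grid, "median": self.median,
                             f"lo{self.interval:.0%}".replace("%", ""):
                                 self.lower,
                             f"hi{self.interval:.0%}".replace("%", ""):
                                 self.upper,
                             "harbor": self.harbor_value})


def waic(pointwise_loglik: np.ndarray, acronym: str | None = None,
         period: int | None = None) -> WAICResult:
    """Widely applicable information criterion from a (draws x obs) matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be 2-D (draws x observations)")
    n_draws, n_obs = ll.shape
    if n_draws < 2:
        raise ValueError("WAIC needs at least 2 draws (pointwise variance)")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite log-likelihood values")
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    w = -2.0 * float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n_obs * elpd_i.var(ddof=1))) if n_obs > 1 else 0.0
    return WAICResult(acronym=acronym, period=period,
                      lppd=float(lppd_i.sum()), p_waic=float(p_i.sum()),
                      waic=w, se=se, pointwise_lppd=lppd_i, pointwise_p=p_i)


def akaike_weights(waics) -> np.ndarray:
    """exp(-Delta/2) weights normalized over a model set."""
    w = np.asarray(waics, dtype=float)
    delta = w - w.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def compare_models(results: list[WAICResult]) -> WAICComparison:
    """Rank one period's models by WAIC with deltas and Akaike weights."""
    if len(results) < 2:
        raise ValueError("need at least 2 models to compare")
    periods = {r.period for r in results}
    if len(periods) > 1:
        raise ValueError(f"mixed periods in comparison: {sorted(map(str, periods))}")
    order = sorted(results, key=lambda r: (r.waic, r.acronym or ""))
    waics = np.array([r.waic for r in order])
    weights = akaike_weights(waics)
    table = pd.DataFrame({
        "acronym": [r.acronym for r in order],
        "waic": waics,
        "delta": waics - waics[0],
        "weight": weights,
    })
    return WAICComparison(period=order[0].period, table=table)


def harbor_contrast(comparison: WAICComparison) -> float:
    """WAIC of the best harbor-free model minus the best harbor model.

    Positive values favour including the harbor term (the headline contrast:
    ~2 in the earliest period of the study system, shrinking over time).
    """
    t = comparison.table
    is_h = t["acronym"].str.endswith(".h")
    if not is_h.any() or is_h.all():
        raise ValueError("comparison must contain both harbor and "
                         "harbor-free models")
    return float(t.loc[~is_h, "waic"].min() - t.loc[is_h, "waic"].min())


def posterior_correlation(samples: DiscoveryCountResults,
                          D: DistanceMatrix, jitter: float = 0.01,
                          ) -> IslandCorrelation:
    """Island correlation matrix implied by the posterior GP.

    The covariance is rebuilt from the posterior medians of eta2 and rho2
    (medians, because eta2's posterior is strongly right-skewed), then
    normalized to a correlation matrix.
    """
    eta2 = float(np.median(samples.draws("eta2")))
    rho2 = float(np.median(samples.draws("rho2")))
    G = gp_covariance(eta2, rho2, D, jitter)
    s = np.sqrt(np.diag(G))
    R = G / np.outer(s, s)
    return IslandCorrelation(islands=list(D.islands), R=R,
                             period=samples.spec.period)


def predictive_curve(samples: DiscoveryCountResults, covariate_grid,
                     harbor_value: int = 0, interval: float = 0.80,
                     psi_mode: str = "zero", seed: int = 0) -> PredictiveCurve:
    """Posterior predictive mean-count curve over a covariate grid.

    For each grid value the posterior distribution of
    lambda = exp(gamma0 + gamma_cov * x + gamma_harbor * h + psi) is summarized
    by its median and a central equal-tailed ``interval``.  ``psi_mode``
    controls the island effect: "zero" fixes psi at its prior mean (a
    new-island interpretation); "sample" draws one psi per posterior draw from
    MVNormal(0, Gamma) built from that draw's eta2, rho2.
    """
    grid = np.asarray(covariate_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("covariate_grid must be a sorted 1-D array")
    names = samples.param_names
    g0 = samples.draws("gamma0")
    gc = samples.draws("gamma_cov")
    lp = g0[:, None] + gc[:, None] * grid[None, :]
    if harbor_value:
        if "gamma_harbor" not in names:
            raise ValueError("harbor stratum requested for a model without "
                             "a harbor term")
        lp = lp + samples.draws("gamma_harbor")[:, None] * float(harbor_value)
    if psi_mode == "sample":
        rng = np.random.default_rng(int(seed) % (2 ** 31))
        eta2 = samples.draws("eta2")
        rho2 = samples.draws("rho2")
        D = samples.model.data.D
        psi_draw = np.empty(len(eta2))
        for i in range(len(eta2)):
            G = gp_covariance(eta2[i], rho2[i], D, samples.model.jitter)
            L = np.linalg.cholesky(G)
            psi_draw[i] = (L @ rng.standard_normal(len(D.islands)))[0]
        lp = lp + psi_draw[:, None]
    elif psi_mode != "zero":
        raise ValueError("psi_mode must be 'zero' or 'sample'")
    lam = np.exp(lp)
    alpha = (1.0 - interval) / 2.0
    return PredictiveCurve(
        grid=grid,
        median=np.median(lam, axis=0),
        lower=np.quantile(lam, alpha, axis=0),
        upper=np.quantile(lam, 1 - alpha, axis=0),
        harbor_value=int(bool(harbor_value)),
        interval=interval,
    )


def comparison_report(comparisons: dict[int, WAICComparison],
                      round_output: bool = True) -> pd.DataFrame:
    """Stack per-period comparisons into one table (period, acronym, waic,
    delta, weight), rounded for presentation (WAIC/delta 1 dp, weight 2 dp)."""
    frames = []
    for period, comp in sorted(comparisons.items()):
        t = comp.table.copy()
        t.insert(0, "period", period)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    if round_output:
        out["waic"] = out["waic"].round(1)
        out["delta"] = out["delta"].round(1)
        out["weight"] = out["weight"].round(2)
    return out
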