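"""Poisson regression with Gaussian-process varying intercepts across islands.

The response is the cumulative number of taxa attributed to each island by a
given year, s_i ~ Poisson(lambda_i) with

    log(lambda_i) = gamma0 + gamma_cov * x_i [+ gamma_harbor * h_i] + psi_i,

where x_i is one standardized island covariate (area, age, altitude or mean
terrain ruggedness), h_i an optional harbor indicator, and the island effects
psi are drawn jointly from MVNormal(0, Gamma) with squared-exponential
covariance

    Gamma_ij = eta2 * exp(-rho2 * D_ij^2) + jitter * delta_ij.

Priors: Normal(0, 10) on each regression coefficient, HalfCauchy(0, 1) on
eta2 and rho2.  The posterior is sampled with adaptive blockwise random-walk
Metropolis; eta2 and rho2 are sampled on the log scale with the Jacobian
correction, and psi is updated as one block with proposals scaled by the
current Cholesky factor of Gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geo import DistanceMatrix, compute_distance_matrix, covariate_vector
from .records import CountPanel, Island

logger = logging.getLogger(__name__)

COVARIATE_ACRONYMS = {"age": "ag", "altitude": "al", "area": "ar", "tri": "tri"}

_LOG_2PI = np.log(2 * np.pi)
_NORMAL10_CONST = -np.log(10.0) - 0.5 * _LOG_2PI  # Normal(0,10) logpdf at 0
_HALFCAUCHY_CONST = np.log(2.0 / np.pi)

TARGET_ACCEPT = 0.234  # optimal random-walk acceptance for multi-dim blocks


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate enters the linear predictor and whether harbor does."""

    covariate: str
    include_harbor: bool = False
    include_gp: bool = True
    period: int | None = None

    def __post_init__(self):
        if self.covariate not in COVARIATE_ACRONYMS:
            raise ValueError(f"covariate must be one of "
                             f"{sorted(COVARIATE_ACRONYMS)}, got "
                             f"{self.covariate!r}")

    @property
    def acronym(self) -> str:
        base = COVARIATE_ACRONYMS[self.covariate]
        return f"{base}.h" if self.include_harbor else base


@dataclass
class ModelData:
    """Aligned per-island vectors and the distance matrix."""

    s: np.ndarray                 # counts
    x: np.ndarray                 # standardized covariate
    h: np.ndarray | None          # harbor indicator (0/1) or None
    D: DistanceMatrix

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        n = len(self.D.islands)
        if not (self.s.shape == self.x.shape == (n,)):
            raise ValueError("s, x and D must share island ordering/length")
        if self.h is not None:
            self.h = np.asarray(self.h, dtype=float)
            if self.h.shape != (n,):
                raise ValueError("h length mismatch")
        if (self.s < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_islands(self) -> int:
        return len(self.D.islands)


@dataclass
class ParameterVector:
    """One point in parameter space (natural scale)."""

    gamma0: float
    gamma_cov: float
    gamma_harbor: float | None
    eta2: float
    rho2: float
    psi: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        if self.eta2 <= 0:
            raise ValueError("eta2 must be > 0")
        if self.rho2 <= 0:
            raise ValueError("rho2 must be > 0")


def gp_covariance(eta2: float, rho2: float, D: DistanceMatrix | np.ndarray,
                  jitter: float = 0.01) -> np.ndarray:
    """Squared-exponential island covariance with diagonal jitter.

    Gamma_ij = eta2 * exp(-rho2 * D_ij^2) + jitter * delta_ij.
    """
    if eta2 <= 0:
        raise ValueError("eta2 must be > 0")
    if rho2 < 0:
        raise ValueError("rho2 must be >= 0")
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    G = eta2 * np.exp(-rho2 * d ** 2)
    G[np.diag_indices_from(G)] += jitter
    return G


def _linear_predictor(data: ModelData, params: ParameterVector) -> np.ndarray:
    lp = params.gamma0 + params.gamma_cov * data.x + params.psi
    if params.gamma_harbor is not None:
        if data.h is None:
            raise ValueError("harbor coefficient given but data has no "
                             "harbor indicator")
        lp = lp + params.gamma_harbor * data.h
    return lp


def log_likelihood(data: ModelData, params: ParameterVector) -> np.ndarray:
    """Per-island Poisson log-likelihood, computed in log space."""
    lp = _linear_predictor(data, params)
    return data.s * lp - np.exp(lp) - gammaln(data.s + 1)


def log_prior(params: ParameterVector, D: DistanceMatrix,
              jitter: float = 0.01) -> float:
    """Joint log prior density at a parameter point (natural scale).

    Normal(0,10) on the regression coefficients, HalfCauchy(0,1) on eta2 and
    rho2, MVNormal(0, Gamma) on psi.  Returns -inf outside the support.
    """
    if params.eta2 <= 0 or params.rho2 <= 0:
        return -np.inf
    gammas = [params.gamma0, params.gamma_cov]
    if params.gamma_harbor is not None:
        gammas.append(params.gamma_harbor)
    g = np.asarray(gammas)
    lp = float(np.sum(_NORMAL10_CONST - 0.5 * (g / 10.0) ** 2))
    for v in (params.eta2, params.rho2):
        lp += _HALFCAUCHY_CONST - np.log1p(v * v)
    from scipy.linalg import solve_triangular

    G = gp_covariance(params.eta2, params.rho2, D, jitter)
    L = np.linalg.cholesky(G)
    z = solve_triangular(L, params.psi, lower=True)
    n = params.psi.size
    lp += -0.5 * float(z @ z) - float(np.log(np.diag(L)).sum()) \
        - 0.5 * n * _LOG_2PI
    return lp


class DiscoveryCountModel:
    """Bayesian GP-varying-intercept Poisson model for one time slice.

    Parameters
    ----------
    data : ModelData
        Counts, standardized covariate, optional harbor indicator and the
        island distance matrix.
    spec : ModelSpec
        Names the covariate and records whether the harbor term is included
        (the harbor vector must be present in ``data`` in that case).
    jitter : float
        Diagonal nugget of the GP covariance (default 0.01; the model has one
        observation per island, so this acts as a fixed numerical constant,
        not an estimated noise variance).
    """

    def __init__(self, data: ModelData, spec: ModelSpec, jitter: float = 0.01):
        if spec.include_harbor and data.h is None:
            raise ValueError("spec includes harbor but data.h is None")
        self.data = data
        self.spec = spec
        self.jitter = float(jitter)
        self.n_islands = data.n_islands
        self.k_gamma = 3 if spec.include_harbor else 2
        self._d2 = data.D.d ** 2
        self._lgamma_s = gammaln(data.s + 1)
        # design matrix columns for the gamma block
        cols = [np.ones(self.n_islands), data.x]
        if spec.include_harbor:
            cols.append(data.h)
        self._X = np.column_stack(cols)

    @classmethod
    def from_panel(cls, panel: CountPanel, islands: list[Island], period: int,
                   covariate: str = "tri", include_harbor: bool = False,
                   rescale_distances: bool = True, log_area: bool = False,
                   jitter: float = 0.01) -> "DiscoveryCountModel":
        """Build the model for one period of a cumulative count panel."""
        codes = [i.code for i in islands]
        if codes != panel.islands:
            raise ValueError("panel and island list must share ordering")
        s = panel.column(period)
        x = covariate_vector(islands, covariate, log_area=log_area)
        h = np.array([i.harbor for i in islands], dtype=float)
        D = compute_distance_matrix(islands, rescale=rescale_distances)
        spec = ModelSpec(covariate=covariate, include_harbor=include_harbor,
                         period=period)
        data = ModelData(s=s, x=x, h=h if include_harbor else h, D=D)
        return cls(data, spec, jitter=jitter)

    # ---- log densities on the flat, transformed parameter vector ----------
    # theta = [gamma..., log eta2, log rho2, psi...]

    @property
    def n_params(self) -> int:
        return self.k_gamma + 2 + self.n_islands

    def _unpack(self, theta: np.ndarray) -> ParameterVector:
        k = self.k_gamma
        return ParameterVector(
            gamma0=float(theta[0]),
            gamma_cov=float(theta[1]),
            gamma_harbor=float(theta[2]) if k == 3 else None,
            eta2=float(np.exp(theta[k])),
            rho2=float(np.exp(theta[k + 1])),
            psi=theta[k + 2:].copy(),
        )

    def _chol(self, le: float, lr: float) -> np.ndarray:
        G = np.exp(le) * np.exp(-np.exp(lr) * self._d2)
        G[np.diag_indices_from(G)] += self.jitter
        return np.linalg.cholesky(G)

    def _log_posterior(self, theta: np.ndarray, L: np.ndarray,
                       prior_only: bool = False) -> float:
        """Log posterior on the transformed scale (includes Jacobian).

        ``L`` must be the Cholesky factor matching theta's (log eta2,
        log rho2); passing it avoids refactorizing when only gamma or psi
        moved.
        """
        k = self.k_gamma
        g = theta[:k]
        le, lr = theta[k], theta[k + 1]
        psi = theta[k + 2:]
        eta2, rho2 = np.exp(le), np.exp(lr)

        lp = float(np.sum(_NORMAL10_CONST - 0.5 * (g / 10.0) ** 2))
        # HalfCauchy(0,1) on natural scale + log-Jacobian of the exp transform
        lp += 2 * _HALFCAUCHY_CONST - np.log1p(eta2 * eta2) \
            - np.log1p(rho2 * rho2) + le + lr
        from scipy.linalg import solve_triangular
        z = solve_triangular(L, psi, lower=True, check_finite=False)
        lp += -0.5 * float(z @ z) - float(np.log(np.diag(L)).sum()) \
            - 0.5 * self.n_islands * _LOG_2PI
        if not prior_only:
            eta = self._X @ g + psi
            lp += float(self.data.s @ eta - np.exp(eta).sum()
                        - self._lgamma_s.sum())
        return lp

    def loglike_pointwise(self, theta_matrix: np.ndarray) -> np.ndarray:
        """Per-draw, per-island log-likelihood matrix (draws x islands)."""
        k = self.k_gamma
        g = theta_matrix[:, :k]
        psi = theta_matrix[:, k + 2:]
        eta = g @ self._X.T + psi
        s = self.data.s[None, :]
        return s * eta - np.exp(eta) - self._lgamma_s[None, :]

    # ---- sampling ----------------------------------------------------------

    def fit(self, n_draws: int = 1000, n_chains: int = 2, seed: int = 0,
            prior_only: bool = False, adapt_window: int = 50,
            thin: int = 1) -> "DiscoveryCountResults":
        """Sample the posterior with adaptive blockwise Metropolis.

        ``n_draws`` post-warmup draws per chain are retained; an equal number
        of warmup iterations is discarded, during which proposal scales adapt
        toward a 0.234 acceptance rate and are then frozen.  Deterministic
        for a given seed.
        """
        if n_chains < 2:
            raise ValueError("n_chains must be >= 2 for split-Rhat diagnostics")
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        chains = []
        accept_rates = []
        for c in range(n_chains):
            rng = np.random.default_rng([int(seed) % (2 ** 31), c])
            draws, acc = self._run_chain(rng, n_draws, prior_only,
                                         adapt_window, thin)
            chains.append(draws)
            accept_rates.append(acc)
        theta = np.stack(chains)  # (chain, draw, param)
        return DiscoveryCountResults(self, theta, accept_rates,
                                     prior_only=prior_only, seed=int(seed))

    def _init_theta(self, rng: np.random.Generator,
                    prior_only: bool) -> tuple[np.ndarray, np.ndarray]:
        for _ in range(100):
            theta = np.zeros(self.n_params)
            theta[:self.k_gamma] = rng.normal(0, 0.5, self.k_gamma)
            theta[self.k_gamma:self.k_gamma + 2] = rng.normal(0, 0.3, 2)
            theta[self.k_gamma + 2:] = rng.normal(0, 0.1, self.n_islands)
            try:
                L = self._chol(theta[self.k_gamma], theta[self.k_gamma + 1])
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(self._log_posterior(theta, L, prior_only)):
                return theta, L
        raise RuntimeError("could not find a finite log-posterior "
                           "initialization in 100 attempts")

    def _run_chain(self, rng, n_draws, prior_only, adapt_window, thin):
        k = self.k_gamma
        n = self.n_islands
        theta, L = self._init_theta(rng, prior_only)
        logp = self._log_posterior(theta, L, prior_only)

        # blocks: gamma, (log eta2/rho2), psi, gamma0/psi ridge translation
        log_scales = np.log([0.5, 0.5, 1.0, 0.5])
        n_iter = 2 * n_draws * thin           # first half is warmup
        warmup = n_draws * thin
        acc_window = np.zeros(4)
        acc_total = np.zeros(4)
        n_total = np.zeros(4)
        out = np.empty((n_draws, self.n_params))
        kept = 0
        window_count = 0

        for it in range(n_iter):
            adapting = it < warmup
            # block 0: regression coefficients
            prop = theta.copy()
            prop[:k] = theta[:k] + np.exp(log_scales[0]) * rng.standard_normal(k)
            logp_new = self._log_posterior(prop, L, prior_only)
            if np.log(rng.random()) < logp_new - logp:
                theta, logp = prop, logp_new
                acc_window[0] += 1
                acc_total[0] += 1

            # block 1: log eta2, log rho2 (needs a new Cholesky factor)
            prop = theta.copy()
            prop[k:k + 2] = theta[k:k + 2] \
                + np.exp(log_scales[1]) * rng.standard_normal(2)
            try:
                L_new = self._chol(prop[k], prop[k + 1])
                logp_new = self._log_posterior(prop, L_new, prior_only)
            except np.linalg.LinAlgError:
                logp_new = -np.inf
            if np.log(rng.random()) < logp_new - logp:
                theta, logp, L = prop, logp_new, L_new
                acc_window[1] += 1
                acc_total[1] += 1

            # block 2: psi jointly, proposal scaled by current chol(Gamma)
            prop = theta.copy()
            prop[k + 2:] = theta[k + 2:] + np.exp(log_scales[2]) \
                * (L @ rng.standard_normal(n))
            logp_new = self._log_posterior(prop, L, prior_only)
            if np.log(rng.random()) < logp_new - logp:
                theta, logp = prop, logp_new
                acc_window[2] += 1
                acc_total[2] += 1

            # block 3: translate along the gamma0/psi ridge (the intercept and
            # the island effects are only separated by the prior, so plain
            # blockwise moves mix slowly along this direction)
            prop = theta.copy()
            shift = np.exp(log_scales[3]) * rng.standard_normal()
            prop[0] = theta[0] + shift
            prop[k + 2:] = theta[k + 2:] - shift
            logp_new = self._log_posterior(prop, L, prior_only)
            if np.log(rng.random()) < logp_new - logp:
                theta, logp = prop, logp_new
                acc_window[3] += 1
                acc_total[3] += 1

            n_total += 1
            if adapting and (it + 1) % adapt_window == 0:
                window_count += 1
                rate = acc_window / adapt_window
                step = min(0.5, 2.0 / np.sqrt(window_count))
                log_scales += step * (rate - TARGET_ACCEPT)
                acc_window[:] = 0

            if it >= warmup and (it - warmup) % thin == 0:
                out[kept] = theta
                kept += 1

        return out[:kept], (acc_total / n_total).tolist()


def fit_all_models(panel: CountPanel, islands: list[Island],
                   periods: list[int] | None = None,
                   covariates: tuple[str, ...] = ("age", "altitude", "area",
                                                  "tri"),
                   n_draws: int = 1000, n_chains: int = 2, seed: int = 0,
                   rescale_distances: bool = True, log_area: bool = False,
                   jitter: float = 0.01
                   ) -> dict[tuple[int, str], "DiscoveryCountResults"]:
    """Fit the full model grid: one covariate at a time (they are strongly
    collinear) x harbor on/off, for every period.

    Returns a mapping (period, acronym) -> results.  A failed fit is logged
    and skipped rather than aborting the grid.
    """
    if periods is None:
        periods = list(panel.periods)
    results: dict[tuple[int, str], DiscoveryCountResults] = {}
    fit_index = 0
    for period in periods:
        for covariate in covariates:
            for include_harbor in (True, False):
                spec_seed = (int(seed) * 1009 + fit_index) % (2 ** 31)
                fit_index += 1
                try:
                    model = DiscoveryCountModel.from_panel(
                        panel, islands, period, covariate=covariate,
                        include_harbor=include_harbor,
                        rescale_distances=rescale_distances,
                        log_area=log_area, jitter=jitter)
                    res = model.fit(n_draws=n_draws, n_chains=n_chains,
                                    seed=spec_seed)
                    results[(period, model.spec.acronym)] = res
                except Exception:
                    logger.exception("fit failed for period=%s covariate=%s "
                                     "harbor=%s; skipped", period, covariate,
                                     include_harbor)
    return results


class DiscoveryCountResults:
    """Posterior draws and diagnostics from a fitted DiscoveryCountModel.

    Draws are stored as a (chain, draw, parameter) array on the transformed
    scale; named accessors return natural-scale arrays.
    """

    def __init__(self, model: DiscoveryCountModel, theta: np.ndarray,
                 accept_rates: list[list[float]], prior_only: bool = False,
                 seed: int = 0):
        self.model = model
        self.spec = model.spec
        self._theta = theta
        self.n_chains, self.n_draws, _ = theta.shape
        self.accept_rates = accept_rates
        self.prior_only = prior_only
        self.seed = seed
        self._flat = theta.reshape(-1, theta.shape[-1])

    # ---- named draws -------------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        k = self.model.k_gamma
        names = ["gamma0", "gamma_cov"]
        if k == 3:
            names.append("gamma_harbor")
        names += ["eta2", "rho2"]
        names += [f"psi[{c}]" for c in self.model.data.D.islands]
        return names

    def draws(self, name: str, flat: bool = True) -> np.ndarray:
        """Natural-scale draws of one parameter.

        ``flat=False`` keeps the (chain, draw) layout.
        """
        k = self.model.k_gamma
        names = self.param_names
        if name not in names:
            raise KeyError(name)
        idx = names.index(name)
        arr = self._theta[:, :, idx]
        if name in ("eta2", "rho2"):
            arr = np.exp(arr)
        return arr.reshape(-1) if flat else arr

    @property
    def pointwise_loglik(self) -> np.ndarray:
        """(total draws x islands) log-likelihood matrix for WAIC."""
        return self.model.loglike_pointwise(self._flat)

    def parameter_vectors(self) -> list[ParameterVector]:
        return [self.model._unpack(row) for row in self._flat]

    def median_params(self) -> ParameterVector:
        """Posterior medians assembled into one ParameterVector (medians are
        used because eta2 has a strongly right-skewed posterior)."""
        k = self.model.k_gamma
        med = np.median(self._flat, axis=0)
        return self.model._unpack(med)

    # ---- diagnostics -------------------------------------------------------

    def diagnostics(self) -> dict:
        import arviz as az

        scalar_names = self.param_names
        data = {n: self.draws(n, flat=False) for n in scalar_names}
        ds = az.convert_to_dataset(data)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
        rhats = {n: float(rhat[n].values) for n in scalar_names}
        worst = max(rhats.values())
        if worst > 1.05:
            logger.warning("split R-hat up to %.3f > 1.05: chains may not "
                           "have converged", worst)
        return {
            "acceptance_rates": self.accept_rates,
            "rhat": rhats,
            "ess": {n: float(ess[n].values) for n in scalar_names},
            "max_rhat": worst,
        }

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, median, 80% interval, R-hat, ESS."""
        import arviz as az

        rows = []
        diag_names = set(self.param_names)
        for name in self.param_names:
            d = self.draws(name, flat=False)
            flat = d.reshape(-1)
            row = {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "median": np.median(flat),
                "q10": np.quantile(flat, 0.10),
                "q90": np.quantile(flat, 0.90),
            }
            if name in diag_names:
                ds = az.convert_to_dataset({name: d})
                row["rhat"] = float(az.rhat(ds)[name].values)
                row["ess"] = float(az.ess(ds)[name].values)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    # ---- evaluation shortcuts ---------------------------------------------

    def waic(self):
        from .evaluation import waic

        return waic(self.pointwise_loglik, acronym=self.spec.acronym,
                    period=self.spec.period)

    def posterior_correlation(self):
        from .evaluation import posterior_correlation

        return posterior_correlation(self, self.model.data.D,
                                     jitter=self.model.jitter)

    def predictive_curve(self, covariate_grid, harbor_value: int = 0,
                         interval: float = 0.80, psi_mode: str = "zero",
                         seed: int = 0):
        from .evaluation import predictive_curve

        return predictive_curve(self, covariate_grid,
                                harbor_value=harbor_value, interval=interval,
                                psi_mode=psi_mode, seed=seed)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw, natural-scale columns, with chain labels."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "draw": np.tile(np.arange(self.n_draws), self.n_chains)}
        for name in self.param_names:
            cols[name] = self.draws(name)
        return pd.DataFrame(cols)
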