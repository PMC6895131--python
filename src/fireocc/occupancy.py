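"""Single-season occupancy model with imperfect detection.

For one species, survey period ``i`` (a site x year combination) and survey
night ``j``:

    z_i  ~ Bernoulli(psi_i)             true occurrence (latent)
    y_ij ~ Bernoulli(p_ij * z_i)        nightly detection

with logit-linear predictors

    logit(p_ij)  = alpha' x_det(i,j)
    logit(psi_i) = beta' x_occ(i) + b_site[site(i)] + b_area[area(i)]

where the random intercepts are hierarchically Gaussian,
``b_site ~ N(0, sigma_site)``, ``b_area ~ N(0, sigma_area)``.

The latent occurrence state is marginalized analytically, giving the exact
per-period likelihood

    L_i = psi_i * prod_j Bern(y_ij | p_ij) + (1 - psi_i) * I(sum_j y_ij = 0)

which keeps the posterior continuous and directly testable against the
two-term enumeration over z. Posterior occurrence draws, when needed
downstream, are recovered from the conditional
``P(z=1 | y, psi, p) = psi q / (psi q + 1 - psi)`` with
``q = prod_j (1 - p_ij)`` for all-zero histories (and 1 otherwise).

Inference is by a self-contained blockwise adaptive random-walk Metropolis
sampler: joint proposals with adapted covariance for the detection and
occurrence fixed-effect blocks, elementwise proposals with independent
accept/reject for site and area intercepts (valid because periods partition
by group), and scalar updates for the log random-effect SDs.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from fireocc.covariates import DET_COLUMNS, OCC_COLUMNS, DesignMatrices
from fireocc.exceptions import (
    DataValidationError,
    InvalidArgumentError,
    ShapeError,
)

# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Prior settings, all on the logit scale.

    Fixed effects get weakly regularizing Normal(0, ``fixed_effect_sd``)
    priors; random-intercept SDs get HalfNormal(scale) priors. Defaults are
    deliberately config-visible and overridable.
    """

    fixed_effect_sd: float = 1.5
    sigma_site_scale: float = 1.0
    sigma_area_scale: float = 1.0


@dataclass
class DetectionHistory:
    """Nightly binary detections for one species, ragged across periods.

    ``y[k]`` is the outcome of nightly record ``k`` and ``obs_period[k]``
    the survey period it belongs to. ``period_site``/``period_area`` map
    periods to random-intercept groups; ``period_year`` is carried for
    bookkeeping.
    """

    y: np.ndarray
    obs_period: np.ndarray
    n_periods: int
    period_site: np.ndarray | None = None
    period_area: np.ndarray | None = None
    period_year: np.ndarray | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.obs_period = np.asarray(self.obs_period, dtype=np.int64)
        if self.y.shape != self.obs_period.shape:
            raise ShapeError("y and obs_period must align")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise DataValidationError("detections must be binary")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def detected_any(self) -> np.ndarray:
        """Boolean per period: at least one nightly detection."""
        return np.bincount(self.obs_period, weights=self.y,
                           minlength=self.n_periods) > 0

    @property
    def nights_per_period(self) -> np.ndarray:
        return np.bincount(self.obs_period, minlength=self.n_periods)

    def naive_occupancy(self) -> float:
        """Fraction of periods with >= 1 detection (no detection correction)."""
        return float(self.detected_any.mean())

    def y_by_period(self, i: int) -> np.ndarray:
        return self.y[self.obs_period == i]


@dataclass
class ModelSpec:
    """Design matrices, grouping indices and priors for one model scale."""

    X_det: np.ndarray
    X_occ: np.ndarray
    obs_period: np.ndarray
    site_idx: np.ndarray
    area_idx: np.ndarray
    priors: PriorConfig = field(default_factory=PriorConfig)
    det_columns: tuple[str, ...] = DET_COLUMNS
    occ_columns: tuple[str, ...] = OCC_COLUMNS
    radius_m: float | None = None

    @classmethod
    def from_design(cls, dm: DesignMatrices,
                    priors: PriorConfig | None = None) -> "ModelSpec":
        return cls(
            X_det=dm.X_det, X_occ=dm.X_occ, obs_period=dm.obs_period,
            site_idx=dm.site_idx, area_idx=dm.area_idx,
            priors=priors or PriorConfig(),
            det_columns=dm.det_columns, occ_columns=dm.occ_columns,
            radius_m=dm.radius_m,
        )

    @property
    def n_obs(self) -> int:
        return self.X_det.shape[0]

    @property
    def n_periods(self) -> int:
        return self.X_occ.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.site_idx.max()) + 1

    @property
    def n_areas(self) -> int:
        return int(self.area_idx.max()) + 1

    @property
    def n_det(self) -> int:
        return self.X_det.shape[1]

    @property
    def n_occ(self) -> int:
        return self.X_occ.shape[1]

    def validate(self, history: DetectionHistory | None = None) -> None:
        for name, X in (("X_det", self.X_det), ("X_occ", self.X_occ)):
            if not np.all(np.isfinite(X)):
                raise DataValidationError(f"{name} contains NaN/inf")
        if len(self.site_idx) != self.n_periods or len(self.area_idx) != self.n_periods:
            raise ShapeError("grouping indices must have one entry per period")
        if len(self.obs_period) != self.n_obs:
            raise ShapeError("obs_period must have one entry per nightly record")
        if history is not None:
            if history.n_periods != self.n_periods:
                raise ShapeError("history and spec disagree on period count")
            if history.n_obs != self.n_obs or not np.array_equal(
                history.obs_period, self.obs_period
            ):
                raise ShapeError("history and spec disagree on nightly records")


@dataclass
class ParamLayout:
    """Flat parameter-vector layout: alpha, beta, b_site, b_area, log sigmas."""

    n_det: int
    n_occ: int
    n_sites: int
    n_areas: int

    @property
    def size(self) -> int:
        return self.n_det + self.n_occ + self.n_sites + self.n_areas + 2

    def unpack(self, params: np.ndarray):
        p = np.asarray(params, dtype=float)
        if p.shape != (self.size,):
            raise ShapeError(f"expected parameter vector of length {self.size}")
        k = 0
        alpha = p[k:k + self.n_det]; k += self.n_det
        beta = p[k:k + self.n_occ]; k += self.n_occ
        b_site = p[k:k + self.n_sites]; k += self.n_sites
        b_area = p[k:k + self.n_areas]; k += self.n_areas
        ls_site, ls_area = p[k], p[k + 1]
        return alpha, beta, b_site, b_area, ls_site, ls_area

    def pack(self, alpha, beta, b_site, b_area, ls_site, ls_area) -> np.ndarray:
        return np.concatenate([
            alpha, beta, b_site, b_area, [ls_site], [ls_area]
        ]).astype(float)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _log_bernoulli_terms(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log p, log(1-p)) for p = expit(eta), numerically stable."""
    return -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta)


def period_loglik(y_i: Sequence[int], psi_i: float,
                  p_i_vec: Sequence[float]) -> float:
    """Log-likelihood of one period's detection history, z marginalized.

    Returns ``log[ psi * prod_j Bern(y_j | p_j) + (1 - psi) * I(sum y = 0) ]``.

    Raises
    ------
    InvalidArgumentError
        If ``psi`` or any ``p`` lies outside the open interval (0, 1).
    DataValidationError
        If ``y`` is not binary or shapes disagree.
    """
    y = np.asarray(y_i, dtype=float)
    p = np.asarray(p_i_vec, dtype=float)
    if y.shape != p.shape:
        raise ShapeError("y and p must have the same length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataValidationError("y must be binary")
    if not (0.0 < psi_i < 1.0) or not np.all((p > 0.0) & (p < 1.0)):
        raise InvalidArgumentError("psi and p must lie in the open interval (0, 1)")
    cond = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    occ = np.log(psi_i) + cond
    if y.sum() == 0:
        return float(np.logaddexp(occ, np.log1p(-psi_i)))
    return float(occ)


def _pointwise_loglik(spec: ModelSpec, history: DetectionHistory,
                      alpha: np.ndarray, beta: np.ndarray,
                      b_site: np.ndarray, b_area: np.ndarray) -> np.ndarray:
    """Vector of per-period marginalized log-likelihood contributions."""
    eta_det = spec.X_det @ alpha
    logp, log1mp = _log_bernoulli_terms(eta_det)
    ll_obs = np.where(history.y == 1, logp, log1mp)
    per_det = np.bincount(spec.obs_period, weights=ll_obs,
                          minlength=spec.n_periods)
    eta_psi = spec.X_occ @ beta + b_site[spec.site_idx] + b_area[spec.area_idx]
    log_psi, log_1mpsi = _log_bernoulli_terms(eta_psi)
    det_any = history.detected_any
    return np.where(det_any, log_psi + per_det,
                    np.logaddexp(log_psi + per_det, log_1mpsi))


def _log_prior(spec: ModelSpec, alpha, beta, b_site, b_area,
               ls_site, ls_area) -> float:
    """Log prior density, including the log-sigma Jacobian terms."""
    pr = spec.priors
    sd = pr.fixed_effect_sd
    lp = -0.5 * (np.sum(alpha**2) + np.sum(beta**2)) / sd**2 \
        - (len(alpha) + len(beta)) * (np.log(sd) + 0.5 * np.log(2 * np.pi))
    for b, ls, scale in ((b_site, ls_site, pr.sigma_site_scale),
                         (b_area, ls_area, pr.sigma_area_scale)):
        sig = np.exp(ls)
        n = len(b)
        lp += -0.5 * np.sum(b**2) / sig**2 - n * (ls + 0.5 * np.log(2 * np.pi))
        # HalfNormal(scale) on sigma, plus Jacobian of the log transform
        lp += 0.5 * np.log(2 / np.pi) - np.log(scale) - 0.5 * (sig / scale) ** 2 + ls
    return float(lp)


def log_posterior(params: np.ndarray, spec: ModelSpec,
                  history: DetectionHistory) -> float:
    """Unnormalized log posterior density at a flat parameter vector.

    Parameter order: alpha, beta, b_site, b_area, log sigma_site,
    log sigma_area (see :class:`ParamLayout`).
    """
    spec.validate(history)
    layout = ParamLayout(spec.n_det, spec.n_occ, spec.n_sites, spec.n_areas)
    alpha, beta, b_site, b_area, ls_s, ls_a = layout.unpack(params)
    ll = _pointwise_loglik(spec, history, alpha, beta, b_site, b_area).sum()
    return float(ll + _log_prior(spec, alpha, beta, b_site, b_area, ls_s, ls_a))


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------

def rhat(draws_by_chain: np.ndarray) -> float:
    """Split R-hat for one scalar parameter.

    ``draws_by_chain`` has shape (chains, draws). Each chain is split in
    half before computing the between/within variance ratio, so within-chain
    drift inflates the statistic. Returns ``nan`` (a flagged sentinel, not
    an exception) when the within-chain variance is zero.

    Raises
    ------
    InvalidArgumentError
        With fewer than 2 chains or fewer than 4 draws per chain.
    """
    x = np.asarray(draws_by_chain, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise InvalidArgumentError("need >= 2 chains with >= 4 draws each")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w == 0.0:
        return float("nan")
    b = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class OccupancyPosterior:
    """MCMC output for one species at one covariate scale.

    ``draws`` maps parameter names to arrays of shape (chains, draws) or
    (chains, draws, dim). ``psi`` holds per-period occupancy-probability
    draws, ``q_miss`` the per-period probability of an all-zero history
    given presence (``prod_j (1 - p_ij)``), and ``log_lik`` the pointwise
    marginalized log-likelihood — everything model comparison and community
    diversity need downstream.
    """

    draws: dict[str, np.ndarray]
    psi: np.ndarray
    q_miss: np.ndarray
    log_lik: np.ndarray
    rhat: dict[str, float]
    accept_rates: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None
    history: DetectionHistory | None = None
    species: str | None = None

    @property
    def n_chains(self) -> int:
        return self.psi.shape[0]

    @property
    def n_draws(self) -> int:
        """Total post-warmup draws pooled over chains."""
        return self.psi.shape[0] * self.psi.shape[1]

    @property
    def converged(self) -> bool:
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        return bool(finite) and max(finite) < 1.1

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains pooled: (chains*draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def psi_stacked(self) -> np.ndarray:
        return self.psi.reshape(-1, self.psi.shape[-1])

    def q_miss_stacked(self) -> np.ndarray:
        return self.q_miss.reshape(-1, self.q_miss.shape[-1])

    def credible_interval(self, name: str, index: int | None = None,
                          prob: float = 0.9) -> tuple[float, float]:
        d = self.stacked(name)
        if d.ndim > 1:
            d = d[:, index]
        lo = (1 - prob) / 2
        return tuple(np.quantile(d, [lo, 1 - lo]))

    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs, central 90% intervals and R-hat."""
        rows = []
        for name in ("alpha", "beta"):
            cols = (self.spec.det_columns if name == "alpha"
                    else self.spec.occ_columns) if self.spec else None
            d = self.stacked(name)
            for k in range(d.shape[1]):
                label = f"{name}[{cols[k]}]" if cols else f"{name}[{k}]"
                rows.append(self._row(label, d[:, k], self.rhat.get(f"{name}_{k}")))
        for name in ("sigma_site", "sigma_area"):
            rows.append(self._row(name, self.stacked(name), self.rhat.get(name)))
        return pd.DataFrame(rows).set_index("parameter")

    @staticmethod
    def _row(label, d, rh):
        lo, hi = np.quantile(d, [0.05, 0.95])
        return {"parameter": label, "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)), "q5": float(lo), "q95": float(hi),
                "rhat": float(rh) if rh is not None else np.nan}


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _combine(det_any, log_psi, log_1mpsi, per_det):
    return np.where(det_any, log_psi + per_det,
                    np.logaddexp(log_psi + per_det, log_1mpsi))


class _ChainState:
    """Cached likelihood pieces for one chain of the block sampler."""

    def __init__(self, spec: ModelSpec, history: DetectionHistory,
                 rng: np.random.Generator):
        self.spec = spec
        self.hist = history
        self.rng = rng
        self.det_any = history.detected_any
        naive_psi = np.clip(history.naive_occupancy(), 0.05, 0.95)
        naive_p = np.clip(float(history.y.mean()), 0.05, 0.95)
        self.alpha = np.zeros(spec.n_det)
        self.alpha[0] = np.clip(logit(naive_p), -3.0, 3.0)
        self.beta = np.zeros(spec.n_occ)
        self.beta[0] = np.clip(logit(naive_psi), -3.0, 3.0)
        self.b_site = np.zeros(spec.n_sites)
        self.b_area = np.zeros(spec.n_areas)
        self.ls_site = np.log(0.5)
        self.ls_area = np.log(0.5)
        # mild overdispersion so R-hat can detect failures to mix
        self.alpha += 0.1 * rng.standard_normal(spec.n_det)
        self.beta += 0.1 * rng.standard_normal(spec.n_occ)
        self._refresh_det()
        self._refresh_psi()

    # -- cached pieces ---------------------------------------------------
    def _refresh_det(self):
        self.eta_det = self.spec.X_det @ self.alpha
        logp, log1mp = _log_bernoulli_terms(self.eta_det)
        ll_obs = np.where(self.hist.y == 1, logp, log1mp)
        self.per_det = np.bincount(self.spec.obs_period, weights=ll_obs,
                                   minlength=self.spec.n_periods)
        self.log1mp = log1mp

    def _refresh_psi(self):
        self.eta_psi = (self.spec.X_occ @ self.beta
                        + self.b_site[self.spec.site_idx]
                        + self.b_area[self.spec.area_idx])
        self.log_psi, self.log_1mpsi = _log_bernoulli_terms(self.eta_psi)
        self.ll_period = _combine(self.det_any, self.log_psi,
                                  self.log_1mpsi, self.per_det)

    # -- block updates; each returns acceptance indicator(s) -------------
    def update_alpha(self, chol, step):
        prop = self.alpha + step * (chol @ self.rng.standard_normal(self.spec.n_det))
        eta = self.spec.X_det @ prop
        logp, log1mp = _log_bernoulli_terms(eta)
        ll_obs = np.where(self.hist.y == 1, logp, log1mp)
        per_det = np.bincount(self.spec.obs_period, weights=ll_obs,
                              minlength=self.spec.n_periods)
        ll_new = _combine(self.det_any, self.log_psi, self.log_1mpsi, per_det)
        sd = self.spec.priors.fixed_effect_sd
        delta = (ll_new.sum() - self.ll_period.sum()
                 - 0.5 * (np.sum(prop**2) - np.sum(self.alpha**2)) / sd**2)
        if np.log(self.rng.random()) < delta:
            self.alpha, self.eta_det, self.log1mp = prop, eta, log1mp
            self.per_det, self.ll_period = per_det, ll_new
            return 1.0
        return 0.0

    def update_beta(self, chol, step):
        prop = self.beta + step * (chol @ self.rng.standard_normal(self.spec.n_occ))
        eta = (self.spec.X_occ @ prop + self.b_site[self.spec.site_idx]
               + self.b_area[self.spec.area_idx])
        log_psi, log_1mpsi = _log_bernoulli_terms(eta)
        ll_new = _combine(self.det_any, log_psi, log_1mpsi, self.per_det)
        sd = self.spec.priors.fixed_effect_sd
        delta = (ll_new.sum() - self.ll_period.sum()
                 - 0.5 * (np.sum(prop**2) - np.sum(self.beta**2)) / sd**2)
        if np.log(self.rng.random()) < delta:
            self.beta, self.eta_psi = prop, eta
            self.log_psi, self.log_1mpsi, self.ll_period = log_psi, log_1mpsi, ll_new
            return 1.0
        return 0.0

    def _update_group(self, b, ls, idx, steps):
        """Elementwise MH for one random-intercept vector.

        Periods partition by group, so accept/reject decisions for distinct
        groups are independent given everything else.
        """
        n = len(b)
        prop = b + steps * self.rng.standard_normal(n)
        eta = self.eta_psi + (prop - b)[idx]
        log_psi, log_1mpsi = _log_bernoulli_terms(eta)
        ll_new = _combine(self.det_any, log_psi, log_1mpsi, self.per_det)
        delta_ll = np.bincount(idx, weights=ll_new - self.ll_period, minlength=n)
        sig2 = np.exp(2 * ls)
        delta = delta_ll - 0.5 * (prop**2 - b**2) / sig2
        accept = np.log(self.rng.random(n)) < delta
        if accept.any():
            b = np.where(accept, prop, b)
            upd = accept[idx]
            self.eta_psi = np.where(upd, eta, self.eta_psi)
            self.log_psi = np.where(upd, log_psi, self.log_psi)
            self.log_1mpsi = np.where(upd, log_1mpsi, self.log_1mpsi)
            self.ll_period = np.where(upd, ll_new, self.ll_period)
        return b, accept.astype(float)

    def update_sites(self, steps):
        self.b_site, acc = self._update_group(
            self.b_site, self.ls_site, self.spec.site_idx, steps)
        return acc

    def update_areas(self, steps):
        self.b_area, acc = self._update_group(
            self.b_area, self.ls_area, self.spec.area_idx, steps)
        return acc

    def _update_log_sigma(self, ls, b, scale, step):
        prop = ls + step * self.rng.standard_normal()

        def logdens(l):
            sig = np.exp(l)
            return (-0.5 * np.sum(b**2) / sig**2 - len(b) * l
                    - 0.5 * (sig / scale) ** 2 + l)

        if np.log(self.rng.random()) < logdens(prop) - logdens(ls):
            return prop, 1.0
        return ls, 0.0

    def update_sigmas(self, step_s, step_a):
        pr = self.spec.priors
        self.ls_site, a1 = self._update_log_sigma(
            self.ls_site, self.b_site, pr.sigma_site_scale, step_s)
        self.ls_area, a2 = self._update_log_sigma(
            self.ls_area, self.b_area, pr.sigma_area_scale, step_a)
        return a1, a2

    def _rescale_group(self, b, ls, idx, scale, step):
        """Non-centered move: propose log sigma holding b/sigma fixed.

        Working in (u, log sigma) with u = b / sigma, the prior on u does
        not involve sigma, so the acceptance ratio reduces to the
        likelihood change plus the (HalfNormal + Jacobian) hyperprior
        change. This breaks the funnel coupling between the intercepts and
        their SD that plain centered updates mix through slowly.
        """
        prop = ls + step * self.rng.standard_normal()
        ratio = np.exp(prop - ls)
        b_new = b * ratio
        eta = self.eta_psi + (b_new - b)[idx]
        log_psi, log_1mpsi = _log_bernoulli_terms(eta)
        ll_new = _combine(self.det_any, log_psi, log_1mpsi, self.per_det)

        def hyper(l):
            sig = np.exp(l)
            return -0.5 * (sig / scale) ** 2 + l

        delta = ll_new.sum() - self.ll_period.sum() + hyper(prop) - hyper(ls)
        if np.log(self.rng.random()) < delta:
            self.eta_psi, self.log_psi, self.log_1mpsi = eta, log_psi, log_1mpsi
            self.ll_period = ll_new
            return b_new, prop, 1.0
        return b, ls, 0.0

    def rescale_sigmas(self, step_s, step_a):
        pr = self.spec.priors
        self.b_site, self.ls_site, a1 = self._rescale_group(
            self.b_site, self.ls_site, self.spec.site_idx,
            pr.sigma_site_scale, step_s)
        self.b_area, self.ls_area, a2 = self._rescale_group(
            self.b_area, self.ls_area, self.spec.area_idx,
            pr.sigma_area_scale, step_a)
        return a1, a2


def fit(spec: ModelSpec, history: DetectionHistory, chains: int = 3,
        iterations: int = 2000, warmup: int = 1000,
        seed: int | None = None, species: str | None = None) -> OccupancyPosterior:
    """Sample the occupancy posterior with adaptive random-walk Metropolis.

    ``iterations`` is the total per-chain length including ``warmup``;
    draws after warmup are retained. Proposal scales (and, for the fixed
    -effect blocks, proposal covariance) adapt during warmup only, so the
    retained draws come from a fixed Markov kernel. R-hat above 1.1 on any
    monitored parameter is flagged in ``warnings`` (never silently).
    """
    spec.validate(history)
    if chains < 1:
        raise InvalidArgumentError("need at least one chain")
    if iterations <= warmup:
        raise InvalidArgumentError("iterations must exceed warmup")
    n_save = iterations - warmup
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    all_draws = {k: [] for k in ("alpha", "beta", "b_site", "b_area",
                                 "sigma_site", "sigma_area")}
    psi_all, q_all, ll_all = [], [], []
    acc_tot: dict[str, list[float]] = {k: [] for k in
                                       ("alpha", "beta", "site", "area", "sigma")}

    for cs_seed in chain_seeds:
        rng = np.random.default_rng(cs_seed)
        st = _ChainState(spec, history, rng)
        chol_a = np.eye(spec.n_det)
        chol_b = np.eye(spec.n_occ)
        step_a, step_b = 0.1, 0.1
        steps_site = np.full(spec.n_sites, 0.5)
        steps_area = np.full(spec.n_areas, 0.5)
        step_ss, step_sa = 0.4, 0.4
        step_rs, step_ra = 0.4, 0.4
        warm_a = np.empty((warmup, spec.n_det))
        warm_b = np.empty((warmup, spec.n_occ))
        rec = {k: np.empty((n_save,) + shp) for k, shp in (
            ("alpha", (spec.n_det,)), ("beta", (spec.n_occ,)),
            ("b_site", (spec.n_sites,)), ("b_area", (spec.n_areas,)),
            ("sigma_site", ()), ("sigma_area", ()))}
        psi_c = np.empty((n_save, spec.n_periods))
        q_c = np.empty((n_save, spec.n_periods))
        ll_c = np.empty((n_save, spec.n_periods))
        acc_c = {k: 0.0 for k in acc_tot}

        for t in range(iterations):
            a_acc = st.update_alpha(chol_a, step_a)
            b_acc = st.update_beta(chol_b, step_b)
            s_acc = st.update_sites(steps_site)
            r_acc = st.update_areas(steps_area)
            g1, g2 = st.update_sigmas(step_ss, step_sa)
            h1, h2 = st.rescale_sigmas(step_rs, step_ra)

            if t < warmup:
                gam = 2.0 * (t + 1) ** -0.6
                step_a *= np.exp(gam * (a_acc - 0.28))
                step_b *= np.exp(gam * (b_acc - 0.28))
                steps_site *= np.exp(gam * (s_acc - 0.44))
                steps_area *= np.exp(gam * (r_acc - 0.44))
                step_ss *= np.exp(gam * (g1 - 0.44))
                step_sa *= np.exp(gam * (g2 - 0.44))
                step_rs *= np.exp(gam * (h1 - 0.44))
                step_ra *= np.exp(gam * (h2 - 0.44))
                warm_a[t] = st.alpha
                warm_b[t] = st.beta
                if t >= 199 and (t + 1) % 200 == 0:
                    lo = max(0, t - 399)
                    for warm, dim, which in ((warm_a, spec.n_det, "a"),
                                             (warm_b, spec.n_occ, "b")):
                        cov = np.cov(warm[lo:t + 1].T) + 1e-8 * np.eye(dim)
                        try:
                            c = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            continue
                        if which == "a":
                            chol_a = c
                        else:
                            chol_b = c
            else:
                k = t - warmup
                rec["alpha"][k] = st.alpha
                rec["beta"][k] = st.beta
                rec["b_site"][k] = st.b_site
                rec["b_area"][k] = st.b_area
                rec["sigma_site"][k] = np.exp(st.ls_site)
                rec["sigma_area"][k] = np.exp(st.ls_area)
                psi_c[k] = expit(st.eta_psi)
                q_c[k] = np.exp(np.bincount(spec.obs_period, weights=st.log1mp,
                                            minlength=spec.n_periods))
                ll_c[k] = st.ll_period
                acc_c["alpha"] += a_acc
                acc_c["beta"] += b_acc
                acc_c["site"] += s_acc.mean()
                acc_c["area"] += r_acc.mean()
                acc_c["sigma"] += 0.25 * (g1 + g2 + h1 + h2)

        for k in all_draws:
            all_draws[k].append(rec[k])
        psi_all.append(psi_c)
        q_all.append(q_c)
        ll_all.append(ll_c)
        for k in acc_tot:
            acc_tot[k].append(acc_c[k] / n_save)

    draws = {k: np.stack(v) for k, v in all_draws.items()}
    rhats: dict[str, float] = {}
    if chains >= 2 and n_save >= 4:
        for name in ("alpha", "beta"):
            for j in range(draws[name].shape[2]):
                rhats[f"{name}_{j}"] = rhat(draws[name][:, :, j])
        for name in ("sigma_site", "sigma_area"):
            rhats[name] = rhat(draws[name])

    warn: list[str] = []
    bad = {k: v for k, v in rhats.items() if np.isfinite(v) and v > 1.1}
    if bad:
        worst = max(bad.values())
        warn.append(f"non-convergence: R-hat > 1.1 for {sorted(bad)} (max {worst:.3f})")
        _warnings.warn(warn[-1], RuntimeWarning, stacklevel=2)
    if chains < 2:
        warn.append("single chain: R-hat not computed")

    return OccupancyPosterior(
        draws=draws,
        psi=np.stack(psi_all),
        q_miss=np.stack(q_all),
        log_lik=np.stack(ll_all),
        rhat=rhats,
        accept_rates={k: float(np.mean(v)) for k, v in acc_tot.items()},
        warnings=warn,
        spec=spec,
        history=history,
        species=species or history.species,
    )
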