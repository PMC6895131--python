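"""Community diversity from per-species occupancy posteriors.

Alpha diversity (species richness) is the sum of per-species occupancy
probabilities, ``R = sum_s psi_s``, evaluated on a burn-severity grid at
three pyrodiversity levels (-2, 0, +2 SD) with all other covariates held
at their (standardized) means and random intercepts at zero — a
population-level prediction. Beta diversity is pairwise Jaccard
dissimilarity computed on detection-corrected occurrence matrices: for each
posterior draw, each species' latent occurrence z is sampled from its
conditional distribution given the observed detection history, so
imperfect detection propagates into the diversity estimates. Full posterior
uncertainty is carried through both calculations draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from fireocc.covariates import OCC_COLUMNS
from fireocc.exceptions import (
    DataValidationError,
    InvalidArgumentError,
    ShapeError,
)
from fireocc.occupancy import DetectionHistory, OccupancyPosterior

#: Severity classes (percent basal-area mortality), half-open at the top.
SEVERITY_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("unchanged", 0.0, 0.0),   # exactly 0
    ("low", 0.0, 25.0),        # (0, 25]
    ("moderate", 25.0, 75.0),  # (25, 75]
    ("high", 75.0, 100.0),     # (75, 100]
)


def severity_class(severity: float) -> str:
    """Class label for a severity value in [0, 100]."""
    if severity < 0 or severity > 100:
        raise InvalidArgumentError("severity must lie in [0, 100]")
    if severity == 0.0:
        return "unchanged"
    for name, lo, hi in SEVERITY_CLASSES[1:]:
        if lo < severity <= hi:
            return name
    raise InvalidArgumentError(f"unclassifiable severity {severity}")


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

@dataclass
class RichnessSurface:
    """Posterior richness over a severity x pyrodiversity grid.

    ``draws`` has shape (n_draws, n_severity, n_pyro); ``summary`` holds
    the posterior mean and central 90% interval per grid cell.
    """

    severity: np.ndarray
    pyro_levels: np.ndarray
    draws: np.ndarray
    summary: pd.DataFrame
    n_species: int


def _occ_col(name: str) -> int:
    return OCC_COLUMNS.index(name)


def richness_curve(
    posteriors: Mapping[str, OccupancyPosterior],
    severity_grid: Sequence[float],
    pyro_levels: Sequence[float] = (-2.0, 0.0, 2.0),
    covariate_centers: Mapping[str, Mapping[str, float]] | None = None,
    interval: float = 0.9,
) -> RichnessSurface:
    """Expected species richness across severity and pyrodiversity.

    ``severity_grid`` is on the natural percent scale and is standardized
    with the center/scale recorded when the design matrices were built
    (``covariate_centers["severity"]``); ``pyro_levels`` are already in SD
    units. Per posterior draw, ``psi_s`` uses each species' occurrence
    coefficients with elevation and water distance at their standardized
    mean (0) and random intercepts at 0; richness is the sum over species.
    """
    sev = np.asarray(severity_grid, dtype=float)
    if sev.min() < 0 or sev.max() > 100:
        raise InvalidArgumentError("severity grid must lie in [0, 100]")
    pyro = np.asarray(pyro_levels, dtype=float)
    if covariate_centers and "severity" in covariate_centers:
        c = covariate_centers["severity"]
        sev_std = (sev - c["center"]) / c["scale"]
    else:
        sev_std = sev
    i0, i_sev, i_sev2, i_pyro = (_occ_col("intercept"), _occ_col("severity"),
                                 _occ_col("severity2"), _occ_col("pyrodiversity"))

    betas = [post.stacked("beta") for post in posteriors.values()]
    n_draws = min(b.shape[0] for b in betas)
    total = None
    for b in betas:
        b = b[:n_draws]
        # logit psi = b0 + b_sev * s + b_sev2 * s^2 + b_pyro * pyro
        eta = (b[:, i0, None, None]
               + b[:, i_sev, None, None] * sev_std[None, :, None]
               + b[:, i_sev2, None, None] * (sev_std**2)[None, :, None]
               + b[:, i_pyro, None, None] * pyro[None, None, :])
        psi = expit(eta)
        total = psi if total is None else total + psi

    lo_q = (1 - interval) / 2
    rows = []
    for a, s in enumerate(sev):
        for bq, pl in enumerate(pyro):
            d = total[:, a, bq]
            lo, hi = np.quantile(d, [lo_q, 1 - lo_q])
            rows.append({"severity": s, "pyro_level": pl,
                         "mean": float(d.mean()), "lo90": float(lo),
                         "hi90": float(hi)})
    return RichnessSurface(severity=sev, pyro_levels=pyro, draws=total,
                           summary=pd.DataFrame(rows),
                           n_species=len(betas))


# ---------------------------------------------------------------------------
# detection-corrected occurrence and Jaccard beta diversity
# ---------------------------------------------------------------------------

def conditional_occurrence_prob(psi: np.ndarray, q_miss: np.ndarray,
                                detected_any: np.ndarray) -> np.ndarray:
    """P(z=1 | y, psi, p): 1 where detected, Bayes rule where not.

    For an all-zero history, ``P(z=1|y) = psi q / (psi q + 1 - psi)`` with
    ``q = prod_j (1 - p_ij)``.
    """
    cond = psi * q_miss / (psi * q_miss + (1.0 - psi))
    return np.where(detected_any, 1.0, cond)


def draw_occurrence_matrix(
    posteriors: Mapping[str, OccupancyPosterior],
    histories: Mapping[str, DetectionHistory],
    draw_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One posterior draw of the periods x species binary occurrence matrix.

    ``draw_index`` indexes pooled (chain-stacked) posterior draws; the same
    index is used for every species so community summaries stay coherent
    across one joint draw.
    """
    rng = rng or np.random.default_rng()
    if set(posteriors) != set(histories):
        raise ShapeError("posteriors and histories must cover the same species")
    cols = []
    n_periods = None
    for sp in posteriors:
        post, hist = posteriors[sp], histories[sp]
        if n_periods is None:
            n_periods = hist.n_periods
        elif hist.n_periods != n_periods:
            raise ShapeError("species disagree on the number of survey periods")
        psi = post.psi_stacked()
        if not 0 <= draw_index < psi.shape[0]:
            raise InvalidArgumentError("draw_index outside the posterior sample")
        prob = conditional_occurrence_prob(
            psi[draw_index], post.q_miss_stacked()[draw_index],
            hist.detected_any,
        )
        cols.append((rng.random(n_periods) < prob).astype(np.int8))
    return np.column_stack(cols)


def jaccard_dissimilarity(occ_row_a: Sequence[int],
                          occ_row_b: Sequence[int]) -> float:
    """1 - |intersection| / |union| of two binary community vectors.

    Two empty communities are identical, so the both-empty case is defined
    as 0 dissimilarity (conventions differ; this one is flagged in docs).
    """
    a = np.asarray(occ_row_a)
    b = np.asarray(occ_row_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("community vectors must be equal-length 1-d")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise DataValidationError("community vectors must be binary")
    union = np.sum((a == 1) | (b == 1))
    if union == 0:
        return 0.0
    inter = np.sum((a == 1) & (b == 1))
    return float(1.0 - inter / union)


def pairwise_jaccard(occ: np.ndarray) -> np.ndarray:
    """Symmetric periods x periods Jaccard dissimilarity matrix."""
    Z = np.asarray(occ, dtype=float)
    inter = Z @ Z.T
    rs = Z.sum(axis=1)
    union = rs[:, None] + rs[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - inter / union
    D[union == 0] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class BetaSummary:
    """Posterior beta-diversity summaries.

    ``correlation`` is the posterior mean (over draws) of the Pearson
    correlation between pairwise Jaccard dissimilarity and severity
    distance; ``correlation_of_mean`` is the same correlation computed on
    the draw-averaged dissimilarity matrix (both are reported because the
    two conventions differ). ``class_means`` is the posterior-mean
    dissimilarity between/within severity classes.
    """

    correlation: float
    correlation_of_mean: float
    correlation_draws: np.ndarray
    class_means: pd.DataFrame
    mean_dissimilarity: np.ndarray
    warnings: list[str] = field(default_factory=list)


def beta_summary(
    occurrence_draws: np.ndarray | Sequence[np.ndarray],
    severity_by_period: Sequence[float],
) -> BetaSummary:
    """Correlate Jaccard dissimilarity with severity distance, per draw.

    ``occurrence_draws`` stacks binary occurrence matrices
    (n_draws, n_periods, n_species). All period pairs are treated as
    independent observations when computing the Pearson correlation. A
    draw with no variation in dissimilarity yields an undefined
    correlation, recorded as NaN (sentinel) and excluded from the
    posterior mean. Severity classes with no periods are dropped with a
    warning.
    """
    occ = np.asarray(occurrence_draws)
    if occ.ndim != 3:
        raise ShapeError("expected (draws, periods, species) occurrence stack")
    sev = np.asarray(severity_by_period, dtype=float)
    n_draws, n_periods, _ = occ.shape
    if sev.shape != (n_periods,):
        raise ShapeError("severity_by_period must have one value per period")

    iu, ju = np.triu_indices(n_periods, k=1)
    sev_dist = np.abs(sev[iu] - sev[ju])
    labels = np.array([severity_class(s) for s in sev])
    class_names = [c[0] for c in SEVERITY_CLASSES]
    present = [c for c in class_names if (labels == c).any()]
    warn = []
    absent = sorted(set(class_names) - set(present))
    if absent:
        warn.append(f"severity classes with no periods dropped: {absent}")

    corr_draws = np.full(n_draws, np.nan)
    mean_D = np.zeros((n_periods, n_periods))
    class_sums = {(a, b): [] for a in present for b in present}
    for d in range(n_draws):
        D = pairwise_jaccard(occ[d])
        mean_D += D / n_draws
        pair_d = D[iu, ju]
        if pair_d.std() > 0 and sev_dist.std() > 0:
            corr_draws[d] = np.corrcoef(pair_d, sev_dist)[0, 1]
        for a in present:
            for b in present:
                ma, mb = labels[iu] == a, labels[ju] == b
                sel = (ma & mb) | ((labels[iu] == b) & (labels[ju] == a))
                if sel.any():
                    class_sums[(a, b)].append(pair_d[sel].mean())

    class_means = pd.DataFrame(index=present, columns=present, dtype=float)
    for (a, b), vals in class_sums.items():
        class_means.loc[a, b] = float(np.mean(vals)) if vals else np.nan

    pair_mean = mean_D[iu, ju]
    if pair_mean.std() > 0 and sev_dist.std() > 0:
        corr_of_mean = float(np.corrcoef(pair_mean, sev_dist)[0, 1])
    else:
        corr_of_mean = float("nan")
        warn.append("dissimilarity has no variation; correlation undefined")
    finite = np.isfinite(corr_draws)
    corr = float(corr_draws[finite].mean()) if finite.any() else float("nan")
    return BetaSummary(
        correlation=corr, correlation_of_mean=corr_of_mean,
        correlation_draws=corr_draws, class_means=class_means,
        mean_dissimilarity=mean_D, warnings=warn,
    )
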