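"""Independent oracles shared across test modules.

Everything here is deliberately written without using the package's own
computation paths (brute-force enumeration, grid quadrature), so tests
compare two independent routes to the same quantity.
"""

import numpy as np
from scipy.special import expit


def enumeration_loglik(y, psi, p):
    """Brute-force marginal likelihood: sum over z in {0, 1}."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    like_occ = np.prod(np.where(y == 1, p, 1 - p))
    like_empty = 1.0 if y.sum() == 0 else 0.0
    return np.log(psi * like_occ + (1 - psi) * like_empty)


def toy_occupancy_loo(seed=5, n_periods=8, nights=2, n_draws=2000, grid=251):
    """Exact LOO for a 2-parameter occupancy toy via grid integration.

    The model has a detection intercept and an occupancy intercept only
    (p = expit(a0), psi = expit(b0)), Normal(0, 1.5) priors, and
    ``n_periods`` periods of ``nights`` nights. Exact leave-one-out
    predictive densities come from 2-d quadrature; posterior draws for
    PSIS are sampled iid from the same discretized posterior.

    Returns ``(ll_draws, elpd_exact)``.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=(n_periods, nights))
    a0 = np.linspace(-4, 4, grid)
    b0 = np.linspace(-4, 4, grid)
    A, B = np.meshgrid(a0, b0, indexing="ij")
    p, psi = expit(A), expit(B)
    ll_grid = np.empty((grid, grid, n_periods))
    for i in range(n_periods):
        det = np.prod([np.where(y[i, j], p, 1 - p) for j in range(nights)],
                      axis=0)
        ll_grid[:, :, i] = np.log(psi * det + (1 - psi) * (y[i].sum() == 0))
    log_prior = -0.5 * (A**2 + B**2) / 1.5**2
    log_post = log_prior + ll_grid.sum(axis=2)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()

    elpd_exact = np.empty(n_periods)
    for i in range(n_periods):
        log_wo = log_prior + ll_grid.sum(axis=2) - ll_grid[:, :, i]
        m = log_wo.max()
        num = np.exp(log_wo - m + ll_grid[:, :, i]).sum()
        den = np.exp(log_wo - m).sum()
        elpd_exact[i] = np.log(num / den)

    flat = rng.choice(grid * grid, size=n_draws, p=w.ravel())
    ll_draws = ll_grid.reshape(-1, n_periods)[flat]
    return ll_draws, float(elpd_exact.sum())


def brute_force_beta_summary(occ, severity):
    """O(n^2) pairwise loop over one occurrence matrix.

    Returns (pairwise dissimilarities, severity distances, Pearson r,
    {frozenset of class pair: mean dissimilarity}).
    """
    from fireocc.community import jaccard_dissimilarity, severity_class

    n = occ.shape[0]
    labels = [severity_class(s) for s in severity]
    ds, dists, pairs = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            ds.append(jaccard_dissimilarity(occ[i], occ[j]))
            dists.append(abs(severity[i] - severity[j]))
            pairs.append(frozenset((labels[i], labels[j]))
                         if labels[i] != labels[j] else frozenset((labels[i],)))
    ds, dists = np.array(ds), np.array(dists)
    r = np.corrcoef(ds, dists)[0, 1] if ds.std() > 0 and dists.std() > 0 \
        else float("nan")
    class_means = {}
    for key in set(pairs):
        sel = np.array([pr == key for pr in pairs])
        class_means[key] = float(ds[sel].mean())
    return ds, dists, r, class_means
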