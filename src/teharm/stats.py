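"""Per-window correlation statistics and the permutation null.

For each window the observed statistic is Pearson's correlation between the
per-element mutation counts in that window (one column of the mutation
matrix) and the per-element activity fractions.  Significance is assessed
against a permutation null: in each iteration every column of the matrix is
independently shuffled across elements, breaking the mutation-activity link
per window while preserving each window's mutation-count distribution, and
the per-window correlations with the fixed activity vector are recorded.

The test is one-sided on the left tail: only negative correlations (more
mutations, less activity) are candidate harmful windows.  Empirical
p-values use the add-one estimator ``(1 + #{null <= observed}) / (n + 1)``
by default, which is never exactly zero and so is safe input for the
q-value estimator; a ``raw`` mode reporting the plain count fraction is
available for windows whose p is best stated as "< 1/n".

Multiple-testing correction uses the Storey q-value machinery.  The
pipeline default fixes pi0 = 1, which reduces exactly to
Benjamini-Hochberg: overlapping windows are strongly positively dependent,
and in that regime the data-driven pi0 estimate (grid of lambda values,
cubic-smoother extrapolation at lambda -> 1) occasionally collapses on
dependent p-value sets, breaking FDR control.  The smoother estimate
remains available (``pi0=None``) for weakly dependent inputs.

Windows whose mutation counts are constant across elements have an
undefined correlation; they are flagged as NaN, excluded from the FDR
estimation, and reported as NA downstream — NaNs are never propagated
silently into significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from .windows import MutationMatrix

__all__ = [
    "WindowStatistics",
    "pearson",
    "observed_correlations",
    "permutation_null",
    "empirical_p_values",
    "estimate_pi0",
    "estimate_q_values",
    "compute_window_statistics",
]

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass(frozen=True)
class WindowStatistics:
    """Observed correlations, empirical p-values and q-values per window."""

    rho_obs: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_perm: int
    seed: int | None
    p_mode: str = "add_one"

    def __post_init__(self) -> None:
        if not (len(self.rho_obs) == len(self.p_values) == len(self.q_values)):
            raise ValueError("rho_obs, p_values and q_values must have equal length")

    @property
    def nw(self) -> int:
        return len(self.rho_obs)

    def defined(self) -> np.ndarray:
        """Boolean mask of windows with a defined correlation."""
        return ~np.isnan(self.rho_obs)


def pearson(x, y) -> float:
    """Pearson's correlation cov(X, Y) / (sigma_X * sigma_Y).

    Returns NaN — the package's explicit "undefined" marker — when either
    argument has zero variance.  Population or sample normalisation cancels,
    so plain centred sums are used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("pearson needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def _columns_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X with y; NaN for
    zero-variance columns."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc * yc))
    sx = np.sqrt(np.sum(Xc * Xc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc.T @ yc) / (sx * sy)
    rho[sx == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def _check_activity(M: MutationMatrix, activity) -> np.ndarray:
    activity = np.asarray(activity, dtype=float)
    if activity.shape != (M.n_elements,):
        raise ValueError(
            f"activity vector length {activity.size} != {M.n_elements} elements"
        )
    if M.n_elements < 2:
        raise ValueError("need at least 2 elements to correlate")
    if np.ptp(activity) == 0:
        raise ValueError("activity vector is constant; correlations are undefined")
    return activity


def observed_correlations(M: MutationMatrix, activity) -> np.ndarray:
    """Observed per-window correlation between mutation counts and activity."""
    activity = _check_activity(M, activity)
    return _columns_correlation(M.values.astype(float), activity)


def permutation_null(
    M: MutationMatrix, activity, n: int, seed=None
) -> np.ndarray:
    """The n x nw matrix of null correlations.

    Column j holds, for each of the n iterations, the correlation between an
    independent random shuffle of matrix column j and the fixed activity
    vector.  Iterations are generated column-by-column from a single seeded
    generator, so results are reproducible given the seed.
    """
    if n < 1:
        raise ValueError("need at least one permutation iteration")
    activity = _check_activity(M, activity)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N, nw = M.values.shape
    yc = activity - activity.mean()
    sy = np.sqrt(np.sum(yc * yc))
    null = np.empty((n, nw))
    for j in range(nw):
        col = M.values[:, j].astype(float)
        colc = col - col.mean()
        sx = np.sqrt(np.sum(colc * colc))
        if sx == 0:
            null[:, j] = np.nan
            continue
        # n independent shuffles of this column, as rows of an (n, N) array
        order = np.argsort(rng.random((n, N)), axis=1)
        perm = colc[order]
        null[:, j] = np.clip((perm @ yc) / (sx * sy), -1.0, 1.0)
    return null


def empirical_p_values(rho_obs, null: np.ndarray, mode: str = "add_one") -> np.ndarray:
    """Left-tail empirical p-value per window: P(rho_null <= rho_observed).

    ``add_one`` (default) returns (1 + count) / (n + 1); ``raw`` returns
    count / n, which can be exactly zero (reported as "< 1/n" by the
    writers).  Undefined windows stay NaN.
    """
    if mode not in ("add_one", "raw"):
        raise ValueError(f"unknown p-value mode {mode!r}")
    rho_obs = np.asarray(rho_obs, dtype=float)
    n = null.shape[0]
    if n < 1:
        raise ValueError("null distribution has no rows")
    p = np.full(rho_obs.shape, np.nan)
    defined = ~np.isnan(rho_obs)
    counts = np.sum(null[:, defined] <= rho_obs[defined], axis=0)
    if mode == "add_one":
        p[defined] = (1.0 + counts) / (n + 1.0)
    else:
        p[defined] = counts / n
    return p


def estimate_pi0(p: np.ndarray, lambda_grid=None) -> float:
    """Storey's estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    and extrapolated to lambda -> 1 with a cubic smoothing spline, then
    clipped into (0, 1].  Degenerate inputs (too few p-values for the
    smoother) fall back to the conservative pi0 = 1.
    """
    p = np.asarray(p, dtype=float)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    m = p.size
    if m == 0:
        raise ValueError("no p-values")
    if m < 8 or p.min() > grid.max():
        return 1.0
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    try:
        spline = UnivariateSpline(grid, pi0_lambda, k=3)
        pi0 = float(spline(grid.max()))
    except Exception:
        pi0 = float(pi0_lambda[-1])
    if not np.isfinite(pi0):
        return 1.0
    return float(min(max(pi0, 1.0 / m), 1.0))


def estimate_q_values(p, pi0: float | None = None, lambda_grid=None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    q_j = pi0 * min over p_k >= p_j of (p_k * m / rank(p_k)), enforced
    monotone non-decreasing in p.  With ``pi0=1`` this is exactly the
    Benjamini-Hochberg step-up adjustment.  NaN entries (undefined windows)
    are excluded from estimation and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    defined = ~np.isnan(p)
    pd = p[defined]
    if pd.size == 0:
        raise ValueError("no defined p-values")
    if np.any((pd <= 0) | (pd > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(pd, lambda_grid)
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m = pd.size
    order = np.argsort(pd, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * pd[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    qd = np.empty(m)
    qd[order] = q_sorted
    q = np.full(p.shape, np.nan)
    q[defined] = qd
    return q


def compute_window_statistics(
    M: MutationMatrix,
    activity,
    n_perm: int = 10_000,
    seed: int | None = None,
    pi0: float | None = 1.0,
    p_mode: str = "add_one",
) -> WindowStatistics:
    """Run the full per-window significance analysis (observed correlation,
    permutation null, empirical p, q).

    ``pi0=1`` (default) applies Benjamini-Hochberg, the appropriate choice
    for the strongly dependent sliding-window p-values; ``pi0=None``
    estimates pi0 with the Storey smoother instead.
    """
    rho_obs = observed_correlations(M, activity)
    null = permutation_null(M, activity, n_perm, seed)
    p = empirical_p_values(rho_obs, null, mode=p_mode)
    if p_mode == "raw":
        # zero p-values would break the q-value estimator; use the add-one
        # estimate for FDR estimation while reporting the raw p.
        p_for_q = empirical_p_values(rho_obs, null, mode="add_one")
    else:
        p_for_q = p
    q = estimate_q_values(p_for_q, pi0=pi0)
    return WindowStatistics(
        rho_obs=rho_obs, p_values=p, q_values=q, n_perm=n_perm, seed=seed, p_mode=p_mode
    )
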