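"""Sliding-window functional network connectivity via tapered covariance and graphical lasso.

Each run's component timecourses are cut into Gaussian-tapered sliding
windows (defaults: width 22 TRs, taper sigma 3 TRs, step 1 TR).  A sparse
precision matrix is estimated per window by L1-penalized Gaussian maximum
likelihood (graphical lasso), with the penalty weight chosen per run by
contiguous-fold cross-validation on held-out window log-likelihood.  The
regularized covariance implied by the precision is normalized to a
correlation matrix and Fisher-z transformed; subject-level covariates
(age, sex, mean framewise displacement) can then be regressed out of the
between-subject variation of the z edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ComponentTimecourse, WindowedFNC, vec_upper

logger = logging.getLogger(__name__)


@dataclass
class TaperedWindow:
    """Normalized Gaussian-tapered window weights."""

    weights: np.ndarray
    width_samples: int
    sigma_samples: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.width_samples:
            raise ValueError("weights length must equal width_samples")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must sum to 1")


@dataclass
class GlassoConfig:
    """Penalty grid and convergence settings for graphical-lasso estimation."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.01), 0.0, 10)
    )
    n_folds: int = 5
    max_iter: int = 200  # outer coordinate-descent sweeps
    tol: float = 1e-5  # duality-gap threshold per matrix dimension

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0:
            raise ValueError("lambda grid must be non-empty")
        if np.any(np.diff(self.lambda_grid) < 0) or np.any(self.lambda_grid < 0):
            raise ValueError("lambda grid must be ascending and nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def gaussian_tapered_window(width_samples: int, sigma_samples: float) -> TaperedWindow:
    """Rectangle convolved with a Gaussian kernel, truncated to the window support.

    The taper is symmetric, center-heavy, and normalized to unit sum; as
    sigma -> 0 it tends to the uniform window.
    """
    if width_samples < 2:
        raise ValueError("window width must be >= 2 samples")
    if sigma_samples <= 0:
        raise ValueError("sigma must be positive")
    rect = np.ones(width_samples)
    half = max(1, int(np.ceil(4 * sigma_samples)))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma_samples) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(rect, kernel, mode="full")  # length width + 2*half
    weights = full[half : half + width_samples]  # truncate to window support
    weights /= weights.sum()
    return TaperedWindow(weights=weights, width_samples=width_samples, sigma_samples=sigma_samples)


def sliding_window_offsets(n_timepoints: int, width: int, step: int = 1) -> np.ndarray:
    """Window start indices: exactly floor((T - w) / step) windows.

    The convention omits the last admissible full window, giving T - w
    windows at step 1 (178 windows for a 200-timepoint run with width 22).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if n_timepoints <= width:
        raise ValueError("need n_timepoints > width")
    n_windows = (n_timepoints - width) // step
    return np.arange(n_windows) * step


def weighted_window_covariance(
    tc: ComponentTimecourse | np.ndarray, offset: int, taper: TaperedWindow
) -> np.ndarray:
    """Taper-weighted sample covariance of one window (weighted mean removed)."""
    data = tc.data if isinstance(tc, ComponentTimecourse) else np.asarray(tc, dtype=float)
    w = taper.weights
    window = data[offset : offset + taper.width_samples]
    if window.shape[0] != taper.width_samples:
        raise ValueError("window does not fit within the run")
    mu = w @ window
    xc = window - mu
    cov = (xc * w[:, None]).T @ xc
    cov = (cov + cov.T) / 2.0
    low_var = np.diag(cov) < 1e-10
    if np.any(low_var):
        logger.warning(
            "window at offset %d: %d zero-variance components; variance floored", offset, low_var.sum()
        )
        cov[low_var, low_var] = 1e-10
    return cov


def _all_window_covariances(
    data: np.ndarray, offsets: np.ndarray, taper: TaperedWindow
) -> np.ndarray:
    """Vectorized tapered covariance for every window of a run (N_w x C x C)."""
    w = taper.weights
    width = taper.width_samples
    windows = np.lib.stride_tricks.sliding_window_view(data, width, axis=0)  # (T-w+1, C, w)
    windows = windows[offsets].transpose(0, 2, 1)  # (N_w, w, C)
    mu = np.einsum("t,ntc->nc", w, windows)
    xc = windows - mu[:, None, :]
    cov = np.einsum("t,nti,ntj->nij", w, xc, xc)
    cov = (cov + cov.transpose(0, 2, 1)) / 2.0
    diag = np.einsum("nii->ni", cov)
    floored = diag < 1e-10
    if np.any(floored):
        logger.warning("%d window variances floored at 1e-10", int(floored.sum()))
        diag[floored] = 1e-10
    return cov


def _glasso_objective(theta: np.ndarray, s: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    off_l1 = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(np.sum(s * theta) - logdet + lam * off_l1)


class GlassoNonConvergence(RuntimeError):
    def __init__(self, gap: float, max_iter: int):
        super().__init__(f"graphical lasso did not converge in {max_iter} iterations (gap={gap:.3e})")
        self.gap = gap


def glasso_precision(
    cov: np.ndarray,
    lam: float,
    config: GlassoConfig | None = None,
    init: np.ndarray | None = None,
    return_info: bool = False,
):
    """Sparse precision by L1-penalized Gaussian maximum likelihood.

    Minimizes ``tr(S @ Theta) - logdet(Theta) + lam * ||Theta||_1,off`` by
    block coordinate descent over columns of the working covariance, each
    column solved by a lasso coordinate-descent inner loop — the standard
    graphical-lasso algorithm, robust to the rank-deficient covariances of
    short tapered windows.  Convergence is declared when the duality-gap
    certificate falls below ``config.tol`` per matrix dimension.
    ``lam = 0`` returns the unpenalized MLE ``inv(S)``.  ``init`` warm-
    starts from a previous precision (useful across adjacent windows).
    With ``return_info=True`` also returns a dict carrying the per-sweep
    objective trace, final gap and sweep count.
    """
    config = config or GlassoConfig()
    s = np.asarray(cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if np.any(np.diag(s) <= 0):
        raise ValueError("covariance diagonal must be positive")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    s = (s + s.T) / 2.0
    d = s.shape[0]
    if lam == 0:
        try:
            theta = np.linalg.inv(s)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance singular; unpenalized MLE undefined") from exc
        theta = (theta + theta.T) / 2.0
        if return_info:
            return theta, {"trace": [_glasso_objective(theta, s, 0.0)], "gap": 0.0, "n_iter": 0}
        return theta

    from ._glasso_kernels import glasso_bcd

    # Working covariance: start at S with slightly shrunk off-diagonals (a
    # strictly feasible, better-conditioned point for singular S).
    if init is not None:
        theta0 = np.asarray(init, dtype=float)
        try:
            w = np.linalg.inv(theta0)
            w = (w + w.T) / 2.0
            np.fill_diagonal(w, np.diag(s))  # BCD invariant: W_ii = S_ii
            b = -theta0 / np.diag(theta0)[None, :]
            np.fill_diagonal(b, 0.0)
        except np.linalg.LinAlgError:
            w, b = None, None
    else:
        w, b = None, None
    if w is None:
        w = s * 0.95
        np.fill_diagonal(w, np.diag(s))
        b = np.zeros((d, d))
    gap_tol = config.tol * d
    scale = float(np.mean(np.diag(s)))
    theta, trace, n_sweeps, gap, status = glasso_bcd(
        np.ascontiguousarray(s),
        np.ascontiguousarray(w),
        np.ascontiguousarray(b),
        lam,
        config.max_iter,
        gap_tol,
        1e-10 * max(scale, 1.0),
        1000,
    )
    if status != 1 and init is not None:
        # Retry cold: a stale warm start can stall or leave W indefinite.
        return glasso_precision(cov, lam, config, init=None, return_info=return_info)
    if status != 1:
        raise GlassoNonConvergence(gap, config.max_iter)
    theta = (theta + theta.T) / 2.0
    if return_info:
        return theta, {"trace": list(trace), "gap": gap, "n_iter": n_sweeps}
    return theta


def precision_to_fc(theta: np.ndarray) -> np.ndarray:
    """Invert a precision matrix and normalize to a correlation matrix."""
    theta = np.asarray(theta, dtype=float)
    try:
        chol = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    ident = np.eye(theta.shape[0])
    inv_chol = np.linalg.solve(chol, ident)
    cov = inv_chol.T @ inv_chol
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _gaussian_loglik(theta: np.ndarray, s: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.sum(s * theta))


def select_lambda_cv(
    tc: ComponentTimecourse | np.ndarray,
    offsets: np.ndarray,
    taper: TaperedWindow,
    config: GlassoConfig | None = None,
    return_scores: bool = False,
    rule: str = "max",
):
    """Choose the graphical-lasso penalty by within-run cross-validation.

    Windows are split into contiguous folds; for each candidate penalty the
    precision is fitted on the pooled (averaged) training-window covariance
    and scored by the mean held-out Gaussian log-likelihood.  Because
    adjacent windows share almost all their samples, training windows whose
    support overlaps the test fold's sample range are embargoed (excluded),
    preventing leakage that would favor overly dense fits.  With
    ``rule="max"`` (default) the penalty maximizing the mean score is
    returned, ties resolving to the larger (sparser) penalty; with
    ``rule="1se"`` the largest penalty within one standard error (across
    folds) of the maximum is returned instead (glmnet-style parsimony).
    """
    config = config or GlassoConfig()
    if config.n_folds < 2:
        raise ValueError("need at least 2 folds")
    data = tc.data if isinstance(tc, ComponentTimecourse) else np.asarray(tc, dtype=float)
    covs = _all_window_covariances(data, np.asarray(offsets), taper)
    n_w = covs.shape[0]
    n_folds = min(config.n_folds, n_w)
    fold_bounds = np.linspace(0, n_w, n_folds + 1, dtype=int)
    n_grid = len(config.lambda_grid)
    fold_scores = np.full((n_folds, n_grid), np.nan)
    offs = np.asarray(offsets)
    width = taper.width_samples
    for f in range(n_folds):
        lo, hi = fold_bounds[f], fold_bounds[f + 1]
        if hi <= lo:
            continue
        test_idx = np.arange(lo, hi)
        # Embargo: drop training windows sharing samples with the test fold.
        test_start, test_end = offs[lo], offs[hi - 1] + width
        keep = (offs + width <= test_start) | (offs >= test_end)
        train_idx = np.flatnonzero(keep)
        if len(train_idx) == 0:
            continue
        s_train = covs[train_idx].mean(axis=0)
        theta = None
        # Warm-start down the grid: fit sparser models first.
        for gi in range(n_grid - 1, -1, -1):
            lam = config.lambda_grid[gi]
            theta = glasso_precision(s_train, lam, config, init=theta)
            fold_scores[f, gi] = np.mean(
                [_gaussian_loglik(theta, covs[t]) for t in test_idx]
            )
    valid = ~np.all(np.isnan(fold_scores), axis=1)
    fold_scores = fold_scores[valid]
    scores = fold_scores.mean(axis=0)
    best = n_grid - 1 - int(np.argmax(scores[::-1]))  # ties -> larger lambda
    if rule == "max":
        chosen = best
    elif rule == "1se":
        if fold_scores.shape[0] > 1:
            se = float(fold_scores[:, best].std(ddof=1) / np.sqrt(fold_scores.shape[0]))
        else:
            se = 0.0
        chosen = int(np.flatnonzero(scores >= scores[best] - se)[-1])
    else:
        raise ValueError(f"unknown selection rule: {rule}")
    lam = float(config.lambda_grid[chosen])
    if return_scores:
        return lam, scores
    return lam


def fisher_z(fc: np.ndarray) -> np.ndarray:
    """Fisher z-transform of a correlation matrix (stack): atanh off-diagonal, zero diagonal."""
    fc = np.asarray(fc, dtype=float)
    offdiag = ~np.eye(fc.shape[-1], dtype=bool)
    vals = fc[..., offdiag]
    if np.any(np.abs(vals) >= 1):
        raise ValueError("off-diagonal correlations must satisfy |r| < 1")
    z = np.arctanh(fc * offdiag)
    z[..., ~offdiag] = 0.0
    return z


@dataclass
class FNCConfig:
    """Window and penalty settings for per-run FNC estimation."""

    width: int = 22
    sigma: float = 3.0
    step: int = 1
    glasso: GlassoConfig = field(default_factory=GlassoConfig)
    method: str = "glasso"  # "glasso" (default) or "tapered" (direct windowed correlation)
    fixed_lambda: float | None = None  # skip CV when set


def estimate_run_fnc(tc: ComponentTimecourse, config: FNCConfig | None = None) -> WindowedFNC:
    """Full per-run estimation: windows -> covariance -> precision -> correlation -> Fisher z.

    With ``method="tapered"`` the tapered window covariance is normalized
    directly to correlation without the sparse precision step — a fast
    diagnostic mode; the graphical-lasso route is the default.
    """
    config = config or FNCConfig()
    taper = gaussian_tapered_window(config.width, config.sigma)
    offsets = sliding_window_offsets(tc.n_timepoints, config.width, config.step)
    covs = _all_window_covariances(tc.data, offsets, taper)
    n_w, c = covs.shape[0], covs.shape[1]
    fc = np.empty_like(covs)
    if config.method == "tapered":
        d = np.sqrt(np.einsum("nii->ni", covs))
        fc = covs / (d[:, :, None] * d[:, None, :])
        np.clip(fc, -0.999999, 0.999999, out=fc)
        ii = np.arange(c)
        fc[:, ii, ii] = 1.0
        lam = 0.0
    elif config.method == "glasso":
        if config.fixed_lambda is not None:
            lam = float(config.fixed_lambda)
        else:
            lam = select_lambda_cv(tc, offsets, taper, config.glasso)
        theta = None
        for i in range(n_w):
            theta = glasso_precision(covs[i], lam, config.glasso, init=theta)
            fc[i] = precision_to_fc(theta)
        np.clip(fc, -0.999999, 0.999999, out=fc)
        ii = np.arange(c)
        fc[:, ii, ii] = 1.0
    else:
        raise ValueError(f"unknown FNC method: {config.method}")
    z = fisher_z(fc)
    return WindowedFNC(
        z=z,
        offsets=offsets,
        lambda_used=lam,
        subject_id=tc.subject_id,
        condition=tc.run_condition,
        width=config.width,
        sigma=config.sigma,
    )


def regress_covariates(
    wfncs: list[WindowedFNC], table: pd.DataFrame
) -> list[WindowedFNC]:
    """Remove between-subject covariate effects from each edge's mean z level.

    For every edge, the subjects' across-window mean z values are regressed
    on mean-centered age, sex (0/1) and mean framewise displacement; the
    fitted covariate contribution is subtracted from all of that subject's
    windows.  The intercept (grand mean) is preserved, so within-run
    dynamics — the object of study — are untouched.
    """
    required = {"age", "sex", "mean_fd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if table.isna().any().any():
        raise ValueError("covariate table contains missing values")
    index = table["subject_id"] if "subject_id" in table.columns else table.index
    table = table.set_index(pd.Index(index))
    subjects = [w.subject_id for w in wfncs]
    if len(set(subjects)) != len(subjects):
        raise ValueError("one WindowedFNC per subject expected for a single condition")
    for s in subjects:
        if s not in table.index:
            raise ValueError(f"subject {s} missing from covariate table")
    n = len(wfncs)
    sex = table.loc[subjects, "sex"]
    sex_num = sex.map({"F": 0.0, "M": 1.0}) if sex.dtype == object else sex.astype(float)
    cov = np.column_stack(
        [
            table.loc[subjects, "age"].astype(float).to_numpy(),
            sex_num.to_numpy(),
            table.loc[subjects, "mean_fd"].astype(float).to_numpy(),
        ]
    )
    if n <= cov.shape[1] + 1:
        raise ValueError("need more subjects than covariates + 1")
    xc = cov - cov.mean(axis=0)
    y = np.stack([vec_upper(w.z).mean(axis=0) for w in wfncs])  # n_subjects x E
    design = np.column_stack([np.ones(n), xc])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted_effect = xc @ beta[1:]  # intercept preserved
    c = wfncs[0].n_components
    iu = np.triu_indices(c, k=1)
    out: list[WindowedFNC] = []
    for i, w in enumerate(wfncs):
        adj_mat = np.zeros((c, c))
        adj_mat[iu] = fitted_effect[i]
        adj_mat = adj_mat + adj_mat.T
        out.append(
            WindowedFNC(
                z=w.z - adj_mat[None, :, :],
                offsets=w.offsets,
                lambda_used=w.lambda_used,
                subject_id=w.subject_id,
                condition=w.condition,
                width=w.width,
                sigma=w.sigma,
            )
        )
    return out
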