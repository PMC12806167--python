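"""Post-ICA temporal denoising of component timecourses.

The chain applies, in order: zero-phase low-pass filtering, robust
MAD-based de-spiking with cubic-spline replacement, polynomial detrending
(up to cubic), and multiple regression against supplied nuisance
regressors.  Every step preserves the T x C shape and is deterministic.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .containers import ComponentTimecourse, NuisanceSet

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma for Gaussian data


@dataclass
class DenoiseConfig:
    cutoff_hz: float = 0.15
    mad_threshold: float = 4.0
    max_order: int = 3
    filter_order: int = 5


def lowpass_filter(tc: ComponentTimecourse, cutoff_hz: float, order: int = 5) -> ComponentTimecourse:
    """Zero-phase Butterworth low-pass filter applied forward-backward per column."""
    nyquist = 1.0 / (2.0 * tc.tr_seconds)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / tc.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, tc.data, axis=0)
    return tc.with_data(filtered)


def despike(
    tc: ComponentTimecourse, mad_threshold: float = 4.0
) -> tuple[ComponentTimecourse, np.ndarray]:
    """Flag per-column outliers by the robust MAD rule and replace them by a cubic spline.

    A sample is flagged when |x - median| > mad_threshold * 1.4826 * MAD.
    Flagged samples are replaced by a third-order spline through the
    unflagged samples; unflagged samples are never altered.  Flagged
    samples outside the unflagged support are replaced by the nearest
    interior spline value (logged).
    """
    if mad_threshold <= 0:
        raise ValueError("mad_threshold must be positive")
    data = tc.data.copy()
    t_len, n_col = data.shape
    mask = np.zeros((t_len, n_col), dtype=bool)
    t_idx = np.arange(t_len)
    for j in range(n_col):
        col = data[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        if mad == 0:
            continue  # constant (or majority-constant) column: nothing to flag
        flags = np.abs(col - med) > mad_threshold * MAD_SCALE * mad
        if flags.mean() > 0.5:
            raise ValueError(
                f"column {j}: {flags.mean():.0%} of samples flagged as outliers; signal unusable"
            )
        if not np.any(flags):
            continue
        mask[:, j] = flags
        good = ~flags
        spline = CubicSpline(t_idx[good], col[good])
        lo, hi = t_idx[good][0], t_idx[good][-1]
        eval_at = np.clip(t_idx[flags], lo, hi)
        if np.any(t_idx[flags] != eval_at):
            logger.info("column %d: boundary spikes replaced by nearest-interior spline value", j)
        data[flags, j] = spline(eval_at)
    return tc.with_data(data), mask


def detrend_poly(tc: ComponentTimecourse, max_order: int = 3) -> ComponentTimecourse:
    """Remove the least-squares polynomial fit up to ``max_order`` from each column."""
    t_len = tc.n_timepoints
    if t_len <= max_order + 1:
        raise ValueError("need T > max_order + 1 timepoints to detrend")
    x = np.linspace(-1.0, 1.0, t_len)
    basis = np.polynomial.polynomial.polyvander(x, max_order)
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("polynomial basis is rank deficient")
    q, _ = np.linalg.qr(basis)
    residual = tc.data - q @ (q.T @ tc.data)
    return tc.with_data(residual)


def regress_nuisance(tc: ComponentTimecourse, nuis: NuisanceSet) -> ComponentTimecourse:
    """Column-wise least-squares residualization against nuisance regressors.

    An intercept is added internally.  Collinear regressors are dropped
    with a warning naming them; the residual is orthogonal to every kept
    regressor.
    """
    reg = nuis.regressors
    if reg.shape[0] != tc.n_timepoints:
        raise ValueError("nuisance regressor rows must match timecourse length")
    design = np.column_stack([np.ones(tc.n_timepoints), reg])
    labels = ["intercept"] + list(nuis.labels)
    # Greedy rank-preserving column selection (intercept always kept).
    kept: list[int] = [0]
    dropped: list[str] = []
    for j in range(1, design.shape[1]):
        cand = design[:, kept + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-10 * max(1.0, np.abs(design).max())) > len(kept):
            kept.append(j)
        else:
            dropped.append(labels[j])
    if dropped:
        warnings.warn(f"dropping collinear nuisance regressors: {dropped}", stacklevel=2)
    x = design[:, kept]
    beta, *_ = np.linalg.lstsq(x, tc.data, rcond=None)
    return tc.with_data(tc.data - x @ beta)


def denoise_run(
    tc: ComponentTimecourse,
    nuis: NuisanceSet | None = None,
    config: DenoiseConfig | None = None,
) -> tuple[ComponentTimecourse, list[dict]]:
    """Full chain: low-pass -> de-spike -> detrend -> nuisance regression.

    Returns the denoised timecourse and a provenance log, one record per
    executed (or skipped) step.
    """
    config = config or DenoiseConfig()
    log: list[dict] = []
    tc = lowpass_filter(tc, config.cutoff_hz, order=config.filter_order)
    log.append({"step": "lowpass", "cutoff_hz": config.cutoff_hz, "order": config.filter_order})
    tc, mask = despike(tc, config.mad_threshold)
    log.append(
        {"step": "despike", "mad_threshold": config.mad_threshold, "n_flagged": int(mask.sum())}
    )
    tc = detrend_poly(tc, config.max_order)
    log.append({"step": "detrend", "max_order": config.max_order})
    if nuis is not None and nuis.n_regressors > 0:
        tc = regress_nuisance(tc, nuis)
        log.append({"step": "nuisance_regression", "n_regressors": nuis.n_regressors})
    else:
        log.append({"step": "nuisance_regression", "skipped": True})
        logger.info("no nuisance regressors supplied; regression step skipped")
    return tc, log
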