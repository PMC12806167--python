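"""Core in-memory containers shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("rest_pre", "brooding", "rest_post")


@dataclass
class ComponentTimecourse:
    """One run's network timecourses: T timepoints x C components.

    ``data`` holds the (possibly denoised) component timecourses sampled
    every ``tr_seconds`` seconds.  Rows are timepoints, columns are
    independent-component networks.
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    run_condition: str = "rest_pre"
    subject_id: str = ""
    component_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timecourse data must be a T x C matrix")
        if self.data.shape[0] < 2:
            raise ValueError("timecourse needs at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timecourse contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.component_names is None:
            self.component_names = [f"IC{i + 1}" for i in range(self.data.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ComponentTimecourse":
        return ComponentTimecourse(
            data=data,
            tr_seconds=self.tr_seconds,
            run_condition=self.run_condition,
            subject_id=self.subject_id,
            component_names=list(self.component_names or []) or None,
        )


@dataclass
class NuisanceSet:
    """Nuisance regressors for one run (T x R), e.g. physiological and motion traces."""

    regressors: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.labels is None:
            self.labels = [f"nuis{i + 1}" for i in range(self.regressors.shape[1])]
        if len(self.labels) != self.regressors.shape[1]:
            raise ValueError("labels must match regressor count")

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


@dataclass
class WindowedFNC:
    """Per-window functional network connectivity for one run, on the Fisher-z scale.

    ``z`` is N_w x C x C, symmetric with zero diagonal; ``offsets`` are the
    window start indices into the run.
    """

    z: np.ndarray
    offsets: np.ndarray
    lambda_used: float
    subject_id: str
    condition: str
    width: int
    sigma: float

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_components(self) -> int:
        return self.z.shape[1]


@dataclass
class FNCVectorSet:
    """Window-level FNC edge vectors pooled across runs.

    ``vectors`` is N x E with E = C(C-1)/2 upper-triangle Fisher-z edges;
    ``provenance`` has one row per vector: subject, condition, window.
    """

    vectors: np.ndarray
    provenance: pd.DataFrame
    n_components: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        c = self.n_components
        if self.vectors.shape[1] != c * (c - 1) // 2:
            raise ValueError("edge dimension inconsistent with n_components")
        if len(self.provenance) != self.vectors.shape[0]:
            raise ValueError("provenance must have one row per vector")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("FNC vectors contain non-finite values")


@dataclass
class StateSequence:
    """Window-wise state labels (1..k) for one run."""

    labels: np.ndarray
    subject_id: str = ""
    condition: str = "rest_pre"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    def __len__(self) -> int:
        return len(self.labels)


def vec_upper(mats: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a (..., C, C) stack."""
    mats = np.asarray(mats)
    c = mats.shape[-1]
    iu = np.triu_indices(c, k=1)
    return mats[..., iu[0], iu[1]]


def mat_from_upper(vec: np.ndarray, n_components: int) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from its strict upper triangle."""
    out = np.zeros((n_components, n_components), dtype=float)
    iu = np.triu_indices(n_components, k=1)
    out[iu] = vec
    return out + out.T
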