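"""Synthetic cohorts of state-switching multivariate timecourses with known ground truth.

The generative model is a first-order hidden Markov chain over K covariance
regimes with zero-mean multivariate Gaussian emissions at the component-
timecourse level.  Each regime ("state") has a block-structured correlation
matrix in which a distinct subset of functional-domain blocks carries
elevated connectivity, so recovered cluster centroids can be matched
against planted ground truth.  A configurable linear link plants a negative
association between the brooding-severity score (RRS-B) and the fraction of
the brooding run spent in one designated state.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import CONDITIONS, ComponentTimecourse

logger = logging.getLogger(__name__)

#: Component counts per functional domain used for the default 34-component
#: block structure: six cortical domains plus a subcortical remainder.
DEFAULT_DOMAIN_BLOCKS: dict[str, int] = {
    "default_mode": 8,
    "central_executive": 6,
    "salience": 4,
    "attention": 4,
    "somatomotor": 3,
    "visual": 6,
    "subcortical": 3,
}


@dataclass
class StateCovarianceSet:
    """K symmetric positive-definite C x C correlation matrices plus the domain partition."""

    covariances: list[np.ndarray]
    domain_blocks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for i, cov in enumerate(self.covariances):
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValueError(f"state {i + 1} covariance is not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-10):
                raise ValueError(f"state {i + 1} covariance diagonal is not 1")
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError(f"state {i + 1} covariance is not positive definite")
            self.covariances[i] = cov

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_components(self) -> int:
        return self.covariances[0].shape[0]


@dataclass
class TransitionModel:
    """Row-stochastic K x K transition matrix plus an initial distribution."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        p, pi = self.transition_matrix, self.initial_distribution
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(p < 0) or np.any(pi < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition-matrix rows must sum to 1")
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        if pi.shape[0] != p.shape[0]:
            raise ValueError("initial distribution length must match state count")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector, normalized)."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        idx = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, idx])
        return pi / pi.sum()

    def boosted(self, state: int, amount: float) -> "TransitionModel":
        """Mix every row with a point mass on ``state`` (1-based).

        ``P'(i, j) = (1 - a) P(i, j) + a [j == state]`` — shifts occupancy
        toward the given state while keeping rows stochastic.  Used to plant
        a post-intervention occupancy increase.
        """
        if not 0.0 <= amount <= 1.0:
            raise ValueError("boost amount must be in [0, 1]")
        k = self.n_states
        point = np.zeros(k)
        point[state - 1] = 1.0
        p = (1.0 - amount) * self.transition_matrix + amount * point[None, :]
        pi = (1.0 - amount) * self.initial_distribution + amount * point
        return TransitionModel(p, pi)


def sticky_transition_model(n_states: int, self_transition: float = 0.9) -> TransitionModel:
    """Uniform-off-diagonal chain with a given self-transition probability."""
    if not 0.0 <= self_transition < 1.0:
        raise ValueError("self_transition must be in [0, 1)")
    if n_states == 1:
        return TransitionModel(np.ones((1, 1)), np.ones(1))
    off = (1.0 - self_transition) / (n_states - 1)
    p = np.full((n_states, n_states), off)
    np.fill_diagonal(p, self_transition)
    return TransitionModel(p, np.full(n_states, 1.0 / n_states))


def _blocks_from_spec(n_components: int, block_spec) -> dict[str, np.ndarray]:
    """Turn a block specification into index arrays partitioning 0..C-1."""
    if block_spec is None:
        base = DEFAULT_DOMAIN_BLOCKS
        total = sum(base.values())
        # Scale the default 34-component partition to other C, keeping >= 1
        # component per block where possible.
        if n_components >= len(base):
            sizes = {k: max(1, round(v * n_components / total)) for k, v in base.items()}
            drift = n_components - sum(sizes.values())
            keys = list(sizes)
            i = 0
            while drift != 0:
                k = keys[i % len(keys)]
                if drift > 0:
                    sizes[k] += 1
                    drift -= 1
                elif sizes[k] > 1:
                    sizes[k] -= 1
                    drift += 1
                i += 1
            block_spec = sizes
        else:
            block_spec = {f"block{i + 1}": 1 for i in range(n_components)}
    if isinstance(block_spec, dict):
        items = list(block_spec.items())
    else:
        items = [(f"block{i + 1}", int(s)) for i, s in enumerate(block_spec)]
    if sum(s for _, s in items) != n_components:
        raise ValueError("block sizes must sum to n_components")
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, size in items:
        if size < 1:
            raise ValueError("block sizes must be >= 1")
        out[name] = np.arange(start, start + size)
        start += size
    return out


def _nearest_spd_correlation(mat: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, min_eig, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    return (repaired + repaired.T) / 2.0


def make_state_covariances(
    n_components: int,
    n_states: int,
    block_spec=None,
    within_block_r: float = 0.6,
    cross_block_r: float = 0.25,
    seed: int | None = None,
) -> StateCovarianceSet:
    """Build K distinct block-structured SPD correlation matrices.

    Each state assigns every domain block a sign (aligned or anti-aligned
    relative to the rest of the brain) and a different subset of blocks is
    sign-elevated per state.  Within a block the off-diagonal correlation
    is ``within_block_r``; between two blocks it is ``+cross_block_r`` when
    their signs agree and ``-cross_block_r`` otherwise — mirroring how
    empirical connectivity states differ in large-scale patterns of
    between-domain (anti-)correlation.  With
    ``0 <= cross_block_r <= within_block_r`` the construction
    ``cross_r * g g' + (within_r - cross_r) * blockdiag + (1 - within_r) * I``
    is positive definite by design; any other setting falls back to a
    nearest-SPD repair (eigenvalue clipping), which is logged.
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    if n_states < 1:
        raise ValueError("need at least 1 state")
    if abs(within_block_r) >= 1 or abs(cross_block_r) >= 1:
        raise ValueError("correlations must have absolute value < 1")
    blocks = _blocks_from_spec(n_components, block_spec)
    names = list(blocks)
    n_blocks = len(names)
    if n_states > 2 ** max(n_blocks - 1, 0):
        raise ValueError("more states than distinct block sign patterns")
    rng = np.random.default_rng(0 if seed is None else seed)
    # Distinct sign patterns over blocks; g and -g give the same matrix, so
    # patterns are kept distinct up to global sign.  The first state is the
    # all-aligned pattern.
    patterns: list[np.ndarray] = []
    while len(patterns) < n_states:
        if not patterns:
            g = np.ones(n_blocks)
        else:
            g = rng.choice([-1.0, 1.0], size=n_blocks)
        if any(np.array_equal(g, p) or np.array_equal(-g, p) for p in patterns):
            continue
        patterns.append(g)
    block_of = np.empty(n_components, dtype=int)
    for b, name in enumerate(names):
        block_of[blocks[name]] = b
    block_mask = block_of[:, None] == block_of[None, :]
    covs: list[np.ndarray] = []
    for s, g in enumerate(patterns):
        gc = g[block_of]
        cov = (
            cross_block_r * np.outer(gc, gc)
            + (within_block_r - cross_block_r) * block_mask
            + (1.0 - within_block_r) * np.eye(n_components)
        )
        np.fill_diagonal(cov, 1.0)
        if np.linalg.eigvalsh(cov)[0] <= 1e-8:
            logger.warning("state %d covariance indefinite; applying nearest-SPD repair", s + 1)
            cov = _nearest_spd_correlation(cov)
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError(f"state {s + 1} covariance not positive definite after repair")
        covs.append(cov)
    return StateCovarianceSet(covariances=covs, domain_blocks=blocks)


def simulate_state_sequence(
    n_timepoints: int, model: TransitionModel, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw a length-T label sequence (1-based states) from the Markov chain."""
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    k = model.n_states
    labels = np.empty(n_timepoints, dtype=int)
    cum_init = np.cumsum(model.initial_distribution)
    cum_rows = np.cumsum(model.transition_matrix, axis=1)
    labels[0] = int(np.searchsorted(cum_init, rng.random(), side="right"))
    u = rng.random(n_timepoints - 1)
    for t in range(1, n_timepoints):
        labels[t] = int(np.searchsorted(cum_rows[labels[t - 1]], u[t - 1], side="right"))
    return labels + 1


@dataclass
class ArtifactSpec:
    """Additive artifacts injected into a simulated run.

    spikes: list of (timepoint, amplitude) global spikes added to every column.
    drift_coefficients: polynomial coefficients (constant first) over
        normalized time in [-1, 1].
    sinusoid: (frequency_hz, amplitude) confound shared by all columns.
    """

    spikes: list[tuple[int, float]] = field(default_factory=list)
    drift_coefficients: list[float] = field(default_factory=list)
    sinusoid: tuple[float, float] | None = None


def simulate_run(
    cov_set: StateCovarianceSet,
    labels: np.ndarray,
    noise_sd: float = 0.0,
    artifact_spec: ArtifactSpec | None = None,
    seed: int | np.random.Generator | None = None,
    tr_seconds: float = 2.0,
    subject_id: str = "",
    condition: str = "rest_pre",
) -> tuple[ComponentTimecourse, dict]:
    """Emit a T x C run: state-conditional Gaussian draws plus optional artifacts.

    Returns the timecourse and a ground-truth record of injected artifact
    locations.
    """
    labels = np.asarray(labels, dtype=int)
    t_len = len(labels)
    if t_len == 0:
        raise ValueError("labels must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if labels.min() < 1 or labels.max() > cov_set.n_states:
        raise ValueError("labels out of range 1..K")
    rng = np.random.default_rng(seed)
    c = cov_set.n_components
    chols = [np.linalg.cholesky(cov) for cov in cov_set.covariances]
    z = rng.standard_normal((t_len, c))
    data = np.empty((t_len, c))
    for s in range(cov_set.n_states):
        mask = labels == s + 1
        if np.any(mask):
            data[mask] = z[mask] @ chols[s].T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((t_len, c))
    truth: dict = {"spike_times": [], "drift_coefficients": [], "sinusoid": None}
    if artifact_spec is not None:
        for t_spike, amp in artifact_spec.spikes:
            if not 0 <= t_spike < t_len:
                raise ValueError("spike timepoint outside run")
            data[t_spike] += amp
            truth["spike_times"].append(int(t_spike))
        if artifact_spec.drift_coefficients:
            x = np.linspace(-1.0, 1.0, t_len)
            drift = np.polynomial.polynomial.polyval(x, artifact_spec.drift_coefficients)
            data = data + drift[:, None]
            truth["drift_coefficients"] = list(artifact_spec.drift_coefficients)
        if artifact_spec.sinusoid is not None:
            freq, amp = artifact_spec.sinusoid
            tt = np.arange(t_len) * tr_seconds
            data = data + amp * np.sin(2 * np.pi * freq * tt)[:, None]
            truth["sinusoid"] = (float(freq), float(amp))
    tc = ComponentTimecourse(
        data=data, tr_seconds=tr_seconds, run_condition=condition, subject_id=subject_id
    )
    return tc, truth


@dataclass
class SyntheticTruth:
    """Planted ground truth retained for recovery tests."""

    state_sequences: dict[str, np.ndarray]
    effect_size: float
    designated_state: int


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # MDD | HC
    arm: str  # active | sham
    age: float
    sex: str  # F | M
    mean_fd: float
    rrs_b: int
    runs: dict[str, ComponentTimecourse]
    truth: SyntheticTruth


@dataclass
class CohortConfig:
    """Study-design settings for the synthetic cohort.

    Defaults mirror the emulated study: 62 subjects in four cells
    (MDD/HC x active/sham = 18/18/13/13), three runs per subject
    (rest_pre, brooding, rest_post) of 200 timepoints at TR = 2 s across
    34 components, four recurring covariance states, and a planted negative
    linear link from brooding-run occupancy of the designated state to the
    integer RRS-B score (range 5..20).
    """

    n_per_cell: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("MDD", "active"): 18,
            ("MDD", "sham"): 18,
            ("HC", "active"): 13,
            ("HC", "sham"): 13,
        }
    )
    n_components: int = 34
    n_states: int = 4
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    block_spec: dict | list | None = None
    within_block_r: float = 0.6
    cross_block_r: float = 0.25
    noise_sd: float = 0.0
    self_transition: float = 0.9
    designated_state: int = 3
    effect_size: float = -20.0
    effect_size_hc: float = 0.0
    post_boost: float = 0.05
    rrs_mean: dict[str, float] = field(default_factory=lambda: {"MDD": 12.7, "HC": 6.2})
    rrs_noise_sd: dict[str, float] = field(default_factory=lambda: {"MDD": 2.5, "HC": 1.1})
    rrs_bounds: tuple[int, int] = (5, 20)
    age_mean: float = 28.0
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (18.0, 65.0)
    p_female: float = 0.74
    fd_mean: float = 0.12
    fd_sd: float = 0.05
    n_fd_outliers: int = 0
    emit_timecourses: bool = True


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    cov_set: StateCovarianceSet
    transition_model: TransitionModel
    config: CohortConfig

    def metadata(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "arm": [s.arm for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "mean_fd": [s.mean_fd for s in self.subjects],
                "rrs_b": [s.rrs_b for s in self.subjects],
            }
        )


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(x, low, high))


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort with retained ground truth.

    RRS-B is generated as
    ``round(group_mean + effect x (true brooding fraction in the designated
    state - cohort mean fraction) + noise)`` clipped to the scale bounds.
    The occupancy-score link is planted in the MDD group
    (``effect_size``); healthy controls get ``effect_size_hc`` (0 by
    default), matching a depression-specific brooding association.  A
    nonzero ``post_boost`` shifts the rest_post transition model of the
    MDD-active cell toward the designated state, planting an intervention
    effect confined to that cell.
    """
    config = config or CohortConfig()
    if any(n < 1 for n in config.n_per_cell.values()):
        raise ValueError("n_per_cell entries must be >= 1")
    if not 1 <= config.designated_state <= config.n_states:
        raise ValueError("designated_state out of range")
    rng = np.random.default_rng(seed)
    cov_set = make_state_covariances(
        config.n_components,
        config.n_states,
        block_spec=config.block_spec,
        within_block_r=config.within_block_r,
        cross_block_r=config.cross_block_r,
    )
    tm = sticky_transition_model(config.n_states, config.self_transition)
    tm_boosted = tm.boosted(config.designated_state, config.post_boost)

    cells = sorted(config.n_per_cell.items())
    roster: list[tuple[str, str, str]] = []
    i = 0
    for (group, arm), n in cells:
        for _ in range(n):
            i += 1
            roster.append((f"sub-{i:03d}", group, arm))

    # Draw all state sequences first so the cohort-mean brooding fraction is
    # available for the RRS-B link.
    sequences: list[dict[str, np.ndarray]] = []
    for subject_id, group, arm in roster:
        seqs = {}
        for cond in CONDITIONS:
            model = tm
            if cond == "rest_post" and group == "MDD" and arm == "active":
                model = tm_boosted
            seqs[cond] = simulate_state_sequence(config.n_timepoints, model, rng)
        sequences.append(seqs)
    fracs = np.array(
        [np.mean(seqs["brooding"] == config.designated_state) for seqs in sequences]
    )
    frac_mean = fracs.mean()

    n_total = len(roster)
    fd_values = np.abs(rng.normal(config.fd_mean, config.fd_sd, size=n_total))
    fd_values = np.minimum(fd_values, 0.3)  # keep the base cohort below the exclusion ceiling
    if config.n_fd_outliers > 0:
        outlier_idx = rng.choice(n_total, size=config.n_fd_outliers, replace=False)
        fd_values[outlier_idx] = 0.31 + np.abs(rng.normal(0.1, 0.05, config.n_fd_outliers))

    subjects: list[SyntheticSubject] = []
    lo, hi = config.rrs_bounds
    for j, (subject_id, group, arm) in enumerate(roster):
        effect = config.effect_size if group == "MDD" else config.effect_size_hc
        score = (
            config.rrs_mean[group]
            + effect * (fracs[j] - frac_mean)
            + rng.normal(0.0, config.rrs_noise_sd[group])
        )
        rrs_b = int(np.clip(round(score), lo, hi))
        runs: dict[str, ComponentTimecourse] = {}
        if config.emit_timecourses:
            for cond in CONDITIONS:
                tc, _ = simulate_run(
                    cov_set,
                    sequences[j][cond],
                    noise_sd=config.noise_sd,
                    seed=rng,
                    tr_seconds=config.tr_seconds,
                    subject_id=subject_id,
                    condition=cond,
                )
                runs[cond] = tc
        subjects.append(
            SyntheticSubject(
                subject_id=subject_id,
                group=group,
                arm=arm,
                age=_truncated_normal(
                    rng, config.age_mean, config.age_sd, *config.age_bounds
                ),
                sex="F" if rng.random() < config.p_female else "M",
                mean_fd=float(fd_values[j]),
                rrs_b=rrs_b,
                runs=runs,
                truth=SyntheticTruth(
                    state_sequences=sequences[j],
                    effect_size=effect,
                    designated_state=config.designated_state,
                ),
            )
        )
    return Cohort(subjects=subjects, cov_set=cov_set, transition_model=tm, config=config)
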