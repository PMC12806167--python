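"""Nonparametric inference on temporal state metrics.

Implements the analysis plan relating state occupancy to diagnostic group,
condition, brooding severity and pre/post intervention: permutation
Wilcoxon rank-sum tests (group contrasts), permutation Wilcoxon
signed-rank tests (pre/post contrasts, with single-step max-statistic
family-wise correction over a shared permutation stream), Kendall tau-b
correlations with Benjamini-Hochberg FDR control, chi-square tests on
state-entry proportions, and a pooled-variance t-test contrasting scores
of subjects with zero versus non-zero occupancy.

Permutation p-values use the add-one estimator (1 + b) / (1 + B), which is
valid and never zero; exhaustive enumeration replaces Monte-Carlo sampling
automatically whenever the total number of arrangements is at most the
requested permutation count.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

OUTCOMES = ("dwell_time", "fraction")


@dataclass
class StatResult:
    method: str
    statistic: float
    p_raw: float
    z_approx: float | None = None
    p_adjusted: float | None = None
    adjustment: str = "none"
    n_perm: int | None = None
    seed: int | None = None
    notes: str = ""


def _tie_corrected_ranksum_var(ranks: np.ndarray, nx: int, ny: int) -> float:
    n = nx + ny
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    return nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))


def perm_rank_sum(
    x, y, n_perm: int = 10_000, seed: int | None = None
) -> StatResult:
    """Two-sided Wilcoxon rank-sum test with a permutation null.

    The statistic is the rank sum of the first sample (midranks for ties).
    The null is generated by shuffling group labels; all C(n, nx)
    arrangements are enumerated when that count does not exceed ``n_perm``,
    otherwise ``n_perm`` Monte-Carlo shuffles are drawn and the add-one
    p-value estimator is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:nx].sum())
    expect = nx * (n + 1) / 2.0
    var = _tie_corrected_ranksum_var(ranks, nx, ny)
    if var <= 0:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return StatResult("perm_rank_sum", w_obs, 1.0, z_approx=0.0, n_perm=n_perm, seed=seed)
    z = (w_obs - expect) / math.sqrt(var)
    dev_obs = abs(w_obs - expect)
    total = math.comb(n, nx)
    eps = 1e-9
    if total <= n_perm:
        count = 0
        for idx in itertools.combinations(range(n), nx):
            dev = abs(ranks[list(idx)].sum() - expect)
            if dev >= dev_obs - eps:
                count += 1
        p = count / total
        note = "exhaustive"
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :nx]
        dev = np.abs(ranks[order].sum(axis=1) - expect)
        p = (1 + int(np.sum(dev >= dev_obs - eps))) / (1 + n_perm)
        note = "monte-carlo"
        n_used = n_perm
    return StatResult(
        "perm_rank_sum", w_obs, float(p), z_approx=float(z), n_perm=n_used, seed=seed, notes=note
    )


def _signed_rank_parts(pre, post) -> tuple[np.ndarray, np.ndarray, int]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("paired samples must have equal length")
    if pre.size == 0:
        raise ValueError("paired samples must be non-empty")
    d = post - pre
    nonzero = d != 0
    n_dropped = int(np.sum(~nonzero))
    d = d[nonzero]
    ranks = sps.rankdata(np.abs(d)) if d.size else np.array([])
    return d, ranks, n_dropped


def perm_signed_rank(
    pre, post, n_perm: int = 10_000, seed: int | None = None
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test with a sign-flip permutation null.

    Zero differences are dropped (count noted).  The null swaps the
    pre/post labels independently within each pair; all 2^m sign patterns
    are enumerated when feasible within ``n_perm``.  ``z_approx`` is the
    tie-corrected normal approximation.
    """
    d, ranks, n_dropped = _signed_rank_parts(pre, post)
    m = d.size
    note = f"n_dropped={n_dropped}"
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return StatResult(
            "perm_signed_rank", 0.0, 1.0, z_approx=0.0, n_perm=n_perm, seed=seed, notes=note
        )
    w_plus = float(ranks[d > 0].sum())
    expect = ranks.sum() / 2.0
    sd = math.sqrt(np.sum(ranks**2)) / 2.0  # midrank-based variance, tie-corrected
    z = (w_plus - expect) / sd if sd > 0 else 0.0
    dev_obs = abs(w_plus - expect)
    eps = 1e-9
    contrib = ranks * np.sign(d)
    if 2**m <= n_perm:
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=m)))
        dev = np.abs(signs @ contrib) / 2.0
        p = float(np.mean(dev >= dev_obs - eps))
        note += ",exhaustive"
        n_used = 2**m
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, m))
        dev = np.abs(signs @ contrib) / 2.0
        p = (1 + int(np.sum(dev >= dev_obs - eps))) / (1 + n_perm)
        note += ",monte-carlo"
        n_used = n_perm
    return StatResult(
        "perm_signed_rank", w_plus, float(p), z_approx=float(z), n_perm=n_used, seed=seed, notes=note
    )


def kendall_tau_b(x, y) -> StatResult:
    """Kendall tau-b correlation with tie-corrected inference.

    tau-b divides concordant-minus-discordant pairs by the geometric mean
    of tie-adjusted pair counts, so heavily tied data (e.g. many exact
    zeros of occupancy) do not inflate the coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined: a sample has zero variance")
    res = sps.kendalltau(x, y, variant="b")
    return StatResult("kendall_tau_b", float(res.statistic), float(res.pvalue))


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def chi2_entry_proportions(table, correction: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 state-entry contingency table (df = 1)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    res = sps.chi2_contingency(table, correction=correction)
    return StatResult("chi2_proportions", float(res.statistic), float(res.pvalue))


def zero_vs_nonzero_ttest(scores, fractions) -> StatResult:
    """Pooled-variance two-sample t-test of scores: zero vs non-zero occupancy strata."""
    scores = np.asarray(scores, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if scores.size != fractions.size:
        raise ValueError("scores and fractions must be aligned")
    zero = scores[fractions == 0]
    nonzero = scores[fractions > 0]
    if zero.size < 2 or nonzero.size < 2:
        raise ValueError("each occupancy stratum needs at least 2 subjects")
    res = sps.ttest_ind(zero, nonzero, equal_var=True)
    out = StatResult("zero_vs_nonzero_t", float(res.statistic), float(res.pvalue))
    out.notes = f"df={zero.size + nonzero.size - 2}"
    return out


def perm_fwe_signed_rank(
    data: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "maxstat",
) -> pd.DataFrame:
    """Family of paired signed-rank tests with shared-permutation FWE control.

    ``data`` has one row per (cell, outcome, subject) with columns
    ``cell``, ``outcome``, ``subject``, ``pre``, ``post``.  Each
    permutation draws one sign per (cell, subject), applied to every
    outcome of that subject, and the single-step max-|z| (Westfall-Young
    style) adjusted p-value is computed across all (cell, outcome) tests.
    ``method="bonferroni"`` multiplies the raw permutation p instead.
    """
    required = {"cell", "outcome", "subject", "pre", "post"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    tests = list(data.groupby(["cell", "outcome"], sort=False).groups)
    if not tests:
        raise ValueError("empty test family")
    rng = np.random.default_rng(seed)
    cells = list(dict.fromkeys(data["cell"]))
    sign_streams: dict[str, np.ndarray] = {}
    subj_index: dict[str, pd.Index] = {}
    for cell in cells:
        subs = pd.Index(dict.fromkeys(data.loc[data["cell"] == cell, "subject"]))
        subj_index[cell] = subs
        sign_streams[cell] = rng.choice([-1.0, 1.0], size=(n_perm, len(subs)))
    z_obs = np.empty(len(tests))
    z_perm = np.empty((n_perm, len(tests)))
    rows = []
    for ti, (cell, outcome) in enumerate(tests):
        sub = data[(data["cell"] == cell) & (data["outcome"] == outcome)]
        sub = sub.set_index("subject").loc[subj_index[cell]]
        d = (sub["post"] - sub["pre"]).to_numpy(dtype=float)
        contrib = np.zeros_like(d)
        nz = d != 0
        if np.any(nz):
            ranks = sps.rankdata(np.abs(d[nz]))
            contrib[nz] = ranks * np.sign(d[nz])
            denom = math.sqrt(np.sum(ranks**2))
        else:
            denom = 0.0
        if denom > 0:
            z_obs[ti] = np.sum(contrib) / denom
            z_perm[:, ti] = (sign_streams[cell] * np.abs(contrib)) .sum(axis=1) / denom
        else:
            z_obs[ti] = 0.0
            z_perm[:, ti] = 0.0
        rows.append({"cell": cell, "outcome": outcome, "n_pairs": len(d), "n_nonzero": int(nz.sum())})
    eps = 1e-12
    abs_obs = np.abs(z_obs)
    p_raw = (1 + np.sum(np.abs(z_perm) >= abs_obs[None, :] - eps, axis=0)) / (1 + n_perm)
    if len(tests) == 1:
        logger.info("family of one test: FWE-adjusted p equals raw p")
        p_fwe = p_raw.copy()
    elif method == "maxstat":
        max_stat = np.abs(z_perm).max(axis=1)
        p_fwe = (1 + np.sum(max_stat[:, None] >= abs_obs[None, :] - eps, axis=0)) / (1 + n_perm)
    elif method == "bonferroni":
        p_fwe = np.minimum(p_raw * len(tests), 1.0)
    else:
        raise ValueError(f"unknown FWE method: {method}")
    out = pd.DataFrame(rows)
    out["z"] = z_obs
    out["p_raw"] = p_raw
    out["p_fwe"] = p_fwe
    out["adjustment"] = f"perm-FWE({method})"
    out["n_perm"] = n_perm
    out["seed"] = seed
    return out


@dataclass
class InferenceConfig:
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int | None = None
    fdr_scope: str = "pooled"  # "pooled" or "per_cell" for the correlation family
    fwe_method: str = "maxstat"
    conditions_baseline: tuple[str, str] = ("rest_pre", "brooding")


@dataclass
class InferenceResults:
    results: pd.DataFrame
    flagged_state: int | None
    flagged_significant: bool
    report: str
    fwe_table: pd.DataFrame | None = None


def _spawn_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_full_inference(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    config: InferenceConfig | None = None,
) -> InferenceResults:
    """Execute the full inferential layer on a tidy metrics table.

    Stages: (a) MDD-vs-HC rank-sum contrasts per state and outcome in the
    two baseline conditions, BH-FDR across the family; (b) Kendall tau-b of
    RRS-B against each outcome within every group x condition cell, BH-FDR
    (pooled by default); (c) chi-square contrasts of state-entry
    proportions; (d) zero-vs-nonzero RRS-B t-test for the state flagged in
    (b); (e) pre-vs-post signed-rank tests of the flagged state's outcomes
    per intervention subgroup, with permutation FWE control across the
    subgroup x outcome family.
    """
    config = config or InferenceConfig()
    need_metrics = {"subject_id", "condition", "state", "dwell_time", "fraction", "visited"}
    missing = need_metrics - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    need_meta = {"subject_id", "group", "arm", "rrs_b"}
    missing = need_meta - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    merged = metrics.merge(metadata, on="subject_id", how="inner", validate="many_to_one")
    k = int(metrics["state"].max())
    states = range(1, k + 1)
    records: list[dict] = []

    # (a) group contrasts -------------------------------------------------
    seeds = iter(_spawn_seeds(config.seed, 1000))
    group_rows = []
    for cond in config.conditions_baseline:
        for state in states:
            cell = merged[(merged["condition"] == cond) & (merged["state"] == state)]
            for outcome in OUTCOMES:
                xs = cell.loc[cell["group"] == "MDD", outcome].to_numpy()
                ys = cell.loc[cell["group"] == "HC", outcome].to_numpy()
                res = perm_rank_sum(xs, ys, n_perm=config.n_perm, seed=next(seeds))
                group_rows.append(
                    {
                        "test": "group_rank_sum",
                        "cell": "MDD_vs_HC",
                        "condition": cond,
                        "state": state,
                        "outcome": outcome,
                        "statistic": res.statistic,
                        "z": res.z_approx,
                        "p_raw": res.p_raw,
                        "adjustment": "BH-FDR",
                        "n_perm": res.n_perm,
                        "seed": res.seed,
                    }
                )
    p_adj, _ = fdr_bh([r["p_raw"] for r in group_rows], config.alpha)
    for r, pa in zip(group_rows, p_adj):
        r["p_adj"] = pa
    records.extend(group_rows)

    # (b) brooding-severity correlations ---------------------------------
    corr_rows = []
    for group in ("MDD", "HC"):
        for cond in config.conditions_baseline:
            cell = merged[(merged["group"] == group) & (merged["condition"] == cond)]
            for state in states:
                sub = cell[cell["state"] == state]
                for outcome in OUTCOMES:
                    row = {
                        "test": "rrs_kendall_tau_b",
                        "cell": group,
                        "condition": cond,
                        "state": state,
                        "outcome": outcome,
                        "adjustment": "BH-FDR",
                        "n_perm": None,
                        "seed": None,
                    }
                    try:
                        res = kendall_tau_b(sub[outcome].to_numpy(), sub["rrs_b"].to_numpy())
                        row.update(statistic=res.statistic, z=None, p_raw=res.p_raw)
                    except ValueError as exc:
                        row.update(statistic=np.nan, z=None, p_raw=np.nan, notes=str(exc))
                    corr_rows.append(row)
    corr_df = pd.DataFrame(corr_rows)
    corr_df["p_adj"] = np.nan
    if config.fdr_scope == "pooled":
        valid = corr_df["p_raw"].notna()
        if valid.any():
            corr_df.loc[valid, "p_adj"], _ = fdr_bh(corr_df.loc[valid, "p_raw"], config.alpha)
    else:
        for (_, _), idx in corr_df.groupby(["cell", "condition"]).groups.items():
            valid = corr_df.loc[idx, "p_raw"].notna()
            vidx = corr_df.loc[idx].index[valid]
            if len(vidx):
                corr_df.loc[vidx, "p_adj"], _ = fdr_bh(corr_df.loc[vidx, "p_raw"], config.alpha)
    records.extend(corr_df.to_dict("records"))

    # (c) entry proportions ----------------------------------------------
    for cond in config.conditions_baseline:
        for state in states:
            cell = merged[(merged["condition"] == cond) & (merged["state"] == state)]
            row = {
                "test": "entry_chi2",
                "cell": "MDD_vs_HC",
                "condition": cond,
                "state": state,
                "outcome": "entered",
                "adjustment": "none",
                "n_perm": None,
                "seed": None,
            }
            table = np.array(
                [
                    [
                        int(cell[(cell["group"] == g) & cell["visited"]].shape[0]),
                        int(cell[(cell["group"] == g) & ~cell["visited"]].shape[0]),
                    ]
                    for g in ("MDD", "HC")
                ]
            )
            try:
                res = chi2_entry_proportions(table)
                row.update(statistic=res.statistic, z=None, p_raw=res.p_raw, p_adj=None)
            except ValueError as exc:
                row.update(statistic=np.nan, z=None, p_raw=np.nan, p_adj=None, notes=str(exc))
            records.append(row)

    # (d) zero vs non-zero occupancy t-test for the flagged state --------
    mdd_brood = corr_df[
        (corr_df["cell"] == "MDD")
        & (corr_df["condition"] == "brooding")
        & corr_df["p_adj"].notna()
    ]
    flagged_state: int | None = None
    flagged_significant = False
    if len(mdd_brood):
        # Smallest adjusted p; ties (BH plateaus) resolve by raw p.
        best = mdd_brood.sort_values(["p_adj", "p_raw"]).iloc[0]
        flagged_state = int(best["state"])
        flagged_significant = bool(best["p_adj"] < config.alpha)
    if flagged_state is not None:
        cell = merged[
            (merged["group"] == "MDD")
            & (merged["condition"] == "brooding")
            & (merged["state"] == flagged_state)
        ]
        row = {
            "test": "zero_vs_nonzero_t",
            "cell": "MDD",
            "condition": "brooding",
            "state": flagged_state,
            "outcome": "rrs_b",
            "adjustment": "none",
            "n_perm": None,
            "seed": None,
        }
        try:
            res = zero_vs_nonzero_ttest(cell["rrs_b"].to_numpy(), cell["fraction"].to_numpy())
            row.update(statistic=res.statistic, z=None, p_raw=res.p_raw, p_adj=None, notes=res.notes)
        except ValueError as exc:
            row.update(statistic=np.nan, z=None, p_raw=np.nan, p_adj=None, notes=str(exc))
        records.append(row)

    # (e) pre/post signed-rank family ------------------------------------
    fwe_table = None
    if flagged_state is not None and {"rest_pre", "rest_post"} <= set(merged["condition"]):
        fam_rows = []
        state_df = merged[merged["state"] == flagged_state]
        wide = state_df.pivot_table(
            index=["subject_id", "group", "arm"],
            columns="condition",
            values=list(OUTCOMES),
        )
        for (subject, group, arm), vals in wide.iterrows():
            for outcome in OUTCOMES:
                if (outcome, "rest_pre") in vals.index and (outcome, "rest_post") in vals.index:
                    fam_rows.append(
                        {
                            "cell": f"{group}_{arm}",
                            "outcome": outcome,
                            "subject": subject,
                            "pre": vals[(outcome, "rest_pre")],
                            "post": vals[(outcome, "rest_post")],
                        }
                    )
        fam = pd.DataFrame(fam_rows).dropna()
        if len(fam):
            fwe_seed = _spawn_seeds(config.seed, 1)[0]
            fwe_table = perm_fwe_signed_rank(
                fam, n_perm=config.n_perm, seed=fwe_seed, method=config.fwe_method
            )
            for _, r in fwe_table.iterrows():
                records.append(
                    {
                        "test": "prepost_signed_rank",
                        "cell": r["cell"],
                        "condition": "rest_pre_vs_rest_post",
                        "state": flagged_state,
                        "outcome": r["outcome"],
                        "statistic": r["z"],
                        "z": r["z"],
                        "p_raw": r["p_raw"],
                        "p_adj": r["p_fwe"],
                        "adjustment": r["adjustment"],
                        "n_perm": r["n_perm"],
                        "seed": r["seed"],
                    }
                )

    results = pd.DataFrame(records)
    report = _format_report(results, flagged_state, flagged_significant, config)
    return InferenceResults(
        results=results,
        flagged_state=flagged_state,
        flagged_significant=flagged_significant,
        report=report,
        fwe_table=fwe_table,
    )


def _format_report(
    results: pd.DataFrame,
    flagged_state: int | None,
    flagged_significant: bool,
    config: InferenceConfig,
) -> str:
    lines = ["Temporal dynamics inference summary", "=" * 36]
    lines.append(f"alpha = {config.alpha}, permutations = {config.n_perm}")
    if flagged_state is None:
        lines.append("No state could be evaluated for a brooding association.")
    else:
        stateword = "FDR-significant" if flagged_significant else "not FDR-significant"
        sub = results[
            (results["test"] == "rrs_kendall_tau_b")
            & (results["cell"] == "MDD")
            & (results["condition"] == "brooding")
            & (results["state"] == flagged_state)
        ]
        taus = ", ".join(
            f"{r['outcome']}: tau={r['statistic']:+.3f} (p_adj={r['p_adj']:.4f})"
            for _, r in sub.iterrows()
            if np.isfinite(r["p_raw"])
        )
        lines.append(
            f"Flagged brooding-related state: {flagged_state} ({stateword} in MDD/brooding): {taus}"
        )
    pre_post = results[results["test"] == "prepost_signed_rank"]
    for _, r in pre_post.iterrows():
        sig = "*" if r["p_adj"] < config.alpha else " "
        lines.append(
            f"  pre->post {r['cell']:>10s} {r['outcome']:<10s} z={r['z']:+.2f} "
            f"FWE-p={r['p_adj']:.4f}{sig}"
        )
    return "\n".join(lines)
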