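"""Two-group differential tests and the drug-responsive-enhancer caller.

The primary test is an empirical-Bayes moderated t-statistic: per-feature
residual variances s^2 (pooled, d = n_t + n_c - 2 df) are shrunk toward a
prior variance s0^2 with prior df d0, both estimated from the spread of
log s^2 across features by moment matching.  The moderated statistic

    t = log_fc / (s_tilde * sqrt(1/n_t + 1/n_c)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

is referred to a t distribution with d + d0 degrees of freedom.  With
d0 = 0 it reduces exactly to the ordinary pooled-variance two-sample t-test.

A Wilcoxon rank-sum test (exact enumeration for small groups, tie-corrected
normal approximation otherwise) serves as a distribution-free cross-check.

Drug-responsive enhancers (diffEnhancers) are features with |log2 fold
change| > 0.5 and p < 0.001 on log2(predicted openness + 1); drug-perturbed
genes use |logFC| > 0.8 and p < 0.05 on expression.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .openness_model import ModelCollection, predict_all

logger = logging.getLogger(__name__)

DIFF_LOGFC_THRESHOLD = 0.5
DIFF_P_THRESHOLD = 0.001
PERTURBED_LOGFC_THRESHOLD = 0.8
PERTURBED_P_THRESHOLD = 0.05


@dataclass
class DiffResult:
    """One feature's treated-vs-control comparison."""

    feature_id: str
    log_fc: float
    statistic: float
    p_value: float
    method: str  # "moderated_t" or "wilcoxon"
    n_treated: int
    n_control: int


@dataclass
class ModeratedTState:
    """Empirical-Bayes hyperparameters shared across features."""

    d0: float  # prior df; 0 disables shrinkage, inf shrinks fully to s0_sq
    s0_sq: float
    residual_df: float


def _split_groups(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    bad = set(lab) - {"control", "treated"}
    if bad:
        raise ValueError(f"condition labels must be control|treated, got {sorted(bad)}")
    treated = np.where(lab == "treated")[0]
    control = np.where(lab == "control")[0]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(treated)} treated / {len(control)} control"
        )
    return treated, control


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log scale)."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s_sq: np.ndarray, residual_df: float) -> ModeratedTState:
    """Fit (d0, s0^2) by matching the moments of log s^2 across features.

    Under the hierarchical model s^2 follows a scaled F distribution, so the
    mean and variance of log s^2 identify the prior df and prior variance
    through digamma/trigamma relations.  Fewer than 10 positive variances,
    or an observed spread no larger than the sampling noise, disable
    shrinkage (d0 = 0 and d0 = inf respectively).
    """
    pos = s_sq[s_sq > 0]
    if len(pos) < 10:
        warnings.warn("too few features to estimate variance prior; shrinkage disabled", stacklevel=2)
        return ModeratedTState(d0=0.0, s0_sq=float(np.median(s_sq)) if len(s_sq) else 1.0,
                               residual_df=residual_df)
    z = np.log(pos)
    if np.ptp(z) == 0.0:
        # identical variances carry no information about a prior; with no
        # dispersion to shrink, the moderated t must reduce to the ordinary t
        return ModeratedTState(d0=0.0, s0_sq=float(pos[0]), residual_df=residual_df)
    half_d = residual_df / 2.0
    e_correction = special.digamma(half_d) - np.log(half_d)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, half_d))
    if evar <= 0:
        # observed spread of variances explained by sampling alone
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z) - e_correction))
    else:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_sq = float(
            np.exp(np.mean(z) - e_correction + special.digamma(half_d0) - np.log(half_d0))
        )
    return ModeratedTState(d0=d0, s0_sq=s0_sq, residual_df=residual_df)


def moderated_t_test(
    matrix: pd.DataFrame,
    condition_labels: Sequence[str],
    d0_override: Optional[float] = None,
) -> list[DiffResult]:
    """Empirical-Bayes moderated t-test per feature (rows) of a log-scale matrix.

    ``condition_labels`` aligns with the matrix columns.  ``d0_override=0``
    disables shrinkage, reproducing the ordinary pooled t-test exactly.
    """
    treated, control = _split_groups(condition_labels)
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite values")
    n_t, n_c = len(treated), len(control)
    d = n_t + n_c - 2

    xt, xc = vals[:, treated], vals[:, control]
    log_fc = xt.mean(axis=1) - xc.mean(axis=1)
    s_sq = ((xt.var(axis=1, ddof=1) * (n_t - 1)) + (xc.var(axis=1, ddof=1) * (n_c - 1))) / d

    if d0_override is not None:
        state = ModeratedTState(d0=float(d0_override), s0_sq=float(np.median(s_sq[s_sq > 0]))
                                if np.any(s_sq > 0) else 1.0, residual_df=float(d))
    else:
        state = estimate_moderation(s_sq, float(d))

    if np.isinf(state.d0):
        s_tilde_sq = np.full_like(s_sq, state.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (state.d0 * state.s0_sq + d * s_sq) / (state.d0 + d)
        df_total = d + state.d0

    se = np.sqrt(s_tilde_sq * (1.0 / n_t + 1.0 / n_c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0),
                          np.where(log_fc == 0, 0.0, np.inf * np.sign(log_fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return [
        DiffResult(
            feature_id=str(fid), log_fc=float(lfc), statistic=float(t),
            p_value=float(pv), method="moderated_t", n_treated=n_t, n_control=n_c,
        )
        for fid, lfc, t, pv in zip(matrix.index, log_fc, t_stat, p)
    ]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _ranksum_exact_p(pooled: np.ndarray, n_treated: int, observed_w: float) -> float:
    """Two-sided p by full enumeration of all treated-label assignments."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n_treated * (n + 1) / 2.0
    obs_dev = abs(observed_w - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_treated):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_test(matrix: pd.DataFrame, condition_labels: Sequence[str]) -> list[DiffResult]:
    """Two-sided Wilcoxon rank-sum test per feature, midranks for ties.

    Groups of at most 8 each are tested by exact enumeration of the
    C(n_t + n_c, n_t) labelings; larger groups use the tie-corrected normal
    approximation with continuity correction.  The reported log_fc is the
    difference of group means (same convention as the moderated t).
    """
    treated, control = _split_groups(condition_labels)
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite values")
    n_t, n_c = len(treated), len(control)
    n = n_t + n_c
    exact = n_t <= 8 and n_c <= 8

    out: list[DiffResult] = []
    for fid, row in zip(matrix.index, vals):
        xt, xc = row[treated], row[control]
        pooled = np.concatenate([xt, xc])
        ranks = stats.rankdata(pooled)
        w = float(ranks[:n_t].sum())
        mu = n_t * (n + 1) / 2.0
        if np.ptp(pooled) == 0:
            p = 1.0  # every value tied across both groups
        elif exact:
            p = _ranksum_exact_p(pooled, n_t, w)
        else:
            _, tie_counts = np.unique(pooled, return_counts=True)
            tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
            var_w = n_t * n_c / 12.0 * ((n + 1) - tie_term)
            z = (abs(w - mu) - 0.5) / np.sqrt(var_w)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
        out.append(
            DiffResult(
                feature_id=str(fid), log_fc=float(xt.mean() - xc.mean()),
                statistic=w - mu, p_value=max(p, np.finfo(float).tiny),
                method="wilcoxon", n_treated=n_t, n_control=n_c,
            )
        )
    return out


# ---------------------------------------------------------------------------
# callers


def adjust_bh(results: list[DiffResult]) -> list[DiffResult]:
    """Benjamini-Hochberg adjusted copies of the results."""
    p = np.array([r.p_value for r in results])
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty_like(p)
    adj[order] = np.clip(ranked, None, 1.0)
    return [
        DiffResult(r.feature_id, r.log_fc, r.statistic, float(a), r.method,
                   r.n_treated, r.n_control)
        for r, a in zip(results, adj)
    ]


def call_diff_enhancers(
    results: list[DiffResult],
    logfc_threshold: float = DIFF_LOGFC_THRESHOLD,
    p_threshold: float = DIFF_P_THRESHOLD,
) -> set[str]:
    """Enhancers with |logFC| strictly above 0.5 and p strictly below 0.001."""
    return {
        r.feature_id
        for r in results
        if abs(r.log_fc) > logfc_threshold and r.p_value < p_threshold
    }


def call_perturbed_genes(
    results: list[DiffResult],
    p_threshold: float = PERTURBED_P_THRESHOLD,
    abs_logfc_threshold: float = PERTURBED_LOGFC_THRESHOLD,
) -> set[str]:
    """Genes with p strictly below 0.05 and |logFC| strictly above 0.8."""
    return {
        r.feature_id
        for r in results
        if abs(r.log_fc) > abs_logfc_threshold and r.p_value < p_threshold
    }


def results_to_frame(results: list[DiffResult], called: Optional[set[str]] = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "log_fc": r.log_fc,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "n_treated": r.n_treated,
                "n_control": r.n_control,
            }
            for r in results
        ]
    )
    if called is not None and len(df):
        df["called"] = df["feature_id"].isin(called)
    return df


# ---------------------------------------------------------------------------
# pipeline


def diff_pipeline(
    models: ModelCollection,
    expr_control: pd.DataFrame,
    expr_treated: pd.DataFrame,
    method: str = "moderated_t",
    logfc_threshold: float = DIFF_LOGFC_THRESHOLD,
    p_threshold: float = DIFF_P_THRESHOLD,
    fc_scale: str = "raw",
) -> tuple[set[str], pd.DataFrame, dict]:
    """Predict openness per condition and call drug-responsive enhancers.

    By default the test runs on the predicted openness values directly, so
    the reported "log_fc" is the mean difference on the openness scale — the
    scale the 0.5 calling threshold refers to; ``fc_scale="log2p1"``
    transforms to log2(x+1) first.  A condition with fewer than
    two samples skips the comparison with a recorded reason, mirroring drugs
    that lack sufficient instances.  Returns (diffEnhancer ids, full result
    table, report dict).
    """
    report: dict = {
        "n_control": expr_control.shape[1],
        "n_treated": expr_treated.shape[1],
        "skip_reason": None,
    }
    if expr_control.shape[1] < 2 or expr_treated.shape[1] < 2:
        report["skip_reason"] = (
            f"insufficient instances ({expr_control.shape[1]} control, "
            f"{expr_treated.shape[1]} treated; need >=2 each)"
        )
        logger.warning("differential analysis skipped: %s", report["skip_reason"])
        return set(), pd.DataFrame(), report

    pred_c = predict_all(models, expr_control)
    pred_t = predict_all(models, expr_treated)
    combined = pd.concat([pred_c, pred_t], axis=1)
    # fraction of samples with at least one active (predicted openness > 0) enhancer
    report["frac_samples_active"] = float((combined > 0).any(axis=0).mean())

    if fc_scale == "log2p1":
        combined = np.log2(combined + 1.0)
    elif fc_scale != "raw":
        raise ValueError(f"fc_scale must be raw|log2p1, got {fc_scale!r}")
    labels = ["control"] * pred_c.shape[1] + ["treated"] * pred_t.shape[1]

    if method == "moderated_t":
        results = moderated_t_test(combined, labels)
    elif method == "wilcoxon":
        results = wilcoxon_test(combined, labels)
    else:
        raise ValueError(f"method must be moderated_t|wilcoxon, got {method!r}")

    called = call_diff_enhancers(results, logfc_threshold, p_threshold)
    report["n_diff_enhancers"] = len(called)
    return called, results_to_frame(results, called), report
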