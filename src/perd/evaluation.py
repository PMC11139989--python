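"""Evaluation statistics for openness prediction and the predictability filter.

Three statistics compare a predicted openness matrix ``Ohat`` with the
measured matrix ``O`` (both enhancers x samples):

* cross-cell correlation  tau_C: per-enhancer Pearson r across samples,
* cross-enhancer correlation  tau_E: per-sample Pearson r across enhancers,
* squared prediction error  tau = sum (O - Ohat)^2 / sum (O - Obar)^2,
  normalized by total variance around the grand mean Obar, so tau = 0 for a
  perfect prediction and tau = 1 for predicting the grand mean everywhere.

Three DH-signal properties characterize which enhancers are predictable:
spread (samples with DH > 0), variation (sd of DH across samples) and
specificity (cell types with DH > 2).  The predictability filter retains
enhancers with spread > 100, variation above the cohort lower quartile and
specificity > 10 (all strict by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .openness_model import ModelCollection, fit_all, predict_all

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """tau_C / tau_E vectors (NaN where undefined) and the scalar tau."""

    cross_cell_pcc: pd.Series  # per enhancer
    cross_enhancer_pcc: pd.Series  # per sample
    squared_error: float

    @property
    def n_defined_cc(self) -> int:
        return int(self.cross_cell_pcc.notna().sum())

    @property
    def n_defined_ce(self) -> int:
        return int(self.cross_enhancer_pcc.notna().sum())

    def summary(self) -> dict:
        return {
            "tau": self.squared_error,
            "median_cross_cell_pcc": float(self.cross_cell_pcc.median()),
            "median_cross_enhancer_pcc": float(self.cross_enhancer_pcc.median()),
            "n_defined_cross_cell": self.n_defined_cc,
            "n_defined_cross_enhancer": self.n_defined_ce,
        }


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of matching rows; NaN where either row is constant."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac**2).sum(axis=1))
    nb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac * bc).sum(axis=1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def _check_aligned(O: pd.DataFrame, Ohat: pd.DataFrame) -> None:
    if O.shape != Ohat.shape or list(O.index) != list(Ohat.index) or list(O.columns) != list(Ohat.columns):
        raise ValueError("O and Ohat must share shape, row order, and column order")


def cross_cell_correlation(O: pd.DataFrame, Ohat: pd.DataFrame) -> pd.Series:
    """Per-enhancer Pearson correlation of measured vs predicted openness across samples."""
    _check_aligned(O, Ohat)
    r = _rowwise_pearson(O.to_numpy(dtype=float), Ohat.to_numpy(dtype=float))
    return pd.Series(r, index=O.index, name="cross_cell_pcc")


def cross_enhancer_correlation(O: pd.DataFrame, Ohat: pd.DataFrame) -> pd.Series:
    """Per-sample Pearson correlation of measured vs predicted openness across enhancers."""
    _check_aligned(O, Ohat)
    r = _rowwise_pearson(O.to_numpy(dtype=float).T, Ohat.to_numpy(dtype=float).T)
    return pd.Series(r, index=O.columns, name="cross_enhancer_pcc")


def squared_prediction_error(O: pd.DataFrame, Ohat: pd.DataFrame) -> float:
    """Total squared error normalized by total variance around the grand mean."""
    _check_aligned(O, Ohat)
    o = O.to_numpy(dtype=float)
    ohat = Ohat.to_numpy(dtype=float)
    denom = float(((o - o.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("measured openness is constant; tau undefined")
    return float(((o - ohat) ** 2).sum() / denom)


def evaluate(O: pd.DataFrame, Ohat: pd.DataFrame) -> EvaluationResult:
    return EvaluationResult(
        cross_cell_pcc=cross_cell_correlation(O, Ohat),
        cross_enhancer_pcc=cross_enhancer_correlation(O, Ohat),
        squared_error=squared_prediction_error(O, Ohat),
    )


# ---------------------------------------------------------------------------
# DH properties and the predictability filter


@dataclass
class DHProperties:
    spread: int  # samples with DH > 0
    variation: float  # sd of DH across samples (ddof=1)
    specificity: int  # cell types with at least one sample with DH > 2


def dh_properties(
    O: pd.DataFrame, cell_type_of_sample: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-enhancer spread / variation / specificity of the DH signal.

    When no sample -> cell-type mapping is given each sample counts as its
    own type (with a warning), so specificity reduces to the count of
    samples with DH > 2.
    """
    if cell_type_of_sample is None:
        warnings.warn("no cell-type labels; treating each sample as its own cell type", stacklevel=2)
        cell_type_of_sample = {s: s for s in O.columns}
    unmapped = [s for s in O.columns if s not in cell_type_of_sample]
    if unmapped:
        raise ValueError(f"samples without a cell-type label: {unmapped[:5]}")

    vals = O.to_numpy(dtype=float)
    spread = (vals > 0).sum(axis=1)
    variation = vals.std(axis=1, ddof=1) if vals.shape[1] > 1 else np.zeros(vals.shape[0])
    types = pd.Series([cell_type_of_sample[s] for s in O.columns], index=O.columns)
    active = pd.DataFrame(vals > 2, index=O.index, columns=O.columns)
    specificity = active.T.groupby(types).any().T.sum(axis=1)
    return pd.DataFrame(
        {
            "spread": spread.astype(int),
            "variation": variation,
            "specificity": specificity.astype(int),
        },
        index=O.index,
    )


def filter_predictable(
    props: pd.DataFrame,
    min_spread: int = 100,
    variation_quantile: float = 0.25,
    min_specificity: int = 10,
    strict: bool = True,
) -> list[str]:
    """Retain enhancers likely to be well predicted.

    Defaults: spread strictly above 100 active samples, variation strictly
    above the cohort lower quartile, specificity strictly above 10 active
    cell types.  The variation quantile is computed on the full input cohort
    before any other filter.
    """
    if props.empty:
        return []
    var_cut = float(props["variation"].quantile(variation_quantile))
    if strict:
        mask = (
            (props["spread"] > min_spread)
            & (props["variation"] > var_cut)
            & (props["specificity"] > min_specificity)
        )
    else:
        mask = (
            (props["spread"] >= min_spread)
            & (props["variation"] >= var_cut)
            & (props["specificity"] >= min_specificity)
        )
    kept = props.index[mask].tolist()
    logger.info(
        "predictability filter: kept %d of %d enhancers (variation cut %.4g)",
        len(kept), len(props), var_cut,
    )
    return kept


def stratified_performance(
    cross_cell_pcc: pd.Series, props: pd.DataFrame, n_bins: int = 4
) -> dict:
    """Median cross-cell PCC per property stratum plus Spearman trend tests.

    For each DH property the defined PCCs are binned into ``n_bins``
    quantile strata; the Spearman correlation of property vs PCC (with its
    rank-based p-value) summarizes the trend.  Degenerate strata (a constant
    property) are flagged as undefined rather than dropped silently.
    """
    joined = props.join(cross_cell_pcc.rename("pcc"), how="inner").dropna(subset=["pcc"])
    out: dict = {"n_enhancers": int(len(joined)), "properties": {}}
    for prop in ("spread", "variation", "specificity"):
        col = joined[prop]
        entry: dict = {}
        if col.nunique() < 2:
            entry["spearman_rho"] = None
            entry["spearman_p"] = None
            entry["note"] = "constant property; correlation undefined"
            entry["bins"] = [{"median_pcc": float(joined["pcc"].median()), "n": int(len(joined))}]
        else:
            rho, p = stats.spearmanr(col, joined["pcc"])
            entry["spearman_rho"] = float(rho)
            entry["spearman_p"] = float(p)
            ranks = col.rank(pct=True)
            bins = np.minimum((ranks * n_bins).astype(int), n_bins - 1)
            entry["bins"] = [
                {
                    "bin": int(b),
                    "median_pcc": float(joined["pcc"][bins == b].median()),
                    "n": int((bins == b).sum()),
                }
                for b in sorted(bins.unique())
            ]
        out["properties"][prop] = entry
    return out


# ---------------------------------------------------------------------------
# leave-one-out driver


def leave_one_out_predictions(
    network,
    expr: pd.DataFrame,
    openness: pd.DataFrame,
    method: str = "elastic_net",
    lambda_: Optional[float] = 0.1,
    gamma_T: float = 1.0,
    gamma_G: float = 1.0,
    feature_mode: str = "TFandTG",
    seed: int = 0,
    preprocess: str = "log_zscore",
) -> pd.DataFrame:
    """Pooled out-of-sample predictions: hold out each sample, refit, predict it.

    Returns an enhancers x samples matrix aligned with ``openness`` (rows
    limited to fittable enhancers).
    """
    shared = [s for s in expr.columns if s in set(openness.columns)]
    preds: dict[str, pd.Series] = {}
    for held in shared:
        train = [s for s in shared if s != held]
        coll = fit_all(
            network, expr[train], openness[train], method=method, lambda_=lambda_,
            gamma_T=gamma_T, gamma_G=gamma_G, feature_mode=feature_mode,
            seed=seed, preprocess=preprocess,
        )
        preds[held] = predict_all(coll, expr[[held]]).iloc[:, 0]
    return pd.DataFrame(preds)


def cross_validated_predictions(
    network,
    expr: pd.DataFrame,
    openness: pd.DataFrame,
    n_folds: int = 5,
    method: str = "elastic_net",
    lambda_: Optional[float] = 0.1,
    gamma_T: float = 1.0,
    gamma_G: float = 1.0,
    feature_mode: str = "TFandTG",
    seed: int = 0,
    preprocess: str = "log_zscore",
) -> pd.DataFrame:
    """K-fold analogue of :func:`leave_one_out_predictions` for larger cohorts.

    Samples are assigned to folds round-robin after a seeded shuffle; each
    fold is predicted by models trained on the remaining folds.
    """
    shared = [s for s in expr.columns if s in set(openness.columns)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(shared))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for k, idx in enumerate(order):
        folds[k % n_folds].append(shared[idx])

    preds: dict[str, pd.Series] = {}
    for fold in folds:
        train = [s for s in shared if s not in set(fold)]
        coll = fit_all(
            network, expr[train], openness[train], method=method, lambda_=lambda_,
            gamma_T=gamma_T, gamma_G=gamma_G, feature_mode=feature_mode,
            seed=seed, preprocess=preprocess,
        )
        block = predict_all(coll, expr[fold])
        for s in fold:
            preds[s] = block[s]
    return pd.DataFrame({s: preds[s] for s in shared})


def write_report(
    cross_cell_pcc: pd.Series,
    props: pd.DataFrame,
    retained: Sequence[str],
    path,
) -> None:
    """Per-enhancer evaluation TSV: PCC, DH properties, retained flag."""
    retained_set = set(retained)
    report = props.copy()
    report.insert(0, "cross_cell_pcc", cross_cell_pcc)
    report["retained"] = [eid in retained_set for eid in report.index]
    report.to_csv(path, sep="\t", index_label="enhancer_id")
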