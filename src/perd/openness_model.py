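"""Per-enhancer regression of chromatin openness on TF and target-gene expression.

For each enhancer the model predicts its openness O (maximum DNase
hypersensitivity over the enhancer's genome bins) across samples from the
expression of the enhancer's binding TFs (E_T) and associated target genes
(E_G):

    min_{a,b}  || O - a0 - gamma_T * sum_p a_p TF_p - gamma_G * sum_q b_q TG_q ||^2
               + lambda * (||a||_2^2 + ||a||_1 + ||b||_2^2 + ||b||_1)

i.e. an elastic net whose L1 and L2 penalties share a single weight lambda.
The same feature -> openness mapping can instead be fitted by a random
forest or an RBF support-vector regressor, each with its own implicit
regularization.  One independent model is fitted per enhancer; there is no
parameter sharing across enhancers.

gamma_T and gamma_G are fixed feature-group weights applied as column
multipliers after preprocessing (both default to 1, making the two groups
exchangeable in the penalty).  Setting ``feature_mode="TGonly"`` drops the
TF columns, the target-genes-only baseline.
"""

from __future__ import annotations

import json
import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression
from sklearn.svm import SVR

from .networks import EnhancerRecord, RegulatoryNetwork

logger = logging.getLogger(__name__)

METHODS = ("elastic_net", "random_forest", "svm")
FEATURE_MODES = ("TFandTG", "TGonly")
PREPROCESS_MODES = ("none", "log", "log_zscore")

# Matrices with entries above this are taken to be on a raw (non-log) scale
# and get log2(x+1)-transformed before standardization.
_LOG_DETECT_THRESHOLD = 50.0


def compute_openness(dh_bins: Sequence[float]) -> float:
    """Openness of an enhancer: the maximum DH signal over its genome bins."""
    bins = np.asarray(dh_bins, dtype=float)
    if bins.size == 0:
        raise ValueError("openness requires at least one DH bin value")
    if np.any(bins < 0):
        raise ValueError("DH bin values must be >= 0")
    return float(bins.max())


@dataclass
class Preprocessing:
    """Per-feature transform state learned on training data and reused at prediction."""

    mode: str
    log_applied: bool
    centers: np.ndarray  # per feature, after optional log
    scales: np.ndarray  # per feature; 1.0 where the training column was constant

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.log_applied:
            x = np.log2(x + 1.0)
        if self.mode == "log_zscore":
            x = (x - self.centers) / self.scales
        return x


@dataclass
class EnhancerModel:
    """A fitted openness predictor for one enhancer."""

    enhancer_id: str
    method: str
    tf_features: list[str]
    tg_features: list[str]
    gamma_T: float
    gamma_G: float
    lambda_: Optional[float]
    preprocessing: Preprocessing
    feature_mode: str
    coefficients: Optional[np.ndarray] = None  # elastic_net only, design order
    intercept: float = 0.0
    predictor: object = None  # opaque backend for random_forest / svm
    degenerate: bool = False  # constant training target
    train_target_range: tuple[float, float] = (0.0, 0.0)

    @property
    def feature_names(self) -> list[str]:
        return list(self.tf_features) + list(self.tg_features)


@dataclass
class ModelCollection:
    """All per-enhancer models from one training run plus its skip report."""

    models: dict[str, EnhancerModel]
    training_samples: list[str]
    config: dict
    skip_report: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# feature assembly


def fit_preprocessing(values: np.ndarray, mode: str) -> Preprocessing:
    """Learn the transform for a samples x features block of raw expression."""
    if mode not in PREPROCESS_MODES:
        raise ValueError(f"preprocessing mode must be one of {PREPROCESS_MODES}")
    x = np.asarray(values, dtype=float)
    log_applied = mode in ("log", "log_zscore") and bool(np.nanmax(x, initial=0.0) > _LOG_DETECT_THRESHOLD)
    if log_applied:
        x = np.log2(x + 1.0)
    centers = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    return Preprocessing(mode=mode, log_applied=log_applied, centers=centers, scales=scales)


def assemble_features(
    enhancer: EnhancerRecord,
    expr: pd.DataFrame,
    gamma_T: float = 1.0,
    gamma_G: float = 1.0,
    feature_mode: str = "TFandTG",
    preprocess: str = "log_zscore",
) -> tuple[pd.DataFrame, list[str], list[str], Preprocessing]:
    """Build the samples x features design matrix for one enhancer.

    Columns are ordered TFs (scaled by gamma_T) then TGs (scaled by gamma_G).
    Feature genes absent from the expression matrix are dropped with a
    warning; fewer than two usable features raises ``ValueError`` and the
    caller records the enhancer as unfittable.  Returns the design, the
    usable TF and TG lists, and the fitted preprocessing state.
    """
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    tfs = sorted(enhancer.binding_tfs) if feature_mode == "TFandTG" else []
    tgs = sorted(enhancer.target_genes)

    avail = set(expr.index)
    missing = [f for f in tfs + tgs if f not in avail]
    if missing:
        warnings.warn(
            f"enhancer {enhancer.enhancer_id}: {len(missing)} feature(s) absent "
            f"from expression matrix: {missing[:5]}",
            stacklevel=2,
        )
    tfs = [t for t in tfs if t in avail]
    tgs = [g for g in tgs if g in avail]
    if len(tfs) + len(tgs) < 2:
        raise ValueError(
            f"enhancer {enhancer.enhancer_id}: fewer than 2 usable features"
        )

    raw = expr.loc[tfs + tgs].T.to_numpy(dtype=float)  # samples x features
    if np.isnan(raw).any():
        raise ValueError(
            f"enhancer {enhancer.enhancer_id}: expression contains missing values"
        )
    prep = fit_preprocessing(raw, preprocess)
    x = prep.apply(raw)
    gammas = np.concatenate([np.full(len(tfs), gamma_T), np.full(len(tgs), gamma_G)])
    design = pd.DataFrame(x * gammas, index=expr.columns, columns=tfs + tgs)
    return design, tfs, tgs, prep


def _elastic_net_params(lambda_: float, n_samples: int) -> tuple[float, float]:
    """Map the single penalty weight lambda onto scikit-learn's (alpha, l1_ratio).

    scikit-learn minimizes  (1/2n)||y-Xw||^2 + alpha*r*||w||_1
    + (alpha*(1-r)/2)*||w||_2^2.  Requiring both penalty terms to carry the
    same weight lambda relative to the unscaled squared error gives
    r = 1/3 and alpha = 3*lambda/(2n).
    """
    return 3.0 * lambda_ / (2.0 * n_samples), 1.0 / 3.0


def fit_enhancer_model(
    design: pd.DataFrame,
    openness_row: np.ndarray | pd.Series,
    method: str = "elastic_net",
    lambda_: Optional[float] = None,
    seed: int = 0,
    *,
    enhancer_id: str = "",
    tf_features: Optional[list[str]] = None,
    tg_features: Optional[list[str]] = None,
    gamma_T: float = 1.0,
    gamma_G: float = 1.0,
    preprocessing: Optional[Preprocessing] = None,
    feature_mode: str = "TFandTG",
) -> EnhancerModel:
    """Fit one enhancer's openness model on an assembled design matrix.

    ``lambda_=None`` selects the elastic-net penalty per enhancer by internal
    5-fold cross-validation; a float fixes it.  A constant training target
    yields a degenerate intercept-only model that predicts the constant.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    y = np.asarray(openness_row, dtype=float)
    X = design.to_numpy(dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design rows and openness samples do not align")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data; impute or drop upstream")

    tf_features = tf_features if tf_features is not None else []
    tg_features = (
        tg_features if tg_features is not None else [c for c in design.columns if c not in tf_features]
    )
    if preprocessing is None:
        preprocessing = Preprocessing(
            mode="none", log_applied=False,
            centers=np.zeros(X.shape[1]), scales=np.ones(X.shape[1]),
        )
    common = dict(
        enhancer_id=enhancer_id,
        method=method,
        tf_features=list(tf_features),
        tg_features=list(tg_features),
        gamma_T=gamma_T,
        gamma_G=gamma_G,
        preprocessing=preprocessing,
        feature_mode=feature_mode,
        train_target_range=(float(y.min()), float(y.max())),
    )

    if np.ptp(y) == 0.0:
        logger.debug("enhancer %s: constant openness, intercept-only model", enhancer_id)
        return EnhancerModel(
            lambda_=lambda_, coefficients=np.zeros(X.shape[1]),
            intercept=float(y[0]), degenerate=True, **common,
        )

    if method == "elastic_net":
        n = X.shape[0]
        if lambda_ is None:
            cv = ElasticNetCV(l1_ratio=1.0 / 3.0, cv=min(5, n), random_state=seed, n_alphas=50)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv.fit(X, y)
            lambda_ = float(cv.alpha_ * 2.0 * n / 3.0)
        if lambda_ == 0.0:
            ols = LinearRegression().fit(X, y)
            coefs, intercept = ols.coef_, float(ols.intercept_)
        else:
            alpha, l1_ratio = _elastic_net_params(lambda_, n)
            en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                en.fit(X, y)
            coefs, intercept = en.coef_, float(en.intercept_)
        return EnhancerModel(lambda_=lambda_, coefficients=coefs, intercept=intercept, **common)

    if method == "random_forest":
        rf = RandomForestRegressor(n_estimators=100, max_features="sqrt", random_state=seed)
        rf.fit(X, y)
        return EnhancerModel(lambda_=lambda_, predictor=rf, **common)

    svr = SVR(kernel="rbf")
    svr.fit(X, y)
    return EnhancerModel(lambda_=lambda_, predictor=svr, **common)


def predict_openness(
    model: EnhancerModel, expr: pd.DataFrame, clip_negative: bool = True
) -> pd.Series:
    """Predict per-sample openness from an expression matrix.

    Training preprocessing (log transform, centering/scaling) and gamma
    weights are re-applied; negative linear-model outputs are clipped to 0
    because openness is a nonnegative DH-derived quantity.
    """
    features = model.feature_names
    missing = [f for f in features if f not in expr.index]
    if missing:
        raise KeyError(f"expression matrix lacks required feature(s): {missing}")
    raw = expr.loc[features].T.to_numpy(dtype=float)
    if np.isnan(raw).any():
        raise ValueError("expression contains missing values")
    x = model.preprocessing.apply(raw)
    gammas = np.concatenate(
        [np.full(len(model.tf_features), model.gamma_T), np.full(len(model.tg_features), model.gamma_G)]
    )
    X = x * gammas

    if model.degenerate:
        pred = np.full(X.shape[0], model.intercept)
    elif model.method == "elastic_net":
        pred = X @ model.coefficients + model.intercept
    else:
        pred = model.predictor.predict(X)
    if clip_negative:
        pred = np.clip(pred, 0.0, None)
    return pd.Series(pred, index=expr.columns, name=model.enhancer_id)


def fit_all(
    network: RegulatoryNetwork,
    expr: pd.DataFrame,
    openness: pd.DataFrame,
    method: str = "elastic_net",
    lambda_: Optional[float] = None,
    gamma_T: float = 1.0,
    gamma_G: float = 1.0,
    feature_mode: str = "TFandTG",
    seed: int = 0,
    preprocess: str = "log_zscore",
) -> ModelCollection:
    """Fit one model per fittable enhancer in the network.

    ``expr`` (genes x samples) and ``openness`` (enhancers x samples) must
    share sample columns; samples are intersected in expression order.
    Unfittable enhancers (too few usable features, no openness row) land in
    the skip report instead of raising.
    """
    shared = [s for s in expr.columns if s in set(openness.columns)]
    if not shared:
        raise ValueError("expression and openness matrices share no samples")
    expr = expr[shared]
    openness = openness[shared]

    models: dict[str, EnhancerModel] = {}
    skips: list[tuple[str, str]] = []
    for enh in network.enhancers:
        if enh.enhancer_id not in openness.index:
            skips.append((enh.enhancer_id, "no openness row"))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design, tfs, tgs, prep = assemble_features(
                    enh, expr, gamma_T=gamma_T, gamma_G=gamma_G,
                    feature_mode=feature_mode, preprocess=preprocess,
                )
        except ValueError as exc:
            skips.append((enh.enhancer_id, str(exc)))
            continue
        model = fit_enhancer_model(
            design,
            openness.loc[enh.enhancer_id].to_numpy(dtype=float),
            method=method,
            lambda_=lambda_,
            seed=seed,
            enhancer_id=enh.enhancer_id,
            tf_features=tfs,
            tg_features=tgs,
            gamma_T=gamma_T,
            gamma_G=gamma_G,
            preprocessing=prep,
            feature_mode=feature_mode,
        )
        models[enh.enhancer_id] = model

    config = {
        "method": method,
        "lambda": lambda_,
        "gamma_T": gamma_T,
        "gamma_G": gamma_G,
        "feature_mode": feature_mode,
        "seed": seed,
        "preprocess": preprocess,
    }
    return ModelCollection(models=models, training_samples=shared, config=config, skip_report=skips)


def predict_all(
    collection: ModelCollection, expr: pd.DataFrame, clip_negative: bool = True
) -> pd.DataFrame:
    """Predicted openness (enhancers x samples) from every model in a collection."""
    rows = {
        eid: predict_openness(m, expr, clip_negative=clip_negative)
        for eid, m in collection.models.items()
    }
    return pd.DataFrame(rows).T.reindex(list(collection.models))


# ---------------------------------------------------------------------------
# serialization: JSON manifest + coefficient TSV + pickled RF/SVM predictors


def save_collection(collection: ModelCollection, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": collection.config,
        "training_samples": collection.training_samples,
        "skip_report": [list(s) for s in collection.skip_report],
        "models": {},
    }
    coef_rows = []
    predictors: dict[str, object] = {}
    for eid, m in collection.models.items():
        manifest["models"][eid] = {
            "method": m.method,
            "tf_features": m.tf_features,
            "tg_features": m.tg_features,
            "gamma_T": m.gamma_T,
            "gamma_G": m.gamma_G,
            "lambda": m.lambda_,
            "intercept": m.intercept,
            "degenerate": m.degenerate,
            "feature_mode": m.feature_mode,
            "train_target_range": list(m.train_target_range),
            "preprocessing": {
                "mode": m.preprocessing.mode,
                "log_applied": m.preprocessing.log_applied,
                "centers": m.preprocessing.centers.tolist(),
                "scales": m.preprocessing.scales.tolist(),
            },
        }
        if m.coefficients is not None:
            for name, coef in zip(m.feature_names, m.coefficients):
                role = "TF" if name in m.tf_features else "TG"
                coef_rows.append(
                    {"enhancer_id": eid, "feature": name, "role": role, "coefficient": coef}
                )
        if m.predictor is not None:
            predictors[eid] = m.predictor
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    pd.DataFrame(coef_rows, columns=["enhancer_id", "feature", "role", "coefficient"]).to_csv(
        outdir / "coefficients.tsv", sep="\t", index=False
    )
    if predictors:
        with open(outdir / "predictors.pkl", "wb") as fh:
            pickle.dump(predictors, fh)


def load_collection(outdir: str | Path) -> ModelCollection:
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    coefs = pd.read_csv(outdir / "coefficients.tsv", sep="\t")
    predictors: dict[str, object] = {}
    if (outdir / "predictors.pkl").exists():
        with open(outdir / "predictors.pkl", "rb") as fh:
            predictors = pickle.load(fh)

    models: dict[str, EnhancerModel] = {}
    for eid, meta in manifest["models"].items():
        prep = Preprocessing(
            mode=meta["preprocessing"]["mode"],
            log_applied=meta["preprocessing"]["log_applied"],
            centers=np.asarray(meta["preprocessing"]["centers"], dtype=float),
            scales=np.asarray(meta["preprocessing"]["scales"], dtype=float),
        )
        coefficients = None
        if meta["method"] == "elastic_net" or meta["degenerate"]:
            sub = coefs[coefs["enhancer_id"] == eid]
            order = meta["tf_features"] + meta["tg_features"]
            if len(sub):
                lookup = dict(zip(sub["feature"], sub["coefficient"]))
                coefficients = np.asarray([lookup.get(f, 0.0) for f in order], dtype=float)
            else:
                coefficients = np.zeros(len(order))
        models[eid] = EnhancerModel(
            enhancer_id=eid,
            method=meta["method"],
            tf_features=meta["tf_features"],
            tg_features=meta["tg_features"],
            gamma_T=meta["gamma_T"],
            gamma_G=meta["gamma_G"],
            lambda_=meta["lambda"],
            preprocessing=prep,
            feature_mode=meta["feature_mode"],
            coefficients=coefficients,
            intercept=meta["intercept"],
            predictor=predictors.get(eid),
            degenerate=meta["degenerate"],
            train_target_range=tuple(meta["train_target_range"]),
        )
    return ModelCollection(
        models=models,
        training_samples=manifest["training_samples"],
        config=manifest["config"],
        skip_report=[tuple(s) for s in manifest["skip_report"]],
    )
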