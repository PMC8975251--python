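"""Penalized-regression epigenetic clocks: training, CV, prediction.

A clock is an elastic-net linear regression of transformed age on beta
values (mixing parameter alpha = 0.5, halfway between ridge and lasso,
not tuned). The penalty strength is chosen automatically by tenfold
internal cross-validation minimizing mean squared error. Unbiased
accuracy estimates come from leave-one-out CV (LOO) or tenfold CV with
folds balanced across species (LOFO10); the penalty is re-selected
inside every outer fold so no held-out sample influences its own model.
Reprogrammed (iPSC) samples are excluded from training by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .agetx import TransformSpec, apply_transform, invert_transform
from .core_io import BetaMatrix, ClockModel, SampleSheet, ValidationError

__all__ = [
    "train_clock",
    "predict_age",
    "loo_cv",
    "lofo10_cv",
    "clock_metrics",
    "two_group_comparison",
]


def _training_frame(betas: BetaMatrix, sheet: SampleSheet, include_ipsc: bool):
    df = sheet.frame
    keep = np.ones(len(df), dtype=bool)
    if not include_ipsc:
        keep = (df["cell_type"] != "iPSC").to_numpy()
    ids = df.loc[keep, "sample_id"].tolist()
    X = betas.values.loc[ids]
    return X, SampleSheet(df.loc[keep])


def _impute_medians(X: pd.DataFrame):
    med = X.median(axis=0, skipna=True)
    if X.isna().any().any():
        X = X.fillna(med)
    return X, med


def train_clock(
    betas: BetaMatrix,
    sheet: SampleSheet,
    transform_spec: TransformSpec,
    alpha: float = 0.5,
    inner_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
    standardize: bool = False,
    include_ipsc: bool = False,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> ClockModel:
    """Fit an elastic-net clock; penalty strength by internal k-fold CV.

    ``alpha`` is the elastic-net mixing parameter (0.5 by convention,
    deliberately not optimized). Only nonzero-coefficient CpGs are
    stored, along with per-CpG training medians for later imputation.
    """
    X, sheet = _training_frame(betas, sheet, include_ipsc)
    n = X.shape[0]
    if n < max(10, inner_folds):
        raise ValidationError(f"need >= {max(10, inner_folds)} samples to train, got {n}")
    y = apply_transform(transform_spec, sheet)
    if np.isnan(y).any():
        raise ValidationError("missing transformed ages")
    X, med = _impute_medians(X)
    arr = X.to_numpy()

    if np.all(arr.std(axis=0) == 0):
        warnings.warn("all CpGs constant; returning intercept-only clock")
        return ClockModel(
            transform=transform_spec,
            intercept=float(np.mean(y)),
            coefficients={},
            training_medians={},
            metadata={"n": n, "alpha": alpha, "seed": seed, "intercept_only": True},
        )

    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambdas,  # int: path length, lambdas chosen from the data
        cv=cv,
        max_iter=max_iter,
        tol=tol,
        selection="cyclic",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # coordinate-descent convergence chatter
        if standardize:
            mu, sd = arr.mean(axis=0), arr.std(axis=0)
            sd[sd == 0] = 1.0
            model.fit((arr - mu) / sd, y)
            coef = model.coef_ / sd
            intercept = float(model.intercept_ - np.dot(mu, coef))
        else:
            model.fit(arr, y)
            coef = model.coef_
            intercept = float(model.intercept_)

    nz = np.nonzero(coef)[0]
    cols = list(X.columns)
    return ClockModel(
        transform=transform_spec,
        intercept=intercept,
        coefficients={cols[j]: float(coef[j]) for j in nz},
        training_medians={cols[j]: float(med.iloc[j]) for j in nz},
        metadata={
            "n": n,
            "alpha": alpha,
            "lambda": float(model.alpha_),
            "seed": seed,
            "n_nonzero": int(nz.size),
            "tissues": sorted(set(sheet.frame["tissue"])),
            "species": sorted(set(sheet.frame["species"])),
        },
    )


def predict_transformed(model: ClockModel, betas: BetaMatrix) -> np.ndarray:
    """Linear predictor on the transformed-age scale."""
    cpgs = list(model.coefficients)
    if not cpgs:
        return np.full(betas.n_samples, model.intercept)
    missing = [c for c in cpgs if c not in betas.values.columns]
    if missing:
        raise ValidationError(f"model CpGs absent from matrix: {missing[:5]}")
    X = betas.values[cpgs]
    if X.isna().any().any():
        X = X.fillna(pd.Series(model.training_medians))
    w = np.array([model.coefficients[c] for c in cpgs])
    return model.intercept + X.to_numpy() @ w


def predict_age(model: ClockModel, betas: BetaMatrix, sheet: SampleSheet | None = None) -> np.ndarray:
    """DNAm age in years (inverse-transformed; may be negative).

    For species-parameterized transforms a sample sheet (ordered like
    the matrix) supplies each sample's species.
    """
    t = predict_transformed(model, betas)
    if model.transform.kind == "identity":
        return t
    if sheet is None:
        raise ValidationError("a sample sheet is required to invert a species-aware transform")
    species = sheet.frame.set_index("sample_id").loc[betas.sample_ids, "species"]
    return invert_transform(model.transform, t, species)


def clock_metrics(predictions: pd.DataFrame) -> dict:
    """Pearson r and median absolute error (years) of CV predictions."""
    if len(predictions) < 3:
        raise ValidationError("need >= 3 predictions for metrics")
    true = predictions["true_age_years"].to_numpy(dtype=float)
    pred = predictions["predicted_age_years"].to_numpy(dtype=float)
    mae = float(np.median(np.abs(pred - true)))
    if np.std(true) == 0 or np.std(pred) == 0:
        return {"pearson_r": np.nan, "median_abs_error_years": mae, "n": len(true), "r_defined": False}
    r = float(np.corrcoef(true, pred)[0, 1])
    return {"pearson_r": r, "median_abs_error_years": mae, "n": len(true), "r_defined": True}


def _cv_core(betas, sheet, transform_spec, folds, seed, **train_kw):
    """Train on each fold's complement, predict the held-out samples."""
    df = sheet.frame
    rows = []
    for fold_idx, test_ids in enumerate(folds):
        test_ids = list(test_ids)
        train_ids = [s for s in df["sample_id"] if s not in set(test_ids)]
        sub_sheet = SampleSheet(df[df["sample_id"].isin(train_ids)])
        sub_betas = BetaMatrix(betas.values.loc[sub_sheet.sample_ids])
        model = train_clock(sub_betas, sub_sheet, transform_spec, seed=seed, **train_kw)
        held = BetaMatrix(betas.values.loc[test_ids])
        held_sheet = SampleSheet(df[df["sample_id"].isin(test_ids)])
        pred = predict_age(model, held, held_sheet)
        true = held_sheet.frame.set_index("sample_id").loc[test_ids, "age_years"].to_numpy()
        for sid, tr, pr in zip(test_ids, true, pred):
            rows.append(
                {
                    "sample_id": sid,
                    "true_age_years": float(tr),
                    "predicted_age_years": float(pr),
                    "fold": fold_idx,
                }
            )
    return pd.DataFrame(rows)


def loo_cv(
    betas: BetaMatrix,
    sheet: SampleSheet,
    transform_spec: TransformSpec,
    alpha: float = 0.5,
    seed: int = 0,
    include_ipsc: bool = False,
    **train_kw,
):
    """Leave-one-out CV: n models, each trained without its test sample."""
    X, sheet = _training_frame(betas, sheet, include_ipsc)
    betas = BetaMatrix(X)
    n = len(sheet)
    if n < 15:
        raise ValidationError(f"LOO needs n >= 15, got {n}")
    folds = [[s] for s in sheet.sample_ids]
    preds = _cv_core(betas, sheet, transform_spec, folds, seed, alpha=alpha, **train_kw)
    return preds, clock_metrics(preds)


def lofo10_cv(
    betas: BetaMatrix,
    sheet: SampleSheet,
    transform_spec: TransformSpec,
    balance_by: str = "species",
    n_folds: int = 10,
    alpha: float = 0.5,
    seed: int = 0,
    include_ipsc: bool = False,
    **train_kw,
):
    """Tenfold CV with folds balanced across a stratifying label.

    Every fold receives ~1/n_folds of each stratum (species by
    default). Returns predictions plus combined and per-stratum
    metrics.
    """
    X, sheet = _training_frame(betas, sheet, include_ipsc)
    betas = BetaMatrix(X)
    df = sheet.frame
    strata = df[balance_by]
    counts = strata.value_counts()
    too_small = counts[counts < n_folds]
    if len(too_small):
        raise ValidationError(
            f"strata with < {n_folds} samples {dict(too_small)}; consider loo_cv instead"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(df), dtype=int)
    for label in counts.index:
        idx = np.flatnonzero((strata == label).to_numpy())
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % n_folds
    folds = [df.loc[fold_of == f, "sample_id"].tolist() for f in range(n_folds)]
    preds = _cv_core(betas, sheet, transform_spec, folds, seed, alpha=alpha, **train_kw)

    merged = preds.merge(df[["sample_id", balance_by]], on="sample_id")
    metrics = {"combined": clock_metrics(preds)}
    for label, grp in merged.groupby(balance_by):
        metrics[str(label)] = clock_metrics(grp)
    return preds, metrics


def two_group_comparison(values, group_labels, equal_var: bool = True) -> dict:
    """Two-sample Student t-test (Welch optional) between two groups.

    Used e.g. for DNAm age of iPSC vs fibroblast samples, or per-sample
    mean methylation between cell types.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    a, b = v[g == labels[0]], v[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "groups": labels,
        "means": {labels[0]: float(np.mean(a)), labels[1]: float(np.mean(b))},
        "n": {labels[0]: int(len(a)), labels[1]: int(len(b))},
        "t": float(t),
        "p": float(p),
    }
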