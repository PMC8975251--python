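"""Breeding-status analyses: differential aging rate and status EWAS.

The central question: do queens (the single breeding female of a
eusocial colony) accumulate epigenetic age more slowly than
nonbreeders? Four complementary designs are implemented:

* an interaction test — DNAm age regressed on chronological age, queen
  status and their product, with a Wald test on the interaction term
  (a negative coefficient means slower aging in queens);
* a status EWAS — each CpG regressed on queen status adjusting for age
  (Wald p for the status coefficient);
* a sector classification — stratified age-EWAS on ln(age) in each
  group, labelling CpGs group-specific when significant in one stratum
  and flat in the other;
* a male-trained / female-tested evaluation — a clock trained only on
  males (so queens cannot shape the fit) is applied to females, and
  predicted age is regressed on age + queen status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agetx import TransformSpec
from .clockfit import predict_age, train_clock
from .core_io import BetaMatrix, SampleSheet, ValidationError
from .ewas import ewas_age

__all__ = [
    "SlopeTestResult",
    "differential_slope_test",
    "ewas_group_status",
    "sector_classification",
    "sex_split_evaluation",
]


@dataclass
class SlopeTestResult:
    """OLS fit of dnam_age ~ age + group + age:group."""

    coef: dict[str, float]
    se: dict[str, float]
    wald_t: float
    p_interaction: float
    n_per_group: dict[str, int]
    rate_ratio: float  # (age slope in group 1) / (age slope in group 0)


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with classical covariance; returns beta, se, df."""
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se, df


def differential_slope_test(dnam_age, age, group_indicator) -> SlopeTestResult:
    """Wald test for a group difference in epigenetic aging rate.

    ``group_indicator`` is binary (1 = queen / focal group). The model
    is dnam_age = b0 + b1*age + b2*group + b3*age*group; b3 < 0 means
    the focal group ages more slowly.
    """
    y = np.asarray(dnam_age, dtype=float)
    a = np.asarray(age, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValidationError("group_indicator must be binary 0/1")
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if n0 < 3 or n1 < 3:
        raise ValidationError(f"need >= 3 samples per group, got {n0} and {n1}")
    X = np.column_stack([np.ones_like(a), a, g, a * g])
    beta, se, df = _ols(X, y)
    scale = float(np.mean(y**2)) + 1.0
    resid = y - X @ beta
    if float(resid @ resid) / df < 1e-24 * scale:
        # perfect fit: the interaction is either exactly present or absent
        tiny = abs(beta[3]) < 1e-9 * np.sqrt(scale)
        t = 0.0 if tiny else np.inf * np.sign(beta[3])
        p = 1.0 if tiny else 0.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[3] / se[3] if se[3] > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df)) if se[3] > 0 else 1.0
    names = ["intercept", "age", "group", "age_x_group"]
    slope0 = beta[1]
    ratio = float((beta[1] + beta[3]) / slope0) if slope0 != 0 else np.nan
    return SlopeTestResult(
        coef=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        wald_t=float(t),
        p_interaction=max(p, np.finfo(float).tiny),
        n_per_group={"group0": n0, "group1": n1},
        rate_ratio=ratio,
    )


def ewas_group_status(betas, group_indicator, ages) -> pd.DataFrame:
    """Per-CpG Wald test for a group effect adjusting for age.

    Fits beta_cpg = b0 + b1*group + b2*age for every CpG by closed-form
    OLS (vectorized across CpGs) and reports the group coefficient, its
    standard error and two-sided Wald p on n-3 df.
    """
    X = betas.values if isinstance(betas, BetaMatrix) else pd.DataFrame(betas)
    g = np.asarray(group_indicator, dtype=float)
    a = np.asarray(ages, dtype=float)
    n1, n0 = int(g.sum()), int((1 - g).sum())
    if n0 < 3 or n1 < 3:
        raise ValidationError(f"need >= 3 samples per group, got {n0} and {n1}")
    if np.std(a) > 0 and abs(np.corrcoef(g, a)[0, 1]) > 0.999:
        warnings.warn("group is collinear with age; group effect not identifiable")

    D = np.column_stack([np.ones_like(g), g, a])
    n, k = D.shape
    DtD_inv = np.linalg.pinv(D.T @ D)
    H = DtD_inv @ D.T  # k x n
    Y = X.to_numpy()
    B = H @ Y  # k x p
    resid = Y - D @ B
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se_g = np.sqrt(DtD_inv[1, 1] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[1] / se_g
    p = 2 * stats.t.sf(np.abs(t), df)
    valid = se_g > 0
    p = np.where(valid, np.maximum(p, np.finfo(float).tiny), np.nan)
    return pd.DataFrame(
        {
            "cpg_id": list(X.columns),
            "group_coef": B[1],
            "group_se": se_g,
            "wald_t": np.where(valid, t, np.nan),
            "p": p,
            "age_coef": B[2],
            "n": n,
            "valid": valid,
        }
    )


def sector_classification(
    betas,
    ages,
    group_indicator,
    p_sig: float = 1e-4,
    p_flat: float = 0.05,
    labels: tuple[str, str] = ("group0", "group1"),
) -> pd.DataFrame:
    """Classify CpGs by which group's age-EWAS (on ln age) they hit.

    Runs an EWAS of ln(age) separately in each stratum; samples with
    age <= 0 are excluded (the count is attached to the result). A CpG
    is labelled ``<X>_specific`` when p < p_sig in X and p > p_flat (or
    undefined) in the other group, ``shared`` when p < p_sig in both,
    otherwise ``neither``.
    """
    X = betas.values if isinstance(betas, BetaMatrix) else pd.DataFrame(betas)
    a = np.asarray(ages, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    pos = a > 0
    n_excluded = int((~pos).sum())
    tables = {}
    for val, lab in ((0.0, labels[0]), (1.0, labels[1])):
        mask = (g == val) & pos
        if mask.sum() < 4:
            raise ValidationError(f"stratum {lab} has {int(mask.sum())} usable samples (< 4)")
        tables[lab] = ewas_age(X.iloc[np.flatnonzero(mask)], np.log(a[mask]), label=lab)
    t0 = tables[labels[0]].set_index("cpg_id")
    t1 = tables[labels[1]].set_index("cpg_id")

    def sig(t):
        return t["valid"] & (t["p"] < p_sig)

    def flat(t):
        return (~t["valid"].astype(bool)) | (t["p"] > p_flat)

    cat = np.select(
        [
            (sig(t0) & sig(t1)).to_numpy(),
            (sig(t0) & flat(t1)).to_numpy(),
            (sig(t1) & flat(t0)).to_numpy(),
        ],
        ["shared", f"{labels[0]}_specific", f"{labels[1]}_specific"],
        default="neither",
    )
    out = pd.DataFrame(
        {
            "cpg_id": t0.index,
            "category": cat,
            f"z_{labels[0]}": t0["fisher_z"].to_numpy(),
            f"p_{labels[0]}": t0["p"].to_numpy(),
            f"z_{labels[1]}": t1["fisher_z"].to_numpy(),
            f"p_{labels[1]}": t1["p"].to_numpy(),
        }
    )
    out.attrs["n_excluded_nonpositive_age"] = n_excluded
    return out


def sex_split_evaluation(
    betas: BetaMatrix,
    sheet: SampleSheet,
    transform_spec: TransformSpec,
    alpha: float = 0.5,
    seed: int = 0,
    max_age: float | None = None,
    **train_kw,
) -> dict:
    """Train a clock on males only; test the queen effect in females.

    Queens never enter the training set, so the clock cannot condition
    out their slower aging. Female DNAm ages are regressed on
    chronological age and queen status; the Wald p of the (main-effect)
    queen coefficient is reported. ``max_age`` optionally restricts the
    evaluation to younger animals.
    """
    df = sheet.frame
    males = df[(df["sex"] == "M") & (df["cell_type"] == "tissue")]
    females = df[(df["sex"] == "F") & (df["breeding_status"] != "unknown")]
    if max_age is not None:
        females = females[females["age_years"] < max_age]
    if len(males) < 15:
        raise ValidationError(f"need >= 15 male training samples, got {len(males)}")
    if len(females) < 5:
        raise ValidationError(f"need >= 5 known-status female samples, got {len(females)}")

    male_sheet = SampleSheet(males)
    model = train_clock(
        BetaMatrix(betas.values.loc[male_sheet.sample_ids]),
        male_sheet,
        transform_spec,
        alpha=alpha,
        seed=seed,
        **train_kw,
    )
    fem_sheet = SampleSheet(females)
    pred = predict_age(model, BetaMatrix(betas.values.loc[fem_sheet.sample_ids]), fem_sheet)

    a = fem_sheet.frame["age_years"].to_numpy()
    q = (fem_sheet.frame["breeding_status"] == "queen").to_numpy(dtype=float)
    if q.sum() == 0 or q.sum() == len(q):
        raise ValidationError("female test set needs both queens and nonbreeders")
    X = np.column_stack([np.ones_like(a), a, q])
    beta, se, dof = _ols(X, pred)
    t = beta[2] / se[2] if se[2] > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), dof)) if se[2] > 0 else 1.0
    return {
        "model": model,
        "predictions": pd.DataFrame(
            {
                "sample_id": fem_sheet.sample_ids,
                "true_age_years": a,
                "predicted_age_years": pred,
                "is_queen": q.astype(bool),
            }
        ),
        "queen_coef": float(beta[2]),
        "queen_se": float(se[2]),
        "p_queen": max(p, np.finfo(float).tiny),
        "n_queens": int(q.sum()),
        "n_females": int(len(q)),
        "n_males_trained": int(len(males)),
    }
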