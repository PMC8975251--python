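"""Per-CpG association of methylation with age and downstream screens.

The per-CpG test is a Pearson correlation of beta values with
(optionally transformed) age. Two derived statistics are reported for
every CpG:

* ``fisher_z`` — atanh(r) * sqrt(n - 3), approximately standard normal
  under the null; its sign is the direction of the aging change.
* ``p`` — the two-sided correlation-test p-value from
  t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom.

Tables from different tissues/strata are combined with Stouffer's
method (Z = sum(w_i z_i) / sqrt(sum(w_i^2)), unweighted by default).
Top-CpG selection, hypergeometric set overlap, upset-style intersection
counts, cross-species concordance, the long-lived-vs-short-lived
divergence screen, and genomic-context summaries operate on these
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, CpGManifest, ValidationError

__all__ = [
    "ewas_age",
    "stouffer_meta",
    "select_top_cpgs",
    "overlap_test",
    "membership_counts",
    "cross_species_concordance",
    "divergent_cpgs",
    "region_class_distribution",
    "island_mean_trajectory",
    "bh_fdr",
]

_R_CAP = 1.0 - 1e-15  # |r|=1 would give infinite fisher z


def _as_values(betas) -> pd.DataFrame:
    return betas.values if isinstance(betas, BetaMatrix) else pd.DataFrame(betas)


def _corr_stats(r: np.ndarray, n: np.ndarray):
    """fisher z and two-sided correlation-test p from r and per-CpG n."""
    r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r) * np.sqrt(np.maximum(n - 3, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
    p = np.where(np.isnan(r), np.nan, np.maximum(p, np.finfo(float).tiny))
    return z, p


def ewas_age(betas, ages, label: str = "all") -> pd.DataFrame:
    """Epigenome-wide Pearson correlation test of methylation vs age.

    Missing betas are handled pairwise-complete per CpG. Constant CpGs
    (or CpGs with fewer than 4 complete pairs) get NaN statistics and
    are flagged in the ``valid`` column.

    Returns a table with columns cpg_id, pearson_r, fisher_z, p, n,
    stratum, valid.
    """
    X = _as_values(betas)
    y = np.asarray(ages, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("ages length does not match number of samples")
    if X.shape[0] < 4:
        raise ValidationError(f"EWAS needs n >= 4 samples, got {X.shape[0]}")

    arr = X.to_numpy()
    if np.isnan(arr).any():
        r = np.empty(arr.shape[1])
        n = np.empty(arr.shape[1], dtype=int)
        for j in range(arr.shape[1]):
            ok = ~np.isnan(arr[:, j])
            n[j] = ok.sum()
            if n[j] < 4 or np.std(arr[ok, j]) == 0 or np.std(y[ok]) == 0:
                r[j] = np.nan
            else:
                r[j] = np.corrcoef(arr[ok, j], y[ok])[0, 1]
    else:
        n = np.full(arr.shape[1], arr.shape[0])
        xc = arr - arr.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc.T @ yc) / (sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan

    z, p = _corr_stats(r, n)
    return pd.DataFrame(
        {
            "cpg_id": list(X.columns),
            "pearson_r": r,
            "fisher_z": z,
            "p": p,
            "n": n,
            "stratum": label,
            "valid": ~np.isnan(r),
        }
    )


def stouffer_meta(tables: list[pd.DataFrame], weights=None) -> pd.DataFrame:
    """Combine per-CpG fisher z across strata with Stouffer's method.

    Z = sum(w_i z_i) / sqrt(sum(w_i^2)). ``weights`` may be None (equal
    weights), "sqrt_n", or an explicit per-table sequence. A CpG missing
    (or invalid) in a stratum simply omits that stratum.
    """
    if not tables:
        raise ValidationError("stouffer_meta needs at least one table")
    frames = []
    for i, tab in enumerate(tables):
        t = tab.loc[tab["valid"], ["cpg_id", "fisher_z", "n"]].copy()
        if weights is None:
            t["w"] = 1.0
        elif weights == "sqrt_n":
            t["w"] = np.sqrt(t["n"].astype(float))
        else:
            t["w"] = float(weights[i])
        frames.append(t)
    cat = pd.concat(frames, ignore_index=True)
    if cat.empty:
        raise ValidationError("no valid CpGs to meta-analyze")
    cat["wz"] = cat["w"] * cat["fisher_z"]
    cat["w2"] = cat["w"] ** 2
    g = cat.groupby("cpg_id", sort=True)
    num = g["wz"].sum()
    den = np.sqrt(g["w2"].sum())
    Z = (num / den).to_numpy()
    p = np.maximum(2.0 * stats.norm.sf(np.abs(Z)), np.finfo(float).tiny)
    out = pd.DataFrame(
        {
            "cpg_id": num.index,
            "fisher_z": Z,
            "p": p,
            "k_strata": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    out["valid"] = True
    return out


def select_top_cpgs(
    table: pd.DataFrame, p_threshold: float = 1e-5, max_per_direction: int = 500
) -> dict[str, list[str]]:
    """Significant CpGs split by direction, truncated per direction.

    Ranking is by smallest p, ties broken by larger |z| then by
    cpg_id (deterministic).
    """
    t = table.loc[table["valid"] & (table["p"] < p_threshold)].copy()
    t["absz"] = t["fisher_z"].abs()
    out = {}
    for name, sign in (("gain", 1), ("loss", -1)):
        d = t[np.sign(t["fisher_z"]) == sign]
        d = d.sort_values(["p", "absz", "cpg_id"], ascending=[True, False, True])
        out[name] = d["cpg_id"].head(max_per_direction).tolist()
    return out


def overlap_test(set_a, set_b, universe_size: int) -> dict:
    """Exact upper-tail hypergeometric probability of >= observed overlap."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValidationError("set larger than universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return {"overlap": k, "p": min(p, 1.0), "n_a": len(a), "n_b": len(b), "universe": universe_size}


def membership_counts(sets_by_label: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every nonempty intersection pattern (upset-plot data)."""
    if len(sets_by_label) < 2:
        raise ValidationError("membership_counts needs >= 2 sets")
    labels = sorted(sets_by_label)
    universe = set().union(*sets_by_label.values())
    counts: dict[tuple[str, ...], int] = {}
    for el in universe:
        pattern = tuple(lab for lab in labels if el in sets_by_label[lab])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def cross_species_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame, shared_cpgs=None) -> dict:
    """Pearson correlation of per-CpG fisher z between two strata/species."""
    a = table_a.set_index("cpg_id")
    b = table_b.set_index("cpg_id")
    ids = a.index.intersection(b.index)
    if shared_cpgs is not None:
        ids = ids.intersection(pd.Index(shared_cpgs))
    za = a.loc[ids, "fisher_z"].to_numpy()
    zb = b.loc[ids, "fisher_z"].to_numpy()
    ok = ~(np.isnan(za) | np.isnan(zb))
    n_dropped = int((~ok).sum())
    if ok.sum() < 10:
        raise ValidationError(f"need >= 10 shared CpGs with defined z, have {int(ok.sum())}")
    r = float(np.corrcoef(za[ok], zb[ok])[0, 1])
    return {"r": r, "n_used": int(ok.sum()), "n_dropped": n_dropped}


def divergent_cpgs(
    table_longlived1: pd.DataFrame,
    table_longlived2: pd.DataFrame,
    table_shortlived: pd.DataFrame,
    p_sig: float = 1e-5,
    p_flat: float = 0.05,
    rule: str = "flat_or_opposite",
) -> dict:
    """CpGs aging concordantly in two long-lived species but not in a
    short-lived one.

    A CpG qualifies when it is significant (p < p_sig) with the same z
    sign in both long-lived tables AND, in the short-lived table, is
    either not significant (p > p_flat; undefined statistics count as
    flat) or — under the default "flat_or_opposite" rule — has the
    opposite sign. rule="flat_only" requires non-significance.
    """
    if rule not in ("flat_or_opposite", "flat_only"):
        raise ValidationError(f"unknown rule {rule!r}")
    l1 = table_longlived1.set_index("cpg_id")
    l2 = table_longlived2.set_index("cpg_id")
    sh = table_shortlived.set_index("cpg_id")
    ids = l1.index.intersection(l2.index).intersection(sh.index)
    l1, l2, sh = l1.loc[ids], l2.loc[ids], sh.loc[ids]

    sig_both = (
        (l1["p"] < p_sig)
        & (l2["p"] < p_sig)
        & (np.sign(l1["fisher_z"]) == np.sign(l2["fisher_z"]))
        & l1["valid"]
        & l2["valid"]
    )
    flat_short = (~sh["valid"].astype(bool)) | (sh["p"] > p_flat)
    if rule == "flat_or_opposite":
        opposite = sh["valid"] & (np.sign(sh["fisher_z"]) != np.sign(l1["fisher_z"]))
        short_ok = flat_short | opposite
    else:
        short_ok = flat_short
    hits = sorted(ids[(sig_both & short_ok).to_numpy()])
    return {"cpg_ids": hits, "rule": rule, "p_sig": p_sig, "p_flat": p_flat}


def region_class_distribution(cpg_set, manifest: CpGManifest, directions=None) -> pd.DataFrame:
    """Proportion of CpGs per region class, vs the manifest background.

    ``directions`` optionally maps cpg_id -> {"gain","loss"}; proportions
    then sum to 1 within each direction. The background row covers the
    whole manifest.
    """
    cpg_set = list(cpg_set)
    if not cpg_set:
        raise ValidationError("empty CpG set")
    man = manifest.frame.set_index("cpg_id")
    missing = set(cpg_set) - set(man.index)
    if missing:
        raise ValidationError(f"CpGs not in manifest: {sorted(missing)[:5]}")

    def props(ids, label):
        counts = man.loc[list(ids), "region_class"].value_counts()
        total = counts.sum()
        return pd.DataFrame(
            {
                "direction": label,
                "region_class": counts.index,
                "proportion": counts.to_numpy() / total,
                "count": counts.to_numpy(),
            }
        )

    parts = []
    if directions is None:
        parts.append(props(cpg_set, "all"))
    else:
        for d in sorted(set(directions.values())):
            ids = [c for c in cpg_set if directions[c] == d]
            if ids:
                parts.append(props(ids, d))
    parts.append(props(man.index, "background"))
    return pd.concat(parts, ignore_index=True)


def island_mean_trajectory(betas, manifest: CpGManifest, ages) -> dict:
    """Per-sample mean beta inside vs outside CpG islands, regressed on age.

    Returns the two per-sample series plus slope, standard error,
    Pearson r and correlation-test p for each stratum.
    """
    X = _as_values(betas)
    y = np.asarray(ages, dtype=float)
    man = manifest.frame.set_index("cpg_id").loc[list(X.columns)]
    island = man["island_flag"].to_numpy()
    if island.sum() == 0 or (~island).sum() == 0:
        raise ValidationError("need >= 1 island and >= 1 non-island CpG")
    out = {}
    for name, mask in (("island", island), ("open_sea", ~island)):
        series = X.loc[:, mask].mean(axis=1).to_numpy()
        if np.std(series) == 0 or np.std(y) == 0:
            slope, se, r, p = 0.0, np.nan, np.nan, np.nan
        else:
            res = stats.linregress(y, series)
            slope, se, r, p = res.slope, res.stderr, res.rvalue, res.pvalue
        out[name] = {
            "mean_beta": series,
            "slope_per_year": float(slope),
            "slope_se": float(se) if se == se else np.nan,
            "pearson_r": float(r) if r == r else np.nan,
            "p": float(p) if p == p else np.nan,
        }
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
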