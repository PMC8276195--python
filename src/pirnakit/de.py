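"""Two-group differential expression with precision weights and moderated t.

The engine is a voom-style procedure: log2-CPM transformation, a lowess fit
of sqrt(residual SD) against mean log2 count giving per-observation
precision weights, weighted least squares per feature, and empirical-Bayes
variance moderation — the posterior variance is

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

with the prior degrees of freedom d0 and prior variance s0^2 fitted by
moment-matching a scaled-F distribution to the observed s^2 (on the log
scale, via digamma/trigamma inversion).  The moderated t has d0 + d degrees
of freedom; p-values are Benjamini-Hochberg adjusted across features.

Results from the genomic and transcriptomic count matrices are merged with a
per-feature consensus label, and up/down classification excludes features
whose two tracks disagree on the sign of the fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def two_group_design(groups: pd.Series, batch: pd.Series | None = None) -> pd.DataFrame:
    """Intercept + group indicator (+ batch indicators); coefficient 1 is the
    log2 fold change of the second group level over the first."""
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"two-group design requires exactly 2 groups, got {levels}")
    cols = {"intercept": np.ones(len(groups)), f"group_{levels[1]}": (groups == levels[1]).astype(float)}
    if batch is not None:
        for b in sorted(batch.unique())[1:]:
            cols[f"batch_{b}"] = (batch == b).astype(float)
    design = pd.DataFrame(cols, index=groups.index)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is not full rank")
    return design


# ---------------------------------------------------------------------------
# voom transform
# ---------------------------------------------------------------------------


@dataclass
class VoomResult:
    log2_cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray


def voom_transform(
    counts: pd.DataFrame,
    size_factors: pd.Series | None,
    design: pd.DataFrame,
    span: float = 0.5,
) -> VoomResult:
    """Log2-CPM with mean-variance precision weights.

    Residual SDs from an unweighted fit are square-rooted and lowess-smoothed
    against average log2 count; the fitted trend, evaluated at each
    observation's fitted log count, is raised to the -4 to give weights
    (clipped to [1e-6, 1e6]).
    """
    groups_ok = design.iloc[:, 1].groupby(design.iloc[:, 1]).size()
    if (groups_ok < 2).any():
        raise ValueError("each group needs at least 2 samples")
    libs = counts.sum(axis=0).astype(float)
    if size_factors is not None:
        libs = libs * size_factors.reindex(libs.index)
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / (libs.to_numpy() + 1.0)[None, :] * 1e6)
    X = design.to_numpy(dtype=float)
    # unweighted LS fit per feature (shared design -> one pseudo-inverse)
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    resid = y - fitted
    df_resid = X.shape[0] - X.shape[1]
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    # mean log2 count of each feature, on the count (not CPM) scale
    sx = y.mean(axis=1) + np.mean(np.log2(libs.to_numpy() + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    fit = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = fit[:, 0], fit[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    fitted_counts = fitted + (np.log2(libs.to_numpy() + 1.0) - np.log2(1e6))[None, :]
    w = np.interp(fitted_counts, tx, ty) ** -4.0
    w = np.clip(w, 1e-6, 1e6)
    return VoomResult(
        log2_cpm=pd.DataFrame(y, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(w, index=counts.index, columns=counts.columns),
        trend_x=tx,
        trend_y=ty,
    )


def sample_quality_weights(log_expr: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-sample quality weights from residual variance, normalised to mean 1.

    Samples whose residuals around the group fit are systematically larger
    get proportionally smaller weights (inverse variance).
    """
    X = design.to_numpy(dtype=float)
    y = log_expr.to_numpy(dtype=float)
    pinv = np.linalg.pinv(X)
    resid = y - (y @ pinv.T) @ X.T
    var = (resid**2).mean(axis=0)
    var = np.maximum(var, 1e-12)
    w = 1.0 / var
    w = w / w.mean()
    return pd.Series(w, index=log_expr.columns, name="sample_weight")


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    return float(optimize.brentq(lambda v: special.polygamma(1, v) - y, 1e-8, 1e8))


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matched (d0, s0^2) of a scaled-F prior for the sample variances.

    Works on z = log(s2): E[z] and Var[z] have closed forms in digamma /
    trigamma, so the excess variance of z over what df alone explains
    determines d0, and the mean determines s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var > 0:
        d0 = 2 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t(
    log_expr: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    coef: int = 1,
    sample_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Weighted least squares + empirical-Bayes moderated t per feature.

    Returns a table with logFC (the requested coefficient), t statistic, raw
    and BH-adjusted p-values, and the residual SD per feature.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    y = log_expr.to_numpy(dtype=float)
    if weights is None:
        W = np.ones_like(y)
    else:
        W = weights.to_numpy(dtype=float)
    if sample_weights is not None:
        W = W * sample_weights.reindex(log_expr.columns).to_numpy()[None, :]
    n_feat = y.shape[0]
    beta_out = np.empty(n_feat)
    s2 = np.empty(n_feat)
    se_unscaled = np.empty(n_feat)
    for g in range(n_feat):
        w = W[g]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = Xw.T @ y[g]
        cov = np.linalg.inv(XtWX)
        beta = cov @ XtWy
        r = y[g] - X @ beta
        s2[g] = float((w * r**2).sum() / df_resid)
        beta_out[g] = beta[coef]
        se_unscaled[g] = np.sqrt(cov[coef, coef])
    s2[s2 < 1e-12] = 0.0  # numerically-zero residual variance
    d0, s0_sq = fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = se_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta_out / se, 0.0)
    if np.isinf(df_total):
        pvals = 2 * sps.norm.sf(np.abs(t))
    else:
        pvals = 2 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "logFC": beta_out,
            "t_stat": t,
            "p_value": pvals,
            "adj_p": bh_adjust(pvals),
            "residual_sd": np.sqrt(s2),
        },
        index=log_expr.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cross-track merge and up/down classification
# ---------------------------------------------------------------------------


def run_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series | None = None,
    batch: pd.Series | None = None,
    quality_weights: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: voom transform then moderated t for one matrix."""
    groups = groups.reindex(counts.columns)
    design = two_group_design(groups, batch.reindex(counts.columns) if batch is not None else None)
    v = voom_transform(counts, size_factors, design)
    sw = sample_quality_weights(v.log2_cpm, design) if quality_weights else None
    return moderated_t(v.log2_cpm, v.weights, design, coef=1, sample_weights=sw)


def merge_de(
    genomic: pd.DataFrame,
    transcriptomic: pd.DataFrame,
    mode: str = "union",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Merge per-track DE tables into one consensus table.

    Per feature: both tracks' logFC and adjusted p side by side, a consensus
    label (both / genomic_only / transcriptomic_only / none, judged at the
    adjusted-p threshold), and membership of the union and intersection
    significant sets at both raw and adjusted alpha.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    all_ids = genomic.index.union(transcriptomic.index)
    g = genomic.reindex(all_ids)
    t = transcriptomic.reindex(all_ids)
    sig_g = (g["adj_p"] < alpha).fillna(False)
    sig_t = (t["adj_p"] < alpha).fillna(False)
    raw_g = (g["p_value"] <= alpha).fillna(False)
    raw_t = (t["p_value"] <= alpha).fillna(False)
    consensus = np.select(
        [sig_g & sig_t, sig_g & ~sig_t, ~sig_g & sig_t],
        ["both", "genomic_only", "transcriptomic_only"],
        default="none",
    )
    return pd.DataFrame(
        {
            "logFC_genomic": g["logFC"],
            "logFC_transcriptomic": t["logFC"],
            "p_genomic": g["p_value"],
            "p_transcriptomic": t["p_value"],
            "adj_p_genomic": g["adj_p"],
            "adj_p_transcriptomic": t["adj_p"],
            "consensus": consensus,
            "in_union_adj": (sig_g | sig_t),
            "in_intersection_adj": (sig_g & sig_t),
            "in_union_raw": (raw_g | raw_t),
            "in_intersection_raw": (raw_g & raw_t),
            "selected": (sig_g | sig_t) if mode == "union" else (sig_g & sig_t),
        },
        index=all_ids,
    )


def heatmap_matrix(merged: pd.DataFrame, log_expr: pd.DataFrame) -> pd.DataFrame:
    """Normalised expression of consensus-significant features, row-centred."""
    feats = merged.index[merged["selected"]].intersection(log_expr.index)
    sub = log_expr.loc[feats]
    return sub.sub(sub.mean(axis=1), axis=0)


def classify_updown(merged: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Split selected features into up / down / discordant.

    A feature with adjusted p below alpha in the selection is "up" when its
    fold changes are positive, "down" when negative; features whose two
    tracks disagree on the sign are flagged discordant and excluded from the
    up/down counts.
    """
    sel = merged[merged["selected"]]
    lg = sel["logFC_genomic"]
    lt = sel["logFC_transcriptomic"]
    sign_g = np.sign(lg.fillna(0))
    sign_t = np.sign(lt.fillna(0))
    discordant = (sign_g * sign_t) < 0
    # effective sign: the available (or agreeing) track's sign
    eff = np.where(sign_g != 0, sign_g, sign_t)
    up = sel.index[(~discordant) & (eff > 0)].tolist()
    down = sel.index[(~discordant) & (eff < 0)].tolist()
    disc = sel.index[discordant].tolist()
    return {
        "up": up,
        "down": down,
        "discordant": disc,
        "n_up": len(up),
        "n_down": len(down),
        "n_discordant": len(disc),
    }
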