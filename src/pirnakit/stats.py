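"""Filtering, normalisation and exploratory summaries for count matrices.

Both quantification tracks are analysed in parallel with the same machinery:
CPM-based low-expression filtering, TMM / TMMwsp / RLE size factors, RLE
diagnostic plots, biotype detection summaries, MDS/PCA ordination and
hierarchical sample clustering.

The TMM implementation follows the published trimmed-mean-of-M-values
algorithm (30% log-ratio trim, 5% A trim, inverse asymptotic-variance
weights, reference = sample whose upper-quartile count fraction is closest
to the mean); TMMwsp adds singleton pairing of zeros for sparse data and
picks the reference by largest sum of sqrt counts, as its authors specify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def cpm(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    log: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over effective library sizes (colsum x size factor).

    In log mode the prior count is added proportionally to each library's
    effective size, so a library twice as deep receives twice the prior —
    this keeps log-CPM comparable across depths.
    """
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"zero-count libraries: {bad}")
    if size_factors is not None:
        libs = libs * size_factors.reindex(libs.index)
    if not log:
        return counts.div(libs, axis=1) * 1e6
    prior_scaled = prior * libs / libs.mean()
    adj = counts.add(prior_scaled, axis=1)
    denom = libs + 2 * prior_scaled
    return np.log2(adj.div(denom, axis=1) * 1e6)


@dataclass
class FilterResult:
    counts: pd.DataFrame
    kept: list[str]
    removed: list[str]
    hist_before: tuple[np.ndarray, np.ndarray]  # (bin_edges, frequencies) of avg log2 CPM
    hist_after: tuple[np.ndarray, np.ndarray]


def filter_low(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_samples: int | None = None,
    group_sizes: dict[str, int] | None = None,
) -> FilterResult:
    """Keep features with CPM >= threshold in at least ``min_samples`` samples.

    ``min_samples`` defaults to the size of the smallest group.  Average
    log2-CPM histograms before and after are returned for diagnostic plots.
    """
    n_samples = counts.shape[1]
    if min_samples is None:
        if group_sizes:
            min_samples = min(group_sizes.values())
        else:
            min_samples = n_samples
    if min_samples > n_samples:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {n_samples}")
    mat = cpm(counts)
    keep_mask = (mat >= cpm_threshold).sum(axis=1) >= min_samples
    kept = counts.index[keep_mask].tolist()
    removed = counts.index[~keep_mask].tolist()

    def _hist(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if frame.empty:
            return np.linspace(-5, 15, 41), np.zeros(40)
        avg = cpm(frame, log=True).mean(axis=1).to_numpy()
        freq, edges = np.histogram(avg, bins=40, range=(-5, 15))
        return edges, freq

    return FilterResult(
        counts=counts.loc[keep_mask],
        kept=kept,
        removed=removed,
        hist_before=_hist(counts),
        hist_after=_hist(counts.loc[keep_mask]),
    )


# ---------------------------------------------------------------------------
# Normalisation factors
# ---------------------------------------------------------------------------


def _rescale_geomean(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Trimmed weighted mean of M-values of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    # inverse asymptotic (delta-method) variance of M as weight
    var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    f = np.sum(M[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2**f)


def _tmmwsp_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """TMM with singleton pairing: zeros in one sample are paired with the
    largest singleton positives of the other so sparse libraries still
    contribute log-ratios; unpaired singletons are discarded."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    npos = 2 * (obs > 0).astype(int) + (ref > 0).astype(int)
    keep = npos > 0
    obs, ref, npos = obs[keep], ref[keep], npos[keep]
    zero_obs = npos == 1
    zero_ref = npos == 2
    single = zero_obs | zero_ref
    n_pairs = min(zero_obs.sum(), zero_ref.sum())
    if n_pairs > 0:
        ref_singles = np.sort(ref[single])[::-1][:n_pairs]
        obs_singles = np.sort(obs[single])[::-1][:n_pairs]
        obs = np.concatenate([obs[~single], obs_singles])
        ref = np.concatenate([ref[~single], ref_singles])
    else:
        obs, ref = obs[~single], ref[~single]
    n = obs.size
    if n == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    M_shrunk = np.log2(((obs + 0.5) / (lib_obs + 0.5)) / ((ref + 0.5) / (lib_ref + 0.5)))
    o_m = np.lexsort((M_shrunk, M))
    o_a = np.argsort(A, kind="stable")
    lo_m = int(n * logratio_trim)
    hi_m = n - lo_m
    lo_a = int(n * sum_trim)
    hi_a = n - lo_a
    keep_m = np.zeros(n, dtype=bool)
    keep_m[o_m[lo_m:hi_m]] = True
    keep_a = np.zeros(n, dtype=bool)
    keep_a[o_a[lo_a:hi_a]] = True
    sel = keep_m & keep_a
    if not sel.any():
        return 1.0
    p_o, p_r = p_obs[sel], p_ref[sel]
    var = (1 - p_o) / p_o / lib_obs + (1 - p_r) / p_r / lib_ref
    w = (1 + 1e-6) / (var + 1e-6)
    f = np.sum(w * M[sel]) / np.sum(w)
    return float(2**f)


def tmm_factors(
    counts: pd.DataFrame,
    variant: str = "TMM",
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """TMM or TMMwsp size factors, rescaled to geometric mean 1."""
    if variant not in ("TMM", "TMMwsp"):
        raise ValueError(f"unknown TMM variant {variant!r}")
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("all-zero sample in count matrix")
    if variant == "TMM":
        f75 = np.array(
            [np.quantile(mat[:, j], 0.75) / libs[j] for j in range(mat.shape[1])]
        )
        if np.median(f75) < 1e-20:
            ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))
        else:
            ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        pair = _tmm_pair
    else:
        ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))
        pair = _tmmwsp_pair
    factors = np.array(
        [
            pair(mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx], logratio_trim, sum_trim)
            for j in range(mat.shape[1])
        ]
    )
    return pd.Series(_rescale_geomean(factors), index=counts.columns, name=variant)


def rle_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (relative log expression) size factors, geomean 1."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.mean(np.log(mat), axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no feature with positive counts in every sample")
    ratios = np.log(mat[usable]) - log_geo[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(_rescale_geomean(factors), index=counts.columns, name="RLE")


def rle_plot_stats(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample quartiles of feature-median-centred log expression."""
    centred = log_expr.sub(log_expr.median(axis=1), axis=0)
    q = centred.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    q.index = ["min", "q1", "median", "q3", "max"]
    return q.T


# ---------------------------------------------------------------------------
# Biotype summaries
# ---------------------------------------------------------------------------


@dataclass
class BiotypeSummary:
    genome_pct: pd.Series  # biotype share of the annotation universe
    detected_pct_of_biotype: pd.DataFrame  # per sample
    within_sample_pct: pd.DataFrame  # per sample, sums to 100
    detected_n: pd.DataFrame
    count_quartiles: pd.DataFrame  # per (sample, biotype) count distribution


def biodetection(
    counts: pd.DataFrame,
    biotype_map: dict[str, str] | pd.Series,
    annotation_universe: dict[str, str] | pd.Series | None = None,
) -> BiotypeSummary:
    """Per-sample biotype detection summary.

    For every biotype and sample: its share of the annotation universe, the
    fraction of its features detected (count > 0), and its share among the
    sample's detected features (which sums to 100% within a sample).
    """
    biotype_map = pd.Series(dict(biotype_map) if isinstance(biotype_map, dict) else biotype_map)
    missing = set(counts.index) - set(biotype_map.index)
    if missing:
        raise ValueError(f"features without biotype: {sorted(missing)[:5]}")
    universe = (
        pd.Series(dict(annotation_universe))
        if isinstance(annotation_universe, dict)
        else (annotation_universe if annotation_universe is not None else biotype_map)
    )
    biotypes = sorted(universe.unique())
    genome_counts = universe.value_counts().reindex(biotypes).fillna(0)
    genome_pct = genome_counts / genome_counts.sum() * 100
    detected_pct = {}
    within_pct = {}
    detected_n = {}
    quart_rows = []
    fb = biotype_map.reindex(counts.index)
    for sample in counts.columns:
        det = counts[sample] > 0
        det_bt = fb[det].value_counts().reindex(biotypes).fillna(0)
        detected_n[sample] = det_bt
        denom = genome_counts.replace(0, np.nan)
        detected_pct[sample] = (det_bt / denom * 100).fillna(0.0)
        total_det = det_bt.sum()
        within_pct[sample] = det_bt / total_det * 100 if total_det else det_bt * 0.0
        for bt in biotypes:
            vals = counts.loc[(fb == bt) & det, sample]
            if len(vals):
                q = np.quantile(vals, [0.25, 0.5, 0.75])
            else:
                q = [np.nan] * 3
            quart_rows.append(
                {"sample": sample, "biotype": bt, "n": len(vals), "q1": q[0], "median": q[1], "q3": q[2]}
            )
    return BiotypeSummary(
        genome_pct=genome_pct,
        detected_pct_of_biotype=pd.DataFrame(detected_pct),
        within_sample_pct=pd.DataFrame(within_pct),
        detected_n=pd.DataFrame(detected_n),
        count_quartiles=pd.DataFrame(quart_rows),
    )


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------


def ordination(log_expr: pd.DataFrame, kind: str = "PCA", top: int = 500):
    """Two-dimensional sample coordinates.

    PCA: feature-centred, first two principal components via SVD, with the
    explained-variance fractions.  MDS: classical scaling of pairwise
    distances, where each pair's distance is the root-mean-square of its
    ``top`` largest squared log-ratios (the standard top-feature MDS used for
    expression QC).
    """
    if log_expr.shape[1] < 3:
        raise ValueError("ordination needs at least 3 samples")
    X = log_expr.to_numpy(dtype=float).T  # samples x features
    samples = log_expr.columns
    if kind == "PCA":
        Xc = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        coords = U[:, :2] * S[:2]
        var = S**2 / max(X.shape[0] - 1, 1)
        explained = var[:2] / var.sum()
        return pd.DataFrame(coords, index=samples, columns=["PC1", "PC2"]), explained
    if kind == "MDS":
        n = X.shape[0]
        D = np.zeros((n, n))
        top_n = min(top, X.shape[1])
        for i in range(n):
            for j in range(i + 1, n):
                sq = (X[i] - X[j]) ** 2
                worst = np.sort(sq)[-top_n:]
                D[i, j] = D[j, i] = np.sqrt(worst.mean())
        # classical MDS (Torgerson double centring)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][:2]
        coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
        return pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"]), None
    raise ValueError(f"unknown ordination kind {kind!r}")


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    cophenetic: pd.DataFrame
    correlation: pd.DataFrame


def cluster_samples(log_expr: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Hierarchical clustering of samples on Euclidean distances.

    ``method`` is one of ward / complete / average.  The Pearson sample
    correlation matrix is returned alongside for the heatmap output.
    """
    if method not in ("ward", "complete", "average"):
        raise ValueError(f"unknown linkage {method!r}")
    X = log_expr.to_numpy(dtype=float).T
    samples = list(log_expr.columns)
    d = pdist(X, metric="euclidean")
    Z = linkage(d, method=method)
    coph = squareform(cophenet(Z, d)[1])
    corr = pd.DataFrame(np.corrcoef(X), index=samples, columns=samples)
    return ClusterResult(
        linkage_matrix=Z,
        leaf_order=[samples[i] for i in leaves_list(Z)],
        cophenetic=pd.DataFrame(coph, index=samples, columns=samples),
        correlation=corr,
    )
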