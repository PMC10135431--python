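"""Normalization and quality control for paired total/polysome count data.

The workflow mirrors standard bulk RNA-seq practice: a depth-anchored
low-abundance filter, trimmed-mean-of-M-values (TMM) scaling factors, log2
counts-per-million with a pseudocount, correlation-based outlier flagging
within each fraction, a location-scale empirical-Bayes batch adjustment, and
PCA for visual QC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import moderate_variances  # noqa: F401  (re-exported for pipelines)

__all__ = [
    "compute_cpm",
    "log2_cpm",
    "filter_low_abundance",
    "tmm_factors",
    "detect_outliers",
    "batch_adjust",
    "pca",
]

#: reads anchoring the abundance filter: the threshold is the CPM one read
#: would have in a library of this depth
FILTER_ANCHOR_READS = 8e6

LOG2_PSEUDOCOUNT = 0.5


def compute_cpm(counts: pd.DataFrame, tmm: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: counts / (library size x TMM factor) x 1e6.

    With ``tmm`` absent all factors are 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    if tmm is None:
        tmm = pd.Series(1.0, index=counts.columns)
    eff = lib * tmm.reindex(counts.columns)
    return counts.div(eff, axis=1) * 1e6


def log2_cpm(counts: pd.DataFrame, tmm: pd.Series | None = None) -> pd.DataFrame:
    """log2(CPM + 0.5); the pseudocount keeps zero counts finite."""
    return np.log2(compute_cpm(counts, tmm) + LOG2_PSEUDOCOUNT)


def filter_low_abundance(
    total_counts: pd.DataFrame,
    polysome_counts: pd.DataFrame,
    min_samples: int = 4,
) -> tuple[list, float]:
    """Keep genes exceeding a depth-anchored CPM threshold in enough samples.

    The threshold ``N`` is the median over *all* samples (both fractions) of
    ``8e6 / library_size``, i.e. the CPM corresponding to a fixed read count
    at the nominal sequencing depth.  A gene is kept iff its plain CPM is
    >= N in at least ``min_samples`` total samples OR at least
    ``min_samples`` polysome samples.  Returns (kept gene ids, N).
    """
    if not total_counts.index.equals(polysome_counts.index):
        raise ValueError("total and polysome matrices must share the gene index")
    if total_counts.shape[1] < min_samples and polysome_counts.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples in one fraction")
    lib = pd.concat([total_counts.sum(axis=0), polysome_counts.sum(axis=0)])
    n_threshold = float(np.median(FILTER_ANCHOR_READS / lib.astype(float)))
    keep = pd.Series(False, index=total_counts.index)
    for counts in (total_counts, polysome_counts):
        if counts.shape[1] == 0:
            continue
        cpm = compute_cpm(counts)
        keep |= (cpm >= n_threshold).sum(axis=1) >= min_samples
    return keep.index[keep].tolist(), n_threshold


def _upper_quartile_depth(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    return np.quantile(counts / lib, 0.75, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    reference: str = "auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson & Oshlack).

    For each sample vs. the reference: genes zero in either are dropped,
    M (log2 expression ratio) and A (average log abundance) are computed on
    depth-normalized counts, the most extreme ``trim_m`` of M and ``trim_a``
    of A are trimmed from each tail, and the factor is 2 to the
    precision-weighted mean of the remaining M values (weights = inverse
    asymptotic binomial variance).  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if reference == "auto":
        uq = _upper_quartile_depth(x, lib)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)
    ref, ref_lib = x[:, ref_idx], lib[ref_idx]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs, obs_lib = x[:, j], lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no nonzero genes with the reference"
            )
        o, r = obs[ok], ref[ok]
        m = np.log2((o / obs_lib) / (r / ref_lib))
        a = 0.5 * np.log2((o / obs_lib) * (r / ref_lib))
        w = (obs_lib - o) / (obs_lib * o) + (ref_lib - r) / (ref_lib * r)
        n = m.size
        # double trim by rank, keeping the central band of both M and A
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            factors[j] = 1.0
            continue
        with np.errstate(divide="ignore"):
            inv_var = 1.0 / w[keep]
        factors[j] = 2.0 ** (np.sum(m[keep] * inv_var) / np.sum(inv_var))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def average_pairwise_correlation(log2cpm: pd.DataFrame) -> pd.Series:
    """Mean Pearson correlation of each sample to the others in the matrix."""
    x = log2cpm.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = log2cpm.columns[sd == 0].tolist()
        raise ValueError(f"constant sample vector(s), correlation undefined: {bad}")
    corr = np.corrcoef(x, rowvar=False)
    n = corr.shape[0]
    mean_r = (corr.sum(axis=1) - 1.0) / (n - 1)
    return pd.Series(mean_r, index=log2cpm.columns, name="mean_pairwise_r")


def detect_outliers(log2cpm: pd.DataFrame, set_label: pd.Series) -> list:
    """Flag samples whose average within-set correlation falls more than
    1.5 IQR below the first quartile of their set's averages.

    ``set_label`` maps each sample to its fraction ("total"/"polysome").
    Quartiles use linear interpolation between order statistics (type 7).
    A single pass; no iterative re-flagging.
    """
    flagged = []
    for label in pd.unique(set_label):
        cols = set_label.index[set_label == label]
        if len(cols) < 4:
            raise ValueError(f"set {label!r} has fewer than 4 samples")
        mean_r = average_pairwise_correlation(log2cpm[cols])
        q1, q3 = np.percentile(mean_r, [25, 75])
        cutoff = q1 - 1.5 * (q3 - q1)
        flagged.extend(mean_r.index[mean_r < cutoff].tolist())
    return flagged


def _group_design(groups: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(groups))
    x = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    return x, levels


def batch_adjust(
    log2cpm: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.Series,
) -> pd.DataFrame:
    """Remove additive/multiplicative batch structure while preserving
    group means.

    Per gene, batch location and scale offsets are estimated from residuals
    after removing the ``covariates`` (age-group) means, shrunk toward their
    across-gene average with precision weights (an empirical-Bayes-style
    location-scale adjustment), then subtracted/rescaled.  Refuses designs
    where batch is confounded with the covariate groups.
    """
    batch = batch.reindex(log2cpm.columns)
    covariates = covariates.reindex(log2cpm.columns)
    batches = list(pd.unique(batch))
    if len(batches) == 1:
        return log2cpm.copy()
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch must contain at least 2 samples")

    x_grp, _ = _group_design(covariates)
    x_batch = np.column_stack([(batch == b).to_numpy(float) for b in batches[1:]])
    full = np.column_stack([x_grp, x_batch])
    expected_rank = x_grp.shape[1] + len(batches) - 1
    if np.linalg.matrix_rank(full) < expected_rank:
        raise ValueError("batch is confounded with the covariate groups")

    y = log2cpm.to_numpy(dtype=float)
    # residuals after removing group means
    fitted = np.zeros_like(y)
    for lv in pd.unique(covariates):
        cols = (covariates == lv).to_numpy()
        fitted[:, cols] = y[:, cols].mean(axis=1, keepdims=True)
    resid = y - fitted
    pooled_var = resid.var(axis=1, ddof=x_grp.shape[1])
    pooled_var = np.maximum(pooled_var, 1e-12)

    adj = resid.copy()
    n_genes = y.shape[0]
    delta_star = np.zeros((n_genes, len(batches)))
    scale_star = np.ones((n_genes, len(batches)))
    n_b = np.zeros(len(batches))
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        n_b[bi] = cols.sum()
        d = resid[:, cols].mean(axis=1)
        # location shrinkage: precision-weighted toward the across-gene mean
        noise_var = pooled_var / n_b[bi]
        tau2 = max(d.var() - noise_var.mean(), 0.0)
        lam = tau2 / (tau2 + noise_var)
        delta_star[:, bi] = lam * d + (1.0 - lam) * d.mean()
        if n_b[bi] >= 3:
            s2_b = resid[:, cols].var(axis=1, ddof=1)
            with np.errstate(divide="ignore"):
                logr = np.log(np.maximum(s2_b, 1e-12) / pooled_var)
            from scipy.special import polygamma

            chi_var = float(polygamma(1, (n_b[bi] - 1) / 2.0))
            tau2_s = max(np.var(logr) - chi_var, 0.0)
            lam_s = tau2_s / (tau2_s + chi_var)
            scale_star[:, bi] = np.sqrt(np.exp(lam_s * logr))
    # keep the overall (sample-weighted) location shift at zero so group
    # means are preserved up to batch/group imbalance
    delta_star -= (delta_star * n_b).sum(axis=1, keepdims=True) / n_b.sum()
    for bi, b in enumerate(batches):
        cols = (batch == b).to_numpy()
        adj[:, cols] = (resid[:, cols] - delta_star[:, [bi]]) / scale_star[:, [bi]]
    return pd.DataFrame(fitted + adj, index=log2cpm.index, columns=log2cpm.columns)


def pca(log2cpm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a gene x sample matrix.

    Genes are centered across samples; scores come from the SVD of the
    centered sample x gene matrix.  Returns (scores, variance fractions).
    """
    if log2cpm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = log2cpm.to_numpy(dtype=float)
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    total = np.sum(s**2)
    var_frac = (s**2 / total) if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=log2cpm.columns, columns=cols), var_frac
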