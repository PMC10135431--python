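"""Regulatory-mode classification from paired total/polysome data.

Per gene and pairwise age contrast, an analysis of partial variance (APV,
a per-gene ANCOVA) regresses polysome-associated expression on total
expression plus a group indicator; the indicator coefficient gamma is the
translational effect not explained by transcript abundance.  Swapping
response and covariate gives the buffering effect gamma_b (total change not
propagated to polysomes).  Significance uses the same empirical-Bayes
moderated-t machinery as the differential expression module, and genes are
assigned one of four modes per contrast:

* ``translation`` — polysome change beyond what total explains,
* ``buffering``   — total change not reflected in polysomes,
* ``abundance``   — congruent, same-sign change in both fractions,
* ``none``        — nothing passes.

Priority when several rules fire: translation > buffering > abundance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_ALPHA, DEFAULT_MIN_ABS_FC, fit_gene_models, test_contrast
from .stats import bh_adjust, moderate_variances, moderated_t_pvalues

__all__ = ["apv_fit", "classify_modes", "fit_regulatory", "summarize_modes"]

MODES = ("abundance", "translation", "buffering", "none")


def _paired_columns(samples: pd.DataFrame, contrast: tuple[int, int]):
    """Sample ids (total, polysome) for subjects with both fractions in the
    two contrast groups, plus the group indicator per subject."""
    age_b, age_a = int(contrast[0]), int(contrast[1])
    sub = samples[samples["age_months"].isin([age_a, age_b])]
    total_cols, poly_cols, indicator = [], [], []
    for subject, grp in sub.groupby("subject_id", sort=True):
        fr = grp.set_index("fraction")["sample_id"]
        if "total" not in fr.index or "polysome" not in fr.index:
            raise ValueError(f"subject {subject!r} lacks a matched fraction")
        total_cols.append(fr["total"])
        poly_cols.append(fr["polysome"])
        indicator.append(1.0 if int(grp["age_months"].iloc[0]) == age_b else 0.0)
    ind = np.asarray(indicator)
    if ind.min() == ind.max():
        raise ValueError("contrast needs subjects from both groups")
    return total_cols, poly_cols, ind


def apv_fit(
    total_log2cpm: pd.DataFrame,
    polysome_log2cpm: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[int, int],
    direction: str = "translation",
) -> pd.DataFrame:
    """Per-gene APV effect and moderated p for one direction of one contrast.

    ``translation``: response = polysome, covariate = total.
    ``buffering``: response = total, covariate = polysome.
    """
    if direction not in ("translation", "buffering"):
        raise ValueError(f"unknown direction {direction!r}")
    total_cols, poly_cols, ind = _paired_columns(samples, contrast)
    t_mat = total_log2cpm[total_cols].to_numpy(dtype=float)
    p_mat = polysome_log2cpm[poly_cols].to_numpy(dtype=float)
    if direction == "translation":
        resp, covar = p_mat, t_mat
    else:
        resp, covar = t_mat, p_mat

    n = ind.size
    df = n - 3
    if df < 1:
        raise ValueError("too few paired subjects for the APV regression")
    n_genes = resp.shape[0]
    gamma = np.zeros(n_genes)
    beta = np.zeros(n_genes)
    unit = np.full(n_genes, np.nan)
    s2 = np.full(n_genes, np.nan)
    ones = np.ones(n)
    for g in range(n_genes):
        x = np.column_stack([ones, covar[g], ind])
        xtx = x.T @ x
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            continue  # constant covariate; gamma stays 0, p becomes 1
        b = xtx_inv @ (x.T @ resp[g])
        r = resp[g] - x @ b
        beta[g] = b[1]
        gamma[g] = b[2]
        s2[g] = float(r @ r) / df
        unit[g] = np.sqrt(xtx_inv[2, 2])

    ok = np.isfinite(s2)
    s2_tilde = np.full(n_genes, np.nan)
    if ok.any():
        s2_tilde[ok], d0, _ = moderate_variances(s2[ok], df)
    else:
        d0 = np.inf
    total_df = df + (d0 if np.isfinite(d0) else 1e9)
    p = np.ones(n_genes)
    t = np.zeros(n_genes)
    if ok.any():
        t[ok], p[ok] = moderated_t_pvalues(gamma[ok], unit[ok], s2_tilde[ok], total_df)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": total_log2cpm.index,
            "contrast": f"{contrast[0]}v{contrast[1]}",
            "direction": direction,
            "effect": gamma,
            "slope": beta,
            "p": p,
            "q": q,
        }
    ).set_index("gene")


def classify_modes(
    apv_translation: pd.DataFrame,
    apv_buffering: pd.DataFrame,
    de_total: pd.DataFrame,
    de_polysome: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_eff: float = DEFAULT_MIN_ABS_FC,
) -> pd.DataFrame:
    """Assign one regulatory mode per gene for one contrast.

    translation iff q(gamma) < alpha and |gamma| > min_eff and the polysome
    change itself is selected (q(dP) < alpha and |dP| > min_eff); else
    buffering iff the mirror holds for gamma_b and dT; else abundance iff dT
    and dP are each significant with the same sign; else none.  Requiring the
    marginal change to be significant — not merely large — mirrors how
    translational-efficiency analyses define the translation and buffering
    groups (a translation call is a *selected* polysome change unexplained by
    total mRNA) and keeps noisy marginal estimates from flipping buffering
    genes into translation calls.
    """
    genes = apv_translation.index
    dt = de_total.loc[genes, "log2fc"].to_numpy()
    dp = de_polysome.loc[genes, "log2fc"].to_numpy()
    qt = de_total.loc[genes, "q"].to_numpy()
    qp = de_polysome.loc[genes, "q"].to_numpy()
    gam = apv_translation["effect"].to_numpy()
    q_gam = apv_translation["q"].to_numpy()
    gam_b = apv_buffering.loc[genes, "effect"].to_numpy()
    q_gam_b = apv_buffering.loc[genes, "q"].to_numpy()

    is_trans = (
        (q_gam < alpha) & (np.abs(gam) > min_eff) & (qp < alpha) & (np.abs(dp) > min_eff)
    )
    is_buff = (
        (q_gam_b < alpha) & (np.abs(gam_b) > min_eff) & (qt < alpha) & (np.abs(dt) > min_eff)
    )
    is_abund = (
        (qt < alpha)
        & (np.abs(dt) > min_eff)
        & (qp < alpha)
        & (np.abs(dp) > min_eff)
        & (np.sign(dt) == np.sign(dp))
    )
    mode = np.where(is_trans, "translation", np.where(is_buff, "buffering",
                    np.where(is_abund, "abundance", "none")))
    return pd.DataFrame(
        {
            "gene": genes,
            "contrast": apv_translation["contrast"].iloc[0] if len(apv_translation) else "",
            "mode": mode,
            "delta_total": dt,
            "delta_polysome": dp,
            "gamma": gam,
            "gamma_b": gam_b,
            "q_gamma": q_gam,
            "q_gamma_b": q_gam_b,
            "q_total": qt,
            "q_polysome": qp,
        }
    ).set_index("gene")


def fit_regulatory(
    total_log2cpm: pd.DataFrame,
    polysome_log2cpm: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts,
    alpha: float = DEFAULT_ALPHA,
    min_eff: float = DEFAULT_MIN_ABS_FC,
) -> pd.DataFrame:
    """Run APV (both directions) + per-fraction DE and classify every
    contrast; returns the concatenated calls table."""
    # contrasts use only subjects with both fractions present (attrition may
    # have removed one of a pair)
    n_fr = samples.groupby("subject_id")["fraction"].nunique()
    paired = set(n_fr.index[n_fr == 2])
    dropped = sorted(set(samples["subject_id"]) - paired)
    if dropped:
        logging.getLogger(__name__).warning("dropping unpaired subjects: %s", dropped)
    samples = samples[samples["subject_id"].isin(paired)]
    total_log2cpm = total_log2cpm[
        [c for c in total_log2cpm.columns if c in set(samples.index)]
    ]
    polysome_log2cpm = polysome_log2cpm[
        [c for c in polysome_log2cpm.columns if c in set(samples.index)]
    ]
    meta_t = samples[samples["fraction"] == "total"]
    meta_p = samples[samples["fraction"] == "polysome"]
    fits_t = fit_gene_models(total_log2cpm[meta_t["sample_id"]], meta_t)
    fits_p = fit_gene_models(polysome_log2cpm[meta_p["sample_id"]], meta_p)
    calls = []
    for contrast in contrasts:
        de_t = test_contrast(fits_t, contrast)
        de_p = test_contrast(fits_p, contrast)
        apv_t = apv_fit(total_log2cpm, polysome_log2cpm, samples, contrast, "translation")
        apv_b = apv_fit(total_log2cpm, polysome_log2cpm, samples, contrast, "buffering")
        calls.append(classify_modes(apv_t, apv_b, de_t, de_p, alpha, min_eff))
    return pd.concat(calls)


def summarize_modes(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-contrast mode counts and the cross-contrast multi-mode flag.

    A gene is multi-mode when it is assigned >= 2 distinct non-none modes
    across contrasts.
    """
    if len(calls) == 0:
        counts = pd.DataFrame(columns=list(MODES))
        return counts, pd.Series(dtype=bool)
    counts = (
        calls.reset_index()
        .groupby(["contrast", "mode"])["gene"]
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(MODES), fill_value=0)
    )
    non_none = calls[calls["mode"] != "none"]
    n_modes = non_none.groupby(level=0)["mode"].nunique()
    multi = n_modes >= 2
    return counts, multi
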