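"""Female-bias and ovary-dominance statistics for sex-linked genes.

Tests whether genes retained on a female-specific W chromosome were already
female-serving before sex linkage (using an outgroup where the homologs are
autosomal as a proxy for ancestral expression), and compares the expression
profile of W gametologs against their Z partners in females.

Expression units are TPM throughout; replicate averaging (arithmetic mean)
is assumed to have happened before any ratio is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genecontent import fisher_exact_2x2

TISSUES = ("brain", "heart", "kidney", "liver", "gonad")
MIN_TPM = 1.0
FOLD_CHANGE = 2.0
OVARY_THRESHOLD = 0.20


@dataclass(frozen=True)
class BiasCall:
    gene_id: str
    tissue: str
    f_over_m: float
    female_biased: bool


def filter_expressed(
    df: pd.DataFrame, columns, min_tpm: float = MIN_TPM
) -> pd.DataFrame:
    """Drop genes with zero or very low expression (TPM < 1) in any of the
    given columns. Applied per comparison: a gene may pass in one tissue
    and fail in another."""
    keep = (df[list(columns)] >= min_tpm).all(axis=1)
    return df[keep]


def female_bias_call(
    gene_id: str, tissue: str, f_tpm: float, m_tpm: float, fold: float = FOLD_CHANGE
) -> BiasCall:
    """Female-biased iff the F/M ratio strictly exceeds the fold cutoff (2)."""
    if m_tpm <= 0:
        raise ValueError("m_tpm must be positive after low-expression filtering")
    ratio = f_tpm / m_tpm
    return BiasCall(gene_id, tissue, ratio, ratio > fold)


def call_female_bias(
    df: pd.DataFrame, tissues=TISSUES, min_tpm: float = MIN_TPM, fold: float = FOLD_CHANGE
) -> list[BiasCall]:
    """Per-tissue female-bias calls over a TPM matrix with tissue_sex columns."""
    calls = []
    for t in tissues:
        f_col, m_col = f"{t}_F", f"{t}_M"
        sub = filter_expressed(df, [f_col, m_col], min_tpm)
        for gid, row in sub.iterrows():
            calls.append(female_bias_call(gid, t, row[f_col], row[m_col], fold))
    return calls


def ovary_dominance(
    tpm_row: pd.Series,
    threshold: float = OVARY_THRESHOLD,
    denominator: str = "other",
    ovary_column: str = "gonad_F",
) -> tuple[float, bool]:
    """R_ovary = E_ovary / sum(E_other_tissue); dominant iff strictly > 20%.

    ``denominator='other'`` excludes the ovary itself from the sum (the
    default, following the formula's other-tissue subscript);
    ``denominator='all'`` includes it. A zero denominator yields r = nan,
    reported not-dominant.
    """
    e_ovary = float(tpm_row[ovary_column])
    total = float(tpm_row.sum())
    denom = total if denominator == "all" else total - e_ovary
    if denominator not in ("other", "all"):
        raise ValueError("denominator must be 'other' or 'all'")
    if denom <= 0:
        return float("nan"), False
    r = e_ovary / denom
    return r, r > threshold


def gametolog_profile_compare(
    z_row: pd.Series, w_row: pd.Series, tissues=TISSUES
) -> tuple[pd.DataFrame, float, float]:
    """Compare female expression profiles of a Z/W gametolog pair.

    Transforms TPM with log1p, returns (per-tissue log1p table, Spearman
    rho of the female profiles, ratio of summed W to summed Z female TPM).
    W gametologs are expressed only in females, so only female columns are
    compared. rho is nan when either profile is constant (e.g. W all-zero).
    """
    f_cols = [f"{t}_F" for t in tissues]
    z_f = z_row[f_cols].astype(float)
    w_f = w_row[f_cols].astype(float)
    table = pd.DataFrame(
        {"Z_log1p": np.log1p(z_f), "W_log1p": np.log1p(w_f)}, index=f_cols
    )
    z_total = float(z_f.sum())
    ratio = float(w_f.sum()) / z_total if z_total > 0 else float("nan")
    if w_f.nunique() <= 1 or z_f.nunique() <= 1:
        rho = float("nan")
    else:
        rz = stats.rankdata(np.log1p(z_f))
        rw = stats.rankdata(np.log1p(w_f))
        n = rz.size
        if np.unique(rz).size == n and np.unique(rw).size == n:
            # classic untied formula; exact (rho = 1.0, not 1 - eps, for equal ranks)
            rho = float(1 - 6 * ((rz - rw) ** 2).sum() / (n * (n * n - 1)))
        else:
            rho = float(stats.pearsonr(rz, rw).statistic)
    return table, rho, ratio


def feminization_enrichment(
    bias_calls, status: dict, tissues=TISSUES
) -> dict:
    """Per-tissue Fisher test: are retained genes more often female-biased?

    2x2 of (retained/lost) x (biased/unbiased) per tissue; a tissue with no
    biased genes at all reports p = 1 with a notice.
    """
    out = {}
    for t in tissues:
        a = b = c = d = 0
        for call in bias_calls:
            if call.tissue != t or call.gene_id not in status:
                continue
            retained = status[call.gene_id] == "retained"
            if retained and call.female_biased:
                a += 1
            elif retained:
                b += 1
            elif call.female_biased:
                c += 1
            else:
                d += 1
        if a + b + c + d == 0:
            out[t] = {"skipped": "no classifiable genes"}
        elif a + c == 0:
            out[t] = {"table": [[a, b], [c, d]], "p": 1.0, "notice": "no biased genes"}
        else:
            out[t] = {"table": [[a, b], [c, d]], "p": fisher_exact_2x2([[a, b], [c, d]])}
    return out


def mean_over_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average tissue_sex_replicate columns down to tissue_sex columns."""
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        parts = col.split("_")
        key = "_".join(parts[:2]) if len(parts) >= 2 else col
        groups.setdefault(key, []).append(col)
    return pd.DataFrame({k: df[cols].mean(axis=1) for k, cols in groups.items()})
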