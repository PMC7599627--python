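"""Retained W-gametolog gene content: conservation, dosage, enrichment.

On a degenerating W chromosome, genes survive non-randomly: purifying
selection preferentially keeps dosage-sensitive and highly expressed genes,
especially where dosage compensation is absent (as in birds). This module
classifies W-linked gametologs by cross-lineage conservation, predicted
haploinsufficiency and expression level, and tests whether retained genes
are enriched for those classes with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("songbirds", "chicken", "ratites", "tinamous")

HI_THRESHOLD = 0.4  # haploinsufficiency score above which a gene is dosage sensitive
TPM_HIGH = 50.0  # mean TPM above which a gene counts as highly expressed


@dataclass
class GametologRecord:
    gene_id: str
    stratum: str  # S0, S1 or S2
    presence: dict  # group name -> bool (W copy present in that group)
    presence_fraction: float | None = None  # fraction of surveyed species with a W copy
    hi_score: float | None = None
    mean_tpm: float | None = None
    status: str = "lost"  # retained | lost

    def __post_init__(self) -> None:
        if self.presence_fraction is not None and not 0 <= self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in [0, 1]")


def conservation_call(presence: dict) -> str:
    """'conserved' when the W copy is shared by >= 2 bird groups."""
    n = sum(bool(presence.get(g, False)) for g in GROUPS)
    return "conserved" if n >= 2 else "non_conserved"


def dosage_class(hi_score: float | None) -> str | None:
    """'sensitive' when HI score strictly exceeds 0.4; None when no score."""
    if hi_score is None or (isinstance(hi_score, float) and math.isnan(hi_score)):
        return None
    if not 0 <= hi_score <= 1:
        raise ValueError("hi_score must be in [0, 1]")
    return "sensitive" if hi_score > HI_THRESHOLD else "insensitive"


def expression_class(mean_tpm: float) -> str:
    """'high' when mean TPM strictly exceeds 50."""
    if mean_tpm < 0:
        raise ValueError("mean_tpm must be non-negative")
    return "high" if mean_tpm > TPM_HIGH else "low"


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, by exact enumeration.

    With margins fixed, sums the hypergeometric probability of every table
    whose probability does not exceed that of the observed one (the
    probability-mass rule used by mainstream statistics packages). Computed
    in exact integer arithmetic; only the final ratio is floating point.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, r2, c1 = a + b, c + d, a + c
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= obs:
            total += w
    return total / math.comb(n, c1)


def presence_hi_correlation(records) -> tuple[float, float]:
    """Pearson r between species-presence fraction and HI score.

    p-value is two-sided from the t transform with n-2 df. Returns
    (nan, nan) when either variable has zero variance.
    """
    pairs = [
        (r.presence_fraction, r.hi_score)
        for r in records
        if r.presence_fraction is not None and dosage_class(r.hi_score) is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 records with presence_fraction and hi_score")
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _contingency(records, class_fn, positive) -> list[list[int]]:
    a = b = c = d = 0
    for r in records:
        cls = class_fn(r)
        if cls is None:
            continue
        if r.status == "retained":
            if cls == positive:
                a += 1
            else:
                b += 1
        else:
            if cls == positive:
                c += 1
            else:
                d += 1
    return [[a, b], [c, d]]


def enrichment_report(
    records,
    strata_filter: tuple[str, ...] = ("S0", "S1"),
    exclude_nonconserved_s1: bool = False,
) -> dict:
    """Fisher enrichment of dosage-sensitive / highly expressed genes
    among retained vs lost gametologs, per stratum subset and pooled.

    ``exclude_nonconserved_s1`` drops retained-but-non-conserved S1 genes:
    they sit in a young stratum and have not had time to be lost, so they
    dilute the purifying-selection signal.
    """
    recs = [r for r in records if r.stratum in strata_filter]
    if exclude_nonconserved_s1:
        recs = [
            r
            for r in recs
            if not (
                r.stratum == "S1"
                and r.status == "retained"
                and conservation_call(r.presence) == "non_conserved"
            )
        ]
    subsets = {"pooled": recs}
    for s in strata_filter:
        subsets[s] = [r for r in recs if r.stratum == s]
    contrasts = {
        "dosage": (lambda r: dosage_class(r.hi_score), "sensitive"),
        "expression": (
            lambda r: expression_class(r.mean_tpm) if r.mean_tpm is not None else None,
            "high",
        ),
    }
    report: dict = {}
    for sub_name, sub in subsets.items():
        report[sub_name] = {}
        for con_name, (fn, positive) in contrasts.items():
            if not sub:
                report[sub_name][con_name] = {"skipped": "empty stratum subset"}
                continue
            tbl = _contingency(sub, fn, positive)
            if sum(map(sum, tbl)) == 0:
                report[sub_name][con_name] = {"skipped": "no classifiable genes"}
                continue
            report[sub_name][con_name] = {
                "table": tbl,
                "p": fisher_exact_2x2(tbl),
            }
    return report


def records_from_frame(df: pd.DataFrame) -> list[GametologRecord]:
    """Build records from a gene table (one row per gametolog).

    Expected columns: gene_id, stratum, one boolean column per group in
    GROUPS, and optionally presence_fraction, hi_score, mean_tpm, status.
    """
    records = []
    for _, row in df.iterrows():
        presence = {g: bool(row[g]) for g in GROUPS if g in row}
        status = row.get("status")
        if status is None or (isinstance(status, float) and math.isnan(status)):
            status = "retained" if any(presence.values()) else "lost"
        records.append(
            GametologRecord(
                gene_id=row["gene_id"],
                stratum=row["stratum"],
                presence=presence,
                presence_fraction=_opt(row.get("presence_fraction")),
                hi_score=_opt(row.get("hi_score")),
                mean_tpm=_opt(row.get("mean_tpm")),
                status=status,
            )
        )
    return records


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)
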