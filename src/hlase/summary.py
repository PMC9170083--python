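"""Descriptive summaries of allelic expression: locus means, allelic
fold-variation ratios and cytokine-stimulation fold-upregulation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _one_condition(expr: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = expr[expr["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no records for condition {condition!r}")
    return sub


def locus_summary(expr: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Arithmetic mean and sample SD of tpm over all allele records per
    locus (each allele copy of each individual is one record)."""
    sub = _one_condition(expr, condition)
    out = (sub.groupby("locus")["tpm"]
              .agg(mean_tpm="mean", sd_tpm=lambda s: s.std(ddof=1), n="size")
              .reset_index())
    out["sd_tpm"] = out["sd_tpm"].fillna(0.0)
    return out


def fold_variation(expr: pd.DataFrame, condition: str,
                   statistic: str = "mean") -> pd.DataFrame:
    """Max-to-min ratio of per-allele central tpm values per locus.

    statistic selects the per-allele central value (mean or median over
    carriers).  Alleles carried by a single record are kept but flagged
    low-support; the ratio is >= 1 by construction.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    sub = _one_condition(expr, condition)
    rows = []
    for locus, grp in sub.groupby("locus"):
        per_allele = grp.groupby("allele")["tpm"].agg(statistic)
        if len(per_allele) < 2:
            raise ValueError(f"need >=2 allele names at locus {locus!r}")
        support = grp.groupby("allele").size()
        top, bottom = per_allele.idxmax(), per_allele.idxmin()
        rows.append({
            "locus": locus,
            "statistic": statistic,
            "max_ratio": float(per_allele.max() / per_allele.min()),
            "top_allele": top,
            "bottom_allele": bottom,
            "low_support": bool(support[top] == 1 or support[bottom] == 1),
        })
    return pd.DataFrame(rows)


def fold_upregulation(expr_unstim: pd.DataFrame, expr_stim: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Stimulation fold-change, paired per allele record.

    fold = tpm_stim / tpm_unstim for each record matched on (sample, locus,
    allele, copy).  Returns (per-allele table with mean and median fold,
    per-locus table with mean fold and the Spearman rho between paired stim
    and unstim tpm, number of unpaired records dropped).  Mean fold is the
    mean of per-record ratios, not the ratio of means.
    """
    key = ["sample_id", "locus", "allele", "copy"]
    u = expr_unstim[expr_unstim["condition"] != "stim"][key + ["tpm"]]
    s = expr_stim[expr_stim["condition"] == "stim"][key + ["tpm"]]
    merged = u.merge(s, on=key, how="outer", suffixes=("_unstim", "_stim"),
                     indicator=True)
    n_dropped = int((merged["_merge"] != "both").sum())
    if n_dropped:
        log.warning("fold_upregulation: dropped %d unpaired record(s)", n_dropped)
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged["fold"] = merged["tpm_stim"] / merged["tpm_unstim"]

    per_allele = (merged.groupby(["locus", "allele"])["fold"]
                        .agg(mean_fold="mean", median_fold="median", n="size")
                        .reset_index())
    per_allele["low_support"] = per_allele["n"] == 1

    rows = []
    for locus, grp in merged.groupby("locus"):
        if len(grp) < 2 or grp["tpm_unstim"].nunique() < 2 or grp["tpm_stim"].nunique() < 2:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(grp["tpm_unstim"], grp["tpm_stim"])
        rows.append({"locus": locus, "mean_fold": float(grp["fold"].mean()),
                     "median_fold": float(grp["fold"].median()),
                     "spearman_rho": float(rho), "spearman_p": float(p),
                     "n": len(grp)})
    return per_allele, pd.DataFrame(rows), n_dropped


def mfi_correlation(mfi_unstim, mfi_stim) -> tuple[float, float]:
    """Spearman correlation of an optional precomputed cell-surface MFI
    table between conditions (values paired by position)."""
    rho, p = stats.spearmanr(np.asarray(mfi_unstim), np.asarray(mfi_stim))
    return float(rho), float(p)
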