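"""Haplotype-level co-expression analysis.

Individuals are grouped by the common HLA-A~B~C~DRB1 haplotype they carry;
expression of the alleles riding on the shared haplotype is regressed
between locus pairs and contrasted against the same regression computed on
the alleles of each carrier's *other* haplotype.  A shared haplotype fixes
both the allele identities and any haplotype-level regulatory effect, so
its inter-locus regression is expected to be tighter (smaller residual
standard error) than the heterogeneous second-haplotype one.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEP = "~"


def haplotype_label(alleles: dict[str, str], loci) -> str:
    return SEP.join(alleles[l] for l in loci)


def parse_haplotype_label(label: str, loci) -> dict[str, str]:
    parts = label.split(SEP)
    if len(parts) != len(loci):
        raise ValueError(f"label {label!r} does not match loci {list(loci)}")
    return dict(zip(loci, parts))


@dataclass
class InterlocusFit:
    haplotype: str
    locus_x: str
    locus_y: str
    slope: float
    intercept: float
    residual_se: float
    n: int


def assign_haplotypes(typings: pd.DataFrame, reference: pd.DataFrame,
                      loci=("A", "B", "C", "DRB1")) -> pd.DataFrame:
    """Greedy haplotype decomposition against a reference table.

    typings: columns sample_id, locus, allele1, allele2.
    reference: one allele column per locus plus frequency.

    A reference haplotype is compatible when its allele at every locus can
    be taken from the individual's genotype (multiset semantics).  If the
    compatible set is a single haplotype — or exactly two that jointly
    exhaust the genotype — the individual is resolved: hap1 is the
    compatible reference haplotype (the more frequent one on ties) and
    hap2 the complementary allele set.  Otherwise unresolved.
    """
    loci = [l for l in loci if l in typings["locus"].unique()]
    ref = reference.sort_values("frequency", ascending=False).reset_index(drop=True)
    ref_sets = [{l: ref.loc[i, l] for l in loci} for i in ref.index]
    ref_labels = [haplotype_label(r, loci) for r in ref_sets]

    rows = []
    for sample, grp in typings.groupby("sample_id", sort=True):
        geno = {r["locus"]: Counter([r["allele1"], r["allele2"]])
                for _, r in grp.iterrows()}
        if set(geno) != set(loci):
            rows.append((sample, None, None, False))
            continue
        compatible = [i for i, r in enumerate(ref_sets)
                      if all(geno[l][r[l]] >= 1 for l in loci)]
        hap1 = hap2 = None
        resolved = False
        if len(compatible) == 1:
            i = compatible[0]
            hap1 = ref_labels[i]
            hap2 = SEP.join(_complement(geno[l], ref_sets[i][l]) for l in loci)
            resolved = True
        elif len(compatible) == 2:
            i, j = compatible
            jointly = all(
                Counter([ref_sets[i][l], ref_sets[j][l]]) == geno[l] for l in loci)
            if jointly:
                hap1, hap2, resolved = ref_labels[i], ref_labels[j], True
        rows.append((sample, hap1, hap2, resolved))
    return pd.DataFrame(rows, columns=["sample_id", "hap1", "hap2", "resolved"])


def _complement(counts: Counter, used: str) -> str:
    c = counts.copy()
    c[used] -= 1
    (allele,) = [a for a, k in c.items() for _ in range(k)]
    return allele


def _haplotype_expression(expr: pd.DataFrame, assignment: pd.DataFrame,
                          which: str, loci) -> pd.DataFrame:
    """Per-sample tpm of the allele carried on one haplotype per locus.

    Homozygous loci are skipped (attribution of tpm to a haplotype is
    ambiguous when both copies share the allele name).
    """
    rows = []
    sub = assignment[assignment["resolved"]]
    for _, r in sub.iterrows():
        hap = parse_haplotype_label(r[which], loci)
        other = parse_haplotype_label(r["hap2" if which == "hap1" else "hap1"], loci)
        e = expr[expr["sample_id"] == r["sample_id"]]
        for locus in loci:
            if locus not in e["locus"].values:
                continue  # e.g. DRB1 carries no class I expression records
            if hap[locus] == other[locus]:
                log.debug("skipping homozygous locus %s for %s", locus, r["sample_id"])
                continue
            rec = e[(e["locus"] == locus) & (e["allele"] == hap[locus])]
            if len(rec) != 1:
                continue
            rows.append((r["sample_id"], locus, float(rec["tpm"].iloc[0])))
    return pd.DataFrame(rows, columns=["sample_id", "locus", "tpm"])


def _ols_fit(x: np.ndarray, y: np.ndarray):
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    se = float(np.sqrt((resid @ resid) / (n - 2))) if n > 2 else 0.0
    return float(coef[1]), float(coef[0]), se


def interlocus_regression(expr: pd.DataFrame, assignment: pd.DataFrame,
                          haplotype_label_: str, locus_pair: tuple[str, str],
                          loci=("A", "B", "C", "DRB1")) -> InterlocusFit:
    """OLS of the locus-2 allele tpm on the locus-1 allele tpm across
    carriers of one haplotype, alleles restricted to that haplotype.
    Residual SE = sqrt(RSS/(n-2))."""
    lx, ly = locus_pair
    carriers = assignment[(assignment["resolved"]) &
                          ((assignment["hap1"] == haplotype_label_) |
                           (assignment["hap2"] == haplotype_label_))].copy()
    carriers["hap1"], carriers["hap2"] = (
        np.where(carriers["hap1"] == haplotype_label_, carriers["hap1"], carriers["hap2"]),
        np.where(carriers["hap1"] == haplotype_label_, carriers["hap2"], carriers["hap1"]),
    )
    he = _haplotype_expression(expr, carriers, "hap1", loci)
    wide = he.pivot(index="sample_id", columns="locus", values="tpm")
    if lx not in wide.columns or ly not in wide.columns:
        raise ValueError(f"fewer than 3 informative carriers for {locus_pair}")
    wide = wide[[lx, ly]].dropna()
    if len(wide) < 3:
        raise ValueError(f"fewer than 3 informative carriers for {locus_pair}")
    slope, intercept, se = _ols_fit(wide[lx].to_numpy(), wide[ly].to_numpy())
    return InterlocusFit(haplotype_label_, lx, ly, slope, intercept, se, len(wide))


def shared_vs_second_contrast(expr: pd.DataFrame, assignment: pd.DataFrame,
                              common_haplotype: str,
                              loci=("A", "B", "C", "DRB1"),
                              expr_loci=("A", "B", "C")) -> pd.DataFrame:
    """Residual SE of the inter-locus regression on the shared (common)
    haplotype vs on the carriers' second haplotypes, computed on the same
    individuals for every locus pair."""
    carriers = assignment[(assignment["resolved"]) &
                          ((assignment["hap1"] == common_haplotype) |
                           (assignment["hap2"] == common_haplotype))].copy()
    flip = carriers["hap1"] != common_haplotype
    carriers.loc[flip, ["hap1", "hap2"]] = carriers.loc[flip, ["hap2", "hap1"]].values
    common = _haplotype_expression(expr, carriers, "hap1", loci)
    second = _haplotype_expression(expr, carriers, "hap2", loci)

    rows = []
    for lx, ly in itertools.combinations(expr_loci, 2):
        wc = common.pivot(index="sample_id", columns="locus", values="tpm")
        ws = second.pivot(index="sample_id", columns="locus", values="tpm")
        if not {lx, ly} <= set(wc.columns) or not {lx, ly} <= set(ws.columns):
            continue
        shared_samples = wc[[lx, ly]].dropna().index.intersection(
            ws[[lx, ly]].dropna().index)
        if len(shared_samples) < 3:
            raise ValueError(f"fewer than 3 informative carriers for {(lx, ly)}")
        _, _, se_c = _ols_fit(wc.loc[shared_samples, lx].to_numpy(),
                              wc.loc[shared_samples, ly].to_numpy())
        _, _, se_s = _ols_fit(ws.loc[shared_samples, lx].to_numpy(),
                              ws.loc[shared_samples, ly].to_numpy())
        rows.append({"locus_x": lx, "locus_y": ly, "residual_se_common": se_c,
                     "residual_se_second": se_s, "n": len(shared_samples)})
    return pd.DataFrame(rows)
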