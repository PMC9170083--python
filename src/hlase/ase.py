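"""Allele-specific expression (ASE) and its allele-constrained permutation null.

ASE here is the ratio of the lower-expressed allele's tpm to the total tpm
of both alleles at one locus in one individual, so 0.5 means perfectly
balanced biallelic expression.  The null model asks: is the observed
balance more extreme than expected if allele tpm values were exchangeable
among carriers of the same allele?  The permutation therefore shuffles
tpm values among the carrier slots of each allele name (every individual
keeps its own HLA typing) and recomputes the per-locus median ASE per
replicate; a one-sided empirical p-value with the (b+1)/(R+1) correction
reports how often a replicate median is at least as close to 0.5 as the
observed one.

A shared per-individual expression factor inflates both alleles of an
individual together and is destroyed by the permutation, so coordinated
cohorts reject this null; with no individual coordination the test is
calibrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    locus: str
    condition: str
    observed_median_ase: float
    replicate_medians: np.ndarray
    R: int
    empirical_p: float

    def __post_init__(self) -> None:
        assert len(self.replicate_medians) == self.R
        assert 1.0 / (self.R + 1) <= self.empirical_p <= 1.0


@dataclass
class PairedTestResult:
    locus: str
    statistic: float
    p_value: float
    median_first: float
    median_second: float
    n_pairs: int
    n_dropped: int


def compute_ase(tpm_a: float, tpm_b: float) -> float:
    """min/(sum) of the two allele tpm values; symmetric; in (0, 0.5]."""
    if tpm_a <= 0 or tpm_b <= 0:
        raise ValueError("tpm values must be positive")
    return min(tpm_a, tpm_b) / (tpm_a + tpm_b)


def ase_table(expr: pd.DataFrame, include_homozygotes: bool = False) -> pd.DataFrame:
    """Per-individual ASE: one row per (sample, locus, condition).

    Homozygotes (both records carry the same allele name) conflate the two
    gene copies and are excluded by default; with include_homozygotes=True
    their min-copy/total ratio is reported like any other.
    """
    rows = []
    for (sample, locus, condition), grp in expr.groupby(
            ["sample_id", "locus", "condition"], sort=True):
        if len(grp) != 2:
            raise ValueError(f"expected 2 records for {(sample, locus, condition)}")
        alleles = grp["allele"].tolist()
        if not include_homozygotes and alleles[0] == alleles[1]:
            continue
        t = grp["tpm"].to_numpy()
        rows.append((sample, locus, condition, t.min() / t.sum()))
    return pd.DataFrame(rows, columns=["sample_id", "locus", "condition", "ase"])


def permute_within_alleles(expr: pd.DataFrame,
                           rng: np.random.Generator) -> pd.DataFrame:
    """One replicate of the allele-constrained permutation.

    For every allele name (in lexicographic order, for reproducibility) the
    tpm values across its carrier slots are uniformly permuted; allele
    names, sample ids and every per-allele tpm multiset are unchanged.
    Requires a single-condition table.
    """
    if expr["condition"].nunique() > 1:
        raise ValueError("permute_within_alleles expects a single condition")
    out = expr.copy()
    tpm = out["tpm"].to_numpy().copy()
    for allele in sorted(out["allele"].unique()):
        idx = np.flatnonzero((out["allele"] == allele).to_numpy())
        tpm[idx] = tpm[idx[rng.permutation(len(idx))]]
    out["tpm"] = tpm
    return out


def _locus_arrays(expr: pd.DataFrame, locus: str):
    """Flatten one locus into slot arrays plus het pair indices."""
    sub = expr[expr["locus"] == locus].sort_values(
        ["sample_id", "copy"], kind="stable")
    tpm = sub["tpm"].to_numpy()
    alleles = sub["allele"].to_numpy()
    samples = sub["sample_id"].to_numpy()
    first = np.arange(0, len(sub), 2)
    if not np.all(samples[first] == samples[first + 1]):
        raise ValueError(f"unpaired allele records at locus {locus!r}")
    het = alleles[first] != alleles[first + 1]
    return tpm, alleles, first[het], first[het] + 1


def _null_median_distribution(tpm: np.ndarray, alleles: np.ndarray,
                              i1: np.ndarray, i2: np.ndarray,
                              R: int, rng: np.random.Generator) -> np.ndarray:
    """Median-ASE null distribution, vectorized over replicates.

    Each replicate permutes tpm within every allele group (groups visited in
    lexicographic order; one uniform permutation per group per replicate via
    argsort of i.i.d. keys), then takes the median over heterozygous
    individuals of min/(sum).
    """
    perm = np.tile(tpm, (R, 1))
    for allele in sorted(np.unique(alleles)):
        idx = np.flatnonzero(alleles == allele)
        if len(idx) < 2:
            continue  # singleton orbit: value maps to itself
        order = np.argsort(rng.random((R, len(idx))), axis=1)
        perm[:, idx] = tpm[idx][order]
    a, b = perm[:, i1], perm[:, i2]
    ase = np.minimum(a, b) / (a + b)
    return np.median(ase, axis=1)


def permutation_test_median_ase(expr: pd.DataFrame, R: int = 1000,
                                rng: np.random.Generator | int | None = None,
                                include_homozygotes: bool = False
                                ) -> dict[str, PermutationResult]:
    """Per-locus permutation test of the observed median ASE.

    One-sided: counts replicates whose median ASE is >= the observed median
    (ties count against rejection); empirical p = (b+1)/(R+1).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if expr["condition"].nunique() > 1:
        raise ValueError("permutation test expects a single condition")
    condition = expr["condition"].iloc[0]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    results: dict[str, PermutationResult] = {}
    for locus in sorted(expr["locus"].unique()):
        tpm, alleles, i1, i2 = _locus_arrays(expr, locus)
        if include_homozygotes:
            first = np.arange(0, len(tpm), 2)
            i1, i2 = first, first + 1
        if len(i1) < 2:
            raise ValueError(f"fewer than 2 informative individuals at locus {locus!r}")
        observed = float(np.median(np.minimum(tpm[i1], tpm[i2]) / (tpm[i1] + tpm[i2])))
        null = _null_median_distribution(tpm, alleles, i1, i2, R, rng)
        b = int((null >= observed).sum())
        results[locus] = PermutationResult(
            locus=locus, condition=condition, observed_median_ase=observed,
            replicate_medians=null, R=R, empirical_p=(b + 1) / (R + 1))
    return results


def paired_condition_test(ase_first: pd.DataFrame, ase_second: pd.DataFrame,
                          locus: str) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired per-individual ASE differences
    between two conditions at one locus (zero differences dropped).

    The matched-pairs signed-rank test is the paired analogue of the rank
    test; both condition medians are reported alongside.
    """
    a = ase_first[ase_first["locus"] == locus].set_index("sample_id")["ase"]
    b = ase_second[ase_second["locus"] == locus].set_index("sample_id")["ase"]
    shared = a.index.intersection(b.index)
    n_dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if n_dropped:
        warnings.warn(f"{n_dropped} unpaired sample(s) dropped at locus {locus!r}")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    diffs = (y - x)[(y - x) != 0]
    if len(diffs) == 0:
        stat, p = 0.0, 1.0
    else:
        _, p = stats.wilcoxon(x, y, zero_method="wilcox")
        # signed rank sum: positive when the second condition is larger
        ranks = stats.rankdata(np.abs(diffs))
        stat = float(np.sum(np.sign(diffs) * ranks))
    return PairedTestResult(locus=locus, statistic=float(stat), p_value=float(p),
                            median_first=float(np.median(x)),
                            median_second=float(np.median(y)),
                            n_pairs=len(shared), n_dropped=int(n_dropped))


def spearman_allele_pairs(expr: pd.DataFrame, locus: str,
                          condition: str) -> tuple[float, float]:
    """Spearman correlation between the two allele tpm values of each
    heterozygous individual, paired as (lower-expressed, higher-expressed)."""
    sub = expr[(expr["locus"] == locus) & (expr["condition"] == condition)]
    tpm, alleles, i1, i2 = _locus_arrays(sub, locus)
    if len(i1) < 3:
        raise ValueError("need at least 3 heterozygous individuals")
    lo = np.minimum(tpm[i1], tpm[i2])
    hi = np.maximum(tpm[i1], tpm[i2])
    rho, p = stats.spearmanr(lo, hi)
    return float(rho), float(p)
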