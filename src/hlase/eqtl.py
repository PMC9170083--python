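"""Compact cis-eQTL stage.

Covers the standard pipeline around a ±1 Mb cis window per gene: variant
QC (MAF / missingness / Hardy-Weinberg), rank-based inverse-normal
phenotype transformation, covariate residualization, the per-variant
linear scan, gene-level significance from phenotype permutations with a
fitted Beta approximation to the null minimum p-value, Benjamini-Hochberg
selection of eGenes, a genotype-by-stimulation interaction contrast for
paired two-condition designs, the Storey pi1 replication statistic and
pairwise LD r².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # ±1 Mb around the TSS, fully closed


@dataclass(frozen=True)
class QcThresholds:
    """Variant QC: drop MAF < maf_min, missingness > missing_max,
    HWE p < hwe_p_min."""

    maf_min: float = 0.01
    missing_max: float = 0.025
    hwe_p_min: float = 1e-5

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.missing_max, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class EqtlResult:
    gene: str
    variant_id: str
    slope: float
    r2: float
    nominal_p: float
    empirical_p: float | None = None
    beta_p: float | None = None
    significant: bool | None = None
    R: int | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.r2 <= 1.0 + 1e-12


@dataclass
class InteractionResult:
    gene: str
    variant_id: str
    genotype_effect: float      # slope in the unstimulated condition
    stimulation_effect: float   # mean expression shift under stimulation
    interaction_effect: float   # stim slope minus unstim slope
    interaction_p: float
    slope_unstim: float
    p_unstim: float
    slope_stim: float
    p_stim: float
    n_pairs: int
    n_dropped: int = 0


@dataclass
class Pi1Estimate:
    pi1: float
    lambda_: float
    m: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.pi1 <= 1.0


# -- variant QC ---------------------------------------------------------------

def hwe_test(n_rr: int, n_ra: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    genotype proportions expected from the allele counts.  Monomorphic
    sites return p = 1."""
    if min(n_rr, n_ra, n_aa) < 0 or (n := n_rr + n_ra + n_aa) < 1:
        raise ValueError("counts must be non-negative with total >= 1")
    p = (2 * n_rr + n_ra) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_rr, n_ra, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter_variants(gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply MAF, missingness and HWE filters; returns the surviving matrix
    plus a per-variant fate log (reason = first failing rule, tested in the
    order maf, missing, hwe)."""
    maf = gm.maf()
    miss = gm.missingness()
    fates = []
    for j in range(gm.n_variants):
        if np.isnan(maf[j]) or maf[j] < thresholds.maf_min:
            fates.append("maf")
        elif miss[j] > thresholds.missing_max:
            fates.append("missing")
        elif hwe_test(*gm.genotype_counts(j)) < thresholds.hwe_p_min:
            fates.append("hwe")
        else:
            fates.append("pass")
    fate = pd.DataFrame({"id": gm.variants["id"], "fate": fates})
    keep = np.array([f == "pass" for f in fates])
    return gm.subset_variants(keep), fate


# -- normalization & covariates ----------------------------------------------

def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: average ranks mapped to
    standard-normal quantiles via (rank - 0.5)/n."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def residualize(phenotype, covariates) -> np.ndarray:
    """OLS residuals of the phenotype on covariates plus an intercept."""
    y = np.asarray(phenotype, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.size == 0:
        return y - y.mean()
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix rank-deficient after adding intercept")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def compute_pcs(data: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-centered matrix
    (rows = samples), each score vector centered and scaled to unit SD."""
    X = np.asarray(data, dtype=float)
    if k < 0 or k > min(X.shape):
        raise ValueError(f"k={k} out of range for shape {X.shape}")
    if k == 0:
        return np.zeros((X.shape[0], 0))
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    scores = scores - scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd


# -- the scan -----------------------------------------------------------------

def _impute_center(dos: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant, then center columns."""
    X = dos.copy()
    mean = np.nanmean(X, axis=0)
    nanmask = np.isnan(X)
    X[nanmask] = np.take(mean, np.nonzero(nanmask)[1])
    return X - X.mean(axis=0)


def cis_window_mask(gm: GenotypeMatrix, chrom: str, tss: int,
                    window: int = CIS_WINDOW) -> np.ndarray:
    v = gm.variants
    return ((v["chrom"].astype(str) == str(chrom))
            & (v["pos"] >= tss - window) & (v["pos"] <= tss + window)).to_numpy()


def cis_scan(phenotype, gm: GenotypeMatrix, chrom: str, tss: int,
             window: int = CIS_WINDOW) -> tuple[pd.DataFrame, EqtlResult]:
    """Per-variant simple linear regression of the phenotype on dosage
    inside the cis window.

    Returns (per-variant table with slope, r2 and two-sided nominal p;
    best-variant result).  Best = smallest nominal p, ties broken by
    distance to the TSS and then variant id.  Missing dosages are
    mean-imputed per variant.
    """
    mask = cis_window_mask(gm, chrom, tss, window)
    if not mask.any():
        raise ValueError(f"no variants within ±{window} of {chrom}:{tss}")
    sub = gm.subset_variants(mask)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    X = _impute_center(sub.dosages)
    yc = y - y.mean()
    sxx = (X ** 2).sum(axis=0)
    syy = float(yc @ yc)
    sxy = X.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        r = np.where(sxx > 0, sxy / np.sqrt(np.where(sxx > 0, sxx, 1.0) * syy), np.nan)
    r2 = r ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    table = sub.variants.copy()
    table["slope"] = slope
    table["r2"] = r2
    table["nominal_p"] = pvals
    table["tss_distance"] = table["pos"] - tss

    ranked = table.dropna(subset=["nominal_p"]).copy()
    if ranked.empty:
        raise ValueError("all cis variants monomorphic")
    ranked["absdist"] = ranked["tss_distance"].abs()
    best = ranked.sort_values(["nominal_p", "absdist", "id"]).iloc[0]
    result = EqtlResult(gene="", variant_id=best["id"], slope=float(best["slope"]),
                        r2=float(best["r2"]), nominal_p=float(best["nominal_p"]))
    return table, result


def _min_p_null(X: np.ndarray, y: np.ndarray, R: int,
                rng: np.random.Generator) -> np.ndarray:
    """Null minimum nominal p over cis variants for R phenotype
    permutations, vectorized through the correlation form of the t-test."""
    n = len(y)
    yc = y - y.mean()
    norm_y = np.sqrt(float(yc @ yc))
    sxx = np.sqrt((X ** 2).sum(axis=0))
    ok = sxx > 0
    Xn = X[:, ok] / sxx[ok]
    perms = np.empty((n, R))
    for r in range(R):
        perms[:, r] = yc[rng.permutation(n)]
    corr = np.abs(Xn.T @ perms) / norm_y  # (variants, R)
    rmax = corr.max(axis=0)
    rmax = np.minimum(rmax, 1.0 - 1e-12)
    t = rmax * np.sqrt((n - 2) / (1.0 - rmax ** 2))
    return 2.0 * stats.t.sf(t, df=n - 2)


def _fit_beta(null_p: np.ndarray) -> tuple[float, float]:
    """Fit Beta(a, b) to the null minima by ML (method-of-moments start,
    bounded optimization); falls back to the moments estimate when the
    optimizer fails."""
    x = np.clip(null_p, 1e-300, 1.0 - 1e-12)
    m, v = float(x.mean()), float(x.var(ddof=1))
    if v <= 0:
        raise ValueError("degenerate null: all permutation minima identical")
    common = m * (1 - m) / v - 1.0
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)

    def nll(params):
        a, b = params
        return -np.sum(stats.beta.logpdf(x, a, b))

    try:
        res = optimize.minimize(nll, x0=[a0, b0], method="L-BFGS-B",
                                bounds=[(1e-3, 1e4), (1e-3, 1e6)])
        if res.success:
            return float(res.x[0]), float(res.x[1])
        log.warning("beta MLE did not converge; using method-of-moments estimate")
    except (ValueError, FloatingPointError):  # pragma: no cover
        log.warning("beta MLE failed; using method-of-moments estimate")
    return a0, b0


def gene_permutation_p(phenotype, gm: GenotypeMatrix, chrom: str, tss: int,
                       R: int = 1000, rng: np.random.Generator | int | None = None,
                       window: int = CIS_WINDOW) -> EqtlResult:
    """Gene-level significance: the best nominal p in the cis window
    referred to the distribution of the minimum nominal p over R phenotype
    permutations.  empirical p = (b+1)/(R+1); the Beta-approximated p is
    the fitted-null CDF at the observed minimum."""
    if R < 100:
        raise ValueError("R must be >= 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    _, best = cis_scan(phenotype, gm, chrom, tss, window)
    mask = cis_window_mask(gm, chrom, tss, window)
    X = _impute_center(gm.subset_variants(mask).dosages)
    null = _min_p_null(X, np.asarray(phenotype, dtype=float), R, rng)
    b = int((null <= best.nominal_p).sum())
    best.empirical_p = (b + 1) / (R + 1)
    a_hat, b_hat = _fit_beta(null)
    best.beta_p = float(stats.beta.cdf(best.nominal_p, a_hat, b_hat))
    best.R = R
    return best


def fdr_select(gene_p: pd.Series | dict, level: float = 0.05
               ) -> tuple[list, float]:
    """Benjamini-Hochberg step-up selection at the given FDR level.
    Returns (selected genes, largest selected p-value or NaN)."""
    s = pd.Series(gene_p, dtype=float)
    if s.empty:
        raise ValueError("no p-values supplied")
    reject, *_ = multipletests(s.to_numpy(), alpha=level, method="fdr_bh")[:1]
    selected = s.index[reject].tolist()
    threshold = float(s[reject].max()) if reject.any() else float("nan")
    return selected, threshold


# -- interaction & replication ------------------------------------------------

def interaction_test(y_unstim: pd.Series, y_stim: pd.Series,
                     dosage: pd.Series, gene: str = "",
                     variant_id: str = "") -> InteractionResult:
    """Genotype × stimulation interaction for a paired two-condition design.

    Within-individual parameterization: regressing the per-individual
    expression difference (stim − unstim) on dosage is the fixed
    per-individual-intercept fit of y ~ genotype + stimulation +
    genotype:stimulation for a balanced paired design; its slope is the
    interaction effect and equals the stratified stim slope minus the
    unstim slope exactly.  Per-condition slopes/p come from
    condition-stratified simple regressions.
    """
    idx = y_unstim.index.intersection(y_stim.index).intersection(dosage.index)
    n_dropped = (len(y_unstim) - len(idx)) + (len(y_stim) - len(idx))
    g = dosage.loc[idx].to_numpy(dtype=float)
    if np.unique(g).size < 2:
        raise ValueError("genotype constant: interaction inestimable")
    yu = y_unstim.loc[idx].to_numpy(dtype=float)
    ys = y_stim.loc[idx].to_numpy(dtype=float)

    res_u = stats.linregress(g, yu)
    res_s = stats.linregress(g, ys)
    diff = ys - yu
    res_d = stats.linregress(g, diff)
    return InteractionResult(
        gene=gene, variant_id=variant_id,
        genotype_effect=float(res_u.slope),
        stimulation_effect=float(np.mean(diff)),
        interaction_effect=float(res_d.slope),
        interaction_p=float(res_d.pvalue),
        slope_unstim=float(res_u.slope), p_unstim=float(res_u.pvalue),
        slope_stim=float(res_s.slope), p_stim=float(res_s.pvalue),
        n_pairs=len(idx), n_dropped=int(n_dropped))


def pi1(replication_p, lambda_: float = 0.5) -> Pi1Estimate:
    """Storey's single-λ estimator of the non-null fraction:
    pi0 = #{p > λ} / ((1−λ)·m), pi1 = 1 − pi0, clipped to [0, 1]."""
    p = np.asarray(replication_p, dtype=float)
    if p.size < 20:
        raise ValueError("need at least 20 replication p-values")
    if not 0.0 < lambda_ < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    pi0 = float((p > lambda_).sum() / ((1.0 - lambda_) * p.size))
    return Pi1Estimate(pi1=float(np.clip(1.0 - pi0, 0.0, 1.0)),
                       lambda_=lambda_, m=int(p.size))


def pi1_grid(replication_p, lambdas=None) -> Pi1Estimate:
    """Grid-averaged variant of the pi1 estimator (mean of single-λ
    estimates over a λ grid)."""
    if lambdas is None:
        lambdas = np.arange(0.2, 0.85, 0.05)
    ests = [pi1(replication_p, float(l)).pi1 for l in lambdas]
    return Pi1Estimate(pi1=float(np.clip(np.mean(ests), 0.0, 1.0)),
                       lambda_=float(np.mean(lambdas)),
                       m=int(np.asarray(replication_p).size))


def ld_r2(gm: GenotypeMatrix, variant_1: str, variant_2: str) -> float:
    """Squared Pearson correlation of the two dosage vectors over samples
    non-missing at both variants."""
    j1, j2 = gm.variant_index(variant_1), gm.variant_index(variant_2)
    d1, d2 = gm.dosages[:, j1], gm.dosages[:, j2]
    ok = ~(np.isnan(d1) | np.isnan(d2))
    d1, d2 = d1[ok], d2[ok]
    if np.unique(d1).size < 2 or np.unique(d2).size < 2:
        raise ValueError("monomorphic variant in LD computation")
    r = np.corrcoef(d1, d2)[0, 1]
    return float(r ** 2)


def choose_covariate_count(phenotypes: pd.DataFrame, gm: GenotypeMatrix,
                           tss_table: pd.DataFrame, candidate_ks,
                           level: float = 0.05, R: int = 200,
                           rng: np.random.Generator | int | None = None,
                           window: int = CIS_WINDOW) -> tuple[int, dict[int, int]]:
    """Pick the number of expression PCs that maximizes the FDR-significant
    eGene count (ties -> smallest k).

    phenotypes: genes × samples; per k the top-k PCs of the phenotype
    matrix are regressed out of each inverse-normal-transformed gene before
    the scan.
    """
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks:
        raise ValueError("candidate k list empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts: dict[int, int] = {}
    for k in ks:
        pcs = compute_pcs(phenotypes.to_numpy().T, k)
        gene_p = {}
        for gene in phenotypes.index:
            y = inverse_normal_transform(phenotypes.loc[gene].to_numpy())
            y = residualize(y, pcs)
            chrom = str(tss_table.loc[gene, "chrom"])
            tss = int(tss_table.loc[gene, "tss"])
            res = gene_permutation_p(y, gm, chrom, tss, R=R,
                                     rng=np.random.default_rng(rng.integers(2**31)),
                                     window=window)
            gene_p[gene] = res.beta_p
        selected, _ = fdr_select(gene_p, level)
        counts[k] = len(selected)
    best = max(ks, key=lambda k: (counts[k], -k))
    return best, counts
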