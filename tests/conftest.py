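import math

import pandas as pd
import pytest

from hlase.simcohort import (GeneratorConfig, HaplotypeSpec,
                             sample_cohort, simulate_expression)


def make_config(n=63, n_alleles=15, sigma_a=0.10, sigma_g=0.40, sigma_e=0.08,
                loci=("A",), seed=0, **kwargs):
    """One-or-more-locus cohort config with equifrequent allele pools."""
    pool = {
        loc: [(f"{loc}*{i + 1:02d}:01", 1.0 / n_alleles) for i in range(n_alleles)]
        for loc in loci
    }
    mu = {loc: math.log(1000.0) for loc in loci}
    return GeneratorConfig(n_individuals=n, loci=list(loci), allele_pool=pool,
                           mu_locus=mu, sigma_a=sigma_a, sigma_g=sigma_g,
                           sigma_e=sigma_e, seed=seed, **kwargs)


def make_expr(condition="unstim", **kwargs):
    cfg = make_config(**kwargs)
    cohort = sample_cohort(cfg)
    return simulate_expression(cohort, cfg, condition)


@pytest.fixture(scope="session")
def demo_expr():
    """63-individual three-locus cohort, unstimulated condition."""
    return make_expr(loci=("A", "B", "C"), seed=0)


def haplotype_demo_config(n=60, sigma_h=0.0, sigma_a=0.10, sigma_g=0.30,
                          sigma_e=0.08, seed=0, markers=(), **kwargs):
    """Cohort drawn from a founder-haplotype table: one common haplotype
    (frequency 0.4) plus five rarer ones with distinct alleles."""
    loci = ["A", "B", "C"]
    haps = []
    freqs = [0.4, 0.2, 0.12, 0.12, 0.08, 0.08]
    for i, f in enumerate(freqs):
        alleles = {loc: f"{loc}*{i + 1:02d}:01" for loc in loci}
        vec = tuple(int(b) for b in format(i, f"0{len(markers)}b")[-len(markers):]) \
            if markers else ()
        haps.append(HaplotypeSpec(alleles, vec, f))
    mu = {loc: math.log(1000.0) for loc in loci}
    return GeneratorConfig(n_individuals=n, loci=loci, haplotype_table=haps,
                           markers=list(markers), mu_locus=mu, sigma_a=sigma_a,
                           sigma_g=sigma_g, sigma_h=sigma_h, sigma_e=sigma_e,
                           seed=seed, **kwargs)


def tiny_expression_frame():
    """Two heterozygous samples, one locus, one condition — hand-checkable."""
    return pd.DataFrame({
        "sample_id": ["S1", "S1", "S2", "S2"],
        "locus": ["A"] * 4,
        "allele": ["A*01:01", "A*02:01", "A*01:01", "A*03:01"],
        "copy": [1, 2, 1, 2],
        "condition": ["unstim"] * 4,
        "tpm": [500.0, 500.0, 200.0, 1800.0],
    })
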