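"""Synthetic HLA class I cohort generator.

Emulates the statistical structure of a bulk RNA-seq cohort in which every
individual carries two HLA alleles per class I locus (HLA-A/B/C) and the
two alleles of a locus are expressed in a coordinated fashion within each
individual.  Expression is modelled on the natural-log scale as a sum of
variance components:

    ln tpm = mu_locus + alpha(allele) + g(individual) + h(haplotype)
             + [stim only: delta_locus + s(allele)]
             + sum_v beta_v * dosage_v            (planted cis-eQTLs)
             + epsilon

with alpha ~ N(0, sigma_A^2) drawn once per allele *name* (allele lineages
have characteristic expression levels), g ~ N(0, sigma_G^2) shared by all
measurements of one individual (the coordinated-expression factor),
h ~ N(0, sigma_H^2) shared by the alleles riding on one founder haplotype,
and epsilon ~ N(0, sigma_E^2) fresh per measurement.  Cytokine stimulation
(TNFa/IFNb) acts multiplicatively on tpm, i.e. additively on the ln scale,
through a per-locus shift delta plus an optional per-allele deviation s.

Everything downstream (allele-specific expression and its permutation
null, stimulation fold-change summaries, haplotype co-expression fits,
the cis-eQTL scan) can be exercised against cohorts drawn from this model
with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GenotypeMatrix

CONDITIONS = ("fresh", "unstim", "stim")
_FREQ_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker site carried on founder haplotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str = "A"
    alt: str = "G"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class HaplotypeSpec:
    """A founder haplotype: one allele per locus, a binary marker vector
    aligned with the configured markers, and a population frequency."""

    alleles: Mapping[str, str]
    markers: tuple[int, ...]
    frequency: float


@dataclass(frozen=True)
class EqtlSpec:
    """A planted cis-eQTL: additive ln-scale effect per alt-dosage unit of
    `marker_id` on the expression of `locus`."""

    marker_id: str
    locus: str
    beta: float


@dataclass
class GeneratorConfig:
    """Parameters of the generative model.

    All effect-size parameters are on the natural-log scale.  ``mu_locus``
    is the ln of the typical tpm at each locus; ``stim_logfold`` is the
    per-locus additive ln-scale stimulation shift (ln 2 doubles tpm).
    ``stim_sigma_a`` / ``stim_sigma_e`` optionally replace ``sigma_a`` /
    ``sigma_e`` under stimulation (reduced-dispersion calibration);
    when ``stim_sigma_a`` is set a fresh set of per-allele effects with
    that SD is used in the stimulated condition.
    """

    n_individuals: int
    loci: Sequence[str]
    allele_pool: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    haplotype_table: Sequence[HaplotypeSpec] | None = None
    mu_locus: Mapping[str, float] = field(default_factory=dict)
    sigma_a: float = 0.10
    sigma_g: float = 0.40
    sigma_h: float = 0.0
    sigma_e: float = 0.08
    stim_logfold: Mapping[str, float] = field(default_factory=dict)
    sigma_s: float = 0.0
    stim_sigma_a: float | None = None
    stim_sigma_e: float | None = None
    shared_allele_effects: bool = True
    eqtl_specs: Sequence[EqtlSpec] = field(default_factory=list)
    markers: Sequence[Marker] = field(default_factory=list)
    tss: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    seed: int = 0

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if d.get("markers"):
            d["markers"] = [Marker(str(m[0]), int(m[1]), *[str(x) for x in m[2:4]])
                            for m in d["markers"]]
        if d.get("haplotype_table"):
            d["haplotype_table"] = [
                HaplotypeSpec(dict(h["alleles"]), tuple(int(x) for x in h.get("markers", ())),
                              float(h["frequency"]))
                for h in d["haplotype_table"]
            ]
        if d.get("eqtl_specs"):
            d["eqtl_specs"] = [EqtlSpec(str(e[0]), str(e[1]), float(e[2]))
                               for e in d["eqtl_specs"]]
        if d.get("allele_pool"):
            d["allele_pool"] = {
                loc: [(str(a), float(f)) for a, f in pool]
                for loc, pool in d["allele_pool"].items()
            }
        if d.get("tss"):
            d["tss"] = {g: (str(c), int(p)) for g, (c, p) in d["tss"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- validation -----------------------------------------------------------

    def pool_for(self, locus: str) -> list[tuple[str, float]]:
        """Allele pool for a locus; derived from the haplotype table when no
        explicit pool is configured."""
        pool = self.allele_pool.get(locus)
        if pool:
            return list(pool)
        if self.haplotype_table:
            freqs: dict[str, float] = {}
            for h in self.haplotype_table:
                freqs[h.alleles[locus]] = freqs.get(h.alleles[locus], 0.0) + h.frequency
            return sorted(freqs.items())
        raise ConfigError(f"empty allele pool for locus {locus!r}")

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        if not self.loci:
            raise ConfigError("at least one locus required")
        for name in ("sigma_a", "sigma_g", "sigma_h", "sigma_e", "sigma_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for locus in self.loci:
            pool = self.pool_for(locus)
            if not pool:
                raise ConfigError(f"empty allele pool for locus {locus!r}")
            tot = sum(f for _, f in pool)
            if abs(tot - 1.0) > _FREQ_TOL:
                raise ConfigError(f"allele frequencies at {locus!r} sum to {tot}, not 1")
        if self.haplotype_table:
            tot = sum(h.frequency for h in self.haplotype_table)
            if abs(tot - 1.0) > _FREQ_TOL:
                raise ConfigError(f"haplotype frequencies sum to {tot}, not 1")
            for h in self.haplotype_table:
                missing = [l for l in self.loci if l not in h.alleles]
                if missing:
                    raise ConfigError(f"haplotype lacks alleles for loci {missing}")
                if len(h.markers) != len(self.markers):
                    raise ConfigError("haplotype marker vector length != marker count")
        elif self.markers:
            raise ConfigError("markers require a haplotype_table")
        elif self.sigma_h > 0:
            raise ConfigError("sigma_h > 0 requires a haplotype_table")
        seen: dict[str, int] = {}
        for m in self.markers:
            prev = seen.get(m.chrom)
            if prev is not None and m.pos <= prev:
                raise ConfigError("marker positions must be strictly increasing per chromosome")
            seen[m.chrom] = m.pos
        ids = {m.id for m in self.markers}
        for e in self.eqtl_specs:
            if e.marker_id not in ids:
                raise ConfigError(f"eQTL spec references unknown marker {e.marker_id!r}")
            if e.locus not in self.loci:
                raise ConfigError(f"eQTL spec references unknown locus {e.locus!r}")

    def marker_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.markers)}


@dataclass(frozen=True)
class Haplotype:
    """One carried haplotype: an allele per locus plus a marker-allele
    vector; ``founder`` indexes the haplotype_table entry it was drawn
    from (None under independent allele sampling)."""

    alleles: Mapping[str, str]
    markers: tuple[int, ...] = ()
    founder: int | None = None


@dataclass(frozen=True)
class Individual:
    sample_id: str
    hap1: Haplotype
    hap2: Haplotype


@dataclass
class Cohort:
    """A sampled cohort together with its realized latent effects."""

    individuals: list[Individual]
    allele_effects: dict[str, float]
    stim_allele_effects: dict[str, float] | None
    stim_deviations: dict[str, float]
    individual_factors: dict[str, float]
    haplotype_effects: dict[int, float]
    carrier_effects: dict[tuple[str, str, int], float] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [ind.sample_id for ind in self.individuals]

    def validate(self, config: GeneratorConfig) -> None:
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids not unique")
        pool_names = {a for locus in config.loci for a, _ in config.pool_for(locus)}
        unknown = set(self.allele_effects) - pool_names
        if unknown:
            raise ValueError(f"realized effects for alleles outside the pool: {sorted(unknown)}")

    def truth(self) -> dict:
        """JSON-serializable record of the realized latent effects."""
        return {
            "allele_effects": self.allele_effects,
            "stim_allele_effects": self.stim_allele_effects,
            "stim_deviations": self.stim_deviations,
            "individual_factors": self.individual_factors,
            "haplotype_effects": {str(k): v for k, v in self.haplotype_effects.items()},
            "haplotypes": {
                ind.sample_id: [dict(ind.hap1.alleles), dict(ind.hap2.alleles)]
                for ind in self.individuals
            },
        }


# -- random streams -----------------------------------------------------------
# Draw order is fixed and documented: effects (stream 0) -> individuals
# (stream 1) -> residuals (stream 2 + condition index).  Residual streams are
# keyed by condition so that simulate_expression calls are order-independent.

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


def _condition_stream(condition: str) -> int:
    try:
        return 2 + CONDITIONS.index(condition)
    except ValueError:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}") from None


# -- operations ---------------------------------------------------------------

def sample_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort: two haplotypes per individual (i.i.d. from the
    haplotype table, or independent alleles per locus), per-allele-name
    effects, per-individual factors, per-founder-haplotype effects.

    Reproducible: the same config (including seed) yields bitwise-identical
    cohorts.
    """
    config.validate()
    n = config.n_individuals
    if n == 0:
        return Cohort([], {}, None, {}, {}, {})

    rng_eff = _rng(config.seed, 0)
    all_names = sorted({a for locus in config.loci for a, _ in config.pool_for(locus)})
    allele_effects = {a: float(rng_eff.normal(0.0, config.sigma_a)) for a in all_names}
    stim_allele_effects = None
    if config.stim_sigma_a is not None:
        stim_allele_effects = {a: float(rng_eff.normal(0.0, config.stim_sigma_a))
                               for a in all_names}
    stim_deviations = {a: float(rng_eff.normal(0.0, config.sigma_s)) for a in all_names}
    haplotype_effects: dict[int, float] = {}
    if config.haplotype_table:
        for i in range(len(config.haplotype_table)):
            haplotype_effects[i] = float(rng_eff.normal(0.0, config.sigma_h))

    rng_ind = _rng(config.seed, 1)
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    if config.haplotype_table:
        freqs = np.array([h.frequency for h in config.haplotype_table])
        freqs = freqs / freqs.sum()
        draws = rng_ind.choice(len(config.haplotype_table), size=(n, 2), p=freqs)
        founders = [Haplotype(dict(h.alleles), h.markers, i)
                    for i, h in enumerate(config.haplotype_table)]
        haps = [(founders[draws[i, 0]], founders[draws[i, 1]]) for i in range(n)]
    else:
        per_locus: dict[str, np.ndarray] = {}
        for locus in config.loci:
            pool = config.pool_for(locus)
            names = [a for a, _ in pool]
            p = np.array([f for _, f in pool])
            p = p / p.sum()
            idx = rng_ind.choice(len(names), size=(n, 2), p=p)
            per_locus[locus] = np.array(names, dtype=object)[idx]
        haps = [
            (
                Haplotype({loc: per_locus[loc][i, 0] for loc in config.loci}),
                Haplotype({loc: per_locus[loc][i, 1] for loc in config.loci}),
            )
            for i in range(n)
        ]

    g = rng_ind.normal(0.0, config.sigma_g, size=n)
    individuals = [Individual(sample_ids[i], haps[i][0], haps[i][1]) for i in range(n)]
    individual_factors = {sample_ids[i]: float(g[i]) for i in range(n)}

    carrier_effects = None
    if not config.shared_allele_effects:
        carrier_effects = {}
        for ind in individuals:
            for locus in config.loci:
                for copy in (1, 2):
                    carrier_effects[(ind.sample_id, locus, copy)] = float(
                        rng_ind.normal(0.0, config.sigma_a))

    cohort = Cohort(individuals, allele_effects, stim_allele_effects,
                    stim_deviations, individual_factors, haplotype_effects,
                    carrier_effects)
    cohort.validate(config)
    return cohort


def _eqtl_shift(cohort: Cohort, config: GeneratorConfig, locus: str) -> np.ndarray:
    """Summed planted-eQTL contribution per individual for one locus."""
    n = len(cohort.individuals)
    shift = np.zeros(n)
    if not config.eqtl_specs:
        return shift
    midx = config.marker_index()
    for spec in config.eqtl_specs:
        if spec.locus != locus:
            continue
        j = midx[spec.marker_id]
        dos = np.array([ind.hap1.markers[j] + ind.hap2.markers[j]
                        for ind in cohort.individuals], dtype=float)
        shift += spec.beta * dos
    return shift


def simulate_expression(cohort: Cohort, config: GeneratorConfig,
                        condition: str = "unstim") -> pd.DataFrame:
    """Simulate one allelic-expression table (tpm per allele copy).

    Returns a DataFrame with columns sample_id, locus, allele, copy,
    condition, tpm — two rows per (sample, locus).  Residuals are drawn
    fresh per record and per condition; alpha, g and h are shared across
    conditions of the same cohort (paired design).
    """
    stream = _condition_stream(condition)
    rng = _rng(config.seed, stream)
    n = len(cohort.individuals)
    stim = condition == "stim"
    sigma_e = config.sigma_e
    if stim and config.stim_sigma_e is not None:
        sigma_e = config.stim_sigma_e
    alpha = cohort.allele_effects
    if stim and cohort.stim_allele_effects is not None:
        alpha = cohort.stim_allele_effects

    frames = []
    # residuals drawn locus-major then individual-major, copies innermost
    for locus in config.loci:
        mu = config.mu_locus.get(locus, math.log(1000.0))
        delta = config.stim_logfold.get(locus, 0.0) if stim else 0.0
        eqtl = _eqtl_shift(cohort, config, locus)
        eps = rng.normal(0.0, sigma_e, size=(n, 2))
        for copy in (1, 2):
            hapattr = "hap1" if copy == 1 else "hap2"
            names = [getattr(ind, hapattr).alleles[locus] for ind in cohort.individuals]
            if cohort.carrier_effects is not None:
                a = np.array([cohort.carrier_effects[(ind.sample_id, locus, copy)]
                              for ind in cohort.individuals])
            else:
                a = np.array([alpha[name] for name in names])
            g = np.array([cohort.individual_factors[ind.sample_id]
                          for ind in cohort.individuals])
            h = np.array([
                cohort.haplotype_effects.get(getattr(ind, hapattr).founder, 0.0)
                if getattr(ind, hapattr).founder is not None else 0.0
                for ind in cohort.individuals
            ])
            s = np.array([cohort.stim_deviations.get(name, 0.0) for name in names]) \
                if stim else np.zeros(n)
            lntpm = mu + a + g + h + delta + s + eqtl + eps[:, copy - 1]
            frames.append(pd.DataFrame({
                "sample_id": cohort.sample_ids,
                "locus": locus,
                "allele": names,
                "copy": copy,
                "condition": condition,
                "tpm": np.exp(lntpm),
            }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sample_id", "locus", "copy"], kind="stable",
                           ignore_index=True)


def simulate_genotypes(cohort: Cohort, config: GeneratorConfig) -> GenotypeMatrix:
    """Dosage matrix at the configured markers: dosage = sum of the two
    carried haplotypes' marker alleles.  LD among markers (and with HLA
    allele names) arises purely from founder-haplotype sharing."""
    if not config.markers:
        raise ConfigError("no markers configured")
    variants = pd.DataFrame({
        "chrom": [m.chrom for m in config.markers],
        "pos": [m.pos for m in config.markers],
        "ref": [m.ref for m in config.markers],
        "alt": [m.alt for m in config.markers],
        "id": [m.id for m in config.markers],
    })
    if cohort.individuals:
        dosages = np.array([
            np.asarray(ind.hap1.markers, dtype=float) + np.asarray(ind.hap2.markers, dtype=float)
            for ind in cohort.individuals
        ])
    else:
        dosages = np.zeros((0, len(config.markers)))
    return GenotypeMatrix(cohort.sample_ids, variants, dosages)


def coding_marker_vector(haplotype_table: Sequence[HaplotypeSpec],
                         locus: str, allele: str) -> tuple[int, ...]:
    """Founder-haplotype allele vector of a *coding* marker tagging one HLA
    allele: 1 exactly on the haplotypes carrying that allele name."""
    return tuple(int(h.alleles[locus] == allele) for h in haplotype_table)


def simulate_heterozygous_pairs(n: int, sigma_a: float, sigma_e: float,
                                mu: float = math.log(1000.0),
                                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Calibration sampler: n heterozygous (tpm_1, tpm_2) pairs with
    independent per-copy allele effects and residuals,

        ln tpm_k = mu + a_k + e_k,  a_k ~ N(0, sigma_a^2), e_k ~ N(0, sigma_e^2).

    The shared individual factor is omitted because it cancels in the
    within-individual ASE ratio.  Under this model the median ASE has the
    closed form 1/(1+exp(0.6745*sqrt(2*(sigma_a^2+sigma_e^2)))).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ln = mu + rng.normal(0.0, sigma_a, size=(n, 2)) + rng.normal(0.0, sigma_e, size=(n, 2))
    return np.exp(ln)


def demo_config(seed: int = 0) -> GeneratorConfig:
    """Default demonstration cohort mirroring the study's shape: 63
    individuals, three class I loci with 15–20 equifrequent alleles, locus
    means matching the reported tpm scale, ~2-fold stimulation shifts."""
    def pool(prefix: str, k: int) -> list[tuple[str, float]]:
        return [(f"{prefix}*{i + 1:02d}:01", 1.0 / k) for i in range(k)]

    sigma_a, sigma_g, sigma_e = 0.10, 0.40, 0.08
    var = sigma_a ** 2 + sigma_g ** 2 + sigma_e ** 2
    means = {"A": 866.0, "B": 1870.0, "C": 1238.0}
    return GeneratorConfig(
        n_individuals=63,
        loci=["A", "B", "C"],
        allele_pool={"A": pool("A", 15), "B": pool("B", 20), "C": pool("C", 15)},
        mu_locus={loc: math.log(m) - var / 2 for loc, m in means.items()},
        sigma_a=sigma_a, sigma_g=sigma_g, sigma_e=sigma_e,
        stim_logfold={"A": math.log(2.5), "B": math.log(2.04), "C": math.log(2.11)},
        sigma_s=0.05,
        tss={"A": ("6", 29942532), "B": ("6", 31353875), "C": ("6", 31268749)},
        seed=seed,
    )
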