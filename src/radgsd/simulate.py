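"""Synthetic RAD-seq cohorts with a known sex-determination system.

The generator emulates the statistical structure the downstream
analyses assume: a strongly structured set of populations (Balding-
Nichols allele frequencies), autosomal SNPs in Hardy-Weinberg
proportions within populations, X/Y (or Z/W) gametologous SNPs that are
heterozygous in the heterogametic sex except for recombination leakage
and Y-allele dropout, hemizygous sex-specific presence loci with
overdispersed read counts, technical missingness, and imperfect or
partial phenotypic sexing.

All random draws condition only on each individual's heterogametic
status, never on the male/female label itself, so an XY and a ZW
simulation from the same seed are numerically identical with the sex
labels swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import (
    FEMALE,
    MALE,
    MISSING,
    UNKNOWN,
    GenotypeMatrix,
    PresenceMatrix,
    SampleTable,
    SnpRecord,
)

HETEROGAMETIC = "heterogametic"
HOMOGAMETIC = "homogametic"

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Conditions for one synthetic cohort.

    Defaults mirror the emulated study's scale: 12 populations of 30
    individuals with strong structure (F=0.08), 27 000 autosomal SNPs,
    500 gametologs, 450 Y-specific loci, mean coverage 37 reads per
    individual per locus, ~15% of individuals phenotypically sexed.

    ``dropout_rate`` is the per individual-locus probability that the
    Y/W allele of a gametolog is unobserved (restriction-site
    polymorphism on the Y); ``sexspecific_dropout_rate`` is the same
    probability for hemizygous Y/W-specific loci and defaults to the
    gametolog rate when left as None.
    """

    system: str = "XY"  # one of {"XY", "ZW", "none"}
    n_populations: int = 12
    n_per_population: int = 30
    sex_ratio: float = 0.5  # fraction of heterogametic-sex individuals
    n_autosomal_snps: int = 27000
    n_gametolog_snps: int = 500
    n_sexspecific_loci: int = 450
    n_autosomal_loci_presence: int = 2000
    fst: float = 0.08
    ancestral_freq_beta: tuple[float, float] = (1.0, 1.0)
    leakage_rate: float = 0.05  # r: recombination/mutation leakage
    dropout_rate: float = 0.05  # d: Y/W allele dropout at gametologs
    sexspecific_dropout_rate: Optional[float] = None
    missing_rate: float = 0.05  # m: technical missingness per cell
    phenotype_error_rate: float = 0.05  # rho: phenotype/genotype mismatch
    sexed_fraction: float = 0.15
    mean_coverage: float = 37.0  # lambda, reads per individual per locus
    coverage_dispersion: float = 2.0  # k of the negative binomial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW", "none"):
            raise ValueError(f"unknown system {self.system!r}")
        for name in (
            "sex_ratio",
            "fst",
            "leakage_rate",
            "dropout_rate",
            "missing_rate",
            "phenotype_error_rate",
            "sexed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fst >= 1.0:
            raise ValueError("fst must be < 1")
        if self.sexspecific_dropout_rate is not None and not (
            0.0 <= self.sexspecific_dropout_rate <= 1.0
        ):
            raise ValueError("sexspecific_dropout_rate must be in [0,1]")
        for name in (
            "n_populations",
            "n_per_population",
            "n_autosomal_snps",
            "n_gametolog_snps",
            "n_sexspecific_loci",
            "n_autosomal_loci_presence",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_populations",) and getattr(self, name) < 1
            ):
                raise ValueError(f"{name} out of range")
        if self.n_per_population < 2:
            raise ValueError("n_per_population must be >= 2")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("mean_coverage and coverage_dispersion must be > 0")

    @property
    def effective_sexspecific_dropout(self) -> float:
        d = self.sexspecific_dropout_rate
        return self.dropout_rate if d is None else d


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    system: str
    snp_classes: np.ndarray = field(repr=False)  # {"autosomal","gametolog"}
    presence_locus_classes: np.ndarray = field(repr=False)  # {"autosomal","sex_specific"}
    genetic_sex: np.ndarray = field(repr=False)  # {"heterogametic","homogametic"}

    def sex_labels(self) -> np.ndarray:
        """Male/female labels implied by the genetic sex.

        In an XY system the heterogametic sex is male; in ZW it is
        female. For system "none" the (arbitrary) heterogametic coin is
        mapped to male so that phenotype labels remain well defined.
        """
        het_label, hom_label = (
            (FEMALE, MALE) if self.system == "ZW" else (MALE, FEMALE)
        )
        return np.where(
            self.genetic_sex == HETEROGAMETIC, het_label, hom_label
        ).astype(object)


def expected_heterogamete_het(r: float, d: float) -> float:
    """Probability a heterogametic individual is heterozygous at a gametolog.

    The X/Y (or Z/W) copies carry divergent alleles; heterozygosity is
    lost either by recombination/mutation leakage (rate ``r``) or by
    dropout of the Y/W allele (rate ``d``), independently: (1-r)(1-d).
    """
    if not (0.0 <= r <= 1.0 and 0.0 <= d <= 1.0):
        raise ValueError("rates must be in [0,1]")
    return (1.0 - r) * (1.0 - d)


def draw_population_freqs(
    p_ancestral: float,
    fst: float,
    n_pops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols per-population allele frequencies.

    Each population's frequency is Beta-distributed with mean
    ``p_ancestral`` and variance ``fst * p (1-p)``; fst=0 degenerates to
    the ancestral frequency everywhere.
    """
    p = np.asarray(p_ancestral, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequency must be strictly inside (0,1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0,1)")
    if fst == 0.0:
        return np.broadcast_to(p, (n_pops,) + p.shape).copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops,) + p.shape)


def _zero_truncated_nb(
    rng: np.random.Generator, mean: float, dispersion: float, size: tuple[int, ...]
) -> np.ndarray:
    """Overdispersed read counts, clamped to >= 1.

    NB(mean, k) with the rare zeros promoted to 1 so that a "present"
    locus is always observed with at least one read; at RAD-scale
    coverage the zero mass is negligible (< 0.3% at mean 37, k 2).
    """
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(counts, 1)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PresenceMatrix, SampleTable, SimulationTruth]:
    """Draw one full synthetic cohort.

    Returns the genotype matrix, presence (read-count) matrix, sample
    metadata and the ground truth. Fully reproducible from the config
    seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pops, n_per = cfg.n_populations, cfg.n_per_population
    n = n_pops * n_per
    pop_labels = [f"POP{p + 1:02d}" for p in range(n_pops)]
    pop_of = np.repeat(np.arange(n_pops), n_per)
    sample_ids = [
        f"{pop_labels[pop_of[i]]}_{i % n_per + 1:03d}" for i in range(n)
    ]

    # 1. Genetic sex: a heterogametic-status coin, label-free.
    heterogametic = rng.random(n) < cfg.sex_ratio

    sexlinked_on = cfg.system in ("XY", "ZW")

    # 2. SNP genotypes. Under "none" the configured gametolog count is
    # generated as ordinary autosomal SNPs (no locus is sex-associated).
    n_auto = cfg.n_autosomal_snps + (0 if sexlinked_on else cfg.n_gametolog_snps)
    n_gam = cfg.n_gametolog_snps if sexlinked_on else 0
    n_snps = n_auto + n_gam

    geno = np.zeros((n, n_snps), dtype=np.int16)
    if n_auto:
        a, b = cfg.ancestral_freq_beta
        p_anc = np.clip(rng.beta(a, b, size=n_auto), 1e-6, 1 - 1e-6)
        pop_freqs = draw_population_freqs(p_anc, cfg.fst, n_pops, rng)
        geno[:, :n_auto] = rng.binomial(2, pop_freqs[pop_of, :]).astype(np.int16)
    if n_gam:
        # Homogametic: homozygous for the X/Z allele (alt count 0).
        # Heterogametic: heterozygous unless leakage or dropout hits.
        p_het = expected_heterogamete_het(cfg.leakage_rate, cfg.dropout_rate)
        het_draw = rng.random((n, n_gam)) < p_het
        gam = np.where(heterogametic[:, None] & het_draw, 1, 0)
        geno[:, n_auto:] = gam.astype(np.int16)

    snp_classes = np.array(
        ["autosomal"] * n_auto + ["gametolog"] * n_gam, dtype=object
    )
    snp_perm = rng.permutation(n_snps)
    geno = geno[:, snp_perm]
    snp_classes = snp_classes[snp_perm]
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    snps = [
        SnpRecord(
            f"snp_{j + 1:06d}", _BASES[ref_idx[j]], _BASES[alt_idx[j]], position=j + 1
        )
        for j in range(n_snps)
    ]

    # 3. Presence loci. Under "none" the configured sex-specific count is
    # generated as additional neutral (everywhere-present) loci.
    n_neutral = cfg.n_autosomal_loci_presence + (
        0 if sexlinked_on else cfg.n_sexspecific_loci
    )
    n_spec = cfg.n_sexspecific_loci if sexlinked_on else 0
    n_loci = n_neutral + n_spec
    counts = np.zeros((n, n_loci), dtype=np.int64)
    if n_neutral:
        counts[:, :n_neutral] = _zero_truncated_nb(
            rng, cfg.mean_coverage, cfg.coverage_dispersion, (n, n_neutral)
        )
    if n_spec:
        spec = _zero_truncated_nb(
            rng, cfg.mean_coverage, cfg.coverage_dispersion, (n, n_spec)
        )
        d_ss = cfg.effective_sexspecific_dropout
        dropped = rng.random((n, n_spec)) < d_ss
        spec[dropped] = 0
        spec[~heterogametic, :] = 0
        counts[:, n_neutral:] = spec
    presence_classes = np.array(
        ["autosomal"] * n_neutral + ["sex_specific"] * n_spec, dtype=object
    )
    locus_perm = rng.permutation(n_loci)
    counts = counts[:, locus_perm]
    presence_classes = presence_classes[locus_perm]
    loci = [f"locus_{j + 1:06d}" for j in range(n_loci)]

    # 4. Technical missingness.
    if cfg.missing_rate > 0:
        geno[rng.random(geno.shape) < cfg.missing_rate] = MISSING
        counts[rng.random(counts.shape) < cfg.missing_rate] = 0

    # 5. Phenotypes: copied from genetic sex, flipped with rate rho,
    # hidden for the unsexed share. Draws precede label mapping so that
    # XY and ZW runs share them exactly.
    flip = rng.random(n) < cfg.phenotype_error_rate
    hidden = rng.random(n) >= cfg.sexed_fraction

    genetic_sex = np.where(heterogametic, HETEROGAMETIC, HOMOGAMETIC).astype(object)
    truth = SimulationTruth(
        system=cfg.system,
        snp_classes=snp_classes,
        presence_locus_classes=presence_classes,
        genetic_sex=genetic_sex,
    )
    labels = truth.sex_labels().copy()
    swapped = np.where(labels == MALE, FEMALE, MALE)
    labels[flip] = swapped[flip]
    labels[hidden] = UNKNOWN

    samples = SampleTable(
        sample_ids=sample_ids,
        populations=[pop_labels[p] for p in pop_of],
        phenotype_sex=list(labels),
    )
    genotypes = GenotypeMatrix(samples=list(sample_ids), snps=snps, values=geno)
    presence = PresenceMatrix(samples=list(sample_ids), loci=loci, counts=counts)
    return genotypes, presence, samples, truth


def write_truth_tsv(truth: SimulationTruth, samples: SampleTable, path: str) -> None:
    """Persist ground truth as three stacked key/id/value sections."""
    import pandas as pd

    rows = (
        [
            ("genetic_sex", sid, gs)
            for sid, gs in zip(samples.sample_ids, truth.genetic_sex)
        ]
        + [
            ("snp_class", f"snp_{j + 1:06d}", c)
            for j, c in enumerate(truth.snp_classes)
        ]
        + [
            ("presence_locus_class", f"locus_{j + 1:06d}", c)
            for j, c in enumerate(truth.presence_locus_classes)
        ]
    )
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
        path, sep="\t", index=False
    )
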