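"""SNP quality filters applied before sex-linkage inference.

Order is fixed (call rate -> MAF -> heterozygote excess) for
reproducible attrition accounting. Filters only ever drop SNP columns;
samples and SNP order are preserved, and every filter is idempotent.

The heterozygote-excess filter (a paralog screen) interacts badly with
sex-linked markers, which are ~50% heterozygous overall in a balanced
cohort: it defaults to off and warns when enabled with a threshold that
would remove them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import MISSING, GenotypeMatrix, SampleTable, check_samples_match


@dataclass
class FilterConfig:
    call_rate_per_pop: float = 0.75
    maf_min: float = 0.0
    het_excess_max: float = 1.0  # 1.0 disables the filter

    def __post_init__(self) -> None:
        for name in ("call_rate_per_pop", "maf_min", "het_excess_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def filter_call_rate(
    genotypes: GenotypeMatrix, samples: SampleTable, threshold: float = 0.75
) -> GenotypeMatrix:
    """Keep SNPs genotyped in >= ``threshold`` of individuals in *every* population."""
    samples = check_samples_match(genotypes.samples, samples)
    called = genotypes.values != MISSING
    pops = np.asarray(samples.populations, dtype=object)
    keep = np.ones(genotypes.n_snps, dtype=bool)
    for pop in np.unique(pops):
        members = pops == pop
        if members.sum() < 1:
            raise ValueError(f"population {pop} has no individuals")
        rate = called[members, :].mean(axis=0)
        keep &= rate >= threshold
    return genotypes.take_snps(np.flatnonzero(keep))


def filter_maf(genotypes: GenotypeMatrix, maf_min: float = 0.0) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below ``maf_min`` over non-missing calls.

    All-missing SNPs are removed with a warning (their MAF is undefined).
    """
    called = genotypes.values != MISSING
    n_called = called.sum(axis=0)
    all_missing = n_called == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} SNP(s) missing in all individuals removed "
            "during MAF filtering",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(called, genotypes.values, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = ~all_missing & (maf >= maf_min)
    return genotypes.take_snps(np.flatnonzero(keep))


def filter_het_excess(
    genotypes: GenotypeMatrix, het_excess_max: float = 1.0
) -> GenotypeMatrix:
    """Drop SNPs whose heterozygote fraction over non-missing calls exceeds the cap."""
    if het_excess_max < 0.6:
        warnings.warn(
            "het_excess_max < 0.6 will remove true sex-linked (gametologous) "
            "SNPs, which are ~50% heterozygous in a balanced cohort",
            stacklevel=2,
        )
    called = genotypes.values != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        het_frac = (genotypes.values == 1).sum(axis=0) / n_called
    keep = ~(het_frac > het_excess_max)  # NaN (all-missing) is kept here
    return genotypes.take_snps(np.flatnonzero(keep))


def apply_filters(
    genotypes: GenotypeMatrix, samples: SampleTable, config: FilterConfig
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Run the fixed filter chain; returns the filtered matrix and attrition counts."""
    attrition: dict[str, int] = {"input_snps": genotypes.n_snps}
    out = filter_call_rate(genotypes, samples, config.call_rate_per_pop)
    attrition["after_call_rate"] = out.n_snps
    out = filter_maf(out, config.maf_min)
    attrition["after_maf"] = out.n_snps
    if config.het_excess_max < 1.0:
        out = filter_het_excess(out, config.het_excess_max)
    attrition["after_het_excess"] = out.n_snps
    return out, attrition
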