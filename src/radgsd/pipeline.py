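"""End-to-end orchestration: simulate/load -> filter -> sex-linked PCA ->
sex-specific loci -> assignment and cross-validation.

`analyze` runs the whole inference in memory; `run_pipeline` wraps it
with file input/output so every stage's tables land on disk together
with a deterministic key/value run summary. Identical seed and inputs
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .assignment import (
    UNASSIGNED,
    CrossValidation,
    assign_by_axis,
    assign_by_specific,
    crossvalidate,
    sex_ratio_by_population,
)
from .data_model import (
    UNKNOWN,
    GenotypeMatrix,
    PresenceMatrix,
    SampleTable,
    check_samples_match,
)
from .filters import FilterConfig, apply_filters
from .sex_specific import (
    SexSpecificResult,
    chance_sexspecific_expectation,
    find_sex_specific,
    min_restriction_sites,
)
from .sexlink import (
    SYSTEM_UNDETERMINED,
    DetectionThresholds,
    PcaResult,
    SexLinkResult,
    detect_sexlinked,
)
from .simulate import SimulationConfig, SimulationTruth, simulate_dataset

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """One reproducible pipeline run: either file inputs or a simulation."""

    output_dir: str
    seed: int = 0
    # exactly one input mode: the three file paths, or a simulation config
    vcf_path: Optional[str] = None
    counts_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    filters: FilterConfig = field(default_factory=FilterConfig)
    dead_zone: float = 0.10
    specific_upper: float = 0.50
    specific_lower: float = 0.05

    def __post_init__(self) -> None:
        have_files = all(
            p is not None for p in (self.vcf_path, self.counts_path, self.metadata_path)
        )
        any_files = any(
            p is not None for p in (self.vcf_path, self.counts_path, self.metadata_path)
        )
        if self.simulation is not None and any_files:
            raise ValueError("supply either input paths or a simulation, not both")
        if self.simulation is None and not have_files:
            raise ValueError(
                "supply vcf_path, counts_path and metadata_path, or a simulation"
            )


@dataclass
class AnalysisResult:
    """All stage outputs of one in-memory run."""

    genotypes_filtered: GenotypeMatrix
    attrition: dict[str, int]
    pca: PcaResult
    sexlink: SexLinkResult
    sexspecific: SexSpecificResult
    crossval: CrossValidation
    sex_ratios: pd.DataFrame = field(repr=False)
    summary: dict[str, object] = field(default_factory=dict)


def analyze(
    genotypes: GenotypeMatrix,
    presence: PresenceMatrix,
    samples: SampleTable,
    thresholds: DetectionThresholds = DetectionThresholds(),
    filters: FilterConfig = FilterConfig(),
    dead_zone: float = 0.10,
    specific_upper: float = 0.50,
    specific_lower: float = 0.05,
    missing_rate_for_expectation: Optional[float] = None,
) -> AnalysisResult:
    """Run filtering, sex-linkage, sex-specific detection and assignment."""
    samples = check_samples_match(genotypes.samples, samples)
    check_samples_match(presence.samples, samples)

    filtered, attrition = apply_filters(genotypes, samples, filters)
    pca, sexlink = detect_sexlinked(filtered, samples, thresholds)

    # Phenotyped individuals that fall on the wrong side of the sex axis
    # are likely mis-sexed (or sex-reversed); counting them would erase
    # true hemizygous loci, so they are excluded from presence/absence
    # detection, exactly as mis-classified females were excluded in the
    # original protocol. They remain in every other stage and are
    # reported as discordant.
    samples_for_specific = samples
    n_axis_discordant = 0
    if sexlink.sex_axis is not None:
        axis_screen, _ = assign_by_axis(
            pca.coordinates[:, sexlink.sex_axis], samples, dead_zone
        )
        phenotype = samples.sex_array()
        mis = (
            (phenotype != UNKNOWN)
            & (axis_screen != UNASSIGNED)
            & (axis_screen != phenotype)
        )
        n_axis_discordant = int(mis.sum())
        if n_axis_discordant:
            masked = list(phenotype)
            for i in np.flatnonzero(mis):
                masked[i] = UNKNOWN
            samples_for_specific = SampleTable(
                list(samples.sample_ids), list(samples.populations), masked
            )
    sexspecific = find_sex_specific(presence, samples_for_specific)

    n_specific = max(
        len(sexspecific.male_specific_loci), len(sexspecific.female_specific_loci)
    )
    # Axis-based calls.
    if sexlink.sex_axis is not None:
        coords = pca.coordinates[:, sexlink.sex_axis]
        axis_calls, _ = assign_by_axis(coords, samples, dead_zone)
    else:
        coords = np.full(samples.n_samples, np.nan)
        axis_calls = np.full(samples.n_samples, UNASSIGNED, dtype=object)
    # Specific-locus calls.
    if n_specific > 0:
        specific_calls, n_present, frac_present = assign_by_specific(
            presence, sexspecific, specific_upper, specific_lower
        )
    else:
        specific_calls = np.full(samples.n_samples, UNASSIGNED, dtype=object)
        n_present = np.zeros(samples.n_samples, dtype=int)
        frac_present = np.zeros(samples.n_samples)
    crossval = crossvalidate(
        axis_calls,
        specific_calls,
        samples,
        axis_coordinates=coords,
        n_specific_present=n_present,
        frac_specific_present=frac_present,
    )
    sex_ratios = sex_ratio_by_population(crossval.table)

    if missing_rate_for_expectation is not None:
        chance_expect = chance_sexspecific_expectation(
            presence.n_loci,
            sexspecific.n_sexed_males,
            sexspecific.n_sexed_females,
            missing_rate_for_expectation,
        )
    else:
        chance_expect = None

    consensus = crossval.table["consensus_sex"]
    n_called = int((consensus != UNASSIGNED).sum())
    summary: dict[str, object] = {
        "n_samples": samples.n_samples,
        "n_snps_input": attrition["input_snps"],
        "n_snps_retained": filtered.n_snps,
        "sex_axis": -1 if sexlink.sex_axis is None else sexlink.sex_axis + 1,
        "sex_axis_separation": sexlink.separation_stat,
        "sex_axis_explained_variance_pct": (
            float(pca.explained_variance_pct[sexlink.sex_axis])
            if sexlink.sex_axis is not None
            else 0.0
        ),
        "n_candidate_snps": len(sexlink.candidate_indices),
        "n_fixed_homogametic": sexlink.n_fixed_homogametic,
        "n_het_all_heterogametic": sexlink.n_het_all_heterogametic,
        "n_diagnostic_snps": sexlink.n_diagnostic,
        "n_sexlinked_snps": sexlink.n_sexlinked,
        "inferred_system": sexlink.inferred_system,
        "n_male_specific_loci": len(sexspecific.male_specific_loci),
        "n_female_specific_loci": len(sexspecific.female_specific_loci),
        "min_restriction_sites": min_restriction_sites(n_specific),
        "n_sexed_males_used": sexspecific.n_sexed_males,
        "n_sexed_females_used": sexspecific.n_sexed_females,
        "n_consensus_called": n_called,
        "consensus_call_fraction": n_called / samples.n_samples,
        "n_discordant_with_phenotype": len(crossval.discordant_samples),
        "n_axis_discordant_excluded": n_axis_discordant,
        "cohort_sex_ratio_p": float(sex_ratios.iloc[0]["p_value"]),
        "threshold_contribution_enrichment": thresholds.contribution_enrichment,
        "threshold_het_fraction_linked": thresholds.het_fraction_linked,
        "threshold_n_axes_scanned": thresholds.n_axes_scanned,
        "threshold_min_separation": thresholds.min_separation,
        "threshold_call_rate_per_pop": filters.call_rate_per_pop,
        "threshold_maf_min": filters.maf_min,
        "threshold_het_excess_max": filters.het_excess_max,
        "threshold_dead_zone": dead_zone,
        "threshold_specific_upper": specific_upper,
        "threshold_specific_lower": specific_lower,
        "sex_ratio_test": "exact_binomial_two_sided",
    }
    if chance_expect is not None:
        summary["chance_sexspecific_expectation"] = chance_expect
    return AnalysisResult(
        genotypes_filtered=filtered,
        attrition=attrition,
        pca=pca,
        sexlink=sexlink,
        sexspecific=sexspecific,
        crossval=crossval,
        sex_ratios=sex_ratios,
        summary=summary,
    )


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline with file IO; returns the run summary."""
    out = rio.ensure_dir(config.output_dir)

    stage = "input"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            genotypes, presence, samples, truth = simulate_dataset(sim)
            rio.write_vcf(genotypes, os.path.join(out, "genotypes.vcf"))
            rio.write_counts_tsv(presence, os.path.join(out, "counts.tsv"))
            rio.write_metadata_tsv(samples, os.path.join(out, "metadata.tsv"))
            from .simulate import write_truth_tsv

            write_truth_tsv(truth, samples, os.path.join(out, "truth.tsv"))
            missing_rate = sim.missing_rate
        else:
            genotypes = rio.read_vcf(config.vcf_path)
            presence = rio.read_counts_tsv(config.counts_path)
            samples = rio.read_metadata_tsv(config.metadata_path)
            missing_rate = None

        stage = "analysis"
        result = analyze(
            genotypes,
            presence,
            samples,
            thresholds=config.thresholds,
            filters=config.filters,
            dead_zone=config.dead_zone,
            specific_upper=config.specific_upper,
            specific_lower=config.specific_lower,
            missing_rate_for_expectation=missing_rate,
        )

        stage = "output"
        _write_outputs(result, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return result.summary


def _write_outputs(result: AnalysisResult, out: str) -> None:
    sl = result.sexlink
    # Per-axis explained variance + chosen axis marker.
    axes = pd.DataFrame(
        {
            "axis": np.arange(1, result.pca.n_axes + 1),
            "explained_variance_pct": result.pca.explained_variance_pct,
            "is_sex_axis": [
                sl.sex_axis is not None and a == sl.sex_axis
                for a in range(result.pca.n_axes)
            ],
        }
    )
    axes.to_csv(
        os.path.join(out, "axis_table.tsv"),
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
    )
    contrib = pd.DataFrame(
        {
            "locus_id": result.genotypes_filtered.snp_ids,
            "contribution_pct": sl.contributions_pct,
        }
    )
    contrib.to_csv(
        os.path.join(out, "snp_contributions.tsv"),
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
    )
    sl.table.to_csv(
        os.path.join(out, "snp_classification.tsv"),
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
    )
    ss = result.sexspecific
    pd.DataFrame(
        {
            "locus_id": ss.male_specific_loci + ss.female_specific_loci,
            "specific_to": ["male"] * len(ss.male_specific_loci)
            + ["female"] * len(ss.female_specific_loci),
        }
    ).to_csv(os.path.join(out, "sexspecific_loci.tsv"), sep="\t", index=False)
    result.crossval.table.to_csv(
        os.path.join(out, "assignments.tsv"),
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
    )
    result.crossval.concordance.to_csv(
        os.path.join(out, "concordance.tsv"), sep="\t"
    )
    result.sex_ratios.to_csv(
        os.path.join(out, "sex_ratios.tsv"),
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
    )
    with open(os.path.join(out, "discordant_samples.txt"), "w") as fh:
        for sid in result.crossval.discordant_samples:
            fh.write(sid + "\n")
    rio.write_summary(result.summary, os.path.join(out, "summary.tsv"))
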