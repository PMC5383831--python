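"""Find sex-linked SNPs by PCA and infer the heterogametic system.

Mean-imputed centred PCA of the filtered genotypes; the axis that best
separates phenotyped males from females is taken as the sex axis (15
axes scanned — a 12-population cohort has up to 11 structure axes, so
the sex axis can only appear beyond them). SNPs enriched on that axis
are classified from their genotype pattern in the two sexes, which
also orients the system (XY when males are the heterozygous sex).
Phenotyped individuals on the wrong side of the axis are recorded for
exclusion from the presence/absence step.
"""

import argparse
import os

import pandas as pd

from radgsd import DetectionThresholds, detect_sexlinked
from radgsd.assignment import UNASSIGNED, assign_by_axis
from radgsd.data_model import UNKNOWN
from radgsd.io import read_metadata_tsv, read_vcf, write_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="scratch/cohort")
    parser.add_argument("--results", default="results")
    parser.add_argument("--n-axes", type=int, default=15)
    args = parser.parse_args()

    genotypes = read_vcf(os.path.join(args.cohort, "genotypes.filtered.vcf"))
    samples = read_metadata_tsv(os.path.join(args.cohort, "metadata.tsv")).aligned_to(
        genotypes.samples
    )
    thresholds = DetectionThresholds(n_axes_scanned=args.n_axes)
    pca, result = detect_sexlinked(genotypes, samples, thresholds)

    os.makedirs(args.results, exist_ok=True)
    pd.DataFrame(
        {
            "axis": range(1, pca.n_axes + 1),
            "explained_variance_pct": pca.explained_variance_pct,
        }
    ).to_csv(
        os.path.join(args.results, "sexlink_axes.tsv"),
        sep="\t",
        index=False,
        float_format="%.4f",
    )
    result.table.to_csv(
        os.path.join("scratch", "snp_classification.tsv"), sep="\t", index=False
    )

    discordant: list[str] = []
    if result.sex_axis is not None:
        calls, _ = assign_by_axis(pca.coordinates[:, result.sex_axis], samples)
        phenotype = samples.sex_array()
        for sid, call, pheno in zip(samples.sample_ids, calls, phenotype):
            if pheno != UNKNOWN and call != UNASSIGNED and call != pheno:
                discordant.append(sid)
    with open(os.path.join(args.results, "axis_discordant_samples.txt"), "w") as fh:
        fh.writelines(s + "\n" for s in discordant)

    summary = {
        "sex_axis": "none" if result.sex_axis is None else result.sex_axis + 1,
        "separation": result.separation_stat,
        "explained_variance_pct": (
            float(pca.explained_variance_pct[result.sex_axis])
            if result.sex_axis is not None
            else 0.0
        ),
        "n_candidates": len(result.candidate_indices),
        "n_diagnostic": result.n_diagnostic,
        "n_sexlinked": result.n_sexlinked,
        "n_fixed_homogametic": result.n_fixed_homogametic,
        "n_het_all_heterogametic": result.n_het_all_heterogametic,
        "inferred_system": result.inferred_system,
        "n_axis_discordant": len(discordant),
    }
    write_summary(summary, os.path.join(args.results, "sexlink_summary.tsv"))
    for key, value in summary.items():
        print(f"{key}\t{value}")


if __name__ == "__main__":
    main()
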