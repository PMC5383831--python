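"""Detect sex-specific (hemizygous) loci from presence/absence.

A locus is male-specific when every phenotyped male has at least one
read and no phenotyped female has any. Individuals flagged as
axis-discordant in step 03 are excluded (their phenotype is suspect and
a single genetically-male "female" would erase every true Y locus).
The chance expectation under pure technical missingness quantifies the
false-positive risk, and the locus count implies a minimum number of
male-specific restriction sites.
"""

import argparse
import os

import pandas as pd

from radgsd import (
    chance_sexspecific_expectation,
    find_sex_specific,
    min_restriction_sites,
)
from radgsd.data_model import SampleTable, UNKNOWN
from radgsd.io import read_counts_tsv, read_metadata_tsv, write_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="scratch/cohort")
    parser.add_argument("--results", default="results")
    parser.add_argument("--missing-rate", type=float, default=0.05)
    args = parser.parse_args()

    presence = read_counts_tsv(os.path.join(args.cohort, "counts.tsv"))
    samples = read_metadata_tsv(os.path.join(args.cohort, "metadata.tsv")).aligned_to(
        presence.samples
    )
    discordant_path = os.path.join(args.results, "axis_discordant_samples.txt")
    excluded = set()
    if os.path.exists(discordant_path):
        with open(discordant_path) as fh:
            excluded = {line.strip() for line in fh if line.strip()}
    sexes = [
        UNKNOWN if sid in excluded else sex
        for sid, sex in zip(samples.sample_ids, samples.phenotype_sex)
    ]
    samples = SampleTable(samples.sample_ids, samples.populations, sexes)

    result = find_sex_specific(presence, samples)
    n_specific = max(
        len(result.male_specific_loci), len(result.female_specific_loci)
    )
    chance = chance_sexspecific_expectation(
        presence.n_loci, result.n_sexed_males, result.n_sexed_females, args.missing_rate
    )
    pd.DataFrame(
        {
            "locus_id": result.male_specific_loci + result.female_specific_loci,
            "specific_to": ["male"] * len(result.male_specific_loci)
            + ["female"] * len(result.female_specific_loci),
        }
    ).to_csv(
        os.path.join(args.results, "sexspecific_loci.tsv"), sep="\t", index=False
    )
    summary = {
        "n_sexed_males": result.n_sexed_males,
        "n_sexed_females": result.n_sexed_females,
        "n_excluded_discordant": len(excluded),
        "n_male_specific": len(result.male_specific_loci),
        "n_female_specific": len(result.female_specific_loci),
        "min_restriction_sites": min_restriction_sites(n_specific),
        "chance_expectation": chance,
    }
    write_summary(summary, os.path.join(args.results, "sexspecific_summary.tsv"))
    for key, value in summary.items():
        print(f"{key}\t{value}")


if __name__ == "__main__":
    main()
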