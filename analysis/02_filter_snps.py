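"""Quality-filter the SNP matrix before sex-linkage inference.

Keeps SNPs genotyped in >= 75% of individuals within every population
(the heterozygote-excess paralog screen stays off: sex-linked markers
are systematically heterozygous in one sex and would be destroyed).
Writes the filtered VCF to scratch/ and the attrition table to results/.
"""

import argparse
import os

import pandas as pd

from radgsd import FilterConfig, apply_filters
from radgsd.io import read_metadata_tsv, read_vcf, write_vcf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="scratch/cohort")
    parser.add_argument("--results", default="results")
    args = parser.parse_args()

    genotypes = read_vcf(os.path.join(args.cohort, "genotypes.vcf"))
    samples = read_metadata_tsv(os.path.join(args.cohort, "metadata.tsv"))
    filtered, attrition = apply_filters(genotypes, samples, FilterConfig())
    write_vcf(filtered, os.path.join(args.cohort, "genotypes.filtered.vcf"))

    os.makedirs(args.results, exist_ok=True)
    pd.DataFrame(attrition.items(), columns=["stage", "n_snps"]).to_csv(
        os.path.join(args.results, "filter_attrition.tsv"), sep="\t", index=False
    )
    print(
        f"{attrition['input_snps']} SNPs in, {filtered.n_snps} retained "
        f"(call rate >= 75% in all {len(set(samples.populations))} populations)"
    )


if __name__ == "__main__":
    main()
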