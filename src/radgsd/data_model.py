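"""Core containers for RAD-seq sex-determination analysis.

Three input artefacts are modelled: a biallelic SNP genotype matrix
(alternate-allele counts 0/1/2 with a missing sentinel), a locus x
individual read-count matrix used for presence/absence analysis, and a
per-sample metadata table carrying population labels and phenotypic sex.
The SNP universe and the presence-locus universe are distinct and need
not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call. Out-of-band by construction —
#: never a valid allele count.
MISSING: int = -9

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
SEX_VALUES = (MALE, FEMALE, UNKNOWN)


class ValidationError(ValueError):
    """Raised when an input artefact violates a structural invariant."""


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    if any(not i for i in ids):
        raise ValidationError(f"empty {what} identifier")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicated {what} identifier: {dup!r}")


@dataclass
class SampleTable:
    """Per-individual metadata: population label and phenotypic sex."""

    sample_ids: list[str]
    populations: list[str]
    phenotype_sex: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.populations = [str(p) for p in self.populations]
        self.phenotype_sex = [str(s) for s in self.phenotype_sex]
        if not (len(self.sample_ids) == len(self.populations) == len(self.phenotype_sex)):
            raise ValidationError("sample table columns have unequal lengths")
        _check_unique_ids(self.sample_ids, "sample")
        for s in self.phenotype_sex:
            if s not in SEX_VALUES:
                raise ValidationError(f"unrecognized phenotype sex {s!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sex_array(self) -> np.ndarray:
        return np.asarray(self.phenotype_sex, dtype=object)

    def indices_of_sex(self, sex: str) -> np.ndarray:
        """Row indices of phenotyped individuals of the given sex."""
        return np.flatnonzero(self.sex_array() == sex)

    @property
    def male_indices(self) -> np.ndarray:
        return self.indices_of_sex(MALE)

    @property
    def female_indices(self) -> np.ndarray:
        return self.indices_of_sex(FEMALE)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Reorder to match ``sample_ids``; the sample sets must agree."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        extra = set(self.sample_ids) - set(sample_ids)
        if missing or extra:
            raise ValidationError(
                "sample sets disagree between matrix and metadata "
                f"(missing from metadata: {sorted(missing)[:5]}, "
                f"absent from matrix: {sorted(extra)[:5]})"
            )
        order = [pos[s] for s in sample_ids]
        return SampleTable(
            [self.sample_ids[i] for i in order],
            [self.populations[i] for i in order],
            [self.phenotype_sex[i] for i in order],
        )


@dataclass
class SnpRecord:
    """A biallelic SNP from an anonymous RAD catalog tag."""

    locus_id: str
    allele_ref: str
    allele_alt: str
    position: Optional[int] = None  # 1-based, optional

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_alt:
            raise ValidationError(
                f"SNP {self.locus_id}: ref and alt alleles are identical"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele counts in {0,1,2, MISSING}."""

    samples: list[str]
    snps: list[SnpRecord]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique_ids(self.samples, "sample")
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("genotype values must be integers")
        if self.values.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"genotype grid shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            bad = self.values[~ok].flat[0]
            raise ValidationError(f"invalid genotype value {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.locus_id for s in self.snps]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns, preserving order of ``index``."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in index],
            values=self.values[:, index].copy(),
        )


@dataclass
class PresenceMatrix:
    """Individuals x catalog loci read counts; presence := count >= 1."""

    samples: list[str]
    loci: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique_ids(self.samples, "sample")
        _check_unique_ids(self.loci, "locus")
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("read counts must be integers")
        if self.counts.shape != (len(self.samples), len(self.loci)):
            raise ValidationError(
                f"count grid shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative read count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence grid (one read or more)."""
        return self.counts >= 1


def check_samples_match(sample_ids: Sequence[str], table: SampleTable) -> SampleTable:
    """Validate sample-set agreement and return the table aligned to the matrix order."""
    return table.aligned_to(sample_ids)
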