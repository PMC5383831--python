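"""Sex-specific (hemizygous) locus detection from presence/absence.

A locus is male-specific when it has at least one read in every
phenotyped male and no read in any phenotyped female (female-specific
symmetrically). Zero reads is treated as absence: technical missingness
and true biological absence are confounded, which is why the chance
expectation under pure missingness is computed alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import PresenceMatrix, SampleTable, check_samples_match


@dataclass
class SexSpecificResult:
    male_specific_loci: list[str]
    female_specific_loci: list[str]
    n_sexed_males: int
    n_sexed_females: int
    #: reads-per-sex summary per detected locus: (locus_id, n males present, n females present)
    presence_by_sex: list[tuple[str, int, int]] = field(default_factory=list)


def find_sex_specific(
    presence: PresenceMatrix,
    samples: SampleTable,
    min_count: int = 1,
    min_sexed_warn: int = 10,
) -> SexSpecificResult:
    """Detect loci present in every individual of one sex, absent in the other.

    Unsexed individuals are ignored. ``min_count`` is the read threshold
    for presence (default 1, i.e. one read or more). Detection on fewer
    than ``min_sexed_warn`` individuals per sex warns about false
    positives from chance missingness.
    """
    samples = check_samples_match(presence.samples, samples)
    males, females = samples.male_indices, samples.female_indices
    if len(males) == 0 and len(females) == 0:
        raise ValueError("sex-specific detection needs phenotyped individuals")
    if 0 < len(males) < min_sexed_warn or 0 < len(females) < min_sexed_warn:
        warnings.warn(
            f"fewer than {min_sexed_warn} sexed individuals in one sex: "
            "sex-specific calls are vulnerable to chance missingness",
            stacklevel=2,
        )
    present = presence.counts >= min_count
    in_all_males = present[males, :].all(axis=0) if len(males) else np.zeros(presence.n_loci, bool)
    in_no_male = ~present[males, :].any(axis=0) if len(males) else np.ones(presence.n_loci, bool)
    in_all_females = present[females, :].all(axis=0) if len(females) else np.zeros(presence.n_loci, bool)
    in_no_female = ~present[females, :].any(axis=0) if len(females) else np.ones(presence.n_loci, bool)
    male_mask = in_all_males & in_no_female
    female_mask = in_all_females & in_no_male
    loci = np.asarray(presence.loci, dtype=object)
    n_pres_m = present[males, :].sum(axis=0)
    n_pres_f = present[females, :].sum(axis=0)
    by_sex = [
        (str(loci[j]), int(n_pres_m[j]), int(n_pres_f[j]))
        for j in np.flatnonzero(male_mask | female_mask)
    ]
    return SexSpecificResult(
        male_specific_loci=[str(x) for x in loci[male_mask]],
        female_specific_loci=[str(x) for x in loci[female_mask]],
        n_sexed_males=len(males),
        n_sexed_females=len(females),
        presence_by_sex=by_sex,
    )


def chance_sexspecific_expectation(
    n_loci: int, n_males: int, n_females: int, missing_rate: float
) -> float:
    """Expected count of everywhere-present loci passing the filter by chance.

    A neutral locus present in all individuals looks sex-specific only
    if technical missingness removes it from every individual of one
    sex while sparing every individual of the other:
    n_loci * [ (1-m)^n_m * m^n_f + (1-m)^n_f * m^n_m ].
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0,1]")
    if n_loci < 0 or n_males < 0 or n_females < 0:
        raise ValueError("counts must be non-negative")
    m = missing_rate
    return n_loci * (
        (1 - m) ** n_males * m**n_females + (1 - m) ** n_females * m**n_males
    )


def min_restriction_sites(n_loci: int) -> int:
    """Minimum number of cut sites implied by a set of single-end RAD loci.

    Each restriction site yields at most two loci, one per flank, so n
    loci require at least ceil(n / 2) sites.
    """
    if n_loci < 0:
        raise ValueError("n_loci must be non-negative")
    return math.ceil(n_loci / 2)
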