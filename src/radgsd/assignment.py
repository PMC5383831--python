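"""Per-individual genetic sexing and cross-validation of the two marker classes.

Every individual is sexed twice — by its coordinate on the sex axis of
the genotype PCA, and by the fraction of detected sex-specific loci it
carries — and the two calls are crossed. Phenotyped individuals whose
consensus genetic sex contradicts the recorded phenotype are flagged,
never relabelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    FEMALE,
    MALE,
    UNKNOWN,
    PresenceMatrix,
    SampleTable,
    check_samples_match,
)
from .sex_specific import SexSpecificResult

UNASSIGNED = "unassigned"


@dataclass
class CrossValidation:
    """Concordance of axis-based and specific-locus-based sexing."""

    table: pd.DataFrame = field(repr=False)  # per-individual assignments
    concordance: pd.DataFrame = field(repr=False)  # axis call x specific call
    discordant_samples: list[str] = field(default_factory=list)


def assign_by_axis(
    coordinates: np.ndarray,
    samples: SampleTable,
    dead_zone: float = 0.10,
) -> tuple[np.ndarray, float]:
    """Call sex from the sex-axis coordinate.

    The decision boundary is the midpoint of the phenotyped male and
    female centroids; individuals falling inside a dead zone of total
    width ``dead_zone`` x centroid distance around the midpoint are left
    unassigned. Returns (calls, midpoint).
    """
    males, females = samples.male_indices, samples.female_indices
    if len(males) < 2 or len(females) < 2:
        raise ValueError("axis assignment needs >= 2 phenotyped individuals per sex")
    cm = float(coordinates[males].mean())
    cf = float(coordinates[females].mean())
    calls = np.full(len(coordinates), UNASSIGNED, dtype=object)
    if cm == cf:
        import warnings

        warnings.warn("male and female centroids coincide; no axis calls made")
        return calls, cm
    mid = 0.5 * (cm + cf)
    half_zone = 0.5 * dead_zone * abs(cm - cf)
    male_side = np.sign(cm - mid)
    offset = (coordinates - mid) * male_side
    calls[offset > half_zone] = MALE
    calls[offset < -half_zone] = FEMALE
    return calls, mid


def assign_by_specific(
    presence: PresenceMatrix,
    specific: SexSpecificResult,
    upper: float = 0.50,
    lower: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Call sex from the fraction of detected sex-specific loci present.

    Uses whichever sex-specific list was detected (male-specific in an
    XY system, female-specific in ZW). An individual carrying at least
    ``upper`` of the loci is called the heterogametic (locus-bearing)
    sex; at most ``lower``, the homogametic sex; otherwise unassigned.
    Returns (calls, n_present, frac_present).
    """
    n_male_loci = len(specific.male_specific_loci)
    n_female_loci = len(specific.female_specific_loci)
    if n_male_loci == 0 and n_female_loci == 0:
        raise ValueError("no sex-specific loci detected; cannot assign")
    if n_male_loci >= n_female_loci:
        target, bearing_sex, other_sex = specific.male_specific_loci, MALE, FEMALE
    else:
        target, bearing_sex, other_sex = specific.female_specific_loci, FEMALE, MALE
    pos = {l: j for j, l in enumerate(presence.loci)}
    idx = np.asarray([pos[l] for l in target], dtype=int)
    present = presence.presence[:, idx]
    n_present = present.sum(axis=1)
    frac = n_present / len(idx)
    calls = np.full(presence.n_samples, UNASSIGNED, dtype=object)
    calls[frac >= upper] = bearing_sex
    calls[frac <= lower] = other_sex
    return calls, n_present.astype(int), frac


def _consensus(axis_call: str, specific_call: str) -> tuple[str, bool]:
    """(consensus sex, conflict flag). Agreement of all *made* calls is required."""
    made = [c for c in (axis_call, specific_call) if c != UNASSIGNED]
    if not made:
        return UNASSIGNED, False
    if all(c == made[0] for c in made):
        return made[0], False
    return UNASSIGNED, True


def crossvalidate(
    axis_calls: Sequence[str],
    specific_calls: Sequence[str],
    samples: SampleTable,
    axis_coordinates: Optional[np.ndarray] = None,
    n_specific_present: Optional[np.ndarray] = None,
    frac_specific_present: Optional[np.ndarray] = None,
) -> CrossValidation:
    """Cross the two call sets and flag phenotype/genotype discordance.

    The consensus is the shared call when the methods agree (a call made
    by only one method stands); method disagreement leaves the
    individual unassigned and flagged. Discordant samples are phenotyped
    individuals whose consensus genetic sex contradicts their phenotype.
    """
    axis_calls = np.asarray(list(axis_calls), dtype=object)
    specific_calls = np.asarray(list(specific_calls), dtype=object)
    if not (len(axis_calls) == len(specific_calls) == samples.n_samples):
        raise ValueError("call vectors and sample table must cover the same individuals")
    n = samples.n_samples
    consensus = np.empty(n, dtype=object)
    conflict = np.zeros(n, dtype=bool)
    for i in range(n):
        consensus[i], conflict[i] = _consensus(axis_calls[i], specific_calls[i])
    phenotype = samples.sex_array()
    discordant = (
        (phenotype != UNKNOWN)
        & (consensus != UNASSIGNED)
        & (consensus != phenotype)
    )
    table = pd.DataFrame(
        {
            "sample_id": samples.sample_ids,
            "population": samples.populations,
            "phenotype_sex": phenotype,
            "axis_coordinate": (
                axis_coordinates if axis_coordinates is not None else np.nan
            ),
            "n_specific_present": (
                n_specific_present if n_specific_present is not None else -1
            ),
            "frac_specific_present": (
                frac_specific_present if frac_specific_present is not None else np.nan
            ),
            "sex_by_axis": axis_calls,
            "sex_by_specific": specific_calls,
            "consensus_sex": consensus,
            "method_conflict": conflict,
            "discordant_with_phenotype": discordant,
        }
    )
    order = [MALE, FEMALE, UNASSIGNED]
    concordance = (
        pd.crosstab(table["sex_by_axis"], table["sex_by_specific"])
        .reindex(index=order, columns=order, fill_value=0)
        .rename_axis(index="sex_by_axis", columns="sex_by_specific")
    )
    return CrossValidation(
        table=table,
        concordance=concordance,
        discordant_samples=list(table.loc[discordant, "sample_id"]),
    )


def sex_ratio_test(
    n_male: int,
    n_female: int,
    randomized: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided exact binomial test of a balanced (1:1) sex ratio.

    With ``randomized=True`` the discrete exact p-value is smoothed by
    the standard randomized construction p = P(T > t) + U * P(T = t) on
    the statistic T = |k - n/2|, which is exactly Uniform(0,1) under the
    null — useful for calibration diagnostics, never for reporting.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("counts must be non-negative")
    n = n_male + n_female
    if n == 0:
        raise ValueError("at least one individual is required")
    if not randomized:
        return float(stats.binomtest(n_male, n, 0.5).pvalue)
    if rng is None:
        rng = np.random.default_rng()
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, 0.5)
    t_all = np.abs(k - n / 2.0)
    t_obs = abs(n_male - n / 2.0)
    p_gt = float(pmf[t_all > t_obs].sum())
    p_eq = float(pmf[t_all == t_obs].sum())
    return p_gt + float(rng.random()) * p_eq


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration for samples of at most 20 without ties; normal
    approximation with tie correction otherwise. Degenerate input (all
    values identical across both groups) returns 1.0.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if max(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def sex_ratio_by_population(
    table: pd.DataFrame, call_column: str = "consensus_sex"
) -> pd.DataFrame:
    """Cohort-wide and per-population balanced-sex-ratio tests on called individuals."""
    rows = []
    groups = [("ALL", table)] + [
        (pop, sub) for pop, sub in table.groupby("population", sort=True)
    ]
    for name, sub in groups:
        n_m = int((sub[call_column] == MALE).sum())
        n_f = int((sub[call_column] == FEMALE).sum())
        p = sex_ratio_test(n_m, n_f) if (n_m + n_f) > 0 else np.nan
        rows.append({"population": name, "n_male": n_m, "n_female": n_f, "p_value": p})
    return pd.DataFrame(rows)
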