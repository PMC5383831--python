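"""Sex-linked SNP discovery via genotype PCA.

A mean-imputed, centred (never scaled) PCA of the genotype matrix is
scanned for the axis that best separates phenotyped males from females.
SNPs loading heavily on that axis are candidate gametologs; their
genotype patterns in the two sexes classify them as diagnostic
(homozygous in every individual of one sex, heterozygous in every
individual of the other), sex-linked (the same pattern up to a
tolerance), or rejected, and the orientation of heterozygosity decides
between male (XY) and female (ZW) heterogamety.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import (
    FEMALE,
    MALE,
    MISSING,
    GenotypeMatrix,
    SampleTable,
    check_samples_match,
)

SYSTEM_XY = "XY"
SYSTEM_ZW = "ZW"
SYSTEM_UNDETERMINED = "undetermined"


@dataclass
class DetectionThresholds:
    """Tunable detection thresholds with the pipeline defaults.

    ``contribution_enrichment``: a SNP is a candidate when its
    contribution to the sex axis exceeds this multiple of the uniform
    expectation 100/S % (an S-SNP axis spreads 100% over S loci, so an
    absolute percent cut cannot mark hundreds of leading SNPs at
    realistic S). Candidacy is deliberately permissive: the decisive
    filter is the genotype-pattern classification, not this cut.
    ``het_fraction_linked``: minimum fraction of the heterogametic sex
    heterozygous (and of the homogametic sex fixed) for the sex-linked
    class. ``min_separation``: minimum standardized male/female
    separation for an axis to count as a sex axis.
    """

    contribution_enrichment: float = 3.0
    het_fraction_linked: float = 0.70
    n_axes_scanned: int = 10
    min_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.contribution_enrichment <= 0:
            raise ValueError("contribution_enrichment must be > 0")
        if not 0.0 <= self.het_fraction_linked <= 1.0:
            raise ValueError("het_fraction_linked must be in [0,1]")
        if self.n_axes_scanned < 1:
            raise ValueError("n_axes_scanned must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass
class PcaResult:
    coordinates: np.ndarray = field(repr=False)  # individuals x axes
    loadings: np.ndarray = field(repr=False)  # SNPs x axes
    explained_variance_pct: np.ndarray = field(repr=False)  # per axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class SexLinkResult:
    sex_axis: Optional[int]  # 0-based axis index, None if undetermined
    separation_stat: float
    contributions_pct: np.ndarray = field(repr=False)
    candidate_indices: np.ndarray = field(repr=False)
    table: pd.DataFrame = field(repr=False)  # per-candidate statistics
    n_fixed_homogametic: int = 0
    n_het_all_heterogametic: int = 0
    n_diagnostic: int = 0
    n_sexlinked: int = 0
    inferred_system: str = SYSTEM_UNDETERMINED


def impute_and_center(genotypes: GenotypeMatrix) -> np.ndarray:
    """Replace missing calls by the per-SNP mean genotype, then centre columns.

    The column mean of 0/1/2 genotypes equals twice the alternate-allele
    frequency, so this is mean-allele-frequency imputation on the
    genotype scale. No variance scaling is applied.
    """
    values = genotypes.values.astype(float)
    called = genotypes.values != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        j = int(np.flatnonzero(n_called == 0)[0])
        raise ValueError(
            f"SNP {genotypes.snps[j].locus_id} is missing in all individuals; "
            "apply the call-rate/MAF filters first"
        )
    col_mean = np.where(called, values, 0.0).sum(axis=0) / n_called
    values = np.where(called, values, col_mean[None, :])
    return values - values.mean(axis=0)[None, :]


def run_pca(matrix: np.ndarray, n_axes: int) -> PcaResult:
    """Deterministic full-SVD PCA of a centred matrix.

    Axes are covariance eigenvectors ordered by decreasing eigenvalue;
    coordinates are projections; explained variance is the eigenvalue
    share. Deterministic up to per-axis sign. ``n_axes`` beyond the
    matrix rank bound min(N-1, S) is truncated with a warning.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    n, s = matrix.shape
    max_axes = max(1, min(n - 1, s))
    if n_axes > max_axes:
        warnings.warn(
            f"n_axes={n_axes} exceeds the rank bound {max_axes}; truncating",
            stacklevel=2,
        )
        n_axes = max_axes
    pca = PCA(n_components=n_axes, svd_solver="full")
    coords = pca.fit_transform(matrix)
    return PcaResult(
        coordinates=coords,
        loadings=pca.components_.T.copy(),
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
    )


def _separation(coords: np.ndarray, males: np.ndarray, females: np.ndarray) -> float:
    """|mean_m - mean_f| / pooled within-sex standard deviation."""
    xm, xf = coords[males], coords[females]
    diff = abs(float(xm.mean()) - float(xf.mean()))
    nm, nf = len(xm), len(xf)
    pooled_var = (
        (nm - 1) * xm.var(ddof=1) + (nf - 1) * xf.var(ddof=1)
    ) / (nm + nf - 2)
    pooled_sd = float(np.sqrt(pooled_var))
    if pooled_sd == 0.0:
        return np.inf if diff > 0 else 0.0
    return diff / pooled_sd


def select_sex_axis(
    pca: PcaResult,
    samples: SampleTable,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> tuple[Optional[int], float]:
    """Pick the axis with the largest standardized male/female separation.

    Scans the first ``n_axes_scanned`` axes; ties break to the lower
    index. Returns (None, best) when the best separation falls short of
    ``min_separation`` — no axis is sex-associated.
    """
    males, females = samples.male_indices, samples.female_indices
    if len(males) < 2 or len(females) < 2:
        raise ValueError(
            "axis selection needs at least 2 phenotyped individuals of each sex"
        )
    n_scan = min(thresholds.n_axes_scanned, pca.n_axes)
    seps = np.array(
        [_separation(pca.coordinates[:, a], males, females) for a in range(n_scan)]
    )
    best = int(np.argmax(seps))  # argmax takes the first (lowest) on ties
    if seps[best] < thresholds.min_separation:
        return None, float(seps[best])
    return best, float(seps[best])


def orient_axis(pca: PcaResult, axis: int, samples: SampleTable) -> PcaResult:
    """Flip the axis sign, if needed, so phenotyped males have positive mean.

    PCA signs are arbitrary; fixing the orientation makes downstream
    sign-based assignment deterministic.
    """
    males = samples.male_indices
    if len(males) and pca.coordinates[males, axis].mean() < 0:
        pca.coordinates[:, axis] *= -1
        pca.loadings[:, axis] *= -1
    return pca


def locus_contributions(pca: PcaResult, axis: int) -> np.ndarray:
    """Per-SNP contribution (%) to one axis: squared loading share; sums to 100."""
    if not 0 <= axis < pca.n_axes:
        raise IndexError(f"axis {axis} out of range")
    loading = pca.loadings[:, axis]
    total = float(np.sum(loading**2))
    if total == 0.0:
        raise ValueError(f"axis {axis} has a zero loading vector")
    return 100.0 * loading**2 / total


def _sex_pattern_stats(
    column: np.ndarray, idx: np.ndarray
) -> tuple[float, float, int]:
    """(fraction heterozygous, fraction fixed for the majority homozygote, n called)."""
    g = column[idx]
    g = g[g != MISSING]
    if len(g) == 0:
        return np.nan, np.nan, 0
    frac_het = float(np.mean(g == 1))
    n_ref, n_alt = int(np.sum(g == 0)), int(np.sum(g == 2))
    majority_hom = 0 if n_ref >= n_alt else 2
    frac_fixed = float(np.mean(g == majority_hom))
    return frac_het, frac_fixed, len(g)


def classify_sexlinked(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    candidate_indices: Sequence[int],
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> pd.DataFrame:
    """Classify candidate SNPs from their genotype pattern in the two sexes.

    Per candidate, over phenotyped non-missing calls: the fraction of
    males heterozygous, the fraction of females homozygous for the
    majority female allele, and the sex-swapped pair. A SNP is
    "diagnostic" when one sex is 100% fixed homozygous and the other
    100% heterozygous; "sex_linked" when both fractions clear
    ``het_fraction_linked`` in a consistent orientation; otherwise
    "rejected". Candidates with no sexed calls are rejected and flagged.
    """
    candidate_indices = np.asarray(list(candidate_indices), dtype=int)
    if len(candidate_indices) == 0:
        raise ValueError("candidate set is empty")
    samples = check_samples_match(genotypes.samples, samples)
    males, females = samples.male_indices, samples.female_indices
    if len(males) == 0 or len(females) == 0:
        raise ValueError("classification needs phenotyped individuals of both sexes")
    t = thresholds.het_fraction_linked
    rows = []
    for j in candidate_indices:
        col = genotypes.values[:, j]
        het_m, fixed_m, n_m = _sex_pattern_stats(col, males)
        het_f, fixed_f, n_f = _sex_pattern_stats(col, females)
        no_calls = n_m == 0 and n_f == 0
        if no_calls or n_m == 0 or n_f == 0:
            label, orientation = "rejected", "none"
        else:
            diag_xy = fixed_f == 1.0 and het_m == 1.0
            diag_zw = fixed_m == 1.0 and het_f == 1.0
            linked_xy = het_m > t and fixed_f >= t
            linked_zw = het_f > t and fixed_m >= t
            if diag_xy or diag_zw:
                label = "diagnostic"
                orientation = SYSTEM_XY if diag_xy else SYSTEM_ZW
            elif linked_xy or linked_zw:
                label = "sex_linked"
                orientation = SYSTEM_XY if linked_xy else SYSTEM_ZW
            else:
                label, orientation = "rejected", "none"
        rows.append(
            {
                "snp_index": int(j),
                "locus_id": genotypes.snps[j].locus_id,
                "fraction_het_in_males": het_m,
                "fraction_fixed_homozygous_in_females": fixed_f,
                "fraction_het_in_females": het_f,
                "fraction_fixed_homozygous_in_males": fixed_m,
                "n_called_males": n_m,
                "n_called_females": n_f,
                "label": label,
                "orientation": orientation,
                "no_sexed_calls": no_calls,
            }
        )
    return pd.DataFrame(rows)


def infer_system(classification: pd.DataFrame) -> str:
    """XY if the heterozygous-enriched sex among informative SNPs is male, ZW if female.

    Informative SNPs are those labelled diagnostic or sex_linked;
    undetermined when neither orientation holds a strict majority (or
    there are no informative SNPs).
    """
    informative = classification[
        classification["label"].isin(("diagnostic", "sex_linked"))
    ]
    n_xy = int((informative["orientation"] == SYSTEM_XY).sum())
    n_zw = int((informative["orientation"] == SYSTEM_ZW).sum())
    if n_xy > n_zw:
        return SYSTEM_XY
    if n_zw > n_xy:
        return SYSTEM_ZW
    return SYSTEM_UNDETERMINED


def detect_sexlinked(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    thresholds: DetectionThresholds = DetectionThresholds(),
) -> tuple[PcaResult, SexLinkResult]:
    """Full sex-linkage scan: PCA, axis choice, contributions, classification."""
    samples = check_samples_match(genotypes.samples, samples)
    centered = impute_and_center(genotypes)
    pca = run_pca(centered, thresholds.n_axes_scanned)
    axis, separation = select_sex_axis(pca, samples, thresholds)
    if axis is None:
        empty = pd.DataFrame(
            columns=[
                "snp_index",
                "locus_id",
                "fraction_het_in_males",
                "fraction_fixed_homozygous_in_females",
                "fraction_het_in_females",
                "fraction_fixed_homozygous_in_males",
                "n_called_males",
                "n_called_females",
                "label",
                "orientation",
                "no_sexed_calls",
            ]
        )
        result = SexLinkResult(
            sex_axis=None,
            separation_stat=separation,
            contributions_pct=np.zeros(genotypes.n_snps),
            candidate_indices=np.array([], dtype=int),
            table=empty,
        )
        return pca, result
    pca = orient_axis(pca, axis, samples)
    contributions = locus_contributions(pca, axis)
    uniform_pct = 100.0 / genotypes.n_snps
    candidates = np.flatnonzero(
        contributions > thresholds.contribution_enrichment * uniform_pct
    )
    if len(candidates) == 0:
        table = classify_sexlinked(
            genotypes, samples, [int(np.argmax(contributions))], thresholds
        ).iloc[0:0]
    else:
        table = classify_sexlinked(genotypes, samples, candidates, thresholds)
    system = infer_system(table) if len(table) else SYSTEM_UNDETERMINED
    het_sex_is_male = system != SYSTEM_ZW  # XY or undetermined -> male orientation
    fixed_col = (
        "fraction_fixed_homozygous_in_females"
        if het_sex_is_male
        else "fraction_fixed_homozygous_in_males"
    )
    het_col = (
        "fraction_het_in_males" if het_sex_is_male else "fraction_het_in_females"
    )
    n_fixed = int((table[fixed_col] == 1.0).sum()) if len(table) else 0
    n_het_all = int((table[het_col] == 1.0).sum()) if len(table) else 0
    result = SexLinkResult(
        sex_axis=axis,
        separation_stat=separation,
        contributions_pct=contributions,
        candidate_indices=candidates,
        table=table,
        n_fixed_homogametic=n_fixed,
        n_het_all_heterogametic=n_het_all,
        n_diagnostic=int((table["label"] == "diagnostic").sum()) if len(table) else 0,
        n_sexlinked=int((table["label"] == "sex_linked").sum()) if len(table) else 0,
        inferred_system=system,
    )
    return pca, result
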