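"""PCA-based sex-linkage detection: imputation, axis choice, classification."""

import numpy as np
import pandas as pd
import pytest

from radgsd import (
    FEMALE,
    MALE,
    MISSING,
    UNKNOWN,
    DetectionThresholds,
    GenotypeMatrix,
    SampleTable,
    SnpRecord,
    classify_sexlinked,
    detect_sexlinked,
    impute_and_center,
    infer_system,
    locus_contributions,
    run_pca,
    select_sex_axis,
    simulate_dataset,
)
from radgsd.sexlink import PcaResult, orient_axis

from conftest import small_config


def make_matrix(values) -> GenotypeMatrix:
    values = np.asarray(values, dtype=np.int16)
    n, s = values.shape
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        snps=[SnpRecord(f"l{j}", "A", "C") for j in range(s)],
        values=values,
    )


def make_sexed_table(sexes) -> SampleTable:
    return SampleTable(
        [f"S{i}" for i in range(len(sexes))], ["P0"] * len(sexes), list(sexes)
    )


class TestImputeAndCenter:
    def test_missing_replaced_by_column_mean_then_centered(self):
        g = make_matrix([[0], [2], [MISSING]])
        out = impute_and_center(g)
        assert out[:, 0] == pytest.approx([-1.0, 1.0, 0.0])

    def test_complete_column_only_centered(self):
        g = make_matrix([[0], [1], [2]])
        assert impute_and_center(g)[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_columns_have_zero_mean(self, rng):
        values = rng.choice([0, 1, 2, MISSING], size=(12, 20), p=[0.3, 0.3, 0.3, 0.1])
        out = impute_and_center(make_matrix(values))
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_all_missing_snp_raises(self):
        g = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="filter"):
            impute_and_center(g)


class TestRunPca:
    def test_rank_one_matrix_explains_everything_on_axis_one(self):
        m = np.outer([1.0, -1.0, 2.0, -2.0], [1.0, 2.0, 3.0])
        m -= m.mean(axis=0)
        p = run_pca(m, 2)
        assert p.explained_variance_pct[0] == pytest.approx(100.0)

    def test_two_by_two_closed_form(self):
        p = run_pca(np.array([[-1.0, -1.0], [1.0, 1.0]]), 1)
        assert np.abs(p.coordinates[:, 0]) == pytest.approx([np.sqrt(2)] * 2)

    def test_excess_axes_truncated_with_warning(self):
        m = np.random.default_rng(0).normal(size=(4, 6))
        m -= m.mean(axis=0)
        with pytest.warns(UserWarning, match="rank"):
            p = run_pca(m, 10)
        assert p.n_axes == 3

    def test_explained_variance_is_a_partition(self, rng):
        m = rng.normal(size=(15, 8))
        m -= m.mean(axis=0)
        p = run_pca(m, 8)
        assert p.explained_variance_pct.sum() == pytest.approx(100.0)
        assert (p.explained_variance_pct >= 0).all()


class TestContributions:
    def test_squared_loading_shares(self):
        p = PcaResult(
            coordinates=np.zeros((2, 1)),
            loadings=np.array([[0.6], [0.8]]),
            explained_variance_pct=np.array([100.0]),
        )
        assert locus_contributions(p, 0) == pytest.approx([36.0, 64.0])

    def test_single_snp_axis_is_total(self):
        p = PcaResult(np.zeros((2, 1)), np.array([[0.3]]), np.array([100.0]))
        assert locus_contributions(p, 0) == pytest.approx([100.0])

    def test_zero_loading_vector_raises(self):
        p = PcaResult(np.zeros((2, 1)), np.zeros((3, 1)), np.array([0.0]))
        with pytest.raises(ValueError):
            locus_contributions(p, 0)

    def test_contributions_sum_to_100_on_every_axis(self, rng):
        loadings = rng.normal(size=(25, 5))
        p = PcaResult(np.zeros((10, 5)), loadings, np.full(5, 20.0))
        for axis in range(5):
            assert locus_contributions(p, axis).sum() == pytest.approx(100.0, abs=1e-9)


class TestSelectSexAxis:
    def test_perfect_separation_selected_with_infinite_stat(self):
        coords = np.array([[1.0, 0.1], [1.0, -0.2], [-1.0, 0.3], [-1.0, 0.0]])
        p = PcaResult(coords, np.zeros((3, 2)), np.array([60.0, 40.0]))
        table = make_sexed_table([MALE, MALE, FEMALE, FEMALE])
        axis, sep = select_sex_axis(p, table)
        assert axis == 0 and np.isinf(sep)

    def test_no_separating_axis_returns_none(self, rng):
        coords = rng.normal(size=(40, 5))
        p = PcaResult(coords, np.zeros((3, 5)), np.full(5, 20.0))
        table = make_sexed_table([MALE, FEMALE] * 20)
        axis, sep = select_sex_axis(p, table)
        assert axis is None and sep < 2.0

    def test_too_few_sexed_individuals_raises(self):
        p = PcaResult(np.zeros((3, 1)), np.zeros((2, 1)), np.array([100.0]))
        table = make_sexed_table([MALE, FEMALE, UNKNOWN])
        with pytest.raises(ValueError):
            select_sex_axis(p, table)

    def test_orientation_makes_male_mean_positive(self):
        coords = np.array([[-2.0], [-2.1], [2.0], [2.2]])
        p = PcaResult(coords, np.ones((3, 1)), np.array([100.0]))
        table = make_sexed_table([MALE, MALE, FEMALE, FEMALE])
        p = orient_axis(p, 0, table)
        assert p.coordinates[:2, 0].mean() > 0
        assert (p.loadings[:, 0] == -1).all()


class TestClassify:
    def test_diagnostic_xy_pattern(self):
        values = [[1], [1], [0], [0]]  # males het, females hom-ref
        table = make_sexed_table([MALE, MALE, FEMALE, FEMALE])
        df = classify_sexlinked(make_matrix(values), table, [0])
        assert df.loc[0, "label"] == "diagnostic"
        assert df.loc[0, "orientation"] == "XY"

    def test_partial_male_heterozygosity_is_sexlinked_not_diagnostic(self):
        # 3 of 4 males het (75% > 70%), females fixed: the reported
        # sex-linked-but-not-diagnostic class.
        values = [[1], [1], [1], [0], [0], [0], [0], [0]]
        table = make_sexed_table([MALE] * 4 + [FEMALE] * 4)
        df = classify_sexlinked(make_matrix(values), table, [0])
        assert df.loc[0, "label"] == "sex_linked"
        assert df.loc[0, "orientation"] == "XY"

    def test_autosomal_hwe_snp_rejected(self, rng):
        g = rng.binomial(2, 0.5, size=(100, 1))
        table = make_sexed_table([MALE] * 50 + [FEMALE] * 50)
        df = classify_sexlinked(make_matrix(g), table, [0])
        assert df.loc[0, "label"] == "rejected"

    def test_allele_relabelling_invariance(self):
        values = np.array([[1], [1], [0], [0]], dtype=np.int16)
        table = make_sexed_table([MALE, MALE, FEMALE, FEMALE])
        a = classify_sexlinked(make_matrix(values), table, [0])
        b = classify_sexlinked(make_matrix(2 - values), table, [0])
        for col in ("label", "orientation", "fraction_het_in_males"):
            assert a.loc[0, col] == b.loc[0, col]

    def test_snp_with_no_sexed_calls_rejected_with_flag(self):
        values = [[MISSING], [MISSING], [1], [1]]
        table = make_sexed_table([MALE, FEMALE, UNKNOWN, UNKNOWN])
        df = classify_sexlinked(make_matrix(values), table, [0])
        assert df.loc[0, "label"] == "rejected"
        assert bool(df.loc[0, "no_sexed_calls"])


class TestInferSystem:
    def test_male_heterozygosity_means_xy_and_swap_means_zw(self):
        values = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int16)
        males_first = make_sexed_table([MALE, MALE, FEMALE, FEMALE])
        females_first = make_sexed_table([FEMALE, FEMALE, MALE, MALE])
        xy = classify_sexlinked(make_matrix(values), males_first, [0, 1])
        zw = classify_sexlinked(make_matrix(values), females_first, [0, 1])
        assert infer_system(xy) == "XY"
        assert infer_system(zw) == "ZW"

    def test_no_informative_snps_is_undetermined(self):
        empty = pd.DataFrame({"label": [], "orientation": []})
        assert infer_system(empty) == "undetermined"


class TestEndToEndDetection:
    def test_clean_xy_simulation_all_gametolog_candidates_diagnostic(
        self, clean_xy_dataset
    ):
        (genotypes, _, samples, truth), _ = clean_xy_dataset
        pca, result = detect_sexlinked(genotypes, samples)
        assert result.inferred_system == "XY"
        assert result.sex_axis is not None
        gametologs = {
            genotypes.snps[j].locus_id
            for j in np.flatnonzero(truth.snp_classes == "gametolog")
        }
        candidates = result.table.set_index("locus_id")
        cand_gametologs = candidates.index.intersection(gametologs)
        assert len(cand_gametologs) > 0
        assert (candidates.loc[cand_gametologs, "label"] == "diagnostic").all()
        assert result.n_diagnostic <= min(
            result.n_fixed_homogametic, result.n_het_all_heterogametic
        )

    def test_null_simulation_is_undetermined(self):
        cfg = small_config(system="none", seed=31)
        genotypes, _, samples, _ = simulate_dataset(cfg)
        _, result = detect_sexlinked(genotypes, samples)
        assert result.inferred_system == "undetermined"
        assert result.n_diagnostic == 0
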