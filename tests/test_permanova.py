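import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import seatherm as st
from seatherm.errors import DesignError, UndefinedValueError, ValidationError
from seatherm.permanova import DissimilarityMatrix, pcoa


def euclid_dm(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    return DissimilarityMatrix(
        squareform(pdist(points)), [f"s{i}" for i in range(len(points))]
    )


@pytest.fixture(scope="module")
def survey_dm(sim_survey):
    samples, _ = sim_survey
    meta, matrix = st.to_wide(samples)
    return st.bray_curtis(matrix, transform="sqrt"), meta


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert st.bray_curtis(matrix, "none").data[0, 1] == 0.0

    def test_disjoint_taxa_one(self):
        matrix = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]], index=["a", "b"])
        assert st.bray_curtis(matrix, "none").data[0, 1] == 1.0

    def test_worked_example_with_and_without_sqrt(self):
        matrix = pd.DataFrame([[1.0, 3.0], [3.0, 1.0]], index=["a", "b"])
        assert st.bray_curtis(matrix, "none").data[0, 1] == pytest.approx(0.5)
        assert st.bray_curtis(matrix, "sqrt").data[0, 1] == pytest.approx(
            2 - np.sqrt(3)
        )

    def test_all_zero_pair_zero_with_warning(self):
        matrix = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]],
                              index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="all-zero"):
            dm = st.bray_curtis(matrix, "none")
        assert dm.data[0, 1] == 0.0

    def test_bounded_and_invariant_to_zero_columns(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.gamma(1.0, 2.0, size=(8, 5)))
        dm = st.bray_curtis(matrix, "sqrt")
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        padded = pd.concat(
            [matrix, pd.DataFrame(0.0, index=matrix.index, columns=["z1", "z2"])],
            axis=1,
        )
        assert np.allclose(st.bray_curtis(padded, "sqrt").data, dm.data)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValidationError):
            st.bray_curtis(pd.DataFrame([[-1.0]]), "none")


class TestOnewayPermanova:
    def test_euclidean_toy_matches_classical_anova_f(self):
        dm = euclid_dm([0.0, 1.0, 2.0, 3.0])
        res = st.oneway_permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res["F"] == pytest.approx(8.0)

    def test_equals_classical_f_on_random_univariate_data(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = st.oneway_permanova(euclid_dm(y), groups, n_perm=9, seed=0)
        classical = stats.f_oneway(*(y[groups == g] for g in "abc")).statistic
        assert res["F"] == pytest.approx(classical, rel=1e-10)

    def test_matches_skbio_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(rng.gamma(1.0, 2.0, size=(12, 6)))
        dm = st.bray_curtis(matrix, "none")
        groups = ["a"] * 6 + ["b"] * 6
        ours = st.oneway_permanova(dm, groups, n_perm=9, seed=0)["F"]
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.data, dm.ids), groups, permutations=9
        )["test statistic"]
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_maximal_separation_attains_minimal_p(self):
        # tight clouds far apart: observed F strictly exceeds every permuted F
        rng = np.random.default_rng(0)
        points = np.vstack(
            [rng.normal(0.0, 1e-3, (6, 2)), rng.normal(10.0, 1e-3, (6, 2))]
        )
        res = st.oneway_permanova(
            euclid_dm(points), ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0
        )
        assert res["p_perm"] == pytest.approx(1 / 100)
        assert res["R2"] > 0.999


class TestNestedPermanova:
    def test_ss_partition_sums_to_total_and_df_to_n_minus_1(self, survey_dm):
        dm, meta = survey_dm
        res = st.permanova(dm, meta, n_perm=49, seed=1)
        table = res.table.set_index("source")
        terms = table.drop("Total")
        assert terms["SS"].sum() == pytest.approx(table.loc["Total", "SS"], rel=1e-8)
        assert terms["df"].sum() == len(dm) - 1
        assert table.loc["Total", "df"] == len(dm) - 1

    def test_denominator_presets(self, survey_dm):
        dm, meta = survey_dm
        printed = st.permanova(dm, meta, n_perm=9, seed=1, denominators="printed")
        ems = st.permanova(dm, meta, n_perm=9, seed=1, denominators="ems")
        get = lambda r, t: r.table.set_index("source").loc[t, "denominator"]
        assert get(printed, "Region") == "TimexRegion"
        assert get(ems, "Region") == "Reef(TxR)"
        assert get(printed, "Time") == get(ems, "Time") == "Reef(TxR)"

    def test_p_values_reproducible_for_seed(self, survey_dm):
        dm, meta = survey_dm
        a = st.permanova(dm, meta, n_perm=99, seed=7).table["p_perm"]
        b = st.permanova(dm, meta, n_perm=99, seed=7).table["p_perm"]
        assert a.fillna(-1).tolist() == b.fillna(-1).tolist()

    def test_strong_time_effect_detected(self, survey_dm):
        dm, meta = survey_dm
        res = st.permanova(dm, meta, n_perm=199, seed=2)
        table = res.table.set_index("source")
        assert table.loc["Time", "p_perm"] <= 0.05

    def test_zero_total_ss_errors(self):
        dm = DissimilarityMatrix(np.zeros((12, 12)), [f"s{i}" for i in range(12)])
        meta = pd.DataFrame(
            {
                "year": ["y1"] * 6 + ["y2"] * 6,
                "region": ["r"] * 12,
                "reef": [f"{y}{i//2}" for y, i in
                         zip(["a"] * 6 + ["b"] * 6, range(12))],
                "quadrat": [1, 2] * 6,
            },
            index=dm.ids,
        )
        with pytest.raises(UndefinedValueError):
            st.permanova(dm, meta, n_perm=9, seed=0)

    def test_unbalanced_design_rejected(self, survey_dm):
        dm, meta = survey_dm
        idx = np.arange(len(dm) - 1)  # drop one quadrat
        sub = DissimilarityMatrix(dm.data[np.ix_(idx, idx)],
                                  [dm.ids[i] for i in idx])
        with pytest.raises(DesignError):
            st.permanova(sub, meta.iloc[:-1], n_perm=9, seed=0)


class TestPairwisePermanova:
    def test_identical_composition_near_zero_r2(self):
        matrix = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0], (8, 1)) + 0.0,
            index=[f"s{i}" for i in range(8)],
        )
        # tiny jitter so SS_total > 0
        matrix.iloc[0, 0] += 1e-6
        meta = pd.DataFrame(
            {"region": ["a"] * 4 + ["b"] * 4, "year": ["y"] * 8},
            index=matrix.index,
        )
        dm = st.bray_curtis(matrix, "none")
        res = st.pairwise_permanova(dm, meta, factor="region", n_perm=49, seed=0)
        assert res.loc[0, "R2"] < 0.5

    def test_outlying_level_pattern(self):
        rng = np.random.default_rng(8)
        base = rng.gamma(2.0, 1.0, size=(12, 6))
        base[8:] += 50.0  # level c far away
        matrix = pd.DataFrame(base, index=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame(
            {"region": ["a"] * 4 + ["b"] * 4 + ["c"] * 4}, index=matrix.index
        )
        dm = st.bray_curtis(matrix, "sqrt")
        res = st.pairwise_permanova(dm, meta, factor="region", n_perm=99, seed=1)
        res = res.set_index(["level_1", "level_2"])
        assert res.loc[("a", "c"), "R2"] > res.loc[("a", "b"), "R2"]
        assert res.loc[("b", "c"), "p_perm"] <= 0.05

    def test_disjoint_levels_minimal_p(self):
        # disjoint taxa between levels, tiny within-level variation
        rng = np.random.default_rng(6)
        block_a = np.column_stack([1.0 + 0.01 * rng.random(6), np.zeros(6)])
        block_b = np.column_stack([np.zeros(6), 1.0 + 0.01 * rng.random(6)])
        matrix = pd.DataFrame(np.vstack([block_a, block_b]),
                              index=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame({"region": ["a"] * 6 + ["b"] * 6}, index=matrix.index)
        res = st.pairwise_permanova(
            st.bray_curtis(matrix, "none"), meta, factor="region",
            n_perm=99, seed=0,
        )
        assert res.loc[0, "R2"] > 0.99
        assert res.loc[0, "p_perm"] == pytest.approx(1 / 100)


class TestPcoa:
    def test_equilateral_triangle_two_equal_eigenvalues(self):
        dm = DissimilarityMatrix(np.ones((3, 3)) - np.eye(3), list("abc"))
        res = pcoa(dm)
        assert res.eigvals[:2] == pytest.approx([0.5, 0.5])
        assert res.coords_imag.size == 0

    def test_euclidean_configuration_reproduced(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(10, 2))
        dm = euclid_dm(points)
        res = pcoa(dm)
        assert np.allclose(res.reconstructed_distances(), dm.data, atol=1e-8)

    def test_matches_skbio_eigenvalues_on_euclidean_input(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        points = rng.normal(size=(8, 3))
        dm = euclid_dm(points)
        ours = pcoa(dm).eigvals[:3]
        theirs = skbio_ordination.pcoa(
            skbio_distance.DistanceMatrix(dm.data, dm.ids)
        ).eigvals.to_numpy()[:3]
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_non_euclidean_keeps_imaginary_axes_and_reconstructs(self, survey_dm):
        dm, _ = survey_dm
        res = pcoa(dm)
        assert res.coords_imag.shape[1] > 0  # Bray-Curtis is non-Euclidean
        assert np.abs(res.reconstructed_distances() - dm.data).max() < 1e-8


class TestPermdisp:
    def test_congruent_clouds_f_zero(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(8, 3))
        points = np.vstack([cloud, cloud + 100.0])
        res = st.permdisp(euclid_dm(points), ["a"] * 8 + ["b"] * 8,
                          n_perm=99, seed=0)
        assert res.f == 0.0

    def test_dispersion_difference_detected(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(10, 3))
        points = np.vstack([cloud, cloud * 5.0])
        res = st.permdisp(euclid_dm(points), ["a"] * 10 + ["b"] * 10,
                          n_perm=199, seed=0)
        assert res.f > 10.0
        assert res.p_perm <= 0.05
        assert res.group_mean_distance["b"] > res.group_mean_distance["a"]

    def test_all_identical_samples_degenerate_f0_p1(self):
        dm = DissimilarityMatrix(np.zeros((6, 6)), [f"s{i}" for i in range(6)])
        res = st.permdisp(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.f == 0.0 and res.p_perm == 1.0

    def test_group_of_size_one_errors(self):
        dm = euclid_dm(np.arange(4.0))
        with pytest.raises(ValidationError):
            st.permdisp(dm, ["a", "b", "b", "b"], n_perm=9, seed=0)
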