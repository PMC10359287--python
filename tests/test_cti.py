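import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import seatherm as st
from seatherm.cti import classify_process
from seatherm.errors import UndefinedValueError, ValidationError


class TestComputeCti:
    def test_single_species_returns_its_sti(self):
        assert st.compute_cti({"a": 5.0}, {"a": 14.0}) == 14.0

    def test_equal_weights_symmetric(self):
        assert st.compute_cti({"a": 2.0, "b": 2.0}, {"a": 10.0, "b": 20.0}) == 15.0

    def test_weighted_mean_worked_example(self):
        assert st.compute_cti({"a": 1.0, "b": 3.0}, {"a": 12.0, "b": 16.0}) == 15.0

    def test_species_without_sti_excluded(self):
        value = st.compute_cti({"a": 1.0, "b": 3.0, "nosti": 100.0},
                               {"a": 12.0, "b": 16.0})
        assert value == 15.0

    def test_no_eligible_species_undefined(self):
        with pytest.raises(UndefinedValueError):
            st.compute_cti({"a": 1.0}, {"b": 14.0})

    @settings(deadline=None, max_examples=50)
    @given(
        hst.lists(
            hst.tuples(hst.floats(0.01, 50), hst.floats(5, 25)),
            min_size=1, max_size=10,
        ),
        hst.floats(0.01, 100),
    )
    def test_bounded_and_scale_invariant(self, pairs, scale):
        weights = {f"t{i}": w for i, (w, _) in enumerate(pairs)}
        stis = {f"t{i}": s for i, (_, s) in enumerate(pairs)}
        cti = st.compute_cti(weights, stis)
        assert min(stis.values()) - 1e-9 <= cti <= max(stis.values()) + 1e-9
        scaled = st.compute_cti({t: w * scale for t, w in weights.items()}, stis)
        assert scaled == pytest.approx(cti, rel=1e-9)

    def test_warmest_species_gain_raises_cti(self):
        weights = {"cold": 3.0, "warm": 1.0}
        stis = {"cold": 12.0, "warm": 18.0}
        base = st.compute_cti(weights, stis)
        boosted = st.compute_cti({"cold": 3.0, "warm": 2.0}, stis)
        assert boosted > base


class TestCtiByUnit:
    def test_single_species_reef_equals_its_sti(self, sample_factory):
        catalog = st.TaxonCatalog.from_records([("A", "species", "turf", 14.0)])
        samples = [sample_factory(f"s{q}", quadrat=q, biomass={"A": float(q)})
                   for q in range(1, 7)]
        for level in ("reef", "region", "dataset"):
            table = st.cti_by_unit(samples, catalog, level=level)
            assert table["cti"].tolist() == [14.0]

    def test_region_mean_and_se_of_reef_ctis(self, sample_factory):
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 12.0), ("B", "species", "turf", 16.0)]
        )
        samples = [
            sample_factory("s1", reef="r1", biomass={"A": 1.0}),
            sample_factory("s2", reef="r2", biomass={"B": 1.0}),
        ]
        table = st.cti_by_unit(samples, catalog, level="region")
        assert table["cti"].tolist() == [14.0]
        assert table["cti_se"].tolist() == [2.0]

    def test_catalog_without_stis_errors(self, sample_factory):
        catalog = st.TaxonCatalog.from_records([("A", "species", "turf", None)])
        with pytest.raises(UndefinedValueError):
            st.cti_by_unit([sample_factory(biomass={"A": 1.0})], catalog)

    def test_reef_without_eligible_species_warned_and_skipped(self, sample_factory):
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 14.0), ("B", "species", "turf", None)]
        )
        samples = [
            sample_factory("s1", reef="r1", biomass={"A": 1.0}),
            sample_factory("s2", reef="r2", biomass={"B": 1.0}),
        ]
        with pytest.warns(UserWarning, match="no STI-bearing species"):
            table = st.cti_by_unit(samples, catalog, level="reef")
        assert len(table) == 1

    def test_coverage_and_weight_totals(self, sample_factory):
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 14.0), ("C", "genus", "turf", None)]
        )
        samples = [sample_factory(biomass={"A": 3.0, "C": 1.0})]
        result = st.reef_cti(samples, catalog)[0]
        assert result.weight_total == 3.0
        assert result.coverage == pytest.approx(0.75)
        assert result.n_species == 1


class TestAffinityAndProcess:
    @pytest.mark.parametrize(
        "sti, ref, expected",
        [(16.0, 14.0, "warm"), (12.0, 14.0, "cold"), (14.0, 14.0, "neutral")],
    )
    def test_classify_affinity(self, sti, ref, expected):
        assert st.classify_affinity(sti, ref) == expected

    @pytest.mark.parametrize(
        "affinity, dw, expected",
        [
            ("warm", 0.2, "tropicalization"),
            ("cold", 0.2, "borealization"),
            ("warm", -0.2, "detropicalization"),
            ("cold", -0.2, "deborealization"),
            ("neutral", 0.2, "none"),
            ("warm", 0.0, "none"),
        ],
    )
    def test_process_sign_table(self, affinity, dw, expected):
        assert classify_process(affinity, dw) == expected


class TestDecomposition:
    def two_time_samples(self, sample_factory, w1, w2):
        return [
            sample_factory("t1", year="2012", biomass=w1),
            sample_factory("t2", year="2018", biomass=w2),
        ]

    def test_identical_times_all_strengths_exactly_zero(self, sample_factory):
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 16.0), ("B", "species", "turf", 12.0)]
        )
        samples = self.two_time_samples(
            sample_factory, {"A": 4.0, "B": 6.0}, {"A": 4.0, "B": 6.0}
        )
        res = st.decompose_cti_change(samples, catalog, region="VIA")
        assert set(res.strengths_dw.values()) == {0.0}
        assert set(res.strengths_weighted.values()) == {0.0}
        assert res.dominant == []

    def test_hand_enumerated_symmetric_shift(self, sample_factory):
        # ref CTI = mean(13.6, 14.4) = 14; dw = +/-0.2 at STIs 16 and 12
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 16.0), ("B", "species", "turf", 12.0)]
        )
        samples = self.two_time_samples(
            sample_factory, {"A": 4.0, "B": 6.0}, {"A": 6.0, "B": 4.0}
        )
        res = st.decompose_cti_change(samples, catalog, region="VIA")
        assert res.reference_cti == pytest.approx(14.0)
        assert res.strengths_weighted["tropicalization"] == pytest.approx(0.4)
        assert res.strengths_weighted["deborealization"] == pytest.approx(0.4)
        assert res.strengths_dw["tropicalization"] == pytest.approx(0.2)
        assert sorted(res.dominant) == ["deborealization", "tropicalization"]

    @staticmethod
    def dataset_dominant(samples, catalog):
        totals = {}
        for res in st.decompose_all_regions(samples, catalog).values():
            for process, value in res.strengths_weighted.items():
                totals[process] = totals.get(process, 0.0) + value
        return max(totals, key=totals.get)

    def test_warming_simulation_recovers_tropicalization(self, default_niches,
                                                         sim_catalog):
        samples, _ = st.simulate_community(
            default_niches, st.ScenarioSpec(delta_t=1.0, seed=17)
        )
        assert self.dataset_dominant(samples, sim_catalog) == "tropicalization"

    def test_cold_loss_simulation_recovers_deborealization(self):
        niches = st.cold_loss_niches()
        samples, _ = st.simulate_community(niches, st.cold_loss_scenario(seed=17))
        assert self.dataset_dominant(
            samples, st.catalog_from_niches(niches)
        ) == "deborealization"

    def test_single_time_errors(self, sample_factory):
        catalog = st.TaxonCatalog.from_records([("A", "species", "turf", 14.0)])
        with pytest.raises(ValidationError, match="two survey times"):
            st.decompose_cti_change(
                [sample_factory(biomass={"A": 1.0})], catalog, region="VIA"
            )

    def test_time_without_eligible_species_errors(self, sample_factory):
        catalog = st.TaxonCatalog.from_records(
            [("A", "species", "turf", 14.0), ("B", "species", "turf", None)]
        )
        samples = self.two_time_samples(
            sample_factory, {"A": 1.0}, {"B": 1.0}
        )
        with pytest.raises(UndefinedValueError):
            st.decompose_cti_change(samples, catalog, region="VIA")
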