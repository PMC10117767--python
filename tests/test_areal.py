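import pytest
from hypothesis import given, settings, strategies as st

from cmnutricycle import areal


class TestFeedRequirements:
    def test_hydrolysate_need_per_kg_cm(self):
        assert areal.protein_feed_per_kg(0.18, 0.24) == pytest.approx(0.75)

    def test_perfect_pce_returns_protein_fraction(self):
        assert areal.protein_feed_per_kg(0.18, 1.0) == pytest.approx(0.18)

    def test_beef_equivalent_protein_need(self):
        assert areal.protein_feed_per_kg(0.22, 0.05) == pytest.approx(4.4)

    def test_glucose_need_per_kg_cm(self):
        need = areal.glucose_feed_per_kg(1400.0, 0.17, 4000.0)
        assert need == pytest.approx(2.06, rel=1e-2)

    def test_glucose_unit_case(self):
        assert areal.glucose_feed_per_kg(4000.0, 1.0, 4000.0) == pytest.approx(1.0)

    def test_per_batch_glucose(self, cm):
        need = areal.glucose_feed_per_kg(
            cm.meat_energy_density * 1000, cm.calorie_conversion_efficiency,
            cm.glucose_energy_density,
        )
        assert need * cm.batch_meat_mass == pytest.approx(710.3, rel=1e-3)

    @pytest.mark.parametrize("fn, args", [
        (areal.protein_feed_per_kg, (0.18, 0.0)),
        (areal.glucose_feed_per_kg, (1400.0, 0.0, 4000.0)),
        (areal.crop_land_per_kg, (0.0,)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestCropLand:
    @pytest.mark.parametrize("yield_mg, expected", [
        (4.12, 2.43),   # soybean
        (13.0, 0.769),  # corn
        (10.0, 1.0),
    ])
    def test_yield_inversion(self, yield_mg, expected):
        assert areal.crop_land_per_kg(yield_mg) == pytest.approx(expected, rel=1e-2)


class TestPriceAllocation:
    def test_soy_oil_meal_shares(self):
        shares = areal.price_allocation({"oil": 0.20, "meal": 0.80},
                                        {"oil": 0.87, "meal": 0.33})
        assert shares["oil"] == pytest.approx(0.397, rel=1e-2)
        assert shares["meal"] == pytest.approx(0.603, rel=1e-2)

    def test_single_component_gets_everything(self):
        assert areal.price_allocation({"meal": 1.0}, {"meal": 0.5}) == {"meal": 1.0}

    def test_equal_value_components_split_evenly(self):
        shares = areal.price_allocation({"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 1.0})
        assert shares["a"] == pytest.approx(0.5)

    def test_all_zero_value_rejected(self):
        with pytest.raises(ValueError):
            areal.price_allocation({"a": 0.5}, {"a": 0.0})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        fracs=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        prices=st.lists(st.floats(0.01, 100.0), min_size=5, max_size=5),
    )
    def test_shares_normalise_and_lie_in_unit_interval(self, fracs, prices):
        mass = {f"c{i}": f for i, f in enumerate(fracs)}
        price = {f"c{i}": prices[i] for i in range(len(fracs))}
        shares = areal.price_allocation(mass, price)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= s <= 1.0 for s in shares.values())


class TestSoyChain:
    def test_as_printed_land(self, soy):
        assert areal.soy_land_per_kg_cm(soy, 0.75) == pytest.approx(2.31, rel=5e-3)

    def test_stated_chain_land(self, soy):
        chain = soy.model_copy(update={"chain_mode": "stated_chain"})
        # 0.75 / (0.80 x 0.48 x 0.80) x 2.427 x 0.603 = 3.57; the full chain
        # costs more land than the as-printed shortcut
        land = areal.soy_land_per_kg_cm(chain, 0.75)
        assert land == pytest.approx(0.75 / 0.3072 * 2.42718 * 0.60274, rel=1e-4)
        assert land > areal.soy_land_per_kg_cm(soy, 0.75)

    def test_zero_need_zero_land(self, soy):
        assert areal.soy_land_per_kg_cm(soy, 0.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(need=st.floats(0.01, 5.0), k=st.floats(0.5, 4.0))
    def test_homogeneity_in_need_and_yield(self, soy, need, k):
        base = areal.soy_land_per_kg_cm(soy, need)
        assert areal.soy_land_per_kg_cm(soy, k * need) == pytest.approx(k * base, rel=1e-9)
        richer = soy.model_copy(update={"yield_mg_per_ha": soy.yield_mg_per_ha * k})
        assert areal.soy_land_per_kg_cm(richer, need) == pytest.approx(base / k, rel=1e-9)


class TestCornChain:
    def test_stated_chain_land(self, corn):
        # the computed value; the published 2.28 is carried as an annotation
        land = areal.corn_land_per_kg_cm(corn, 2.0588)
        assert land == pytest.approx(1.75, rel=5e-3)
        assert corn.printed_land_reference == 2.28

    def test_without_allocation(self, corn):
        chain = corn.model_copy(update={"allocation_mode": "none"})
        assert areal.corn_land_per_kg_cm(chain, 2.0588) == pytest.approx(2.36, rel=5e-3)

    def test_zero_need_zero_land(self, corn):
        assert areal.corn_land_per_kg_cm(corn, 0.0) == 0.0


class TestProductivity:
    def test_broiler_conversion(self):
        p = areal.landuse_to_productivity(8.7, 0.17, 1430.0, label="broiler")
        assert p.protein_productivity == pytest.approx(19.5, rel=1e-2)
        assert p.energy_productivity == pytest.approx(0.69, rel=1e-2)

    def test_cm_at_reference_total_land(self):
        p = areal.landuse_to_productivity(4.58, 0.18, 1400.0, label="cm")
        assert p.protein_productivity == pytest.approx(39.3, rel=1e-2)
        assert p.energy_productivity == pytest.approx(1.28, rel=1e-2)

    def test_unit_land_full_protein(self):
        p = areal.landuse_to_productivity(1.0, 1.0, 1000.0)
        assert p.protein_productivity == pytest.approx(1000.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(land=st.floats(0.1, 500.0), protein=st.floats(0.01, 1.0),
           energy=st.floats(100.0, 10_000.0))
    def test_productivity_times_land_recovers_content(self, land, protein, energy):
        p = areal.landuse_to_productivity(land, protein, energy)
        assert p.protein_productivity * land == pytest.approx(1000.0 * protein, rel=1e-9)
        assert p.energy_productivity * land == pytest.approx(energy * 4.184 / 1000.0, rel=1e-9)

    def test_nonpositive_land_rejected(self):
        with pytest.raises(ValueError):
            areal.landuse_to_productivity(0.0, 0.2, 1000.0)


class TestCMLandUse:
    def test_ledger_is_reproducible(self, cm, soy, corn):
        lu = areal.cm_land_use(cm, soy, corn)
        assert lu.total_land == pytest.approx(lu.protein_land + lu.energy_land)
        assert lu.ledger["protein_need_kg_per_kg"] == pytest.approx(0.75)
        assert lu.ledger["glucose_need_kg_per_kg"] == pytest.approx(2.06, rel=1e-2)
        assert lu.ledger["corn_allocation_share"] == pytest.approx(0.74)

    def test_productivity_table_has_all_systems(self, scenario):
        from cmnutricycle.params import livestock_land_use

        df = areal.productivity_table(
            scenario.cm_batch, scenario.feedstocks["soy"],
            scenario.feedstocks["corn"], livestock_land_use(),
        )
        assert set(df.index) == {"swine", "beef", "broiler", "cm"}
        # beef midpoint land (222 m2) makes it the least productive system
        assert df.loc["beef", "protein_productivity_g_per_m2_yr"] == df[
            "protein_productivity_g_per_m2_yr"
        ].min()
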