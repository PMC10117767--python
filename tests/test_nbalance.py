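import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmnutricycle import nbalance
from cmnutricycle.params import CMBatchSpec, mattick_batch


class TestProteinNitrogen:
    def test_batch_protein_ledger(self, cm):
        fed, retained, waste, n = nbalance.batch_protein_nitrogen(cm)
        assert retained == pytest.approx(62.1)
        assert fed == pytest.approx(258.75)
        assert waste == pytest.approx(196.65)
        assert n == pytest.approx(31.5, rel=1e-2)

    def test_perfect_pce_no_waste(self, cm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = CMBatchSpec.model_validate(
                cm.model_dump() | {"protein_conversion_efficiency": 1.0}
            )
        fed, retained, waste, n = nbalance.batch_protein_nitrogen(spec)
        assert waste == pytest.approx(0.0, abs=1e-12)
        assert n == pytest.approx(0.0, abs=1e-12)

    def test_half_pce(self, cm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = CMBatchSpec.model_validate(
                cm.model_dump() | {"protein_conversion_efficiency": 0.5}
            )
        fed, retained, waste, n = nbalance.batch_protein_nitrogen(spec)
        assert waste == pytest.approx(retained)
        assert n == pytest.approx(0.16 * 62.1)


class TestWaterBalance:
    def test_wastewater_volume(self, cm):
        assert nbalance.batch_water(cm) == pytest.approx(29.71, rel=1e-3)

    def test_meat_takes_about_one_percent_of_input(self, cm):
        meat_water = cm.batch_meat_mass * cm.water_balance_moisture / 1000.0
        assert meat_water / cm.water_per_batch == pytest.approx(0.01, abs=2e-3)

    def test_cleaning_water_option(self, cm):
        assert nbalance.batch_water(cm, include_cleaning=True) == pytest.approx(
            29.71 + 45.0, rel=1e-3
        )

    def test_concentration(self):
        assert nbalance.nitrogen_concentration(31.46, 29.71) == pytest.approx(1.06, rel=1e-2)

    def test_concentration_scale_invariant(self):
        c1 = nbalance.nitrogen_concentration(31.46, 29.71)
        c2 = nbalance.nitrogen_concentration(31.46 * 1160, 29.71 * 1160)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            nbalance.nitrogen_concentration(1.0, 0.0)


class TestOxygenAndRespiration:
    def test_batch_oxygen_uptake(self, cm):
        # arithmetic-mean proliferation count; the published 72 kg does not
        # follow from the stated procedure and is not asserted
        assert nbalance.oxygen_uptake(cm) == pytest.approx(85.4, rel=1e-3)

    def test_proliferation_term_only(self, cm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = CMBatchSpec.model_validate(cm.model_dump() | {"maturation_duration": 0.0})
        # mean(3e12, 6e13) cells x 118 h x 332.2 nmol/h/1e6 x 32 g/mol
        expected = 0.5 * (3e12 + 6e13) * 118 * 332.2e-15 * 32 / 1000
        assert nbalance.oxygen_uptake(spec) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(39.5, rel=1e-2)

    def test_geometric_mean_rule_is_lower(self, cm):
        assert nbalance.oxygen_uptake(cm, "geometric") < nbalance.oxygen_uptake(cm)

    def test_zero_our_zero_uptake(self, cm):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = CMBatchSpec.model_validate(cm.model_dump() | {"oxygen_uptake_rate": 0.0})
        assert nbalance.oxygen_uptake(spec) == 0.0

    @pytest.mark.parametrize("o2, expected", [
        (85.44, 80.1),
        (192.0, 180.0),
        (0.0, 0.0),
    ])
    def test_respiration_stoichiometry(self, o2, expected):
        assert nbalance.glucose_respired(o2) == pytest.approx(expected, rel=1e-2)


class TestGlucoseCOD:
    def test_waste_and_respired_share(self, cm, batch):
        waste, cod = nbalance.glucose_cod(cm, batch.glucose_fed, batch.glucose_respired)
        assert waste == pytest.approx(509.4, rel=1e-3)
        assert batch.glucose_respired / batch.glucose_fed == pytest.approx(0.113, abs=1e-3)
        assert cod == pytest.approx(542.0, rel=1e-3)

    def test_closed_ledger_gives_zero_waste(self, cm):
        fed = 100.0
        respired = fed * (1 - cm.calorie_conversion_efficiency)
        waste, cod = nbalance.glucose_cod(cm, fed, respired)
        assert waste == pytest.approx(0.0, abs=1e-9)
        assert cod == pytest.approx(0.0, abs=1e-9)

    def test_overdrawn_ledger_rejected(self, cm):
        with pytest.raises(ValueError):
            nbalance.glucose_cod(cm, 100.0, 100.0)


@st.composite
def valid_batch_specs(draw):
    initial = draw(st.floats(1e4, 1e7))
    final = initial * draw(st.floats(1.0, 100.0))
    mass = draw(st.floats(10.0, 1000.0))
    moisture = draw(st.floats(0.5, 0.9))
    water = mass * moisture / 1000.0 + draw(st.floats(1.0, 100.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CMBatchSpec(
                reactor_volume=draw(st.floats(1.0, 50.0)),
                initial_cell_density=initial,
                final_cell_density=final,
                cell_wet_mass=draw(st.floats(1e-9, 1e-8)),
                proliferation_duration=draw(st.floats(10.0, 300.0)),
                maturation_duration=draw(st.floats(0.0, 300.0)),
                batch_days=draw(st.floats(1.0, 30.0)),
                batch_meat_mass=mass,
                meat_protein_fraction=draw(st.floats(0.1, 0.3)),
                meat_moisture_fraction=0.70,
                water_balance_moisture=moisture,
                water_per_batch=water,
                cleaning_water_per_batch=0.0,
                oxygen_uptake_rate=draw(st.floats(0.0, 10.0)),
                meat_energy_density=draw(st.floats(1.0, 3.0)),
                protein_conversion_efficiency=draw(st.floats(0.05, 1.0)),
                calorie_conversion_efficiency=draw(st.floats(0.05, 0.5)),
                glucose_energy_density=4000.0,
    )


class TestConservationProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(spec=valid_batch_specs())
    def test_ledgers_close_to_machine_precision(self, spec):
        """Protein and glucose ledgers are exact mass balances."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                bal = nbalance.batch_balance(spec)
            except ValueError:
                # respiration can exceed the feed for extreme OUR draws;
                # the balance refuses rather than producing negative waste
                return
        assert bal.protein_fed == pytest.approx(
            bal.protein_retained + bal.protein_waste, rel=1e-12
        )
        assert bal.glucose_fed == pytest.approx(
            bal.glucose_retained + bal.glucose_respired + bal.glucose_waste, rel=1e-12
        )
        assert bal.nitrogen_waste == pytest.approx(0.16 * bal.protein_waste, rel=1e-12)
        assert min(
            bal.protein_fed, bal.protein_retained, bal.protein_waste,
            bal.glucose_fed, bal.glucose_waste, bal.cod_waste,
        ) >= 0.0

    def test_thousand_random_specs_conserve(self):
        """Ledger closure across a large seeded ensemble of valid specs."""
        rng = np.random.default_rng(2024)
        base = mattick_batch().model_dump()
        for _ in range(1000):
            pce = rng.uniform(0.05, 1.0)
            cce = rng.uniform(0.12, 0.5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = CMBatchSpec.model_validate(
                    base | {
                        "protein_conversion_efficiency": pce,
                        "calorie_conversion_efficiency": cce,
                        "batch_meat_mass": rng.uniform(50, 500),
                        "oxygen_uptake_rate": rng.uniform(0, 60),
                    }
                )
            try:
                bal = nbalance.batch_balance(spec)
            except ValueError:
                continue
            assert abs(bal.protein_fed - bal.protein_retained - bal.protein_waste) < 1e-9
            assert abs(
                bal.glucose_fed - bal.glucose_retained - bal.glucose_respired - bal.glucose_waste
            ) < 1e-9


class TestScenarioScaling:
    def test_high_price_scenario(self, scen_high):
        assert scen_high.annual_mass == pytest.approx(400_000.0)
        assert scen_high.batches_per_year == 1160
        assert scen_high.batches_per_reactor_year == 33
        assert scen_high.reactors == 35
        assert scen_high.annual_nitrogen == pytest.approx(36_500.0, rel=5e-3)
        assert scen_high.annual_cod == pytest.approx(628_800.0, rel=5e-3)

    def test_low_price_scenario(self, scen_low):
        assert scen_low.annual_mass == pytest.approx(1_000_000.0)
        assert scen_low.batches_per_year == 2899
        assert scen_low.reactors == 88
        assert scen_low.annual_nitrogen == pytest.approx(91_200.0, rel=5e-3)
        assert scen_low.annual_cod == pytest.approx(1_570_000.0, rel=5e-3)

    def test_zero_revenue_zero_scenario(self, cm, batch):
        scen = nbalance.scale_scenario(cm, 25.0, 0.0, batch)
        assert scen.batches_per_year == 0
        assert scen.annual_nitrogen == 0.0

    def test_nonpositive_price_rejected(self, cm, batch):
        with pytest.raises(ValueError):
            nbalance.scale_scenario(cm, 0.0, 1e7, batch)

    def test_annual_loads_equal_batchwise_sum(self, cm, batch, scen_high):
        """Oracle: summing the per-batch loads batch-by-batch reproduces the
        scaled annual totals."""
        total_n = sum(batch.nitrogen_waste for _ in range(scen_high.batches_per_year))
        assert scen_high.annual_nitrogen == pytest.approx(total_n, rel=1e-12)

    def test_annual_nitrogen_decreases_with_pce(self, cm):
        """Higher protein conversion leaves strictly less N in the media."""
        loads = []
        for pce in np.linspace(0.17, 0.33, 9):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec = CMBatchSpec.model_validate(
                    cm.model_dump() | {"protein_conversion_efficiency": float(pce)}
                )
            bal = nbalance.batch_balance(spec)
            loads.append(nbalance.scale_scenario(spec, 25.0, 1e7, bal).annual_nitrogen)
        assert all(a > b for a, b in zip(loads, loads[1:]))
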