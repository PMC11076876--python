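"""Selectivity, EEO allocation, balances and phase averaging."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ceflux.metrics import (
    count_elongation_steps,
    excessive_ethanol_oxidation,
    phase_average,
    product_selectivity,
)


class TestProductSelectivity:
    def test_single_product(self):
        assert product_selectivity({"n-caproate": 300.0}) == {"n-caproate": 100.0}

    def test_caproate_dominant_mix(self):
        sel = product_selectivity(
            {"n-caproate": 480.0, "n-butanol": 10.0, "n-hexanol": 10.0}
        )
        assert sel["n-caproate"] == pytest.approx(96.0)

    def test_high_selectivity_mix(self):
        sel = product_selectivity(
            {"n-caproate": 291.0, "i-butyrate": 3.0, "n-butanol": 2.0, "n-hexanol": 4.0}
        )
        assert sel["n-caproate"] == pytest.approx(97.0)

    def test_substrates_and_donor_excluded(self):
        sel = product_selectivity(
            {"ethanol": 5.0, "n-butyrate": -40.0, "n-caproate": 100.0}
        )
        assert set(sel) == {"n-caproate"}

    def test_no_products_warns_empty(self):
        with pytest.warns(UserWarning, match="selectivity"):
            assert product_selectivity({"ethanol": -100.0}) == {}

    @given(
        st.dictionaries(
            st.sampled_from(
                ["acetate", "n-butyrate", "n-caproate", "n-butanol", "n-hexanol"]
            ),
            st.floats(min_value=0.1, max_value=1e4),
            min_size=1,
        ),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariant_and_sums_to_100(self, rates, k):
        sel = product_selectivity(rates)
        scaled = product_selectivity({c: k * r for c, r in rates.items()})
        assert sum(sel.values()) == pytest.approx(100.0)
        for c in sel:
            assert scaled[c] == pytest.approx(sel[c], rel=1e-9)


class TestStepCounting:
    def test_butyrate_production_is_one_step_per_mol(self):
        # 5 mol/L/d butyrate formed from acetate
        assert count_elongation_steps({"n-butyrate": 5.0}) == pytest.approx(5.0)

    def test_consumed_butyrate_routes_to_caproate(self):
        # 4 mol C4 consumed feed 4 of the 6 mol C6 (1 step each);
        # remaining 2 mol C6 come from acetate (2 steps each)
        mol = {"n-butyrate": -4.0, "n-caproate": 6.0}
        assert count_elongation_steps(mol) == pytest.approx(8.0)
        assert count_elongation_steps(mol, strategy="from_acetate") == pytest.approx(
            12.0
        )

    def test_alcohols_fold_into_precursor_acid(self):
        # butanol counts as butyrate for step accounting
        assert count_elongation_steps(
            {"n-butyrate": 3.0, "n-butanol": 2.0}
        ) == pytest.approx(5.0)

    def test_isomerization_counts_no_steps(self):
        assert count_elongation_steps({"i-butyrate": 3.0}) == pytest.approx(0.0)

    def test_odd_chain_from_propionate(self):
        assert count_elongation_steps({"n-valerate": 2.0}) == pytest.approx(2.0)


class TestEEO:
    def _rates(self, ethanol_mol, butyrate_mol):
        # mCmol/L/d inputs: ethanol has 2 C, butyrate 4 C
        return {"ethanol": -2.0 * ethanol_mol, "n-butyrate": 4.0 * butyrate_mol}

    def test_expected_stoichiometry_gives_zero(self):
        # E_cons = 1.2 S: exactly 1 oxidation per 5 elongation steps
        alloc = excessive_ethanol_oxidation(self._rates(6.0, 5.0))
        assert alloc.eeo_pct == pytest.approx(0.0, abs=1e-9)

    def test_half_excess(self):
        # E_cons = 12, S = 5: 100 * (12 - 5 - 0 - 1) / 12 = 50%
        alloc = excessive_ethanol_oxidation(self._rates(12.0, 5.0))
        assert alloc.eeo_pct == pytest.approx(50.0)

    def test_negative_regime(self):
        # E_cons = 5.5, S = 5 -> -9.09%: less ethanol burned than the
        # 1-per-5 assumption predicts
        alloc = excessive_ethanol_oxidation(self._rates(5.5, 5.0))
        assert alloc.eeo_pct == pytest.approx(-9.0909, abs=1e-3)

    def test_allocation_sums_to_consumption(self):
        rates = {
            "ethanol": -100.0,
            "n-butyrate": -20.0,
            "n-caproate": 120.0,
            "n-butanol": 8.0,
            "n-hexanol": 6.0,
        }
        alloc = excessive_ethanol_oxidation(rates)
        assert alloc.total == pytest.approx(50.0)  # 100 mCmol / 2 C
        parts = alloc.as_cmol()
        assert sum(parts.values()) == pytest.approx(100.0)

    def test_reduction_exchange_counted(self):
        # 2 mol butanol formed: 2 ethanol booked under reduction
        rates = {"ethanol": -2.0 * 10.0, "n-butanol": 4.0 * 2.0}
        alloc = excessive_ethanol_oxidation(rates)
        assert alloc.reduction_exchange == pytest.approx(2.0)
        assert alloc.elongation == pytest.approx(2.0)  # folded to butyrate

    def test_undefined_without_ethanol_consumption(self):
        with pytest.warns(UserWarning, match="EEO"):
            assert excessive_ethanol_oxidation({"ethanol": 10.0}) is None


class TestPhaseAverage:
    def _frame(self, values, phase="IV"):
        return pd.DataFrame(
            {
                "t_d": np.arange(len(values), dtype=float),
                "phase": phase,
                "eeo_pct": values,
            }
        )

    def test_constant_metrics(self):
        avg = phase_average(self._frame([5.0] * 6), "IV", n_last=3)
        assert avg["eeo_pct"] == pytest.approx(5.0)

    def test_n_last_one_is_last_record(self):
        avg = phase_average(self._frame([1.0, 2.0, 3.0]), "IV", n_last=1)
        assert avg["eeo_pct"] == pytest.approx(3.0)

    def test_ramp_mean_of_tail(self):
        avg = phase_average(self._frame([0.0, 10.0, 20.0, 30.0, 40.0]), "IV", 3)
        assert avg["eeo_pct"] == pytest.approx(30.0)

    def test_too_few_records_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="only"):
            avg = phase_average(self._frame([2.0, 4.0]), "IV", n_last=5)
        assert avg["eeo_pct"] == pytest.approx(3.0)
        assert avg["n_records"] == 2

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            phase_average(self._frame([1.0]), "nope", 1)
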