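"""Design enumeration, titration ladders, and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import effortdisc as ed
from effortdisc.design import InvalidSpecError, SchemaError

PRINTED_80 = (80, 79, 77, 74, 71, 68, 65, 62, 59, 56, 53, 50, 47, 44, 41,
              38, 35, 32, 29, 26, 23, 20, 17, 14, 11, 8, 5, 2, 1, 0)


class TestEnumerateConditions:
    def test_default_design_has_30_conditions(self, spec):
        conditions = ed.enumerate_conditions(spec)
        assert len(conditions) == 30
        assert spec.n_conditions == 30

    @pytest.mark.parametrize("domains,amounts,levels,expected", [
        (("physical",), (100,), (10,), 1),
        (("physical", "cognitive"), (10, 20), (1, 2), 8),
    ])
    def test_small_products(self, domains, amounts, levels, expected):
        s = ed.DesignSpec(effort_domains=domains, amounts=amounts,
                          effort_levels=levels)
        assert len(ed.enumerate_conditions(s)) == expected

    @given(nd=st.integers(1, 3), na=st.integers(1, 4), nl=st.integers(1, 6))
    def test_count_is_product_of_factor_sizes(self, nd, na, nl):
        s = ed.DesignSpec(
            effort_domains=tuple(f"d{i}" for i in range(nd)),
            amounts=tuple(10 * (i + 1) for i in range(na)),
            effort_levels=tuple(5 * (i + 1) for i in range(nl)))
        assert len(ed.enumerate_conditions(s)) == nd * na * nl

    def test_zero_effort_pages_flagged_and_not_counted(self, spec):
        with_zero = ed.enumerate_conditions(spec, include_zero_effort=True)
        regular = [c for c in with_zero if not c.is_zero_effort]
        zero = [c for c in with_zero if c.is_zero_effort]
        assert len(regular) == 30
        assert len(zero) == len(spec.effort_domains) * len(spec.amounts)

    @pytest.mark.parametrize("kwargs", [
        {"amounts": ()},
        {"effort_levels": ()},
        {"effort_domains": ()},
        {"amounts": (80, 80)},
        {"amounts": (400, 80)},
        {"effort_levels": (30, -60)},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            ed.DesignSpec(**kwargs)


class TestBuildLadder:
    def test_pln80_matches_printed_list(self):
        assert ed.build_ladder(80).rows == PRINTED_80

    def test_known_rows(self):
        ladder = ed.build_ladder(80)
        assert ladder.value_at(10) == 56
        assert ladder.value_at(1) == 80
        assert ladder.value_at(30) == 0

    def test_scaled_ladder_row10(self):
        assert ed.build_ladder(400).value_at(10) == 280  # 0.70 * 400

    def test_half_up_rounding(self):
        # 68/80 * 50 = 42.5 rounds up, not to even
        assert ed.build_ladder(50).rows[5] == 43

    @pytest.mark.parametrize("amount", [50, 400, 3000, 12345])
    def test_ladder_shape_and_percent_recovery(self, amount):
        ladder = ed.build_ladder(amount)
        rows = np.array(ladder.rows)
        assert len(rows) == 30
        assert rows[0] == amount and rows[-1] == 0
        assert (np.diff(rows) <= 0).all()
        # scaling back recovers the canonical percentage profile to rounding
        percent = rows / amount
        assert np.abs(percent - np.array(PRINTED_80) / 80).max() \
            <= (0.5 + 1e-9) / amount

    def test_invalid_amount(self):
        with pytest.raises(InvalidSpecError):
            ed.build_ladder(0)
        with pytest.raises(InvalidSpecError):
            ed.build_ladder(-5)


class TestChoiceIO:
    def _records(self):
        return pd.DataFrame({
            "participant_id": ["P1"] * 3,
            "domain": ["physical"] * 3,
            "amount": [80] * 3,
            "effort_level": [30] * 3,
            "row_index": [1, 2, 3],
            "effortless_value": [80, 79, 77],
            "choice": ["effortless", "effortless", "effortful"],
        })

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "choices.csv"
        records = self._records()
        ed.write_choices(records, path)
        first = path.read_bytes()
        back = ed.read_choices(path)
        pd.testing.assert_frame_equal(back, records)
        ed.write_choices(back, path)
        assert path.read_bytes() == first

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "choices.csv"
        ed.write_choices(self._records().iloc[:0], path)
        assert ed.read_choices(path).empty

    def test_missing_column_and_bad_token(self, tmp_path):
        path = tmp_path / "choices.csv"
        self._records().drop(columns=["choice"]).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            ed.read_choices(path)
        bad = self._records().assign(choice=["yes", "no", "yes"])
        bad.to_csv(path, index=False)
        with pytest.raises(SchemaError):
            ed.read_choices(path)

    def test_single_switch_violation_flagged(self):
        records = self._records()
        records.loc[1, "choice"] = "effortful"
        records.loc[2, "choice"] = "effortless"
        records = pd.concat([records, records.iloc[[2]].assign(
            row_index=4, choice="effortful")], ignore_index=True)
        violations = ed.validate_choices(records)
        assert violations == [("P1", "physical", 80, 30)]
        assert ed.validate_choices(self._records()) == []


class TestIPTableIO:
    def test_round_trip_and_boundaries(self, tmp_path):
        path = tmp_path / "ips.csv"
        table = pd.DataFrame({
            "participant_id": ["P1", "P1"],
            "domain": ["physical", "cognitive"],
            "amount": [80, 80],
            "effort_level": [30, 30],
            "ip": [80.0, 0.0],  # no discounting and full discounting
        })
        ed.write_ip_table(table, path)
        pd.testing.assert_frame_equal(ed.read_ip_table(path), table)

    def test_out_of_range_ip_rejected(self, tmp_path):
        path = tmp_path / "ips.csv"
        table = pd.DataFrame({
            "participant_id": ["P1"], "domain": ["physical"],
            "amount": [80], "effort_level": [30], "ip": [81.0]})
        table.to_csv(path, index=False)
        with pytest.raises(SchemaError):
            ed.read_ip_table(path)


class TestConfig:
    def test_yaml_and_json_configs(self, tmp_path):
        (tmp_path / "c.yaml").write_text("amounts: [10, 20]\n")
        (tmp_path / "c.json").write_text('{"amounts": [10, 20]}')
        for name in ("c.yaml", "c.json"):
            data = ed.load_config(tmp_path / name)
            assert ed.DesignSpec.from_dict(data).amounts == (10, 20)

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidSpecError):
            ed.DesignSpec.from_dict({"amounts": [10], "typo_key": 1})
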