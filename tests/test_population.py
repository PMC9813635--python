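"""Population table validation, CSV round trips and generator calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltimpact import (
    AGE_BANDS,
    ConfigError,
    DuplicateKeyError,
    GeneratorConfig,
    PopulationTable,
    RangeError,
    SchemaError,
    Stratum,
    generate_population,
    load_population,
    write_population,
)
from saltimpact.population import POPULATION_COLUMNS


def _stratum_row(**overrides):
    row = dict(
        region="north", sex="male", age_band="35-44", population=1e6,
        salt_mean=11.0, salt_sd=1.5, sbp_mean=120.0, sbp_sd=12.0,
        htn_prev=0.2, ihd_incidence=0.001, stroke_incidence=0.002,
        ihd_fatal_frac=0.3, stroke_fatal_frac=0.4,
    )
    row.update(overrides)
    return row


class TestValidation:
    def test_stratum_rejects_out_of_range_fraction(self):
        with pytest.raises(RangeError, match="htn_prev"):
            Stratum(**_stratum_row(htn_prev=1.3))

    def test_stratum_rejects_unknown_age_band(self):
        with pytest.raises(RangeError, match="age_band"):
            Stratum(**_stratum_row(age_band="25-34"))

    def test_duplicate_key_rejected(self):
        frame = pd.DataFrame([_stratum_row(), _stratum_row(salt_mean=9.0)])
        with pytest.raises(DuplicateKeyError, match="north"):
            PopulationTable(frame)

    def test_missing_column_rejected(self):
        frame = pd.DataFrame([_stratum_row()]).drop(columns=["sbp_sd"])
        with pytest.raises(SchemaError, match="sbp_sd"):
            PopulationTable(frame)

    def test_non_numeric_cell_rejected(self):
        frame = pd.DataFrame([_stratum_row(population="many")])
        with pytest.raises(SchemaError, match="population"):
            PopulationTable(frame)

    def test_empty_table_rejected(self):
        with pytest.raises(SchemaError, match="at least one"):
            PopulationTable(pd.DataFrame(columns=POPULATION_COLUMNS))


class TestCsvRoundTrip:
    def test_write_then_load_is_identity(self, default_pop, tmp_path):
        path = tmp_path / "pop.csv"
        write_population(default_pop, path)
        assert load_population(path) == default_pop

    def test_written_file_has_header_plus_one_line_per_stratum(
        self, default_pop, tmp_path
    ):
        path = tmp_path / "pop.csv"
        write_population(default_pop, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + default_pop.n_strata == 21
        assert lines[0] == ",".join(POPULATION_COLUMNS)

    def test_load_rejects_out_of_range_value(self, default_pop, tmp_path):
        path = tmp_path / "pop.csv"
        frame = default_pop.frame
        frame.loc[0, "htn_prev"] = 1.3
        frame.to_csv(path, index=False)
        with pytest.raises(RangeError, match="htn_prev"):
            load_population(path)

    def test_load_rejects_duplicated_stratum(self, default_pop, tmp_path):
        path = tmp_path / "pop.csv"
        frame = default_pop.frame
        pd.concat([frame, frame.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(DuplicateKeyError):
            load_population(path)


@st.composite
def population_frames(draw):
    keys = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["north", "south"]),
                st.sampled_from(["male", "female"]),
                st.sampled_from(AGE_BANDS),
            ),
            min_size=1,
            max_size=8,
            unique=True,
        )
    )
    pos = st.floats(0.5, 1e7, allow_nan=False)
    frac = st.floats(0.0, 1.0, allow_nan=False)
    rows = []
    for region, sex, band in keys:
        rows.append(
            dict(
                region=region, sex=sex, age_band=band,
                population=draw(pos),
                salt_mean=draw(st.floats(1.0, 20.0)),
                salt_sd=draw(st.floats(0.0, 5.0)),
                sbp_mean=draw(st.floats(80.0, 200.0)),
                sbp_sd=draw(st.floats(0.0, 30.0)),
                htn_prev=draw(frac),
                ihd_incidence=draw(st.floats(0.0, 0.1)),
                stroke_incidence=draw(st.floats(0.0, 0.1)),
                ihd_fatal_frac=draw(frac),
                stroke_fatal_frac=draw(frac),
            )
        )
    return pd.DataFrame(rows)


@given(frame=population_frames())
@settings(max_examples=25, derandomize=True, deadline=None)
def test_roundtrip_identity_on_random_valid_tables(frame, tmp_path_factory):
    table = PopulationTable(frame)
    path = tmp_path_factory.mktemp("roundtrip") / "pop.csv"
    write_population(table, path)
    assert load_population(path) == table


class TestGenerator:
    def test_default_table_shape(self, default_pop):
        assert default_pop.n_strata == 20
        keys = default_pop.keys()
        assert len(set(keys)) == 20

    @pytest.mark.parametrize("seed", [0, 1, 7, 12345])
    def test_calibration_to_national_aggregates(self, seed):
        pop = generate_population(GeneratorConfig(seed=seed))
        assert pop.salt_mean == pytest.approx(11.1, abs=0.05)
        assert pop.sbp_mean == pytest.approx(128.1, abs=0.5)
        assert pop.htn_prev == pytest.approx(0.40, abs=0.01)

    def test_same_seed_identical_different_seed_differs(self):
        a = generate_population(GeneratorConfig(seed=3))
        b = generate_population(GeneratorConfig(seed=3))
        c = generate_population(GeneratorConfig(seed=4))
        assert a == b
        assert a != c

    def test_north_south_salt_gap(self):
        config = GeneratorConfig(seed=2, north_south_salt_gap=1.5)
        frame = generate_population(config).frame
        means = {}
        for region, sub in frame.groupby("region"):
            means[region] = np.average(sub["salt_mean"], weights=sub["population"])
        assert means["north"] - means["south"] == pytest.approx(1.5, abs=0.1)

    def test_incidence_increases_with_age(self, default_pop):
        frame = default_pop.frame
        order = {band: i for i, band in enumerate(AGE_BANDS)}
        for _, sub in frame.groupby(["region", "sex"]):
            sub = sub.sort_values("age_band", key=lambda s: s.map(order))
            assert sub["ihd_incidence"].is_monotonic_increasing
            assert sub["stroke_incidence"].is_monotonic_increasing

    def test_aggregate_fatal_fraction_near_target(self, default_pop):
        frame = default_pop.frame
        for disease in ("ihd", "stroke"):
            events = frame["population"] * frame[f"{disease}_incidence"]
            agg = np.average(frame[f"{disease}_fatal_frac"], weights=events)
            assert agg == pytest.approx(0.44, abs=0.02)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="target_salt_mean"):
            generate_population(GeneratorConfig(target_salt_mean=-1.0))
        with pytest.raises(ConfigError, match="fatal_frac_target"):
            generate_population(GeneratorConfig(fatal_frac_target=1.4))
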