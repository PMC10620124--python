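"""Table IO, acquisition filtering, mol% normalization, replicate averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidiff import ingest
from lipidiff.errors import (
    DegenerateSampleError,
    NomenclatureError,
    SchemaError,
    ValidationError,
)

from conftest import make_table


# ---------------------------------------------------------------- read_table
def _write_fixture(tmp_path, matrix_text, meta_text, sep=","):
    matrix = tmp_path / "matrix.csv"
    meta = tmp_path / "meta.csv"
    matrix.write_text(matrix_text.replace("|", sep))
    meta.write_text(meta_text.replace("|", sep))
    return matrix, meta


META_2 = "sample_id|cell_line|treatment|replicate\nS1|THLE2|none|1\nS2|HUH7|none|1\n"


def test_read_well_formed_table(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path,
        "lipid|S1|S2\nPC 16:0/18:1|10|20\nCer 18:1;2/17:0|1|2\nTAG 17:0/17:0/17:0|5|6\n",
        META_2,
    )
    table = ingest.read_table(matrix, meta)
    assert table.n_lipids == 3 and table.n_samples == 2
    assert table.values.notna().all().all()
    assert table.unit == "pmol"
    assert [s.lipid_class for s in table.lipids] == ["PC", "Cer", "TAG"]


def test_read_table_tab_delimited(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path, "lipid|S1|S2\nPC 16:0/18:1|10|20\n", META_2, sep="\t"
    )
    assert ingest.read_table(matrix, meta).n_lipids == 1


def test_empty_cell_is_missing_not_zero(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path, "lipid|S1|S2\nPC 16:0/18:1||20\nPE 16:0/18:1|0|1\n", META_2
    )
    table = ingest.read_table(matrix, meta)
    assert np.isnan(table.values.loc["PC 16:0/18:1", "S1"])
    assert table.values.loc["PE 16:0/18:1", "S1"] == 0.0  # measured zero kept


def test_unmatched_sample_column_is_schema_error(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path, "lipid|S1|S9\nPC 16:0/18:1|10|20\n", META_2
    )
    with pytest.raises(SchemaError, match="S9"):
        ingest.read_table(matrix, meta)


def test_unparseable_lipid_reports_row(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path, "lipid|S1|S2\nPC 16:0/18:1|1|1\nBOGUS 1:2|1|1\n", META_2
    )
    with pytest.raises(NomenclatureError, match="row 1"):
        ingest.read_table(matrix, meta)


def test_negative_value_rejected(tmp_path):
    matrix, meta = _write_fixture(
        tmp_path, "lipid|S1|S2\nPC 16:0/18:1|-1|1\n", META_2
    )
    with pytest.raises(ValidationError):
        ingest.read_table(matrix, meta)


def test_roundtrip_to_csv(tmp_path):
    table = make_table(
        {"PC 16:0/18:1": [1, None, 3], "Cer 18:1;2/17:0": [4, 5, 6]},
        [("THLE2", "none")] * 3,
    )
    table.to_csv(tmp_path / "m.csv", tmp_path / "s.csv")
    back = ingest.read_table(tmp_path / "m.csv", tmp_path / "s.csv")
    pd.testing.assert_frame_equal(back.values, table.values, check_names=False)
    assert back.samples["replicate"].tolist() == [1, 2, 3]


def test_duplicate_replicate_triple_rejected():
    with pytest.raises(SchemaError):
        table = make_table({"PC 16:0/18:1": [1, 2]}, [("A", "none")] * 2)
        meta = table.samples.copy()
        meta["replicate"] = [1, 1]
        ingest.ConcentrationTable(table.values, table.lipids, meta)


# -------------------------------------------------------- acquisition_filter
def test_filter_keeps_cell_passing_both_thresholds():
    keep = ingest.acquisition_filter([[60.0]], [[10.0]], [10.0])
    assert keep[0, 0]


def test_filter_snr_strictly_greater():
    # SNR exactly 5 fails the strict > 5 rule
    keep = ingest.acquisition_filter([[50.0]], [[10.0]], [0.0])
    assert not keep[0, 0]


def test_filter_is_a_conjunction():
    # passes blank test trivially (blank 0) but fails SNR
    keep = ingest.acquisition_filter([[1.0]], [[1.0]], [0.0])
    assert not keep[0, 0]
    # passes SNR but sits exactly at 5x blank: fails
    keep = ingest.acquisition_filter([[50.0]], [[1.0]], [10.0])
    assert not keep[0, 0]


def test_filter_shape_mismatch():
    with pytest.raises(ValidationError):
        ingest.acquisition_filter([[1.0, 2.0]], [[1.0]], [0.0])


def test_filter_monotone_in_thresholds(rng):
    signal = rng.lognormal(3, 1, size=(30, 8))
    noise = rng.lognormal(0, 0.5, size=(30, 8))
    blank = rng.lognormal(0, 1, size=30)
    loose = ingest.acquisition_filter(signal, noise, blank, ingest.FilterParams(5, 5))
    tight = ingest.acquisition_filter(signal, noise, blank, ingest.FilterParams(8, 9))
    assert not (tight & ~loose).any()  # raising thresholds never rescues a cell


# --------------------------------------------------------- normalize_mol_pct
def test_normalize_simple_proportions():
    table = make_table(
        {"PC 16:0/18:1": [2.0], "PE 16:0/18:1": [3.0], "PI 16:0/16:0": [5.0]},
        [("A", "none")],
    )
    normed = ingest.normalize_mol_pct(table)
    assert normed.unit == "mol_pct"
    np.testing.assert_allclose(
        normed.values.iloc[:, 0].to_numpy(), [20.0, 30.0, 50.0]
    )


def test_normalize_ignores_missing_in_denominator():
    table = make_table(
        {"PC 16:0/18:1": [4.0], "PE 16:0/18:1": [None], "PI 16:0/16:0": [6.0]},
        [("A", "none")],
    )
    normed = ingest.normalize_mol_pct(table)
    col = normed.values.iloc[:, 0]
    np.testing.assert_allclose(col[["PC 16:0/18:1", "PI 16:0/16:0"]], [40.0, 60.0])
    assert np.isnan(col["PE 16:0/18:1"])


def test_normalize_idempotent(rng):
    vals = rng.lognormal(2, 1, size=(12, 4))
    table = make_table(
        {f"PC {14 + i}:0/18:1": list(vals[i]) for i in range(12)},
        [("A", "none"), ("A", "none"), ("B", "none"), ("B", "none")],
    )
    once = ingest.normalize_mol_pct(table)
    twice = ingest.normalize_mol_pct(once)
    np.testing.assert_allclose(
        once.values.to_numpy(), twice.values.to_numpy(), rtol=1e-12
    )


def test_normalized_samples_sum_to_100(rng):
    vals = rng.lognormal(1, 2, size=(50, 6))
    vals[rng.random(vals.shape) < 0.2] = np.nan
    table = make_table(
        {f"PC {10 + i}:{i % 5}/18:1": list(vals[i]) for i in range(50)},
        [("A", "none")] * 3 + [("B", "none")] * 3,
    )
    normed = ingest.normalize_mol_pct(table)
    sums = np.nansum(normed.values.to_numpy(), axis=0)
    np.testing.assert_allclose(sums, 100.0, rtol=1e-9)


@settings(derandomize=True, max_examples=50)
@given(scale=st.floats(min_value=1e-6, max_value=1e6))
def test_normalization_scale_invariant(scale):
    base = make_table(
        {"PC 16:0/18:1": [2.0, 2.0], "PE 16:0/18:1": [8.0, 8.0]},
        [("A", "none"), ("B", "none")],
    )
    scaled = make_table(
        {"PC 16:0/18:1": [2.0 * scale, 2.0], "PE 16:0/18:1": [8.0 * scale, 8.0]},
        [("A", "none"), ("B", "none")],
    )
    np.testing.assert_allclose(
        ingest.normalize_mol_pct(base).values.to_numpy(),
        ingest.normalize_mol_pct(scaled).values.to_numpy(),
        rtol=1e-9,
    )


def test_all_missing_sample_is_degenerate():
    table = make_table(
        {"PC 16:0/18:1": [None, 1.0], "PE 16:0/18:1": [None, 2.0]},
        [("A", "none"), ("B", "none")],
    )
    with pytest.raises(DegenerateSampleError, match="A_none_r1"):
        ingest.normalize_mol_pct(table)


# -------------------------------------------------------- average_replicates
def test_average_over_present_replicates_only():
    table = make_table(
        {
            "PC 16:0/18:1": [10.0, 12.0, 14.0],
            "PE 16:0/18:1": [10.0, None, 14.0],
            "PI 16:0/16:0": [None, None, None],
        },
        [("A", "none")] * 3,
    )
    avg = ingest.average_replicates(table, ("A", "none"))
    assert avg.loc["PC 16:0/18:1", "mean"] == 12.0
    assert avg.loc["PC 16:0/18:1", "n"] == 3
    assert avg.loc["PE 16:0/18:1", "mean"] == 12.0
    assert avg.loc["PE 16:0/18:1", "n"] == 2
    assert np.isnan(avg.loc["PI 16:0/16:0", "mean"])
    assert avg.loc["PI 16:0/16:0", "n"] == 0


def test_unknown_group_is_error():
    table = make_table({"PC 16:0/18:1": [1.0]}, [("A", "none")])
    with pytest.raises(ValidationError):
        ingest.average_replicates(table, ("NOPE", "none"))
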