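"""Parsing, validation and panel-assembly contracts of the CSV layer."""

import numpy as np
import pandas as pd
import pytest

from fibroburden import gbd_io
from fibroburden.synthetic import write_panel_csvs

HEADER = "measure_name,location_name,cause_name,metric_name,age_name,year,val,upper,lower\n"


def _write(tmp_path, rows, header=HEADER, name="burden.csv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows), encoding="utf-8")
    return path


def test_well_formed_rows_parse_to_matching_records(tmp_path):
    path = _write(tmp_path, [
        "Deaths,France,Neoplasms,Rate,Age-standardized,1990,148.24,154.39,140.18\n",
        "DALYs (Disability-Adjusted Life Years),France,Neoplasms,Rate,Age-standardized,1990,3969.21,4135.06,3792.05\n",
        "Deaths,Chad,Tuberculosis,Number,All ages,2021,1200,1300,1100\n",
    ])
    df = gbd_io.read_burden_csv(path)
    assert len(df) == 3
    assert df.loc[0, "measure"] == "deaths"
    assert df.loc[1, "measure"] == "dalys"
    assert df.loc[2, "age_type"] == "all_age"
    assert df.loc[0, "value"] == pytest.approx(148.24)
    assert df.loc[2, "metric"] == "number"


def test_interval_violation_cites_offending_row(tmp_path):
    path = _write(tmp_path, [
        "Deaths,France,Neoplasms,Rate,Age-standardized,1990,148.24,154.39,140.18\n",
        "Deaths,Chad,Neoplasms,Rate,Age-standardized,1990,100.0,120.0,110.0\n",
    ])
    with pytest.raises(gbd_io.ValidationError, match=r"\[3\]"):
        gbd_io.read_burden_csv(path)


def test_percent_above_100_rejected(tmp_path):
    path = _write(tmp_path, [
        "Deaths,France,Neoplasms,Percent,All ages,1990,104.0,110.0,90.0\n",
    ])
    with pytest.raises(gbd_io.ValidationError, match="percent"):
        gbd_io.read_burden_csv(path)


def test_missing_column_is_configuration_error(tmp_path):
    header = HEADER.replace("cause_name,", "disease,")
    path = _write(tmp_path, [], header=header)
    with pytest.raises(gbd_io.ConfigurationError, match="cause_name"):
        gbd_io.read_burden_csv(path)


def test_thousands_separators_rejected(tmp_path):
    path = _write(tmp_path, [
        'Deaths,France,Neoplasms,Number,All ages,1990,"1,234",1300,1100\n',
    ])
    with pytest.raises(gbd_io.ValidationError, match="non-numeric"):
        gbd_io.read_burden_csv(path)


def test_unmapped_measure_rejected_with_row(tmp_path):
    path = _write(tmp_path, [
        "Prevalence,France,Neoplasms,Rate,Age-standardized,1990,10,11,9\n",
    ])
    with pytest.raises(gbd_io.ValidationError, match="measure"):
        gbd_io.read_burden_csv(path)


def test_sdi_bounds(tmp_path):
    ok = tmp_path / "sdi_ok.csv"
    ok.write_text("location_name,year,sdi\nFrance,1990,0.5\n", encoding="utf-8")
    assert gbd_io.read_sdi_csv(ok)["sdi"].iloc[0] == pytest.approx(0.5)
    bad = tmp_path / "sdi_bad.csv"
    bad.write_text("location_name,year,sdi\nFrance,1990,1.2\n", encoding="utf-8")
    with pytest.raises(gbd_io.ValidationError, match="sdi"):
        gbd_io.read_sdi_csv(bad)


def test_write_read_round_trip_is_exact(small_panel, tmp_path):
    panel, _ = small_panel
    paths = write_panel_csvs(panel, tmp_path)
    assert set(paths) == {"burden", "sdi", "population"}
    burden = gbd_io.read_burden_csv(paths["burden"])
    for col in ("value", "lower", "upper"):
        np.testing.assert_array_equal(burden[col].to_numpy(),
                                      panel.burden[col].to_numpy())
    sdi = gbd_io.read_sdi_csv(paths["sdi"])
    np.testing.assert_array_equal(sdi["sdi"].to_numpy(), panel.sdi["sdi"].to_numpy())
    pop = gbd_io.read_population_csv(paths["population"])
    np.testing.assert_array_equal(pop["population"].to_numpy(),
                                  panel.population["population"].to_numpy())


def test_assemble_complete_panel_has_empty_missing_list(small_panel):
    panel, _ = small_panel
    assert panel.missing == []
    assert len(panel.locations) == 30
    assert panel.years == list(range(2000, 2010))


def test_dropping_one_sdi_record_is_reported(small_panel):
    panel, _ = small_panel
    sdi = panel.sdi.drop(panel.sdi.index[0])
    dropped = (panel.sdi.iloc[0]["location"], int(panel.sdi.iloc[0]["year"]))
    rebuilt = gbd_io.assemble_panel(panel.burden, sdi, panel.population)
    assert rebuilt.missing == [dropped]


def test_duplicate_burden_key_raises(small_panel):
    panel, _ = small_panel
    dup = pd.concat([panel.burden, panel.burden.iloc[[0]]], ignore_index=True)
    with pytest.raises(gbd_io.PanelError, match="duplicate"):
        gbd_io.assemble_panel(dup, panel.sdi, panel.population)


def test_disjoint_locations_raise(small_panel):
    panel, _ = small_panel
    sdi = panel.sdi.copy()
    sdi["location"] = "Nowhere"
    with pytest.raises(gbd_io.PanelError, match="no location"):
        gbd_io.assemble_panel(panel.burden, sdi, panel.population)


def test_slice_is_complete_and_sdi_ordered(small_panel):
    panel, _ = small_panel
    s = gbd_io.slice_panel(panel, 2005, "Neoplasms")
    assert len(s) == 30
    assert s["sdi"].is_monotonic_increasing


def test_slice_tie_break_is_alphabetical():
    burden = pd.DataFrame({
        "location": ["Zeta", "Alpha", "Mid"], "location_id": np.nan,
        "year": 2000, "cause": "Neoplasms", "measure": "dalys",
        "metric": "rate", "age_type": "age_standardized",
        "value": [10.0, 20.0, 30.0], "lower": [9.0, 19.0, 29.0],
        "upper": [11.0, 21.0, 31.0],
    })
    sdi = pd.DataFrame({"location": ["Zeta", "Alpha", "Mid"], "year": 2000,
                        "sdi": [0.5, 0.5, 0.2]})
    pop = pd.DataFrame({"location": ["Zeta", "Alpha", "Mid"], "year": 2000,
                        "population": [1.0, 1.0, 1.0]})
    panel = gbd_io.assemble_panel(burden, sdi, pop)
    s = gbd_io.slice_panel(panel, 2000, "Neoplasms")
    assert s["location"].tolist() == ["Mid", "Alpha", "Zeta"]


def test_empty_slice_names_the_missing_key(small_panel):
    panel, _ = small_panel
    with pytest.raises(gbd_io.PanelError, match="Ghost cause"):
        gbd_io.slice_panel(panel, 2005, "Ghost cause")


def test_slice_values_match_generator_truth(small_panel):
    """Sliced rates equal frontier + inefficiency + (truncated) noise >= frontier."""
    panel, truth = small_panel
    s = gbd_io.slice_panel(panel, 2004, "Tuberculosis")
    f = truth.frontier.query("cause == 'Tuberculosis' and measure == 'dalys' and year == 2004")
    merged = s.merge(f, on="location")
    assert (merged["value"] >= merged["frontier"] - 1e-9).all()
    d = truth.deltas.query("cause == 'Tuberculosis' and measure == 'dalys'")
    merged = merged.merge(d, on="location")
    # noise is mean-zero and truncated at the frontier, so values scatter
    # around frontier + delta without falling below the frontier
    resid = merged["value"] - merged["frontier"] - merged["delta"]
    assert abs(resid.mean()) < 5 * 15.0 / np.sqrt(len(resid))
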