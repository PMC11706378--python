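"""Panel assembly: parsing, validation, exclusion rules, round trips."""

import numpy as np
import pandas as pd
import pytest

from ghsdid import (
    ConfigurationError,
    DuplicateKeyError,
    Panel,
    PanelConfig,
    ValidationError,
    VocabularyError,
    assemble_panel,
    read_attributes,
    read_coverage,
)
from conftest import make_coverage_frame


def write_csv(path, text):
    path.write_text(text)
    return path


class TestReadCoverage:
    def test_well_formed_rows_become_observations(self, tmp_path):
        p = write_csv(
            tmp_path / "cov.csv",
            "iso3,vaccine,year,coverage\nALB,DTP3,2019,98\nALB,DTP3,2020,97.5\n",
        )
        obs = read_coverage(p)
        assert len(obs) == 2
        assert obs["coverage"].tolist() == [98.0, 97.5]
        assert not obs["is_missing"].any()

    def test_out_of_range_coverage_rejected(self, tmp_path):
        p = write_csv(tmp_path / "cov.csv", "iso3,vaccine,year,coverage\nALB,DTP3,2019,101\n")
        with pytest.raises(ValidationError, match="outside"):
            read_coverage(p)

    def test_blank_coverage_becomes_missing(self, tmp_path):
        p = write_csv(tmp_path / "cov.csv", "iso3,vaccine,year,coverage\nALB,BCG,2022,\n")
        obs = read_coverage(p)
        assert obs["is_missing"].tolist() == [True]
        assert np.isnan(obs["coverage"].iloc[0])

    def test_unparseable_year_names_row(self, tmp_path):
        p = write_csv(tmp_path / "cov.csv", "iso3,vaccine,year,coverage\nALB,BCG,20x9,90\n")
        with pytest.raises(ValidationError, match="year"):
            read_coverage(p)

    def test_duplicate_key_rejected(self, tmp_path):
        p = write_csv(
            tmp_path / "cov.csv",
            "iso3,vaccine,year,coverage\nALB,BCG,2019,90\nALB,BCG,2019,91\n",
        )
        with pytest.raises(DuplicateKeyError):
            read_coverage(p)

    def test_custom_dialect_maps_headers(self, tmp_path):
        p = write_csv(tmp_path / "cov.csv", "code,antigen,yr,pct\nALB,BCG,2019,90\n")
        obs = read_coverage(
            p, dialect={"country": "code", "vaccine": "antigen", "year": "yr", "coverage": "pct"}
        )
        assert obs.loc[0, "iso3"] == "ALB"
        assert obs.loc[0, "coverage"] == 90.0


class TestReadAttributes:
    def test_labels_normalized_case_insensitively(self, tmp_path):
        p = write_csv(
            tmp_path / "attr.csv",
            "iso3,income_group,who_region\nalb,high,EUROPE\nken,lower middle,africa\n",
        )
        attrs = read_attributes(p)
        assert attrs["income_group"].tolist() == ["High", "Lower-Middle"]
        assert attrs["who_region"].tolist() == ["Europe", "Africa"]

    def test_unknown_region_rejected(self, tmp_path):
        p = write_csv(tmp_path / "attr.csv", "iso3,income_group,who_region\nFJI,High,Oceania\n")
        with pytest.raises(VocabularyError, match="Oceania"):
            read_attributes(p)

    def test_governance_out_of_range_rejected(self, tmp_path):
        p = write_csv(
            tmp_path / "attr.csv",
            "iso3,income_group,who_region,rule_of_law\nALB,High,Europe,3.0\n",
        )
        with pytest.raises(ValidationError, match="governance"):
            read_attributes(p)


def study_shaped_input():
    """195 countries x 14 vaccines x 2015-2023, before exclusions."""
    countries = [f"C{k:02d}" for k in range(191)] + ["COK", "NIU", "PSE", "PRK"]
    vaccines = [
        "BCG", "DTP1", "DTP3", "HEPB3", "HEPBB", "HIB3", "MCV1",
        "MCV2", "PCV3", "POL3", "RCV1", "ROTAC", "YFV", "IPV1",
    ]
    years = range(2014, 2023)  # includes one pre-window year
    coverage = make_coverage_frame(countries, vaccines, years)
    attributes = pd.DataFrame(
        {
            "iso3": countries,
            "income_group": ["High"] * 98 + ["Low"] * 97,
            "who_region": ["Europe"] * 98 + ["Africa"] * 97,
        }
    )
    return coverage, attributes


class TestAssemblePanel:
    def test_default_exclusions_reproduce_study_shape(self):
        coverage, attributes = study_shaped_input()
        panel = assemble_panel(coverage, attributes, PanelConfig())
        assert panel.summary.n_countries == 191
        assert panel.summary.n_vaccines == 12
        assert panel.summary.n_kept == 191 * 12 * 8

    def test_empty_exclusions_keep_panel_unchanged(self):
        coverage, attributes = study_shaped_input()
        config = PanelConfig(year_window=(2014, 2022), excluded_vaccines=(), excluded_countries=())
        panel = assemble_panel(coverage, attributes, config)
        assert panel.summary.n_kept == len(coverage)
        assert panel.summary.n_countries == 195

    def test_counting_conservation_per_rule(self):
        coverage, attributes = study_shaped_input()
        panel = assemble_panel(coverage, attributes, PanelConfig())
        s = panel.summary
        assert s.n_rows_in == s.n_kept + sum(s.dropped.values())
        assert s.dropped["excluded_country"] == 4 * 12 * 8  # after vaccine exclusions
        assert s.dropped["excluded_vaccine"] == 195 * 2 * 8  # before country exclusions

    def test_missing_fraction_of_twelve_bcg_cells(self):
        coverage, attributes = study_shaped_input()
        twelve = coverage["iso3"].unique()[:12]
        mask = (
            coverage["iso3"].isin(twelve)
            & (coverage["vaccine"] == "BCG")
            & (coverage["year"] == 2022)
        )
        coverage.loc[mask, "coverage"] = np.nan
        coverage.loc[mask, "is_missing"] = True
        panel = assemble_panel(coverage, attributes, PanelConfig())
        assert panel.summary.n_missing == 12
        assert round(100 * panel.summary.missing_fraction, 2) == 0.07

    def test_country_without_attributes_dropped_with_tally(self):
        coverage, attributes = study_shaped_input()
        attributes = attributes[attributes["iso3"] != "C00"]
        panel = assemble_panel(coverage, attributes, PanelConfig())
        assert panel.summary.n_countries == 190
        assert panel.summary.dropped["no_attributes"] == 12 * 8  # within window, after vaccine exclusions

    def test_assembly_is_idempotent(self):
        coverage, attributes = study_shaped_input()
        config = PanelConfig()
        once = assemble_panel(coverage, attributes, config)
        twice = assemble_panel(once.observations, once.attributes, config)
        pd.testing.assert_frame_equal(once.observations, twice.observations)
        pd.testing.assert_frame_equal(once.attributes, twice.attributes)

    def test_everything_excluded_raises(self):
        coverage, attributes = study_shaped_input()
        config = PanelConfig(year_window=(1990, 1991))
        with pytest.raises(ConfigurationError):
            assemble_panel(coverage, attributes, config)


def test_csv_round_trip_preserves_panel(tmp_path, small_panel):
    from ghsdid import inject_missingness

    _, panel, _ = small_panel
    panel = inject_missingness(panel, rate=0.01, seed=3)
    panel.to_csv(tmp_path)
    back = Panel.from_csv(tmp_path, PanelConfig(excluded_vaccines=(), excluded_countries=()))
    a = panel.observations.sort_values(["iso3", "vaccine", "year"]).reset_index(drop=True)
    b = back.observations.sort_values(["iso3", "vaccine", "year"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(
        panel.attributes.reset_index(drop=True), back.attributes.reset_index(drop=True)
    )
    assert back.year_window == panel.year_window
    assert back.vaccine_set == panel.vaccine_set
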