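"""Model/Results orchestration, report files and the command-line interface."""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mutclust.cli import main as cli_main
from mutclust.model import CLUSTERS_COLUMNS, ELEMENTS_COLUMNS, ClusteringModel
from mutclust.pipeline import run
from mutclust.simulation import SimulationConfig
from mutclust.synth import FixtureSpec, build_fixture, write_fixture

QUICK = SimulationConfig(n_simulations=100)


@pytest.fixture(scope="module")
def small_spec():
    return FixtureSpec(
        n_elements=6,
        element_length=300,
        n_segments=2,
        mutations_per_element=25,
        hotspots=(("E003", 150, 0.4),),
        seed=77,
    )


@pytest.fixture(scope="module")
def small_fixture(small_spec):
    return build_fixture(small_spec)


@pytest.fixture(scope="module")
def small_files(small_spec, tmp_path_factory):
    return write_fixture(small_spec, tmp_path_factory.mktemp("fixture"))


class TestClusteringModel:
    def test_fit_produces_expected_tables(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        results = ClusteringModel(mutations, elements, genome, config=QUICK).fit()
        df = results.elements
        assert list(df.columns) == ELEMENTS_COLUMNS
        assert len(df) == 6
        assert list(results.clusters.columns) == CLUSTERS_COLUMNS
        # sorted by q, then p
        assert df["q_value"].is_monotonic_increasing
        # the planted hotspot element ranks first
        assert df.iloc[0]["element_id"] == "E003"

    def test_cluster_genomic_coordinates_map_into_segments(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        results = ClusteringModel(mutations, elements, genome, config=QUICK).fit()
        by_id = {e.element_id: e for e in elements}
        for row in results.clusters.itertuples():
            element = by_id[row.element_id]
            for pos1 in (row.genomic_left, row.genomic_right, row.genomic_peak):
                assert any(s < pos1 <= e for s, e in element.segments)

    def test_mutation_accounting_is_conserved(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        results = ClusteringModel(mutations, elements, genome, config=QUICK).fit()
        c = results.metadata()["counters"]
        assert c["snvs"] == c["reference_mismatch"] + c["assigned"] + c["unassigned"]
        assert c["assigned"] == c["profile_counted"] + c["context_undefined"]

    def test_fit_is_independent_of_element_order(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        r1 = ClusteringModel(mutations, elements, genome, config=QUICK).fit()
        r2 = ClusteringModel(mutations, elements[::-1], genome, config=QUICK).fit()
        merged = r1.elements.merge(r2.elements, on="element_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_value_a"], merged["p_value_b"])
        assert np.allclose(merged["score_a"], merged["score_b"])

    def test_no_assigned_mutations_is_an_error(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        far = [m for m in mutations if False]
        with pytest.raises(ValueError):
            ClusteringModel(far, elements, genome, config=QUICK)

    def test_summary_mentions_key_quantities(self, small_fixture):
        genome, elements, mutations, _ = small_fixture
        results = ClusteringModel(mutations, elements, genome, config=QUICK).fit()
        text = results.summary()
        assert "elements analyzed: 6" in text
        assert "E003" in text

    def test_precomputed_profile_is_honored(self, small_fixture, tmp_path):
        from mutclust.profiles import uniform_profile

        genome, elements, mutations, _ = small_fixture
        profile = uniform_profile(3)
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        model = ClusteringModel(
            mutations,
            elements,
            genome,
            config=QUICK,
            profile=profile,
        )
        assert model.profile.probabilities == profile.probabilities
        from mutclust.profiles import MutationalProfile

        loaded = MutationalProfile.from_tsv(path)
        assert loaded.probabilities.keys() == profile.probabilities.keys()


class TestRun:
    def test_run_writes_reports(self, small_files, tmp_path):
        report = run(
            QUICK,
            small_files["mutations"],
            small_files["regions"],
            small_files["genome"],
            tmp_path / "out",
        )
        for key in ("elements", "clusters", "metadata", "log"):
            assert report.paths[key].exists()
        elements = pd.read_csv(report.paths["elements"], sep="\t")
        assert list(elements.columns) == ELEMENTS_COLUMNS
        assert len(elements) == 6
        meta = json.loads(report.paths["metadata"].read_text())
        assert meta["config"]["n_simulations"] == 100
        assert meta["counters"]["snvs"] == 150

    def test_element_rows_count_matches_clusters(self, small_files, tmp_path):
        report = run(
            QUICK,
            small_files["mutations"],
            small_files["regions"],
            small_files["genome"],
            tmp_path / "out",
        )
        clusters = pd.read_csv(report.paths["clusters"], sep="\t")
        per_element = clusters.groupby("element_id").size()
        elements = report.elements.set_index("element_id")
        for element_id, n in per_element.items():
            assert elements.loc[element_id, "n_clusters"] == n

    def test_empty_mutation_file_is_an_error(self, small_files, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("chromosome\tposition\tref\talt\tsample\n")
        with pytest.raises(ValueError, match="no single-nucleotide substitutions"):
            run(
                QUICK,
                empty,
                small_files["regions"],
                small_files["genome"],
                tmp_path / "out",
            )


class TestCli:
    def test_cli_end_to_end(self, small_files, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cliout"
        result = runner.invoke(
            cli_main,
            [
                "--mutations", str(small_files["mutations"]),
                "--regions", str(small_files["regions"]),
                "--genome", str(small_files["genome"]),
                "--output", str(out),
                "--n-simulations", "50",
                "--seed", "99",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "Somatic mutation clustering analysis" in result.output
        assert (out / "elements.tsv").exists()

    def test_cli_reports_errors_with_nonzero_exit(self, small_files, tmp_path):
        runner = CliRunner()
        empty = tmp_path / "empty.tsv"
        empty.write_text("chromosome\tposition\tref\talt\tsample\n")
        result = runner.invoke(
            cli_main,
            [
                "--mutations", str(empty),
                "--regions", str(small_files["regions"]),
                "--genome", str(small_files["genome"]),
                "--output", str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 1
        assert "error" in result.output
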