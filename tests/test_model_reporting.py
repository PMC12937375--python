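"""Model/Results facade, heatmap matrices, pipeline driver and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from contactatlas.cli import main as cli_main
from contactatlas.model import ContactPersistenceModel
from contactatlas.reporting import RunConfig, build_duration_matrix, run_pipeline
from contactatlas.synthetic import default_spec, two_variant_specs, write_fixture

from test_persistence import _toy_atlas

# desk-scale run: 150 ns per replica, 135 ns analysis window
TEST_FRAMES = 1500
TEST_WINDOW = (15.0, 150.0)


@pytest.fixture(scope="module")
def fitted_results():
    spec = default_spec(seed=11, n_frames=TEST_FRAMES)
    model = ContactPersistenceModel.from_spec(spec, window=TEST_WINDOW)
    return spec, model.fit()


class TestModelResults:
    def test_only_designated_pairs_detected(self, fitted_results):
        """Ground-truth manifest comparison: every detected residue pair is
        a programmed pair (the layout guarantees no strays)."""
        spec, res = fitted_results
        programmed = {
            frozenset((p.static, p.mobile)) for p in spec.pairs
        }
        seen = {
            frozenset(((k.chain_a, k.res_a), (k.chain_b, k.res_b)))
            for k in res.atlas.records
        }
        assert seen <= programmed
        # and every programmed pair was seen in its designated type
        designated = {
            frozenset((p.static, p.mobile)): p.itype for p in spec.pairs
        }
        for k in res.atlas.records:
            fs = frozenset(((k.chain_a, k.res_a), (k.chain_b, k.res_b)))
            assert fs in designated
        seen_types = {
            (frozenset(((k.chain_a, k.res_a), (k.chain_b, k.res_b))), k.itype)
            for k in res.atlas.records
        }
        for fs, itype in designated.items():
            assert (fs, itype) in seen_types

    def test_bookkeeping_identity(self, fitted_results):
        """Sum of per-pair presences equals sum of per-frame contact counts."""
        spec, res = fitted_results
        # integer frame arithmetic: durations / dt are exact frame counts
        frames_per_pair = sum(
            int(round(d / res.atlas.dt_ns))
            for r in res.atlas.records.values()
            for d in r.per_replica_duration_ns
        )
        assert frames_per_pair == res.total_presences()

    def test_summary_mentions_key_facts(self, fitted_results):
        spec, res = fitted_results
        text = res.summary()
        assert "variant-A" in text
        assert "ASP241" in text  # the persistent programmed salt bridge
        assert str(res.atlas.n_replicas) in text

    def test_filter_returns_new_results(self, fitted_results):
        _, res = fitted_results
        kept = res.filter("occupancy_min", 0.10)
        assert len(kept.atlas) <= len(res.atlas)
        assert kept.atlas.filters_applied == ["occupancy_min>=0.1"]

    def test_occupancy_recovery_within_three_se(self, fitted_results):
        """Pipeline-recovered occupancy of each designated pair tracks the
        programmed stationary value within 3 analytic standard errors."""
        from contactatlas.synthetic import expected_occupancy, occupancy_standard_error

        spec, res = fitted_results
        window_ns = TEST_WINDOW[1] - TEST_WINDOW[0]
        checked = 0
        for p in spec.pairs:
            for key, rec in res.atlas.records.items():
                pair = {(key.chain_a, key.res_a), (key.chain_b, key.res_b)}
                if pair == {p.static, p.mobile} and key.itype == p.itype:
                    occ = float(np.mean(rec.per_replica_occupancy))
                    se = occupancy_standard_error(
                        p.k_on, p.k_off, window_ns, n_replicas=spec.n_replicas
                    )
                    assert abs(occ - expected_occupancy(p.k_on, p.k_off)) < 3 * se
                    checked += 1
        assert checked == len(spec.pairs)


class TestHeatmap:
    def test_single_record_matrix(self):
        atlas = _toy_atlas({("A", 265, "C", 120, "hbond"): [700.0] * 4})
        m = build_duration_matrix(atlas, ("A", "C"), "hbond")
        assert m.values.shape == (1, 1)
        assert m.values.iloc[0, 0] == pytest.approx(700.0)

    def test_shared_row(self):
        atlas = _toy_atlas({
            ("A", 239, "C", 120, "hbond"): [300.0] * 4,
            ("A", 239, "C", 134, "hbond"): [100.0] * 4,
        })
        m = build_duration_matrix(atlas, ("A", "C"), "hbond")
        assert m.values.shape == (1, 2)

    def test_display_floor_drops_row_and_column(self):
        atlas = _toy_atlas({
            ("A", 239, "C", 120, "hbond"): [44.0] * 4,
            ("A", 265, "C", 134, "hbond"): [500.0] * 4,
        })
        m = build_duration_matrix(atlas, ("A", "C"), "hbond", display_min_ns=45.0)
        assert m.values.shape == (1, 1)
        assert "ALA239" not in m.values.index

    def test_cells_equal_atlas_means_exactly(self):
        atlas = _toy_atlas({
            ("A", 239, "C", 120, "hbond"): [123.456] * 4,
        })
        m = build_duration_matrix(atlas, ("A", "C"), "hbond")
        assert m.values.iloc[0, 0] == atlas.records[next(iter(atlas.records))].mean_duration_ns

    def test_empty_atlas_warns(self):
        atlas = _toy_atlas({})
        with pytest.warns(UserWarning, match="no hbond records"):
            m = build_duration_matrix(atlas, ("A", "C"), "hbond")
        assert m.values.empty


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    """Two-variant on-disk fixture (XTC) at desk scale plus a run config."""
    root = tmp_path_factory.mktemp("fixtures")
    specs = two_variant_specs(seed=13, n_frames=TEST_FRAMES)
    complexes = []
    for spec in specs:
        paths = write_fixture(spec, root / spec.label, fmt="xtc")
        complexes.append(
            {"label": spec.label, "topology": paths["topology"],
             "replicas": paths["replicas"], "dt_ns": spec.dt_ns}
        )
    cfg = {
        "output_dir": str(root / "report"),
        "window_start_ns": TEST_WINDOW[0],
        "window_end_ns": TEST_WINDOW[1],
        "display_min_ns": 10.0,
        "persistent_min_ns": 30.0,
        "complexes": complexes,
        "make_figures": False,
    }
    cfg_path = root / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return root, cfg_path, specs


@pytest.fixture(scope="module")
def pipeline_bundle(fixture_dir):
    root, cfg_path, specs = fixture_dir
    config = RunConfig.from_yaml(cfg_path)
    return config, run_pipeline(config)


class TestPipeline:
    def test_bundle_and_programmed_differential(self, pipeline_bundle):
        """The report bundle flags the programmed kinetics difference as a
        significant differential contact."""
        config, bundle = pipeline_bundle
        assert set(bundle["complexes"]) == {"variant-A", "variant-B"}
        diff = pd.read_csv(bundle["differentials"][0], sep="\t")
        # the destabilised salt bridge: A:241 x C:120
        row = diff[(diff.res_a == 241) & (diff.res_b == 120) & (diff.type == "ionic")]
        assert len(row) == 1
        assert bool(row.significant.iloc[0])
        assert row.delta_ns.iloc[0] > 0  # variant-A more persistent

    def test_rerun_byte_identical(self, tmp_path):
        """Same config + seed twice: every exported TSV is byte-identical."""
        spec = default_spec(seed=21, n_frames=600, n_replicas=2)
        paths = write_fixture(spec, tmp_path / "fx", fmt="xtc")
        raw = {
            "output_dir": "",
            "window_start_ns": 6.0,
            "window_end_ns": 60.0,
            "make_figures": False,
            "complexes": [{"label": spec.label, "topology": paths["topology"],
                           "replicas": paths["replicas"], "dt_ns": spec.dt_ns}],
        }
        outputs = []
        for run in ("one", "two"):
            raw["output_dir"] = str(tmp_path / run)
            run_pipeline(RunConfig.from_dict(raw))
            tsvs = sorted(p for p in (tmp_path / run).rglob("*.tsv"))
            outputs.append({p.relative_to(tmp_path / run): p.read_bytes() for p in tsvs})
        assert outputs[0].keys() == outputs[1].keys()
        for k in outputs[0]:
            assert outputs[0][k] == outputs[1][k], f"{k} differs between reruns"

    def test_atlas_tsv_has_provenance_sidecar(self, pipeline_bundle):
        config, bundle = pipeline_bundle
        from pathlib import Path

        atlas_path = Path(bundle["complexes"]["variant-A"]["atlas"])
        sidecar = json.loads(atlas_path.with_suffix(".json").read_text())
        assert sidecar["parameters"]["hbond_max_da_dist_A"] == 3.5
        assert sidecar["window_start_ns"] == TEST_WINDOW[0]
        prov = json.loads((Path(config.output_dir) / "provenance.json").read_text())
        assert prov["detection"] == config.detection.as_dict()

    def test_config_validation_before_io(self, tmp_path):
        """A config missing dt_ns fails validation before any file is read
        (the referenced paths do not exist)."""
        raw = {
            "output_dir": str(tmp_path / "out"),
            "complexes": [
                {"label": "x", "topology": "does-not-exist.pdb",
                 "replicas": ["missing.pdb"]}
            ],
        }
        with pytest.raises(ValueError, match="dt_ns"):
            RunConfig.from_dict(raw)


class TestCli:
    def test_simulate_run_compare(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["simulate", "-o", str(tmp_path), "--seed", "3", "--n-frames", "300",
             "--n-replicas", "2"],
        )
        assert r.exit_code == 0, r.output
        cfg = yaml.safe_load((tmp_path / "config.yaml").read_text())
        cfg["make_figures"] = False
        cfg["display_min_ns"] = 5.0
        (tmp_path / "config.yaml").write_text(yaml.safe_dump(cfg))
        r = runner.invoke(cli_main, ["run", "-c", str(tmp_path / "config.yaml")])
        assert r.exit_code == 0, r.output
        atlas_a = tmp_path / "report/variant-A/atlas.tsv"
        atlas_b = tmp_path / "report/variant-B/atlas.tsv"
        assert atlas_a.exists() and atlas_b.exists()
        r = runner.invoke(
            cli_main,
            ["compare", str(atlas_a), str(atlas_b), "--alpha", "0.05",
             "-o", str(tmp_path / "diff.tsv")],
        )
        assert r.exit_code == 0, r.output
        diff = pd.read_csv(tmp_path / "diff.tsv", sep="\t")
        assert {"delta_ns", "p", "status", "significant"} <= set(diff.columns)

    def test_missing_config_key_fails_cleanly(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump({"output_dir": "x", "complexes": [
            {"label": "a", "topology": "t.pdb", "replicas": ["r.pdb"]}
        ]}))
        r = CliRunner().invoke(cli_main, ["run", "-c", str(bad)])
        assert r.exit_code != 0
        assert "dt_ns" in r.output
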