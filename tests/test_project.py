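"""Project parsing, staleness-driven builds and the comparison report."""

import json
import logging
import shutil

import pytest
import yaml

from hicfold import make_synthetic_project, parse_project
from hicfold.project import build, export_report, plan_build


def write_yaml(path, payload):
    path.write_text(yaml.safe_dump(payload))


def minimal_project(tmp_path, n_datasets=2):
    d = tmp_path / "proj"
    d.mkdir()
    names = ["control", "condition"][:n_datasets]
    for name in names:
        (d / f"{name}.txt").write_text("0 2 5.0\n1 3 5.0\n")
    payload = {
        "datasets": [
            {"name": name, "data": f"{name}.txt"} for name in names
        ],
    }
    write_yaml(d / "project.yaml", payload)
    return d


def fast_project(tmp_path, n_beads=40, seed=1):
    """Synthetic project with reduced step budgets injected into the YAML."""
    d = make_synthetic_project(tmp_path / "proj", n_beads=n_beads, seed=seed)
    payload = yaml.safe_load((d / "project.yaml").read_text())
    payload["project"]["simulation"] = {
        "max_steps_formation": 3000,
        "max_steps_production": 2000,
        "check_interval": 250,
    }
    write_yaml(d / "project.yaml", payload)
    return d


class TestParseProject:
    def test_minimal_two_dataset_file(self, tmp_path):
        config = parse_project(minimal_project(tmp_path))
        assert len(config.datasets) == 2
        assert config.tracks == [] and config.annotations == [] and config.bookmarks == []
        assert config.count_threshold == 2.0  # injected default

    def test_full_synthetic_file_resolves_everything(self, tmp_path):
        d = make_synthetic_project(tmp_path / "p", n_beads=40, seed=2)
        config = parse_project(d)
        assert config.tracks[0].name == "arms"
        assert config.annotations[0].path.suffix == ".gff3"
        assert {b.name for b in config.bookmarks} == {"domain A", "domain B", "first ten bins"}

    def test_single_dataset_rejected(self, tmp_path):
        d = minimal_project(tmp_path, n_datasets=1)
        with pytest.raises(ValueError, match="exactly two comparable datasets"):
            parse_project(d)

    def test_missing_datasets_section_rejected(self, tmp_path):
        d = tmp_path / "p"
        d.mkdir()
        write_yaml(d / "project.yaml", {"project": {"name": "x"}})
        with pytest.raises(ValueError, match="datasets required"):
            parse_project(d)

    def test_missing_file_named_in_error(self, tmp_path):
        d = tmp_path / "p"
        d.mkdir()
        write_yaml(d / "project.yaml",
                   {"datasets": [{"name": "a", "data": "gone.txt"},
                                 {"name": "b", "data": "gone.txt"}]})
        with pytest.raises(FileNotFoundError, match="gone.txt"):
            parse_project(d)

    def test_unknown_keys_warn_not_fail(self, tmp_path):
        d = minimal_project(tmp_path)
        payload = yaml.safe_load((d / "project.yaml").read_text())
        payload["frobnicate"] = True
        write_yaml(d / "project.yaml", payload)
        with pytest.warns(UserWarning, match="frobnicate"):
            parse_project(d)


class TestPlanAndBuild:
    def test_empty_build_dir_marks_all_stale(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        plan = plan_build(config, config.project_dir / ".build")
        assert plan == {"control": True, "condition": True}

    def test_build_then_replan_is_fresh_and_idempotent(self, tmp_path, caplog):
        config = parse_project(fast_project(tmp_path))
        result = build(config)
        assert not result.errors
        assert all(result.steps_run[n] > 0 for n in ("control", "condition"))
        plan = plan_build(config, result.build_dir)
        assert plan == {"control": False, "condition": False}

        with caplog.at_level(logging.INFO, logger="hicfold"):
            again = build(config)
        assert again.steps_run == {"control": 0, "condition": 0}
        assert "structures up to date" in caplog.text

    def test_expected_artifacts_exist(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        result = build(config)
        for name in ("control", "condition"):
            for suffix in (".pdb", ".xyz", ".csv"):
                assert (result.build_dir / f"structure_{name}{suffix}").exists()
            assert (result.build_dir / f"history_{name}.csv").exists()
            assert (result.build_dir / f"metrics_{name}.json").exists()
        assert (result.build_dir / "tracks" / "arms_control.csv").exists()
        assert (result.build_dir / "selections.json").exists()
        assert (result.build_dir / "manifest.json").exists()

    def test_track_edit_never_marks_structures_stale(self, tmp_path):
        d = fast_project(tmp_path)
        config = parse_project(d)
        build(config)
        # edit the track: structures stay fresh, fused output refreshes
        arms = d / "arms.csv"
        arms.write_text(arms.read_text().replace("0,1.0", "0,9.0"))
        config = parse_project(d)
        result = build(config)
        assert result.steps_run == {"control": 0, "condition": 0}
        fused = (result.build_dir / "tracks" / "arms.csv").read_text()
        assert "9.0" in fused

    def test_copied_project_stays_fresh(self, tmp_path):
        d = fast_project(tmp_path)
        config = parse_project(d)
        build(config)
        copy = tmp_path / "copy"
        shutil.copytree(d, copy)
        config2 = parse_project(copy)
        result = build(config2)  # content-hash based: no re-simulation
        assert result.steps_run == {"control": 0, "condition": 0}

    def test_corrupt_manifest_treated_as_stale(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        result = build(config)
        (result.build_dir / "manifest.json").write_text("{ not json")
        with pytest.warns(UserWarning, match="corrupt"):
            plan = plan_build(config, result.build_dir)
        assert plan == {"control": True, "condition": True}

    def test_config_change_triggers_rebuild(self, tmp_path):
        d = fast_project(tmp_path)
        config = parse_project(d)
        build(config)
        payload = yaml.safe_load((d / "project.yaml").read_text())
        payload["project"]["count_threshold"] = 1.5
        write_yaml(d / "project.yaml", payload)
        plan = plan_build(parse_project(d), d / ".build")
        assert plan == {"control": True, "condition": True}


class TestReport:
    def test_incomplete_build_lists_missing_artifacts(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        with pytest.raises(FileNotFoundError, match="metrics_control.json"):
            export_report(config, config.project_dir / ".build")

    def test_identical_datasets_have_zero_rmsd(self, tmp_path):
        d = fast_project(tmp_path)
        shutil.copyfile(d / "control.coo.txt", d / "condition.coo.txt")
        config = parse_project(d)
        build(config)
        json_path, html_path = export_report(config)
        report = json.loads(json_path.read_text())
        assert report["comparison"]["overall_rmsd"] == pytest.approx(0.0, abs=1e-8)
        assert html_path.exists()

    def test_report_regeneration_is_byte_identical(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        build(config)
        json_path, _ = export_report(config)
        first = json_path.read_bytes()
        json_path, _ = export_report(config)
        assert json_path.read_bytes() == first

    def test_report_summarizes_both_conditions(self, tmp_path):
        config = parse_project(fast_project(tmp_path))
        build(config)
        json_path, _ = export_report(config)
        report = json.loads(json_path.read_text())
        assert set(report["datasets"]) == {"control", "condition"}
        for m in report["datasets"].values():
            assert 0.0 <= m["satisfied_fraction"] <= 1.0
        sel = report["comparison"]["per_selection_rmsd"]
        assert any(k.endswith("domainA") for k in sel)
        assert any(k.startswith("bookmark:") for k in sel)


class TestPerturbationLocalization:
    def test_perturbed_domain_moves_more_than_untouched_domain(self, tmp_path):
        # control vs condition differ only in domain B (compacted), so the
        # per-range superposition RMSD must be larger for B than for A
        d = make_synthetic_project(tmp_path / "proj", n_beads=80, seed=3)
        payload = yaml.safe_load((d / "project.yaml").read_text())
        payload["project"]["simulation"] = {
            "max_steps_formation": 8000,
            "max_steps_production": 6000,
        }
        write_yaml(d / "project.yaml", payload)
        config = parse_project(d)
        build(config)
        json_path, _ = export_report(config)
        sel = json.loads(json_path.read_text())["comparison"]["per_selection_rmsd"]
        rmsd_a = sel["annotation:features:domainA"]["rmsd"]
        rmsd_b = sel["annotation:features:domainB"]["rmsd"]
        assert rmsd_b > rmsd_a


class TestCli:
    def test_template_build_run_cycle(self, tmp_path):
        from click.testing import CliRunner

        from hicfold.cli import main

        runner = CliRunner()
        proj_dir = tmp_path / "demo"
        res = runner.invoke(main, ["template", "--output", str(proj_dir), "--n-beads", "30"])
        assert res.exit_code == 0, res.output
        # speed the simulation up before running
        payload = yaml.safe_load((proj_dir / "project.yaml").read_text())
        payload["project"]["simulation"] = {
            "max_steps_formation": 2000, "max_steps_production": 1500,
        }
        write_yaml(proj_dir / "project.yaml", payload)

        res = runner.invoke(main, ["run", str(proj_dir)])
        assert res.exit_code == 0, res.output
        assert (proj_dir / ".build" / "report.json").exists()
        assert (proj_dir / ".build" / "report.html").exists()

        res = runner.invoke(main, ["build", str(proj_dir)])
        assert res.exit_code == 0, res.output
        assert "up to date" in res.output
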