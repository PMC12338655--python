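"""Project orchestration: parse the YAML config, build with staleness
detection, and export a static two-condition comparison report.

A *project* is a directory holding two comparable Hi-C contact files (control
and condition), optional tracks/annotations/bookmarks, and a ``project.yaml``
with the six sections ``workflow / project / datasets / tracks / annotations
/ bookmarks``.  Building reconstructs a 3D model per dataset and writes all
artifacts as plain text under ``.build/`` inside the project directory.

Structure reconstruction is the expensive step, so it is re-run only when the
content hash of the contact file or the simulation-relevant configuration
changes; editing tracks, annotations or bookmarks never triggers a
re-simulation.  Hashing content (not timestamps) keeps copied or archived
projects fresh.  Both datasets share one seed so they start from the same
initial coil and stay comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contactmap as cm
from . import metrics, simulator, tracks as tr
from .polymer import ForceFieldParams
from .simulator import SimulationConfig

__all__ = [
    "ProjectConfig",
    "DatasetSpec",
    "parse_project",
    "plan_build",
    "build",
    "export_report",
    "BuildResult",
]

logger = logging.getLogger("hicfold")

_KNOWN_SECTIONS = {"workflow", "project", "datasets", "tracks", "annotations", "bookmarks"}
_KNOWN_PROJECT_KEYS = {
    "name", "chromosome", "resolution", "count_threshold", "n_bins", "seed",
    "apply_kr", "allow_single", "simulation", "forcefield",
}


@dataclass
class DatasetSpec:
    name: str
    path: Path
    format: str = "coo-text"


@dataclass
class TrackSpec:
    name: str
    path: Path
    column_kind: str = "bin"
    units: str = ""


@dataclass
class AnnotationSpec:
    name: str
    path: Path
    format: str | None = None


@dataclass
class ProjectConfig:
    """Validated project configuration."""

    project_dir: Path
    workflow: dict
    name: str
    chromosome: str
    resolution: int
    count_threshold: float
    n_bins: int | None
    seed: int
    apply_kr: bool
    datasets: list[DatasetSpec]
    tracks: list[TrackSpec] = field(default_factory=list)
    annotations: list[AnnotationSpec] = field(default_factory=list)
    bookmarks: list[tr.Bookmark] = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    allow_single: bool = False


def parse_project(path) -> ProjectConfig:
    """Parse and validate a ``project.yaml``.

    Unknown keys warn but do not fail; missing referenced files fail at parse
    time; defaults are injected (count threshold 2.0, default simulation and
    force-field parameters).
    """
    path = Path(path)
    if path.is_dir():
        path = path / "project.yaml"
    raw = yaml.safe_load(path.read_text()) or {}
    project_dir = path.parent

    for key in raw:
        if key not in _KNOWN_SECTIONS:
            warnings.warn(f"unknown project.yaml section {key!r} ignored", stacklevel=2)

    proj = raw.get("project") or {}
    for key in proj:
        if key not in _KNOWN_PROJECT_KEYS:
            warnings.warn(f"unknown project setting {key!r} ignored", stacklevel=2)

    ds_raw = raw.get("datasets")
    if not ds_raw:
        raise ValueError("datasets required: project.yaml must define a datasets section")
    allow_single = bool(proj.get("allow_single", False))
    if len(ds_raw) != 2 and not (allow_single and len(ds_raw) == 1):
        raise ValueError(
            f"exactly two comparable datasets required (got {len(ds_raw)})"
        )

    def resolve(p) -> Path:
        fp = project_dir / p
        if not fp.exists():
            raise FileNotFoundError(f"referenced file not found: {fp}")
        return fp

    datasets = [
        DatasetSpec(
            name=str(d["name"]),
            path=resolve(d.get("data") or d.get("file")),
            format=str(d.get("format", "coo-text")),
        )
        for d in ds_raw
    ]
    track_specs = [
        TrackSpec(
            name=str(t["name"]),
            path=resolve(t["file"]),
            column_kind=str(t.get("columns", "bin")),
            units=str(t.get("units", "")),
        )
        for t in (raw.get("tracks") or [])
    ]
    ann_specs = [
        AnnotationSpec(
            name=str(a["name"]),
            path=resolve(a["file"]),
            format=a.get("format"),
        )
        for a in (raw.get("annotations") or [])
    ]
    bookmarks = []
    for b in raw.get("bookmarks") or []:
        bins = tuple(b["bins"]) if "bins" in b else None
        bookmarks.append(tr.Bookmark(name=str(b["name"]), bins=bins, feature=b.get("feature")))

    count_threshold = float(proj.get("count_threshold", 2.0))
    if count_threshold <= 0:
        raise ValueError("invalid threshold: count_threshold must be positive")

    sim_kwargs = dict(proj.get("simulation") or {})
    seed = int(proj.get("seed", 0))
    sim_kwargs.setdefault("seed", seed)
    ff_kwargs = dict(proj.get("forcefield") or {})

    return ProjectConfig(
        project_dir=project_dir,
        workflow=dict(raw.get("workflow") or {}),
        name=str(proj.get("name", project_dir.name)),
        chromosome=str(proj.get("chromosome", "chr")),
        resolution=int(proj.get("resolution", 200_000)),
        count_threshold=count_threshold,
        n_bins=int(proj["n_bins"]) if "n_bins" in proj else None,
        seed=seed,
        apply_kr=bool(proj.get("apply_kr", True)),
        datasets=datasets,
        tracks=track_specs,
        annotations=ann_specs,
        bookmarks=bookmarks,
        simulation=SimulationConfig(**sim_kwargs),
        forcefield=ForceFieldParams(**ff_kwargs),
        allow_single=allow_single,
    )


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _structure_fingerprint(config: ProjectConfig, ds: DatasetSpec) -> str:
    """Hash of everything a re-simulation would depend on."""
    payload = {
        "contact_sha256": _sha256_file(ds.path),
        "format": ds.format,
        "chromosome": config.chromosome,
        "resolution": config.resolution,
        "count_threshold": config.count_threshold,
        "n_bins": config.n_bins,
        "apply_kr": config.apply_kr,
        "simulation": asdict(config.simulation),
        "forcefield": asdict(config.forcefield),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _load_manifest(build_dir: Path) -> dict:
    manifest_path = build_dir / "manifest.json"
    if not manifest_path.exists():
        return {}
    try:
        return json.loads(manifest_path.read_text())
    except (json.JSONDecodeError, OSError):
        warnings.warn("corrupt build manifest; treating all structures as stale", stacklevel=2)
        return {}


def _write_manifest(build_dir: Path, manifest: dict) -> None:
    # temp-file + rename: an interrupted build never claims freshness
    tmp = build_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    os.replace(tmp, build_dir / "manifest.json")


def plan_build(config: ProjectConfig, build_dir) -> dict[str, bool]:
    """Per-dataset staleness: True means the structure must be re-simulated.

    A dataset is stale iff its structure fingerprint (contact-file content
    hash plus the simulation-relevant config subset) differs from the one in
    the build manifest, or its artifacts are missing.  Track/annotation/
    bookmark changes never mark a structure stale.
    """
    build_dir = Path(build_dir)
    manifest = _load_manifest(build_dir)
    plan: dict[str, bool] = {}
    for ds in config.datasets:
        entry = manifest.get("datasets", {}).get(ds.name, {})
        fingerprint = _structure_fingerprint(config, ds)
        fresh = (
            entry.get("fingerprint") == fingerprint
            and entry.get("error") is None
            and all((build_dir / a).exists() for a in entry.get("artifacts", []))
            and bool(entry.get("artifacts"))
        )
        plan[ds.name] = not fresh
    return plan


@dataclass
class BuildResult:
    build_dir: Path
    dataset_stale: dict[str, bool]
    steps_run: dict[str, int]
    errors: dict[str, str] = field(default_factory=dict)


def _build_dataset(config: ProjectConfig, ds: DatasetSpec, build_dir: Path) -> tuple[list[str], int]:
    matrix = cm.load_contacts(
        ds.path, format=ds.format, chromosome=config.chromosome,
        resolution=config.resolution, n_bins=config.n_bins,
    )
    bmap = cm.preprocess(matrix, config.count_threshold, balance=config.apply_kr)
    result = simulator.reconstruct(bmap, config.forcefield, config.simulation)

    artifacts: list[str] = []
    paths = simulator.write_structure_files(result.chain, build_dir / f"structure_{ds.name}")
    artifacts += [p.name for p in paths.values()]
    simulator.write_history_csv(result.history, build_dir / f"history_{ds.name}.csv")
    artifacts.append(f"history_{ds.name}.csv")
    cm.write_binary_map(
        bmap, build_dir / f"contacts_{ds.name}.csv", build_dir / f"unmappable_{ds.name}.txt"
    )
    artifacts += [f"contacts_{ds.name}.csv", f"unmappable_{ds.name}.txt"]

    total_steps = result.history[-1].step if result.history else 0
    metrics_payload = {
        "dataset": ds.name,
        "n_beads": result.chain.n_beads,
        "n_unmappable": int(np.count_nonzero(result.chain.unmappable)),
        "n_restraints": len(result.restraints),
        "satisfied_fraction": result.satisfied_fraction,
        "contact_satisfied_fraction": result.contact_satisfied_fraction,
        "bonded_fraction_at_gate": result.bonded_fraction_at_gate,
        "formation_end_step": result.formation_end_step,
        "termination_formation": result.termination_formation,
        "termination_production": result.termination_production,
        "final_pearson": None if math.isnan(result.final_pearson) else result.final_pearson,
        "seed": result.seed,
        "total_steps": total_steps,
    }
    (build_dir / f"metrics_{ds.name}.json").write_text(
        json.dumps(metrics_payload, sort_keys=True, indent=2) + "\n"
    )
    artifacts.append(f"metrics_{ds.name}.json")
    _plot_history(result.history, build_dir / f"history_{ds.name}.svg")
    artifacts.append(f"history_{ds.name}.svg")
    return artifacts, total_steps


def _plot_history(history, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = [h.step for h in history]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(steps, [h.bonded_fraction for h in history], label="bonded fraction")
    ax.plot(steps, [h.satisfied_fraction for h in history], label="satisfied fraction")
    pr = [(h.step, h.pearson_r) for h in history if not math.isnan(h.pearson_r)]
    if pr:
        ax.plot([s for s, _ in pr], [r for _, r in pr], label="Pearson r")
    ax.set_xlabel("step")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def build(config: ProjectConfig, build_dir=None, force: bool = False) -> BuildResult:
    """Build the project: simulate stale datasets, always re-fuse tracks.

    For each stale dataset: preprocessing -> reconstruction -> serialization
    (structure as PDB/XYZ/CSV, history, metrics, binary map).  Tracks,
    annotations and bookmarks are refreshed on every build — they are cheap
    and never require re-simulation.  A dataset whose stage fails is recorded
    in the manifest; the other dataset still builds.
    """
    build_dir = Path(build_dir) if build_dir is not None else config.project_dir / ".build"
    build_dir.mkdir(parents=True, exist_ok=True)
    plan = plan_build(config, build_dir) if not force else {d.name: True for d in config.datasets}
    manifest = _load_manifest(build_dir)
    manifest.setdefault("datasets", {})

    steps_run: dict[str, int] = {}
    errors: dict[str, str] = {}
    for ds in config.datasets:
        if not plan[ds.name]:
            logger.info("dataset %s: structure up to date, simulation skipped", ds.name)
            steps_run[ds.name] = 0
            continue
        logger.info("dataset %s: structure stale, running reconstruction", ds.name)
        try:
            artifacts, steps = _build_dataset(config, ds, build_dir)
        except Exception as exc:  # record and continue with the other dataset
            logger.error("dataset %s failed: %s", ds.name, exc)
            errors[ds.name] = str(exc)
            manifest["datasets"][ds.name] = {
                "fingerprint": None, "artifacts": [], "error": str(exc),
            }
            _write_manifest(build_dir, manifest)
            continue
        steps_run[ds.name] = steps
        manifest["datasets"][ds.name] = {
            "fingerprint": _structure_fingerprint(config, ds),
            "artifacts": artifacts,
            "error": None,
        }
        _write_manifest(build_dir, manifest)  # after artifacts: crash safe
    if not any(plan.values()):
        logger.info("structures up to date")

    _fuse_tracks(config, build_dir)
    _resolve_selections(config, build_dir)
    _write_manifest(build_dir, manifest)
    return BuildResult(build_dir, plan, steps_run, errors)


def _binning(config: ProjectConfig, n_bins: int) -> cm.GenomicBinning:
    return cm.GenomicBinning(config.chromosome, config.resolution, n_bins)


def _dataset_chain(build_dir: Path, name: str, binning=None):
    return simulator.read_structure_csv(build_dir / f"structure_{name}.csv", binning)


def _project_n_bins(config: ProjectConfig, build_dir: Path) -> int | None:
    if config.n_bins is not None:
        return config.n_bins
    for ds in config.datasets:
        p = build_dir / f"structure_{ds.name}.csv"
        if p.exists():
            return simulator.read_structure_csv(p).n_beads
    return None


def _fuse_tracks(config: ProjectConfig, build_dir: Path) -> None:
    n_bins = _project_n_bins(config, build_dir)
    if n_bins is None:
        return
    binning = _binning(config, n_bins)
    tdir = build_dir / "tracks"
    tdir.mkdir(exist_ok=True)
    for spec in config.tracks:
        track = tr.load_track_csv(
            spec.path, binning, column_kind=spec.column_kind, name=spec.name, units=spec.units
        )
        tr.write_track_csv(track, tdir / f"{spec.name}.csv")
        for ds in config.datasets:
            sp = build_dir / f"structure_{ds.name}.csv"
            if not sp.exists():
                continue
            chain = simulator.read_structure_csv(sp, binning)
            bead = tr.map_track_to_beads(track, chain)
            rows = ["bead,value,missing,unmappable"]
            for k in range(chain.n_beads):
                v = "" if bead.missing[k] else repr(float(bead.values[k]))
                rows.append(f"{k},{v},{int(bead.missing[k])},{int(bead.unmappable[k])}")
            (tdir / f"{spec.name}_{ds.name}.csv").write_text("\n".join(rows) + "\n")


def _resolve_selections(config: ProjectConfig, build_dir: Path) -> None:
    n_bins = _project_n_bins(config, build_dir)
    if n_bins is None:
        return
    binning = _binning(config, n_bins)
    annotations = [
        tr.load_annotation(a.path, binning, format=a.format, name=a.name)
        for a in config.annotations
    ]
    selections: dict[str, dict] = {}
    for ann in annotations:
        for iv in ann.intervals:
            b0, b1 = tr.interval_to_bead_range(iv, binning)
            selections[f"annotation:{ann.name}:{iv.label}"] = {
                "source": "annotation", "beads": [b0, b1],
                "bp": [iv.start, iv.end], "label": iv.label,
            }
    for bm in config.bookmarks:
        b0, b1 = tr.resolve_bookmark(bm, binning, annotations)
        selections[f"bookmark:{bm.name}"] = {
            "source": "bookmark", "beads": [b0, b1], "label": bm.name,
        }
    (build_dir / "selections.json").write_text(
        json.dumps(selections, sort_keys=True, indent=2) + "\n"
    )


def _range_rmsd(chain_a, chain_b, b0: int, b1: int) -> float | None:
    from .polymer import BeadChain

    if b1 - b0 < 3:
        return None
    sub_a = BeadChain(chain_a.positions[b0:b1], chain_a.unmappable[b0:b1])
    sub_b = BeadChain(chain_b.positions[b0:b1], chain_b.unmappable[b0:b1])
    try:
        return metrics.superpose_rmsd(sub_a, sub_b)
    except ValueError:
        return None


def export_report(config: ProjectConfig, build_dir=None) -> tuple[Path, Path]:
    """Write the static comparison report (JSON + HTML) for a completed build.

    Per dataset: bead counts, unmappable counts, restraint satisfaction and
    final map correlation.  Across the two conditions: whole-structure
    superposition RMSD and per-selection RMSD for every annotation feature
    and bookmark, plus per-track summary tables over bookmarked selections.
    """
    build_dir = Path(build_dir) if build_dir is not None else config.project_dir / ".build"
    missing = []
    per_dataset: dict[str, dict] = {}
    for ds in config.datasets:
        mp = build_dir / f"metrics_{ds.name}.json"
        sp = build_dir / f"structure_{ds.name}.csv"
        if not mp.exists() or not sp.exists():
            missing += [str(p.name) for p in (mp, sp) if not p.exists()]
            continue
        per_dataset[ds.name] = json.loads(mp.read_text())
    if missing:
        raise FileNotFoundError(f"incomplete build; missing artifacts: {', '.join(missing)}")

    report: dict = {"project": config.name, "seed": config.seed, "datasets": per_dataset}

    comparison: dict = {}
    if len(config.datasets) == 2:
        a, b = config.datasets
        n_bins = _project_n_bins(config, build_dir)
        binning = _binning(config, n_bins)
        chain_a = _dataset_chain(build_dir, a.name, binning)
        chain_b = _dataset_chain(build_dir, b.name, binning)
        comparison["overall_rmsd"] = metrics.superpose_rmsd(chain_a, chain_b)
        sel_path = build_dir / "selections.json"
        selections = json.loads(sel_path.read_text()) if sel_path.exists() else {}
        per_sel = {}
        for key, sel in selections.items():
            b0, b1 = sel["beads"]
            rmsd = _range_rmsd(chain_a, chain_b, b0, b1)
            per_sel[key] = {"beads": [b0, b1], "rmsd": rmsd}
        comparison["per_selection_rmsd"] = per_sel

        track_tables: dict = {}
        for spec in config.tracks:
            table = {}
            for ds in config.datasets:
                tp = build_dir / "tracks" / f"{spec.name}_{ds.name}.csv"
                if not tp.exists():
                    continue
                rows = tp.read_text().splitlines()[1:]
                vals = np.array([float(r.split(",")[1]) if r.split(",")[1] else np.nan
                                 for r in rows])
                sel_means = {}
                for key, sel in selections.items():
                    if sel.get("source") != "bookmark":
                        continue
                    b0, b1 = sel["beads"]
                    window = vals[b0:b1]
                    sel_means[key] = (None if np.all(np.isnan(window))
                                      else float(np.nanmean(window)))
                table[ds.name] = sel_means
            track_tables[spec.name] = table
        comparison["track_means_by_bookmark"] = track_tables
    report["comparison"] = comparison

    json_path = build_dir / "report.json"
    json_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    html_path = build_dir / "report.html"
    html_path.write_text(_render_html(report))
    return json_path, html_path


def _render_html(report: dict) -> str:
    def table(rows: list[tuple], headers: tuple) -> str:
        head = "".join(f"<th>{h}</th>" for h in headers)
        body = "".join(
            "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows
        )
        return f"<table border='1' cellpadding='4'><tr>{head}</tr>{body}</table>"

    ds_rows = [
        (name, m["n_beads"], m["n_unmappable"], m["n_restraints"],
         f"{m['satisfied_fraction']:.4f}",
         "" if m["final_pearson"] is None else f"{m['final_pearson']:.4f}")
        for name, m in sorted(report["datasets"].items())
    ]
    parts = [
        "<html><head><title>hicfold report</title></head><body>",
        f"<h1>Project: {report['project']}</h1>",
        f"<p>seed: {report['seed']}</p>",
        "<h2>Datasets</h2>",
        table(ds_rows, ("dataset", "beads", "unmappable", "restraints",
                        "satisfied fraction", "map Pearson r")),
    ]
    comp = report.get("comparison") or {}
    if "overall_rmsd" in comp:
        parts.append("<h2>Condition comparison</h2>")
        parts.append(f"<p>Overall superposition RMSD: {comp['overall_rmsd']:.4f}</p>")
        sel_rows = [
            (key, f"{v['beads'][0]}-{v['beads'][1]}",
             "" if v["rmsd"] is None else f"{v['rmsd']:.4f}")
            for key, v in sorted(comp.get("per_selection_rmsd", {}).items())
        ]
        parts.append(table(sel_rows, ("selection", "bead range", "RMSD")))
    parts.append("</body></html>")
    return "\n".join(parts)
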