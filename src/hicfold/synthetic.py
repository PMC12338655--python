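"""Synthetic ground truth: conformations, contact maps and whole projects.

Real chromosome-scale Hi-C inputs require accession downloads; this module
generates the study conditions instead.  A known 3D conformation is built
(helix, two compact domains, or a confined coil), its binary contact map is
derived with the same geometric rule the metrics use, optional Bernoulli
noise flips eligible cells, and a complete two-condition project directory
(contact files, arm/centromere track, GFF3 annotations, bookmarks, YAML) can
be written so that every pipeline stage runs end-to-end without downloads.

The two-condition default emulates a perturbation experiment: the control is
a two-domain conformation; the condition keeps domain A untouched and
compacts domain B, the kind of local compaction reported after chromatin-
modifying treatments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .contactmap import BinaryContactMap, GenomicBinning
from .metrics import contact_map_from_structure
from .polymer import BeadChain, init_self_avoiding_walk

__all__ = [
    "make_toy_conformation",
    "contacts_from_conformation",
    "make_synthetic_project",
]

_KINDS = ("helix", "two_domain", "confined_walk")


def _confined_walk(
    n: int,
    center: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    max_attempts: int = 2000,
) -> np.ndarray:
    """Unit-step random walk confined to a sphere (compact globule)."""
    pos = np.zeros((n, 3))
    pos[0] = center if start is None else start
    for k in range(1, n):
        for _ in range(max_attempts):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = pos[k - 1] + v
            if np.linalg.norm(cand - center) <= radius:
                pos[k] = cand
                break
        else:
            raise RuntimeError("confined walk could not stay inside the sphere")
    return pos


def make_toy_conformation(
    kind: str,
    n_beads: int,
    seed: int = 0,
    params: dict | None = None,
) -> BeadChain:
    """Build a ground-truth conformation with unit bond lengths.

    Kinds
    -----
    ``helix``
        Analytic helix; deterministic.  ``params``: ``radius`` (default 1.2),
        ``turn`` (radians per bead, default 0.4).
    ``two_domain``
        Two compact globules (confined unit-step walks) joined along the
        chain.  ``params``: ``split`` (first bead of domain B, default n/2),
        ``radius_a`` / ``radius_b`` (sphere radii; default ``0.8 * m**(1/3)``
        per domain size ``m``), ``gap`` (extra centre separation, default 2.0).
    ``confined_walk``
        Self-avoiding walk relaxed inside one sphere.  ``params``:
        ``radius`` (default ``1.0 * n**(1/3)``), ``min_separation`` (0.7).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown conformation kind {kind!r}; choose from {_KINDS}")
    if n_beads < 10:
        raise ValueError("n_beads must be at least 10")
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "helix":
        radius = p.get("radius", 1.2)
        turn = p.get("turn", 0.4)
        chord = 2.0 * radius * np.sin(turn / 2.0)
        if chord >= 1.0:
            raise ValueError("helix radius/turn give chord >= bond length")
        pitch = np.sqrt(1.0 - chord**2)
        k = np.arange(n_beads)
        pos = np.column_stack([
            radius * np.cos(k * turn),
            radius * np.sin(k * turn),
            k * pitch,
        ])
        return BeadChain(pos)

    if kind == "two_domain":
        split = int(p.get("split", n_beads // 2))
        if not (2 <= split <= n_beads - 2):
            raise ValueError("split must leave at least 2 beads per domain")
        ra = p.get("radius_a", 0.8 * split ** (1.0 / 3.0))
        rb = p.get("radius_b", 0.8 * (n_beads - split) ** (1.0 / 3.0))
        gap = p.get("gap", 2.0)
        center_a = np.zeros(3)
        center_b = np.array([ra + rb + gap, 0.0, 0.0])
        pos = np.zeros((n_beads, 3))
        pos[:split] = _confined_walk(split, center_a, ra, rng)
        # walk straight toward domain B's sphere, then fill it
        cur = pos[split - 1].copy()
        k = split
        while k < n_beads and np.linalg.norm(cur - center_b) > rb:
            direction = center_b - cur
            cur = cur + direction / np.linalg.norm(direction)
            pos[k] = cur
            k += 1
        if k < n_beads:
            pos[k:] = _confined_walk(n_beads - k + 1, center_b, rb, rng, start=cur)[1:]
        return BeadChain(pos)

    # confined_walk: SAW relaxed inside a sphere
    radius = p.get("radius", 1.0 * n_beads ** (1.0 / 3.0))
    min_sep = p.get("min_separation", 0.7)
    pos = np.zeros((n_beads, 3))
    for k in range(1, n_beads):
        for _ in range(2000):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = pos[k - 1] + v
            if np.linalg.norm(cand) > radius:
                continue
            if k >= 2:
                d2 = np.sum((pos[: k - 1] - cand) ** 2, axis=1)
                if np.min(d2) < min_sep**2:
                    continue
            pos[k] = cand
            break
        else:
            raise RuntimeError(
                "confined self-avoiding walk failed; increase radius or lower min_separation"
            )
    return BeadChain(pos)


def contacts_from_conformation(
    chain: BeadChain,
    r_contact: float = 2.0,
    noise_rate: float = 0.0,
    seed: int = 0,
    binning: GenomicBinning | None = None,
) -> BinaryContactMap:
    """Forward model: geometric contacts plus independent cell flips.

    With ``noise_rate`` 0 this is exactly
    :func:`hicfold.metrics.contact_map_from_structure`; otherwise every
    eligible cell (``i < j``, ``|i - j| >= 2``, both bins mappable) is flipped
    independently with probability ``noise_rate``.
    """
    if not (0.0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must be in [0, 0.5)")
    chain = chain.copy()
    if binning is None and chain.binning is None:
        chain.binning = GenomicBinning("synthetic", 200_000, chain.n_beads)
    elif binning is not None:
        chain.binning = binning
    bmap = contact_map_from_structure(chain, r_contact)
    if noise_rate == 0.0:
        return bmap
    rng = np.random.default_rng(seed)
    n = chain.n_beads
    iu, ju = np.triu_indices(n, k=2)
    keep = ~(chain.unmappable[iu] | chain.unmappable[ju])
    iu, ju = iu[keep], ju[keep]
    flip = rng.random(len(iu)) < noise_rate
    pairs = set(bmap.pairs)
    for i, j in zip(iu[flip], ju[flip]):
        key = (int(i), int(j))
        if key in pairs:
            pairs.remove(key)
        else:
            pairs.add(key)
    return BinaryContactMap(chain.binning, pairs, chain.unmappable.copy())


def _write_coo(bmap: BinaryContactMap, path: Path, chromosome: str, count: float = 10.0) -> None:
    lines = [f"# chrom: {chromosome}", "# bin_i bin_j count"]
    lines += [f"{i} {j} {count}" for i, j in sorted(bmap.pairs)]
    path.write_text("\n".join(lines) + "\n")


def make_synthetic_project(
    directory,
    n_beads: int = 100,
    seed: int = 0,
    resolution: int = 200_000,
    force: bool = False,
) -> Path:
    """Write a complete, immediately buildable two-condition project.

    The control contact file comes from a two-domain conformation; the
    condition compacts domain B (radius scaled by 0.7) while domain A is
    untouched.  Also written: an arm-coding track CSV (p arm = 1, q arm = -1,
    centromere bins = 0), a GFF3 with named domain features, bookmarks, and a
    ``project.yaml`` tying everything together.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} exists and is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    chromosome = "chrS"
    binning = GenomicBinning(chromosome, resolution, n_beads)
    split = n_beads // 2

    control = make_toy_conformation("two_domain", n_beads, seed=seed, params={"split": split})
    rb = 0.8 * (n_beads - split) ** (1.0 / 3.0)
    condition = make_toy_conformation(
        "two_domain", n_beads, seed=seed,
        params={"split": split, "radius_b": 0.7 * rb},
    )
    map_c = contacts_from_conformation(control, binning=binning)
    map_t = contacts_from_conformation(condition, binning=binning)
    _write_coo(map_c, directory / "control.coo.txt", chromosome)
    _write_coo(map_t, directory / "condition.coo.txt", chromosome)

    # p/q arm coding: p arm 1, q arm -1, two centromere-adjacent bins 0
    cen = {split - 1, split}
    rows = ["bin,value"]
    for k in range(n_beads):
        v = 0.0 if k in cen else (1.0 if k < split else -1.0)
        rows.append(f"{k},{v!r}")
    (directory / "arms.csv").write_text("\n".join(rows) + "\n")

    res = resolution
    gff = [
        "##gff-version 3",
        f"{chromosome}\thicfold\tregion\t1\t{split * res}\t.\t+\t.\tID=domainA;Name=domainA",
        f"{chromosome}\thicfold\tregion\t{split * res + 1}\t{n_beads * res}\t.\t+\t.\tID=domainB;Name=domainB",
        f"{chromosome}\thicfold\tcentromere\t{(split - 1) * res + 1}\t{(split + 1) * res}\t.\t.\t.\tID=cen;Name=centromere",
    ]
    (directory / "features.gff3").write_text("\n".join(gff) + "\n")

    yaml_text = f"""\
workflow:
  name: synthetic two-condition demo
  version: 1
project:
  name: synthetic
  chromosome: {chromosome}
  resolution: {resolution}
  count_threshold: 2.0
  n_bins: {n_beads}
  seed: {seed}
datasets:
  - name: control
    data: control.coo.txt
    format: coo-text
  - name: condition
    data: condition.coo.txt
    format: coo-text
tracks:
  - name: arms
    file: arms.csv
    columns: bin
annotations:
  - name: features
    file: features.gff3
    format: gff3
bookmarks:
  - name: domain A
    feature: domainA
  - name: domain B
    feature: domainB
  - name: first ten bins
    bins: [0, 10]
"""
    (directory / "project.yaml").write_text(yaml_text)
    return directory
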