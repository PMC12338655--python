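# hicfold

Reconstruct 3D chromosome models from Hi-C contact maps with restraint-driven
polymer dynamics, paint genomic tracks onto them, and compare two
experimental conditions side by side — all from a plain-text project
directory, on a laptop-class CPU.

`hicfold` is aimed at researchers who have per-chromosome Hi-C contact
matrices (plus optional ATAC-seq/ChIP-seq-style tracks and annotations) for
two comparable samples — control vs treatment, two time points, two alleles —
and want physically grounded 3D models of each condition and a quantitative
comparison between them, without a cluster or an external molecular-dynamics
engine.

## Method in brief

For one chromosome at one resolution, the balanced contact matrix
`A` (`D A D` with a common row sum, Sinkhorn-style) has its self-contact
diagonal removed and is binarized at a count threshold *t* (default 2.0):

    contact(i, j)  ⇔  A'_ij ≥ t,   |i − j| ≥ 2

Each contact becomes a *virtual Hi-C bond* between beads *i* and *j* of a
bead-spring chain (one bead per bin).  Starting from an open self-avoiding
coil, overdamped Langevin dynamics

    x ← x + (dt/γ) F + √(2 kT dt/γ) ξ,   ξ ~ N(0, 1)

fold the chain in two phases: *bond formation*, in which pending bonds exert
a constant pull and become permanent harmonic springs
`½ k_r (r − r0)²` once their pair first comes within the capture radius
`r_cap`, until over 80% of bonds have formed; then *production*, an annealed
quench during which convergence is monitored as the Pearson correlation
between the experimental binary map and the map recomputed from the model at
cutoff `r_contact`.  A WCA repulsion keeps the chain self-avoiding; bins with
no contact signal (centromeres, unmappable sequence) carry no restraints and
loop out of the folded model.  Final quality is reported as the restraint
*satisfaction fraction* — the share of virtual bonds within `r_cap` in the
final structure, ≥ 90% on the reference fixtures.

Everything is seeded and bit-reproducible; both conditions share one seed
(hence one initial coil) so their structures are comparable, and differences
are localized with whole-structure and per-region superposition RMSD
(Kabsch).

See `docs/methods.md` for the model, parameter defaults and their rationale,
and known limitations.

## Worked example

Create a ready-made synthetic two-condition project (a two-domain chromosome
vs a variant with a compacted second domain) and run the whole pipeline:

```sh
$ hicfold template --output demo
template project written to demo
$ hicfold run demo
INFO hicfold: dataset control: structure stale, running reconstruction
INFO hicfold: dataset condition: structure stale, running reconstruction
report: demo/.build/report.json
report: demo/.build/report.html
```

The run takes ~20 s and writes per-condition structures (PDB/XYZ/CSV),
trajectory histories, fused tracks and the comparison report under
`demo/.build/`.  From `report.json`:

```
control    sat=0.980  gate=0.811  pearson=0.749  restraints=954
condition  sat=0.945  gate=0.891  pearson=0.799  restraints=1263
overall RMSD 1.395   domainA RMSD 0.699   domainB RMSD 1.297
```

Reading these numbers: both models satisfy well over 90% of their Hi-C
restraints (`sat`), the bond-formation phase handed off to production above
the 80% gate (`gate`), and the maps recomputed from the models correlate
with the inputs (`pearson`).  The two conditions differ only in the second
domain by construction — and the per-region comparison localizes exactly
that: domain B moved almost twice as much (RMSD 1.30, in bead units) as the
untouched domain A (0.70).

Editing only tracks, annotations or bookmarks and re-running is nearly
instant: structures are cached by content hash and the log reports
`structures up to date`.

The same flow works on real data: point the `datasets` section of
`project.yaml` at per-chromosome contact files (COO text `bin_i bin_j count`
or dense CSV; convert `.hic` with standard tools), set `chromosome`,
`resolution` and `count_threshold` under `project`, and list tracks
(`.csv`), annotations (`.gff3`/`.csv`) and bookmarks as needed.

## Library use

```python
from hicfold import (load_contacts, preprocess, reconstruct,
                     SimulationConfig)

matrix = load_contacts("chr22.coo.txt", "coo-text", "chr22", 200_000)
bmap = preprocess(matrix, count_threshold=2.0)       # balance, de-diagonal, binarize
result = reconstruct(bmap, cfg=SimulationConfig(seed=1))
print(result.satisfied_fraction, result.final_pearson)
```

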