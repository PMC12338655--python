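# Methods

## Overview

`hicfold` reconstructs a 3D model of a single chromosome from a Hi-C contact
map and compares two experimental conditions side by side.  The method treats
the chromosome as a coarse-grained bead-spring polymer — one bead per genomic
bin — and folds an initially open coil under harmonic restraints derived from
the thresholded contact map, using overdamped Langevin dynamics.  Model
quality is judged by the fraction of restraints satisfied in the final
structure and by the Pearson correlation between the experimental binary map
and the map recomputed from the model.

## Preprocessing

Contact records for one chromosome at one resolution (COO text or dense CSV)
are assembled into a symmetric matrix.  Coverage bias is removed by matrix
balancing: a positive diagonal scaling `D` is found so that every non-zero
row of `D A D` sums to a common constant, computed by symmetric alternating
(Sinkhorn-style) scaling.  All-zero rows are skipped.  The target row sum
defaults to the mean non-zero row sum of the input rather than 1, so balanced
entries stay on the original count scale and the count threshold keeps its
meaning; a unit target is available as a parameter.  Balancing fails with an
explicit error when the matrix lacks total support (a genuinely unbalanceable
pattern), which does not arise for ordinary Hi-C matrices.

The self-contact diagonal is zeroed, bins whose entire row is zero are
flagged *unmappable* (centromeres and other unsequenceable regions), and the
matrix is binarized: cell `(i, j)` becomes a contact iff its balanced count
is at least the count threshold (default 2.0, configurable per project).
Unmappable bins carry no contacts and therefore no restraints; in the folded
model they simply loop out, held only by the backbone, and are excluded from
superpositions and map comparisons.

## Model and force field

Reduced units: backbone bond length `b = 1`, thermal energy `kT = 1`.
The potential energy is

* backbone: `½ k_bb (r − b)²` between consecutive beads, `k_bb = 100`;
* virtual Hi-C bonds: `½ k_r (r − r0)²` for each *formed* restraint,
  `k_r = 50`, `r0 = 1.2` (an optional flat-bottom variant applies the spring
  only when stretched beyond `r0`);
* pending restraints: a linear potential `f_p · r` (`f_p = 5`), i.e. a
  constant-magnitude pull directing the pair to meet regardless of distance —
  this guarantees monotone progress toward the formation gate without the
  long-range blow-ups a harmonic term would cause;
* excluded volume: purely repulsive truncated-shifted Lennard-Jones (WCA)
  between all pairs at chain distance ≥ 2, diameter `σ = 0.8`, strength
  `ε = 1`; backbone neighbours are bonded and exempt.

Forces are exact negative gradients (verified against central differences in
the tests); each bead's total force is then capped at `f_max = 50` as a
stability guard.  The cap bounds every integration step, so the dynamics
cannot overflow; a non-finite state can only enter through corrupted input
and is rejected with an explicit error.

### Why `σ = 0.8` and `r_cap = r_contact = 2.0`

A restraint counts as satisfied when its bead pair lies within the capture
radius `r_cap`; the same radius converts a pending restraint into a formed
bond.  We set `r_cap` equal to the contact cutoff `r_contact = 2` used when
deriving maps from structures: a constraint is satisfied exactly when the
pair would register as a contact by the criterion that defined it.  With a
capture radius *below* the contact cutoff, a dense contact map is
geometrically unsatisfiable — a bead with ~20 restrained partners cannot hold
them all closer than the packing of unit hard cores allows — and measured
satisfaction saturated near 50–80% no matter the protocol.  Likewise the
excluded-volume diameter is set below the bond length (`σ = 0.8 b`): a
bead-per-bin polymer grossly overstates the incompressibility of chromatin at
hundreds of kilobases per bead, and a full-diameter core caps the achievable
contact density below what real maps demand.  These two choices were
calibrated once on the synthetic fixtures and are ordinary config parameters.

## Two-phase protocol

1. **Initialization.**  A self-avoiding random walk grows the open coil:
   consecutive beads at distance exactly `b`, all other pairs at least
   `min_separation = 0.8` apart, reproducible per seed.
2. **Bond formation.**  Overdamped Langevin dynamics
   (`x ← x + (dt/γ)F + √(2 kT dt/γ) ξ`, `dt = 0.005`, `γ = 1`) run at
   `kT = 1` while pending restraints pull their pairs together; a pair first
   reaching `r_cap` forms a permanent harmonic bond (bonds never break, so
   the bonded fraction is monotone).  The phase ends when the bonded fraction
   reaches the gate (default 80%) or the step budget (20 000) is exhausted.
3. **Production.**  Dynamics continue as an annealed quench: temperature
   ramps linearly from 1 to 0 over the first 60% of the production budget
   (10 000 steps), then stays at the final temperature.  Every 250 steps the
   contact map implied by the structure is correlated (Pearson r over
   eligible cells) with the experimental map; the run stops when r fails to
   improve for 8 consecutive checks — counted only once cooling has finished,
   since convergence cannot be judged mid-quench — and the best-correlating
   snapshot is kept.  Pending restraints may still capture during production.

Constant-temperature production at `kT = 1` was measurably worse (final
satisfaction 0.79–0.85 versus 0.95+ with the quench): thermal agitation keeps
stretching formed bonds past the capture radius, and the structure never
settles into the energy minimum the restraint network defines.

All randomness flows from a single seeded generator; the same map, parameters
and seed reproduce the output bit for bit.

## Validation metrics

* **Satisfaction fraction**: share of restraints within `r_cap` in a given
  frame; an empty restraint set is vacuously satisfied (1.0).  Reported both
  by capture-radius distance and by recomputed-contact membership (identical
  when `r_cap = r_contact`).
* **Map Pearson r**: binary indicators over eligible cells (`i < j`,
  `|i − j| ≥ 2`, both bins mappable in both maps); undefined (None) when
  either vector is constant.  Adjacent cells are excluded because the
  backbone makes them contacts trivially.
* **Superposition RMSD**: least-squares rigid fit (Kabsch, SVD) with proper
  rotations only by default; a flag admits improper rotations so mirror
  images can be recognized.  Unmappable beads are excluded from the fit.

## Synthetic ground truth

Because chromosome-scale inputs require accession downloads, the package
generates its own study conditions.  `two_domain` builds two compact globules
(unit-step random walks confined to spheres of radius `0.8 m^(1/3)` for `m`
beads) joined along the chain — a minimal caricature of two interacting
compartments; `helix` and `confined_walk` cover regular and homogeneous
geometries.  The forward model derives the binary map geometrically at
`r_contact` and optionally flips each eligible cell independently with a
given noise rate.  The standard fixture is the noise-free 200-bead two-domain
map; reconstruction from it reaches ≥ 90% restraint satisfaction and
distance-matrix Spearman ≥ 0.9, and recovery degrades monotonically as map
noise grows.

What this does **not** show about real data: synthetic maps are noise-free
(or Bernoulli-noised) and geometrically self-consistent, with no
distance-dependent contact decay, no coverage bias for balancing to remove,
and domain structure far cleaner than real compartments.  Passing these
fixtures demonstrates that the pipeline solves the inverse problem it poses,
not that any particular biological conclusion follows from a real map.

The synthetic two-condition project emulates a perturbation experiment:
control versus a variant whose second domain is compacted (radius × 0.7),
with an arm-coding track (p = 1, q = −1, centromere = 0), GFF3 domain
features and bookmarks.

## Projects, builds and reports

A project directory holds two comparable contact files, optional tracks
(CSV, bin- or bp-keyed, sub-bin rows aggregated by mean by default),
annotations (GFF3 1-based closed, converted once at ingestion, or CSV
0-based half-open) and bookmarks; `project.yaml` ties them together with the
sections `workflow / project / datasets / tracks / annotations / bookmarks`.
Builds write plain-text artifacts (PDB/XYZ/CSV structures, history CSV,
metrics JSON, fused tracks, report) under `.build/`.

Structure reconstruction re-runs only when the *content hash* of the contact
file or the simulation-relevant config subset changes — never on track,
annotation or bookmark edits.  Hashing content instead of timestamps keeps
copied or archived projects fresh.  The manifest is written after the
artifacts it describes (temp file + atomic rename), so an interrupted build
cannot claim freshness for a structure that was never written.  Both
datasets share one seed and therefore one initial coil, keeping the two
conditions comparable; the report includes whole-structure and per-selection
superposition RMSD between them.

## Numerical choices and limitations

* Step budgets (20 000 formation / 10 000 production) and the fixture sizes
  used in tests (40–200 beads) are calibrated so a full two-condition build
  completes in seconds to tens of seconds on one CPU core; larger chromosomes
  scale near-quadratically in bead count (the all-pairs excluded-volume term
  dominates) and are insensitive to the number of contacts.
* Balancing tolerance 1e-6, maximum 5000 iterations; Pearson improvement
  threshold 1e-12; degenerate geometry guards (`r ≥ 1e-12`) in all force
  terms.
* Single chromosome per run; no trans contacts, no time-resolved morphing
  between conditions, no thermostat varieties.
* The binary `.hic` format is not read directly; convert with standard tools
  to COO text first.
* The reconstruction is a single representative conformation, not an
  ensemble; restraint satisfaction near 100% on a noisy map indicates
  overfitting to noise, which is why map noise degrades recovery smoothly
  rather than failing loudly.
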