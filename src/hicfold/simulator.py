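"""Two-phase restraint-driven folding of the bead chain.

Phase 1 (*bond formation*): the chain starts as an open self-avoiding coil;
pending virtual Hi-C bonds pull their bead pairs together under overdamped
Langevin dynamics, and each pair that first comes within the capture radius
forms a permanent harmonic bond.  The phase ends once the bonded fraction
reaches the gate (default 80%) or the step budget runs out.

Phase 2 (*production*): dynamics continue with the formed harmonic bonds;
every ``check_interval`` steps a contact map is derived from the current
structure and correlated (Pearson r) with the experimental map.  The run
stops when r stops improving for ``convergence_patience`` consecutive checks
or the budget is exhausted; the best-correlating snapshot is retained.

The integrator is position (overdamped) Langevin:
``x <- x + (dt / gamma) F + sqrt(2 kT dt / gamma) N(0, 1)`` per coordinate,
driven by a single seeded generator so every run is reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contactmap import BinaryContactMap
from .metrics import contact_map_from_structure, map_pearson, satisfaction_fraction
from .polymer import (
    BeadChain,
    ForceFieldParams,
    NumericalBlowupError,
    RestraintSet,
    forces_and_energy,
    init_self_avoiding_walk,
    restraints_from_map,
)

__all__ = [
    "SimulationConfig",
    "CheckRecord",
    "SimulationResult",
    "step_dynamics",
    "run_bond_formation",
    "run_production",
    "reconstruct",
    "write_structure_files",
    "read_structure_csv",
    "write_history_csv",
]


@dataclass
class SimulationConfig:
    """Protocol parameters (reduced units; kT enters only via the noise).

    Formation runs at constant ``temperature``; production is an annealed
    quench — temperature ramps linearly from ``temperature`` to
    ``temperature_final`` (default 0) over the first ``anneal_fraction`` of
    the production budget, then stays at the final temperature while the
    Pearson-r plateau is monitored.  Convergence is only ever declared at the
    target temperature: the patience counter is frozen while still cooling.
    """

    dt: float = 0.005
    gamma: float = 1.0
    temperature: float = 1.0
    temperature_final: float = 0.0
    anneal_fraction: float = 0.6
    seed: int = 0
    gate_fraction: float = 0.80
    max_steps_formation: int = 20000
    max_steps_production: int = 10000
    check_interval: int = 250
    convergence_patience: int = 8
    saw_min_separation: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.gate_fraction <= 1):
            raise ValueError("gate_fraction must be in (0, 1]")
        if self.dt <= 0 or self.gamma <= 0:
            raise ValueError("dt and gamma must be positive")
        if self.temperature < 0 or self.temperature_final < 0:
            raise ValueError("temperatures must be non-negative")
        if self.max_steps_formation < 0 or self.max_steps_production < 0:
            raise ValueError("step budgets must be non-negative")
        if self.check_interval < 1:
            raise ValueError("check_interval must be positive")
        if not (0.0 <= self.anneal_fraction <= 1.0):
            raise ValueError("anneal_fraction must be in [0, 1]")


@dataclass
class CheckRecord:
    """One metric evaluation along the trajectory."""

    step: int
    phase: str  # "formation" | "production"
    bonded_fraction: float
    satisfied_fraction: float
    pearson_r: float  # NaN when not evaluated / undefined


@dataclass
class SimulationResult:
    """Outcome of a full reconstruction run."""

    chain: BeadChain
    restraints: RestraintSet
    history: list[CheckRecord]
    formation_end_step: int | None
    termination_formation: str
    termination_production: str
    seed: int
    satisfied_fraction: float          # capture-radius distance on final frame
    contact_satisfied_fraction: float  # restrained pairs recovered at r_contact
    bonded_fraction_at_gate: float | None
    final_pearson: float               # NaN if undefined
    params: ForceFieldParams = field(default_factory=ForceFieldParams)
    config: SimulationConfig = field(default_factory=SimulationConfig)


def step_dynamics(
    chain: BeadChain,
    restraints: RestraintSet,
    params: ForceFieldParams,
    cfg: SimulationConfig,
    n_steps: int,
    rng: np.random.Generator | None = None,
) -> BeadChain:
    """Advance the chain ``n_steps`` of overdamped Langevin dynamics."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = chain.copy()
    x = out.positions
    mobility = cfg.dt / cfg.gamma
    amp = math.sqrt(2.0 * cfg.temperature * cfg.dt / cfg.gamma)
    for s in range(n_steps):
        _, F = forces_and_energy(out, restraints, params, cap=True)
        x += mobility * F
        if amp > 0:
            x += amp * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)):
            raise NumericalBlowupError(
                f"numerical blow-up at step {s + 1}: try a smaller dt"
            )
    return out


def _capture(chain: BeadChain, restraints: RestraintSet, r_cap: float) -> None:
    """Flip pending restraints within the capture radius to bonded (permanent)."""
    if len(restraints) == 0:
        return
    pend = ~restraints.bonded
    if not np.any(pend):
        return
    d = np.linalg.norm(
        chain.positions[restraints.j[pend]] - chain.positions[restraints.i[pend]], axis=1
    )
    flip = np.nonzero(pend)[0][d <= r_cap]
    restraints.bonded[flip] = True


def run_bond_formation(
    chain: BeadChain,
    restraints: RestraintSet,
    params: ForceFieldParams,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    start_step: int = 0,
) -> tuple[BeadChain, list[CheckRecord], str]:
    """Directed bond formation up to the gate fraction.

    Returns the evolved chain, the per-check history and a termination reason
    (``"gate_reached"`` or ``"max_steps_formation"``).  Restraint states are
    updated in place; the bonded fraction can only grow.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    history: list[CheckRecord] = []

    def record(step: int) -> None:
        history.append(CheckRecord(
            step=step,
            phase="formation",
            bonded_fraction=restraints.bonded_fraction,
            satisfied_fraction=satisfaction_fraction(chain, restraints, params.r_cap),
            pearson_r=float("nan"),
        ))

    _capture(chain, restraints, params.r_cap)
    record(start_step)
    steps_done = 0
    while restraints.bonded_fraction < cfg.gate_fraction and steps_done < cfg.max_steps_formation:
        k = min(cfg.check_interval, cfg.max_steps_formation - steps_done)
        chain = step_dynamics(chain, restraints, params, cfg, k, rng)
        steps_done += k
        _capture(chain, restraints, params.r_cap)
        record(start_step + steps_done)
    reason = "gate_reached" if restraints.bonded_fraction >= cfg.gate_fraction else "max_steps_formation"
    return chain, history, reason


def run_production(
    chain: BeadChain,
    restraints: RestraintSet,
    params: ForceFieldParams,
    cfg: SimulationConfig,
    experimental_map: BinaryContactMap,
    rng: np.random.Generator | None = None,
    start_step: int = 0,
) -> tuple[BeadChain, list[CheckRecord], str]:
    """Production dynamics with Pearson-r convergence monitoring.

    Temperature is annealed linearly from ``cfg.temperature`` to
    ``cfg.temperature_final`` over the production budget.  Every
    ``check_interval`` steps the simulated contact map is correlated with the
    experimental one; the run stops on a patience-based plateau or when the
    step budget is exhausted.  The snapshot with the best Pearson r is
    returned.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    history: list[CheckRecord] = []

    def evaluate(step: int) -> float:
        sim_map = contact_map_from_structure(chain, params.r_contact)
        r = map_pearson(sim_map, experimental_map)
        r_val = float("nan") if r is None else r
        history.append(CheckRecord(
            step=step,
            phase="production",
            bonded_fraction=restraints.bonded_fraction,
            satisfied_fraction=satisfaction_fraction(chain, restraints, params.r_cap),
            pearson_r=r_val,
        ))
        return r_val

    best_r = evaluate(start_step)
    best_chain = chain.copy()
    patience = 0
    steps_done = 0
    reason = "max_steps_production"
    anneal_steps = cfg.anneal_fraction * cfg.max_steps_production
    while steps_done < cfg.max_steps_production:
        k = min(cfg.check_interval, cfg.max_steps_production - steps_done)
        frac = 1.0 if anneal_steps == 0 else min(1.0, steps_done / anneal_steps)
        temp = cfg.temperature + frac * (cfg.temperature_final - cfg.temperature)
        chunk_cfg = dataclasses.replace(cfg, temperature=temp)
        chain = step_dynamics(chain, restraints, params, chunk_cfg, k, rng)
        steps_done += k
        _capture(chain, restraints, params.r_cap)
        r = evaluate(start_step + steps_done)
        improved = (not math.isnan(r)) and (math.isnan(best_r) or r > best_r + 1e-12)
        if improved:
            best_r, best_chain, patience = r, chain.copy(), 0
        elif frac >= 1.0:  # plateau only counts once cooling has finished
            patience += 1
            if patience >= cfg.convergence_patience:
                reason = "pearson_plateau"
                break
    return best_chain, history, reason


def reconstruct(
    bmap: BinaryContactMap,
    params: ForceFieldParams | None = None,
    cfg: SimulationConfig | None = None,
) -> SimulationResult:
    """Full reconstruction: open coil -> directed bond formation -> production.

    The initial configuration is a self-avoiding random walk; thresholded
    contacts become pending virtual Hi-C bonds; the two-phase protocol folds
    the chain.  Fully reproducible given (map, params, cfg.seed).
    """
    params = params or ForceFieldParams()
    cfg = cfg or SimulationConfig()
    n = bmap.binning.n_bins

    try:
        chain = init_self_avoiding_walk(
            n, b=params.b, min_separation=cfg.saw_min_separation, seed=cfg.seed
        )
        chain.unmappable = bmap.unmappable.copy()
        chain.binning = bmap.binning
        restraints = restraints_from_map(bmap, params)
        rng = np.random.default_rng(cfg.seed)
    except Exception as exc:
        raise _StageError(f"stage 'initialization': {exc}") from exc

    try:
        chain, hist_f, reason_f = run_bond_formation(chain, restraints, params, cfg, rng)
    except Exception as exc:
        raise _StageError(f"stage 'bond_formation': {exc}") from exc
    formation_end = hist_f[-1].step if hist_f else None
    bonded_at_gate = hist_f[-1].bonded_fraction if hist_f else None

    try:
        chain, hist_p, reason_p = run_production(
            chain, restraints, params, cfg, bmap, rng,
            start_step=formation_end or 0,
        )
    except Exception as exc:
        raise _StageError(f"stage 'production': {exc}") from exc

    final_sat = satisfaction_fraction(chain, restraints, params.r_cap)
    sim_map = contact_map_from_structure(chain, params.r_contact)
    if len(restraints):
        pairs = set(zip(restraints.i.tolist(), restraints.j.tolist()))
        contact_sat = len(pairs & sim_map.pairs) / len(pairs)
    else:
        contact_sat = 1.0
    r_final = map_pearson(sim_map, bmap)
    return SimulationResult(
        chain=chain,
        restraints=restraints,
        history=hist_f + hist_p,
        formation_end_step=formation_end,
        termination_formation=reason_f,
        termination_production=reason_p,
        seed=cfg.seed,
        satisfied_fraction=final_sat,
        contact_satisfied_fraction=float(contact_sat),
        bonded_fraction_at_gate=bonded_at_gate,
        final_pearson=float("nan") if r_final is None else r_final,
        params=params,
        config=cfg,
    )


class _StageError(RuntimeError):
    """Stage-annotated reconstruction failure."""


def write_structure_files(chain: BeadChain, prefix) -> dict[str, Path]:
    """Export a structure as PDB (CA trace, chain A), XYZ and CSV.

    PDB residue numbers are ``bin index + 1``; the CSV carries
    ``bead,x,y,z,unmappable`` rows and round-trips coordinates exactly.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = chain.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = chain.positions.astype(np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_path = prefix.with_suffix(".pdb")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(pdb_path))

    xyz_path = prefix.with_suffix(".xyz")
    lines = [str(n), "bead chain"]
    lines += [f"C {x:.6f} {y:.6f} {z:.6f}" for x, y, z in chain.positions]
    xyz_path.write_text("\n".join(lines) + "\n")

    csv_path = prefix.with_suffix(".csv")
    rows = ["bead,x,y,z,unmappable"]
    rows += [
        f"{k},{float(x)!r},{float(y)!r},{float(z)!r},{int(u)}"
        for k, ((x, y, z), u) in enumerate(zip(chain.positions, chain.unmappable))
    ]
    csv_path.write_text("\n".join(rows) + "\n")
    return {"pdb": pdb_path, "xyz": xyz_path, "csv": csv_path}


def read_structure_csv(path, binning=None) -> BeadChain:
    """Load a chain from the ``bead,x,y,z,unmappable`` CSV export."""
    lines = Path(path).read_text().splitlines()[1:]
    pos, unmap = [], []
    for line in lines:
        if not line.strip():
            continue
        _, x, y, z, u = line.split(",")
        pos.append((float(x), float(y), float(z)))
        unmap.append(bool(int(u)))
    return BeadChain(np.array(pos), np.array(unmap, dtype=bool), binning)


def write_history_csv(history: list[CheckRecord], path) -> Path:
    """Per-check trajectory metrics as CSV."""
    path = Path(path)
    rows = ["step,phase,bonded_fraction,satisfied_fraction,pearson_r"]
    for rec in history:
        r = "" if math.isnan(rec.pearson_r) else repr(rec.pearson_r)
        rows.append(
            f"{rec.step},{rec.phase},{rec.bonded_fraction!r},{rec.satisfied_fraction!r},{r}"
        )
    path.write_text("\n".join(rows) + "\n")
    return path
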