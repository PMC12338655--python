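"""Quantitative validation of reconstructed structures.

The reconstruction is judged the way the experiment speaks: derive a binary
contact map from the 3D model at a distance cutoff and correlate it, cell by
cell, with the experimental binary map (Pearson r over the eligible
off-diagonal cells).  Constraint satisfaction — the share of virtual Hi-C
bonds whose bead pair sits within the capture radius — is the headline
quality number.  Rigid superposition (Kabsch) supports two-condition
structure comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .contactmap import BinaryContactMap
from .polymer import BeadChain, RestraintSet

__all__ = [
    "contact_map_from_structure",
    "satisfaction_fraction",
    "map_pearson",
    "superpose_rmsd",
]


def contact_map_from_structure(chain: BeadChain, r_contact: float) -> BinaryContactMap:
    """Simulated contact map: pairs with |i - j| >= 2 within ``r_contact``.

    Unmappable beads (looped-out regions) are excluded, mirroring the
    experimental map they will be compared against.
    """
    if chain.binning is None:
        raise ValueError("chain has no binning reference")
    x = chain.positions
    n = len(x)
    d = squareform(pdist(x))
    idx = np.arange(n)
    eligible = (np.abs(idx[:, None] - idx[None, :]) >= 2) & (d <= r_contact)
    eligible &= ~(chain.unmappable[:, None] | chain.unmappable[None, :])
    iu, ju = np.nonzero(np.triu(eligible, k=2))
    pairs = {(int(i), int(j)) for i, j in zip(iu, ju)}
    return BinaryContactMap(chain.binning, pairs, chain.unmappable.copy())


def satisfaction_fraction(chain: BeadChain, restraints: RestraintSet, r_cap: float) -> float:
    """Fraction of restraints whose bead pair lies within the capture radius.

    By convention an empty restraint set is vacuously fully satisfied (1.0).
    """
    if len(restraints) == 0:
        return 1.0
    d = np.linalg.norm(chain.positions[restraints.j] - chain.positions[restraints.i], axis=1)
    return float(np.mean(d <= r_cap))


def _eligible_cells(map_a: BinaryContactMap, map_b: BinaryContactMap) -> tuple[np.ndarray, np.ndarray]:
    n = map_a.binning.n_bins
    bad = map_a.unmappable | map_b.unmappable
    iu, ju = np.triu_indices(n, k=2)
    keep = ~(bad[iu] | bad[ju])
    return iu[keep], ju[keep]


def map_pearson(map_a: BinaryContactMap, map_b: BinaryContactMap) -> float | None:
    """Pearson r between two binary maps over their eligible cells.

    Cells with ``i < j``, ``|i - j| >= 2`` and both bins mappable in both maps
    enter as 0/1 indicators.  Returns ``None`` when either indicator vector is
    constant (correlation undefined).
    """
    if (map_a.binning.n_bins != map_b.binning.n_bins
            or map_a.binning.resolution != map_b.binning.resolution):
        raise ValueError("incompatible maps: binnings differ")
    iu, ju = _eligible_cells(map_a, map_b)
    if len(iu) == 0:
        return None

    def indicator(m: BinaryContactMap) -> np.ndarray:
        dense = np.zeros((m.binning.n_bins,) * 2, dtype=bool)
        arr = m.pair_array()
        if len(arr):
            dense[arr[:, 0], arr[:, 1]] = True
        return dense[iu, ju].astype(float)

    a, b = indicator(map_a), indicator(map_b)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    am, bm = a - a.mean(), b - b.mean()
    return float(np.dot(am, bm) / np.sqrt(np.dot(am, am) * np.dot(bm, bm)))


def superpose_rmsd(
    chain_a: BeadChain,
    chain_b: BeadChain,
    allow_reflection: bool = False,
    include_unmappable: bool = False,
) -> float:
    """RMSD after least-squares rigid superposition (Kabsch).

    By default only proper rotations are allowed, so a mirror image keeps a
    positive RMSD; ``allow_reflection=True`` also permits improper rotations.
    Unmappable (looped-out) beads are excluded from the fit by default since
    their positions are unconstrained by data.
    """
    if chain_a.n_beads != chain_b.n_beads:
        raise ValueError("incomparable structures: bead counts differ")
    if include_unmappable:
        sel = np.ones(chain_a.n_beads, dtype=bool)
    else:
        sel = ~(chain_a.unmappable | chain_b.unmappable)
    if np.count_nonzero(sel) < 3:
        raise ValueError("incomparable structures: fewer than 3 mappable beads")
    A = chain_a.positions[sel] - chain_a.positions[sel].mean(axis=0)
    B = chain_b.positions[sel] - chain_b.positions[sel].mean(axis=0)
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    if det < 0 and not allow_reflection:
        U = U.copy()
        U[:, -1] *= -1.0  # force a proper rotation
    R = U @ Vt
    diff = B @ R - A
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
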