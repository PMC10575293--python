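"""Lattice agent-based model of cell activity on the 50 um grid.

Each lattice site holds at most one cell (MSC, fibroblast, chondrocyte or
osteoblast) and one tissue label (granulation, fibrous, cartilage, bone).
Cells live only inside the healing region (callus + scaffold pores + the
marrow seeding band).  One iteration represents one healing day and applies,
in this fixed order: MSC migration (7 single-site jumps), proliferation,
mechanoregulated MSC differentiation, tissue deposition, apoptosis.

Stochastic sub-steps are vectorized synchronous rounds: every eligible cell
draws its event from one shared generator, and conflicting claims on the same
target site are resolved by a fresh random priority permutation (losers
forfeit the event, matching the "failed jumps are forfeited" rule).  All
randomness flows through one ``numpy.random.Generator``, so a fixed seed
gives bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ossify.config import Cell, KineticsTable, RegulationParams, Tissue
from ossify.geometry import DomainModel
from ossify.mechanoregulation import TissueOutcome, classify

#: face-neighbor offsets (6-connectivity)
NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

_OUTCOME_TO_CELL = {
    TissueOutcome.BONE: Cell.OSTEOBLAST,
    TissueOutcome.CARTILAGE: Cell.CHONDROCYTE,
    TissueOutcome.FIBROUS: Cell.FIBROBLAST,
}

_CELL_TO_TISSUE = {
    Cell.OSTEOBLAST: Tissue.BONE,
    Cell.CHONDROCYTE: Tissue.CARTILAGE,
    Cell.FIBROBLAST: Tissue.FIBROUS,
}


@dataclass
class CellLattice:
    """Cell occupancy + tissue state on the full voxel grid.

    ``occupancy`` uses the fixed integer codes (empty=0, MSC=1, osteoblast=2,
    chondrocyte=3, fibroblast=4); ``tissue`` the codes granulation=0,
    fibrous=1, cartilage=2, bone=3.  ``resorb_flag`` marks sites whose formed
    bone is scheduled for removal at the next deposition step.
    """

    spacing: float
    occupancy: np.ndarray  # uint8
    tissue: np.ndarray  # uint8
    healing_mask: np.ndarray  # bool
    resorb_flag: np.ndarray  # bool

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def site_volume(self) -> float:
        """Volume of one lattice site in mm^3 (1.25e-4 at 50 um)."""
        return self.spacing**3

    def copy(self) -> "CellLattice":
        return CellLattice(
            spacing=self.spacing,
            occupancy=self.occupancy.copy(),
            tissue=self.tissue.copy(),
            healing_mask=self.healing_mask,
            resorb_flag=self.resorb_flag.copy(),
        )

    def cell_positions(self, code: int | None = None) -> np.ndarray:
        """(N, 3) integer positions of cells (of one type, or any)."""
        if code is None:
            mask = self.occupancy != Cell.EMPTY
        else:
            mask = self.occupancy == code
        return np.argwhere(mask)

    def cell_counts(self) -> dict[str, int]:
        return {c.name: int(np.sum(self.occupancy == c)) for c in Cell if c != Cell.EMPTY}

    def tissue_counts(self) -> dict[str, int]:
        m = self.healing_mask
        return {t.name: int(np.sum(self.tissue[m] == t)) for t in Tissue}

    def check_invariants(self) -> None:
        occupied = self.occupancy != Cell.EMPTY
        if np.any(occupied & ~self.healing_mask):
            raise AssertionError("cells found outside the healing region")


def seed_initial(
    domain: DomainModel, fraction: float = 0.3, rng: np.random.Generator | int | None = 0
) -> CellLattice:
    """Granulation-filled healing region with MSCs on the seeding masks.

    Exactly ``round(fraction * |marrow_seed ∪ periosteum|)`` MSCs are placed
    by sampling sites without replacement, giving reproducible counts at
    small mask sizes.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("seeding fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    healing = domain.region_masks["healing"]
    seed_mask = domain.region_masks["marrow_seed"] | domain.region_masks["periosteum"]
    seed_mask = seed_mask & healing
    if not seed_mask.any():
        raise ValueError("MSC seeding masks are empty")

    occupancy = np.zeros(domain.dims, dtype=np.uint8)
    tissue = np.zeros(domain.dims, dtype=np.uint8)  # granulation everywhere
    flat = np.flatnonzero(seed_mask)
    n = int(round(fraction * flat.size))
    if n > 0:
        chosen = rng.choice(flat, size=n, replace=False)
        occupancy.reshape(-1)[chosen] = Cell.MSC
    return CellLattice(
        spacing=domain.spacing,
        occupancy=occupancy,
        tissue=tissue,
        healing_mask=healing,
        resorb_flag=np.zeros(domain.dims, dtype=bool),
    )


def _flat(pos: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    return np.ravel_multi_index((pos[:, 0], pos[:, 1], pos[:, 2]), dims)


def _in_bounds(pos: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    return np.all((pos >= 0) & (pos < np.asarray(dims)), axis=1)


def _claim_targets(order: np.ndarray, targets_flat: np.ndarray) -> np.ndarray:
    """Resolve conflicting claims: first in ``order`` wins each target.

    Returns indices (into the candidate arrays) of the winners.
    """
    t_ord = targets_flat[order]
    _, first = np.unique(t_ord, return_index=True)
    return order[first]


def migrate(
    lattice: CellLattice, rng: np.random.Generator, jumps: int = 7
) -> CellLattice:
    """Random-walk migration of MSCs: ``jumps`` single-site face jumps/day.

    Each jump picks one of the six face neighbors uniformly and succeeds only
    if the target lies in the healing region and is empty; blocked or
    conflicting jumps are forfeited.  Only MSCs migrate.
    """
    dims = lattice.dims
    occ = lattice.occupancy
    pos = lattice.cell_positions(Cell.MSC)
    if pos.size == 0:
        return lattice
    heal_flat = lattice.healing_mask.reshape(-1)
    occ_flat = occ.reshape(-1)
    n = len(pos)
    for _ in range(jumps):
        dirs = rng.integers(0, 6, size=n)
        cand = pos + NEIGHBOR_OFFSETS[dirs]
        ok = _in_bounds(cand, dims)
        tflat = np.zeros(n, dtype=np.int64)
        tflat[ok] = _flat(cand[ok], dims)
        ok &= heal_flat[tflat] & (occ_flat[tflat] == Cell.EMPTY)
        order = rng.permutation(n)
        order = order[ok[order]]
        if order.size == 0:
            continue
        winners = _claim_targets(order, tflat)
        src = _flat(pos[winners], dims)
        occ_flat[src] = Cell.EMPTY
        occ_flat[tflat[winners]] = Cell.MSC
        pos[winners] = cand[winners]
    return lattice


def _empty_neighbors(lattice: CellLattice, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(M,6) emptiness mask and (M,6) flat neighbor ids (invalid -> -1)."""
    dims = lattice.dims
    nb = pos[:, None, :] + NEIGHBOR_OFFSETS[None, :, :]  # (M,6,3)
    flatshape = nb.shape[:2]
    ok = np.all((nb >= 0) & (nb < np.asarray(dims)), axis=2)
    nflat = np.full(flatshape, -1, dtype=np.int64)
    nb_ok = nb[ok]
    nflat[ok] = np.ravel_multi_index((nb_ok[:, 0], nb_ok[:, 1], nb_ok[:, 2]), dims)
    occ_flat = lattice.occupancy.reshape(-1)
    heal_flat = lattice.healing_mask.reshape(-1)
    empty = ok.copy()
    empty[ok] = heal_flat[nflat[ok]] & (occ_flat[nflat[ok]] == Cell.EMPTY)
    return empty, nflat


def proliferate(
    lattice: CellLattice,
    kinetics: KineticsTable,
    day: int,
    rng: np.random.Generator,
) -> CellLattice:
    """Daily cell division into a uniformly chosen empty face neighbor.

    Each cell divides with its phenotype's daily probability (baseline during
    the latency period, reduced afterwards); cells with no empty neighbor in
    the healing region do not divide; conflicting daughter placements are
    resolved by random priority and losers forfeit.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    pos = lattice.cell_positions()
    if pos.size == 0:
        return lattice
    codes = lattice.occupancy[pos[:, 0], pos[:, 1], pos[:, 2]]
    rate_lut = np.zeros(5)
    for c in (Cell.MSC, Cell.OSTEOBLAST, Cell.CHONDROCYTE, Cell.FIBROBLAST):
        rate_lut[c] = kinetics.proliferation_rate(c, day)
    divide = rng.random(len(pos)) < rate_lut[codes]
    if not divide.any():
        return lattice
    p_div = pos[divide]
    c_div = codes[divide]
    empty, nflat = _empty_neighbors(lattice, p_div)
    counts = empty.sum(axis=1)
    u = rng.random(len(p_div))
    has = counts > 0
    if not has.any():
        return lattice
    j = np.floor(u[has] * counts[has]).astype(np.int64)
    cum = np.cumsum(empty[has], axis=1)
    sel = (cum > j[:, None]).argmax(axis=1)
    targets = nflat[np.flatnonzero(has), sel]
    order = rng.permutation(len(targets))
    winners = _claim_targets(order, targets)
    occ_flat = lattice.occupancy.reshape(-1)
    occ_flat[targets[winners]] = c_div[has][winners]
    return lattice


def differentiate(
    lattice: CellLattice,
    site_stimulus: np.ndarray | None,
    kinetics: KineticsTable,
    day: int,
    rng: np.random.Generator,
    regulation: RegulationParams | None = None,
) -> CellLattice:
    """Mechanoregulated MSC differentiation.

    Each MSC differentiates with the daily probability (0.3 during latency,
    0.06 after); the target phenotype follows the stimulus classification at
    its site (bone -> osteoblast, cartilage -> chondrocyte, fibrous ->
    fibroblast).  A resorption outcome leaves the MSC unchanged but flags the
    site so formed bone there is removed at deposition.  Differentiated cells
    never revert.
    """
    regulation = regulation or RegulationParams()
    pos = lattice.cell_positions(Cell.MSC)
    if pos.size == 0:
        return lattice
    if site_stimulus is None:
        raise ValueError("stimulus field is required for differentiation")
    S = site_stimulus[pos[:, 0], pos[:, 1], pos[:, 2]]
    if not np.all(np.isfinite(S)):
        raise ValueError("stimulus missing (non-finite) at occupied healing sites")
    prob = kinetics.differentiation_rate(Cell.MSC, day)
    triggered = rng.random(len(pos)) < prob
    if not triggered.any():
        return lattice
    outcomes = classify(S[triggered], regulation)
    p_t = pos[triggered]
    for outc, cell in _OUTCOME_TO_CELL.items():
        m = outcomes == outc
        lattice.occupancy[p_t[m, 0], p_t[m, 1], p_t[m, 2]] = cell
    m = outcomes == TissueOutcome.RESORPTION
    lattice.resorb_flag[p_t[m, 0], p_t[m, 1], p_t[m, 2]] = True
    return lattice


def apoptose(
    lattice: CellLattice, kinetics: KineticsTable, rng: np.random.Generator
) -> CellLattice:
    """Daily apoptosis at phenotype-specific rates; deposited tissue persists."""
    pos = lattice.cell_positions()
    if pos.size == 0:
        return lattice
    codes = lattice.occupancy[pos[:, 0], pos[:, 1], pos[:, 2]]
    rate_lut = np.zeros(5)
    for c in (Cell.MSC, Cell.OSTEOBLAST, Cell.CHONDROCYTE, Cell.FIBROBLAST):
        rate_lut[c] = kinetics.by_cell(c).apoptosis
    dies = rng.random(len(pos)) < rate_lut[codes]
    p_d = pos[dies]
    lattice.occupancy[p_d[:, 0], p_d[:, 1], p_d[:, 2]] = Cell.EMPTY
    return lattice


def deposit_tissue(lattice: CellLattice) -> CellLattice:
    """Write tissue labels under differentiated cells; apply resorption.

    Osteoblast/chondrocyte/fibroblast sites set their tissue label to bone/
    cartilage/fibrous; sites flagged for resorption revert formed bone to
    granulation.  Flags are consumed.
    """
    for cell, tis in _CELL_TO_TISSUE.items():
        lattice.tissue[lattice.occupancy == cell] = tis
    resorb = lattice.resorb_flag & (lattice.tissue == Tissue.BONE)
    lattice.tissue[resorb] = Tissue.GRANULATION
    lattice.resorb_flag[:] = False
    return lattice


def daily_step(
    lattice: CellLattice,
    site_stimulus: np.ndarray,
    kinetics: KineticsTable,
    day: int,
    rng: np.random.Generator,
    regulation: RegulationParams | None = None,
) -> CellLattice:
    """One healing day: migrate -> proliferate -> differentiate -> deposit -> apoptose."""
    migrate(lattice, rng, jumps=kinetics.jumps_per_day)
    proliferate(lattice, kinetics, day, rng)
    differentiate(lattice, site_stimulus, kinetics, day, rng, regulation)
    deposit_tissue(lattice)
    apoptose(lattice, kinetics, rng)
    return lattice
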