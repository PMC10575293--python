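"""Mechanoregulation: stimulus, tissue-outcome classification, material update.

The local mechanical stimulus is

    S = |gamma| / a + |p| / b,        a = 0.0375, b = 0.003,

with gamma the minimal principal strain and p the hydrostatic stress (MPa,
compression positive).  Magnitudes are used so S >= 0 regardless of the sign
conventions upstream.  Note the constant b descends from a stimulus theory
formulated on interstitial fluid velocity (units mm/s); it is applied here
literally to a stress in MPa — see docs/methods.md for the discussion.

S intervals map to tissue outcomes (low to high): resorption of formed bone,
bone, cartilage, fibrous tissue.  Boundary values belong to the lower
interval.  Every ``update_period`` (3) daily iterations, the finite-element
material field is refreshed from the lattice tissue composition using the
average stimulus of the previous three iterations.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from ossify.config import Phase, RegulationParams, Tissue

__all__ = ["TissueOutcome", "stimulus", "classify", "material_update"]


class TissueOutcome(IntEnum):
    RESORPTION = 0
    BONE = 1
    CARTILAGE = 2
    FIBROUS = 3


def stimulus(gamma, p, params: RegulationParams | None = None):
    """Mechanoregulatory stimulus S = |gamma|/a + |p|/b (dimensionless)."""
    params = params or RegulationParams()
    gamma = np.asarray(gamma, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(p))):
        raise ValueError("stimulus inputs must be finite")
    S = np.abs(gamma) / params.a + np.abs(p) / params.b
    return S if S.ndim else float(S)


def classify(S, params: RegulationParams | None = None):
    """Map stimulus values to tissue outcomes (piecewise-constant, total).

    S < resorption_max -> RESORPTION; S <= bone_max -> BONE;
    S <= cartilage_max -> CARTILAGE; else FIBROUS.  Negative S violates the
    magnitude convention and raises.
    """
    params = params or RegulationParams()
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stimulus must be non-negative (magnitude convention)")
    out = np.full(S.shape, TissueOutcome.FIBROUS, dtype=np.int64)
    out[S <= params.cartilage_max] = TissueOutcome.CARTILAGE
    out[S <= params.bone_max] = TissueOutcome.BONE
    out[S < params.resorption_max] = TissueOutcome.RESORPTION
    return out if out.ndim else TissueOutcome(int(out))


def average_stimulus(stimulus_history: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of the last three per-element stimulus fields."""
    if len(stimulus_history) < 3:
        raise ValueError("need three days of stimulus history for the update")
    return np.mean(np.stack(stimulus_history[-3:]), axis=0)


def material_update(
    lattice,
    stimulus_history: list[np.ndarray],
    materials,
    day: int,
    params: RegulationParams | None = None,
    final: bool = False,
):
    """Refresh the voxel material field from the lattice tissue composition.

    Healing-region voxels take the material of their current tissue label
    (granulation / fibrous / cartilage from the material table, newly formed
    bone at ``params.new_bone_modulus``); voxels outside the healing region
    keep their prior values, so the finite-element block averaging realizes
    the volume-weighted mixture over each element's member sites.  The update
    is idempotent for a fixed lattice.  Returns (MaterialField, mean 3-day
    stimulus per element).
    """
    from ossify.config import TISSUE_MATERIALS
    from ossify.fem import MaterialField

    params = params or RegulationParams()
    if day % params.update_period != 0 and not final:
        raise ValueError(
            f"material update scheduled every {params.update_period} iterations; "
            f"day {day} is not a multiple"
        )
    avg_S = average_stimulus(stimulus_history)

    E = materials.E.copy()
    nu = materials.nu.copy()
    mask = lattice.healing_mask
    tissue_table = dict(TISSUE_MATERIALS)
    tissue_table[Tissue.BONE] = (params.new_bone_modulus, params.new_bone_poisson)
    for t, (e, n) in tissue_table.items():
        m = mask & (lattice.tissue == t)
        E[m] = e
        nu[m] = n
    return MaterialField(E=E, nu=nu), avg_S
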