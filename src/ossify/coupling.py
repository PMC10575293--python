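"""Day-by-day coupling of the FE mechanics and the cell lattice.

One iteration is one healing day.  The stimulus field from the most recent FE
solve is broadcast to the lattice and drives MSC differentiation every day;
every ``update_period`` (3) iterations — and once more at the configured
final day if it is not itself an update day — the FE material field is
refreshed from the lattice tissue composition using the 3-day average
stimulus and the mechanics are re-solved.  The loop therefore performs
ceil(total_days / update_period) + 1 FE solves (the initial one plus one per
update).  Runs are bit-reproducible for a fixed seed, and a run stopped at
day d and resumed from its checkpoint reproduces the uninterrupted run
bit-exactly.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ossify import abm, fem, mechanoregulation as mreg, report
from ossify.config import SCAFFOLD_MATERIALS, SimConfig
from ossify.geometry import (
    DomainModel,
    build_domain,
    make_miniature_scaffold_spec,
    make_scaffold_spec,
    miniature_geometry_params,
)

log = logging.getLogger(__name__)


@dataclass
class HealingHistory:
    """Per-day tissue volumes (mm^3) and run metadata."""

    seed: int
    days: list[int] = field(default_factory=list)
    bone_mm3: list[float] = field(default_factory=list)
    cartilage_mm3: list[float] = field(default_factory=list)
    fibrous_mm3: list[float] = field(default_factory=list)
    stimulus_summaries: list[dict] = field(default_factory=list)
    snapshot_paths: list[str] = field(default_factory=list)
    n_fe_solves: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "bone_mm3": self.bone_mm3,
                "cartilage_mm3": self.cartilage_mm3,
                "fibrous_mm3": self.fibrous_mm3,
            }
        )

    def weekly(self, weeks=(4, 8, 12, 16)) -> dict[int, dict[str, float]]:
        """Volumes at the weekly reporting days (28/56/84/112 by default)."""
        out = {}
        for w in weeks:
            d = 7 * w
            if d in self.days:
                i = self.days.index(d)
                out[w] = {
                    "bone_mm3": self.bone_mm3[i],
                    "cartilage_mm3": self.cartilage_mm3[i],
                    "fibrous_mm3": self.fibrous_mm3[i],
                }
        return out


def build_config_domain(config: SimConfig) -> DomainModel:
    """Domain for a configuration (full-size or miniature)."""
    if config.miniature:
        spec = make_miniature_scaffold_spec(config.design_id)
        params = miniature_geometry_params()
    else:
        spec = make_scaffold_spec(config.design_id, length=config.scaffold_length)
        params = None
    return build_domain(
        spec,
        spacing=config.spacing,
        params=params,
        memory_budget_voxels=config.memory_budget_voxels,
    )


def _scaffold_material(config: SimConfig) -> tuple[float, float]:
    key = str(config.design_id).upper().replace("MINI_", "")
    return SCAFFOLD_MATERIALS.get(key, (1000.0, 0.3))


def _solve_stimulus(config, domain, materials, x0=None):
    system = fem.assemble_system(domain, materials, coarsening=config.fe_coarsening)
    disp = fem.solve_displacements(system, config.load_case, tol=config.solver_tol, x0=x0)
    stim = fem.element_fields(system, disp)
    stim.S = mreg.stimulus(stim.gamma, stim.p, config.regulation)
    site_S = stim.site_values("S", domain.dims)
    return disp, stim, site_S


class _RunState:
    """Mutable full simulation state (checkpointable)."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.day = 0
        self.rng = np.random.default_rng(config.seed)
        self.domain = build_config_domain(config)
        self.materials = fem.materials_from_phase(self.domain, _scaffold_material(config))
        self.lattice = abm.seed_initial(self.domain, config.seeding_fraction, self.rng)
        self.history = HealingHistory(seed=config.seed)
        self.disp, self.stim, self.site_S = _solve_stimulus(config, self.domain, self.materials)
        self.history.n_fe_solves = 1
        self.stim_history: list[np.ndarray] = []

    def checkpoint(self, path: str | Path) -> None:
        state = {
            "config": self.config.to_dict(),
            "day": self.day,
            "rng_state": self.rng.bit_generator.state,
            "occupancy": self.lattice.occupancy,
            "tissue": self.lattice.tissue,
            "resorb_flag": self.lattice.resorb_flag,
            "materials_E": self.materials.E,
            "materials_nu": self.materials.nu,
            "stim_history": self.stim_history,
            "stim": self.stim,
            "site_S": self.site_S,
            "disp_u": self.disp.u,
            "history": self.history,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def restore(cls, path: str | Path) -> "_RunState":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        config = SimConfig.from_dict(state["config"])
        obj = cls.__new__(cls)
        obj.config = config
        obj.day = state["day"]
        obj.rng = np.random.default_rng(config.seed)
        obj.rng.bit_generator.state = state["rng_state"]
        obj.domain = build_config_domain(config)
        obj.materials = fem.MaterialField(E=state["materials_E"], nu=state["materials_nu"])
        obj.lattice = abm.CellLattice(
            spacing=config.spacing,
            occupancy=state["occupancy"],
            tissue=state["tissue"],
            healing_mask=obj.domain.region_masks["healing"],
            resorb_flag=state["resorb_flag"],
        )
        obj.stim_history = state["stim_history"]
        obj.stim = state["stim"]
        obj.site_S = state["site_S"]
        obj.disp = fem.DisplacementField(
            u=state["disp_u"],
            fixed_dofs=np.empty(0, dtype=np.int64),
            residual=0.0,
            residual_history=[],
        )
        obj.history = state["history"]
        return obj


def run_simulation(
    config: SimConfig | None = None,
    resume_from: str | Path | None = None,
    stop_after: int | None = None,
    checkpoint_path: str | Path | None = None,
) -> HealingHistory:
    """Run (or resume) one coupled healing simulation.

    Day 0 initializes the granulation fill, the MSC seeding, and the first FE
    solve; days 1..total_days apply the ABM sub-steps with the current
    stimulus and refresh the FE materials on the update schedule.  With
    ``stop_after=d`` the loop stops after day d (writing ``checkpoint_path``
    if given); ``resume_from`` continues such a run bit-exactly to the
    configured horizon.
    """
    if resume_from is not None:
        state = _RunState.restore(resume_from)
        config = state.config
    else:
        if config is None:
            raise ValueError("either config or resume_from is required")
        config.validate()
        state = _RunState(config)
    horizon = config.total_days
    target = horizon if stop_after is None else min(stop_after, horizon)

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    period = config.regulation.update_period
    while state.day < target:
        state.day += 1
        day = state.day
        try:
            abm.daily_step(
                state.lattice, state.site_S, config.kinetics, day, state.rng,
                config.regulation,
            )
            state.lattice.check_invariants()
        except Exception as exc:  # dump state for post-mortem per contract
            if outdir:
                state.checkpoint(outdir / f"crash_day{day:03d}.ckpt")
            raise RuntimeError(f"simulation aborted at day {day}: {exc}") from exc

        state.stim_history.append(state.stim.S)
        state.stim_history = state.stim_history[-3:]

        vols = report.tissue_volumes(state.lattice)
        state.history.days.append(day)
        state.history.bone_mm3.append(vols["bone_mm3"])
        state.history.cartilage_mm3.append(vols["cartilage_mm3"])
        state.history.fibrous_mm3.append(vols["fibrous_mm3"])
        log.info(
            "day %d: bone %.4f cartilage %.4f fibrous %.4f mm^3",
            day, vols["bone_mm3"], vols["cartilage_mm3"], vols["fibrous_mm3"],
        )

        if outdir:
            snap = outdir / f"day_{day:03d}.csv"
            report.write_day_csv(state.lattice, snap)
            state.history.snapshot_paths.append(str(snap))

        # material update: every `period` days, plus once at the configured
        # horizon if it is not an update day (the schedule is a property of
        # the run horizon, so stopping early never adds an extra update)
        if day % period == 0 or day == horizon:
            hist3 = (
                state.stim_history
                if len(state.stim_history) >= 3
                else state.stim_history * 3
            )
            state.materials, avg_S = mreg.material_update(
                state.lattice, hist3, state.materials, day, config.regulation,
                final=(day == horizon),
            )
            act = state.stim.active
            state.history.stimulus_summaries.append(
                {
                    "day": day,
                    "mean_S": float(np.mean(avg_S[act])),
                    "max_S": float(np.max(avg_S[act])),
                }
            )
            state.disp, state.stim, state.site_S = _solve_stimulus(
                config, state.domain, state.materials, x0=state.disp.flat
            )
            state.history.n_fe_solves += 1

        if config.checkpoint_every and outdir and day % config.checkpoint_every == 0:
            state.checkpoint(outdir / f"checkpoint_day{day:03d}.ckpt")

    if checkpoint_path is not None:
        state.checkpoint(checkpoint_path)
    return state.history


def replicate_runs(config: SimConfig, n_seeds: int) -> list[HealingHistory]:
    """Independent replicates with seeds config.seed + 0..n_seeds-1."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    out = []
    for i in range(n_seeds):
        cfg = SimConfig.from_dict(config.to_dict())
        cfg.seed = config.seed + i
        out.append(run_simulation(cfg))
    return out
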