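"""Energy minimization and Langevin dynamics.

The integrator is BAOAB splitting, which stays accurate for configurational
averages at the high friction used here (50 ps^-1, matching the collision
frequency of water) and reduces exactly to velocity Verlet at zero friction.
Thermal noise is drawn in blocks from a seeded generator, so a given
(system, parameters, seed) reproduces the same trajectory bit-for-bit on one
platform.

Run protocols mirror the three experiment levels: an isolated Nup runs a
single 100 ns trajectory; ring and whole-NPC systems are clash-minimized,
relaxed for 100 ns, then run for 900 ns of production.  Every duration
scales by a single factor so the same protocol runs at desk scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import KB
from .forcefield import ForceField, ForceFieldParams
from .system import System


@dataclass
class SimulationParams:
    timestep: float = 0.02           # ps
    friction: float = 50.0           # ps^-1
    temperature: float = 300.0       # K
    n_steps: int = 10000
    sampling_interval: int = 100     # steps between saved frames
    seed: int = 0
    # minimization protocol
    min_max_iter: int = 2000
    min_force_tol: float = 10.0      # kJ/mol/nm
    min_max_disp: float = 0.02       # nm, displacement cap per step
    # relaxation stage of the ring/NPC protocol, run at reduced temperature
    relax_temperature_factor: float = 1.0 / 3.0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered bead coordinates plus run metadata."""

    frames: np.ndarray               # (F, N, 3) nm
    times: np.ndarray                # (F,) ps
    params: SimulationParams
    seed: int
    system_hash: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.attrs["seed"] = self.seed
            f.attrs["system_hash"] = self.system_hash
            f.attrs["timestep"] = self.params.timestep
            f.attrs["friction"] = self.params.friction
            f.attrs["temperature"] = self.params.temperature
            f.attrs["sampling_interval"] = self.params.sampling_interval

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            params = SimulationParams(
                timestep=float(f.attrs["timestep"]),
                friction=float(f.attrs["friction"]),
                temperature=float(f.attrs["temperature"]),
                sampling_interval=int(f.attrs["sampling_interval"]),
            )
            return cls(
                frames=f["frames"][...],
                times=f["times"][...],
                params=params,
                seed=int(f.attrs["seed"]),
                system_hash=str(f.attrs["system_hash"]),
            )

    def save_pdb(self, path, stride: int = 1) -> None:
        """Multi-model PDB with one pseudo-atom per bead (coordinates in Å)."""
        with open(path, "w") as fh:
            for m, frame in enumerate(self.frames[::stride], start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for i, (x, y, z) in enumerate(frame * 10.0, start=1):
                    serial = i % 100000
                    fh.write(
                        f"ATOM  {serial:5d}  CA  GLY A{i % 10000:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")


def system_hash(system: System) -> str:
    h = hashlib.sha256()
    for arr in (system.positions, system.masses, system.charges,
                system.hydrophobicity, system.chain_id,
                system.fixed.astype(np.uint8)):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def minimize(
    system: System,
    ff_params: ForceFieldParams | None = None,
    params: SimulationParams | None = None,
    return_trace: bool = False,
):
    """Three-stage clash removal by displacement-capped steepest descent.

    Stage 1 relaxes bonds + excluded volume (+ scaffold) only, stage 2 adds
    bending/torsion, stage 3 the full potential.  Accepted steps never
    increase the energy; the step size adapts (halved on uphill trials).
    """
    ff_params = ff_params or ForceFieldParams()
    params = params or SimulationParams()
    ff = ForceField(system, ff_params)
    pos = system.positions.copy()
    free = ~system.fixed
    trace: list[np.ndarray] = []
    stages = [
        dict(do_angles=False, do_att=False, do_elec=False),
        dict(do_angles=True, do_att=False, do_elec=False),
        dict(do_angles=True, do_att=True, do_elec=True),
    ]
    for si, masks in enumerate(stages):
        energy, forces = ff.energy_forces(pos, **masks)
        if si == 0 and not np.isfinite(energy):
            raise ValueError("non-finite energy in stage 1: pathological build")
        alpha = 1e-4
        stage_trace: list[float] = []
        trace.append(stage_trace)
        for _ in range(params.min_max_iter):
            forces[~free] = 0.0
            fmax = np.max(np.abs(forces)) if len(forces) else 0.0
            stage_trace.append(energy)
            if fmax < params.min_force_tol:
                break
            step = alpha * forces
            norms = np.linalg.norm(step, axis=1, keepdims=True)
            over = norms[:, 0] > params.min_max_disp
            if np.any(over):
                step[over] *= params.min_max_disp / norms[over]
            trial = pos + step
            e_new, f_new = ff.energy_forces(trial, **masks)
            if e_new <= energy and np.isfinite(e_new):
                pos, energy, forces = trial, e_new, f_new
                alpha = min(alpha * 1.2, 1e-2)
            else:
                alpha = max(alpha * 0.5, 1e-8)
    out = system.copy()
    out.positions = pos
    if return_trace:
        return out, [np.array(t) for t in trace]
    return out


def run_langevin(
    system: System,
    ff_params: ForceFieldParams | None = None,
    params: SimulationParams | None = None,
    velocities: np.ndarray | None = None,
    block_size: int = 2000,
) -> Trajectory:
    """BAOAB Langevin dynamics at the set temperature and friction.

    The trajectory contains the initial frame plus every
    ``sampling_interval``-th step: ``floor(n_steps / interval) + 1`` frames.
    Tethered beads never move.  ``meta['kinetic_per_bead']`` records the
    time-averaged kinetic energy per free bead (kJ/mol).
    """
    ff_params = ff_params or ForceFieldParams()
    params = params or SimulationParams()
    ff = ForceField(system, ff_params)
    n = system.n_beads
    dt, gamma = params.timestep, params.friction
    kT = KB * params.temperature
    rng = np.random.default_rng(params.seed)

    pos = system.positions.copy()
    inv_mass = np.where(system.fixed, 0.0, 1.0 / system.masses)
    if velocities is None:
        vel = rng.standard_normal((n, 3)) * np.sqrt(kT * inv_mass)[:, None]
    else:
        vel = velocities.copy()
        vel[system.fixed] = 0.0

    n_save = params.n_steps // params.sampling_interval + 1
    frames = np.empty((n_save, n, 3))
    frames[0] = pos
    save_idx = 1

    pi, pj, npairs, ci, cj, ncoul = ff.build_pair_list(pos)
    ref_pos = pos.copy()
    _, forces = ff.energy_forces(pos, pairs=(pi, pj, npairs, ci, cj, ncoul))

    ke_sum, ke_count = 0.0, 0
    step = 0
    while step < params.n_steps:
        nb = min(block_size, params.n_steps - step)
        noise = rng.standard_normal((nb, n, 3))
        while True:
            saved = (pos.copy(), vel.copy(), forces.copy(), npairs, ncoul,
                     ref_pos.copy(), save_idx)
            (status, npairs, ncoul, save_idx, ks, kc,
             err_step) = _kernels.baoab_block(
                pos, vel, inv_mass, forces, noise, dt, gamma, kT,
                pi, pj, npairs, ci, cj, ncoul, ref_pos, ff_params.skin,
                ff.cutoff_vdw_list, ff.cutoff_coul_list, ff.charged,
                system.chain_id, ff_params.exclusion_depth,
                frames, save_idx, params.sampling_interval, step,
                *ff._bonded_args, *ff._nonbonded_args,
                True, True, True,
            )
            if status == 0:
                ke_sum += ks
                ke_count += kc
                break
            pos, vel, forces, npairs, ncoul, ref_pos, save_idx = saved
            pos, vel, forces, ref_pos = (pos.copy(), vel.copy(),
                                         forces.copy(), ref_pos.copy())
            if status == 1:  # pair storage overflow: grow and redo the block
                ff._cap_vdw *= 2
                ff._cap_coul *= 2
                pi, pj, npairs, ci, cj, ncoul = ff.build_pair_list(pos)
                ref_pos = pos.copy()
            else:
                raise FloatingPointError(
                    f"non-finite coordinates at step {err_step}: "
                    "timestep too large or unresolved clash"
                )
        step += nb

    n_free = int(np.sum(~system.fixed))
    times = np.arange(n_save) * params.sampling_interval * dt
    return Trajectory(
        frames=frames,
        times=times,
        params=params,
        seed=params.seed,
        system_hash=system_hash(system),
        meta={
            "kinetic_per_bead": ke_sum / (ke_count * n_free) if ke_count else 0.0,
            "final_velocities": vel,
        },
    )


#: Nominal stage durations in ns at scale 1, per experiment level.
PROTOCOL_STAGES = {
    "individual": (("production", 100.0),),
    "ring": (("relaxation", 100.0), ("production", 900.0)),
    "npc": (("relaxation", 100.0), ("production", 900.0)),
}


def protocol_plan(
    protocol: str, params: SimulationParams, scale: float = 1.0
) -> dict:
    """Stage durations (ns) and step counts for a protocol at a given scale."""
    if protocol not in PROTOCOL_STAGES:
        raise ValueError(f"unknown protocol {protocol!r}")
    stages = []
    for name, ns in PROTOCOL_STAGES[protocol]:
        duration = ns * scale
        stages.append(
            {
                "stage": name,
                "duration_ns": duration,
                "n_steps": int(round(duration * 1000.0 / params.timestep)),
            }
        )
    return {"protocol": protocol, "scale": scale, "stages": stages,
            "minimize": protocol in ("ring", "npc")}


def run_protocol(
    system: System,
    ff_params: ForceFieldParams | None = None,
    params: SimulationParams | None = None,
    protocol: str = "individual",
    scale: float = 1.0,
    replicate: int = 0,
) -> Trajectory:
    """Run one experiment-level protocol and return the production trajectory.

    Ring/NPC systems are clash-minimized, then relaxed for the (scaled)
    relaxation stage at reduced temperature, then run for the production
    stage at full temperature.  ``replicate`` offsets the seed.
    """
    ff_params = ff_params or ForceFieldParams()
    params = params or SimulationParams()
    plan = protocol_plan(protocol, params, scale)
    seed = (params.seed + 7919 * replicate) % (2**31 - 1)

    sys_run = system
    if plan["minimize"]:
        sys_run = minimize(sys_run, ff_params, params)

    velocities = None
    relax_frames = 0
    for stage in plan["stages"]:
        is_relax = stage["stage"] == "relaxation"
        temp = params.temperature * (
            params.relax_temperature_factor if is_relax else 1.0
        )
        stage_params = replace(
            params,
            n_steps=max(stage["n_steps"], 1),
            temperature=temp,
            seed=(seed + (1 if is_relax else 0)) % (2**31 - 1),
        )
        traj = run_langevin(sys_run, ff_params, stage_params,
                            velocities=velocities)
        velocities = traj.meta["final_velocities"]
        sys_run = sys_run.copy()
        sys_run.positions = traj.frames[-1].copy()
        if is_relax:
            relax_frames = traj.n_frames
    traj.meta["protocol"] = plan
    traj.meta["replicate"] = replicate
    traj.meta["relax_frames_discarded"] = relax_frames
    return traj
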