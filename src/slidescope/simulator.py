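"""Langevin dynamics of a coarse-grained protein around static B-DNA.

The integrator is BAOAB with unit bead masses and k_B = 1 (reduced units).
The DNA never moves; the protein is confined by reflecting walls in X/Y
while Z is periodic with the DNA length (minimum-image in the pair kernels),
so the duplex behaves as if infinite.  Saved frames carry the protein beads
only, rigidly shifted so the protein COM stays within one Z period.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels
from .forcefield import ElectrostaticModel, ForceFieldParams, System, build_system, forces
from .structure_io import BDNADuplex, CGProtein

__all__ = [
    "SimulationConfig",
    "SimState",
    "Trajectory",
    "SimulationError",
    "InstabilityError",
    "TrajectoryIOError",
    "init_state",
    "langevin_step",
    "run_simulation",
    "write_trajectory",
    "read_trajectory",
    "export_xyz",
    "kinetic_temperature",
]

_TRAJ_VERSION = 1


class SimulationError(RuntimeError):
    pass


class InstabilityError(SimulationError):
    """Integration blew up; carries the index of the last stable frame."""

    def __init__(self, message: str, last_frame: int, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.last_frame = last_frame
        self.trajectory = trajectory


class TrajectoryIOError(IOError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    temperature: float = 0.4        # reduced
    friction: float = 0.05          # reduced
    dt: float = 0.005               # reduced
    n_steps: int = 10_000_000
    stride: int = 1000
    box_edge: float | None = None   # Å; None -> DNA length (or 300 without DNA)
    salt_molar: float = 0.01
    seed: int = 0
    start_radius: float = 25.0      # Å from the DNA axis
    start_z_offset: float = 0.0     # Å from mid-DNA
    elec_cutoff: float = 0.0        # Å; 0 = no cutoff
    rep_cutoff_factor: float = 0.0  # units of C_ij; 0 = no cutoff
    max_step_displacement: float = 2.0  # Å; instability threshold
    log_every: int = 10             # frames between energy log records
    dna_bead_radius: float | None = None  # Å; None -> backbone radius

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.stride < 1 or self.n_steps % self.stride != 0:
            raise ValueError("stride must divide n_steps evenly")
        if self.temperature < 0 or self.friction < 0 or self.dt <= 0:
            raise ValueError("invalid temperature/friction/dt")


@dataclass
class SimState:
    positions: np.ndarray        # (n_total, 3), protein first
    velocities: np.ndarray       # (n_total, 3); DNA rows stay zero
    forces: np.ndarray
    system: System
    config: SimulationConfig
    rng: np.random.Generator
    step: int = 0

    @property
    def protein_positions(self) -> np.ndarray:
        return self.positions[: self.system.n_protein]

    def protein_com(self) -> np.ndarray:
        return self.protein_positions.mean(axis=0)


@dataclass
class Trajectory:
    """Protein bead positions over time in the (static) DNA frame."""

    times: np.ndarray            # (F,) reduced time
    frames: np.ndarray           # (F, n_protein, 3) Å
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_beads(self) -> int:
        return int(self.frames.shape[1])

    def com(self) -> np.ndarray:
        """(F, 3) centre of mass per frame (uniform bead masses)."""
        return self.frames.mean(axis=1)

    def com_selection(self, mask: np.ndarray) -> np.ndarray:
        return self.frames[:, mask, :].mean(axis=1)


def _topology_hash(protein: CGProtein) -> str:
    h = hashlib.sha256()
    for arr in (protein.positions, protein.charges, protein.bonds,
                protein.bond_r0, protein.angles, protein.angle_t0,
                protein.dihedrals, protein.dihedral_p0,
                protein.contacts, protein.contact_r0):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _default_box(dna: BDNADuplex | None) -> float:
    return float(dna.z_length) if dna is not None else 300.0


def init_state(
    protein: CGProtein,
    dna: BDNADuplex | None,
    config: SimulationConfig,
    params: ForceFieldParams = ForceFieldParams(),
) -> SimState:
    """Place the protein near the DNA and draw thermal velocities.

    The protein COM is translated to ``start_radius`` from the Z axis (+X
    direction) at mid-DNA Z plus ``start_z_offset``.
    """
    model = ElectrostaticModel(salt_molar=config.salt_molar,
                               dielectric=params.dielectric)
    system = build_system(
        protein, dna, model=model, params=params,
        elec_cutoff=config.elec_cutoff,
        rep_cutoff_factor=config.rep_cutoff_factor,
        dna_bead_radius=config.dna_bead_radius,
    )
    pos = system.positions0.copy()
    npb = system.n_protein
    com = pos[:npb].mean(axis=0)
    z_target = (dna.z_length / 2.0 if dna is not None else 0.0) + config.start_z_offset
    pos[:npb] += np.array([config.start_radius, 0.0, z_target]) - com

    if dna is not None:
        d = pos[:npb, None, :] - pos[None, npb:, :]
        dist = np.sqrt((d ** 2).sum(axis=-1))
        dna_radius = (params.backbone_radius if config.dna_bead_radius is None
                      else config.dna_bead_radius)
        min_c = 0.5 * (protein.repulsion_radii[:, None] + dna_radius)
        if (dist < min_c).any():
            raise SimulationError(
                "initial protein placement overlaps the DNA; "
                "increase start_radius"
            )

    rng = np.random.default_rng(config.seed)
    vel = np.zeros_like(pos)
    if config.temperature > 0:
        vel[:npb] = rng.standard_normal((npb, 3)) * np.sqrt(config.temperature)

    f, _ = forces(pos, system)
    f[npb:] = 0.0
    return SimState(pos, vel, f, system, config, rng)


def _advance(state: SimState, n_steps: int) -> int:
    """Run ``n_steps`` BAOAB steps in place; returns -1 or the failing step."""
    cfg = state.config
    sys_ = state.system
    npb = sys_.n_protein
    noise = state.rng.standard_normal((n_steps, npb, 3))
    half_box = _default_box_from_config(state) / 2.0
    bad = _kernels.baoab_chunk(
        state.positions, state.velocities, state.forces, noise, npb,
        cfg.dt, cfg.friction, cfg.temperature, half_box,
        cfg.max_step_displacement,
        *sys_._kernel_args(),
    )
    if bad < 0:
        state.step += n_steps
    else:
        state.step += bad
    return bad


def _default_box_from_config(state: SimState) -> float:
    if state.config.box_edge is not None:
        return float(state.config.box_edge)
    if state.system.z_period > 0:
        return state.system.z_period
    return 300.0


def langevin_step(state: SimState) -> SimState:
    """One Langevin update in place (DNA beads never move)."""
    bad = _advance(state, 1)
    if bad >= 0:
        raise InstabilityError(
            f"unstable step: per-bead displacement exceeded "
            f"{state.config.max_step_displacement} Å with dt={state.config.dt}; "
            "reduce dt or increase friction",
            last_frame=state.step,
        )
    return state


def _rewrap_z(state: SimState) -> None:
    """Shift the whole protein by multiples of the Z period to keep the COM
    inside [0, L); forces are invariant under this shift."""
    L = state.system.z_period
    if L <= 0:
        return
    com_z = state.protein_positions[:, 2].mean()
    shift = np.floor(com_z / L) * L
    if shift != 0.0:
        state.positions[: state.system.n_protein, 2] -= shift


def kinetic_temperature(state: SimState) -> float:
    npb = state.system.n_protein
    v = state.velocities[:npb]
    return float((v ** 2).sum() / (3.0 * npb))


def run_simulation(
    protein: CGProtein,
    dna: BDNADuplex | None,
    config: SimulationConfig,
    params: ForceFieldParams = ForceFieldParams(),
) -> Trajectory:
    """Simulate and record ``n_steps/stride + 1`` stride-spaced frames."""
    state = init_state(protein, dna, config, params)
    n_chunks = config.n_steps // config.stride
    npb = state.system.n_protein
    frames = np.empty((n_chunks + 1, npb, 3))
    times = np.empty(n_chunks + 1)
    log: list[dict] = []
    frames[0] = state.protein_positions
    times[0] = 0.0

    def log_record(frame_idx: int) -> None:
        from .forcefield import energy as ff_energy
        br = ff_energy(state.positions, state.system)
        com = state.protein_com()
        log.append({
            "frame": frame_idx,
            "step": state.step,
            "kinetic_temperature": kinetic_temperature(state),
            "com_axis_distance": float(np.hypot(com[0], com[1])),
            **{k: float(v) for k, v in br.as_dict().items()},
        })

    log_record(0)
    for chunk in range(1, n_chunks + 1):
        bad = _advance(state, config.stride)
        if bad >= 0:
            partial = Trajectory(
                times[:chunk].copy(), frames[:chunk].copy(),
                _metadata(protein, state, config),
            )
            raise InstabilityError(
                f"simulation unstable at step {state.step} (dt={config.dt}); "
                f"last stable frame index {chunk - 1}",
                last_frame=chunk - 1,
                trajectory=partial,
            )
        _rewrap_z(state)
        frames[chunk] = state.protein_positions
        times[chunk] = state.step * config.dt
        if chunk % config.log_every == 0 or chunk == n_chunks:
            log_record(chunk)

    meta = _metadata(protein, state, config)
    meta["log"] = log
    return Trajectory(times, frames, meta)


def _metadata(protein: CGProtein, state: SimState, config: SimulationConfig) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "topology_hash": _topology_hash(protein),
        "z_period": state.system.z_period,
        "chain_ids": [str(c) for c in protein.chain_ids],
        "charges": [float(q) for q in protein.charges],
        "label": protein.label,
    }


# --------------------------------------------------------------------------
# Trajectory I/O
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "slidescope-trajectory"
        fh.attrs["version"] = _TRAJ_VERSION
        fh.attrs["metadata"] = json.dumps(traj.metadata)
        # track_times=False keeps regenerated files byte-identical
        fh.create_dataset("times", data=traj.times, track_times=False)
        fh.create_dataset("frames", data=traj.frames, track_times=False)


def read_trajectory(path) -> Trajectory:
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "slidescope-trajectory":
                raise TrajectoryIOError(f"{path}: not a slidescope trajectory file")
            version = int(fh.attrs.get("version", -1))
            if version != _TRAJ_VERSION:
                raise TrajectoryIOError(
                    f"{path}: unsupported trajectory version {version} "
                    f"(expected {_TRAJ_VERSION})"
                )
            times = fh["times"][...]
            frames = fh["frames"][...]
            metadata = json.loads(fh.attrs["metadata"])
    except OSError as exc:
        raise TrajectoryIOError(f"{path}: cannot read trajectory ({exc})") from exc
    if times.shape[0] != frames.shape[0]:
        raise TrajectoryIOError(f"{path}: truncated trajectory")
    return Trajectory(times, frames, metadata)


def export_xyz(traj: Trajectory, path, name: str = "CA") -> None:
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.frames):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(f"t={t:.6f}\n")
            for x, y, z in frame:
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
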