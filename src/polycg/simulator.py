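"""NVT Langevin dynamics for coarse-grained bead systems in a periodic box.

The integrator is the BAOAB splitting of Langevin dynamics: velocity-Verlet
half-kicks and half-drifts around an exact Ornstein-Uhlenbeck friction step.
With ``friction = 0`` the scheme reduces to plain velocity Verlet (NVE test
mode). Bead masses are uniform; only equilibrium observables feed the
downstream analysis, so kinetics need not be calibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .force_field import (
    KB,
    EnergyEvaluator,
    ForceFieldError,
    ForceFieldParams,
    System,
    kappa_for_salt,
    _min_image,
)
from .model import CGModel

AVERAGE_RESIDUE_MASS = 110.0  # g/mol, uniform bead mass
MAX_FORCE = 1.0e7  # kJ/mol/nm, numeric blow-up guard
MAX_STEP_DISPLACEMENT = 5.0  # nm per step


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    temperature: float = 300.0  # K
    timestep: float = 0.02  # ps
    friction: float = 0.02  # ps^-1; 0 = NVE mode
    salt_mM: float | None = 100.0  # None keeps the force-field kappa as-is
    box_edge: float | None = None  # nm; None = no periodic boundaries
    n_steps: int = 100_000
    save_interval: int = 100
    seed: int = 0
    equilibration_fraction: float = 0.2
    mass: float = AVERAGE_RESIDUE_MASS

    def __post_init__(self):
        if self.timestep <= 0:
            raise SimulationError("timestep must be positive")
        if self.friction < 0:
            raise SimulationError("friction must be >= 0")
        if self.box_edge is not None and self.box_edge <= 0:
            raise SimulationError("box edge must be positive")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise SimulationError("equilibration fraction must be in [0, 1)")


@dataclass
class Trajectory:
    frames: np.ndarray  # (T, n, 3) nm
    times: np.ndarray  # (T,) ps
    box: float | None
    config: SimulationConfig
    potential_energies: np.ndarray  # (T,) kJ/mol
    kinetic_temperatures: np.ndarray  # (T,) K

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def production(self) -> np.ndarray:
        """Frames after the equilibration window (the analysed portion)."""
        start = int(np.ceil(self.config.equilibration_fraction * self.n_frames))
        return self.frames[start:]

    def production_temperatures(self) -> np.ndarray:
        start = int(np.ceil(self.config.equilibration_fraction * self.n_frames))
        return self.kinetic_temperatures[start:]

    def write_xyz(self, path, names=None) -> None:
        """Portable plain-text trajectory (nm coordinates)."""
        n = self.frames.shape[1]
        if names is None:
            names = ["C"] * n
        with open(path, "w") as fh:
            for t, frame in zip(self.times, self.frames):
                fh.write(f"{n}\ntime={t} ps box={self.box}\n")
                for name, xyz in zip(names, frame):
                    fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            frames=self.frames,
            times=self.times,
            box=np.asarray(-1.0 if self.box is None else self.box),
            potential_energies=self.potential_energies,
            kinetic_temperatures=self.kinetic_temperatures,
            config=json.dumps(asdict(self.config)),
        )

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        d = np.load(path, allow_pickle=False)
        box = float(d["box"])
        return cls(
            frames=d["frames"],
            times=d["times"],
            box=None if box < 0 else box,
            config=SimulationConfig(**json.loads(str(d["config"]))),
            potential_energies=d["potential_energies"],
            kinetic_temperatures=d["kinetic_temperatures"],
        )


# ----------------------------------------------------------------------
def run_langevin(
    system,
    config: SimulationConfig,
    params: ForceFieldParams | None = None,
    positions=None,
    velocities=None,
) -> Trajectory:
    """Propagate a system and return the saved trajectory.

    ``system`` may be a :class:`System`, a single model, or a list of models.
    Reproducible: identical (seed, config, inputs) give identical output.
    """
    if not isinstance(system, System):
        system = System(system)
    params = params or ForceFieldParams()
    if config.salt_mM is not None:
        params = params.with_salt(config.salt_mM)
    evaluator = EnergyEvaluator(system, params)
    box = config.box_edge
    if box is not None and params.cutoff is not None and box < 2 * params.cutoff:
        raise SimulationError("box edge must be at least twice the cutoff")

    pos = np.array(system.positions if positions is None else positions, dtype=float)
    n = len(pos)
    rng = np.random.default_rng(config.seed)
    m = config.mass
    kt = KB * config.temperature
    if velocities is None:
        vel = rng.normal(0.0, np.sqrt(kt / m), size=(n, 3))
    else:
        vel = np.array(velocities, dtype=float)

    dt = config.timestep
    gamma = config.friction
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kt / m * (1.0 - c1 * c1))
    else:
        c1, c2 = 1.0, 0.0

    energy, forces = evaluator.energy_forces(pos, box)

    n_saved = config.n_steps // config.save_interval + 1
    frames = np.empty((n_saved, n, 3))
    times = np.empty(n_saved)
    pot = np.empty(n_saved)
    temps = np.empty(n_saved)

    def record(k, step):
        frames[k] = pos
        times[k] = step * dt
        pot[k] = energy
        ke = 0.5 * m * float((vel**2).sum())
        temps[k] = 2.0 * ke / (3.0 * n * KB)

    record(0, 0)
    k = 1
    half = 0.5 * dt
    for step in range(1, config.n_steps + 1):
        vel += half / m * forces
        pos += half * vel
        if gamma > 0:
            vel = c1 * vel + c2 * rng.standard_normal((n, 3))
        pos += half * vel
        try:
            energy, forces = evaluator.energy_forces(pos, box)
        except ForceFieldError as exc:
            raise SimulationError(f"force evaluation failed at step {step}: {exc}") from exc
        if np.abs(forces).max() > MAX_FORCE or np.abs(vel).max() * dt > MAX_STEP_DISPLACEMENT:
            raise SimulationError(f"numeric blow-up at step {step}")
        vel += half / m * forces
        if step % config.save_interval == 0:
            record(k, step)
            k += 1

    return Trajectory(
        frames=frames,
        times=times,
        box=box,
        config=config,
        potential_energies=pot,
        kinetic_temperatures=temps,
    )


# ----------------------------------------------------------------------
def _extent(positions) -> float:
    """Diameter of the bounding sphere (approximated via centroid radius)."""
    c = positions.mean(axis=0)
    return 2.0 * float(np.linalg.norm(positions - c, axis=1).max())


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def place_complex(
    polypr: CGModel,
    component: CGModel,
    seed: int = 0,
    distance: float | None = None,
    min_separation: float = 0.3,
    box_edge: float | None = None,
    cutoff: float = 2.5,
    max_retries: int = 200,
    direction=None,
):
    """Seeded initial placement of a peptide next to a folded component.

    Returns ``(system, box_edge)`` where the system holds the placed
    coordinates. The component is centered at the origin; the peptide is
    rotated randomly and its centroid put at ``distance`` (default:
    component Rg + peptide contour/2 + 1 nm) along ``direction`` (default: a
    seeded random unit vector; pass e.g. the negative dipole direction to
    start on a chosen face). Retries until no inter-molecular bead pair is
    closer than ``min_separation``.
    """
    rng = np.random.default_rng(seed)
    comp_pos = component.positions - component.positions.mean(axis=0)
    pep_pos0 = polypr.positions - polypr.positions.mean(axis=0)
    if distance is None:
        rg = float(np.sqrt(((comp_pos) ** 2).sum(axis=1).mean()))
        contour = 0.38 * (polypr.n_beads - 1)
        distance = rg + contour / 2.0 + 1.0
    if box_edge is None:
        box_edge = 2.0 * max(_extent(comp_pos), _extent(pep_pos0), distance) + cutoff

    for _ in range(max_retries):
        if direction is None:
            u = rng.normal(size=3)
        else:
            u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        pep_pos = pep_pos0 @ _random_rotation(rng).T + distance * u
        d2 = ((pep_pos[:, None, :] - comp_pos[None, :, :]) ** 2).sum(axis=-1)
        if np.sqrt(d2.min()) >= min_separation:
            comp = component.copy()
            comp.positions = comp_pos
            pep = polypr.copy()
            pep.positions = pep_pos
            system = System([comp, pep], roles=["component", "polypr"])
            return system, float(box_edge)
    raise SimulationError(
        f"could not place molecules without overlap after {max_retries} retries"
    )


# ----------------------------------------------------------------------
def neighbor_list(positions, box: float, cutoff: float) -> np.ndarray:
    """All pairs within ``cutoff`` under the minimum-image convention.

    Cell-list search, O(N) in bead count; requires ``cutoff <= box/2``.
    Returns a sorted (m, 2) integer array of i < j pairs.
    """
    pos = np.asarray(positions, dtype=float)
    if cutoff > box / 2.0:
        raise SimulationError("cutoff must not exceed half the box edge")
    n = len(pos)
    ncell = max(int(np.floor(box / cutoff)), 1)
    if ncell < 3:
        # too few cells for a gain; brute force with minimum image
        ii, jj = np.triu_indices(n, k=1)
        dx = _min_image(pos[ii] - pos[jj], box)
        keep = (dx**2).sum(axis=1) <= cutoff**2
        return np.stack([ii[keep], jj[keep]], axis=1)

    size = box / ncell
    cells = np.floor((pos % box) / size).astype(int) % ncell
    cell_of = cells[:, 0] * ncell * ncell + cells[:, 1] * ncell + cells[:, 2]
    order = np.argsort(cell_of, kind="stable")
    sorted_cells = cell_of[order]
    starts = np.searchsorted(sorted_cells, np.arange(ncell**3))
    ends = np.searchsorted(sorted_cells, np.arange(ncell**3), side="right")

    offsets = [
        (a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    ]
    pairs = []
    cut2 = cutoff**2
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c_id = cx * ncell * ncell + cy * ncell + cz
                mine = order[starts[c_id]:ends[c_id]]
                if len(mine) == 0:
                    continue
                for a, b, c in offsets:
                    nx, ny, nz = (cx + a) % ncell, (cy + b) % ncell, (cz + c) % ncell
                    n_id = nx * ncell * ncell + ny * ncell + nz
                    if n_id < c_id:
                        continue
                    other = order[starts[n_id]:ends[n_id]]
                    if len(other) == 0:
                        continue
                    if n_id == c_id:
                        if len(mine) < 2:
                            continue
                        ai, aj = np.triu_indices(len(mine), k=1)
                        pi, pj = mine[ai], mine[aj]
                    else:
                        pi = np.repeat(mine, len(other))
                        pj = np.tile(other, len(mine))
                    dx = _min_image(pos[pi] - pos[pj], box)
                    keep = (dx**2).sum(axis=1) <= cut2
                    if keep.any():
                        lo = np.minimum(pi[keep], pj[keep])
                        hi = np.maximum(pi[keep], pj[keep])
                        pairs.append(np.stack([lo, hi], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    out = np.unique(np.concatenate(pairs), axis=0)
    return out
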