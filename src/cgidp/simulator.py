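"""System construction and Langevin NVT dynamics.

Chains are linear bead strings connected by harmonic bonds.  Single chains
start fully extended in a cubic box of side 0.38(N−1)+4 nm; slab systems
place extended chains along z with middle beads scattered in the xy plane.
Dynamics use a BAOAB-split Langevin integrator (10 fs timestep, friction
0.01 ps⁻¹ by default) in reduced MD units (nm, ps, Da, kJ/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import H_MASS, KB, OH_MASS
from .energetics import (
    COULOMB_PREFACTOR,
    ElectrostaticsContext,
    _RMIN_FACTOR,
    minimum_image,
)
from .model_core import ParameterSet, ProteinSpec, SolutionConditions, chain_charges

__all__ = [
    "Topology",
    "Configuration",
    "Trajectory",
    "SamplingSchedule",
    "SimulationSettings",
    "build_single_chain_system",
    "build_slab_system",
    "sampling_schedule",
    "run_langevin",
    "run_single_chain_replicas",
    "replica_seed",
    "save_configuration",
    "load_configuration",
]


@dataclass
class Topology:
    """Bead-resolution topology: chains, bonds and per-bead parameters."""

    chains: list[str]
    codes: list[str]
    bonds: np.ndarray           # (n_bonds, 2) consecutive beads within chains
    chain_index: np.ndarray     # (n_beads,) chain id per bead
    charges: np.ndarray         # (n_beads,) elementary charges
    masses: np.ndarray          # (n_beads,) Da (termini carry +H / +OH)

    @property
    def n_beads(self) -> int:
        return len(self.codes)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @classmethod
    def from_chains(
        cls,
        sequences: list[str],
        params: ParameterSet,
        pH: float = 7.0,
    ) -> "Topology":
        codes: list[str] = []
        bonds: list[tuple[int, int]] = []
        chain_index: list[int] = []
        charges: list[float] = []
        masses: list[float] = []
        offset = 0
        for ci, seq in enumerate(sequences):
            codes.extend(seq)
            chain_index.extend([ci] * len(seq))
            bonds.extend((offset + k, offset + k + 1) for k in range(len(seq) - 1))
            charges.extend(chain_charges(seq, pH, params))
            m = [params[c].mass for c in seq]
            m[0] += H_MASS
            m[-1] += OH_MASS
            masses.extend(m)
            offset += len(seq)
        return cls(
            chains=list(sequences),
            codes=codes,
            bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
            chain_index=np.asarray(chain_index, dtype=int),
            charges=np.asarray(charges, dtype=float),
            masses=np.asarray(masses, dtype=float),
        )


@dataclass
class Configuration:
    """Positions (nm) in a periodic cuboidal box [Lx, Ly, Lz] (nm)."""

    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")


@dataclass
class Trajectory:
    """Time-ordered saved configurations of one run."""

    frames: np.ndarray          # (n_frames, n_beads, 3) nm
    box: np.ndarray             # (3,) nm
    frame_interval: float       # ps between saved frames
    kinetic_energies: np.ndarray | None = None  # kJ/mol per saved frame

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SamplingSchedule:
    """Frame-saving schedule of the single-chain protocol."""

    save_interval: float        # ps
    n_frames_saved: int
    n_discard: int
    n_replicas: int

    def __post_init__(self) -> None:
        if self.n_discard >= self.n_frames_saved:
            raise ValueError("n_discard must be smaller than n_frames_saved")

    @property
    def n_retained_total(self) -> int:
        return self.n_replicas * (self.n_frames_saved - self.n_discard)


@dataclass(frozen=True)
class SimulationSettings:
    """Integrator settings: 10 fs timestep and 0.01 ps⁻¹ friction default."""

    temperature: float
    timestep: float = 10.0      # fs
    friction: float = 0.01      # ps^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be positive")


def sampling_schedule(N: int, n_replicas: int = 10) -> SamplingSchedule:
    """Saving schedule: Δt = 3N² fs for N > 100 else 30 ps; 600 frames per
    replica with the first 100 discarded (10 replicas → 5000 retained)."""
    if N < 1:
        raise ValueError("N must be at least 1")
    interval = 3.0 * N * N * 1e-3 if N > 100 else 30.0  # ps
    return SamplingSchedule(
        save_interval=interval, n_frames_saved=600, n_discard=100,
        n_replicas=n_replicas,
    )


def build_single_chain_system(
    spec: ProteinSpec,
    params: ParameterSet,
    box_side: float | None = None,
) -> tuple[Topology, Configuration]:
    """Extended linear chain centered in a cubic box of side 0.38(N−1)+4 nm.

    ``box_side`` overrides the default box (e.g. to satisfy the
    minimum-image requirement for very short test chains).
    """
    n = len(spec.sequence)
    pH = spec.conditions.pH if spec.conditions else 7.0
    top = Topology.from_chains([spec.sequence], params, pH=pH)
    side = box_side if box_side is not None else 0.38 * (n - 1) + 4.0
    box = np.array([side, side, side])
    z = np.arange(n) * params.bond_r0
    z -= z.mean()
    positions = np.zeros((n, 3))
    positions[:, 2] = z
    positions += box / 2.0
    return top, Configuration(positions=positions, box=box)


def build_slab_system(
    spec: ProteinSpec,
    n_chains: int,
    params: ParameterSet,
    box: tuple[float, float, float] = (15.0, 15.0, 150.0),
    min_separation: float = 0.7,
    seed: int = 0,
    max_tries: int = 100_000,
) -> tuple[Topology, Configuration]:
    """Slab starting configuration: n_chains extended chains parallel to z,
    middle beads in the xy plane at seeded random positions pairwise more
    than ``min_separation`` nm apart (periodic xy distance)."""
    n = len(spec.sequence)
    box = np.asarray(box, dtype=float)
    extent = params.bond_r0 * (n - 1)
    if extent >= box[2]:
        raise ValueError(
            f"chain extent {extent:.1f} nm does not fit along z ({box[2]} nm)"
        )
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_chains:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_chains} chains {min_separation} nm apart "
                f"in a {box[0]}x{box[1]} nm cross-section; use a larger box"
            )
        tries += 1
        xy = rng.uniform(0.0, box[:2])
        ok = True
        for other in placed:
            d = xy - other
            d -= box[:2] * np.round(d / box[:2])
            if np.hypot(*d) <= min_separation:
                ok = False
                break
        if ok:
            placed.append(xy)
    pH = spec.conditions.pH if spec.conditions else 7.0
    top = Topology.from_chains([spec.sequence] * n_chains, params, pH=pH)
    z = np.arange(n) * params.bond_r0
    z -= z[n // 2]  # middle bead in the xy-plane
    positions = np.zeros((n_chains * n, 3))
    for ci, xy in enumerate(placed):
        sl = slice(ci * n, (ci + 1) * n)
        positions[sl, 0] = xy[0]
        positions[sl, 1] = xy[1]
        positions[sl, 2] = (z + box[2] / 2.0) % box[2]
    return top, Configuration(positions=positions, box=box)


# ---------------------------------------------------------------------------
# forces and integration


class _Forces:
    """Precomputed pair tables and vectorized force evaluation."""

    def __init__(self, topology: Topology, params: ParameterSet,
                 ctx: ElectrostaticsContext, box, intra_only: bool = False):
        from .energetics import _pair_arrays

        self.box = np.asarray(box, dtype=float)
        rc_max = max(params.rc_nonionic, params.rc_ionic)
        if np.min(self.box) < 2.0 * rc_max:
            raise ValueError(
                f"box {self.box} too small for cutoff {rc_max} nm (minimum image)"
            )
        self.k = params.bond_k
        self.r0 = params.bond_r0
        self.eps = params.epsilon
        self.rc_n = params.rc_nonionic
        self.rc_i = params.rc_ionic
        self.bonds = topology.bonds
        i_idx, j_idx, sigma_ij, lambda_ij = _pair_arrays(topology, params,
                                                         intra_only=intra_only)
        q = topology.charges
        self.i, self.j = i_idx, j_idx
        self.sigma, self.lam = sigma_ij, lambda_ij
        self.qq = q[i_idx] * q[j_idx]
        self.dh_coef = COULOMB_PREFACTOR / ctx.dielectric * self.qq
        self.debye = ctx.debye
        self.has_charges = bool(np.any(self.qq != 0.0))
        self.n = topology.n_beads

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        f = np.zeros_like(positions)
        # bonds
        if len(self.bonds):
            db = minimum_image(
                positions[self.bonds[:, 0]] - positions[self.bonds[:, 1]], self.box
            )
            rb = np.linalg.norm(db, axis=1)
            if np.any(rb < 1e-9):
                bad = self.bonds[int(np.argmin(rb))]
                raise FloatingPointError(f"bond collapse between beads {tuple(bad)}")
            mag = -self.k * (rb - self.r0) / rb
            fb = mag[:, None] * db
            np.add.at(f, self.bonds[:, 0], fb)
            np.add.at(f, self.bonds[:, 1], -fb)
        if len(self.i) == 0:
            return f
        delta = minimum_image(positions[self.i] - positions[self.j], self.box)
        r2 = np.einsum("ij,ij->i", delta, delta)
        r = np.sqrt(r2)
        if np.any(r < 1e-4):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"overlapping beads {int(self.i[k])} and {int(self.j[k])} "
                f"(r = {r[k]:.2e} nm)"
            )
        # AH: du/dr = uLJ'(r) inner, λ uLJ'(r) outer, 0 beyond rc
        within = r <= self.rc_n
        dudr = np.zeros_like(r)
        s6 = (self.sigma[within] / r[within]) ** 6
        uljp = -24.0 * self.eps * (2.0 * s6 * s6 - s6) / r[within]
        inner = r[within] <= _RMIN_FACTOR * self.sigma[within]
        dudr[within] = np.where(inner, uljp, self.lam[within] * uljp)
        # DH: du/dr = −coef e^{−r/D} (1/r² + 1/(rD)), 0 beyond rc
        if self.has_charges:
            act = (self.qq != 0.0) & (r <= self.rc_i)
            ra = r[act]
            dudr[act] += -self.dh_coef[act] * np.exp(-ra / self.debye) * (
                1.0 / (ra * ra) + 1.0 / (ra * self.debye)
            )
        mag = -dudr / r
        fp = mag[:, None] * delta
        np.add.at(f, self.i, fp)
        np.add.at(f, self.j, -fp)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite forces")
        return f


def replica_seed(master_seed: int, replica: int) -> np.random.SeedSequence:
    """Per-replica seed derivation: SeedSequence spawned by replica index."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replica,))


def run_langevin(
    topology: Topology,
    config: Configuration,
    params: ParameterSet,
    settings: SimulationSettings,
    n_steps: int,
    save_every: int,
    conditions: SolutionConditions | None = None,
    rng: np.random.Generator | None = None,
    intra_only: bool = False,
    backend: str = "auto",
) -> Trajectory:
    """NVT Langevin dynamics with BAOAB splitting.

    Saves a frame every ``save_every`` steps (the initial configuration is
    not saved; ``n_steps == 0`` returns it unchanged as the only frame).
    Deterministic for a fixed seed and backend.  Kinetic energies of saved
    frames are recorded for thermostat checks.  ``intra_only=True``
    disables inter-chain nonbonded interactions (independent-replica
    batching).  ``backend`` selects "numpy" (reference engine) or "numba"
    (compiled kernels, same physics); "auto" prefers the compiled engine.
    Both consume the identical noise stream, so they differ only by
    floating-point summation order.
    """
    from ._engine_numba import HAVE_NUMBA

    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"
    if backend == "numba" and not HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is unavailable")
    ionic = conditions.ionic_strength if conditions else 0.15
    ctx = ElectrostaticsContext.create(settings.temperature, ionic)
    force = _Forces(topology, params, ctx, config.box, intra_only=intra_only)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    dt = settings.timestep * 1e-3  # fs -> ps
    gamma = settings.friction
    kT = KB * settings.temperature
    m = topology.masses[:, None]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    x = config.positions.copy()
    v = rng.normal(0.0, np.sqrt(kT / m), size=x.shape)
    if n_steps == 0:
        return Trajectory(frames=x[None].copy(), box=config.box.copy(),
                          frame_interval=0.0,
                          kinetic_energies=np.array([0.5 * np.sum(m * v * v)]))
    if backend == "numba":
        return _run_numba(force, topology, config, x, v, rng, dt, c1, c2,
                          n_steps, save_every)
    f = force(x)
    frames, kes = [], []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 / np.sqrt(m) * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f = force(x)
        v += 0.5 * dt * f / m
        if step % save_every == 0:
            frames.append(x.copy())
            kes.append(0.5 * float(np.sum(m * v * v)))
    return Trajectory(
        frames=np.asarray(frames), box=config.box.copy(),
        frame_interval=save_every * dt,
        kinetic_energies=np.asarray(kes),
    )


def _run_numba(force, topology, config, x, v, rng, dt, c1, c2,
               n_steps, save_every, chunk: int = 4000) -> Trajectory:
    """Compiled-kernel integration path (noise drawn chunk-wise from the
    same stream the reference engine consumes per step)."""
    from ._engine_numba import _baoab_chunk, _forces as _forces_kernel

    n = topology.n_beads
    debye = force.debye if np.isfinite(force.debye) else 1e12
    bonds = np.ascontiguousarray(force.bonds, dtype=np.int64)
    pi = np.ascontiguousarray(force.i, dtype=np.int64)
    pj = np.ascontiguousarray(force.j, dtype=np.int64)
    f = np.zeros_like(x)
    _forces_kernel(x, force.box, bonds, force.k, force.r0, pi, pj,
                   force.sigma, force.lam, force.dh_coef,
                   force.eps, force.rc_n, force.rc_i, debye, f)
    n_save = n_steps // save_every
    frames = np.empty((n_save, n, 3))
    kes = np.empty(n_save)
    masses = topology.masses
    nsaved, step0 = 0, 0
    while step0 < n_steps:
        S = min(chunk, n_steps - step0)
        noise = rng.standard_normal((S, n, 3))
        nsaved, rmin = _baoab_chunk(
            x, v, f, masses, force.box, dt, c1, c2, noise,
            bonds, force.k, force.r0, pi, pj, force.sigma, force.lam,
            force.dh_coef, force.eps, force.rc_n, force.rc_i, debye,
            step0, save_every, frames, kes, nsaved,
        )
        if rmin < 1e-4 or not np.all(np.isfinite(x)):
            force(x)  # reference path identifies the offending pair
            raise FloatingPointError("overlapping beads (unidentified pair)")
        step0 += S
    return Trajectory(
        frames=frames, box=config.box.copy(),
        frame_interval=save_every * dt,
        kinetic_energies=kes,
    )


def run_single_chain_replicas(
    spec: ProteinSpec,
    params: ParameterSet,
    settings: SimulationSettings,
    schedule: SamplingSchedule,
    box_side: float | None = None,
    save_every: int | None = None,
    backend: str = "auto",
) -> tuple[Topology, Trajectory]:
    """Replica protocol: ``schedule.n_replicas`` independent copies of the
    chain, each started fully extended, sampled in one batched run.

    Replicas are realized as chains whose nonbonded interactions are
    restricted to intra-chain pairs (``intra_only``), so they share one
    integrator call but never see each other — exactly independent replicas
    driven by one seeded noise stream.  The first ``n_discard`` frames of
    each replica are discarded and the remainder pooled.  Returns the
    single-chain topology together with the pooled trajectory of shape
    (n_replicas × retained, N, 3).
    """
    top_one, config_one = build_single_chain_system(spec, params,
                                                    box_side=box_side)
    R = schedule.n_replicas
    pH = spec.conditions.pH if spec.conditions else 7.0
    top = Topology.from_chains([spec.sequence] * R, params, pH=pH)
    positions = np.tile(config_one.positions, (R, 1))
    config = Configuration(positions=positions, box=config_one.box)
    dt_ps = settings.timestep * 1e-3
    if save_every is None:
        save_every = max(1, int(round(schedule.save_interval / dt_ps)))
    n_steps = save_every * schedule.n_frames_saved
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    traj = run_langevin(top, config, params, settings, n_steps, save_every,
                        conditions=spec.conditions, rng=rng, intra_only=True,
                        backend=backend)
    n = len(spec.sequence)
    kept = traj.frames[schedule.n_discard:]
    # (frames, R, N, 3) -> replica-major pooling
    per_replica = kept.reshape(len(kept), R, n, 3).transpose(1, 0, 2, 3)
    pooled = per_replica.reshape(-1, n, 3)
    return top_one, Trajectory(
        frames=pooled, box=config.box,
        frame_interval=save_every * dt_ps,
    )


# ---------------------------------------------------------------------------
# plain-text snapshot format (fixture-friendly)


def save_configuration(config: Configuration, path) -> None:
    """Whitespace-delimited snapshot: header line ``box Lx Ly Lz`` then one
    ``x y z`` row per bead."""
    with open(path, "w") as fh:
        fh.write("box " + " ".join(f"{b:.8f}" for b in config.box) + "\n")
        np.savetxt(fh, config.positions, fmt="%.8f")


def load_configuration(path) -> Configuration:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["box"]:
            raise ValueError("snapshot must start with a 'box Lx Ly Lz' line")
        box = np.array([float(t) for t in header[1:4]])
        positions = np.loadtxt(fh, ndmin=2)
    return Configuration(positions=positions, box=box)


def save_trajectory(trajectory: Trajectory, path) -> None:
    """Multi-frame text format: ``box`` header, then ``frame k`` blocks."""
    with open(path, "w") as fh:
        fh.write("box " + " ".join(f"{b:.8f}" for b in trajectory.box))
        fh.write(f" interval_ps {trajectory.frame_interval:.6f}\n")
        for k, frame in enumerate(trajectory.frames):
            fh.write(f"frame {k}\n")
            np.savetxt(fh, frame, fmt="%.6f")


def load_trajectory(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["box"]:
            raise ValueError("trajectory must start with a 'box' header line")
        box = np.array([float(t) for t in header[1:4]])
        interval = float(header[5]) if len(header) > 5 else 0.0
        frames, current = [], []
        for line in fh:
            if line.startswith("frame"):
                if current:
                    frames.append(current)
                current = []
            elif line.strip():
                current.append([float(t) for t in line.split()])
        if current:
            frames.append(current)
    return Trajectory(frames=np.asarray(frames, dtype=float), box=box,
                      frame_interval=interval)
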