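"""Synthetic fixtures and small self-contained study problems.

Everything here generates data programmatically from a seed: tanh-shaped
density profiles (with or without a bead-level realization), AR(1) scalar
series for error-estimator checks, toy hydrophobicity-scale tables, and a
small-alphabet parameter-recovery problem in which pseudo-experimental
radii of gyration are simulated at a known ground-truth λ*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_analysis import ExperimentalRg, rg_series
from .constants import DA_PER_NM3_TO_MG_PER_ML
from .energetics import LinearizedAH
from .model_core import (
    CANONICAL_RESIDUES,
    ParameterSet,
    ProteinSpec,
    SolutionConditions,
    load_calvados,
)
from .optimizer import Ensemble, HydrophobicityScale
from .simulator import (
    SamplingSchedule,
    SimulationSettings,
    Trajectory,
    run_single_chain_replicas,
)
from .slab_analysis import DensityProfile, tanh_profile

__all__ = [
    "generate_tanh_fixture",
    "generate_slab_configuration",
    "generate_ar1_series",
    "generate_synthetic_scales",
    "ToyRecoveryProblem",
    "make_toy_recovery_problem",
]


def generate_tanh_fixture(
    rho_a: float,
    rho_b: float,
    z_ds: float,
    t: float,
    noise: float = 0.0,
    box=(15.0, 15.0, 150.0),
    bin_width: float = 1.0,
    n_frames: int = 1,
    seed: int = 0,
) -> DensityProfile:
    """Density profile following the tanh interface form exactly, with
    optional multiplicative gaussian noise per frame (seeded)."""
    if rho_a < rho_b or rho_b < 0:
        raise ValueError("need rho_a >= rho_b >= 0")
    box = np.asarray(box, dtype=float)
    nbins = int(round(box[2] / bin_width))
    edges = np.linspace(-box[2] / 2.0, box[2] / 2.0, nbins + 1)
    z = (edges[:-1] + edges[1:]) / 2.0
    clean = tanh_profile(z, rho_a, rho_b, z_ds, t)
    rng = np.random.default_rng(seed)
    per_frame = np.stack([
        clean * (1.0 + noise * rng.standard_normal(nbins)) if noise > 0 else clean
        for _ in range(n_frames)
    ])
    return DensityProfile(
        z_centers=z,
        density=per_frame.mean(axis=0),
        n_frames_averaged=n_frames,
        bin_width=box[2] / nbins,
        cross_section=float(box[0] * box[1]),
        per_frame=per_frame,
    )


def generate_slab_configuration(
    rho_dense: float,
    rho_dilute: float,
    half_width: float,
    box=(15.0, 15.0, 150.0),
    bead_mass: float = 110.0,
    n_frames: int = 1,
    center: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Bead-level realization of a two-plateau slab.

    Beads of mass ``bead_mass`` are Poisson-placed so the mass density is
    ``rho_dense`` (mg/mL) inside |z − center| < half_width (periodic) and
    ``rho_dilute`` outside.  Returns a trajectory (frames share the bead
    count of frame 0) and the bead masses.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    area = box[0] * box[1]
    v_dense = 2.0 * half_width * area
    v_dilute = (box[2] - 2.0 * half_width) * area
    number_density = lambda rho: rho / DA_PER_NM3_TO_MG_PER_ML / bead_mass
    n_dense = rng.poisson(number_density(rho_dense) * v_dense)
    n_dilute = rng.poisson(number_density(rho_dilute) * v_dilute)
    frames = []
    n_total = None
    for _ in range(n_frames):
        zd = center + rng.uniform(-half_width, half_width, n_dense)
        lo = center + half_width
        zf = (lo + rng.uniform(0.0, box[2] - 2.0 * half_width, n_dilute))
        z = np.concatenate([zd, zf])
        z = (z + box[2] / 2.0) % box[2]  # box coordinates in [0, Lz)
        xy = rng.uniform(0.0, box[:2], size=(len(z), 2))
        frames.append(np.column_stack([xy, z]))
        n_total = len(z)
    return (
        Trajectory(frames=np.asarray(frames), box=box, frame_interval=1.0),
        np.full(n_total, bead_mass),
    )


def generate_ar1_series(
    phi: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """Stationary AR(1) draw with lag-1 coefficient φ and marginal std σ."""
    if not -1.0 < phi < 1.0:
        raise ValueError("|phi| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def generate_synthetic_scales(
    n_scales: int, seed: int = 0, n_reversed: int = 0
) -> list[HydrophobicityScale]:
    """Toy multi-scale hydrophobicity table: correlated random rankings
    around a common latent hydropathy, arbitrary affine ranges."""
    rng = np.random.default_rng(seed)
    latent = rng.uniform(0.0, 1.0, 20)
    scales = []
    for k in range(n_scales):
        noise = rng.normal(0.0, 0.15, 20)
        a, b = rng.uniform(0.5, 5.0), rng.uniform(-3.0, 3.0)
        rev = k < n_reversed
        v = latent + noise
        if rev:
            v = -v
        scales.append(
            HydrophobicityScale(
                name=f"synthetic_{k}",
                values=dict(zip(CANONICAL_RESIDUES, a * v + b)),
                reversed=rev,
            )
        )
    return scales


# ---------------------------------------------------------------------------
# toy parameter-recovery problem


@dataclass
class ToyRecoveryProblem:
    """A small-alphabet λ-recovery study.

    ``targets`` are pseudo-experimental ⟨Rg⟩ values simulated at the
    ground-truth ``lambda_star``; ``hook`` re-simulates every toy protein
    at a requested λ and returns optimizer ensembles.
    """

    alphabet: str
    sequences: list[str]
    lambda_star: np.ndarray
    params: ParameterSet
    conditions: SolutionConditions
    settings: SimulationSettings
    schedule: SamplingSchedule
    targets: dict
    save_every: int

    def hook(self, lambda_vector: np.ndarray):
        params_k = self.params.with_lambda(np.asarray(lambda_vector))
        ensembles = {}
        for seq in self.sequences:
            rg, lin, A, b = _simulate_toy(seq, params_k, self.conditions,
                                          self.settings, self.schedule,
                                          self.save_every)
            ensembles[seq] = Ensemble(
                rg=rg, lin=lin, A=A, b=b,
                temperature=self.conditions.temperature,
                rg_target=self.targets[seq],
            )
        return ensembles


def _simulate_toy(seq, params, conditions, settings, schedule, save_every):
    spec = ProteinSpec(name=seq, sequence=seq, conditions=conditions)
    top, traj = run_single_chain_replicas(
        spec, params, settings, schedule, save_every=save_every
    )
    rg = rg_series(traj, top)
    lin = LinearizedAH(top, params)
    A, b = lin.decompose(traj.frames, traj.box)
    return rg, lin, A, b


def make_toy_recovery_problem(
    alphabet: str = "FMY",
    lambda_star: dict | None = None,
    chain_length: int = 16,
    n_mixed: int = 1,
    sigma_exp: float = 0.01,
    temperature: float = 288.0,
    n_frames: int = 600,
    n_discard: int = 100,
    n_replicas: int = 10,
    save_every: int = 100,
    seed: int = 0,
) -> ToyRecoveryProblem:
    """Build the toy study: homopolymers of each alphabet letter plus
    ``n_mixed`` random mixed sequences; pseudo-experimental ⟨Rg⟩ simulated
    at λ* with stated uncertainty ``sigma_exp`` (nm).

    The default alphabet uses large, λ-responsive beads (F, M, Y) so each
    homopolymer's compaction pins its own stickiness.  Ground-truth λ*
    defaults to (0.40, 0.55, 0.60) over the alphabet letters, around the
    protocol's λ0 = 0.5 start.  The replica schedule mirrors the
    single-chain protocol (10 replicas, first 100 of 600 frames discarded
    → 5000 pooled conformations per protein).

    The toy model variant is uncharged (no termini charges; the default
    alphabet carries no ionizable residues), so the nonionic stickiness is
    the only sequence-dependent interaction — exactly the term the
    optimizer learns.
    """
    if lambda_star is None:
        defaults = (0.40, 0.55, 0.60)
        lambda_star = {c: defaults[k % 3] for k, c in enumerate(alphabet)}
    rng = np.random.default_rng(seed)
    sequences = [c * chain_length for c in alphabet]
    for _ in range(n_mixed):
        sequences.append("".join(rng.choice(list(alphabet), chain_length)))
    base = load_calvados(2, termini_charges=False)
    lam_vec = base.lambda_vector()
    for c, v in lambda_star.items():
        lam_vec[CANONICAL_RESIDUES.index(c)] = v
    params_star = base.with_lambda(lam_vec)
    conditions = SolutionConditions(temperature=temperature,
                                    ionic_strength=0.15)
    settings = SimulationSettings(temperature=temperature, friction=0.2,
                                  seed=seed)
    schedule = SamplingSchedule(save_interval=save_every * 0.01,
                                n_frames_saved=n_frames,
                                n_discard=n_discard, n_replicas=n_replicas)
    targets = {}
    for seq in sequences:
        rg, *_ = _simulate_toy(seq, params_star, conditions, settings,
                               schedule, save_every)
        targets[seq] = ExperimentalRg(value=float(rg.mean()),
                                      sigma_exp=sigma_exp)
    return ToyRecoveryProblem(
        alphabet=alphabet,
        sequences=sequences,
        lambda_star=lam_vec,
        params=base,
        conditions=conditions,
        settings=settings,
        schedule=schedule,
        targets=targets,
        save_every=save_every,
    )
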