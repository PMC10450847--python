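"""Pairwise potentials and system energy evaluation.

Nonionic interactions follow the truncated-and-shifted Ashbaugh–Hatch form:
a Lennard-Jones potential whose attractive tail is scaled by the pair
stickiness λ and which is purely repulsive for λ = 0.  Electrostatics are
salt-screened Debye–Hückel interactions with a temperature-dependent
dielectric, truncated and shifted at 4 nm.  Bonds are harmonic.

Energies are kJ/mol, lengths nm, temperatures K.  Small pair-boundary
values are conventionally quoted in J/mol (multiply by 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_PREFACTOR, KB, MOLAR_TO_PER_NM3
from .model_core import ParameterSet, SolutionConditions

__all__ = [
    "lj_potential",
    "ah_potential",
    "dielectric_constant",
    "bjerrum_length",
    "debye_length",
    "ElectrostaticsContext",
    "dh_potential",
    "bond_potential",
    "EnergyBreakdown",
    "system_energy",
    "nonionic_energy_unshifted",
    "LinearizedAH",
    "minimum_image",
]

_RMIN_FACTOR = 2.0 ** (1.0 / 6.0)


def lj_potential(r, sigma, eps):
    """Lennard-Jones potential 4ε[(σ/r)^12 − (σ/r)^6]; minimum −ε at 2^{1/6}σ."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s6 = (sigma / r) ** 6
    return 4.0 * eps * (s6 * s6 - s6)


def ah_potential(r, sigma, lam, rc, eps=0.8368, shifted=True):
    """Ashbaugh–Hatch pair potential.

    shifted=True gives the truncated-and-shifted form used in simulations:
    ``u_LJ(r) − λ u_LJ(rc) + (1−λ)ε`` below the LJ minimum,
    ``λ[u_LJ(r) − u_LJ(rc)]`` between the minimum and rc, and 0 beyond rc
    (continuous everywhere, exactly 0 at rc).  shifted=False returns the
    bare (infinite-range) pair energy — the inner branch ``u_LJ + (1−λ)ε``
    and outer branch ``λ u_LJ`` without truncation — used for
    cutoff-loss accounting.
    """
    rmin = _RMIN_FACTOR * sigma
    if shifted and rc <= rmin:
        raise ValueError(f"cutoff {rc} nm not beyond the LJ minimum {rmin:.3f} nm")
    r = np.asarray(r, dtype=float)
    ulj = lj_potential(r, sigma, eps)
    inner = r <= rmin
    if shifted:
        uljc = lj_potential(rc, sigma, eps)
        u = np.where(inner, ulj - lam * uljc + (1.0 - lam) * eps,
                     lam * (ulj - uljc))
        return np.where(r > rc, 0.0, u)
    return np.where(inner, ulj + (1.0 - lam) * eps, lam * ulj)


def dielectric_constant(T):
    """Empirical dielectric constant of water as a function of T (K).

    Valid for liquid water; inputs outside (250, 400) K are rejected.
    """
    T = np.asarray(T, dtype=float)
    if np.any((T <= 250.0) | (T >= 400.0)):
        raise ValueError("temperature outside the validated liquid-water range")
    return (5321.0 / T + 233.76 - 0.9297 * T
            + 1.417e-3 * T**2 - 8.292e-7 * T**3)


def bjerrum_length(T):
    """Bjerrum length λ_B = e²/(4π ε0 ε_r(T) k_B T) in nm."""
    return COULOMB_PREFACTOR / (dielectric_constant(T) * KB * T)


def debye_length(T, ionic_strength):
    """Debye screening length D = (8π λ_B n_s)^{−1/2} in nm.

    n_s is the salt number density of a monovalent electrolyte of the given
    ionic strength (mol/L).  Zero ionic strength returns ``inf`` (unscreened
    limit) rather than raising.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return float("inf")
    ns = ionic_strength * MOLAR_TO_PER_NM3
    return float(1.0 / np.sqrt(8.0 * np.pi * bjerrum_length(T) * ns))


@dataclass(frozen=True)
class ElectrostaticsContext:
    """Derived electrostatic quantities at fixed temperature and salt."""

    temperature: float
    ionic_strength: float
    dielectric: float
    bjerrum: float
    debye: float

    @classmethod
    def create(cls, temperature, ionic_strength):
        return cls(
            temperature=float(temperature),
            ionic_strength=float(ionic_strength),
            dielectric=float(dielectric_constant(temperature)),
            bjerrum=float(bjerrum_length(temperature)),
            debye=debye_length(temperature, ionic_strength),
        )

    @classmethod
    def from_conditions(cls, conditions: SolutionConditions):
        return cls.create(conditions.temperature, conditions.ionic_strength)


def dh_potential(r, q_i, q_j, ctx: ElectrostaticsContext, rc=4.0, shifted=True):
    """Debye–Hückel potential q_i q_j e²/(4π ε0 ε_r) exp(−r/D)/r, kJ/mol.

    shifted=True subtracts the value at rc and is zero beyond rc.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    coef = COULOMB_PREFACTOR / ctx.dielectric * q_i * q_j
    u = coef * np.exp(-r / ctx.debye) / r
    if shifted:
        u_rc = coef * np.exp(-rc / ctx.debye) / rc
        return np.where(r > rc, 0.0, u - u_rc)
    return u


def bond_potential(r, k=8033.0, r0=0.38):
    """Harmonic bond energy ½k(r−r0)²."""
    r = np.asarray(r, dtype=float)
    return 0.5 * k * (r - r0) ** 2


# ---------------------------------------------------------------------------
# system-level evaluation


def _ah_pairwise(r, sigma, lam, rc, eps, shifted):
    """Vectorized AH over pair arrays (r, sigma, lam all same shape, r ≤ rc)."""
    s6 = (sigma / r) ** 6
    ulj = 4.0 * eps * (s6 * s6 - s6)
    inner = r <= _RMIN_FACTOR * sigma
    if shifted:
        s6c = (sigma / rc) ** 6
        uljc = 4.0 * eps * (s6c * s6c - s6c)
        return np.where(inner, ulj - lam * uljc + (1.0 - lam) * eps,
                        lam * (ulj - uljc))
    return np.where(inner, ulj + (1.0 - lam) * eps, lam * ulj)


def minimum_image(delta, box):
    """Wrap displacement vectors to the nearest periodic image."""
    return delta - box * np.round(delta / box)


def _candidate_pairs_direct(n):
    return np.triu_indices(n, k=1)


def _candidate_pairs_cell(positions, box, cutoff):
    """Cell-list candidate pairs (superset of all pairs within cutoff)."""
    ncell = np.maximum((box // cutoff).astype(int), 1)
    if np.any(ncell < 3):
        return _candidate_pairs_direct(len(positions))
    frac = (positions / box) % 1.0
    cell = np.minimum((frac * ncell).astype(int), ncell - 1)
    flat = (cell[:, 0] * ncell[1] + cell[:, 1]) * ncell[2] + cell[:, 2]
    occupants: dict[int, list[int]] = {}
    for idx, c in enumerate(flat):
        occupants.setdefault(int(c), []).append(idx)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
    ii, jj = [], []
    for (cx, cy, cz), members in (
        ((int(k) // (ncell[1] * ncell[2]),
          (int(k) // ncell[2]) % ncell[1],
          int(k) % ncell[2]), v)
        for k, v in occupants.items()
    ):
        for dx, dy, dz in offsets:
            nk = (((cx + dx) % ncell[0]) * ncell[1] + (cy + dy) % ncell[1]) \
                * ncell[2] + (cz + dz) % ncell[2]
            other = occupants.get(int(nk))
            if other is None:
                continue
            for a in members:
                for b in other:
                    if a < b:
                        ii.append(a)
                        jj.append(b)
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    pairs = np.unique(np.stack([ii, jj], axis=1), axis=0)
    return pairs[:, 0], pairs[:, 1]


@dataclass
class EnergyBreakdown:
    """Energy decomposition in kJ/mol; per-chain nonionic attributes half of
    each pair energy to each participating chain."""

    bonded: float
    nonionic: float
    ionic: float
    per_chain_nonionic: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def total(self) -> float:
        return self.bonded + self.nonionic + self.ionic


def _pair_arrays(topology, params: ParameterSet, intra_only: bool = False):
    """Nonbonded pair indices (1–2 exclusions applied) and per-pair σ, λ.

    ``intra_only=True`` keeps only same-chain pairs — used to batch
    independent single-chain replicas in one system without cross-talk.
    """
    codes = topology.codes
    n = len(codes)
    i_idx, j_idx = _candidate_pairs_direct(n)
    if intra_only:
        same = topology.chain_index[i_idx] == topology.chain_index[j_idx]
        i_idx, j_idx = i_idx[same], j_idx[same]
    bonded = set(map(tuple, np.sort(np.asarray(topology.bonds).reshape(-1, 2),
                                    axis=1)))
    keep = np.fromiter(((a, b) not in bonded for a, b in zip(i_idx, j_idx)),
                       dtype=bool, count=len(i_idx))
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    sig = np.array([params[c].sigma for c in codes])
    lam = np.array([params[c].lambda_stickiness for c in codes])
    sigma_ij = 0.5 * (sig[i_idx] + sig[j_idx])
    lambda_ij = 0.5 * (lam[i_idx] + lam[j_idx])
    return i_idx, j_idx, sigma_ij, lambda_ij


def system_energy(
    positions,
    box,
    topology,
    params: ParameterSet,
    ctx: ElectrostaticsContext,
    shifted: bool = True,
    method: str = "direct",
    rc_nonionic: float | None = None,
) -> EnergyBreakdown:
    """Total bonded + nonionic (AH) + ionic (DH) energy of a configuration.

    Nonbonded terms run over all pairs under the minimum-image convention,
    excluding directly bonded (1–2) pairs.  ``method`` selects the pair
    search ("direct" double loop or "cell" lists); both give identical
    energies.  The box must accommodate both cutoffs (min side ≥ 2 rc).
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    rc_n = params.rc_nonionic if rc_nonionic is None else rc_nonionic
    rc_max = max(rc_n, params.rc_ionic)
    if np.min(box) < 2.0 * rc_max:
        raise ValueError(
            f"box {box} too small for minimum-image convention with rc={rc_max} nm"
        )
    codes = topology.codes
    n = len(codes)
    if method == "cell":
        ci, cj = _candidate_pairs_cell(positions, box, rc_max)
        bonded = set(map(tuple, np.sort(np.asarray(topology.bonds).reshape(-1, 2),
                                        axis=1)))
        keep = np.fromiter(((a, b) not in bonded for a, b in zip(ci, cj)),
                           dtype=bool, count=len(ci))
        i_idx, j_idx = ci[keep], cj[keep]
        sig = np.array([params[c].sigma for c in codes])
        lam = np.array([params[c].lambda_stickiness for c in codes])
        sigma_ij = 0.5 * (sig[i_idx] + sig[j_idx])
        lambda_ij = 0.5 * (lam[i_idx] + lam[j_idx])
    elif method == "direct":
        i_idx, j_idx, sigma_ij, lambda_ij = _pair_arrays(topology, params)
    else:
        raise ValueError(f"unknown pair-search method {method!r}")

    delta = minimum_image(positions[i_idx] - positions[j_idx], box)
    r = np.linalg.norm(delta, axis=1)

    # nonionic
    u_ah = np.zeros_like(r)
    within = r <= rc_n
    if np.any(within):
        u_ah[within] = _ah_pairwise(
            r[within], sigma_ij[within], lambda_ij[within],
            rc_n, params.epsilon, shifted,
        )
    nonionic = float(u_ah.sum())

    # ionic
    q = topology.charges
    qq = q[i_idx] * q[j_idx]
    charged = (qq != 0) & (r <= params.rc_ionic)
    ionic = 0.0
    if np.any(charged):
        coef = COULOMB_PREFACTOR / ctx.dielectric * qq[charged]
        u = coef * np.exp(-r[charged] / ctx.debye) / r[charged]
        if shifted:
            u = u - coef * np.exp(-params.rc_ionic / ctx.debye) / params.rc_ionic
        ionic = float(u.sum())

    # bonds
    bonds = np.asarray(topology.bonds)
    bonded_energy = 0.0
    if len(bonds):
        db = minimum_image(positions[bonds[:, 0]] - positions[bonds[:, 1]], box)
        rb = np.linalg.norm(db, axis=1)
        bonded_energy = float(bond_potential(rb, params.bond_k, params.bond_r0).sum())

    # per-chain nonionic attribution: half of each pair energy to each chain
    chain_idx = topology.chain_index
    per_chain = np.zeros(topology.n_chains)
    np.add.at(per_chain, chain_idx[i_idx], 0.5 * u_ah)
    np.add.at(per_chain, chain_idx[j_idx], 0.5 * u_ah)

    return EnergyBreakdown(
        bonded=bonded_energy, nonionic=nonionic, ionic=ionic,
        per_chain_nonionic=per_chain,
    )


def nonionic_energy_unshifted(positions, box, topology, params, rc):
    """Sum of bare (unshifted) AH pair energies over pairs with r ≤ rc.

    The cutoff-loss accounting used to compare nonionic energies between two
    cutoffs: U(rc_small) − U(rc_large) = −Σ_{rc_small < r ≤ rc_large} u(r).
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    i_idx, j_idx, sigma_ij, lambda_ij = _pair_arrays(topology, params)
    delta = minimum_image(positions[i_idx] - positions[j_idx], box)
    r = np.linalg.norm(delta, axis=1)
    within = r <= rc
    s6 = (sigma_ij[within] / r[within]) ** 6
    ulj = 4.0 * params.epsilon * (s6 * s6 - s6)
    inner = r[within] <= _RMIN_FACTOR * sigma_ij[within]
    lam = lambda_ij[within]
    u = np.where(inner, ulj + (1.0 - lam) * params.epsilon, lam * ulj)
    return float(u.sum())


class LinearizedAH:
    """Per-frame nonionic energy as an affine function of the λ table.

    Both AH branches are affine in the pair stickiness λ_ij, and λ_ij is
    linear in the 20-dim λ vector, so the total nonionic energy of a frame
    is U(λ) = A·(Mλ) + b with frame-independent composition matrix M.  The
    optimizer exploits this to reweight ensembles at arbitrary trial λ
    without touching coordinates again.
    """

    def __init__(self, topology, params: ParameterSet, rc: float | None = None,
                 shifted: bool = True):
        from .model_core import CANONICAL_RESIDUES

        self.rc = params.rc_nonionic if rc is None else rc
        self.eps = params.epsilon
        self.shifted = shifted
        codes = topology.codes
        i_idx, j_idx, sigma_ij, _ = _pair_arrays(topology, params)
        self._i, self._j, self._sigma = i_idx, j_idx, sigma_ij
        # pair types by unordered residue-code pair
        keys = [tuple(sorted((codes[a], codes[b]))) for a, b in zip(i_idx, j_idx)]
        self.types = sorted(set(keys))
        tindex = {t: k for k, t in enumerate(self.types)}
        self._type_of_pair = np.array([tindex[k] for k in keys])
        M = np.zeros((len(self.types), 20))
        col = {c: k for k, c in enumerate(CANONICAL_RESIDUES)}
        for t, (a, b) in enumerate(self.types):
            M[t, col[a]] += 0.5
            M[t, col[b]] += 0.5
        self.M = M
        self._topology = topology

    def decompose(self, positions_frames, box):
        """Return (A, b): A has shape (n_frames, n_types), b (n_frames,)."""
        frames = np.asarray(positions_frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        box = np.asarray(box, dtype=float)
        nF = len(frames)
        A = np.zeros((nF, len(self.types)))
        b = np.zeros(nF)
        sig = self._sigma
        rmin = _RMIN_FACTOR * sig
        s6c = (sig / self.rc) ** 6
        uljc = 4.0 * self.eps * (s6c * s6c - s6c)
        for f, pos in enumerate(frames):
            delta = minimum_image(pos[self._i] - pos[self._j], box)
            r = np.linalg.norm(delta, axis=1)
            within = r <= self.rc
            if not np.any(within):
                continue
            rw = r[within]
            sw = sig[within]
            tw = self._type_of_pair[within]
            s6 = (sw / rw) ** 6
            ulj = 4.0 * self.eps * (s6 * s6 - s6)
            inner = rw <= rmin[within]
            if self.shifted:
                a_coef = np.where(inner, -(uljc[within] + self.eps),
                                  ulj - uljc[within])
            else:
                a_coef = np.where(inner, -self.eps, ulj)
            b_coef = np.where(inner, ulj + self.eps, 0.0)
            np.add.at(A[f], tw, a_coef)
            b[f] += b_coef.sum()
        return A, b

    def energies(self, A, b, lambda_vector):
        """Nonionic energy per frame for a canonical-order 20-vector λ."""
        lam_t = self.M @ np.asarray(lambda_vector, dtype=float)
        return A @ lam_t + b
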