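"""Bayesian learning of the residue stickiness scale λ.

The 20 per-residue stickiness parameters are tuned against experimental
radii of gyration (and optionally PRE data) by an annealed stochastic
search.  Trial moves nudge five random residues; the cost of a trial set is
evaluated on the reference simulation ensemble by thermodynamic
reweighting, gated by the effective fraction of frames φ_eff, and accepted
by a Metropolis criterion with an annealed control parameter ξ.  A prior
built by kernel density estimation over published hydrophobicity scales
regularizes the search.

Cost function:  L(λ) = ⟨χ²_Rg(λ)⟩ + η ⟨χ²_PRE(λ)⟩ − θ ln P(λ)
with η = 0.1 and θ = 0.05; the angle brackets are means over the proteins
in each data class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KernelDensity

from .chain_analysis import ExperimentalRg, PREDataset, chi2_pre, chi2_rg
from .constants import KB
from .model_core import CANONICAL_RESIDUES

__all__ = [
    "HydrophobicityScale",
    "normalize_and_deduplicate",
    "PriorModel",
    "build_prior",
    "ReweightResult",
    "reweight",
    "CostResult",
    "cost",
    "propose",
    "xi_iterations",
    "Ensemble",
    "OptimizerConfig",
    "OptimizerResult",
    "optimize",
]

_CODE_INDEX = {c: k for k, c in enumerate(CANONICAL_RESIDUES)}

#: fallback log-prior when the KDE underflows to exactly zero density
_LOG_PRIOR_FLOOR = -1e4


@dataclass(frozen=True)
class HydrophobicityScale:
    """A literature hydropathy scale: raw per-residue values plus an
    orientation flag (reversed scales rank hydrophilic residues high)."""

    name: str
    values: dict[str, float]
    reversed: bool = False

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL_RESIDUES) - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {missing}")

    def vector(self) -> np.ndarray:
        return np.array([self.values[c] for c in CANONICAL_RESIDUES])


def normalize_and_deduplicate(
    scales: list[HydrophobicityScale],
) -> list[HydrophobicityScale]:
    """Min-max normalize each scale to [0, 1], flip reversed scales as
    1 − normalized, and drop exact duplicates (first occurrence kept).

    Affine transforms of one another collapse to the same normalized scale.
    Degenerate scales (all residues equal) raise.
    """
    out: list[HydrophobicityScale] = []
    seen: set[tuple] = set()
    for scale in scales:
        v = scale.vector()
        span = v.max() - v.min()
        if span == 0:
            raise ValueError(f"degenerate scale {scale.name!r}: zero range")
        norm = (v - v.min()) / span
        if scale.reversed:
            norm = 1.0 - norm
        key = tuple(np.round(norm, 9))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            HydrophobicityScale(
                name=scale.name,
                values=dict(zip(CANONICAL_RESIDUES, norm)),
                reversed=False,
            )
        )
    return out


def load_hydrophobicity_scales(path) -> list[HydrophobicityScale]:
    """Read a scale table from CSV: first column ``one_letter``, one column
    per scale.  Orientation is assumed pre-applied (reversed scales already
    flipped); pass the result through :func:`normalize_and_deduplicate`
    before building a prior."""
    import pandas as pd

    df = pd.read_csv(path).set_index("one_letter")
    return [
        HydrophobicityScale(name=col, values=df[col].to_dict())
        for col in df.columns
    ]


@dataclass
class PriorModel:
    """20-dimensional Gaussian KDE over normalized hydrophobicity scales."""

    training_points: np.ndarray
    bandwidth: float
    _kde: KernelDensity = field(repr=False, default=None)

    def log_density(self, lam: np.ndarray) -> float:
        """ln P(λ) for a canonical-order 20-vector; exact zeros are floored
        to a large-but-finite penalty with a warning."""
        val = float(self._kde.score_samples(np.asarray(lam)[None, :])[0])
        if not np.isfinite(val):
            warnings.warn("prior density underflow; applying finite floor",
                          RuntimeWarning, stacklevel=2)
            return _LOG_PRIOR_FLOOR
        return val

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        return self._kde.sample(n, random_state=seed)


def build_prior(
    scales: list[HydrophobicityScale], bandwidth: float = 0.05
) -> PriorModel:
    """Fit the λ prior: Gaussian KDE (bandwidth 0.05) over the scale vectors."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(scales) < 2:
        raise ValueError("need at least two scales for a prior")
    X = np.stack([s.vector() for s in scales])
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(X)
    return PriorModel(training_points=X, bandwidth=bandwidth, _kde=kde)


@dataclass
class ReweightResult:
    """Normalized frame weights and the effective fraction of frames
    φ_eff = exp[−Σ_i w_i ln(w_i N_frames)] ∈ (0, 1]."""

    weights: np.ndarray
    phi_eff: float


def reweight(u_ref, u_trial, temperature: float) -> ReweightResult:
    """Boltzmann reweighting from the reference λ to a trial λ.

    w_i ∝ exp{−[U(r_i, λ_trial) − U(r_i, λ_ref)]/k_B T} over the frames of
    the reference ensemble, normalized to sum to one.
    """
    u_ref = np.asarray(u_ref, dtype=float)
    u_trial = np.asarray(u_trial, dtype=float)
    if u_ref.shape != u_trial.shape:
        raise ValueError("energy series must cover the same frames")
    if not (np.all(np.isfinite(u_ref)) and np.all(np.isfinite(u_trial))):
        raise ValueError("non-finite energies")
    log_w = -(u_trial - u_ref) / (KB * temperature)
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()
    n = len(w)
    pos = w > 0
    phi = float(np.exp(-np.sum(w[pos] * np.log(w[pos] * n))))
    return ReweightResult(weights=w, phi_eff=phi)


@dataclass
class CostResult:
    total: float
    chi2_rg_mean: float
    chi2_pre_mean: float
    neg_log_prior: float      # −ln P(λ); the cost adds θ × this


def cost(
    lam: np.ndarray,
    chi2_rg_values,
    chi2_pre_values=(),
    prior: PriorModel | None = None,
    eta: float = 0.1,
    theta: float = 0.05,
) -> CostResult:
    """L(λ) = ⟨χ²_Rg⟩ + η⟨χ²_PRE⟩ − θ ln P(λ), components reported separately.

    ⟨·⟩ are uniform means over the proteins of each data class; an empty
    class contributes zero.  ``prior=None`` is the flat-prior limit.
    """
    rg_mean = float(np.mean(chi2_rg_values)) if len(chi2_rg_values) else 0.0
    pre_mean = float(np.mean(chi2_pre_values)) if len(chi2_pre_values) else 0.0
    nlp = -prior.log_density(np.asarray(lam)) if prior is not None else 0.0
    return CostResult(
        total=rg_mean + eta * pre_mean + theta * nlp,
        chi2_rg_mean=rg_mean,
        chi2_pre_mean=pre_mean,
        neg_log_prior=nlp,
    )


def propose(
    lam: np.ndarray,
    rng: np.random.Generator,
    n_perturb: int = 5,
    sd: float = 0.05,
    free_idx: np.ndarray | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Trial move: nudge a random selection of ``n_perturb`` distinct
    residues by N(0, sd) noise (sd = 0.05), others untouched; values are
    clipped to ``bounds``."""
    lam = np.asarray(lam, dtype=float)
    free = np.arange(len(lam)) if free_idx is None else np.asarray(free_idx)
    k = min(n_perturb, len(free))
    chosen = rng.choice(free, size=k, replace=False)
    trial = lam.copy()
    for idx in chosen:
        for _ in range(100):
            new = float(np.clip(lam[idx] + rng.normal(0.0, sd), *bounds))
            if new != lam[idx]:
                trial[idx] = new
                break
    return trial


def xi_iterations(xi0: float = 0.1, decay: float = 0.99,
                  xi_min: float = 1e-8) -> int:
    """Number of iterations in one annealing sweep (1604 for the defaults:
    0.1·0.99^k first drops below 1e-8 at k = 1604)."""
    return int(np.ceil(np.log(xi_min / xi0) / np.log(decay)))


# ---------------------------------------------------------------------------
# the annealed search


@dataclass
class Ensemble:
    """Reference ensemble of one protein for reweighted cost evaluation.

    ``A``/``b`` are the λ-linearized nonionic energy decomposition from
    :class:`cgidp.energetics.LinearizedAH` (``lin``); ``rg`` the per-frame
    radius of gyration; ``y_frames`` optional per-frame PRE observables of
    shape (n_frames, n_labels, n_residues).
    """

    rg: np.ndarray
    lin: object
    A: np.ndarray
    b: np.ndarray
    temperature: float
    rg_target: ExperimentalRg | None = None
    pre_target: PREDataset | None = None
    y_frames: np.ndarray | None = None

    def energies(self, lam: np.ndarray) -> np.ndarray:
        return self.lin.energies(self.A, self.b, lam)


@dataclass
class OptimizerConfig:
    eta: float = 0.1
    theta: float = 0.05
    xi0: float = 0.1
    xi_decay: float = 0.99
    xi_min: float = 1e-8
    n_microcycles: int = 10
    n_cycles: int = 2
    phi_eff_min: float = 0.6
    n_perturb: int = 5
    proposal_sd: float = 0.05
    free_residues: str | None = None   # e.g. "AGY" for a toy alphabet
    xi_reset_per_microcycle: bool = True
    seed: int = 0


@dataclass
class OptimizerResult:
    lambda_best: np.ndarray
    cost_best: float
    lambda_per_cycle: list
    cost_per_cycle: list
    history: list                      # per-iteration audit records

    def lambda_dict(self) -> dict[str, float]:
        return dict(zip(CANONICAL_RESIDUES, self.lambda_best))

    def dump_history(self, path) -> None:
        """Audit trail as JSON-lines."""
        with open(path, "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")


def _evaluate(lam, ensembles, prior, cfg):
    """Reweighted cost of a trial λ on the reference ensembles.

    Returns (CostResult, min φ_eff) or (None, φ_min) when gated.
    """
    weights = {}
    phi_min = 1.0
    for name, ens in ensembles.items():
        rw = reweight(ens._u_ref, ens.energies(lam), ens.temperature)
        weights[name] = rw.weights
        phi_min = min(phi_min, rw.phi_eff)
    if phi_min < cfg.phi_eff_min:
        return None, phi_min
    chi_rg, chi_pre = [], []
    for name, ens in ensembles.items():
        w = weights[name]
        if ens.rg_target is not None:
            chi_rg.append(chi2_rg(float(w @ ens.rg), ens.rg_target))
        if ens.pre_target is not None and ens.y_frames is not None:
            y = np.tensordot(w, ens.y_frames, axes=1)
            chi_pre.append(chi2_pre(y, ens.pre_target))
    return cost(lam, chi_rg, chi_pre, prior, cfg.eta, cfg.theta), phi_min


def optimize(
    lambda_init: np.ndarray,
    simulator_hook,
    config: OptimizerConfig,
    prior: PriorModel | None = None,
) -> OptimizerResult:
    """Annealed stochastic minimization of the reweighted cost.

    ``simulator_hook(lambda_vector)`` must return ``{name: Ensemble}``
    simulated at that λ.  Each cycle re-simulates at the current best λ and
    runs ``n_microcycles`` annealing sweeps; within a sweep ξ starts at
    ``xi0`` and decays by 1% per iteration until it drops below ``xi_min``.
    Trial sets whose effective fraction of frames falls below
    ``phi_eff_min`` (60%) are discarded before cost evaluation; otherwise
    acceptance follows min{1, exp[(L(λ_{k−1}) − L(λ_k))/ξ_k]}.  The λ with
    the lowest recorded cost is returned, with a full audit trail.
    """
    rng = np.random.default_rng(config.seed)
    lam_ref = np.asarray(lambda_init, dtype=float).copy()
    free_idx = None
    if config.free_residues is not None:
        free_idx = np.array([_CODE_INDEX[c] for c in config.free_residues])
    history: list[dict] = []
    lambda_per_cycle, cost_per_cycle = [], []
    best_overall = (np.inf, lam_ref.copy())

    for cycle in range(config.n_cycles):
        ensembles = simulator_hook(lam_ref)
        for ens in ensembles.values():
            ens._u_ref = ens.energies(lam_ref)
        res, _ = _evaluate(lam_ref, ensembles, prior, config)
        current_lam, current_cost = lam_ref.copy(), res.total
        best_cycle = (current_cost, current_lam.copy())
        xi = config.xi0
        for micro in range(config.n_microcycles):
            if config.xi_reset_per_microcycle or micro == 0:
                xi = config.xi0
            it = 0
            while xi >= config.xi_min:
                trial = propose(current_lam, rng, config.n_perturb,
                                config.proposal_sd, free_idx)
                res, phi_min = _evaluate(trial, ensembles, prior, config)
                gated = res is None
                accepted = False
                if not gated:
                    dL = current_cost - res.total
                    if dL >= 0 or rng.random() < np.exp(dL / xi):
                        accepted = True
                        current_lam = trial
                        current_cost = res.total
                        if current_cost < best_cycle[0]:
                            best_cycle = (current_cost, current_lam.copy())
                history.append({
                    "cycle": cycle, "micro": micro, "iter": it,
                    "xi": xi, "phi_min": phi_min, "gated": gated,
                    "accepted": accepted,
                    "cost": None if gated else res.total,
                })
                xi *= config.xi_decay
                it += 1
        lambda_per_cycle.append(best_cycle[1].copy())
        cost_per_cycle.append(best_cycle[0])
        if best_cycle[0] < best_overall[0]:
            best_overall = (best_cycle[0], best_cycle[1].copy())
        lam_ref = best_cycle[1].copy()

    return OptimizerResult(
        lambda_best=best_overall[1],
        cost_best=best_overall[0],
        lambda_per_cycle=lambda_per_cycle,
        cost_per_cycle=cost_per_cycle,
        history=history,
    )
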