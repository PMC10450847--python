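"""Single-chain observables: radius of gyration, autocorrelation, blocking
errors and χ² terms against experimental data.

The ensemble average of the radius of gyration is reported both as the mean
⟨Rg⟩ and as the root-mean-square √⟨Rg²⟩; the rms is systematically the
larger of the two (Jensen), which matters when comparing models calibrated
against one or the other convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "unwrap_chain",
    "radius_of_gyration",
    "rg_series",
    "ensemble_rg",
    "ExperimentalRg",
    "chi2_rg",
    "PREDataset",
    "chi2_pre",
    "acf",
    "blocking_error",
]


def unwrap_chain(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping along a linear chain.

    Walks the chain bead-by-bead keeping each consecutive displacement at
    its minimum image, so an intact (bond-length ≪ box) chain becomes
    contiguous in space.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    out = positions.copy()
    deltas = np.diff(positions, axis=0)
    deltas -= box * np.round(deltas / box)
    out[1:] = out[0] + np.cumsum(deltas, axis=0)
    return out


def radius_of_gyration(
    positions: np.ndarray,
    masses: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> float:
    """Radius of gyration of one frame, nm.

    Mass-weighted rms distance from the center of mass by default; pass
    ``masses=None``-equivalent uniform weights explicitly with
    ``np.ones(n)`` if unweighted Rg is wanted.  If ``box`` is given the
    chain is unwrapped across periodic boundaries first.
    """
    positions = np.asarray(positions, dtype=float)
    if box is not None:
        positions = unwrap_chain(positions, box)
    n = len(positions)
    w = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    w = w / w.sum()
    com = w @ positions
    d2 = np.sum((positions - com) ** 2, axis=1)
    return float(np.sqrt(w @ d2))


def rg_series(trajectory, topology=None, masses=None, chain: int = 0) -> np.ndarray:
    """Per-frame Rg of one chain of a trajectory."""
    if topology is not None:
        sel = topology.chain_index == chain
        if masses is None:
            masses = topology.masses[sel]
    else:
        sel = slice(None)
    return np.array([
        radius_of_gyration(frame[sel], masses, box=trajectory.box)
        for frame in trajectory.frames
    ])


def ensemble_rg(series) -> tuple[float, float]:
    """(⟨Rg⟩, √⟨Rg²⟩).  The rms is always ≥ the mean."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty Rg series")
    return float(series.mean()), float(np.sqrt(np.mean(series**2)))


@dataclass(frozen=True)
class ExperimentalRg:
    """An experimental radius of gyration with its uncertainty, nm."""

    value: float
    sigma_exp: float

    def __post_init__(self) -> None:
        if self.sigma_exp <= 0:
            raise ValueError("sigma_exp must be positive")


def chi2_rg(calc: float, exp: ExperimentalRg) -> float:
    """Squared standardized residual [(Rg_exp − Rg_calc)/σ_exp]²."""
    return float(((exp.value - calc) / exp.sigma_exp) ** 2)


@dataclass
class PREDataset:
    """Paramagnetic relaxation enhancement data: label × residue matrices.

    ``values``/``sigma`` have shape (n_labels, n_residues); missing entries
    are NaN in ``values`` and are excluded from χ² (the normalization then
    uses the count of observed entries).  ``observable_kind`` is "rates" or
    "intensity_ratios"; spectrometer frequency is metadata only.
    """

    observable_kind: str
    values: np.ndarray
    sigma: np.ndarray
    spectrometer_frequency: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.values.shape != self.sigma.shape:
            raise ValueError("values and sigma must have matching shapes")
        observed = ~np.isnan(self.values)
        if np.any(self.sigma[observed] <= 0):
            raise ValueError("sigma must be positive where values are defined")

    @property
    def n_labels(self) -> int:
        return self.values.shape[0]


def chi2_pre(y_calc: np.ndarray, dataset: PREDataset) -> float:
    """Mean squared standardized residual over observed PRE entries:
    (1 / N_obs) Σ_j Σ_i [(Y_ij_exp − Y_ij_calc)/σ_ij]²."""
    y_calc = np.asarray(y_calc, dtype=float)
    if y_calc.shape != dataset.values.shape:
        raise ValueError(
            f"shape mismatch: calc {y_calc.shape} vs data {dataset.values.shape}"
        )
    mask = ~np.isnan(dataset.values)
    if not np.any(mask):
        raise ValueError("PRE dataset has no observed entries")
    res = (dataset.values[mask] - y_calc[mask]) / dataset.sigma[mask]
    return float(np.mean(res**2))


def acf(series, lag: int) -> float:
    """Normalized autocorrelation of a scalar series at one lag.

    Uses the standard estimator with the global mean and variance.  A
    constant series has undefined autocorrelation and raises ValueError.
    """
    x = np.asarray(series, dtype=float)
    if not 0 <= lag < len(x):
        raise ValueError("lag must satisfy 0 <= lag < len(series)")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    if lag == 0:
        return 1.0
    return float(np.dot(x[:-lag], x[lag:]) / var)


def blocking_error(series, return_levels: bool = False):
    """Standard error of the mean by the blocking (block-transform) method.

    Repeatedly averages pairs of neighbours; at each level the naive error
    estimate of the blocked series is recorded with its statistical
    uncertainty.  The reported error is the first level whose estimate is
    consistent (within combined uncertainties) with the next two levels —
    the plateau — falling back to the maximum over levels when no plateau
    is found (conservative for strongly correlated data).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("series too short for blocking (need >= 8 points)")
    if np.allclose(x, x[0]):
        return (0.0, []) if return_levels else 0.0
    estimates: list[tuple[float, float]] = []
    while len(x) >= 4:
        nb = len(x)
        var = x.var(ddof=1)
        se = np.sqrt(var / nb)
        dse = se / np.sqrt(2.0 * (nb - 1))
        estimates.append((se, dse))
        if nb % 2 == 1:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    chosen = None
    for k in range(len(estimates) - 2):
        se, dse = estimates[k]
        ok = True
        for se2, dse2 in estimates[k + 1:k + 3]:
            if abs(se2 - se) > 2.0 * np.hypot(dse, dse2):
                ok = False
                break
        if ok:
            chosen = se
            break
    if chosen is None:
        chosen = max(se for se, _ in estimates)
    if return_levels:
        return float(chosen), estimates
    return float(chosen)
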