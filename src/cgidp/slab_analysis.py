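"""Direct-coexistence (slab) trajectory analysis.

A slab simulation holds a protein-rich condensate in equilibrium with its
dilute phase in an elongated periodic box.  The pipeline is: center the
condensate at z = 0 in every frame, accumulate the time-averaged mass
density profile ρ(z), fit each semi-profile to
ρ(z) = (ρ_a + ρ_b)/2 + (ρ_b − ρ_a)/2 · tanh[(|z| − z_DS)/t],
and read the phase concentrations from the plateau regions
|z| < z_DS − t/2 (condensate) and |z| > z_DS + 6t (dilute phase).

Profiles are mass concentrations in mg/mL; phase concentrations are
converted to molar units with the chain molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import DA_PER_NM3_TO_MG_PER_ML
from .energetics import nonionic_energy_unshifted

__all__ = [
    "center_slab",
    "DensityProfile",
    "density_profile",
    "TanhFit",
    "fit_tanh_profile",
    "PhaseDensities",
    "phase_concentrations",
    "cutoff_energy_difference",
]


def _center_shift(z, masses, Lz, nbins=100):
    """Periodic shift (nm) that brings the densest window to the box center.

    Maximizes the mass inside a circular window of width Lz/2 on a coarse
    profile; robust to dilute-phase noise and to slabs wrapped across the
    boundary.  Within the best window the circular center of mass provides
    sub-bin refinement.
    """
    hist, edges = np.histogram(z % Lz, bins=nbins, range=(0.0, Lz),
                               weights=masses)
    half = nbins // 2
    kernel = np.zeros(nbins)
    kernel[:half] = 1.0
    kernel = np.roll(kernel, -half // 2)  # window centered on bin 0
    # circular correlation: mass in window centered at each bin
    wsum = np.real(np.fft.ifft(np.fft.fft(hist) * np.conj(np.fft.fft(kernel))))
    c = int(np.argmax(wsum))
    centers = (edges[:-1] + edges[1:]) / 2.0
    # circular center-of-mass of the best window
    rel = np.arange(nbins) - c
    rel = (rel + nbins // 2) % nbins - nbins // 2
    inwin = np.abs(rel) <= half // 2
    m = hist[inwin]
    if m.sum() > 0:
        offset = float(np.sum(rel[inwin] * m) / m.sum()) * (Lz / nbins)
    else:
        offset = 0.0
    return Lz / 2.0 - (centers[c] + offset)


def center_slab(trajectory, masses, nbins: int = 100):
    """Return a copy of the trajectory with the condensate centered.

    Applies a per-frame circular shift along z so the densest region sits
    at the middle of the box; idempotent up to the coarse-bin resolution.
    """
    from .simulator import Trajectory

    masses = np.asarray(masses, dtype=float)
    Lz = trajectory.box[2]
    frames = trajectory.frames.copy()
    for f in range(len(frames)):
        shift = _center_shift(frames[f][:, 2], masses, Lz, nbins=nbins)
        frames[f][:, 2] = (frames[f][:, 2] + shift) % Lz
    return Trajectory(frames=frames, box=trajectory.box.copy(),
                      frame_interval=trajectory.frame_interval,
                      kinetic_energies=trajectory.kinetic_energies)


@dataclass
class DensityProfile:
    """Time-averaged mass-density profile ρ(z).

    ``z_centers`` are bin centers relative to the box middle (nm);
    ``density`` is in mg/mL.  ``per_frame`` holds the per-frame histograms
    (same units) for block-error estimation.
    """

    z_centers: np.ndarray
    density: np.ndarray
    n_frames_averaged: int
    bin_width: float
    cross_section: float       # Lx*Ly, nm^2
    per_frame: np.ndarray | None = None

    def total_mass(self, frame: int | None = None) -> float:
        """Mass (Da) represented by the profile (per frame if given)."""
        rho = self.density if frame is None else self.per_frame[frame]
        volume = self.bin_width * self.cross_section
        return float(rho.sum() * volume / DA_PER_NM3_TO_MG_PER_ML)


def density_profile(trajectory, masses, bin_width: float = 1.0,
                    keep_frames: bool = True) -> DensityProfile:
    """Histogram bead masses along z, averaged over frames, in mg/mL."""
    masses = np.asarray(masses, dtype=float)
    Lz = float(trajectory.box[2])
    nbins = max(int(round(Lz / bin_width)), 1)
    width = Lz / nbins
    area = float(trajectory.box[0] * trajectory.box[1])
    volume = width * area
    per_frame = np.empty((trajectory.n_frames, nbins))
    for f, frame in enumerate(trajectory.frames):
        hist, edges = np.histogram(frame[:, 2] % Lz, bins=nbins,
                                   range=(0.0, Lz), weights=masses)
        per_frame[f] = hist / volume * DA_PER_NM3_TO_MG_PER_ML
    centers = (edges[:-1] + edges[1:]) / 2.0 - Lz / 2.0
    return DensityProfile(
        z_centers=centers,
        density=per_frame.mean(axis=0),
        n_frames_averaged=trajectory.n_frames,
        bin_width=width,
        cross_section=area,
        per_frame=per_frame if keep_frames else None,
    )


def tanh_profile(z, rho_a, rho_b, z_ds, t):
    """Interface model: ρ_a condensate plateau, ρ_b dilute plateau."""
    return (rho_a + rho_b) / 2.0 + (rho_b - rho_a) / 2.0 * np.tanh(
        (np.abs(z) - z_ds) / t
    )


@dataclass
class TanhFit:
    """Fitted interface parameters (side-averaged) with uncertainties."""

    rho_dense: float
    rho_dilute: float
    z_interface: float
    width: float
    phase_separated: bool
    per_side: dict = field(default_factory=dict)
    uncertainties: dict = field(default_factory=dict)


def _fit_semi(z, rho, z_max):
    order = np.argsort(z)
    z, rho = z[order], rho[order]
    rho_a0 = float(np.percentile(rho, 98))
    rho_b0 = max(float(np.percentile(rho, 5)), 0.0)
    half = (rho_a0 + rho_b0) / 2.0
    below = np.nonzero(rho < half)[0]
    z_ds0 = float(z[below[0]]) if len(below) else z_max / 4.0
    p0 = [rho_a0, rho_b0, max(z_ds0, 1e-2), max(2.0 * (z[1] - z[0]), 1e-2)]
    bounds = ([0.0, 0.0, 0.0, 1e-4], [np.inf, np.inf, z_max, z_max])
    popt, pcov = curve_fit(tanh_profile, z, rho, p0=p0, bounds=bounds,
                           maxfev=20000)
    return popt, np.sqrt(np.diag(pcov))


def fit_tanh_profile(profile: DensityProfile, min_contrast: float = 1.5) -> TanhFit:
    """Least-squares tanh fit of each semi-profile (z > 0 and z < 0).

    Parameters are averaged over the two sides; uncertainties are
    covariance-based, combined in quadrature.  If the fit does not converge
    or the plateau contrast ρ_a/ρ_b falls below ``min_contrast`` the
    outcome is flagged as "no phase separation" rather than raising.
    """
    z, rho = profile.z_centers, profile.density
    if len(z) < 40:
        raise ValueError("profile too coarse: need >= 20 bins per side")
    z_max = float(np.max(np.abs(z)))
    sides = []
    errs = []
    try:
        for mask in (z > 0, z < 0):
            popt, perr = _fit_semi(np.abs(z[mask]), rho[mask], z_max)
            sides.append(popt)
            errs.append(perr)
    except (RuntimeError, ValueError):
        flat = float(np.mean(rho))
        return TanhFit(rho_dense=flat, rho_dilute=flat, z_interface=0.0,
                       width=0.0, phase_separated=False)
    mean = np.mean(sides, axis=0)
    err = np.sqrt(np.sum(np.square(errs), axis=0)) / len(errs)
    rho_a, rho_b, z_ds, t = (float(v) for v in mean)
    separated = rho_a > min_contrast * max(rho_b, 1e-12) and rho_a > rho_b
    return TanhFit(
        rho_dense=rho_a, rho_dilute=rho_b, z_interface=z_ds, width=t,
        phase_separated=separated,
        per_side={"z>0": sides[0], "z<0": sides[1]},
        uncertainties=dict(zip(("rho_dense", "rho_dilute", "z_interface",
                                "width"), (float(e) for e in err))),
    )


@dataclass
class PhaseDensities:
    """Coexisting phase concentrations.

    c_sat (dilute phase) and c_con (condensate) in mM; errors are blocking
    standard errors over per-frame region averages when per-frame profiles
    are available.  ``dilute_empty`` flags a c_sat of exactly zero coming
    from an empty dilute region.
    """

    c_sat: float
    c_con: float
    c_sat_err: float = float("nan")
    c_con_err: float = float("nan")
    dilute_empty: bool = False

    @property
    def c_sat_uM(self) -> float:
        return self.c_sat * 1e3


def _region_stats(profile, mask, chain_mass):
    to_mM = 1e3 / chain_mass  # mg/mL = g/L -> mM
    mean = float(profile.density[mask].mean()) * to_mM
    err = float("nan")
    if profile.per_frame is not None and profile.n_frames_averaged >= 8:
        from .chain_analysis import blocking_error

        series = profile.per_frame[:, mask].mean(axis=1) * to_mM
        err = blocking_error(series)
    return mean, err


def phase_concentrations(profile: DensityProfile, fit: TanhFit,
                         chain_mass: float) -> PhaseDensities:
    """Phase concentrations from the plateau regions of a fitted profile.

    The central region |z| < z_DS − t/2 is assigned to the condensate and
    the far region |z| > z_DS + 6t to the dilute phase (the slab is
    central by construction).  Mass density is converted to molarity with
    the chain molecular weight (Da).
    """
    z = profile.z_centers
    dense_mask = np.abs(z) < fit.z_interface - fit.width / 2.0
    dilute_mask = np.abs(z) > fit.z_interface + 6.0 * fit.width
    if not np.any(dense_mask):
        raise ValueError("empty condensate region; fit too narrow")
    c_con, c_con_err = _region_stats(profile, dense_mask, chain_mass)
    if not np.any(dilute_mask) or profile.density[dilute_mask].sum() == 0:
        return PhaseDensities(c_sat=0.0, c_con=c_con, c_con_err=c_con_err,
                              dilute_empty=True)
    c_sat, c_sat_err = _region_stats(profile, dilute_mask, chain_mass)
    return PhaseDensities(c_sat=c_sat, c_con=c_con,
                          c_sat_err=c_sat_err, c_con_err=c_con_err)


def cutoff_energy_difference(trajectory, topology, params, rc_small: float,
                             rc_large: float) -> tuple[float, float]:
    """Per-protein nonionic energy gained by shortening the cutoff.

    Returns the mean and standard deviation over frames of
    [U_nonionic(rc_small) − U_nonionic(rc_large)] / n_chains with bare
    (unshifted) pair accounting — the energy of the pair interactions a
    shorter cutoff ignores, a positive number for attractive tails.
    """
    per_frame = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.frames):
        u_small = nonionic_energy_unshifted(frame, trajectory.box, topology,
                                            params, rc_small)
        u_large = nonionic_energy_unshifted(frame, trajectory.box, topology,
                                            params, rc_large)
        per_frame[f] = (u_small - u_large) / topology.n_chains
    return float(per_frame.mean()), float(per_frame.std())
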