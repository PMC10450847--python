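# Methods

This note documents the model, the numerical choices, and what the test
fixtures do and do not probe. Units throughout: nm, kJ/mol, Da, ps, K,
elementary charges; this unit system is closed under Newton's equations
(1 kJ mol⁻¹ / 1 g mol⁻¹ = 1 nm² ps⁻²).

## Model and parameters

One bead per residue. Per-residue parameters live in packaged CSV tables
(`data/residues_calvados{1,2}.csv`, schema `one_letter, lambda, sigma_nm,
charge, mass_Da, pKa`, sha256-checksummed sidecars): stickiness λ, bead
diameter σ from van-der-Waals volumes, formal charge, residue mass, and a
pKa only for histidine (6.0). The two packaged variants are transcriptions
of the published CALVADOS 1 (M1) and CALVADOS 2 stickiness scales; they
are run with nonionic cutoffs of 4 and 2 nm respectively, which is part of
the model definition, not a numerical convenience. The loader refuses
incomplete or out-of-range tables rather than imputing.

Potentials:

- Harmonic bonds, ½k(r−r0)², k = 8033 kJ mol⁻¹ nm⁻², r0 = 0.38 nm.
- Ashbaugh–Hatch nonionic pair potential, truncated and shifted at rc,
  with ε = 0.8368 kJ/mol multiplying the Lennard-Jones bracket and the
  inner-branch constant written as (1−λ)ε. (Some typeset forms of this
  potential drop ε from both places; restoring it is required for
  dimensional consistency and reproduces the printed pair-energy values,
  e.g. W–W at 2 nm = −5 J/mol.)
- Debye–Hückel electrostatics with the empirical ε_r(T) polynomial for
  liquid water (validated 250–400 K; outside that range the code refuses),
  Bjerrum length λ_B = e²/(4πε0 ε_r k_B T), Debye length from the salt
  number density of a monovalent electrolyte (I = c_s). Always truncated
  and shifted at rc_ionic = 4 nm regardless of the nonionic cutoff; a 6 nm
  setting is available for low-salt sensitivity studies. Zero ionic
  strength returns an infinite Debye length (unscreened limit) rather than
  an error.
- 1–2 (directly bonded) pairs are excluded from all nonbonded terms.

Terminal ionization is not part of the residue tables; by default the
first bead of each chain carries +1 and the last −1 (standard practice for
this model family near neutral pH). A `ParameterSet.termini_charges` flag
disables this for the strict bare-residue reading. Chain masses add H to
the N-terminal bead and OH to the C-terminal bead so the chain mass equals
the peptide molecular weight.

## Energy evaluation

`system_energy` sums bonds, AH and DH terms under the minimum-image
convention and refuses boxes smaller than twice the largest cutoff. Pair
search is either a direct double loop or cell lists; both routes are
required (and tested) to agree to 1e-9 relative. Per-chain nonionic
energies attribute half of each pair energy to each participating chain,
so they sum exactly to the total. Cutoff-difference accounting
(`cutoff_energy_difference`) uses bare (unshifted) pair energies: the
difference U(rc_small) − U(rc_large) is minus the sum of bare pair
energies in the shell rc_small < r ≤ rc_large, which is what "energy
ignored by the shorter cutoff" means physically.

Because both AH branches are affine in the pair λ and pair λ is linear in
the 20-vector of residue stickiness, a frame's nonionic energy is
U(λ) = A·(Mλ) + b with coordinate-independent M. `LinearizedAH`
precomputes (A, b) per frame so the optimizer can reweight ensembles at
arbitrary trial λ without revisiting coordinates.

## Sampling

Langevin NVT dynamics with BAOAB splitting, default 10 fs timestep and
0.01 ps⁻¹ friction. Two engines share one contract: a pure-NumPy
reference and a numba-compiled accelerated engine. They consume the
identical noise stream, so short trajectories agree to floating-point
reordering; each is bitwise-reproducible for a fixed seed. Overlapping
beads (r < 1e-4 nm) abort with the offending pair identified.

Single chains start fully extended in a cubic box of side 0.38(N−1)+4 nm;
frames are saved every 3N² fs for N > 100 and every 30 ps otherwise, 600
frames per replica, ten replicas, the first 100 frames of each discarded —
5000 retained conformations per protein. Replicas are batched as chains
whose nonbonded pair list is restricted to intra-chain pairs: they share
one integrator call and one noise stream but are exactly mutually
invisible, which is what independent replicas mean; this is purely a
throughput device.

Slab systems place n_chains extended chains along z with middle beads at
seeded random xy positions pairwise > 0.7 nm apart; boxes default to
[15, 15, 150] nm with [17, 17, 300] and [25, 25, 300] selectable for long
chains (a chain longer than Lz is refused).

Two distributional checks define "sampling correctness" here: the bond
length of a harmonic dimer must follow p(r) ∝ r² exp(−βu_bond) (two-sample
KS test against direct rejection sampling), and kinetic energy per degree
of freedom must equal k_BT/2 within 2 blocking standard errors. These
tests run at thermostat friction 1–5 ps⁻¹: at the production value of
0.01 ps⁻¹ the kinetic energy inherits a slowly-relaxing component from the
near-conserved total energy and its correlation time exceeds any desk-scale
budget. The stationary distribution does not depend on the friction, so
the stronger coupling changes nothing about what is being verified. At
10 fs the splitting also carries a small O(Δt²) kinetic-temperature bias
(≈0.5–1% for the stiffest bond modes); configurational averages, which are
what the model predicts, are substantially more accurate than that.

## Slab analysis

Per frame, the condensate is centered by maximizing the mass inside a
circular window of width Lz/2 on a coarse (100-bin) profile, refined by
the circular center of mass of the best window. (The published protocol
cites an earlier description for this step; the estimator here is our own
choice of gauge fixing and is robust to dilute-phase noise and to slabs
wrapped across the boundary.) Density profiles are mass histograms in
1 nm bins (configurable), in mg/mL. Interface parameters come from
least-squares tanh fits of the two semi-profiles, averaged; uncertainties
are covariance-based. Non-convergent fits or plateau contrast below 1.5×
yield an explicit "no phase separation" outcome rather than an exception.

Phase concentrations: the central region |z| < z_DS − t/2 is the
condensate and |z| > z_DS + 6t the dilute phase. (The source text pairs
the labels the other way around, which inverts the physical geometry of a
central slab; we assign the regions physically.) Mass densities convert
to molar units via the chain molecular weight; uncertainties are blocking
errors over per-frame region means.

## Optimizer

Cost L(λ) = ⟨χ²_Rg⟩ + η⟨χ²_PRE⟩ − θ ln P(λ), η = 0.1, θ = 0.05, with
uniform means over the proteins of each data class. χ²_Rg uses the
ensemble-average ⟨Rg⟩ (not the rms). χ²_PRE normalizes by the count of
observed matrix entries so datasets with gaps are handled consistently.
The PRE forward model is a pluggable interface consuming per-frame
observables; no default implementation ships.

The prior is a Gaussian KDE (bandwidth 0.05) over min-max-normalized
hydrophobicity scales, reversed scales flipped as 1 − normalized, exact
duplicates removed. The published prior uses 70 literature scales whose
numeric values live in the cited compilation and are not redistributable
from here; the packaged `synthetic_hydrophobicity_scales.csv` is a
synthetic stand-in (generated by `generate_synthetic_scales`, labelled as
such) that exercises the identical code path. A KDE underflow to zero
density maps to a large-but-finite penalty with a warning.

Search: trial moves nudge 5 random residues by N(0, 0.05); reweighting
w_i ∝ exp[−ΔU_i/k_BT] uses each protein's own training temperature and the
nonionic energy only (electrostatics are λ-independent and cancel); trials
with min-over-proteins φ_eff < 60% are discarded before cost evaluation;
acceptance is Metropolis with control parameter ξ starting at 0.1 and
decaying by 1% per iteration until ξ < 1e-8 (1604 iterations per sweep),
ten sweeps per cycle with ξ reset at each sweep (a config flag spans ξ
across the cycle instead, since the protocol text admits both readings);
each new cycle re-simulates at the best λ so far. φ_eff uses normalized
weights, exp[−Σ w_i ln(w_i N)], which is 1 exactly at uniformity and 1/N
at single-frame support — the two identities the tests pin. λ proposals
are clipped to [0, 1].

## Synthetic study problems

The toy recovery study (`make_toy_recovery_problem`) checks that the full
loop — simulate, reweight, anneal, re-simulate — can find a known ground
truth. Defaults: three-letter alphabet F/M/Y (large, λ-responsive beads;
small beads like alanine barely move a short chain's Rg), 16-mers, three
homopolymers plus one mixed sequence, uncharged variant, 288 K, friction
0.2 ps⁻¹, frames every 1 ps, 10 replicas × 600 frames with 100 discarded
(5000 pooled conformations), ground truth λ* = (0.40, 0.55, 0.60) around
the λ0 = 0.5 start, pseudo-experimental σ = 0.01 nm. Three cycles recover
λ* to a few hundredths per coordinate, well inside the 0.1 tolerance the
recovery test asserts. What this shows: the estimator machinery is
consistent. What it does not show: transferability of a learned scale to
real sequences, which requires the full 55-protein training set and
cluster-scale sampling.

Other fixtures: tanh density profiles with seeded multiplicative noise
(fit-bias Monte Carlo), Poisson bead realizations of two-plateau slabs
(centering/profile/phase tests at exactly known densities), and AR(1)
series with known marginal variance and lag-1 correlation (ACF and
blocking-error oracles; blocking is Flyvbjerg-style pair averaging with a
plateau rule — first level consistent with the next two within combined
uncertainties, falling back to the maximum over levels).

## Known limitations

- The cutoff-effect results at trajectory scale (percent-level ⟨Rg⟩ shifts
  between rc = 2 and 4 nm; the ~13 kJ/mol per-protein slab energy
  difference) require hours of sampling on many cores; the tests cover the
  accounting exactly on small fixtures instead.
- The packaged λ tables are transcriptions of the published scales; see
  the repository history for their provenance. Mean-hydropathy spot
  checks against printed reference values agree for hnRNPA1 LCD (0.61,
  both variants) and Tau 2N4R (0.38, CALVADOS 2); α-synuclein computes to
  0.315 (CALVADOS 1) / 0.341 (CALVADOS 2) against a printed 0.33.
- No NPT, no explicit ions, no Ewald electrostatics, no hydrodynamics;
  folded domains and post-translational modifications are out of scope.
- c_sat from a single slab geometry carries finite-size effects that this
  package does not attempt to extrapolate away.
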