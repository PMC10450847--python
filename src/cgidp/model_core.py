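"""Residue parameter tables, sequences and model-variant definitions.

A model variant (:class:`ParameterSet`) bundles the per-residue stickiness
scale λ, bead diameters σ (from van-der-Waals volumes), formal charges,
residue masses, and the global energy/bond/cutoff constants of the
one-bead-per-residue model.  Two published variants are packaged:
``CALVADOS1`` (run with a 4 nm nonionic cutoff) and ``CALVADOS2`` (run with
a 2 nm cutoff); custom tables can be loaded from CSV with the same schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CANONICAL_RESIDUES",
    "AminoAcidParams",
    "ParameterSet",
    "SolutionConditions",
    "ProteinSpec",
    "residue_charge",
    "chain_charges",
    "mean_hydropathy",
    "chain_mass",
    "pair_params",
    "load_parameter_set",
    "write_parameter_set",
    "load_calvados",
    "load_sequences",
    "packaged_sequences",
    "packaged_table",
]

#: Canonical one-letter codes in fixed order; this order defines the layout
#: of every 20-vector in the package (e.g. the λ vector of the optimizer).
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class UnknownResidueError(KeyError):
    """Raised when a sequence contains a symbol absent from the table."""


@dataclass(frozen=True)
class AminoAcidParams:
    """Parameters of one amino-acid bead.

    lambda_stickiness is the dimensionless hydropathy scaling the attractive
    tail of the nonionic potential; sigma the bead diameter in nm;
    ref_charge the formal charge at neutral pH; mass the residue mass in Da.
    pKa is set only for titratable histidine (value 6).
    """

    code: str
    lambda_stickiness: float
    sigma: float
    ref_charge: int
    mass: float
    pKa: float | None = None

    def __post_init__(self) -> None:
        if not (-0.2 <= self.lambda_stickiness <= 1.2) or not np.isfinite(
            self.lambda_stickiness
        ):
            raise ValueError(
                f"lambda for {self.code!r} out of range: {self.lambda_stickiness}"
            )
        if not (0.2 < self.sigma < 1.0):
            raise ValueError(f"sigma for {self.code!r} out of range: {self.sigma}")
        if self.mass <= 0:
            raise ValueError(f"mass for {self.code!r} must be positive")


@dataclass(frozen=True)
class SolutionConditions:
    """Temperature (K), ionic strength (M, monovalent salt) and pH."""

    temperature: float
    ionic_strength: float
    pH: float = 7.0

    def __post_init__(self) -> None:
        if not (250.0 < self.temperature < 400.0):
            raise ValueError(f"temperature out of range: {self.temperature} K")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH out of range: {self.pH}")


@dataclass(frozen=True)
class ProteinSpec:
    """A named sequence with its solution conditions."""

    name: str
    sequence: str
    conditions: SolutionConditions | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - set(CANONICAL_RESIDUES)
        if bad:
            raise UnknownResidueError(
                f"{self.name}: non-canonical residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ParameterSet:
    """A complete model variant.

    epsilon is the Ashbaugh–Hatch energy scale (kJ/mol); bond_k and bond_r0
    the harmonic-bond force constant (kJ mol^-1 nm^-2) and rest length (nm);
    rc_nonionic/rc_ionic the nonionic and electrostatic cutoffs (nm).
    termini_charges=True adds +1 e to the first bead and −1 e to the last
    bead of each chain (standard for this model family near neutral pH; set
    False for the strict bare-residue reading).
    """

    name: str
    residues: dict[str, AminoAcidParams]
    epsilon: float = 0.8368
    bond_k: float = 8033.0
    bond_r0: float = 0.38
    rc_nonionic: float = 2.0
    rc_ionic: float = 4.0
    termini_charges: bool = True

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL_RESIDUES) - set(self.residues))
        if missing:
            raise ValueError(f"incomplete parameter table, missing {missing}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        max_sigma = max(p.sigma for p in self.residues.values())
        if self.rc_nonionic < 2 ** (1 / 6) * max_sigma:
            raise ValueError("rc_nonionic below the repulsive minimum distance")
        if self.rc_ionic <= 0:
            raise ValueError("rc_ionic must be positive")

    def __getitem__(self, code: str) -> AminoAcidParams:
        try:
            return self.residues[code]
        except KeyError:
            raise UnknownResidueError(f"unknown residue code {code!r}") from None

    def lambda_vector(self) -> np.ndarray:
        """λ as a 20-vector in :data:`CANONICAL_RESIDUES` order."""
        return np.array(
            [self.residues[c].lambda_stickiness for c in CANONICAL_RESIDUES]
        )

    def with_lambda(self, lam: dict[str, float] | np.ndarray) -> "ParameterSet":
        """Return a copy with λ replaced (dict by code, or canonical 20-vector)."""
        if isinstance(lam, dict):
            mapping = lam
        else:
            lam = np.asarray(lam, dtype=float)
            if lam.shape != (20,):
                raise ValueError("lambda vector must have shape (20,)")
            mapping = dict(zip(CANONICAL_RESIDUES, lam))
        residues = {
            c: (
                replace(p, lambda_stickiness=float(mapping[c]))
                if c in mapping
                else p
            )
            for c, p in self.residues.items()
        }
        return replace(self, name=f"{self.name}*", residues=residues)


# ---------------------------------------------------------------------------
# per-residue operations

def residue_charge(code: str, pH: float, params: ParameterSet) -> float:
    """Average charge of a residue at the given pH, in elementary charges.

    D/E carry −1, K/R +1, all others 0 except histidine whose average
    protonation follows Henderson–Hasselbalch with pKa = 6:
    q_H = 1 / (1 + 10^(pH − pKa)).
    """
    p = params[code]
    if p.pKa is None:
        return float(p.ref_charge)
    return 1.0 / (1.0 + 10.0 ** (pH - p.pKa))


def chain_charges(
    sequence: str, pH: float, params: ParameterSet, termini: bool | None = None
) -> np.ndarray:
    """Per-bead charges of a chain, optionally with +1/−1 terminal beads."""
    q = np.array([residue_charge(c, pH, params) for c in sequence])
    if termini is None:
        termini = params.termini_charges
    if termini and len(q) > 0:
        q[0] += 1.0
        q[-1] -= 1.0
    return q


def mean_hydropathy(sequence: str, params: ParameterSet) -> float:
    """Arithmetic mean of per-residue λ over the chain, ⟨λ⟩."""
    if not sequence:
        raise ValueError("empty sequence")
    return float(
        np.mean([params[c].lambda_stickiness for c in sequence])
    )


def chain_mass(sequence: str, params: ParameterSet) -> float:
    """Molecular weight of the peptide in Da (residue masses + one water)."""
    from .constants import WATER_MASS

    return float(sum(params[c].mass for c in sequence) + WATER_MASS)


def pair_params(
    code_i: str, code_j: str, params: ParameterSet
) -> tuple[float, float]:
    """Combination rule: arithmetic means (σ_ij, λ_ij) for a residue pair."""
    pi, pj = params[code_i], params[code_j]
    return (
        0.5 * (pi.sigma + pj.sigma),
        0.5 * (pi.lambda_stickiness + pj.lambda_stickiness),
    )


# ---------------------------------------------------------------------------
# I/O

_VARIANT_FILES = {
    "CALVADOS1": "residues_calvados1.csv",
    "CALVADOS2": "residues_calvados2.csv",
}
_VARIANT_RC = {"CALVADOS1": 4.0, "CALVADOS2": 2.0}


def _table_from_frame(df: pd.DataFrame, name: str, **kwargs) -> ParameterSet:
    required = {"one_letter", "lambda", "sigma_nm", "charge", "mass_Da"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"parameter file missing columns {sorted(missing_cols)}")
    residues: dict[str, AminoAcidParams] = {}
    defects: list[str] = []
    for _, row in df.iterrows():
        code = str(row["one_letter"]).strip()
        if len(code) != 1 or code not in CANONICAL_RESIDUES:
            defects.append(f"unknown residue row {code!r}")
            continue
        pka = row.get("pKa")
        pka = None if pd.isna(pka) else float(pka)
        try:
            residues[code] = AminoAcidParams(
                code=code,
                lambda_stickiness=float(row["lambda"]),
                sigma=float(row["sigma_nm"]),
                ref_charge=int(row["charge"]),
                mass=float(row["mass_Da"]),
                pKa=pka,
            )
        except ValueError as exc:
            defects.append(str(exc))
    missing = sorted(set(CANONICAL_RESIDUES) - set(residues))
    if missing:
        defects.append(f"missing residue(s) {missing}")
    if defects:
        raise ValueError("defective parameter table: " + "; ".join(defects))
    return ParameterSet(name=name, residues=residues, **kwargs)


def load_parameter_set(path: str | Path, name: str | None = None, **kwargs) -> ParameterSet:
    """Load a residue table from CSV (schema: one_letter, lambda, sigma_nm,
    charge, mass_Da, pKa).  If a sidecar ``<path>.json`` exists its sha256
    checksum is verified against the file contents."""
    path = Path(path)
    meta = path.with_suffix(path.suffix + ".json")
    if meta.exists():
        recorded = json.loads(meta.read_text()).get("sha256")
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if recorded and recorded != actual:
            raise ValueError(f"checksum mismatch for {path.name}")
    df = pd.read_csv(path)
    return _table_from_frame(df, name or path.stem, **kwargs)


def write_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a table back to CSV (round-trips through the loader) and a
    sidecar JSON with name and sha256 checksum."""
    path = Path(path)
    rows = [
        {
            "one_letter": c,
            "lambda": p.lambda_stickiness,
            "sigma_nm": p.sigma,
            "charge": p.ref_charge,
            "mass_Da": p.mass,
            "pKa": p.pKa,
        }
        for c, p in sorted(params.residues.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "name": params.name,
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        "epsilon": params.epsilon,
        "rc_nonionic": params.rc_nonionic,
        "rc_ionic": params.rc_ionic,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def packaged_table(filename: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("cgidp.data") / filename)


def load_calvados(version: int = 2, **overrides) -> ParameterSet:
    """Load a packaged model variant (1 or 2) with its published cutoff."""
    name = f"CALVADOS{version}"
    if name not in _VARIANT_FILES:
        raise ValueError(f"unknown variant {name}")
    kwargs = {"rc_nonionic": _VARIANT_RC[name]}
    kwargs.update(overrides)
    return load_parameter_set(packaged_table(_VARIANT_FILES[name]), name=name, **kwargs)


def load_sequences(
    path: str | Path, conditions: SolutionConditions | None = None
) -> list[ProteinSpec]:
    """Read a FASTA file into :class:`ProteinSpec` records, in file order."""
    specs = []
    for record in SeqIO.parse(str(path), "fasta"):
        specs.append(
            ProteinSpec(name=record.id, sequence=str(record.seq).upper(),
                        conditions=conditions)
        )
    if not specs:
        raise ValueError(f"no FASTA records found in {path}")
    return specs


def packaged_sequences() -> dict[str, ProteinSpec]:
    """The packaged reference sequences keyed by name."""
    return {s.name: s for s in load_sequences(packaged_table("sequences.fasta"))}
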