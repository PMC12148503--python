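"""AMBER torsion-energy terms for the three cystine dihedrals.

The classic AMBER dihedral parameters for the cysteine side chain and
the disulfide bond give three pure cosine series (kcal/mol):

    E(χ1) = 2.0 (1 + cos 3χ1)
    E(χ2) = 1.0 (1 + cos 3χ2)
    E(χ3) = 3.5 (1 + cos 2χ3) + 0.6 (1 + cos 3χ3)

Each term is non-negative, even and 360°-periodic.  The χ3 series has
its unique global maximum of 8.2 kcal/mol at the syn-periplanar 0°
conformation and minima of 0.6 near ±90° — the analytic statement of
why an eclipsed disulfide is strained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["e_chi1", "e_chi2", "e_chi3", "energy_profile", "EnergyProfile"]


def e_chi1(chi1):
    """Torsion energy of χ1 in kcal/mol: 2.0·(1 + cos 3χ1)."""
    return 2.0 * (1.0 + np.cos(np.radians(3.0 * np.asarray(chi1, dtype=float))))


def e_chi2(chi2):
    """Torsion energy of χ2 in kcal/mol: 1.0·(1 + cos 3χ2)."""
    return 1.0 * (1.0 + np.cos(np.radians(3.0 * np.asarray(chi2, dtype=float))))


def e_chi3(chi3):
    """Torsion energy of χ3 in kcal/mol:
    3.5·(1 + cos 2χ3) + 0.6·(1 + cos 3χ3)."""
    x = np.radians(np.asarray(chi3, dtype=float))
    return 3.5 * (1.0 + np.cos(2.0 * x)) + 0.6 * (1.0 + np.cos(3.0 * x))


_TERMS = {"chi1": e_chi1, "chi2": e_chi2, "chi3": e_chi3}


@dataclass(frozen=True)
class TorsionEnergies:
    """Per-dihedral torsion strain of one cystine, kcal/mol."""

    e_chi1: float
    e_chi2: float
    e_chi3: float
    e_chi2p: float
    e_chi1p: float

    @property
    def total(self) -> float:
        return self.e_chi1 + self.e_chi2 + self.e_chi3 + self.e_chi2p + self.e_chi1p


def quintet_energies(quintet) -> TorsionEnergies:
    """Evaluate the three torsion terms across a dihedral quintet."""
    c1, c2, c3, c2p, c1p = quintet
    return TorsionEnergies(
        e_chi1=float(e_chi1(c1)),
        e_chi2=float(e_chi2(c2)),
        e_chi3=float(e_chi3(c3)),
        e_chi2p=float(e_chi2(c2p)),
        e_chi1p=float(e_chi1(c1p)),
    )


@dataclass(frozen=True)
class EnergyProfile:
    angles: np.ndarray  # degrees, grid over (-180, 180]
    values: np.ndarray  # kcal/mol
    which: str

    @property
    def argmax(self) -> float:
        return float(self.angles[int(np.argmax(self.values))])

    @property
    def argmin(self) -> float:
        return float(self.angles[int(np.argmin(self.values))])

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.angles, self.values]),
                   fmt="%.4f", delimiter="\t",
                   header=f"angle_deg\te_{self.which}_kcal_mol", comments="")


def energy_profile(which: str, step: float = 1.0) -> EnergyProfile:
    """Dense energy curve on the grid (-180 + step, ..., 180]."""
    if which not in _TERMS:
        raise ValueError(f"unknown dihedral {which!r}")
    n = 360.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide 360")
    angles = -180.0 + step * np.arange(1, int(round(n)) + 1)
    return EnergyProfile(angles=angles, values=_TERMS[which](angles), which=which)
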