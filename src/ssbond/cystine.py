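"""Cystine dihedral quintets, screw-sign descriptors and the
cysteinylation mass shift.

A disulfide bridge is described by five torsions: χ1 (N-Cα-Cβ-Sγ) and
χ2 (Cα-Cβ-Sγ-Sγ′) on each cysteine plus the shared χ3 (Cβ-Sγ-Sγ′-Cβ′)
across the S-S bond.  χ3 near ±90° is relaxed; χ3 = 0 (syn-periplanar,
the two Cβ eclipsed across the bond) is the maximally strained
conformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .geom import dihedral, wrap_angle
from .structure_io import CystinePair, CysteineSite


class IncompleteCystineError(ValueError):
    """A cystine is missing one of the N/CA/CB/SG anchors."""


@dataclass(frozen=True)
class DihedralQuintet:
    """(χ1, χ2, χ3, χ2′, χ1′) in degrees; unprimed is the site with the
    lexicographically smaller (chain, residue) key."""

    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float

    def __iter__(self):
        return iter((self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p))

    def reversed(self) -> "DihedralQuintet":
        return DihedralQuintet(self.chi1p, self.chi2p, self.chi3, self.chi2, self.chi1)


@dataclass(frozen=True)
class ScrewSigns:
    """Per-angle signs and χ3 handedness.

    A torsion of exactly 0 gets "+" by convention and sets *boundary*;
    its handedness is None so the syn-periplanar case never silently
    acquires one.
    """

    signs: tuple[str, str, str, str, str]
    handedness: Optional[str]
    boundary: bool = False


def cystine_dihedrals(pair: CystinePair) -> DihedralQuintet:
    """The five torsions of a disulfide, canonically ordered.

    χ3 is identical whichever site is unprimed; swapping the sites maps
    (χ1, χ2, χ3, χ2′, χ1′) to (χ1′, χ2′, χ3, χ2, χ1).
    """
    a, b = sorted((pair.site_a, pair.site_b), key=lambda s: s.key)
    for s in (a, b):
        if s.sg_pos is None:
            raise IncompleteCystineError(f"site {s.key} lacks Sγ")
    return DihedralQuintet(
        chi1=dihedral(a.n_pos, a.ca_pos, a.cb_pos, a.sg_pos),
        chi2=dihedral(a.ca_pos, a.cb_pos, a.sg_pos, b.sg_pos),
        chi3=dihedral(a.cb_pos, a.sg_pos, b.sg_pos, b.cb_pos),
        chi2p=dihedral(b.ca_pos, b.cb_pos, b.sg_pos, a.sg_pos),
        chi1p=dihedral(b.n_pos, b.ca_pos, b.cb_pos, b.sg_pos),
    )


def chi1_of_site(site: CysteineSite) -> float:
    """χ1 of a single (possibly free) cysteine with a modeled Sγ."""
    if site.sg_pos is None:
        raise IncompleteCystineError(f"site {site.key} lacks Sγ")
    return dihedral(site.n_pos, site.ca_pos, site.cb_pos, site.sg_pos)


def screw_signs(q: DihedralQuintet) -> ScrewSigns:
    signs = tuple("+" if x >= 0.0 else "-" for x in q)
    boundary = any(x == 0.0 for x in q)
    if q.chi3 > 0.0:
        handedness = "right"
    elif q.chi3 < 0.0:
        handedness = "left"
    else:
        handedness = None
    return ScrewSigns(signs=signs, handedness=handedness, boundary=boundary)


# ------------------------------------------------- cysteinylation mass

# Standard atomic masses: CIAAW conventional atomic weights (average) and
# principal-isotope masses (monoisotopic).
_AVERAGE = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
_MONO = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
         "O": 15.9949146196, "S": 31.97207100}

_CYSTEINE_FORMULA = {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}


def cysteinylation_mass_shift(kind: str = "average") -> float:
    """Mass added by attaching a free cysteine via a disulfide, in Da.

    The linkage releases two hydrogens, so the shift is the mass of
    cysteine (C3H7NO2S) minus 2 H: ≈119.14 Da average (119 Da at
    integer precision, the value seen in intact-mass spectra of
    cysteinylated monomers), ≈119.004 Da monoisotopic.
    """
    if kind == "average":
        table = _AVERAGE
    elif kind == "monoisotopic":
        table = _MONO
    else:
        raise ValueError(f"unknown kind {kind!r}")
    cys = sum(n * table[el] for el, n in _CYSTEINE_FORMULA.items())
    return cys - 2.0 * table["H"]


def wrap_quintet(*angles: float) -> DihedralQuintet:
    """Build a quintet, wrapping each angle onto (-180, +180]."""
    if len(angles) != 5:
        raise ValueError("a quintet needs five angles")
    return DihedralQuintet(*(wrap_angle(a) for a in angles))
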