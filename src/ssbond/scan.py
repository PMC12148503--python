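"""χ1-sweep accessibility scan for interchain disulfide formation.

For a free cysteine the sulfur can sit anywhere on a cone around the
Cα-Cβ axis: fixed Cβ-S bond length (1.81 Å) and Cα-Cβ-S angle (114.3°),
with χ1 selecting the position on the circle.  Sweeping χ1 of the two
opposing cysteines of a dimer in one-degree increments, discarding
positions that clash with surrounding heavy atoms, and asking which
remaining pairs come within disulfide bonding distance (2.0 ± 0.1 Å)
identifies every rotamer pair that could actually form the bond.

The same machinery re-runs under rigid registration shifts of one
protomer to ask whether a shifted interface would open an unstrained
(χ3 near ±90°) disulfide geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geom import bond_angle, dihedral, place_atom
from .structure_io import Atom, CysteineSite, Residue, StructureModel

__all__ = [
    "SweepParams",
    "SweepProfile",
    "FeasibilityResult",
    "RigidTransform",
    "ShiftResult",
    "place_sulfur",
    "sweep_positions",
    "clash_scan",
    "min_cross_distances",
    "feasibility",
    "registration_shift_scan",
]

DEFAULT_VDW = {"S": 1.80, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "SE": 1.90}


def default_clash_exclusion(site: CysteineSite, residue: Residue, atom: Atom) -> bool:
    """True if *atom* is exempt from clashing with the virtual sulfur.

    The virtual sulfur is covalently bonded to the site's Cβ, so all
    atoms of its own residue plus the backbone N/C/O of the immediate
    sequence neighbours (1-2/1-3/1-4 relationships) are exempt.
    """
    if residue.key == site.residue.key:
        return True
    if (residue.chain_id == site.residue.chain_id
            and residue.icode == site.residue.icode == ""
            and abs(residue.seq_num - site.residue.seq_num) == 1
            and atom.name in ("N", "C", "O")):
        return True
    return False


@dataclass(frozen=True)
class SweepParams:
    bond_length: float = 1.81       # Cβ-S, Å
    bond_angle: float = 114.3       # Cα-Cβ-S, degrees
    step: float = 1.0               # sweep increment, degrees
    ss_target: float = 2.0          # ideal S-S bond length, Å
    ss_tolerance: float = 0.1       # Å
    apply_lower_bound: bool = False  # also require d >= ss_target - tol
    clash_overlap: float = 0.4      # vdW overlap needed to call a clash, Å
    vdw_radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW))
    default_radius: float = 1.70    # for elements missing from the table
    clash_exclusion: Callable = default_clash_exclusion

    def __post_init__(self):
        if not self.bond_length > 0:
            raise ValueError("bond_length must be > 0")
        if not 0 < self.bond_angle < 180:
            raise ValueError("bond_angle must be in (0, 180)")
        n = 360.0 / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"step {self.step} does not divide 360")
        if self.ss_tolerance < 0:
            raise ValueError("ss_tolerance must be >= 0")

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.step))

    def grid(self) -> np.ndarray:
        """χ1 grid on (-180, +180], anchored at -180 + step."""
        return -180.0 + self.step * np.arange(1, self.n_angles + 1)

    @property
    def cone_radius(self) -> float:
        """Radius of the sulfur circle about the Cα-Cβ axis."""
        return self.bond_length * np.sin(np.radians(180.0 - self.bond_angle))

    @property
    def cone_height(self) -> float:
        """Offset of the circle plane beyond Cβ along Cα->Cβ."""
        return self.bond_length * np.cos(np.radians(180.0 - self.bond_angle))

    def radius_of(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), self.default_radius)


@dataclass
class SweepProfile:
    site: CysteineSite
    angles: np.ndarray                      # χ1 grid, degrees
    positions: np.ndarray                   # (n, 3) sulfur positions
    clash: Optional[np.ndarray] = None      # bool per angle
    clash_atoms: Optional[list] = None      # per angle: list of residue/atom keys
    min_cross: Optional[np.ndarray] = None  # Å per angle (pair mode)
    partner_angle: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.angles)

    def clash_free_angles(self) -> np.ndarray:
        if self.clash is None:
            return self.angles
        return self.angles[~self.clash]


@dataclass(frozen=True)
class FeasibilityResult:
    feasible_pairs: tuple            # ((θA, θB), ...) degrees
    best_pair: Optional[tuple]       # the pair minimizing |d - ss_target|
    best_distance: Optional[float]
    any_feasible: bool
    per_angle_feasible: np.ndarray   # bool per θA grid angle

    def __post_init__(self):
        if self.any_feasible and self.best_pair not in self.feasible_pairs:
            raise ValueError("best_pair must be a feasible pair")


# ------------------------------------------------------------ placement

def place_sulfur(site: CysteineSite, chi1: float, params: SweepParams = SweepParams()) -> np.ndarray:
    """The unique sulfur position with torsion N-Cα-Cβ-S = *chi1*.

    Internal-coordinate placement: distance ``bond_length`` from Cβ,
    angle ``bond_angle`` at Cβ with Cα.  Equivalent to composing the
    height vector bond_length·cos(π - angle) along Cα->Cβ with a radial
    vector of magnitude bond_length·sin(π - angle) rotated by χ1.
    """
    return place_atom(site.n_pos, site.ca_pos, site.cb_pos,
                      params.bond_length, params.bond_angle, chi1)


def sweep_positions(site: CysteineSite, params: SweepParams = SweepParams()) -> SweepProfile:
    """Sulfur positions for every χ1 grid angle (the Fig-style circle)."""
    angles = params.grid()
    pos = np.array([place_sulfur(site, a, params) for a in angles])
    return SweepProfile(site=site, angles=angles, positions=pos)


# ---------------------------------------------------------------- clash

def _clash_candidates(site: CysteineSite, model: StructureModel, params: SweepParams):
    """Heavy, non-water, non-exempt atoms and their vdW radii."""
    coords, radii, keys = [], [], []
    for res, atom in model.iter_atoms():
        if atom.element.upper() in ("H", "D"):
            continue
        if res.res_name in ("HOH", "WAT", "DOD"):
            continue
        if params.clash_exclusion(site, res, atom):
            continue
        coords.append(atom.pos)
        radii.append(params.radius_of(atom.element))
        keys.append((res.key, atom.name))
    if not coords:
        return np.empty((0, 3)), np.empty(0), []
    return np.array(coords), np.array(radii), keys


def clash_scan(profile: SweepProfile, model: StructureModel,
               params: SweepParams = SweepParams()) -> SweepProfile:
    """Mark every sweep angle whose virtual sulfur overlaps a heavy atom.

    An angle clashes iff overlap = (r_S + r_other) - distance exceeds
    ``clash_overlap`` for any non-exempt heavy atom.  Hydrogens are
    absent from the X-ray models in scope; the heavy-atom radii absorb
    them.
    """
    coords, radii, keys = _clash_candidates(profile.site, model, params)
    r_s = params.radius_of("S")
    if len(coords) == 0:
        mask = np.zeros(profile.n, dtype=bool)
        return replace(profile, clash=mask, clash_atoms=[[] for _ in range(profile.n)])
    d = cdist(profile.positions, coords)          # (n_angles, n_atoms)
    overlap = (r_s + radii)[None, :] - d
    hits = overlap > params.clash_overlap
    mask = hits.any(axis=1)
    clash_atoms = [[keys[j] for j in np.flatnonzero(row)] for row in hits]
    return replace(profile, clash=mask, clash_atoms=clash_atoms)


# ------------------------------------------------------------ distances

class GridMismatchError(ValueError):
    pass


def _check_grids(profile_a: SweepProfile, profile_b: SweepProfile):
    if profile_a.n != profile_b.n or not np.allclose(profile_a.angles, profile_b.angles):
        raise GridMismatchError("sweep profiles are on different χ1 grids")


def min_cross_distances(profile_a: SweepProfile, profile_b: SweepProfile,
                        exclude_clashing: bool = False) -> SweepProfile:
    """For each θA, the minimum over θB of |S_A(θA) - S_B(θB)|.

    With *exclude_clashing*, clash-marked angles of profile_b are left
    out of the minimum (profile_b.clash must then be filled); by default
    all angles enter and feasibility applies the clash filter instead.
    """
    _check_grids(profile_a, profile_b)
    d = cdist(profile_a.positions, profile_b.positions)
    if exclude_clashing:
        if profile_b.clash is None:
            raise ValueError("exclude_clashing requires a clash-scanned profile_b")
        d = np.where(profile_b.clash[None, :], np.inf, d)
    idx = np.argmin(d, axis=1)
    return replace(
        profile_a,
        min_cross=d[np.arange(profile_a.n), idx],
        partner_angle=profile_b.angles[idx],
    )


def feasibility(profile_a: SweepProfile, profile_b: SweepProfile,
                params: SweepParams = SweepParams()) -> FeasibilityResult:
    """Which clash-free (θA, θB) pairs put the sulfurs in bonding range.

    Feasible means: clash-free on both sites and cross distance at most
    ss_target + ss_tolerance (an optional lower bound ss_target -
    ss_tolerance is applied when params.apply_lower_bound is set, since
    a much closer approach is itself a clash).
    """
    _check_grids(profile_a, profile_b)
    d = cdist(profile_a.positions, profile_b.positions)
    ok = d <= params.ss_target + params.ss_tolerance
    if params.apply_lower_bound:
        ok &= d >= params.ss_target - params.ss_tolerance
    if profile_a.clash is not None:
        ok &= ~profile_a.clash[:, None]
    if profile_b.clash is not None:
        ok &= ~profile_b.clash[None, :]
    ii, jj = np.nonzero(ok)
    pairs = tuple(
        (float(profile_a.angles[i]), float(profile_b.angles[j])) for i, j in zip(ii, jj)
    )
    if len(ii) == 0:
        return FeasibilityResult(
            feasible_pairs=(), best_pair=None, best_distance=None,
            any_feasible=False, per_angle_feasible=ok.any(axis=1),
        )
    dev = np.abs(d[ii, jj] - params.ss_target)
    k = int(np.argmin(dev))
    return FeasibilityResult(
        feasible_pairs=pairs,
        best_pair=pairs[k],
        best_distance=float(d[ii[k], jj[k]]),
        any_feasible=True,
        per_angle_feasible=ok.any(axis=1),
    )


# --------------------------------------------------- registration shifts

@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t applied to one protomer."""

    rot: np.ndarray = field(default_factory=lambda: np.eye(3))
    trans: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ np.asarray(self.rot).T + np.asarray(self.trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def translation(cls, v) -> "RigidTransform":
        return cls(trans=np.asarray(v, dtype=float))


def _transform_model_chain(model: StructureModel, chain_id: str,
                           t: RigidTransform) -> StructureModel:
    out = []
    for res in model.residues:
        if res.chain_id != chain_id:
            out.append(res)
            continue
        atoms = [replace(a, pos=t.apply(a.pos)) for a in res.atoms]
        out.append(replace(res, atoms=atoms))
    return replace(model, residues=out)


def _transform_site(site: CysteineSite, t: RigidTransform) -> CysteineSite:
    return CysteineSite(
        residue=site.residue,
        n_pos=t.apply(site.n_pos),
        ca_pos=t.apply(site.ca_pos),
        cb_pos=t.apply(site.cb_pos),
        sg_pos=None if site.sg_pos is None else t.apply(site.sg_pos),
        is_free=site.is_free,
    )


@dataclass(frozen=True)
class ShiftResult:
    transform: RigidTransform
    result: FeasibilityResult
    best_chi3: Optional[float]   # χ3 at the best feasible pair, degrees
    unstrained: bool             # some feasible pair has χ3 within the ±90° window


def _achieved_chi3(site_a: CysteineSite, site_b: CysteineSite,
                   pos_a: np.ndarray, pos_b: np.ndarray) -> float:
    return dihedral(site_a.cb_pos, pos_a, pos_b, site_b.cb_pos)


def scan_pair(site_a: CysteineSite, site_b: CysteineSite, model: StructureModel,
              params: SweepParams = SweepParams()):
    """Sweep both sites, clash-scan against *model*, fill cross distances.

    Returns (profile_a, profile_b, FeasibilityResult) — the one-call
    version of the full accessibility analysis.
    """
    pa = clash_scan(sweep_positions(site_a, params), model, params)
    pb = clash_scan(sweep_positions(site_b, params), model, params)
    pa = min_cross_distances(pa, pb)
    return pa, pb, feasibility(pa, pb, params)


def registration_shift_scan(site_a: CysteineSite, site_b: CysteineSite,
                            model: StructureModel,
                            shifts: Sequence[RigidTransform],
                            params: SweepParams = SweepParams(),
                            chi3_window: float = 30.0) -> list[ShiftResult]:
    """Re-run the feasibility scan under rigid shifts of protomer B.

    Each transform is applied to the protomer (chain) containing
    *site_b*, including its clash atoms.  A shift is reported as
    unstrained when some feasible pair achieves |χ3| within
    *chi3_window* degrees of 90° (χ3 computed from the placed sulfurs
    and the fixed Cβ positions).
    """
    shifts = list(shifts)
    if not shifts:
        raise ValueError("empty transform grid")
    chain_b = site_b.residue.chain_id
    out = []
    for t in shifts:
        m = _transform_model_chain(model, chain_b, t)
        sb = _transform_site(site_b, t)
        pa, pb, res = scan_pair(site_a, sb, m, params)
        best_chi3 = None
        unstrained = False
        if res.any_feasible:
            ia = {a: i for i, a in enumerate(np.round(pa.angles, 9))}
            for (ta, tb) in res.feasible_pairs:
                c3 = _achieved_chi3(
                    site_a, sb,
                    pa.positions[ia[round(ta, 9)]],
                    pb.positions[ia[round(tb, 9)]],
                )
                if (ta, tb) == res.best_pair:
                    best_chi3 = c3
                if abs(abs(c3) - 90.0) <= chi3_window:
                    unstrained = True
        out.append(ShiftResult(transform=t, result=res,
                               best_chi3=best_chi3, unstrained=unstrained))
    return out
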