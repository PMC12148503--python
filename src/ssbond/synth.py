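"""Synthetic structure and ensemble generators for testing.

Everything the analysis stages consume can be built here without any
downloads: an ideal cysteine residue, a C2-symmetric two-protomer
arrangement with tunable separation and registration, clash probes that
eliminate a prescribed arc of the χ1 sweep (emulating a blocking side
chain such as a valine), and wrapped-normal dihedral ensembles with
known parameters for the survey statistics.

All generators are deterministic under a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import gemmi
import numpy as np

from .cystine import DihedralQuintet
from .geom import place_atom, rotation_about_axis, wrap_angle
from .scan import SweepParams, place_sulfur, sweep_positions
from .structure_io import (Atom, CysteineSite, Residue, StructureModel,
                           find_cysteines)
from .survey import SurveyRecord

__all__ = [
    "IDEAL",
    "ConstructionError",
    "DimerSpec",
    "EnsembleSpec",
    "make_ideal_cysteine",
    "make_c2_dimer",
    "engineered_separation",
    "add_clash_probe",
    "sample_dihedral_ensemble",
    "write_fixture",
]

# Ideal covalent geometry for the cysteine fragment (bond lengths in Å,
# angles in degrees).  Fixed documented constants; their exact values
# shift absolute coordinates only, never any invariant under test.
IDEAL = {
    "N-CA": 1.458,
    "CA-CB": 1.530,
    "CA-C": 1.525,
    "C-O": 1.231,
    "N-CA-CB": 110.5,
    "N-CA-C": 111.2,
    "CA-C-O": 120.8,
    "CB-S-S": 104.2,
    "S-CB-CA": 114.3,
}


class ConstructionError(ValueError):
    """A requested synthetic geometry is unrealizable."""


def _cys_residue(chain_id: str, seq_num: int, coords: dict[str, np.ndarray]) -> Residue:
    elements = {"N": "N", "CA": "C", "CB": "C", "C": "C", "O": "O", "SG": "S"}
    atoms = [Atom(name=n, element=elements[n], pos=p) for n, p in coords.items()]
    return Residue(chain_id=chain_id, seq_num=seq_num, res_name="CYS", atoms=atoms)


def make_ideal_cysteine(origin=(0.0, 0.0, 0.0), orientation=None,
                        chi1: Optional[float] = None,
                        chain_id: str = "A", seq_num: int = 1,
                        params: SweepParams = SweepParams()) -> Residue:
    """A cysteine residue with ideal covalent geometry.

    Built in a local frame with Cα at the origin and the Cα->Cβ bond
    along +z, then rotated by *orientation* (3x3 matrix) and translated
    to *origin*.  When *chi1* is given, Sγ is placed on the sweep cone
    at that torsion via the same internal-coordinate placement the scan
    uses, so generator and analyser close over each other exactly.
    """
    ca = np.zeros(3)
    cb = np.array([0.0, 0.0, IDEAL["CA-CB"]])
    th = np.radians(IDEAL["N-CA-CB"])
    n = ca + IDEAL["N-CA"] * np.array([np.sin(th), 0.0, np.cos(th)])
    c = place_atom(cb, n, ca, IDEAL["CA-C"], IDEAL["N-CA-C"], -120.0)
    o = place_atom(n, ca, c, IDEAL["C-O"], IDEAL["CA-C-O"], 180.0)
    coords = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}
    if chi1 is not None:
        site = CysteineSite(
            residue=Residue(chain_id=chain_id, seq_num=seq_num, res_name="CYS"),
            n_pos=n, ca_pos=ca, cb_pos=cb,
        )
        coords["SG"] = place_sulfur(site, chi1, params)
    rot = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    origin = np.asarray(origin, dtype=float)
    coords = {k: rot @ v + origin for k, v in coords.items()}
    return _cys_residue(chain_id, seq_num, coords)


@dataclass(frozen=True)
class DimerSpec:
    """Geometry of a two-protomer cysteine stub arrangement.

    Without a target quintet the two protomers are exact C2 images
    about z with Cβ-Cβ distance *cb_separation*; each cysteine's
    sulfur cone faces the partner, with the closest approach at
    χ1 = *chi1_closest* on both sites.  *twist* rotates protomer B
    further about the C2 axis and *lateral_offset* translates it along
    y (a registration shift), both breaking exact C2.

    With *target_quintet* the cystine is built outward from internal
    coordinates so the full dihedral quintet is realized exactly
    (S-S bond length *ss_length*); the Cβ separation is then implied,
    and a conflicting *cb_separation* raises ConstructionError.
    """

    cb_separation: Optional[float] = None
    twist: float = 0.0
    lateral_offset: float = 0.0
    chi1_closest: float = -120.0
    sg_chi1: Optional[float] = None      # place free Sγ at this χ1 on both sites
    target_quintet: Optional[DihedralQuintet] = None
    ss_length: float = 2.05
    seq_num: int = 392
    seed: int = 0

    def __post_init__(self):
        if self.target_quintet is None:
            if self.cb_separation is None or not self.cb_separation > 0:
                raise ValueError("cb_separation must be > 0")


def engineered_separation(d_min: float, params: SweepParams = SweepParams()) -> float:
    """Cβ-Cβ separation making *d_min* the minimum cross S-S distance.

    Closed form from the cone geometry: the two sulfur circles of a
    face-on C2 dimer are coplanar with centres 2x0 apart, so the
    closest approach is cb_separation - 2·r_cone.
    """
    return d_min + 2.0 * params.cone_radius


def _protomer_a(spec: DimerSpec, params: SweepParams) -> dict[str, np.ndarray]:
    x0 = spec.cb_separation / 2.0
    cb = np.array([x0, 0.0, 0.0])
    ca = cb - np.array([0.0, 0.0, IDEAL["CA-CB"]])   # Cα->Cβ along +z
    # the closest cone point to the C2 axis sits at azimuth pointing at -x
    h, r = params.cone_height, params.cone_radius
    s_star = np.array([x0 - r, 0.0, h])
    n = place_atom(s_star, cb, ca, IDEAL["N-CA"], IDEAL["N-CA-CB"], spec.chi1_closest)
    c = place_atom(cb, n, ca, IDEAL["CA-C"], IDEAL["N-CA-C"], -120.0)
    o = place_atom(n, ca, c, IDEAL["C-O"], IDEAL["CA-C-O"], 180.0)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _quintet_dimer(spec: DimerSpec) -> tuple[dict, dict]:
    q = spec.target_quintet
    ca_a = np.zeros(3)
    cb_a = np.array([0.0, 0.0, IDEAL["CA-CB"]])
    th = np.radians(IDEAL["N-CA-CB"])
    n_a = ca_a + IDEAL["N-CA"] * np.array([np.sin(th), 0.0, np.cos(th)])
    sg_a = place_atom(n_a, ca_a, cb_a, 1.81, IDEAL["S-CB-CA"], q.chi1)
    sg_b = place_atom(ca_a, cb_a, sg_a, spec.ss_length, IDEAL["CB-S-S"], q.chi2)
    cb_b = place_atom(cb_a, sg_a, sg_b, 1.81, IDEAL["CB-S-S"], q.chi3)
    ca_b = place_atom(sg_a, sg_b, cb_b, IDEAL["CA-CB"], IDEAL["S-CB-CA"], q.chi2p)
    n_b = place_atom(sg_b, cb_b, ca_b, IDEAL["N-CA"], IDEAL["N-CA-CB"], q.chi1p)
    implied = float(np.linalg.norm(cb_a - cb_b))
    if spec.cb_separation is not None and abs(implied - spec.cb_separation) > 1e-6:
        raise ConstructionError(
            f"quintet fixes the Cβ separation at {implied:.6f} Å "
            f"(S-S length {spec.ss_length} Å); requested {spec.cb_separation} Å"
        )

    def complete(n, ca, cb):
        c = place_atom(cb, n, ca, IDEAL["CA-C"], IDEAL["N-CA-C"], -120.0)
        o = place_atom(n, ca, c, IDEAL["C-O"], IDEAL["CA-C-O"], 180.0)
        return c, o

    c_a, o_a = complete(n_a, ca_a, cb_a)
    c_b, o_b = complete(n_b, ca_b, cb_b)
    prot_a = {"N": n_a, "CA": ca_a, "C": c_a, "O": o_a, "CB": cb_a, "SG": sg_a}
    prot_b = {"N": n_b, "CA": ca_b, "C": c_b, "O": o_b, "CB": cb_b, "SG": sg_b}
    return prot_a, prot_b


def make_c2_dimer(spec: DimerSpec, params: SweepParams = SweepParams()) -> StructureModel:
    """Two cysteine-bearing protomer stubs arranged per *spec*."""
    if spec.target_quintet is not None:
        prot_a, prot_b = _quintet_dimer(spec)
    else:
        prot_a = _protomer_a(spec, params)
        rot = rotation_about_axis([0.0, 0.0, 1.0], 180.0 + spec.twist)
        off = np.array([0.0, spec.lateral_offset, 0.0])
        prot_b = {k: rot @ v + off for k, v in prot_a.items()}
        if spec.sg_chi1 is not None:
            for prot in (prot_a, prot_b):
                site = CysteineSite(
                    residue=Residue(chain_id="_", seq_num=spec.seq_num, res_name="CYS"),
                    n_pos=prot["N"], ca_pos=prot["CA"], cb_pos=prot["CB"],
                )
                prot["SG"] = place_sulfur(site, spec.sg_chi1, params)
    res_a = _cys_residue("A", spec.seq_num, prot_a)
    res_b = _cys_residue("B", spec.seq_num, prot_b)
    return StructureModel(entry_id="SYNTH-DIMER", residues=[res_a, res_b],
                          resolution=None, source_format="synthetic")


def dimer_sites(model: StructureModel) -> tuple[CysteineSite, CysteineSite]:
    """The two cysteine sites of a generated dimer, chain A first."""
    sites = sorted(find_cysteines(model), key=lambda s: s.key)
    if len(sites) != 2:
        raise ValueError(f"expected 2 cysteines, found {len(sites)}")
    return sites[0], sites[1]


# ------------------------------------------------------------- probes

def add_clash_probe(model: StructureModel, site: CysteineSite,
                    arc_center: float, arc_halfwidth: float,
                    params: SweepParams = SweepParams()) -> StructureModel:
    """Pseudo-atoms that make clash_scan eliminate exactly one χ1 arc.

    One carbon-radius probe per grid step across the arc, each placed
    above its cone point along the Cα->Cβ axis at the distance where
    the vdW overlap criterion fires for angular offsets strictly inside
    the probe's coverage half-width.  The union covers
    [center - halfwidth, center + halfwidth] to within one grid step.
    Probes sit out of the cone plane, so a facing protomer's cone (at
    bonding-range distances) is never touched.
    """
    if not 0.0 <= arc_halfwidth < 180.0:
        raise ValueError("arc halfwidth must be in [0, 180)")
    clash_dist = params.radius_of("S") + params.radius_of("C") - params.clash_overlap
    r = params.cone_radius
    u = site.cb_pos - site.ca_pos
    u = u / np.linalg.norm(u)
    if arc_halfwidth == 0.0:
        probe_angles = [arc_center]
        hw0 = 0.45 * params.step
    else:
        k = int(np.floor(arc_halfwidth / params.step + 1e-9))
        probe_angles = [arc_center + i * params.step for i in range(-k, k + 1)]
        hw0 = 0.6 * params.step
    chord = 2.0 * r * np.sin(np.radians(hw0) / 2.0)
    if chord >= clash_dist:
        raise ConstructionError("probe coverage unachievable: cone chord exceeds clash range")
    dz = float(np.sqrt(clash_dist**2 - chord**2))
    seq0 = max((res.seq_num for res in model.residues), default=0) + 1
    probes = []
    for i, ang in enumerate(probe_angles):
        p = place_sulfur(site, wrap_angle(ang), params) + dz * u
        probes.append(Residue(chain_id="P", seq_num=seq0 + i, res_name="PRB",
                              atoms=[Atom(name="CP", element="C", pos=p)]))
    return replace(model, residues=list(model.residues) + probes)


# ------------------------------------------------------------ ensembles

@dataclass(frozen=True)
class EnsembleSpec:
    """Wrapped-normal mixture per dihedral: ((mean, sd, weight), ...)."""

    n: int = 1000
    chi1: tuple = ((-60.0, 10.0, 1.0),)
    chi2: tuple = ((-80.0, 10.0, 1.0),)
    chi3: tuple = ((95.0, 8.0, 0.5), (-87.0, 8.0, 0.5))
    seed: int = 0
    resolution: float = 1.5   # below any filter under test

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("chi1", "chi2", "chi3"):
            comps = getattr(self, name)
            if abs(sum(w for _, _, w in comps) - 1.0) > 1e-9:
                raise ValueError(f"{name} component weights must sum to 1")
            if any(sd <= 0 for _, sd, _ in comps):
                raise ValueError(f"{name} component sd must be > 0")


def _sample_mixture(rng: np.random.Generator, comps: tuple, n: int) -> np.ndarray:
    means = np.array([c[0] for c in comps])
    sds = np.array([c[1] for c in comps])
    ws = np.array([c[2] for c in comps])
    idx = rng.choice(len(comps), size=n, p=ws)
    raw = rng.normal(means[idx], sds[idx])
    return wrap_angle(raw)


def sample_dihedral_ensemble(spec: EnsembleSpec) -> list[SurveyRecord]:
    """Seeded wrapped-normal mixture samples emitted as survey records."""
    rng = np.random.default_rng(spec.seed)
    c1 = _sample_mixture(rng, spec.chi1, spec.n)
    c2 = _sample_mixture(rng, spec.chi2, spec.n)
    c3 = _sample_mixture(rng, spec.chi3, spec.n)
    return [
        SurveyRecord(
            entry_id=f"SYN{i:05d}", resolution=spec.resolution,
            chain_a="A", res_a=1, chain_b="B", res_b=1,
            chi1=float(c1[i]), chi2=float(c2[i]), chi3=float(c3[i]),
        )
        for i in range(spec.n)
    ]


# ------------------------------------------------------------- fixtures

def write_fixture(model: StructureModel, path) -> None:
    """Write a model as PDB, round-trippable by read_structure to 1e-3 Å."""
    st = gemmi.Structure()
    st.name = model.entry_id
    if model.resolution is not None:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gr = gemmi.Residue()
        gr.name = res.res_name
        gr.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
        gr.het_flag = "A" if res.res_name in ("CYS",) else "H"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            if a.altloc:
                ga.altloc = a.altloc
            gr.add_atom(ga)
        ch.add_residue(gr)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
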