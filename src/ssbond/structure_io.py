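"""Uniform atomic model on top of gemmi: parsing, altloc resolution,
cysteine location, disulfide detection and distance measurement.

The model deliberately keeps only what the downstream geometry needs:
chains, residues, heavy-atom names/positions/occupancies and the
reported crystallographic resolution.  The first model of a multi-model
file is used; coordinates are ångströms throughout.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

from .geom import as_vec3

logger = logging.getLogger(__name__)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC",
}


class FormatError(ValueError):
    """Unknown or undeclared coordinate format."""


class ParseError(ValueError):
    """The file could not be parsed in the named dialect."""


class SelectionError(KeyError):
    """An atom selector matched nothing."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        self.pos = as_vec3(self.pos)


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.icode)

    def get(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            k = (a.name, a.altloc)
            if k in seen:
                raise ValueError(f"duplicate atom {k} in residue {self.key}")
            seen.add(k)


@dataclass
class StructureModel:
    entry_id: str
    residues: list[Residue]
    resolution: Optional[float] = None
    source_format: str = "synthetic"

    def __post_init__(self):
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution, when present, must be > 0")

    def iter_atoms(self):
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def find_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.key == (chain_id, seq_num, icode):
                return r
        return None


@dataclass
class CysteineSite:
    """One cysteine's anchor atoms for the dihedral/sweep machinery."""

    residue: Residue
    n_pos: np.ndarray
    ca_pos: np.ndarray
    cb_pos: np.ndarray
    sg_pos: Optional[np.ndarray] = None
    is_free: bool = True

    def __post_init__(self):
        self.n_pos = as_vec3(self.n_pos)
        self.ca_pos = as_vec3(self.ca_pos)
        self.cb_pos = as_vec3(self.cb_pos)
        if self.sg_pos is not None:
            self.sg_pos = as_vec3(self.sg_pos)
        d = float(np.linalg.norm(self.ca_pos - self.cb_pos))
        if not 1.2 <= d <= 1.9:
            raise ValueError(f"Cα-Cβ distance {d:.3f} Å outside sanity band [1.2, 1.9]")

    @property
    def key(self) -> tuple:
        return self.residue.key


@dataclass
class CystinePair:
    site_a: CysteineSite
    site_b: CysteineSite
    ss_distance: float
    interchain: bool

    def __post_init__(self):
        if self.site_a.sg_pos is None or self.site_b.sg_pos is None:
            raise ValueError("both sites of a cystine must have Sγ")
        if not self.ss_distance > 0:
            raise ValueError("ss_distance must be > 0")


# ---------------------------------------------------------------- parsing

def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    if any(s in (".pdb", ".ent") for s in suffixes):
        return "pdb"
    raise FormatError(f"cannot infer coordinate format from name {path.name!r}")


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Resolution is taken from REMARK 2 / ``_refine.ls_d_res_high`` when
    present.  Only the first model of a multi-model file is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r}")
    coorfmt = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=coorfmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    residues: list[Residue] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                atoms = []
                for at in res:
                    atoms.append(
                        Atom(
                            name=at.name,
                            element=at.element.name,
                            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            altloc=at.altloc if at.altloc != "\x00" else "",
                            occupancy=float(min(max(at.occ, 0.0), 1.0)),
                            b_factor=float(at.b_iso),
                        )
                    )
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        res_name=res.name,
                        atoms=atoms,
                        icode=res.seqid.icode.strip(),
                    )
                )
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        entry_id=st.name or path.stem,
        residues=residues,
        resolution=resolution,
        source_format=fmt,
    )


# ------------------------------------------------------------- altlocs

def select_altloc(model: StructureModel, policy: str = "highest_occupancy",
                  label: str = "A") -> StructureModel:
    """Collapse alternate locations to one conformer per atom name.

    ``highest_occupancy`` keeps the conformer with the largest occupancy,
    ties broken by altloc label order.  ``label`` keeps the conformer
    with the given altloc (falling back to blank-altloc atoms).
    A model without altlocs passes through unchanged.
    """
    if policy not in ("highest_occupancy", "label"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    out_res = []
    for res in model.residues:
        by_name: dict[str, list[Atom]] = {}
        order: list[str] = []
        for a in res.atoms:
            if a.name not in by_name:
                order.append(a.name)
            by_name.setdefault(a.name, []).append(a)
        chosen = []
        for name in order:
            group = by_name[name]
            if len(group) == 1:
                chosen.append(group[0])
            elif policy == "highest_occupancy":
                chosen.append(max(group, key=lambda a: (a.occupancy, a.altloc == "",
                                                        -ord(a.altloc or "~"))))
            else:
                match = [a for a in group if a.altloc in ("", label)]
                chosen.append(sorted(match or group, key=lambda a: a.altloc)[0])
        out_res.append(replace(res, atoms=chosen))
    return replace(model, residues=out_res)


# ------------------------------------------------------------ cysteines

def find_cysteines(model: StructureModel) -> list[CysteineSite]:
    """One site per CYS residue carrying complete N/CA/CB anchors.

    Residues missing an anchor atom are excluded with a log message;
    altlocs must have been resolved first (see :func:`select_altloc`).
    """
    sites = []
    for res in model.residues:
        if res.res_name != "CYS":
            continue
        n, ca, cb = res.get("N"), res.get("CA"), res.get("CB")
        if n is None or ca is None or cb is None:
            missing = [x for x, a in (("N", n), ("CA", ca), ("CB", cb)) if a is None]
            logger.warning("excluding CYS %s: missing %s", res.key, ",".join(missing))
            continue
        sg = res.get("SG")
        try:
            site = CysteineSite(
                residue=res,
                n_pos=n.pos,
                ca_pos=ca.pos,
                cb_pos=cb.pos,
                sg_pos=None if sg is None else sg.pos,
            )
        except ValueError as exc:
            logger.warning("excluding CYS %s: %s", res.key, exc)
            continue
        sites.append(site)
    return sites


def detect_disulfides(sites: Iterable[CysteineSite], max_ss: float = 2.3) -> list[CystinePair]:
    """Pair Sγ atoms within *max_ss* ångströms, greedily by distance.

    Each sulfur joins at most one partner; remaining sites are flagged
    free.  The default 2.3 Å covers the ideal 2.05 Å bond plus
    refinement slack.  A sulfur within range of a second partner after
    assignment triggers an ambiguity warning.
    """
    sites = list(sites)
    withsg = [s for s in sites if s.sg_pos is not None]
    cands = []
    for i in range(len(withsg)):
        for j in range(i + 1, len(withsg)):
            d = float(np.linalg.norm(withsg[i].sg_pos - withsg[j].sg_pos))
            if d <= max_ss:
                cands.append((d, i, j))
    cands.sort(key=lambda t: (t[0], withsg[t[1]].key, withsg[t[2]].key))
    used: set[int] = set()
    pairs = []
    for d, i, j in cands:
        if i in used or j in used:
            if not (i in used and j in used):
                logger.warning(
                    "ambiguous disulfide: %s within %.2f Å of an already-paired Sγ",
                    (withsg[j] if i in used else withsg[i]).key, d,
                )
            continue
        used.add(i)
        used.add(j)
        a, b = sorted((withsg[i], withsg[j]), key=lambda s: s.key)
        a.is_free = b.is_free = False
        pairs.append(
            CystinePair(
                site_a=a,
                site_b=b,
                ss_distance=d,
                interchain=a.residue.chain_id != b.residue.chain_id,
            )
        )
    for s in sites:
        if s.key not in {x.key for p in pairs for x in (p.site_a, p.site_b)}:
            s.is_free = True
    pairs.sort(key=lambda p: (p.site_a.key, p.site_b.key))
    return pairs


# ------------------------------------------------------------ distances

def _resolve_selector(model: StructureModel, sel: str) -> list[np.ndarray]:
    """Resolve ``chain:resnum[icode]:atomname`` (glob allowed on the atom
    name) to a list of positions."""
    try:
        chain, resnum, atname = sel.split(":")
    except ValueError as exc:
        raise SelectionError(f"malformed selector {sel!r}; want chain:resnum:atom") from exc
    icode = ""
    if resnum and resnum[-1].isalpha():
        resnum, icode = resnum[:-1], resnum[-1]
    num = int(resnum)
    out = []
    for res in model.residues:
        if res.chain_id != chain or res.seq_num != num or res.icode != icode:
            continue
        for a in res.atoms:
            if fnmatch.fnmatchcase(a.name, atname):
                out.append(a.pos)
    if not out:
        raise SelectionError(f"selector {sel!r} matched no atoms")
    return out


def measure_distance(model: StructureModel, sel_a: str, sel_b: str,
                     mode: str = "single") -> float:
    """Distance between two atom selections, reported to 0.01 Å.

    ``single`` requires each selector to resolve to exactly one atom;
    ``min_over_set`` takes the minimum over the selection product.
    """
    pa = _resolve_selector(model, sel_a)
    pb = _resolve_selector(model, sel_b)
    if mode == "single":
        if len(pa) != 1 or len(pb) != 1:
            raise SelectionError(
                f"mode='single' needs unique atoms, got {len(pa)} x {len(pb)}; "
                "use mode='min_over_set'"
            )
        d = float(np.linalg.norm(pa[0] - pb[0]))
    elif mode == "min_over_set":
        d = min(float(np.linalg.norm(a - b)) for a in pa for b in pb)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return round(d, 2)
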