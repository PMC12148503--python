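"""Shared fixtures and independent brute-force oracles.

The oracles re-implement the sweep computations as plain loops over the
definitions, independent of the vectorized implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ssbond.scan import SweepParams
from ssbond.structure_io import StructureModel
from ssbond.synth import DimerSpec, dimer_sites, engineered_separation, make_c2_dimer


# ------------------------------------------------------------- oracles

def oracle_min_cross(pos_a: np.ndarray, pos_b: np.ndarray):
    """Exhaustive per-angle minimum cross distance (pure loops)."""
    mins, argmins = [], []
    for i in range(len(pos_a)):
        best, bestj = math.inf, -1
        for j in range(len(pos_b)):
            d = math.dist(pos_a[i], pos_b[j])
            if d < best:
                best, bestj = d, j
        mins.append(best)
        argmins.append(bestj)
    return np.array(mins), np.array(argmins)


def oracle_clash_mask(positions: np.ndarray, model: StructureModel, site,
                      params: SweepParams) -> np.ndarray:
    """Naive all-pairs vdW overlap test, straight from the definition."""
    r_s = params.radius_of("S")
    mask = np.zeros(len(positions), dtype=bool)
    for i, p in enumerate(positions):
        for res, atom in model.iter_atoms():
            if atom.element.upper() in ("H", "D"):
                continue
            if res.res_name in ("HOH", "WAT", "DOD"):
                continue
            if params.clash_exclusion(site, res, atom):
                continue
            d = math.dist(p, atom.pos)
            if (r_s + params.radius_of(atom.element)) - d > params.clash_overlap:
                mask[i] = True
                break
    return mask


def oracle_feasible_pairs(pos_a, pos_b, angles, clash_a, clash_b,
                          params: SweepParams):
    """Exhaustive feasibility enumeration from the definition."""
    pairs = []
    lo = params.ss_target - params.ss_tolerance if params.apply_lower_bound else -math.inf
    hi = params.ss_target + params.ss_tolerance
    for i in range(len(pos_a)):
        if clash_a is not None and clash_a[i]:
            continue
        for j in range(len(pos_b)):
            if clash_b is not None and clash_b[j]:
                continue
            d = math.dist(pos_a[i], pos_b[j])
            if lo <= d <= hi:
                pairs.append((float(angles[i]), float(angles[j])))
    return pairs


def random_rigid(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


# ------------------------------------------------------------ fixtures

@pytest.fixture(scope="session")
def params() -> SweepParams:
    return SweepParams()


@pytest.fixture(scope="session")
def engineered_dimer(params):
    """C2 dimer whose minimum cross S-S distance is exactly 2.05 Å at
    χ1 = (-120°, -120°)."""
    sep = engineered_separation(2.05, params)
    model = make_c2_dimer(DimerSpec(cb_separation=sep))
    site_a, site_b = dimer_sites(model)
    return model, site_a, site_b
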