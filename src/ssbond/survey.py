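"""Background distributions of cystine dihedrals.

A collection of structures (supplied explicitly, e.g. via a manifest of
files — typically cystine-knot cytokine, snake-toxin-like and zona
pellucida folds) is filtered by crystallographic resolution, its
disulfides are collected, and each dihedral is binned on [-180, 180]
with a 5° width.  An observed cystine is then scored against the
histogram by the empirical frequency of its bin — the operational form
of calling a conformation an outlier.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cystine import cystine_dihedrals
from .geom import wrap_angle
from .structure_io import StructureModel, detect_disulfides, find_cysteines, select_altloc

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyConfig",
    "SurveyRecord",
    "Histogram",
    "EmptySurveyError",
    "collect_cystines",
    "build_histogram",
    "empirical_percentile",
    "write_records_tsv",
    "read_records_tsv",
]


class EmptySurveyError(ValueError):
    """No records survive the filters."""


@dataclass(frozen=True)
class SurveyConfig:
    resolution_max: float = 2.5          # Å, keep strictly better (<=) entries
    exclusion_ids: frozenset = frozenset()
    bin_width: float = 5.0               # degrees
    ss_max: float = 2.3                  # Sγ-Sγ detection threshold, Å
    density: bool = False                # normalize freq by bin width

    def __post_init__(self):
        n = 360.0 / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"bin width {self.bin_width} does not divide 360")
        if not self.resolution_max > 0:
            raise ValueError("resolution_max must be > 0")


@dataclass(frozen=True)
class SurveyRecord:
    entry_id: str
    resolution: float
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    chi1: float
    chi2: float
    chi3: float


def collect_cystines(models: Iterable[StructureModel],
                     cfg: SurveyConfig = SurveyConfig()) -> list[SurveyRecord]:
    """Per-cystine dihedral records from a structure collection.

    Rules re-expressing the survey's filtering: entries above the
    resolution cutoff or in the exclusion list are dropped whole; a
    cysteine whose Sγ has two or more partners within the detection
    threshold is dropped (ambiguous bonding); free cysteines and
    cysteines missing anchors contribute nothing.  χ1/χ2 of each record
    come from the canonical (lexicographically first) site.
    """
    records: list[SurveyRecord] = []
    for model in models:
        if model.entry_id in cfg.exclusion_ids:
            logger.info("survey: %s excluded by id", model.entry_id)
            continue
        if model.resolution is None or model.resolution > cfg.resolution_max:
            logger.info("survey: %s dropped by resolution filter (%s)",
                        model.entry_id, model.resolution)
            continue
        sites = find_cysteines(select_altloc(model))
        withsg = [s for s in sites if s.sg_pos is not None]
        # ambiguity rule: a sulfur near two partners is not a clean cystine
        ambiguous = set()
        for i, si in enumerate(withsg):
            n_near = sum(
                1 for j, sj in enumerate(withsg)
                if j != i and np.linalg.norm(si.sg_pos - sj.sg_pos) <= cfg.ss_max
            )
            if n_near > 1:
                ambiguous.add(si.key)
                logger.info("survey: %s %s ambiguous (%d partners in range)",
                            model.entry_id, si.key, n_near)
        clean = [s for s in withsg if s.key not in ambiguous]
        for pair in detect_disulfides(clean, max_ss=cfg.ss_max):
            q = cystine_dihedrals(pair)
            records.append(
                SurveyRecord(
                    entry_id=model.entry_id,
                    resolution=model.resolution,
                    chain_a=pair.site_a.residue.chain_id,
                    res_a=pair.site_a.residue.seq_num,
                    chain_b=pair.site_b.residue.chain_id,
                    res_b=pair.site_b.residue.seq_num,
                    chi1=q.chi1,
                    chi2=q.chi2,
                    chi3=q.chi3,
                )
            )
    return records


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray   # bin edges, -180..180
    counts: np.ndarray  # per bin
    freq: np.ndarray    # normalized to sum 1 (or density when cfg.density)
    which: str

    @property
    def n_records(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_index(self, angle: float) -> int:
        w = wrap_angle(angle)
        width = self.edges[1] - self.edges[0]
        return min(int((w + 180.0) // width), len(self.counts) - 1)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["bin_lo", "bin_hi", "count", "freq"])
            for lo, hi, c, f in zip(self.edges[:-1], self.edges[1:],
                                    self.counts, self.freq):
                w.writerow([f"{lo:g}", f"{hi:g}", int(c), f"{f:.8g}"])


def build_histogram(records: Sequence[SurveyRecord], which: str,
                    cfg: SurveyConfig = SurveyConfig()) -> Histogram:
    """Bin one dihedral of the records on [-180, 180].

    Bins are half-open [lo, hi) with +180 assigned to the last bin
    (numpy's convention).  Frequencies sum to 1, or integrate to 1 when
    cfg.density is set.
    """
    if which not in ("chi1", "chi2", "chi3"):
        raise ValueError(f"unknown dihedral {which!r}")
    if len(records) == 0:
        raise EmptySurveyError("no records to bin")
    vals = np.array([wrap_angle(getattr(r, which)) for r in records])
    nbins = int(round(360.0 / cfg.bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    freq = counts / counts.sum()
    if cfg.density:
        freq = freq / cfg.bin_width
    return Histogram(edges=edges, counts=counts, freq=freq, which=which)


@dataclass(frozen=True)
class RarityScore:
    bin_freq: float   # empirical frequency of the angle's bin
    rarity: float     # fraction of records in bins no more populated


def empirical_percentile(angle: float, hist: Histogram) -> RarityScore:
    """Score an angle against the background histogram.

    ``bin_freq`` is the frequency of the bin containing the angle;
    ``rarity`` is the fraction of all records falling in bins whose
    frequency does not exceed that bin's — 0 for an angle in an empty
    region, 1 at the histogram's mode.
    """
    if hist.n_records == 0:
        raise EmptySurveyError("empty histogram")
    idx = hist.bin_index(angle)
    f = hist.freq[idx]
    probs = hist.counts / hist.counts.sum()
    rarity = float(probs[hist.freq <= f].sum())
    if hist.counts[idx] == 0:
        rarity = 0.0
    return RarityScore(bin_freq=float(f), rarity=rarity)


# ------------------------------------------------------------------ I/O

_FIELDS = ["entry_id", "resolution", "chain_a", "res_a", "chain_b", "res_b",
           "chi1", "chi2", "chi3"]


def write_records_tsv(records: Sequence[SurveyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_FIELDS)
        for r in records:
            w.writerow([r.entry_id, f"{r.resolution:g}", r.chain_a, r.res_a,
                        r.chain_b, r.res_b,
                        f"{r.chi1:.6f}", f"{r.chi2:.6f}", f"{r.chi3:.6f}"])


def read_records_tsv(path) -> list[SurveyRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(SurveyRecord(
                entry_id=row["entry_id"],
                resolution=float(row["resolution"]),
                chain_a=row["chain_a"], res_a=int(row["res_a"]),
                chain_b=row["chain_b"], res_b=int(row["res_b"]),
                chi1=float(row["chi1"]), chi2=float(row["chi2"]),
                chi3=float(row["chi3"]),
            ))
    return out
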