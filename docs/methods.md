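# Methods

This note documents the models, conventions and numerical choices
behind `ssbond`, and what the synthetic test fixtures do and do not
establish about real structures.

## Coordinate model and parsing

Structures are read through gemmi (PDB fixed-column and mmCIF
`atom_site`), keeping chains, residues, heavy atoms, occupancies and
the reported resolution (REMARK 2 / `_refine.ls_d_res_high`).  Only the
first model of a multi-model file is used; coordinates are ångströms;
residues are identified by (chain, residue number, insertion code).
Hydrogens are ignored throughout — the X-ray models this package
targets rarely include them — and the clash criterion compensates with
heavy-atom van der Waals radii.

Alternate locations are collapsed before any geometry is computed.
The default policy keeps the highest-occupancy conformer, ties broken
by altloc label order; a fixed-label policy is available.  This choice
is material: structures crystallized from bonded/free cysteine
mixtures model the interchain cysteine in two conformations, and which
conformer survives decides every downstream dihedral.  The policy is
therefore explicit, logged, and applied identically in the survey.

## Dihedrals and the cystine quintet

Torsions follow the IUPAC sign convention (cis = 0°, positive =
clockwise viewed along the central bond), reported on (−180°, +180°].
A disulfide is summarized by χ1 = N-Cα-Cβ-Sγ, χ2 = Cα-Cβ-Sγ-Sγ′ on
each side and the shared χ3 = Cβ-Sγ-Sγ′-Cβ′.  The quintet is
canonically ordered by the lexicographically smaller (chain, residue)
key, which makes χ3 bit-identical under site exchange and maps the
quintet to its primed reversal.

Screw-sign descriptors report the sign quintet and χ3 handedness
(right iff χ3 > 0).  A torsion of exactly 0° is assigned "+" by
convention, flagged as a boundary case, and given *no* handedness: a
syn-periplanar bond must not silently read as right- or left-handed.
The full 20-name screw taxonomy is deliberately not implemented — for
strained geometries it adds no discriminating information.

Disulfide detection pairs Sγ atoms within 2.3 Å greedily by ascending
distance (the ideal bond is ~2.05 Å; the margin absorbs refinement
noise).  Each sulfur joins at most one partner; ambiguous sulfurs
(a second partner in range) are warned about and, in the survey,
excluded outright.

The cysteinylation mass shift is cysteine (C3H7NO2S) minus two
hydrogens: 119.14 Da with CIAAW average masses (119 Da at integer
precision, rounding half away from zero) and 119.004 Da monoisotopic.

## Torsion energies

The three AMBER cosine series (amplitudes 2.0, 1.0 and 3.5 + 0.6
kcal/mol) are evaluated in degrees and exposed per-dihedral plus as a
per-cystine total; the parameter set's unit (kcal/mol) labels all
outputs.  Whether a figure-style strain axis should show per-dihedral
terms or the cystine total is a presentation choice; both are computed.

## The χ1-sweep accessibility scan

Sulfur placement uses internal coordinates (natural-extension /
NeRF construction): the unique point at bond length 1.81 Å from Cβ,
bond angle 114.3° at Cβ, torsion χ1 about N-Cα-Cβ.  This is
algebraically the same as composing a height vector
1.81·cos(π − 114.3°) along Cα→Cβ with a radial vector
1.81·sin(π − 114.3°) rotated by χ1, and round-trips the torsion to
better than 1e-6° over random rigid placements.  The default grid is
1° anchored at −180° + step, so the canonical m/p/t rotamers
(−60°/+60°/180°) are grid points.

An angle is eliminated as clashing when its virtual sulfur overlaps a
heavy atom by more than 0.4 Å, with radii S 1.80, C 1.70, N 1.55,
O 1.52 Å (others 1.70 Å).  Exempt by default: the sulfur's own residue
and the backbone N/C/O of its immediate sequence neighbours (the
1-2/1-3/1-4 bonded relationships); waters are skipped.  The published
analyses this emulates judged clashes by interactive MolProbity-style
inspection, which fixes no single numeric threshold — the 0.4 Å
overlap is this package's default and every ingredient is
configurable.  Arc endpoints can shift by a few degrees under
defensible alternative thresholds.

Cross-protomer minima are exhaustive over the grid product (the
per-angle minimum and arg-min partner are reported; clash-marked
partners can be excluded by flag, though by default all angles enter
and feasibility applies the clash filter).  Feasibility requires both
angles clash-free and the distance at most 2.0 + 0.1 Å.  No lower
bound is applied by default — the criterion is phrased as not
exceeding the maximum permissible bond length, and a much closer
approach already registers as a clash — but an optional
[1.9, 2.1] Å band exists.  The best pair minimizes |d − 2.0 Å|.

Because the cross-distance function is smooth and flat (O(δ²)) around
its minimum, distance alone can never isolate a single 1°-grid pair
inside a ±0.1 Å band; single-pair verdicts arise only when clash
elimination narrows the rotamer windows.  This is a property of the
geometry, worth keeping in mind when reading feasibility sets.

Registration-shift scans re-run the full analysis after applying a
rigid transform to the protomer containing the second site (clash
atoms included), and report, per shift, the feasibility verdict plus
the χ3 each feasible pair would adopt (computed from the placed
sulfurs and fixed Cβ positions); a shift is called unstrained when
some feasible pair has |χ3| within 30° of 90° (configurable).

## Dihedral surveys

The survey takes an explicit collection of structures (or a manifest
file listing them — one path per line, optional resolution override)
rather than querying a database, so it is reproducible from a pinned
input list.  Entries are dropped whole when their resolution is
unknown or worse than 2.5 Å, or when their id is excluded.  Records
are per-cystine; χ1/χ2 come from the canonical site (whether both
protomers' χ1/χ2 should enter the histograms is a survey-design choice;
one-per-cystine keeps the three histograms on the same record count).
Records count 1 regardless of conformer occupancy, since the altloc
policy has already selected one conformer.  Published survey counts
from any specific database snapshot are historical context, not
reproducible targets.

Histograms use 72 half-open 5° bins on [−180°, 180°] with +180°
assigned to the last bin; frequencies sum to 1 (per-bin probability;
density per degree by flag).  The rarity score of an angle is the
fraction of records in bins no more populated than the angle's bin —
0 in an empty region, 1 at the mode — an empirical, assumption-free
way to quantify "extreme outlier".

## Synthetic generators

`make_ideal_cysteine` uses fixed ideal internal coordinates
(N-Cα 1.458 Å, Cα-Cβ 1.530 Å, N-Cα-Cβ 110.5°, plus stub C/O).
`make_c2_dimer` either (a) arranges two such residues as exact C2
images about z with the sulfur cones facing each other — the closest
cone approach is then cb_separation − 2·r_cone at a chosen χ1, which
gives a closed-form recipe for engineering a feasibility minimum
(e.g. 2.05 Å at χ1 = −120°/−120°) — or (b) builds a complete cystine
outward from internal coordinates so a requested dihedral quintet is
realized exactly (a conflicting requested Cβ separation raises a
construction error naming the obstruction).

Clash probes place one carbon pseudo-atom per grid step along a
requested arc, each offset from its cone point along the Cα→Cβ axis at
the distance where the overlap criterion fires only within the probe's
per-step angular coverage; the union eliminates the arc to within one
grid step.  Probes sit out of the cone plane, so a facing protomer's
cone at bonding-range distances is never touched (verified against the
brute-force oracle; callers building other geometries should re-check
with the oracle, which the tests do).

Dihedral ensembles are wrapped-normal mixtures — chosen over von Mises
because the recovery formulas (circular component means, standard
errors ~ sd/√n_component) are elementary — sampled with numpy's
seeded Generator and emitted as survey records with synthetic ids and
a resolution below any filter under test.  The default χ3 background
(equal modes at +95° and −87°, sd 8°) emulates the bimodal ±90°
concentration of relaxed disulfides; defaults for χ1/χ2 are single
wells at −60°/−80°.  What passing these tests shows is that the
statistics pipeline recovers known truth at survey-scale n; it does
not certify any claim about the conformational content of real
crystallographic ensembles, which carry correlations, refinement
restraints and occupancy mixtures the generator does not emulate.

## Problem sizes and determinism

Default analyses use the 1° grid (360 positions per site, 129,600
cross pairs), ensembles of 10,000 records, and 10,000 random draws for
the placement round-trip property; all complete in seconds.  Brute-
force oracles (naive all-pairs loops) back the vectorized paths in the
test suite and acceptance script.  All randomness flows through
numpy `default_rng` seeds; generators are bit-deterministic under a
fixed spec and seed.  Fixture round-trips through PDB files carry the
format's 1e-3 Å coordinate precision, i.e. ~0.05° on dihedrals.

## Known limitations

* Only χ1 is swept; χ2 of an existing partner sulfur is honoured but
  not varied, and there is no continuous optimization between grid
  points or energy-weighted sampling.
* Clash detection is a single-threshold heavy-atom overlap test, not a
  full MolProbity contact analysis (no hydrogens, no aromatic/polar
  special-casing).
* The survey requires user-supplied structure files; there is no
  database retrieval, and no kernel density estimation beyond the
  histograms.
* Users must supply biological-assembly coordinates; no symmetry-mate
  expansion is performed.
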