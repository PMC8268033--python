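# Methods

## The quality model

Each assessable entity — a bound small molecule, or one residue of its
binding site — receives an integer penalty score: one point per violated
check among

| check | quantity | limit | direction |
|---|---|---|---|
| a | real-space R-factor (RSR) | 0.4 | value must be ≤ |
| b | "Good" RSR | 0.24 | value must be ≤ |
| c | real-space correlation coefficient (RSCC) | 0.9 | value must be ≥ |
| d | average occupancy | 1.0 | value must be = |
| e | occupancy-weighted average B-factor (OWAB) | 50 Å² | value must be ≤ |
| f | R_free | 0.3 | value must be ≤ |
| g | R_free − R_work | 0.05 | value must be ≤ |

Scores map to categories Good (0), Dubious (1–2), Bad (>2). The binding
site takes the maximum score over its residues (all residues attaining the
maximum are listed for inspection), and the ligand and site category
initials form the pair code (GG … BB).

Three readings of the check list are deliberate design choices:

* **Equality passes.** "Maximum X: L" is read as X ≤ L acceptable, so a
  value exactly at a limit is never penalized. The choice is configurable
  only by moving the limit itself.
* **RSR above 0.4 costs two points** (checks a and b are distinct
  parameters). This is the only reading under which the maximum
  single-entity score of 7 is attainable, and that maximum is observed in
  practice.
* **The global checks f and g apply to every entity** of an entry, for the
  same reason: a single ligand can only reach 7 if entry-level R-factor
  failures count toward its score.

Checks whose inputs are unavailable are *skipped* and the entity is flagged
incomplete: absence of evidence must not manufacture a penalty, and the flag
preserves auditability. An `exclude_incomplete` switch drops such rows
entirely, mirroring workflows that discard entries lacking deposited
structure factors. Average occupancy is computed per atom site with
alternate-location occupancies summed first, so full-occupancy disorder
(A 0.5 + B 0.5) is not mistaken for partial occupancy; sums above 1 raise a
data-quality warning, not a penalty. OWAB is defined here as
Σ(occ·B)/Σ(occ) over heavy atoms (the quantity is conventionally named but
not given a formula alongside its limit; hydrogens are excluded because
most crystallographic models lack them).

## Ligand selection and binding sites

A residue is an assessable ligand when it is a non-polymer component with at
least one carbon atom, a molecular weight inside the inclusive 70–800 Da
window, and a component code not on the exclusion list. The default
exclusion list is water (HOH, DOD) plus common carbon-containing
cryo-solvents and buffers (EDO, GOL, PEG, PGE, DMS, ACT, MPD, EOH, IPA);
metal ions and carbon-free anions fall to the carbon rule. The list is a
reasonable stand-in for archive practice and fully configurable. Molecular
weight uses the component formula when supplied (capturing implicit
hydrogens), otherwise the summed masses of the atoms present, each site
counted once across alternate locations.

The binding site is the set of polymer amino-acid residues with at least one
heavy atom within 4.5 Å (inclusive) of any ligand heavy atom. Heavy-atom
distances are used because deposited structures rarely carry hydrogens;
waters and other hetero groups near the ligand are not site residues.
Covalent attachment is flagged either from explicit connectivity records
(which take precedence) or when a ligand heavy atom lies within the covalent
radius sum + 0.45 Å of a polymer heavy atom; covalently bound ligands are
reported but not pair-classified, since the occupancy/fit checks presuppose
a discrete non-covalent entity. Only model 1 is assessed by default.

## Density-support scores and polder maps

EDIA-style per-atom scores are consumed, never computed from maps. Support
categories use the published boundaries (≥ 0.8 satisfactory, ≥ 0.4 medium,
else poor). OPIA is reconstructed from per-atom values plus the ligand's
heavy-atom bond graph: atoms at or above 0.8 are well-resolved, and the
reported percentage counts only well-resolved atoms lying in connected
components of size ≥ 2 of the graph restricted to well-resolved atoms —
an isolated supported atom in an otherwise unsupported ligand does not
count. Both the threshold and the minimum component size are parameters.

The polder procedure yields three maps — m1 (calculated, omitted atoms
present), m2 (calculated, omitted atoms absent / bulk solvent), m3
(polder map from experimental data) — and three pairwise correlations.
The qualitative rule "m3 should correlate sufficiently better with m1" is
quantified with two knobs: a dominance margin (default 0.05) and a CC(1,3)
floor (default 0.8). Supported requires both; a CC(1,3) below the floor, or
the bulk-solvent correlation exceeding CC(1,3) by the margin, indicates
bulk solvent or noise; everything else is ambiguous. When the ligand's mean
B-factor exceeds the site mean by the flag ratio, the verdict carries a
mobile-atom caveat (a smeared m1 can masquerade as bulk solvent).

## Stereochemistry

All three measures use coordinates only and are deterministic.

**Clashes.** A bad clash is a ligand-heavy/protein-heavy pair with van der
Waals overlap r_i + r_j − d ≥ 0.4 Å (a 1e-9 Å guard absorbs float
representation error at the boundary). Because inputs lack hydrogens,
hydrogen bonds are excluded by proxy: donor–acceptor element pairs (N/O/S
with N/O) at 2.4–3.5 Å are marked excluded rather than bad. The radius set
is a standard Bondi-style table, configurable.

**Energy.** The published semi-empirical force field behind bound-state
energy scores (grids, desolvation, torsions) is not reproduced. The
surrogate keeps its contracts — sign convention (negative favorable),
per-heavy-atom normalization, positivity on clashes — with a pairwise 12-6
dispersion–repulsion term (r_min = r_i + r_j, well depth the geometric mean
of per-element depths) plus Coulomb electrostatics under a
distance-dependent dielectric ε(r) = 4r, summed within an 8 Å cutoff, in
kcal/mol. Per-element default charges (C 0.0, N −0.35, O −0.45, S −0.15)
apply only when the input carries none; they are a fixture convention, not
chemistry. An optional 12-10 hydrogen-bond well can replace the 12-6 term
for donor–acceptor pairs. Parameter tables are pluggable so a full force
field can be swapped in. A well-packed apolar pose lands in the plausible
−1.0 to 0.0 kcal·mol⁻¹·atom⁻¹ band (the example prints −0.36).

**Packing density.** Per atom, the ratio of van der Waals volume to locally
available volume under the additively-weighted (radius-offset) Voronoi
partition, with each cell capped at r_atom + 2·probe (probe 1.4 Å): an
isolated atom's density is exactly (r/(r+2·probe))³ ≈ 0.054 for carbon.
Volumes are integrated on a cubic grid (default 0.2 Å) with linear
anti-aliasing of the boundary surfaces — each grid point near a cell face,
the sphere surface or the cap contributes fractionally according to its
signed distance — which removes the O(h) surface quantization bias of plain
counting; halving the spacing changes densities by well under 0.02 on the
fixture suite, and the twelve-neighbor contact shell reproduces the analytic
FCC-cell value 0.740 to within 0.003 at 0.1 Å spacing. Atoms involved in
bad clashes are excluded from the ligand mean (their cells are unreliable).
Exact packing values from other implementations on undisclosed structures
are not reproduction targets; range, ordering and convergence are.

## Survey aggregation

Year-wise percentages divide each (category, year) count by the *whole
dataset's* pair count, so all cells across categories and years sum to
100%. "2.5 Å or better" means resolution ≤ 2.5 (crystallographic
convention: smaller is better). The deposition year is used; records
without one are excluded from year tables. Percentages are reported to one
decimal with raw counts always alongside. The low-attention rollup is the
GG+GD+DG+DD share of all pairs.

## Synthetic data

The generators produce structurally faithful inputs, not physics:

* **Pockets** place a rigid 7-atom carbon-ring-plus-oxygen ligand (88.06
  Da) at the origin and glycine-like stubs (N, CA, C, O, CB) along
  golden-spiral shell directions, pushed out by bisection until the minimum
  heavy-atom distance matches the target to 1e-4 Å (well inside the
  documented 0.01 Å tolerance). The first residue realizes the target
  exactly; later residues add the optional uniform radius jitter. Injected
  clash residues place their CB at r_CB + r_target − overlap from the most
  exposed ligand atom. Default target distance 4.4 Å: inside the 4.5 Å
  site criterion but clash-free.
* **Metric tables** sample every value strictly on the prescribed side of
  its limit with a margin of 5% of the limit's magnitude, so scoring
  round-trips are unambiguous under floating point. Prescriptions
  containing check (a) without (b) are rejected: a single RSR value above
  0.4 is necessarily above 0.24, so 96 of the 2⁷ violation subsets are
  realizable. Category quotas are realized exactly by largest-remainder
  apportionment. The default survey mix (ligand margins 27/51/22, pair GG
  and BB at 11%, a low-attention rollup near two thirds) is shaped like a
  realistic archive-wide survey.
* **Survey sets** draw pair codes from prescribed probabilities, scores
  consistent with each code (G = 0, D ∈ {1,2}, B ∈ {3..7}), years uniform
  over the range, and resolutions from a clipped normal (mean 2.1 Å,
  sd 0.6, bounds 0.8–4.5 Å).

All generators are pure functions of (spec, seed) via numpy's PCG64;
regenerating yields byte-identical files. What passing tests show: the
scoring, geometry and aggregation machinery is correct on inputs with known
ground truth. What they do not show: agreement with any particular archive
snapshot — real validation data has correlated metrics, heterogeneous
chemistry and missing values that the generators only caricature, so
dataset-level percentages from synthetic runs characterize the generator,
not the archive.

## Numerical choices and degenerate inputs

Distances in Å, B-factors in Å², energies in kcal/mol. Inclusive
comparisons at decision boundaries carry a 1e-9 guard only where float
representation demands it (clash threshold); score limits use exact
comparisons on the raw values. Empty binding sites cannot be labeled
(error); all-zero occupancies make OWAB undefined (error); coincident atoms
make the energy undefined (error); an empty record set has no distribution
(error). A degenerate packing cell fully swallowed by neighbors reports
density 1.0. Ties for the worst site residue are all reported, sorted by
residue key.

## Known limitations

* No chemistry perception: bond orders, protonation and hydrogen placement
  are out of scope; the hydrogen-bond proxy is element+distance only.
* RSCC/RSR/EDIA/polder values are inputs; nothing is computed from maps or
  structure factors.
* The energy surrogate omits desolvation, torsional strain and explicit
  hydrogen bonding by default; its absolute values are comparable only
  within this package.
* Multi-ligand sites are assessed per ligand independently; ligand–ligand
  interactions are not modeled.
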