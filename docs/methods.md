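# Methods

This note records the scientific conventions the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Solvation-energy stability maps

The stability metric is a surface-area–based solvation free energy of the
folded fibril relative to an unfolded reference, evaluated on a *central
chain*: one chain per protofilament at the median axial position, so the
scored chain has both axial neighbors and the full lateral environment.
At least three assigned layers are therefore required.

Per heavy atom: `ΔG = ASP · (SASA_fold − SASA_ref) / 1000` kcal/mol, with
negative = stabilizing. (Equivalently, the buried area `SASA_ref − SASA_fold`
times the ASP, output with the sign flipped; the convention is stamped into
every output's metadata as `fold-minus-ref (negative = stabilizing)`.)

- **ASP table** (`data/asp.tsv`): the classic five-class atomic solvation
  parameters — carbon +16, neutral N/O −6, charged carboxylate O⁻ −24,
  charged N⁺ −50, sulfur +21 cal·mol⁻¹·Å⁻². The table is an editable data
  file and its identity is recorded in every energy map, because published
  per-chain figures for deposited fibrils can only be matched within a
  tolerance, not bit-exactly, under any independently chosen parameter set.
- **Charge classes** are assigned by a deterministic heavy-atom rule with no
  pKa calculation: Asp OD1/OD2, Glu OE1/OE2 and C-terminal OXT are O⁻;
  Lys NZ and Arg NE/NH1/NH2 are N⁺; His ND1/NE2 become N⁺ only under an
  explicit protonation flag (default off).
- **Entropy term** (`data/entropy.tsv`): a per-residue ordering penalty
  (side-chain conformational entropy scale, TΔS near 298 K; Gly/Ala/Pro 0,
  up to ~2.1 kcal/mol for Gln/Arg), added once per scored residue. The
  precise accounting behind published fibril numbers is not uniquely
  determined, so the shipped scale is a declared stand-in with an off-switch
  (`include_entropy=False`) so its contribution can be isolated.
- **Ligands** are environment by default: they occlude the scored chain's
  folded-state surface but are not themselves scored.
- **Additivity is exact**: chain totals equal residue sums equal atom sums
  plus entropy, to 1e-9 (pure summation, no renormalization).
- **Difference maps** pair atoms by (chain rank, residue number, residue
  name, atom name) so two structures with different chain labels still
  align; unpaired atoms are excluded and counted, and more than 5% unpaired
  aborts the comparison as a likely construct mismatch. The difference is
  antisymmetric by construction.

## SASA engine

Shrake–Rupley with a deterministic generalized-spiral (golden-angle) point
set — no random sphere orientations, so results are bit-reproducible run to
run. Defaults: probe 1.4 Å, 960 points per atom (convergence against 3840
points is better than 1% on fixture totals; agreement with the analytic
two-sphere cap formula is ~0.5% at 960 points). Hydrogens are ignored:
deposited fibril models are heavy-atom and the ASP classes are
heavy-atom-typed. Van der Waals radii come from one element-keyed Bondi-type
table (`data/vdw_radii.tsv`).

**Reference state.** Two modes:

- `extended-rebuild` (default): an ideal extended backbone is generated by
  natural-extension (NeRF) chain building with φ = −120°, ψ = +120°,
  ω = 180° and Engh–Huber-like bond geometry, and each residue of the input
  chain is moved rigidly onto it (least-squares fit of its N/CA/C onto the
  ideal trace). Residue identity, atom composition and internal side-chain
  geometry are preserved exactly. We deliberately do not re-derive side-chain
  chi angles: in an extended strand neighboring side chains are far apart,
  so the reference area is insensitive to chi, and a per-residue-topology
  rebuilder would add failure modes without changing the observable.
  Residues missing backbone atoms fall back to their as-posed coordinates
  and are listed in the result.
- `isolated-chain`: the chain as posed, all other chains removed. In this
  mode the reference area bounds the folded area atom-by-atom (burial can
  only reduce area); in extended-rebuild mode that bound holds for chain
  totals but not necessarily per atom, since the conformation changes.

## Density maps and occupancy

Maps are read/written as MRC2014 via `mrcfile`; the axis-correspondence
header fields are honored and grids are canonicalized to x/y/z order.
Non-orthogonal cells and anisotropic voxels are rejected (cryoEM maps are
orthogonal).

The three-mask occupancy estimate uses: site mask = voxels within 2.0 Å of
any ligand atom; reference mask = within 2.0 Å of the backbone (N/CA/C/O) of
a residue stretch modeled at full occupancy (345–352 by default for tau);
solvent mask = a 6–12 Å shell from any model atom. All radii are
configurable. A shell was chosen over "everything that is not model" so the
solvent statistic is insensitive to box padding and map edges. `max` is the
literal maximum voxel value inside a mask; a trimmed maximum (99th
percentile) is available for noisy maps and demonstrably reduces
seed-to-seed variance in the tests, but is off by default because the
formula's literal reading uses the maximum. Estimates are not clamped to
[0, 1], and the three intermediate statistics are always reported.

Model-map fit is a masked Pearson correlation against a Gaussian-atom
simulated map: one isotropic Gaussian per heavy atom, σ = resolution/3,
amplitude proportional to atomic number. This is a stated convention —
adequate for pose ranking and occupancy fixtures, not a physical scattering
model.

## Interface metrics

- **Buried area**: SASA(partner alone) − SASA(partner in complex). The
  receptor-side convention is the default and the headline number (the area
  a ligand buries *on the fibril surface*); the ligand side and the exact
  average are also available. For a ligand column, selecting one copy keeps
  the axial neighbor copies in the receptor, matching the "single molecule
  buried by the fibril and other ligand copies" reading.
- **Hydrogen bonds**: heavy-atom N/O pairs across two disjoint selections in
  different residues, distance ≤ 3.5 Å; the D–H…A angle criterion (≥ 120°)
  applies only when explicit hydrogens are present. In heavy-atom models the
  donor is reported as the nitrogen of an N/O pair; the pair list is
  symmetric under swapping the selections.
- **Stacking**: ligand copies are ordered along the fibril axis; per
  adjacent pair the whole-molecule centroid separation, least-squares
  plane–plane tilt (0–90°) and per-ring centroid separations are reported.
  Rings are classified solvent-facing vs fibril-facing by mean radial
  distance from the axis; a curved (compressed) stack shows solvent-face
  separations below the rise and fibril-face separations above it.
- **Pose report**: per candidate pose the masked real-space correlation
  (when a map is given), receptor-side buried area, hydrogen-bond count,
  clash count (heavy-atom pairs closer than 0.6× the radius sum) and a
  *simplified* complementarity score: the fraction of ligand van der Waals
  surface points whose gap to the nearest receptor atom surface lies within
  [0, 1] Å. This is explicitly non-canonical (a full surface-normal
  complementarity statistic is out of scope) but monotone for ranking one
  ligand in one site. Ranking is lexicographic — correlation, then clashes,
  hydrogen bonds, buried area, complementarity — and the rule string is
  recorded in the output.

## Layer spacing

Spacing is the Euclidean Cα–Cα distance between layer-equivalent residues of
adjacent layers within a protofilament, aggregated over layer pairs and
frames (mean, sample sd, max). Euclidean distance was chosen over axial
projection as the primary mode because it tracks "separation between
molecules" even when a prying ligand tilts a layer; an `axial` mode is
provided, and is exact (equal to the rise) for any twist, whereas the
Euclidean spacing of an atom at radius r gains a chord contribution
2·r·sin(twist/2) — about 0.07 Å at a 1.2° twist and 40 Å radius.
Perturbation profiles subtract a control profile residue-wise, propagate
spreads in quadrature, and report the argmax residue; both the mean and the
max spacing are emitted because a hinged layer shows up much more strongly
in the max.

## Screen ranking

One score per (compound, engine), lower = stronger. Z-scores are computed
per engine over the full screened library (≥ 3 scores required; zero spread
is an error naming the engine), so rankings are invariant under affine
rescaling of any single engine's score scale. The consensus is the
unweighted mean of available engine z's — the fusion rule is not uniquely
determined by practice, so per-engine columns are kept alongside. Hit
selection takes consensus z ≤ threshold (default −2), optionally truncated,
with spiked control compounds flagged rather than removed. Docking-box
helpers emit a 20 × 16 × 12 Å grid-box config (the cleft-site default) and a
7 Å edge parameter for sphere-style engines, centered on the bound-ligand
centroid.

## The synthetic generator

`FixtureSpec` describes one world; every output is a pure function of it
(bit-identical under the same seed, which only randomness — map noise —
consumes). Defaults are the stated fibril conditions: 5 layers, 2
protofilaments (10 chains), 4.8 Å rise, −1.2°/layer twist (a fixture
convention at the typical PHF scale, not a measured value), residues
numbered 306–353, ligand column of one copy per layer at 4.8 Å spacing, 1 Å
voxels at 3.8 Å nominal resolution.

- The template layer is a flat poly-Ala hairpin (or poly-Gly strand): two
  extended strands per protofilament at x = 7 and 16 Å, protofilament B the
  C2 image about the fibril axis. The 14 Å inter-protofilament cleft keeps
  ligand density resolvable from the walls at the default resolution — with
  a tighter cleft the site mask reads protein density and the occupancy
  estimator is biased high, which is a real effect the estimator does not
  correct for.
- The mock ligand is a rigid planar tri-ring scaffold (18 carbons, rings
  RA/RC/RD) with no chemistry beyond geometry. A "curved stack" is produced
  by an index-proportional shear that places adjacent solvent-facing ring
  centroids exactly at the requested compression (e.g. 3.5 Å) while the
  fibril-facing spacing widens — an idealized curvature, not an energy
  minimum.
- Maps are Gaussian-atom simulations; the ligand component is normalized so
  that at amplitude fraction 1.0 its peak equals the protein peak over the
  reference backbone, making the fraction the ground-truth occupancy by
  construction. Noise is independent Gaussian per voxel; correlated cryoEM
  noise, B-factors, sharpening artifacts and projection effects are *not*
  modeled.

Hence a green synthetic test establishes that the estimators recover known
geometric/statistical ground truth through the full code path — it does not
establish agreement with any published per-structure number, which requires
the deposited coordinates and maps as inputs (the corresponding acceptance
test states this explicitly when those files are absent).

## Numerical choices

- Coordinates are Å throughout; mmCIF author numbering is used (matching
  tau residue numbers 306–378 in deposited models). Coordinates are stored
  in float32 (the container's native precision), so rigid-transform
  invariances are asserted at ~1e-4 Å on ~40 Å structures.
- Layer clustering splits sorted axial centroid projections at gaps larger
  than 2.4 Å (half a cross-β rise; configurable — use ~rise/2 for unusual
  symmetries). A chain spanning more than 1.5× the estimated rise along the
  axis is reported as ambiguous by name.
- The fibril-axis estimate uses the principal direction of nearest-neighbor
  chain-centroid displacements, not centroid PCA: in a two-protofilament
  fibril the in-plane spread can exceed the axial spread and PCA then picks
  the wrong direction, whereas each chain's nearest neighbor is its axial
  partner one rise away.
- Helical expansion rotates about the axis line through the origin; the
  generator builds its templates in that frame. Chain ids are minted
  deterministically from a fixed alphabet, template ids first.
- Ties in ranking tables are broken lexicographically by compound/pose id
  (stable sorts), so outputs are reproducible across runs and platforms.

## Known limitations

- No electrostatics, force-field energies or conformational sampling: the
  stability metric is surface-area–based by design.
- The extended reference rebuild keeps side chains rigid (see above); an
  alternative reference convention (e.g. Gly-X-Gly maxima) would shift
  absolute chain energies, which is one reason published per-chain values
  carry a generous tolerance.
- Occupancy assumes the reference backbone stretch is at full occupancy and
  that the solvent shell is free of unmodeled density.
- The hydrogen-bond detector does not type sp2/sp3 geometry or restrict
  acceptor lone-pair directions; in heavy-atom models it is distance-only.
- Trajectory formats are not parsed; ensembles enter as multi-model
  coordinate files converted upstream.
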