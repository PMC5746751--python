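# Methods

## System and conventions

The package analyzes planar bilayers of ion-pair amphiphiles (IPAs): each
complex pairs a C_mTMA+ cation (head nitrogen, m chain carbons) with a
C_nS- anion (head sulfur, n chain carbons). The bilayer normal is fixed to
the z axis; no principal-axis detection is attempted, which keeps every
estimator deterministic and matches the standard simulation setup in which
the membrane is built normal to z. Units are nm, ps and degrees at all API
boundaries; molar energies are J/mol with R·T evaluated at 298 K by default
(CODATA constants; k_B·298 K = 4.1143e-21 J).

Carbon numbering starts at C1 on the carbon bonded to the charged head and
increases toward the terminal methyl. The asymmetry index ΔC = m − (n + 1)
counts the intrinsic one-atom offset of the pair: the sulfate bridging
oxygen sits at the height of the cation's first chain carbon, so even m = n
complexes are asymmetric.

Trajectory I/O goes through MDAnalysis (GRO/PDB coordinates, XTC/DCD
trajectories); positions are converted to nm on read. Molecules are made
whole by walking each chain atom-by-atom and taking the minimum image of
every bonded step, since bonded distances are always far below half a box
edge — anchoring on the head atom alone would mis-wrap long chains in small
boxes. Residue roles and chain lengths come from a small YAML declaration
(resname → {role, chain_length}); cation and anion residues are paired in
file order.

## Estimators

**Area per complex.** A_IPA = ⟨A⟩/N from the lateral box area series; N is
the per-leaflet complex count.

**Midplane and leaflets.** The midplane is the mean z of all chain carbons.
A complex is assigned to the upper leaflet iff its head nitrogen lies above
the midplane; the anion chain follows its own sulfur, so interdigitated
configurations can in principle split. Heads exactly on the midplane fall
back to the chain-centroid sign with a warning.

**Density profiles.** Head-species z positions relative to the per-frame
midplane, histogrammed at 0.05 nm (default); the profile integrates to the
per-frame atom count. The head-alignment offset is the signed N-minus-S
argmax-bin difference per leaflet, leaflet-mirrored and averaged; no
smoothing is applied, so the result carries one bin width of uncertainty.

**Tilt.** The chain director runs from C1 to the second-last carbon. The
tilt angle is folded to [0, 90] degrees via arccos(|d_z|/|d|), which
implements the leaflet sign convention symmetrically: a chain along either
leaflet's outward normal measures 0. Distributions use 1-degree bins
(default), fine enough to resolve the narrow gel-phase peaks at this system
size.

**S_CD.** United-atom chains carry no hydrogens, so the two methylene H
positions of carbon i are reconstructed from C_{i-1}, C_i, C_{i+1} by ideal
tetrahedral geometry: the H pair lies in the plane perpendicular to the
C_{i-1}→C_{i+1} axis, straddling the backbone bisector at an H–C–H angle of
109.47 degrees. S_CD = ½⟨3cos²α − 1⟩ is averaged over both hydrogens,
molecules and frames, keeping the sign internally (reports use |S_CD|).
C1 and the terminal methyl lack two carbon neighbors and are excluded, so
the profile covers carbons 2..L−1. Exact limits used as test oracles: an
all-trans chain whose director lies along z has every C_{i-1}→C_{i+1} axis
parallel to z, giving S_CD = −1/2 on every methylene; for a tilted all-trans
chain averaged over spin about its director the addition theorem gives
S_CD = −½·P2(cos θ); isotropic orientations average to zero.

**Gauche fractions.** A torsion is gauche iff it lies strictly inside
(−120, 120) degrees; ±120 exactly counts as trans. A chain of L carbons has
L−3 rotatable dihedrals; the dihedral over carbons (i..i+3) is labeled by
its first carbon i (the literature plots profiles against carbon position
without fixing a convention; this one is documented in the outputs).

**Middle-segment averages.** Per-carbon profiles are averaged over carbons
2..min(m, n), capped per chain at the last computable index (L−1 for S_CD,
L−3 for dihedral labels), then averaged over the two chains. For m = n
compositions the window cap at the last computable carbon is flagged in
report metadata, as the asymmetric worked definitions do not pin this case
down.

**Area expansion modulus.** K_A = k_B T ⟨A⟩/(N ⟨δA²⟩) with the population
(1/M) variance, converted to mN/m (1 J/nm² = 10²¹ mN/m). Block-averaged
standard errors of the area series are reported by the convergence
diagnostic.

**Boltzmann inversion and tilt modulus.** F(θ) = −RT ln[P(θ)/sin θ] over
occupied bins, shifted so min F = 0; sin θ is the polar-angle Jacobian, so
uniformly oriented directors invert to a flat profile. A printed variant
multiplying instead of dividing by sin θ is kept configurable
(`jacobian="multiply"`), with division the default and the only reading
consistent with calling sin θ a Jacobian normalization. The modulus χ is
twice the leading coefficient of a least-squares quadratic over the
contiguous run of bins around the global minimum with F ≤ 2RT (window
multiple configurable); fits report θ0, the window, and R². On an exact
parabola the fit is exact regardless of window; flat profiles return χ = 0.
χ is computed per chain type and pooled; the pooled value is the reported
one.

**Splay and bending rigidity.** Each cation/anion chain is a unit keyed by
its head heavy atom (N or S). Two chains of *different* complexes in the
same leaflet whose head atoms lie within a 1.0 nm lateral cutoff (default,
minimum-image in xy) form a pair — ++, −− or +− — and contribute the angle
between their directors. The intra-complex N–S pair is excluded so pairs
always span two complexes. Pair distributions are inverted and fit exactly
as the tilt modulus (shared code path), the curvature converted to
k_B T/rad², and the effective bending rigidity is the φ-weighted harmonic
mean 1/KC_eff = (Σ φij/χij)/(Σ φij) with φij the per-frame sample counts
(whether the weighting scheme counts unique pairs or per-frame samples is
not fixed by the literature formulation; per-frame samples are used and
flagged). Delta-like distributions are flagged as the stiff limit
(χij = ∞, which simply drops out of the harmonic mean).

## Phase classification

Thresholds: A_IPA = 0.45 nm², K_A = 700 mN/m, χ = 10 J/mol/deg²,
KC_eff = 20 k_B T, |S_CD| = 0.31, gauche = 0.15. A property votes gel when
it lies strictly on the ordered side (boundary equality votes Ld: the
thresholds separate groups whose printed values never touch them, with the
gel group strictly inside). The overall call is the majority of
non-abstaining votes, ties broken by the area vote — area is the most
cleanly separated single criterion. The composition rule (gel iff
min(m, n) ≥ 12) serves as the expected label in reports.

On the packaged 16-system reference survey the majority vote agrees with
the composition rule for all 16 systems. One system (16-14) dissents on a
single property: its |S_CD| of 0.305 sits just below the 0.31 threshold
while all five other properties vote gel. The survey text and its table are
not mutually consistent on this point (the prose asserts gel-phase averages
above 0.33); the classifier does not force agreement — the majority vote
simply absorbs the dissent, and the report prints per-property votes so the
discrepancy stays visible.

## Synthetic bilayer generator

The generator produces two-leaflet bilayers (default 64 complexes per
leaflet, the standard 128-molecule setup) whose *statistical* properties
are known exactly, so every estimator can be tested by parameter recovery
without running MD:

- **Chains** are ideal united-atom alkanes (bond length 0.153 nm, bond
  angle 114°) built by internal-coordinate (NeRF) construction; each of the
  L−3 rotatable dihedrals is independently trans (180°) with probability
  1 − p_gauche, else ±60° with equal probability — a binomial oracle for
  the gauche estimator.
- **Tilt** angles are drawn on [0°, 90°] from
  P(θ) ∝ sin θ · exp(−χ(θ−θ0)²/2RT) by rejection sampling; the chain is
  spun uniformly about its director and the director mapped exactly onto
  the target orientation (pointing into the bilayer), so the folded tilt of
  every generated chain equals its drawn angle and Jacobian-corrected
  Boltzmann inversion recovers χ in expectation.
- **Heads** sit on flat planes at ±2 nm (configurable) with a configurable
  signed N-minus-S offset (0 reproduces the head-alignment property of real
  IPA bilayers).
- **Areas** are i.i.d. Gaussian per frame; the variance for a target
  modulus K_A* is obtained by inverting the fluctuation relation. An
  optional AR(1) correlation (default off) exists to exercise the
  block-average diagnostics.

Fixed seeds give bit-identical trajectories and ground-truth records. The
generator deliberately omits excluded volume, water, inter-chain packing
correlations and phase transitions: estimators are pure statistics of
geometry, so passing recovery tests demonstrates estimator correctness, not
force-field realism. Two consequences matter for interpretation: (i) chain
azimuths are independent, so a tilted ensemble (θ0 > 0) carries large
neighbor-to-neighbor splay and a low KC_eff — the gel-like demo spec
therefore uses θ0 = 0 (stiff, near-vertical directors, as in an untilted
gel) to land on the gel side of the KC_eff threshold; (ii) S_CD in the
generator reflects tilt and gauche disorder only, not packing.

The gel-like demo conditions (0.425 nm² per complex, K_A* = 1500 mN/m,
χ = 80 J/mol/deg² about θ0 = 0, p_gauche = 0.05) and fluid-like conditions
(0.50 nm², K_A* = 450 mN/m, χ = 3 J/mol/deg² about θ0 = 30°,
p_gauche = 0.25) mirror the measured property ranges of gel and Ld systems
in the reference survey.

## Problem sizes and numerical choices

Recovery studies run at sizes where sampling error is comfortably inside
the stated tolerances: gauche recovery uses 128 molecules × 80 frames
(≈10⁴ samples per dihedral, 3σ binomial ≈ 0.014 at p = 0.3); K_A recovery
uses 5·10⁴-frame area series (relative standard error √(2/F) ≈ 0.6%); tilt
recovery uses 64 molecules × 5000 frames (6.4·10⁵ director samples, 1°
bins, recovered within a few percent of χ = 40 J/mol/deg²). The pipeline
demos use 32 complexes × 200 frames, enough for all six properties to land
clearly on their ground-truth side of the thresholds.

The default analysis window is the final 25% of frames (configurable),
mirroring the convention of analyzing the equilibrated tail of a long run;
synthetic data are stationary by construction, so the window only matters
for real trajectories. The convergence diagnostic splits each observable
series into k = 5 blocks (configurable) and flags drift when the first and
last block means differ by more than twice their pooled standard error —
roughly a 5% false-positive rate on stationary series, verified by Monte
Carlo in the tests.

Degenerate inputs are handled explicitly: zero-variance area series raise
(infinite modulus), empty histograms and all-abstain vote sets raise,
single-bin distributions invert to a single zero-energy point, delta-like
splay distributions flag the stiff limit, and non-positive area draws are
redrawn with a warning.

## Known limitations

- The splay-pair definition (chain-level, distinct complexes, lateral
  cutoff 1.0 nm) follows the tilt-director convention; other neighbor
  criteria (Voronoi, fixed k-nearest) would shift χij somewhat.
- Peak finding for the head-alignment offset is argmax-bin without
  smoothing; sub-bin offsets are not resolved.
- The classifier's boundary-equality-votes-Ld rule is a convention; no
  measured value in the reference survey sits exactly on a threshold.
- Real Table-2-scale property values (e.g., K_A of a specific m-n system)
  require actual MD trajectories; the package analyzes them when provided
  but cannot generate them.
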