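# Methods

`membranekit` implements the quantitative analyses used to argue that a
transmembrane lipid-saturation sensor (the yeast transcription factor
precursor whose single TMH carries the sensory tryptophan W1042) reads the
*local lipid-packing density* of the bilayer rather than bulk membrane
fluidity.  This note documents the models, the synthetic-data generators,
the numerical choices, and what the tests do and do not demonstrate.

## Local number-density maps

A bilayer trajectory is a stack of frames (positions in Å, orthorhombic
box, per-atom labels assigning each atom to a lipid, a leaflet, a role —
headgroup/glycerol/chain — and a chain segment).  Frames are first
centered: the midplane, defined as the mean of the two per-leaflet mean
headgroup z coordinates, is translated to z = 0, and coordinates are
wrapped periodically (laterally into [0, L); z into [−Lz/2, Lz/2)).

`voxel_density` counts lipid atoms in cubic voxels (default edge 1 Å,
half-open intervals [k, k+1), grid anchored at the box origin), averages
counts over frames, and divides by the voxel volume to give atoms/Å³.
Numerical choices:

* The grid spans the box to the *nearest* whole voxel per axis.  This
  keeps per-voxel densities comparable between compositions whose boxes
  are not integer multiples of the voxel edge: a composition with a
  smaller area per lipid is then genuinely denser per voxel instead of
  being spread over a grid larger than its box.
* Atoms exactly on the upper box face wrap to voxel 0 (deterministic
  binning); the integral of the map times the voxel volume equals the
  mean atom count per frame to machine precision (tested at 1e-6
  relative error, and against a brute-force per-atom binning loop).
* Frames with fluctuating boxes are binned on their own box and averaged
  on the common grid, cropped laterally from the far face and
  symmetrically about z = 0 in depth.
* "Lipid atoms" means every atom carrying an `include_in_density` flag;
  the flag lets users restrict the selection (e.g. heavy atoms only).

`project_depth_lateral` averages the 3D map over the second lateral axis
(y) to produce the depth × lateral representation; a single-voxel slice
would also be faithful to a 2D rendering of the map, but the y-average has
lower variance and is the default.  `depth_profile` additionally averages
laterally, optionally folding +z and −z bins together.  `difference_map`
subtracts two maps voxel-wise on the common grid (equal voxel edges
required).  `band_statistic` reports mean ± SD over voxels with
z_min ≤ |z| ≤ z_max, default 3–10 Å from the bilayer center — the depth
range occupied by the sensory tryptophan.

## Bilayer descriptors

* Area per lipid: lateral box area / lipids per leaflet, frame-averaged;
  per-leaflet values are returned when the leaflets are asymmetric.
* Thickness: distance between the mean z of headgroup reference atoms in
  the two leaflets (the headgroup plane is the phosphate-analog reference;
  which atoms defined thickness in comparable published analyses varies,
  so the reference role is a parameter).
* Chain order: S = ⟨(3 cos²θ − 1)/2⟩ with θ between a chain vector and the
  bilayer normal (+z after centering; flat-bilayer assumption).  The
  default `segment` convention uses the vector segment(i−1)→segment(i+1),
  standard for reduced chain representations without hydrogens; a `bond`
  convention (consecutive segments) is also provided.  S is bounded in
  [−0.5, 1]; degenerate zero-length vectors are skipped and counted.

## TMH-dimer rotational states

Each protomer's helix axis is the dominant principal component of its
backbone trace, oriented N→C.  The sensor residue's azimuth φ is measured
in the plane normal to the axis, from the connector pointing toward the
partner helix (0° = facing the partner; positive rotation right-handed
about the N→C axis).  Frames are classified with a facing threshold of 60°
(exposed as a parameter; the three-configuration partition itself is the
modeled claim, the exact boundary is an implementation choice):
both |φ| < 60° → facing-facing; both |φ| > 120° → away-away; otherwise
mixed.  Frames whose helix axes cross at more than 45° are flagged instead
of classified, because the azimuth construction degrades for strongly
non-parallel helices.  State populations are empirical fractions with
percentile-bootstrap confidence intervals over frames (plain bootstrap;
for autocorrelated trajectories the fractions are still consistent but the
CIs are optimistic — a block bootstrap is a known extension that this
package does not implement).

## Spectroscopy reductions

* **Generalized polarization.**  GP = (I_Ch1 − I_Ch2)/(I_Ch1 + I_Ch2) with
  trapezoidal integrals over 400–460 nm and 470–530 nm on the native grid
  (exact band edges inserted by linear interpolation; channel bounds
  inclusive).  GP ranges from +1 (all intensity in the blue channel, most
  ordered) to −1 (most disordered) and is invariant to intensity scaling.
  Blank spectra on the same grid are subtracted first, clipped at zero.
* **Ratiometric FRET.**  E_rel = I_A/(I_D + I_A) with intensities read at
  exactly 525 and 614 nm by linear interpolation.  Donor-excitation
  spectra can first be normalized to the maximal intensity after direct
  acceptor excitation, which cancels reconstitution-yield differences.
* **FCS.**  G(τ) = (1 + T/(1−T)·e^(−τ/τ_T)) · (1/N) · (1 + τ/τ_D)^(−1),
  the two-dimensional diffusion + triplet model appropriate for a probe
  confined to a membrane.  Fitting is weighted least squares (lmfit
  Levenberg–Marquardt), weights 1/SD when per-point SDs exist, otherwise
  unweighted.  Initial guesses come from the curve (N from 1/G at the
  smallest lags, τ_D from the half-amplitude lag); bounds are 0 ≤ T < 1
  and positive times.  Non-convergence, missing error bars, or τ_D
  escaping to its bound mark the fit as not converged; a triplet fraction
  pinned at a bound is flagged separately.  D = w²/(4τ_D) converts the
  diffusion time to a coefficient; the beam waist w is an instrument
  calibration the user must supply.
* **cwEPR proximity index.**  I_Lf/I_Mf is the ratio of the low-field to
  the mid-field positive-lobe amplitude of the first-derivative spectrum,
  after max-normalization.  The mid-field line is the tallest positive
  peak, the low-field line the strongest resolvable positive peak at lower
  field (scipy peak detection with a minimum-prominence criterion).  The
  index is invariant to field offset and intensity scale; published
  variants of the extremum convention exist (e.g. peak-to-peak), so the
  positive-lobe reading documented here is the one implemented.  Higher
  values indicate a shorter average interspin distance.

## Liposome acyl-chain molarity

A unilamellar vesicle of outer diameter d and bilayer thickness t has
membrane volume (4/3)π(r_out³ − r_in³), r_in = r_out − t, and lipid count
4π(r_out² + r_in²)/APL (two-leaflet mode; a midplane mode using twice the
midplane sphere area is provided, as both conventions are in circulation).
The unsaturated-chain concentration is lipid count × mean unsaturated
chains per lipid / (N_A × membrane volume).  Defaults d = 200 nm,
t = 4 nm, APL = 0.65 nm² are typical fluid-phase values and simultaneously
give ≈4.83×10⁻¹⁹ L and ≈3.7×10⁵ lipids; with them a pure POPC vesicle
(50% unsaturated chains) holds ≈1.3 M unsaturated chains and a 50:50
DOPC:POPC vesicle (75%) ≈1.9 M — the ON and OFF conditions of the sensor.
Explicit lipid counts or volumes override the geometry.  Molarity is
linear in the unsaturated-chain fraction at fixed geometry; the package
deliberately does not model the ON/OFF mapping itself, which is empirical.

## Synthetic-data generators

The generators exist so that every stage has inputs with known ground
truth; they model geometry and sampling distributions, not physics (no
force fields, no integrators, no thermodynamic realism).

**Bilayer.**  Lipids sit on a square lateral grid with the requested area
per lipid (so the box edge is √(N·APL) exactly and the generated area per
lipid is recovered identically).  Each lipid has a ring of headgroup atoms
(count configurable; the PC analog has more than the PE analog), two
glycerol atoms, and jointed-segment-stick chains with a 1.27 Å rise per
segment.  A straight chain descends to ≈1 Å above the midplane.  A kinked
chain bends by `kink_angle` at `kink_position`; with the default cis-analog
angle (80°) the distal chain runs nearly flat and terminates *above* the
3–10 Å band.  This single geometric device reproduces, by construction,
the qualitative depth-density signatures the density module is meant to
resolve: straight (saturated/trans-analog) chains are strictly denser in
the 3–10 Å band than kinked (cis-analog) chains at equal area per lipid,
the band density is strictly monotone in the kinked fraction, and the
saturated-minus-cis difference profile is concentrated around the band.
The 80° bend is deliberately larger than a literal cis double-bond angle:
at this coarse resolution it stands in for the cumulative splay and
disorder of the distal chain, not for one bond geometry.  The PE analog
(fewer headgroup atoms, area per lipid 62 vs 64 Å²) instead produces a
small density increase spread uniformly along the chain region —
a mild, delocalized contrast against the sharp, localized saturation
contrast.  The lower leaflet mirrors the upper exactly; iid Gaussian
thermal noise (per atom, per frame) breaks the mirror only stochastically.
Composition presets (`cis_pc`, `mixed_pc`, `halfsat_pc`, `trans_pc`,
`pe40`) map the studied lipid systems onto kinked fractions equal to their
unsaturated-chain fractions.

What the toy bilayer does *not* emulate: atomic packing correlations,
headgroup chemistry, undulations, interdigitation, or realistic absolute
densities.  Passing direction-of-effect tests on it shows the analysis
stack resolves the constructed contrast at toy scale — full-scale
densities require all-atom trajectories supplied by the user.

**Dimer.**  Ideal α-helices (100°/residue, 1.5 Å rise, 2.3 Å Cα radius)
separated by 10 Å along x.  Per frame a state is drawn from the state
weights and each protomer's sensor azimuth from a wrapped normal (SD 15°
by default) around that state's center pair; the helix is rotated about
its own axis to realize the azimuth.  State centers are (φ1, φ2) pairs —
(0°, 0°), (0°, 180°), (180°, 180°) — because a single angle per state
cannot express the mixed configuration.  With the default SD the
misclassification probability against the 60° threshold is negligible, so
recovered populations are binomially distributed around the weights.

**Spectra.**  Emission spectra are sums of Gaussian bands plus optional
Gaussian noise, clipped at zero.  FCS curves evaluate the closed-form
model on a logarithmic lag grid (10⁻⁶·⁵–1 s) with multiplicative Gaussian
noise.  cwEPR spectra are three derivative-of-Gaussian lines at
nitroxide-like centers (331.6/335.0/338.4 mT, base width 0.35 mT) whose
`amplitudes` parameter sets the positive-lobe heights at zero broadening;
the outer lines' widths grow with the broadening parameter ~3× faster
than the central line's, so the low/mid amplitude ratio falls
monotonically with broadening by construction.

All generators are bit-reproducible given their seed.

## Problem sizes and tolerances

The shipped tests run on deliberately small systems chosen to make the
checked contrasts unambiguous: bilayers of 16–36 lipids per leaflet and
1–3 frames (the band orderings hold with margins far above the thermal
noise at these sizes), 10⁴-frame dimer mixtures (3-binomial-SE recovery),
20-seed FCS ensembles at 1% noise (τ_D within 5%), and 10⁵-vector Monte
Carlo for the isotropic order-parameter limit (3 SE ≈ 0.004).  Exact
identities (GP bounds, counting oracles, round trips) are asserted at
1e-9–1e-12 absolute or to the precision of the format (10⁻³ Å for PDB).

## Known limitations

* The voxel grid assumes orthorhombic boxes and a flat bilayer normal
  along z; curved or undulating membranes are out of scope.
* The lateral pressure profile is not computed (it requires local-stress
  fields from an MD engine), and no MD is run here.
* The cwEPR index is semi-quantitative; no dipolar distance extraction.
* The plain bootstrap understates rotamer-population uncertainty for
  strongly autocorrelated trajectories.
* The FCS model is strictly 2D + triplet; 3D diffusion or anomalous
  exponents are not modeled.
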