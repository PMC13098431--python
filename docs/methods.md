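# Methods

`sdrcensus` analyses conformational ensembles of short-chain
dehydrogenase/reductase (SDR) sugar nucleotide epimerases — enzymes that
invert a sugar stereocenter through NAD⁺-dependent oxidation, rotation of a
transient keto intermediate, and nonstereospecific re-reduction.  The
package answers one question about such an ensemble: *which fraction of the
sampled substrate poses is geometrically competent for catalysis, and how is
the remainder distributed over torsional, puckering and free-energy space?*

## Catalytic-plausibility census

A frame is *catalytically plausible* when the canonical SDR alcohol-oxidation
geometry holds, expressed as four heavy-atom distance criteria with a common
cutoff of 3.5 Å:

1. the phenolic oxygen of the catalytic tyrosine (the general base) is
   within hydrogen-bonding distance of the reactive sugar C2 oxygen;
2. so is the threonine side-chain oxygen of the Thr–Tyr–Lys triad;
3. the lysine NZ reaches a nicotinamide-ribose hydroxyl oxygen of NAD⁺ —
   by default *either* hydroxyl suffices (min-over-pairs); the stricter
   both-hydroxyls reading is available via `lys_requires_both=True`;
4. the nicotinamide C4 is within hydride-transfer distance of the sugar C2.

Distances are plain Euclidean; input frames must be imaged beforehand, since
active-site distances are short-range and no periodic-boundary treatment is
applied anywhere.  The boundary is inclusive: a distance exactly at the
cutoff passes.  The C2–H2–C4 hydride-transfer *angle* (vertex at the
explicit H2 hydrogen; hydrogens are never reconstructed) is reported as an
ensemble statistic but deliberately does not gate the classification — the
ensemble fractions are defined by distances alone, with an optional angle
gate for sensitivity analysis.

The census reports the plausible fraction with a Wilson 95% interval
(statsmodels), per-criterion marginal pass rates (the conjunction is bounded
above by the smallest marginal), and labelled contact sub-censuses.  Contact
fractions are denominator-sensitive — "x% of all frames" and "x% of
catalytically plausible poses" differ by a factor of ~25 at a 4% plausible
fraction — so every contact result carries its denominator explicitly and
both can be computed.  Side-chain amide-carbon probes (Asn CG, Gln CD) use a
4.0 Å cutoff because the amide O/N orientation cannot be predefined;
backbone carbonyl-oxygen probes use 3.5 Å.  An empty denominator raises an
error rather than returning 0.

## Ring puckering

Cremer–Pople coordinates are computed with ring atoms in O5, C1, C2, C3,
C4, C5 order and the Fourier phase origin at O5; under this carbohydrate
convention the ⁴C₁ chair of an α-D-pyranose maps to θ = 0° and ¹C₄ to
θ = 180°.  The mean plane passes through the geometric center with its
normal built from the two sin/cos-weighted lattice vectors; out-of-plane
displacements give (q₂, φ) from the second-order Fourier sums and the
alternating third-order amplitude q₃, with Q² = q₂² + q₃² and
cos θ = q₃/Q.  The normal's orientation is fixed so that an O5-up ideal
chair lands on θ = 0 — conformer labels are meaningless without this choice,
which is why it is stated here.

Conformer assignment is nearest-reference by great-circle distance on the
(θ, φ) sphere over the 38 canonical references: chairs at the poles, boats
(φ ≡ 0 mod 60°) and twist-boats (φ ≡ 30 mod 60°) on the equator, and
envelopes/half-chairs alternating every 30° in φ on the θ = 54.74°/125.26°
circles (the magic-angle tropics).  The tropic positions were derived
analytically from the inverse z-displacement formula rather than copied
from a diagram: at θ = atan√2, φ ≡ 0 mod 60° yields a single dominant
out-of-plane atom (an envelope) and φ ≡ 30 mod 60° an adjacent
equal-and-opposite pair (a half-chair).  Exact ties break lexicographically
by name, so assignment is total and deterministic.  Rings with Q < 0.1 Å
are reported as planar/unassigned because φ is numerically unstable as
Q → 0; population tables normalize over assigned frames and count planar
frames separately.

`build_ring` inverts the transform (atoms on a circle of radius 1.43 Å, the
mean pyranose bond projection — this only affects synthetic geometry, never
analysis), and the forward∘inverse identity holds to 10⁻⁶ Å / 10⁻⁴ degrees
across the (Q, θ, φ) grid exercised in the tests.

## Free-energy landscapes and circular statistics

Landscapes are histogram potentials of mean force, F = −k_B T ln(n/n_max),
referenced to the most populated bin so min F = 0.  Defaults: T = 333 K
(the production temperature of the thermophilic-enzyme simulations this
package targets), 5° bins on torsion axes, 0.25 Å bins on distance axes;
all three are configurable.  k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, so one
k_BT ≈ 0.662 kcal mol⁻¹ at 333 K.  Torsion axes are periodic (samples
wrapped to [−180°, 180°), grid tiling the circle); bins are half-open with
the top edge closed.  Empty bins are masked, never assigned +∞ or a
pseudo-count: the estimator cannot distinguish an unsampled bin from a high
barrier, and fabricating barrier heights would be worse than admitting
ignorance.  Consequently F is only defined relative to sampled regions, and
ΔF between basins is reliable only where both are well sampled.

Basins are unmasked local minima over the 8-neighborhood below a threshold,
reported at bin-center resolution (no sub-bin interpolation); equal-F
plateaus collapse deterministically to the lowest row-major bin index.

Torsion series are summarized by the wrapped-histogram mode (ties break
toward the smaller absolute angle) and by the circular mean/resultant
length; an antipodal sample set has resultant length 0 and its mean is
flagged undefined.  For a von Mises(μ, κ) torsion the 1D PMF approaches
k_BT·κ·(1 − cos(x − μ)) + const, which the tests verify at κ = 2.

## Superposition and displacement profiles

Rigid superposition is least-squares (Kabsch) restricted to proper
rotations via `scipy.spatial.transform.Rotation.align_vectors`, so mirror
images retain a non-zero residual.  Induced-fit displacement profiles
superpose structure B onto A using a rigid-core selection matched by
(chain, resid, name), then report the mean displacement of each residue's
selected atoms; residues missing from either structure are listed as absent
rather than reported as zero.  No outlier rejection is applied: the RMSD is
over all matched atoms, which will not reproduce numbers quoted from
software that trims poorly fitting atoms before reporting.

## Synthetic ensembles

The generator exists so that every analysis stage can be tested against a
known ground truth without multi-microsecond trajectories.  It emits a
minimal pseudo-active-site topology (triad atoms, ribose hydroxyls,
nicotinamide C4, sugar C2/H2/O2/O3/O4, contact probes, an O1–P1–O12–P2
pyrophosphate chain, and a detached six-atom pyranose ring) and constructs
coordinates so each frame *exactly* realizes its sampled class:

* plausible frames draw all four criterion distances from a truncated
  normal (mean 3.0 Å, SD 0.25, support (2.5, 3.5]) — hydrogen-bond-like
  and at-or-below the cutoff by construction;
* unproductive frames redraw a random non-empty subset of criteria (each
  with probability 0.75, at least one forced) from a truncated normal above
  the cutoff (mean 4.8 Å, SD 0.8, support (3.7, 9.0]); the 0.2 Å margin
  makes the class label a hard geometric guarantee, not a statistical one;
* the pyrophosphate torsion realizes a von Mises mixture draw exactly via
  internal-coordinate placement of the terminal phosphorus;
* the hydride angle realizes a truncated normal (mean 135°, SD 8°, support
  (100°, 162°]) at the H2 vertex while independently preserving the drawn
  donor–acceptor distance;
* contact probes are placed inside/outside their cutoff according to
  independent planted Bernoulli indicators (one plant per probe atom — a
  shared probe cannot realize two independent indicators and is rejected);
* the ring is built at the canonical (θ, φ) of a conformer drawn from a
  stated menu (Q = 0.57 Å) plus isotropic coordinate noise (SD 0.02 Å).

Criterion partners sit on fixed, mutually distant unit directions from
their anchors, which decouples the criteria so classes can be planted
exactly.  This is deliberately non-physical: the generator reproduces the
*statistical* structure the analysis assumes (mixture fractions, distance
and angle distributions, torsion modes, pucker menu), not protein
chemistry, sterics, solvent, or correlations between observables.  Passing
recovery tests therefore demonstrates correctness of the analysis code, not
of any force field, and says nothing about real trajectories beyond the
statistics modelled.  Everything is reproducible bitwise from the config
seed.

Two named presets encode the study conditions the package is aimed at:
`cdp-glc-like` (plausible fraction 0.016 over 24 000 frames, torsion mode
170°, tightly ⁴C₁-confined pucker menu, Asn-CG/C3-O contact probability
0.0018) and `cdp-man-like` (fraction 0.0418, mode 130°, a broader menu —
⁴C₁ 0.80 with ¹H₀/¹E/¹H₂ minors and a small ⁰S₂ cluster — and backbone
contact probabilities led by Val-O/C3-O at 0.0313).

## Problem sizes and numerical choices

Tests and the acceptance script run ensembles of 10⁴–2.4 × 10⁴ frames —
the scale at which a 1.6–4.2% planted fraction is recovered within ±3
binomial standard errors and Wilson intervals attain nominal coverage —
and 10⁵–10⁶ draws for the circular-mode and PMF-limit checks.  Statistical
assertions use 3-SE bands; exact assertions (class consistency, round
trips, torsion/angle realization) use absolute tolerances of 10⁻⁶ or
tighter.  Degenerate inputs fail loudly: zero-length angle arms, collinear
dihedral frames, empty selections, empty histogram, sub-threshold pucker
amplitude, and empty contact denominators all raise typed errors.

## Known limitations

* No reweighted estimators (WHAM/MBAR), kernel density estimation, or
  block-averaged error bars on F.
* No hydrogen-bond angular terms or energy-based interaction analysis; the
  census is purely geometric.
* No furanose (five-membered) puckering.
* The all-common-atom RMSD will not match published values produced with
  per-atom rejection schemes.
* DCD reading requires the optional mdtraj dependency; AMBER topology
  parsing is not implemented (XYZ and multi-model PDB are the portable
  interchange formats).
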