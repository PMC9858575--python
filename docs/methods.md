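# Methods

## Forward model

The generator is a deterministic analytic stand-in for full Monte Carlo
photon transport of a diagnostic X-ray tube. It keeps exactly the physics
that shapes the kerma map a surrogate must learn — spectrum, heel asymmetry,
filtration, geometry — and drops everything stochastic:

1. **Spectrum.** Thick-target bremsstrahlung in the Kramers approximation,
   `f(E) ∝ Z (kVp − E)/E` for tungsten (Z = 74), on 1 keV bins from 10 keV to
   the set kVp. Energies below 10 keV are outside the embedded coefficient
   tables and contribute negligibly after target and window filtration.
   Characteristic tungsten K-lines are omitted; below the K edge (69.5 keV)
   they do not exist, and above it they perturb the kerma map without
   changing its structure.
2. **Heel effect.** Photons are produced at an effective depth
   `d = 3 µm` below the anode surface and exit along a path
   `L = d / sin α`, `α = θ_anode − θ cos φ` (θ_anode = 20°), attenuated by
   Beer–Lambert through tungsten (19 290 kg/m³). φ = 0 points toward the
   anode, so `α` shrinks and `L` grows on that side: the beam is dimmer and
   harder toward the anode, uniform top-to-bottom (mirror-symmetric in φ).
   The takeoff angle is floored at 2°: the model's grazing-exit divergence
   (`L → ∞` as `α → 0`, reached at the grid corner θ = 20°, φ = 0°) is not
   physical — real tubes blur it over surface roughness and the ~1 mm focal
   spot, neither of which a point-source model resolves. With the floor
   disabled such rays are a geometry error.
3. **Window.** 1 mm beryllium (1850 kg/m³), Beer–Lambert per bin.
4. **Kerma.** `K = (1/r²) Σ_E f(E) E (μ_en/ρ)_air(E)`, in relative units per
   source electron; there is no absolute calibration, and the surrogate is
   scale-invariant after its log-target transform anyway. Air attenuation
   over ≤ 125 mm (≲ 1 % at these energies) is neglected, which makes the
   inverse-square law an exact invariant — deliberately testable.

Attenuation and energy-absorption coefficients (tungsten μ/ρ with K-edge
knots, beryllium μ/ρ, air μ_en/ρ; 10–150 keV) are shipped as CSV and
interpolated log-log linearly, with no extrapolation outside the tabulated
span. L-edge fine structure of tungsten (10–12 keV) is smoothed over by the
knot spacing; at those energies the self-attenuated fluence is tiny.

**What the generator does not emulate:** Monte Carlo statistical noise,
scattered radiation, electron transport in the target, off-focal radiation,
detector response, absolute units. Tests passing against this generator
establish that the surrogate pipeline learns a physically structured,
heel-asymmetric, voltage- and distance-dependent kerma field; they do not
certify accuracy against measured or transport-computed data.

## Sampling protocol

Reference grid: radii {25, 50, 75, 100, 125} mm, θ = 0–20° in 2° steps,
φ = 0–360° in 15° steps. Both φ endpoints are kept as distinct grid points
although they coincide physically, so the grid enumerates 5 × 11 × 25 = 1375
positions; with voltages {40, 60, 80, 100, 120, 140} kV the dataset has 8250
samples in deterministic voltage-major order. The 70/30 split (5775/2475) is
a uniform random partition, reproducible under its seed; train size is
N·fraction rounded half away from zero. Features are stored raw
(mm, deg, deg, kV) and normalized only inside the model, keeping the CSV
physically interpretable.

## Surrogate

Classical three-layer RBF network, implemented from scratch:

- **Normalization:** per-feature min-max to [0, 1] over the training set;
  parameters stored in the model and reused at prediction.
- **Targets:** fitted on `log(kerma)` and exponentiated at prediction. Kerma
  spans ~25× from inverse square alone and far more across the heel, and the
  evaluation criterion is relative, so the error structure should be
  multiplicative.
- **Centers:** Lloyd's K-means with k-means++ seeding, 100 iterations,
  5 restarts keeping the lowest within-cluster sum of squares, empty clusters
  re-seeded to the farthest point. Deterministic under its seed. k defaults
  to 50 (`k ≤ n_train` enforced).
- **Width:** one shared σ = 2.0 × the mean nearest-neighbor distance among
  the centers — a standard heuristic; the factor is exposed in the training
  config. The model container also accepts a per-center σ vector.
- **Output layer:** rank-tolerant linear least squares (`numpy.linalg.lstsq`)
  on the hidden activations plus a bias column; closed-form and
  deterministic.

Serialization is plain JSON (centers, σ, weights, normalization, config) and
round-trips bit-exactly.

## Evaluation

MRE% is implemented with the *predicted* value in the denominator — an
unusual convention, kept deliberately; a flag switches to the conventional
experimental-value denominator. RMSE is on the raw kerma scale. Both metrics
are checked against independent single-loop references and are permutation
invariant.

## Accuracy of the 50-unit surrogate, and a known limitation

On the reference synthetic dataset the k = 50 network reaches a held-out MRE
of ~15% (median over 5 seeds; `scripts/acceptance.py` recomputes this). The
error is bias, not variance: train and test MRE coincide, and widening or
per-center σ variants plateau near 11%. Two causes, quantified during
development:

- the shared isotropic σ in the 4-D normalized input space is a weak
  representation — even with the heel nearly disabled (an effectively 2-D
  smooth target) 50 such units leave ~5% MRE;
- the heel ridge `L ∝ 1/sin α` near the anode-side field edge gives the
  log-kerma surface large high-order derivatives; a gauge fit using the
  function's own smooth coordinates (ln r, α, kVp) still needs ~210 free
  parameters to reach 2% MRE, so no ~51-parameter linear-in-basis model can
  approach sub-percent error on this generator.

Sub-percent MREs reported for RBF surrogates of transport-computed kerma
maps therefore reflect smoother targets than this generator produces at the
anode-side field edge. Users who need tighter accuracy on this model's data
should raise k (test error drops monotonically — median RMSE 15.0 → 4.3 over
k = 5 → 50 — and continues falling to k = 400) or restrict the grid away
from grazing takeoff angles.

## Numerical choices and degeneracies

- Grid steps must divide their ranges to ~1e-9 relative, else an error.
- Constant features normalize to 0 with scale 1.
- `k = n` K-means fixes centers at the points (zero WCSS), making the
  network an exact interpolator — used as a test oracle.
- Kerma is strictly positive for every valid configuration (the hardest ray
  at 40 kV through the floored heel path still transmits ~1e-4 of its top
  bin), so the log transform is always defined.
- Pipeline stage seeds are spawned from one root seed via
  `numpy.random.SeedSequence` and reduced below 2³¹; the manifest records
  them with SHA-256 digests of all artifacts.
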