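# Methods

## Physical model and geometry

The scene is the trial geometry of an underwater matching-to-sample
setup: a sample box whose back wall defines the coordinate origin, z
increasing towards an acoustically transparent screen at z = 0.23 m.
Targets are skeletons of 32 mm PVC pipe lying in the object plane
(z = 0.03 m, i.e. 0.20 m behind the screen); the receive array sits at
z = 0.20 m (0.03 m behind the screen); the transmitters — three elements
inside a 36 cm disc standing in for a dolphin's head — sit 1 m in front
of the screen, below the object axis, beams aimed at the scan-region
centre.  The 16-element receive layout is a 4 × 4 lattice filling the
87 × 78 cm frame with one faulty corner element excluded (15 active);
the exact physical layout is not published, so a regular lattice with the
documented frame size and ≥ 12.5 cm spacing is used.  Sound speed
defaults to 1530 m/s.

Echo formation is linear: each occupied voxel of a 2-D scan grid
re-radiates the incident click, and the received spectrum at sensor m is
a superposition of unit-modulus phasors with exact Euclidean propagation
delays (transmitter → voxel → sensor).  Spreading-loss amplitudes vary by
well under 5% across the array at these ranges and are absorbed into the
occupancy amplitudes (far-field amplitude approximation); no far-field
*phase* approximation is made.  Transmit directivity is modelled as a
Gaussian beam in off-axis angle with a 10 dB two-sided width of 20°; the
published hardware gives only this width, not a beam shape, so the
Gaussian is a modelling choice (a binary on/off fall-back exists via
`directivity=False`).

## Processors

**Bartlett.**  Known transmit: per click,
ĝₙ(k) = sqrt(Σᵢ |aₙ(fᵢ,k)ᴴ y(fᵢ,k)|²), coherent across frequency; the
image is the click average.  Unknown transmit: phases cannot be aligned
across frequency, so per-frequency magnitudes |bₙᴴx| are averaged over
frequency and clicks.  Both are verified against naive triple-loop
implementations to 1e−9 relative.

**Sparsity-aware.**  Known transmit solves, per click,
min ‖g‖_p s.t. Σᵢ‖y − A g‖² ≤ ε with p = 1.05; unknown transmit solves
min ‖G‖_{p,2} with p = 1 over the N × F occupancy matrix, whose row
grouping enforces that an active voxel carries energy across the whole
band while inactive rows vanish.  The strict inequality of the
constraint is implemented as ≤ (closed constraint; the distinction is
measure-zero).  ε defaults to 0.1 × the click's data energy; the value
is always recorded in the output diagnostics.  The fraction is a free
parameter of the method: smaller values force the image to explain the
data more exactly (denser, noisier), larger values prune harder.

## Solver

No external conic-programming stack is used; the programs are solved by
an accelerated proximal-gradient (FISTA) iteration on the penalized form
½·residual + λ·Σφ(|gₙ|), φ(r) = rᵖ, combined with a monotone search over
λ: the residual of the penalized path increases with λ, so the largest λ
whose solution meets the budget ε is bracketed geometrically and refined
by bisection (stopping once the residual is within 5% below ε, always
returning a feasible iterate).  Minimizing Σ|gₙ|ᵖ under the constraint
selects the same minimizers as ‖g‖_p itself (monotone transform).  The
scalar proximal map of t·rᵖ is soft-thresholding at p = 1 and otherwise
the root of the strictly monotone equation r + tp·r^(p−1) = u, solved by
a bracket-safeguarded Newton iteration (verified against grid-search and
scipy oracles to ~1e−7 of the data scale).  The step size is set from
the largest squared singular value of the stacked model matrix (power
iteration, deterministic start, 2% safety margin).

Complex unknowns are handled natively; a real/imaginary-stacked backend
(`backend="real"`, each voxel a group of 2 or 2F real variables) is
mathematically identical and agrees with the native route to better than
1e−6 on test problems — a useful consistency check on the group-norm
machinery.

Degenerate inputs: ε ≥ data energy returns the exactly zero image with a
warning (zero is feasible and optimal); an all-zero click makes the
energy-fraction ε undefined and raises; failure to reach the budget
raises with diagnostics rather than returning a silent zero.

## Preprocessing

Raw multichannel records are bandpass filtered to 50–170 kHz (zero-phase
Butterworth, ≥ 40 dB stopband), clicks are detected as analytic-envelope
bursts above a threshold (default 6× the median envelope — a robust
noise-floor multiple; the original threshold is unpublished) with
candidates closer than 4 ms suppressed in favour of the stronger burst;
listening windows are cut per click, optionally matched-filtered against
the transmit template, and projected onto the analysis bins by FFT
(requested frequencies snap to the nearest FFT bin of the window; the
realized bin frequencies travel with the dataset).  Known-transmit phase
is re-referenced to the transmit instant.  Band selection keeps the
(sensor, frequency) cells whose click-averaged SNR exceeds 0 dB
(strictly); processors honour the mask by deleting the corresponding
sensor rows of data and model per frequency.  An end-to-end test closes
the loop: time-domain synthesis → preprocessing reproduces the directly
simulated frequency-domain data to ~1e−9 per entry for a single
scatterer.

## Synthetic scenes and what they do (not) show

The default study scene is: a preset target mask (SQ square outline or
FF double-F glyphs, equated in rasterized area within 2% at 0.5 cm
resolution, both built at 32 mm stroke width), unit reflectivity on the
mask, three transmitters firing one click each, Gaussian-beam
directivity, and white Gaussian noise at 20 dB SNR under the norm-ratio
convention 10·log₁₀(‖S‖_F/‖N‖_F), realized exactly by rescaling the
generated noise.  Analysis uses F = 10 bins evenly spanning 105–140 kHz
on the fast grid (the number of analysis bins is a processing choice;
15 is the default elsewhere).  Clicks are Gaussian-windowed 120 kHz tone
bursts with > 90% of spectral energy inside 105–140 kHz — the published
transmit click is not available, and any broadband click with that band
serves the same role.

Two grid scales exist: the full 0.5 cm grid (101 × 101 = 10201 voxels
over ±0.25 m) and a "desk" grid at 1 cm over ±0.20 m (41 × 41 = 1681
voxels) on which the packaged studies run; the preset shapes are drawn
at 0.28 m size there so the target sits inside the scanned region with
margin.  Problem sizes of the packaged studies: discrimination uses
10 seeds × 2 shapes × 3 clicks on the desk grid (M = 15, F = 10);
grating-lobe uses a 4 × 4 array at 6.4 cm spacing (≈ 10 half-wavelengths)
with a single scatterer; the repeated-click study uses K ∈ {1, 3, 9}
clicks per transmitter.

The simulator deliberately omits pool reverberation and multipath,
frequency-dependent absorption, transducer/hydrophone responses, target
scattering physics (a voxel re-radiates isotropically with unit
reflectivity) and source movement.  Passing results therefore validate
the *processing chain* — model construction, inversion, aggregation,
scoring — under the stated geometry and noise, not performance on real
pool recordings.

## Design choices where the design was open

* Exact target dimensions and per-transmitter coordinates are not
  published; presets are parametric stylized skeletons and the
  transmitter cluster is a symmetric triad inside the documented 36 cm
  disc.
* Detection tie-break inside the 4 ms window: the stronger burst wins.
* Percentiles for rendering colour limits (5th/99.5th) use linear
  interpolation between order statistics; a constant image falls back to
  full range with a warning.
* The loader for externally deposited processed data recognizes this
  package's own HDF5 layout and otherwise reports the structure it found
  instead of guessing; adapters can be added once a layout is known.
* The behavioural significance threshold α = 0.01 is a reporting
  default, not hard-coded logic.

## Known limitations

* The λ-search solves a sequence of penalized problems; for very small ε
  (≲1e−8 of the data energy) convergence slows and `max_iter` may need
  raising.
* p < 1 (non-convex) sparse recovery is rejected by construction.
* The grid is strictly 2-D at a fixed depth plane; 3-D extension is out
  of scope.
* Discrimination values on synthetic scenes are not comparable in
  absolute terms to values measured on real recordings: the synthetic
  targets reflect ideally and the noise is white, so R values here are
  systematically larger.
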