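# biosonar

Dolphin-inspired compact sonar imaging: broadband matched-field (Bartlett)
and sparsity-aware convex-inversion processing of click echoes on a sparse
hydrophone array, with a synthetic echo simulator, a preprocessing chain
for raw recordings, shape-discrimination metrics and a command-line
pipeline.

## The problem

Echolocating dolphins discriminate object shapes with a sensory aperture
of roughly a head diameter, D ≈ 20 cm, at click frequencies near 120 kHz.
A conventional narrowband array of that size would need more than
πD²/(4(λ/2)²) ≈ 773 sensors to avoid spatial aliasing and would still be
limited to ~λ/D ≈ 3.6° of angular resolution.  A practical compact array
(here: 15 working hydrophones on an 87 × 78 cm frame, pairwise spacing
≥ 12.5 cm) is therefore *heavily undersampled*: conventional beamforming
produces grating lobes that bury the target's shape.

This package implements the processing that closes part of that gap:

* **Forward model.**  The scan region is a 2-D voxel grid; each occupied
  voxel re-radiates the incident click.  With known transmit parameters
  the matched-filtered data at frequency *f*, click *k* is
  `y(f,k) = A(f,k) g(k) + v(f,k)` with steering entries
  `exp(−i2πf(pₙ(k)+tₙ(m))/c)`; with unknown transmit (listening to a
  dolphin) only the return path is modelled, `x(f,k) = B(f) g(f,k) + w(f,k)`,
  and the occupancy becomes frequency-dependent.
* **Bartlett processor.**  Per click,
  `ĝ_B(k)ₙ = sqrt(Σᵢ |aₙ(fᵢ,k)ᴴ y(fᵢ,k)|²)` (coherent across frequency
  when transmit is known, incoherent `|bₙᴴx|` averaging otherwise), then
  averaged over clicks.
* **Sparsity-aware (SA) processor.**  Per click, the convex program
  `min ‖g‖_p  s.t.  Σᵢ ‖y(fᵢ,k) − A(fᵢ,k)g‖₂² ≤ ε`  (p = 1.05) or its
  unknown-transmit variant `min ‖G‖_{p,2}` (p = 1, row sparsity coupling
  all frequencies of a voxel), solved by an accelerated proximal-gradient
  method with a penalty search that meets the residual budget ε (default:
  10% of the click's data energy).
* **Discrimination metric.**  `C_i = hᵀs_i/(‖h‖‖s_i‖)` against binary
  shape templates, `R = 20·log₁₀(C_sample/C_alt)` in dB; `R > 0` means
  the image favours the correct shape.

## Worked example

```python
from biosonar.fixtures import make_fixture, FixtureSpec
from biosonar.processors import bartlett_known, sa_known, SolverConfig
from biosonar.metrics import discrimination

# square-outline PVC target, 15 sensors, 3 transmitters (one click each),
# 20 dB SNR, 41 x 41 voxel grid at 1 cm spacing
fix = make_fixture(FixtureSpec(shape="SQ", snr_db=20, seed=1))
h_b = bartlett_known(fix.dataset, fix.steering)
h_sa = sa_known(fix.dataset, fix.steering, SolverConfig(max_iter=400))
for name, out in (("bartlett", h_b), ("sa", h_sa)):
    r = discrimination(out.h, fix.masks["SQ"], fix.masks["FF"])
    print(f"R_{name} = {r.r_db:+.2f} dB")
```

prints

```
R_bartlett = -0.68 dB
R_sa = +7.50 dB
```

The Bartlett image of this aliased array cannot tell the square from the
double-F alternative (R ≈ 0), while the sparsity-aware image
discriminates it by several dB — the qualitative behaviour the method is
designed to deliver.  The same comparison from the shell:

```bash
biosonar simulate --shape SQ --snr 20 --seed 1 --out ds.h5
biosonar image --input ds.h5 --processor sa --out img.h5 --png img.png
biosonar discriminate --input img.h5 --sample SQ --alt FF
biosonar stats --k 13 --n 20 --p0 0.25     # behavioural significance
```

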