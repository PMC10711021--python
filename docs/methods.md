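# Methods

## Model and procedure

A particle image is modeled as `b = A x + n`, where `A` is the forward
operator (ZYZ intrinsic Euler rotation in the RELION convention, central
Fourier-slice projection along the rotated z-axis, in-plane translation,
CTF multiplication) and `n` is white Gaussian noise. The sieving score

    g = ||H b||² − ||H (b − A x)||² = 2⟨H b, H A x⟩ − ||H A x||²

uses a sharp radial highpass projector `H` (idempotent, self-adjoint;
the DC term is always removed). Under the Gaussian noise model,
`E[g] = +||H A x||²` when the particle genuinely contains the projected
signal in the band and `E[g] ≈ −||H A x||²` when it does not (wrong pose,
wrong CTF, or band energy erased by damage), with fluctuation
`2σ·||H A x||`; ranking by `g` therefore separates the two populations
whenever the reference's band energy exceeds the per-pixel noise scale.
Because the score is a *difference of energies*, it depends on the
reference map's absolute amplitude — no per-particle rescaling is applied
before scoring (an optional least-squares scale of the projection onto
the image exists but is off by default).

The iteration driver keeps the two half-sets fully independent: each
half-set is scored only against its own half-map, rankings are never
pooled, and each iteration retains the top `floor(0.8·n)` per half-set
(ties broken by ascending original index, for determinism). Retained
index sets are nested across iterations by construction, and the driver
asserts this after every pass. Before scoring, the half-map is multiplied
by a soft mask derived from the map itself (lowpass 8 Å, binarize at
0.2·max, dilate 4 px, 4 px raised-cosine edge); a user mask overrides
this. The cutoff frequency of `H` rises linearly **in frequency** from
1/40 Å⁻¹ to 1/3 Å⁻¹ across the scheduled iterations.

The sieve does not re-estimate poses between iterations; evaluating a
sieved subset by ab initio re-refinement is an external step, outside
this package's scope.

## Forward projection and reconstruction

Slice extraction uses trilinear interpolation in the FFT of the
zero-padded volume. Padding ×3 is the default: on a band-limited ball
phantom the relative RMS error against a line-integral oracle is ~1.7%
at ×3 versus ~3.8% at ×2 (box 32), and the score's cross term benefits
directly from slice accuracy; ×2 remains available via
`FourierProjector(pad=2)`. FFT conventions are global: forward
unnormalized, inverse divided by element count, all real-space images
centered via an ifftshift/fftshift sandwich, and all energies compared on
one side of the transform. The particle shift is folded into the
projection (`A x` carries the shift), so observed images are compared
against already-shifted projections; reconstruction removes the shift by
the conjugate phase ramp before slice insertion.

Reconstruction is direct Fourier inversion: CTF-premultiplied image
transforms are spread into a ×2-oversampled 3D grid with trilinear
weights, CTF² weights are accumulated, and the grid is divided by
(weights + ε) with ε = 10⁻³ × mean nonzero weight — a fixed Wiener-style
regularizer standing in for the iterative gridding correction of
production reconstruction programs. Its adequacy at package scale is
established by a round-trip oracle (2000 noise-free projections of a blob
phantom reconstruct to >0.99 real-space correlation up to 2/3 Nyquist)
and by an ε-insensitivity check (±10× around the default changes a
well-sampled reconstruction by <1%). Duplicating particles leaves the
result unchanged (numerator and weights scale together).

FSC uses one-voxel-wide shells with no implicit masking; masking is an
explicit pre-step, and masked-FSC phase-randomization correction is out
of scope. Threshold resolution is linearly interpolated between shells
and never extrapolated past Nyquist (a never-crossing curve returns
Nyquist, flagged).

## CTF

`CTF(f, θ) = −√(1−A²)·sin χ − A·cos χ`, with
`χ = πλΔz(θ)f² − (π/2)Cs λ³ f⁴ + phase_shift` and underfocus positive:
negative contrast at low frequency, the convention of mainstream SPA
packages. The sign matters — flipping it flips the score's cross term —
so tests pin it. No envelope is folded into the CTF; amplitude decay is
modeled separately (see damage below). On an even grid the unpaired
−Nyquist row cannot be mirror-symmetric for an astigmatic CTF, and a
fractional Fourier shift is likewise only exactly invertible on
band-limited images; both are standard discrete-grid caveats, documented
in the tests that touch them.

## Synthetic data

The generator emulates what the sieve exploits, not image formation
physics: CTF-modulated central-slice projections of a phantom at uniform
random orientations; per-particle dose-dependent damage as a B-factor
envelope `exp(−(b·dose)·f²/4)` with `b = 2 Å² per e⁻/Å²` by default and
four dose groups at 14.8/22.7/30.5/38.3 e⁻/Å² (the mean accumulated doses
of frame windows 5–14, 10–19, 15–24, 20–29 of a 32-frame movie carrying
50 e⁻/Å²); white Gaussian pixel noise (single global σ, or a target
signal-to-noise variance ratio); and corruption of a chosen fraction of
*records* with independently re-drawn poses or defocus, so metadata
disagrees with image content while the truth table keeps both. Defocus is
drawn uniformly in 0.5–1.5 μm; 300 kV, Cs 2.7 mm, amplitude contrast 0.1.
One seeded generator drives every draw: an identical spec reproduces the
stack bit for bit.

The default blob phantom uses many small scatterers (300 blobs, σ =
1.5–2.5% of the box, floored at 0.9 voxels) because the score inspects
the 3–8 Å band: a phantom made of a few large blobs carries ~10⁻⁵ of its
energy there and no sorter can rank particles on an empty band. Smooth
variants (for interpolation oracles) are available through `n_blobs` /
`blob_sigma_frac`.

What the generator does **not** model: structured/colored noise, ice
gradients, beam-induced motion, charging, preferred orientation,
frame-accurate radiolysis chemistry. Passing tests therefore demonstrate
the score's behavior under its own stated assumptions (Gaussian noise,
multiplicative band attenuation), not performance on pathological real
micrographs.

## Reference experiments and their scale

*Wrong-pose removal*: 400 particles, box 64 at 1.0 Å/px, half the records
given re-drawn random Euler angles, SNR 0.05, one scoring pass against
the masked true map at an 8 Å cutoff, bottom half removed; accuracy is
the corrupted fraction of the removed set, averaged over five seeds
(typically ~98%).

*Radiation-damage ranking*: 800 particles, box 48 at 1.5 Å/px, four equal
dose groups, SNR 1.0, the full nine-iteration sieve run with both the
band-energy score and NCC, retained fractions read at iteration 6 (26.2%
cumulative retention). The noise here is deliberately lower than in the
wrong-pose experiment: at full scale the per-iteration reference maps are
rebuilt from tens of thousands of images and are essentially noiseless,
while at a few hundred particles the reference's high-frequency fidelity
— not per-particle band SNR — becomes the binding constraint. Reducing
the noise restores reference quality comparable to the full-scale
setting while keeping the experiment seconds-scale; box sizes and
particle counts throughout were chosen as the smallest at which the
respective effects are statistically stable.

## Numerical choices and edge cases

- Sharp (binary) highpass rather than soft-edged: the score's algebraic
  identities and the projector property (idempotence) hold exactly;
  `highpass` rejects cutoffs beyond Nyquist.
- `floor()` for retained counts; the reported cumulative percentage is
  the scheduled `0.8^k` (the quantity quoted in the literature), while
  actual per-half-set counts appear separately (floor() deviates for
  small stacks).
- A half-set shrinking below 16 particles halts the sieve with a clear
  status; partial results are preserved.
- The "finest subset" is *suggested*, not chosen: the reported heuristic
  (last iteration within 0.05 Å of the best FSC resolution) is labeled as
  such, and the per-iteration report is the real product.
- Limits are printed with half-up integer rounding and folds with one
  decimal, matching the formatting conventions of published tables.
- The B-factor fit regresses `ln N` on `1/d²`, ignoring the slowly
  varying `1/d` prefactor (the classical Rosenthal–Henderson plot); a
  flag restores the `ln(1/d)` correction. Repeated (N, d) points — e.g.
  half-splitting replicates — enter one joint fit.

## Known limitations

- Trilinear gridding without iterative correction biases the highest
  shells of a reconstruction (visible as FSC sag near Nyquist); adequate
  at package scale, not a production reconstructor.
- No beam tilt, higher-order aberrations, anisotropic magnification or
  Ewald-sphere curvature; per-particle defocus is taken as given.
- CryoSPARC `.cs` containers and movie formats are not read; MRC2014 and
  RELION STAR (3.1 with 3.0 fallback) are the interchange formats.
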