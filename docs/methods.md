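# Methods

## Pipeline overview

The pipeline chains five stages, each usable on its own:

1. **Calibration** — device geometry to physical pitches. The axial
   pitch is `depth_range_mm × 1000 / n_axial_px`, divided by the tissue
   refractive index (default n = 1.4) for in-tissue depths; defaults
   (1.9 mm, 512 px) give 3.71 µm/px in air and 2.65 µm/px in tissue.
   The lateral pitch is `fov_mm × 1000 / n_lateral_px` and is constant
   (≈7.06 µm/px) across the device's selectable field of view. Pitches
   are carried unrounded; printed values are rounded at report time
   (2 decimals for µm, 1 for mm). Pixel indices are 0-based, depth
   increases into the tissue, and all lateral intervals are half-open
   `[start, end)`.

2. **Delimitation** — the dermatoscopy image carries a white line
   marking the OCT scan path. A band of ±10 rows around it is converted
   to luminance; rows whose median luminance saturates (the line
   itself) are masked so they cannot dominate the histogram. Otsu's
   threshold (256-bin between-class-variance argmax, lowest level on
   ties) splits dark (pigmented lesion) from light (skin); columns more
   than half dark are lesion candidates and the longest run wins. A
   constant dark band means the lesion fills the scan span. Bounds map
   onto B-scan columns by fractional position along the scan span with
   half-up rounding. Lesion polarity is fixed "darker than
   surroundings", appropriate for pigmented melanocytic lesions.

3. **ROI extraction** — the lesion ROI is 100 px wide, centred on the
   floor midpoint of the bounds (left-biased for even widths, clipped
   with a warning at borders); healthy ROIs of 100 px flank the lesion
   immediately on each side that has room (a configurable guard gap
   defaults to 0), and their A-scans are pooled. Flattening shifts each
   column so the tissue entry is row 0: the entry defaults to the
   annotated surface row, refined to the first local maximum within
   15 px below it that exceeds 2× the column median (the bright entry
   peak). Taking the *first* qualifying peak rather than the brightest
   matters under speckle: the brightest-peak rule preferentially
   anchors columns on upward noise excursions and inflates fitted
   attenuation by several percent. Vacated bottom rows are zero-filled
   and treated as padding downstream. Depth is truncated to 150 px
   (~0.4 mm) for attenuation — deeper rows carry no tissue signal — and
   75 px (~0.2 mm) for texture.

4. **Attenuation** — each column is fitted by nonlinear least squares
   to `I(z) = A·exp(−2 µt z) + C` (round-trip factor in the exponent;
   reported µt is single-pass). The fit window runs from row 0 to the
   last nonzero row, capped at 150 px. Initialization: C₀ from the mean
   of the last 10 samples (clamped into the C box), A₀ = I₀ − C₀, µt₀
   from the log-linear slope of the offset-corrected profile; a second
   start near C = 0 is tried and the lower-residual fit kept. All three
   parameters are box-constrained non-negative. Per-region summaries
   are the median, Q1, Q3, and IQR = Q3 − Q1 (linear-interpolation
   quartiles) of converged fits; fewer than half converging is a
   quality error; the lesion-vs-healthy comparison is the difference of
   medians, reported to 2 decimals.

5. **Texture** — boxes of 25×25 px tile each depth section (0–25,
   25–50, 50–75 px) without overlap, partial boxes discarded. Gray
   values are uniformly requantized to 64 levels (625-pixel boxes
   cannot populate a 256² matrix). Per box, the GLCM is computed at
   offset d = 2 for the four axis directions — 0°→(0,+d), 90°→(−d,0),
   180°→(0,−d), 270°→(+d,0) in (row, col) — and contrast,
   dissimilarity, homogeneity, energy (√ of the angular second moment),
   and correlation are averaged over the directions (averaging opposite
   directions equals using symmetric pair counts, since reversing the
   offset transposes the matrix and every feature is
   transpose-invariant). Correlation of a zero-variance box is defined
   as 1 with an undefined flag. Sections are summarized by the median
   and IQR over boxes.

## The offset bound in the attenuation fit

Over a 0.4 mm window, decays with µt below ~1.25 mm⁻¹ retain close to
half of the signal, so the data barely distinguish the offset C from
late signal: the unconstrained three-parameter least-squares problem
has a spurious basin in which C absorbs the profile tail and µt roughly
doubles. Simulations at speckle shape k = 20 measured +15–30% mean bias
in µt with C free (or bounded only by the profile minimum). The fit
therefore bounds C to at most 4% of the profile peak (`c_rel_cap`,
exposed as a parameter). This encodes what C physically is — the dark
noise floor of an 8-bit display image, where air rows render below 1%
of the entry peak — and it removes the spurious basin: measured mean
bias drops to ≤2% at k = 20 across µt from 0.6 to 2.8 mm⁻¹. Because the
cap is a fraction of the peak, fits remain exactly equivariant under
rescaling the profile. Profiles with a genuinely bright floor (for
instance, log-compressed data that was not background-subtracted) need
a larger cap. After this change the residual bias at moderate speckle
sits below the Monte-Carlo resolution of a 200-fit mean, so noise
consistency is asserted on the RMS error (which shrinks monotonically
with the speckle shape) rather than on ordering bias estimates.

Absolute A and C are device-arbitrary display units; only µt is
interpreted. The pipeline fits stored image values as-is.

## Phantom generator

The generator emulates the statistical structure the analysis relies
on, not OCT wave physics:

- **Geometry** — a 512×425 B-scan (1.9 mm depth, 3 mm field of view).
  The tissue surface is a slow sinusoid (amplitude 5 px around row 40)
  plus a raised-cosine overelevation bump (default 12 px) over the
  lesion, so flattening is exercised non-trivially. Air above the
  surface renders at 0–2 gray levels.
- **Signal** — from the surface down, `A·exp(−2 µt z) + C` with
  A = 180, C = 4, z in in-tissue millimetres from the surface row; the
  z = 0 sample is the bright entry peak. The per-column µt map is
  healthy (default 0.8 mm⁻¹) outside the lesion interval and lesion
  (default 2.0 mm⁻¹) inside — within the ranges measured for healthy
  skin (0.6–1.0) and pigmented lesions (0.8–2.9) at 1300 nm.
- **Speckle** — multiplicative Gamma(k, 1/k) noise, unit mean and
  variance 1/k; k = 20 (≈22% contrast) is the default
  signal-to-noise knob. The Gamma surrogate is the standard
  single-parameter stand-in for fully/partially developed OCT speckle;
  no claim is made about any specific instrument's speckle statistics.
  A per-region shape (`lesion_speckle_shape`) makes lesion texture
  rougher or smoother at equal attenuation, and `grain_px` renders
  speckle in square cells for coarser texture at fixed variance.
- **Quantization** — after adding the floor, values are rounded and
  clipped to 8 bits, which the GLCM stage requires. The
  `noiseless()` helper disables speckle and quantization, making the
  columns exact members of the fit's model class (used to verify exact
  recovery).
- **Dermatoscopy pairing** — a skin-toned RGB image with a dark
  superellipse blob whose horizontal extent sits at the same fractional
  position along the scan span as the lesion columns in the B-scan,
  crossed by a 3-row white scan line. The superellipse exponent keeps
  blob edges near-vertical across the ±10-row band, so the band's dark
  columns align with the lesion to within a few B-scan columns.
- **Determinism** — one integer seed drives all draws; identical
  configs produce bit-identical images, annotations, and truth.

What the phantom does *not* model — and hence what passing tests do not
show about clinical data: hair, blood, and motion artifacts; specular
reflections; depth-dependent beam focus and sensitivity roll-off;
layered anatomy (epidermis/dermis boundaries, rete ridges); lesion
heterogeneity beyond a single µt contrast and speckle roughness; any
relationship between dermatoscopic color and histology. Results on
phantoms validate the machinery (geometry, estimators, bookkeeping),
not diagnostic performance.

## Scenario library and study sizes

Eight named scenarios (two each CN, IN, MIS, SSM) pair lesion/healthy
µt values spanning the medians reported for those subtypes; they are
fixtures for exercising the pipeline, not claims of clinical
equivalence. The population study uses 50 random phantoms (healthy µt
uniform on 0.6–1.0 mm⁻¹, lesion on 0.8–2.9 mm⁻¹, lesion width 80–200
columns, varying surface geometry), sized so that delimitation overlap
and ordering rates are stable while the full study runs in about a
minute on one CPU; the recovery study uses 200 A-scans per condition,
which resolves mean bias to about 1%.

## Numerical conventions and edge cases

- Quartiles: linear interpolation (numpy default); IQR = Q3 − Q1.
- Otsu ties: lowest qualifying level; thresholded split is
  `{v ≤ t} | {v > t}` with the lesion on the dark side.
- Co-registration rounding: half-up; mapped intervals are clipped and
  kept non-degenerate.
- Even-width lesions: centre is the floor midpoint (left-biased).
  Width-1 lesions are accepted and centred on their single column.
- Constant profiles fit as µt = 0 with zero residual; all-zero columns
  are unusable and counted as excluded.
- A flattened column whose nonzero extent is shorter than 10 samples
  cannot be fitted and is excluded from the region summary.
- GLCM boxes smaller than the pair offset are rejected; a section
  yielding no complete box raises an error naming the section.

## Known limitations

- The attenuation model is single-scattering with a global offset; µa
  and µs are not separated, and no confocal/roll-off correction is
  applied.
- The offset cap assumes a dark noise floor; data with bright floors
  need the cap widened, at the cost of shallow-µt stability.
- Delimitation assumes one dominant dark lesion crossing the scan line;
  multifocal or non-pigmented lesions are out of scope.
- The healthy-vs-lesion comparison pools both healthy flanks when
  available; with a guard gap of 0, partial-volume effects at the
  lesion border can blur the contrast for poorly delimited lesions.
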