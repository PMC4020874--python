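# Methods

`corneadyn` analyses high-speed cross-sectional image sequences of the
cornea recorded by a non-contact (air-puff) tonometer of the Corvis type.
Each recording is an M×N×I grayscale block (rows × columns × frames,
typically 200×576×140) showing a bright corneal arc that is indented by
an air puff while the whole eyeball recedes into the orbit.  The package
separates these two motions, quantifies rapid (hundreds of Hz) corneal
oscillations, condenses each eye into three dynamic features and assigns
one of four deformation classes.

## Model and procedure

**Coordinates and units.**  Row index m grows downward (into the eye),
column index n left to right, frame index i in time; intensities are
normalised to [0, 1]; all maps are in pixel units.  Indexing is 0-based
throughout.  The default frame interval is 231 µs: 140 frames then span
~32.3 ms and the FFT harmonics 7–15 of a record cover 216–464 Hz, which
is the band in which rapid corneal oscillations are observed.  (The
vendor documentation prints 23 µs per frame; that value is kept in
sequence metadata but is inconsistent with the oscillation-band
arithmetic over a 140-frame record and is not used in analysis.)

**Pre-processing.**  The sequence is median-filtered with a 3×3×3 voxel
mask (larger masks start deleting the thin corneal band).  The outer
corneal edge L_P(n, i) is then the topmost detected boundary row per
column, via either of two routes:

* *Otsu route* — each column is binarised at v_r = 0.5 times its own
  Otsu threshold (256-bin histogram of [0, 1]; exhaustive between-class
  variance maximisation); XOR of the binary frame with its 3×3 erosion
  leaves the 8-connected inner boundary; the contour is the topmost
  boundary row.  Bright iris cross-sections below the cornea inflate the
  column threshold and make this route fail more often.
* *Canny route (default)* — per-frame Canny edge map with Gaussian
  σ = 0.99 and hysteresis thresholds 0.1 (high) and 0.04 (low),
  interpreted as fractions of the frame's maximum Sobel gradient
  magnitude (the convention of the classical implementations this
  parameterisation comes from; on an absolute scale 0.1 sits below the
  Sobel response of mild sensor noise).  Frames are replicate-padded
  before edge detection so the outermost columns are not lost to the
  detector's border mask, and the 3×3 morphological closing runs before
  the padding is cropped.

Both routes optionally (default on) refine the integer topmost row to
sub-pixel precision with the centroid of the positive vertical intensity
gradient in a ±2-row window.  For a linear-coverage edge the centroid is
exact.  The pipeline refines on the *unfiltered* frames: the 3-D median
mixes neighbouring frames, which biases the partial edge pixel of a
*moving* edge by up to ~0.2 px toward its recent positions; the raw
frames carry no such bias.  Without sub-pixel refinement the
amplitude-recovery accuracy below is quantisation-limited at ±0.5 px.

A contour map is *valid* when no column is missing in any frame and no
column moves ≥ 10 px between consecutive frames (the cornea physically
cannot).  Isolated missing columns are filled by per-frame linear
interpolation; a frame with no detection at all aborts the analysis.
The repaired map is smoothed with a 3×3 median over (n, i).

**Separation of eyeball and cornea.**  Relative deformation
L_T(n,i) = L_P(n,i) − L_P(n,0) removes the resting corneal shape.  The
whole-eyeball displacement L_TO is, per frame, the straight line (affine
in n) through L_T at the left and right image borders, where the cornea
is assumed undeformed; the corneal deflection is L_TR = L_T − L_TO.
The decomposition is linear, idempotent on its own output and
conservative bit for bit (the returned L_T is the recomposed sum, within
one ulp of the input).  A configurable border band (default width 1
column, the exact border rule) can average several outermost columns
when border noise warrants it.  The scalar summary max(L_TR) is the
global maximum over (n, i).

**Rapid deformations.**  A flat grayscale opening of L_TR with a 33×33
structuring element (columns × frames; 33 frames ≈ 7.6 ms, longer than
one period of any 200+ Hz oscillation) passes only slow content, so
L_Q = L_TR − opening(L_TR) retains the fast deformations.  Two time
signals L_QL/L_QR average L_Q over the lateral column bands
[N/8, 3N/8) and [5N/8, 7N/8) — the borders themselves are identically
zero after the separation and the apex is dominated by the indentation;
the exact pixel sets behind these signals are this package's definition,
as no canonical one exists.  Their one-sided FFT magnitudes (no window,
no padding; array index = harmonic number, DC at 0) are F_QL/F_QR.
Band masks split each signal into a slow component (region I, harmonics
below 150 Hz) and a fast component (region II, 200 Hz and above, up to
Nyquist by default).  Region II is defined by its lower edge; capping it
at 500 Hz (the upper end of the *empirically observed* oscillation
range) would leave only ~10 harmonics at I = 140 and smear the time
support of short bursts by ~30 %, so no upper cap is applied by default
(configurable).  Harmonics in [150, 200) Hz belong to neither region.

**Features and classification.**  The per-eye response pattern is
L_V(n,i) = L_TO(N/2, i) + opening(L_TR)(n,i) and the pattern error is
L_Δ = L_T − L_V.  The features are

* w(1) = max over (n,i) of L_Δ (px) — dominated by the across-image
  residue of the eyeball motion plus whatever the opening clips off the
  indentation peak;
* w(2) = max of F_QL and F_QR over harmonics 7–15 (216–464 Hz) — the
  spectral amplitude of the rapid oscillation, in raw FFT-magnitude
  units (px·frames; spectra are not normalised by I, so w(2)'s absolute
  scale is tied to the 140-frame record);
* w(3) = duration (frames) for which the envelope
  e(i) = max(|comp_II_L|, |comp_II_R|) stays at or above 80 % of its
  peak, counted from first to last super-threshold frame inclusive.

Classes 1–4 are assigned by a CART decision tree: greedy binary splits
minimising weighted Gini impurity, candidate thresholds at midpoints
between consecutive sorted unique feature values, grown until leaves are
pure (no pruning, no minimum node size — with ~10 training eyes any
pruning would discard real structure).  Ties break deterministically:
lowest impurity, then lowest feature index, then lowest threshold;
impure leaves (conflicting duplicate vectors) keep the majority label.
The tree is serialised as JSON.  The published 10-eye reference feature
table ships with the package as the canonical small training set; the
tree is always re-induced from data rather than hard-coding thresholds.

## Synthetic phantoms

Real recordings are not redistributable, so every stage is validated on
phantoms with known ground truth.  A phantom's contour is

    contour(n,i) = baseline(n) + eyeball(n,i) + deflection(n,i) + ripple(n,i)

with a parabolic arc baseline (apex row 45, sagitta 55 px), an
affine-in-n eyeball displacement rising with a raised cosine (onset
frame 35, plateau from frame 120), a Gaussian-in-n indentation
(σ = 60 px, tapered to exactly zero within a 40-column border margin so
the border separation assumption holds; raised-cosine onset/peak/offset
at frames 30/70/110) and an optional fixed-frequency ripple inside a
boxcar frame window, spatially confined to the cornea.  Frames are
rendered as a 25 px bright band (intensity 0.9) below the contour with
linear pixel-coverage edges (sub-pixel accurate), a smooth bottom
falloff, optional bright iris-like bands below the cornea (the classic
failure mode of threshold-based edge detection) and clipped additive
Gaussian noise (default σ = 0.02).  Generation is byte-deterministic
under a fixed seed, and the returned truth object carries every
constituent field, built so the separation identities hold bit-exactly.

What the phantoms deliberately do *not* model: speckle statistics and
illumination falloff of a real Scheimpflug camera, corneal thickness
changes, out-of-plane and rotational eyeball motion, multi-frequency or
chirped oscillations, and applanation-specific intensity artefacts.
Passing the closed-loop tests therefore demonstrates correctness of the
algorithmic chain under the stated image model, not clinical accuracy on
patient data.

**Cohorts.**  `generate_cohort` samples eyes from four class recipes
that mirror the qualitative response types: (1) strong eyeball reaction
/ quiet cornea (border displacement 28–38 px, ripple ≤ 0.05 px),
(2) quiet eye (2–6 px, ripple ≤ 0.05 px), (3) strong rapid oscillation
(2–6 px, ripple 1.5–2.5 px at 250–400 Hz), (4) both strong.  The shared
indentation range (25–35 px) is kept narrower than the class contrasts
so the classes are separable by construction — the cohort tests verify
that the *pipeline* preserves that separation, not that CART can untangle
arbitrary overlap.

## Numerical choices and degenerate inputs

* Missing contour values are NaN (0 is a valid row); CSV serialisation
  uses empty cells.
* Otsu on a constant column is degenerate; such columns become missing
  and are interpolated.  The returned threshold is the upper edge of the
  winning histogram bin, so `value > threshold` selects the bright class;
  argmax ties break toward the lowest threshold.
* Morphological and median filters use edge replication at borders;
  the binary erosion in the Otsu route treats out-of-image as foreground
  so the frame border is never itself a boundary.
* Spectra require I ≥ 16 frames; the opening requires the 33×33 element
  to fit.  Degenerate cases raise typed errors rather than return junk.
* The analysis pipeline is deterministic; randomness exists only in the
  generators and is fully seed-controlled.
* Full-resolution analysis of one eye takes a few seconds on one CPU,
  dominated by the 3-D median filter.

## Known limitations

* The opening residual L_Q is non-negative by construction, so the
  border signals carry the ripple *plus its own amplitude as an offset*.
  Consequences: (a) the magnitude spectra always have a dominant slow
  lobe near DC — which is exactly why w(2) is windowed to harmonics
  7–15 — and any "where is the spectral peak" question must exclude the
  first few harmonics; (b) the band-II envelope is amplitude-modulated,
  so the 80 %-rule duration w(3) measured through the full pipeline
  systematically underestimates the true burst duration (roughly by
  half for a 40-frame burst).  w(3) is therefore a comparative feature,
  not a calibrated duration; applied to a band-limited signal directly
  (as in the signal-level tests) the rule is accurate to ±1 frame.
* The 80 %-rule itself is phase-sensitive for bursts a few periods long:
  the envelope is sampled through |comp_II|, whose sub-period zero
  crossings can shift the first/last super-threshold frame by a few
  frames depending on the carrier phase at the burst edges.
* The contour validity rule flags gaps and jumps; a dense noise field
  that happens to produce a complete, smooth topmost contour (e.g.
  high-variance bright noise over the whole frame) passes it.  Validity
  is a necessary sanity check, not a guarantee of anatomical meaning.
* max(L_TR) inherits a small positive bias (~0.05–0.2 px under sensor
  noise) because it is the maximum of a noisy field; at indentations of
  only a few pixels this bias dominates the relative recovery error.
* Eq.-style single-column border readings make the eyeball estimate
  sensitive to border-column noise; the configurable border band trades
  paper-faithfulness for robustness.
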