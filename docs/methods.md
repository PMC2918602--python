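# Methods

This note records the models, numerical choices and known limitations
behind `mousecmr`, in the order the pipeline runs.

## Digital heart phantom

Each short-axis slice of the left ventricle is a pair of concentric
circles. The endocardial radius contracts sinusoidally over the cardiac
cycle, r_endo(φ) = r_ED·[1 − (1 − α)(1 − cos 2πφ)/2] with α = √(1 − EF),
so the stack of cylindrical slices reaches the configured ejection
fraction exactly at φ = 0.5 (end-systole). The epicardial radius follows
from myocardial incompressibility, r_epi² = r_endo² + const per slice, so
wall cross-section (and hence LV mass) is conserved over the cycle and
the wall thickens at systole, as real myocardium does. Slices taper
toward the apex along an ellipsoid. Defaults (basal endocardial radius
1.85 mm, wall 0.9 mm, 5 × 1 mm slices, EF 0.72) put EDV ≈ 44 µl,
ESV ≈ 12 µl — the healthy-mouse scale. The infarct variant thins the wall
by a configurable factor (default 0.5) over a sector (default 90°) and
dilates the cavity (default ×1.4, EF ≈ 0.24), moving EDV to ≈ 86 µl.
All cavity/myocardial volumes, mass and wall-thickness profiles have
closed forms (`compute_ground_truth`), which is the point of the circular
geometry: recovery tests never depend on a voxelized "truth".

A right-ventricular crescent and an elliptical torso (intensity 0.25,
darker than myocardium: the tissue bordering a short-axis mouse heart is
largely lung) make the scene realistic enough for coil calibration and
segmentation to face the same hazards as in vivo. Contrast is pure tissue
intensity — black-blood cavities at 0.08, myocardium at 1.0 — with no
relaxation or flow physics; TE/TR are metadata.

Rendering uses a linear partial-volume ramp of one pixel width at every
boundary (the exact behavior of area-integrating pixels over a sharp
edge), so voxel-counting comparisons against the analytic areas are
meaningful at any matrix size.

### Motion

Respiration is a rigid in-plane translation with a narrow Gaussian
displacement bump (σ = 0.055 cycle) once per cycle: the heart rests for
~75% of the respiratory period and moves inside the remaining ~25%
window — exactly the lines a retrospective gater should discard into the
respiratory frame. Heart and respiratory rates default to 498 bpm and
85 breaths/min (the healthy-mouse regime) and carry slow sinusoidal rate
variability (2% over 5 s, 3% over 11 s). The variability is not
cosmetic: a perfectly periodic heart can phase-lock with the repeating
phase-encode sweep (for unlucky rate/TR ratios a given line revisits the
same one or two cardiac phases forever, starving most gating bins), a
pathology real rodents do not exhibit because their rates drift.

### Acquisition model

The simulated sequence acquires slices sequentially; within a slice, each
repetition sweeps the (possibly reduced) phase-encode set bottom-to-top,
one line per TR. Each line is a row of the centered 2D DFT of
(coil sensitivity × heart frame at the current cardiac phase), with the
respiratory shift applied as the equivalent k-space phase ramp and
correlated complex Gaussian coil noise (Hermitian PSD Ψ, AR(1)-like
correlation ρ = 0.25) added per sample. Cardiac phase is quantized to
1/96 of a cycle so per-slice coil k-spaces can be cached; the resulting
phase error (≤ 0.5% of a cycle) is an order of magnitude below the
1/10-cycle gating bins. One navigator sample per TR is the complex sum of
the mid-ventricular slice seen through an off-center Gaussian weighting,
so cardiac contraction and the respiratory shift both modulate it; this
waveform is a generic self-gating surrogate, not a model of any vendor's
navigator processing.

The raw-line noise level (image-referred SD 0.05 per single excitation)
was chosen so that the binned, fully sampled cine shows myocardial SNR of
roughly 40–50 and the 3×-accelerated cine roughly 15–20 after the g·√R
penalty — the regime reported for in vivo accelerated self-gated cines,
where R = 3 images still allow unambiguous wall/cavity delineation.

## Self-gating

The navigator magnitude is band-pass filtered (zero-phase Butterworth,
order 3) into cardiac (5–12 Hz) and respiratory (0.5–3 Hz) waveforms.
Triggers are local maxima with a refractory period of 60% of the median
period, refined to sub-sample precision by parabolic interpolation —
without the refinement, trigger intervals are integer multiples of TR and
the quantization ripples the frame occupancy by several percent. Cardiac
phase is (t − t_prev)/(t_next − t_prev); frame = ⌊phase·10⌋. Lines inside
the respiratory motion window (default 25% of the cycle centered on the
displacement peak) or outside the first/last trigger of either rhythm go
to the respiratory frame. Binning complex-averages multiple hits of the
same (frame, slice, line); a bin never hit is borrowed from the
acquisition of that line whose phase is nearest the bin center, and every
borrow is itemized in the fill report. With the default study protocol
(NR = 80) each bin averages ≈ 6 acquisitions and borrows are ≲ 1%.

## Reconstruction

Sensitivity maps come from a separate low-resolution scan (full readout,
32 central phase-encode lines, cardiac-cycle-averaged contrast),
zero-fill interpolated to the target grid. The reference is the
sum-of-squares magnitude with the phase of the coil sum; the object mask
is τ = MEAN + 2·SD of a pure-noise corner region, largest connected
component, holes closed. The division I_c/reference is restricted to
pixels above 15% of the reference's 99th percentile — near-zero reference
pixels (dark blood, truncation-ringing zero crossings) make the quotient
blow up, and since true coil profiles are smooth those pixels are better
recovered by the iterative nearest-neighbor region growing that
extrapolates the maps beyond the mask anyway. Maps are lightly smoothed
(masked Gaussian, σ = 1 px). The noise covariance is the sample
covariance of a separate 20 000-sample noise scan.

Unfolding pre-whitens data and maps with the Cholesky factor of Ψ and
solves the regularized normal equations per fully-sampled readout column.
Tikhonov weight λ = λ_rel · mean diag(EᴴΨ⁻¹E) with λ_rel = 10⁻³ by
default; λ_rel = 0 requests the exact least-squares solution and raises
on singular systems (e.g. identical coils) instead of returning garbage.
For uniform integer stride R | N_pe the solve factorizes into
m = N_pe/R independent R-unknown aliasing groups (the classic unfolding;
batched 3×3 solves at R = 3); any other pattern — including fractional
R = 1.5/2.5, whose floor(N_pe/R) near-uniform line sets have no clean
group structure — goes through the general per-column N_pe×N_pe solve.
Both paths are verified against an independent stacked-matrix
least-squares oracle to 10⁻⁸. The g-factor map uses the unregularized
system; singular groups report +inf.

The coil model defaults (4 elements on a 12 mm ring, 7 mm exponential
falloff, one phase cycle across the FOV, first element at 20°) were set
by a conditioning analysis: an arrangement mirror-symmetric about the
phase-encode axis makes aliased pixel triples on the central column
rank-deficient at R = 3 regardless of map accuracy, while the asymmetric
default keeps g ≈ 1.2–2 in the heart at R = 3 with localized higher
values elsewhere — the regime a tight 2×2 surface array provides in
practice.

## LV analysis

Segmentation thresholds each slice's cavity+wall ROI at
τ = factor × mean ROI intensity, with the mean pooled over all ten cine
frames. Pooling matters: a per-frame mean is higher at end-systole (more
bright wall in the ROI), which cuts ED and ES at different levels and
biases EDV down and ESV up simultaneously — an error no single factor can
remove, and one that SV = EDV − ESV amplifies. The cavity is the
below-threshold connected component at the ROI center, holes filled,
plus an additive morphological closing that reclaims single-pixel
boundary intrusions from noise flips (a no-op on clean masks; without it,
the low τ of dilated infarcted hearts sits close to the Rician magnitude
floor at R = 3 and boundary noise erodes several percent of the cavity).
The wall is the complementary component adjacent to the cavity. A cavity
that vanishes (lost contrast) raises an error, never a silent zero.

The default threshold factor is 0.6, the value calibrated in vivo against
literature volumes. That calibration is contrast- and resolution-
specific, so the package exposes the same procedure for the phantom:
`calibrate_threshold_factor` picks the factor minimizing the ED+ES volume
error against the analytic truth on directly rendered frames (0.9 for the
phantom's contrast at the in vivo matrix). Acceleration-comparison
studies keep 0.6 — any fixed factor cancels in R-vs-R deviations — while
absolute-recovery tests use the calibrated value, as the original
procedure did.

Volumes are voxel counts × voxel volume per frame; ED/ES are the
max/min-volume frames; mass is the ED wall-mask count × voxel volume ×
1.05 mg/mm³. CNR_wall–cavity = |S_w − S_c| / √((SD_w² + SD_c²)/2) (the
RMS-of-SDs denominator; mean-of-SDs and quadrature variants are
selectable but comparisons across R must fix one). Wall thickness casts
rays from the cavity center every 15° and takes the sub-pixel distance
between the half-level crossings of the wall mask. Cohort deviations use
ΔP_LV = (100/N)·Σ|P_R,i − P_ref,i|/P_ref,i and cross-sectional areas are
compared by ordinary least squares.

### What measured volumes are compared against

A 10-frame retrospective cine measures *bin averages* of the volume
curve, and the navigator of this phantom peaks at end-systole, which
places true ED and ES on bin edges — even a perfect pipeline reads SV
about 3% low against the instantaneous truth. Recovery tests therefore
compare against the analytically bin-averaged volumes
(`binned_cavity_volumes`); the instantaneous comparison is kept at a
documented looser bound. Deviation studies between accelerations are
unaffected (both Rs share the binning).

## Study sizes

The cohort studies (8 healthy + 6 infarcted subjects, R ∈ {1.0, 3.0})
run at a 96×96 matrix over the in vivo 25 mm FOV, 5 slices, TR 5.2 ms,
NR = 80 — the in vivo geometry and timing at a matrix that keeps a full
14-subject × 2-acceleration study at a few minutes on one CPU. The
absolute-recovery cohort runs fully sampled at the in vivo 154 matrix,
where voxel-counting granularity matches the published protocol. Subject
jitter draws anatomy (radii ±4–6%, position ±0.4 mm), physiology
(HR 498 ± 46 bpm, RR 85 ± 16 /min, EF ± 1.5%) and noise seeds from a
per-subject seed.

## Limitations

- No relaxation, flow or saturation physics: black/bright blood is an
  intensity label, so CNR magnitudes are not comparable to in vivo
  values (region SDs here are mostly coil shading plus noise, not tissue
  heterogeneity); only CNR *trends* across R are meaningful.
- The navigator waveform is a geometric surrogate; conclusions about
  vendor self-gating implementations do not follow.
- LV mass from threshold masks includes the RV insertion region inside
  the analysis ROI (the in vivo procedure outlined the epicardium
  manually), so pipeline mass runs high against the analytic truth;
  mass *deviations* between accelerations remain valid.
- Threshold segmentation with a fixed factor carries a resolution-
  dependent boundary bias (the τ crossing sits below the partial-volume
  midpoint); at the 96 matrix this is −6…−9% on absolute volumes. It is
  common mode between accelerations.
- Gated noise is treated as homoscedastic within a frame although bins
  average varying numbers of acquisitions; the residual heteroscedasticity
  is invisible at the default fill fractions.
- No through-plane motion, no arrhythmia, one navigator gates all slices.
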