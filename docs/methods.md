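# Methods

## The phantom

**Geometry.** The LV cavity is a truncated half-ellipsoid: base plane at
z = 0, apex at z = c (`long_axis_length`, default 90 mm), in-plane semi-axes
(a, b) (`cavity_semiaxes_ed`; the presets use a = b). The compact wall is the
shell between this surface and a concentric half-ellipsoid with semi-axes
(a + w, b + w, c + w), where w is the wall thickness. Papillary muscles are
vertical cylinders (default two, at the anterolateral and posteromedial
positions, axis at half the cavity radius, spanning 15–60% of the long
axis) placed inside the blood pool. Trabeculations are sinusoidal radial
ridges of the endocardial surface: at angle θ the endocardial radius is
reduced by `amp · max(sin(kθ), 0)` with k ridges per revolution (default 12,
chosen so that individual ridge widths straddle the 1.5-mm filter at the
default resolution), capped at 60% of the local radius so ridges never reach
the cavity axis.

**Kinematics.** A raised-cosine contraction fraction g(p) runs from 0 at
end-diastole (phase 0) to 1 at end-systole (40% of the cycle; phase 8 of
20). Per phase, the in-plane cavity scale s is solved (Brent's method) so
that the *blood-only* cavity volume equals
V_ED · (1 − EF_true · g(p)) — the requested ejection fraction is realised
exactly, and the ground-truth stroke volume is the volume-curve range by
construction. Wall thickness interpolates from its ED to its ES value
(systolic thickening factor 1.35). The trabecular ridge depth scales as
amp(p)/s(p): trabecular tissue volume is conserved under cavity contraction
(tissue is incompressible), so the *apparent* compaction of trabeculae into
the wall is governed by the amplitude interpolation amp_ED → amp_ES alone,
plus the merging of papillary cross-sections into the wall as the cavity
shrinks around them.

**Ground truth.** Blood-only and P&T volumes per phase are computed by
radial-interval quadrature of the continuous geometry (241 z-planes × 480
angles, with exact ray–cylinder intersections for the papillaries), not by
voxel counting; for a = b the section integrals are exact up to the
quadrature grid. Label volumes (background / blood / compact myocardium /
P&T) are the majority class of the supersampled point classification per
voxel. Total true LVM is (compact shell + P&T at ED) × 1.05 g/ml.

**Imaging.** Voxel intensities are partial-volume mixtures
f_blood·I_blood + f_tissue·I_myo (defaults 500 and 200 a.u.), with the class
fractions obtained by supersampled averaging — in-plane over the pixel and
through-plane over the excited 8-mm slab only; the 2-mm inter-slice gap is
not sampled, as in a gapped 2D multi-slice protocol. Slices sit centred in
consecutive (thickness + gap) cells starting at the base plane. Additive
Gaussian noise (default SD 20 a.u., i.e. myocardial SNR 10) approximates
Rician noise at high SNR; intensities are floored at zero. The velocity
series uses a parabolic (Poiseuille) profile in a 15-mm-radius vessel whose
per-phase peak is scaled to the systolic cavity-volume loss rate, so the
noise-free forward integral equals the true stroke volume (verified to 1%);
velocity noise is Gaussian (default 2 cm/s).

**Cohort presets.** Rather than hand-tuned geometry constants, each sampled
subject starts from anatomical targets — blood EDV, LVM, EF, P&T mass
fraction, long axis, and (Fabry) a systolic compaction volume — drawn from
truncated normals whose means are the published group means and whose SDs
are the corresponding SEMs × √20. The geometry is then *solved* from the
targets: cavity radius from EDV + P&T volume; wall thickness from the shell
volume (Brent); papillary radius from a fixed 35% papillary share of P&T;
ridge amplitude by a short secant iteration against the quadrature; the ES
amplitude from the compaction target (clamped to the physically reachable
range — with very deep ridges the 60%-radius cap itself compacts tissue and
sets a floor). Calibration is therefore by construction; the test suite
checks that 100 control draws recover the 13% fraction target within 0.02.
Heights and weights are truncated normals (178 ± 7 cm, 80 ± 10 kg), a
plausible adult-male distribution. Control subjects have no amplitude
compaction (amp_ES = amp_ED); Fabry subjects target 11 ± 5 ml.

## Segmentation

All contours that were manual in the source protocol are deterministic
intensity/morphology operators here.

**Class levels.** Three-class Otsu on the first phase yields the
background/myocardium and myocardium/blood thresholds; pure-class levels are
sigma-clipped medians of the two tissue classes (plain means — and to a
lesser degree medians — are pulled toward the other class by partial-volume
pixels, which would bias every partial-volume inversion below). Derived
levels: `blood_mid`, the 50% mixing point, and `wall_core`, the 75%-tissue
point. A degenerate-contrast guard rejects stacks whose class gap is below
twice the within-class spread (a unimodal noise histogram splits at ~1.4).

**Phases and slices.** ED/ES are the argmax/argmin (ties to the earliest
phase) of the blood-pool volume curve. The basal slice is the first whose
cavity boundary is at least 50% adjacent to myocardium at ED
(boundary-adjacency operationalisation of the visual criterion); the apical
cavity slice is the last with a detectable pool. Tissue-only slices beyond
it still contribute their epicardial area to LVM (the epicardial contour
runs base to apex; the cavity does not).

**The smooth (M_ex) contour.** The cavity is bounded by *definitely compact*
myocardium: pixels below `wall_core` on a lightly denoised image (Gaussian,
1.5 mm). Everything inside the epicardial region that is not such tissue
forms the cavity zone; components are kept if they touch the blood pool or,
at the other phase of the pair, the same slice's cavity footprint — the cine
prior a human reader uses when compacted trabeculae seal recesses off from
the pool. Morphological closing (disk, 8 mm) then swallows solid P&T cores.
A 5-mm closing radius cannot span the ridge-base width at the default
trabecular frequency, which is why the default is 8 mm.

**The band (M_inc) rule.** P&T candidates are below-`blood_mid` pixels
inside the smooth cavity; a candidate component is accepted when it contains
a pixel whose intensity lies within `intensity_band_sd` (default 1.0) sample
SDs (n − 1) of the free-wall reference signal — the inclusive two-sided
band; exact equality when the SD is zero — and reaches the cavity interior
(a "structure" confined to the contour's outermost pixel layer is
partial-volume wall, not P&T). The free-wall reference is the lateral 120°
sector of the mid-wall (eroded compact wall) on the mid-ventricular slice.
Accepted components thinner than `min_trabecula_width` (default 1.5 mm,
strict "below"; survival of an opening whose discrete disk radius is the
largest r with 2r + 1 ≤ width in pixels, so ties resolve toward keeping) are
removed from the P&T mask.

**Sub-pixel volumetry.** Pixel counting quantizes every contour by roughly
half a pixel, which matters when two ~100-ml volumes are differenced against
a flow reference. Two linear partial-volume estimators remove most of it:
the blood-only (M_inc) cavity area is the *blood-fraction integral*
Σ (I − I_myo)/(I_blood − I_myo) over the smooth-cavity region (unclipped, so
zero-mean noise cancels); the M_ex ED area re-weights the boundary ring of
the mask by the same blood fraction wherever the ring does not abut P&T
(against mixed trabecular tissue the two-class inversion is invalid, so
those pixels count whole, and the ES area — whose boundary is mostly such
tissue — stays a plain pixel count). Operator parameters (wall-core
fraction, denoise sigma, closing radius) were calibrated on noiseless
phantoms against the analytic truth, the standard way phantom studies
calibrate an operator; the tests pin the resulting accuracy (volumes and
M_inc mass within 3% of truth on the noiseless Fabry phantom).

## Flow

The vessel ROI is found without a manual region: a core above 50% of the
global temporal-peak speed, grown to the smoothed mean-forward-speed region
above 5% of its own peak (a plain 0.5-of-peak threshold would select only
half the lumen of a parabolic profile). Stroke volume is the net signed flow
integral over the cycle (clipping negative phases is available as
`clip_regurgitation`, but with no regurgitation modelled the net integral is
the forward volume and is unbiased under zero-mean velocity noise, which
per-phase clipping is not).

## Statistics

Mean ± SEM summaries; paired t within groups between methods (identical
vectors return p = 1; constant non-zero differences raise a degenerate-data
error); Welch t between groups (Student's form by option); two-sided α =
0.05. Bland-Altman reports the mean difference, SD, mean ± 1.96 SD limits
of agreement and the coefficient of repeatability 1.96 × SD (the factor is
configurable; some literature uses 2). Observer repeatability is simulated —
re-rendering the acquisition with fresh noise and rotating the free-wall
sector on half the cohort — a stand-in for human observers, not a claim of
equivalence to them.

One bookkeeping note: the published Fabry M_inc stroke volume (103 ml) is
inconsistent with its own printed EDV − ESV (127 − 34 = 93 ml); this package
computes LVSV strictly as LVEDV − LVESV.

## What the phantom does and does not show

Passing tests demonstrate that the operators recover known geometry,
volumes, masses and their method-dependent differences from images with
realistic contrast, partial volume and noise — including the two study-level
effects: a ~20% P&T mass fraction in the hypertrophic preset and the
stroke-volume overestimation of the smooth-contour method against the flow
reference, which both emerge from the simulated physiology rather than
being asserted. They do not demonstrate performance on clinical images: the
phantom has no banding or flow artifacts, no breath-hold misregistration,
single-chamber anatomy with a convex cavity, stylised sinusoidal trabeculae,
and Gaussian rather than Rician noise. Known residual limitations, visible
in the tests' tolerances: gapped-Simpson slice-profile discretisation
under-measures the tapering apex by ~2% of LVM; subjects drawn with extreme
trabeculation (ridge depth ≳ 9 mm) have end-systolic trabecular bands below
the resolution limit, which biases the smooth-contour ESV low and the
stroke-volume overestimation a few ml high — the same difficulty that
motivates preferring the P&T-inclusive convention in hypertrophy.

## Problem sizes

Default cohorts are n = 20 per group at 1.5-mm pixels, 8 mm + 2 mm slices,
20 phases, supersampling 2 — the full simulated study runs in about a
minute. Unit tests use smaller phantoms (6 phases, coarser pixels) where the
property under test does not depend on the full protocol.
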