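# Methods

## The measurement model

The functional base of support (fBOS) of one foot is defined as the
convex hull of centre-of-pressure (COP) samples recorded while a
standing participant sweeps the COP in large slow loops with both feet
flat, each foot on its own force plate. The convex hull is appropriate
because the set of statically sustainable COP positions under a rigid
flat foot is convex; it is much smaller than the anatomical footprint
because only part of the sole can bear a large fraction of body weight.

### COP computation and filtering

For a plate with surface-level origin, COPx = −My/Fz + ox and
COPy = Mx/Fz + oy; for an origin a depth d below the surface the
horizontal-force lever terms Fx·d and Fy·d are added to the moments
first. Samples with Fz ≤ 50 N are masked (COP is ill-conditioned at low
load). The COP is filtered with a zero-phase (forward–backward)
second-order low-pass Butterworth at half the marker rate (75 Hz for
150 Hz markers) and then decimated by the integer rate ratio so its
samples coincide with the marker clock. Zero-phase filtering is
required because the COP extremes define the hull: phase lag would
displace them.

### Flat-foot selection rules

A COP sample contributes to the fBOS only inside maximal runs that
jointly satisfy: run length ≥ 150 samples (1 s at 150 Hz); plate load
≥ 40% of body weight; heel and toe-tip markers within 5 mm of their
quiet-standing height with vertical speed < 0.02 m/s (computed on
10 Hz low-passed marker height — raw differentiation of marker noise
would swamp the velocity criterion); after which the samples whose
frame-to-frame COP displacement exceeds the 99.9th percentile of
displacements over the retained runs are removed and the runs
re-checked against the 1 s minimum. Body weight is estimated as the
mean total vertical force over a quiet-standing window (default the
first 2 s). The weight-share criterion is in practice the dominant
excluder; the selection report counts rejections per criterion. The
transition quantile is computed per foot and per trial (the criterion
targets intra-trial slips, and pooling feet would let a quiet foot
mask a slipping one); the report flags this scope.

### Foot frame, reflection and averaging

The foot frame is planar: origin at the heel marker's floor projection,
+y along the heel→toe-tip floor projection, +x completing a
right-handed frame with z up (so the little-toe side is +x on the right
foot and −x on the left). It is fitted from time-averaged markers over
the quiet window; markers above the floor (ankles) are projected
vertically, treating the footprint as planar. Foot length L is the
heel–toe-tip distance, foot width W the mediolateral separation
|x(MTP1) − x(MTP5)| in frame coordinates — width is mediolateral by
construction rather than a Euclidean marker distance. The anterior axis
uses the toe-tip marker; using an MTP midpoint instead is a sensitivity
question the data here cannot settle.

Per participant, the COP samples of each foot are projected into that
foot's frame and hulled; the right-foot hull is mirrored (x → −x) into
the left convention; the two hulls are averaged by arc-length-indexed
boundary averaging: each boundary is resampled at n = 100 equal
fractions of perimeter starting from a canonical anchor — the boundary
intersection of the +y (anterior) ray from the polygon centroid,
tie-broken by smallest x — and the boundaries are averaged vertex-wise,
then re-hulled. n = 100 keeps the perimeter discretisation error well
below marker noise; identity-averaging a polygon with itself is exact
up to that discretisation. Shape metrics are computed on the averaged
metric polygon against the combined frame: area ratio (hull area /
footprint-hexagon area), normalised length and width (bounding-box
extents over L and W), and inward distances from the toe, heel,
lateral-ankle and MTP5 markers to the corresponding bounding extents.
The lateral inward distances are signed mediolateral bounding-box
offsets, matching the anterior–posterior treatment, not
nearest-boundary Euclidean distances. Metrics are deliberately computed
on the averaged polygon (not per foot and then averaged), following the
order of operations of the measurement protocol. The polygon is then
normalised (x/W, y/L) for cross-participant averaging into group
templates, which scale back to any foot by (x·W, y·L) with an optional
mediolateral mirror.

A participant whose fBOS looks anomalously large relative to the group
is flagged through the metrics (`outside_footprint`) and the selection
report, never auto-dropped; exclusion is a manual QC decision.

## Walking analysis

Force and moment channels are zero-phase low-passed at 10 Hz; stance is
the maximal contiguous window with Fz > 50 N, discarding windows
shorter than 0.2 s. The foot-normalised COP path length is
P = (max − min of the COP projected on the travel axis)/L, with the
travel axis taken as the unit vector of net heel-marker displacement —
self-contained and invariant to the lab's axis conventions. The
mediolateral direction is not assessed (the COP does not traverse the
foot width during gait). Stride speed is net heel displacement over the
record divided by its duration.

## Statistics

Group comparisons use Kruskal-Wallis with tie correction; post-hoc
pairwise comparisons standardise differences of group mean ranks with
the tie-corrected pooled rank variance and refer them to the
studentized range with infinite degrees of freedom (a Tukey-Kramer
critical range, the default multiple-comparison behaviour of the
environment the analysis mirrors); a Dunn-Bonferroni variant is
available behind a flag. Correlations are Spearman's rho with average
ranks and Kendall's tau-b, whose tie correction matters for heavily
tied clinical scores (SPPB, FES-I, frailty levels). Two-sample and
paired comparisons use Wilcoxon rank-sum / signed-rank with exact small
sample distributions where there are no ties. Missing values are
removed per test and every reported n counts the rows actually used.
No multiplicity control is applied beyond the post-hoc family.

## Synthetic data: what it emulates and what it does not

**Standing trials.** The COP loop is generated by a ray from the true
polygon's centroid rotating at 0.1 Hz whose radius factor is a clipped
raised sinusoid plateauing at exactly 1; the modulation frequency is a
golden-ratio multiple of the loop rate so successive boundary plateaus
fall at well-spread angles and the sample hull converges to the true
polygon (a commensurate ratio would revisit the same angles and leave
permanent gaps). Weight share follows a 0.05 Hz sinusoid between the
configured bounds (default 40–60% body weight per plate); lifts are
raised-cosine bumps (≥ 2 cm on the heel or toe marker, weight share
pushed below 40%). Plate moments are synthesised from the (tremor-
corrupted) COP and vertical force as Mx = (COPy − oy)·Fz,
My = −(COPx − ox)·Fz, so the COP computation inverts them exactly —
the round trip isolates processing error from generator noise. Noise
defaults are 0.5 mm COP tremor and 0.5 mm marker noise, reflecting
research-grade plates under > 40% body-weight load and optical capture
residuals. The generator does **not** model body dynamics, sway
spectra, realistic lift kinematics or shear forces; passing recovery
tests therefore demonstrates correctness of the geometry and selection
logic under controlled contamination, not robustness to every
behaviour of human participants. Loop and modulation frequencies are
free parameters of the artifact, not claims about human sway.

**Walking strides.** Single-foot stance with a half-sine vertical force
(one rise above and fall below 50 N) and a monotone smoothstep COP
progression spanning exactly the target fraction of foot length; the
heel advances one stride length over the record through a smooth swing.
The 50 N threshold clips ~0.3% of the COP extent at the stance edges, a
bias an order of magnitude below the ±0.03 recovery band.

**Cohorts.** One standard-normal latent "balance capacity" per
participant; the normalised fBOS area is a strictly monotone bounded
map of the latent whose per-group median and range are configured
(defaults: area 22/22/13% with the observed ranges; length 65/61/53%;
width 35/35/21%; toe distance 21/21/28%; heel distance 17/18/20% for
young/middle/old; the lateral distances have no group effect). Other
outcomes load on the latent via a Gaussian copula; Spearman/Kendall
targets convert to copula correlations through r = 2·sin(πρ/6) and
r = sin(πτ/2), and infeasible targets (loadings outside [−1, 1]) raise
an explicit error. Clinical covariates exist only in the older group,
as in the study design (younger groups saturate them). Frailty levels
get exact counts 7/13/10/4 ordered by a noisy reversed capacity;
walking COP path length is linked to standing fBOS length with a
copula loading targeting ρ = 0.49; stride speed is independent of it;
one older participant's walking data is missing (n = 33 of 34). A
simulation during design showed the between-group area distributions
alone induce a cohort-wide Spearman(age, area) ≈ −0.52, so the
within-group age coupling defaults to zero. A small shod/barefoot
sub-sample (8 middle-aged, 3 older) differs only by multiplicative
noise, giving a null paired comparison.

## Numerical choices and degenerate inputs

* Convex hulls via Qhull; < 3 points or collinear sets raise errors.
* Shoelace areas are orientation- and start-invariant; all polygon
  rings are stored open and counter-clockwise.
* The arc-length anchor handles a ray grazing an edge by taking the
  intersection point with smallest x, then smallest y.
* Decimation requires an exact integer rate ratio; anything else is an
  error rather than a silent resample.
* Filter cutoffs at or above Nyquist are rejected.
* An all-sub-threshold plate yields an empty COP trajectory with a
  warning, not an exception; an empty selection yields an empty segment
  list plus a per-criterion rejection report.
* Polygon model files are validated on read: deduplicated, re-ordered
  counter-clockwise if stored clockwise, rejected if non-convex.

## Problem sizes in the validation suite

The recovery studies use 200 synthetic participants (60 s standing
trials) and 50 strides; Monte-Carlo area oracles use 10⁶ points. Group
templates average 100-point boundaries. These sizes put every sampling
error well below the acceptance bands while keeping the whole suite in
the tens of seconds on one CPU.

## Known limitations

* C3D input is not supported; trials exchange through the documented
  TSV layout (markers, per-plate forces, meta.json).
* The exact column headers of external cohort workbooks vary; the
  reader maps them through an explicit alias table and refuses to
  guess unknown columns.
* Foot-flat tolerances (5 mm, 0.02 m/s) are configurable defaults
  observable from the data at hand, not a validated clinical standard.
* Marker-dispersion ellipses for templates are reported as per-vertex
  radial standard deviations of the resampled boundaries, a simpler
  summary than full covariance ellipses.
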