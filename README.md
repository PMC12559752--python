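# fbos — functional base-of-support analysis

Balance analyses that use the margin of stability need a geometric model
of the base of support (BOS). Using the anatomical footprint — or single
toe/heel markers — overstates the region that can actually bear weight:
only part of the sole can support a large fraction of body weight with
the foot flat. The **functional base of support (fBOS)** measures that
region directly: standing participants sweep their centre of pressure
(COP) in the largest possible loops while keeping both feet flat, and
the fBOS of each foot is the convex hull of the COP samples recorded
under strict flat-foot, high-load selection rules.

This package implements that analysis end to end for movement
scientists:

* **COP processing** — COP from force-plate forces/moments above a 50 N
  threshold, zero-phase second-order Butterworth filtering at half the
  marker rate, decimation to the marker clock, and selection of COP
  runs that are ≥ 1 s long, carry ≥ 40% body weight, have flat
  heel/toe markers, and survive removal of the largest 0.1% COP
  transitions;
* **foot geometry** — a planar foot-fixed frame (origin at the heel,
  anterior axis heel→toe-tip) built from quiet standing, and the
  footprint hexagon through the six foot markers (heel, medial/lateral
  ankle, MTP1, MTP5, toe tip);
* **fBOS model** — per-foot convex hulls, mediolateral reflection of
  the right foot, arc-length-indexed polygon averaging across feet and
  participants, normalisation by foot length L and width W, shape
  metrics (area ratio A_fBOS/A_footprint, normalised length and width,
  inward distances from the toe, heel, lateral ankle and little toe),
  and scalable group templates;
* **walking analysis** — stance detection (10 Hz filter, 50 N
  threshold) and the foot-normalised COP path length
  P = (max − min COP along travel)/L, plus stride speed;
* **cohort statistics** — Kruskal-Wallis with mean-rank post-hoc
  comparisons (Tukey-Kramer critical range), Spearman and tie-corrected
  Kendall correlations, rank-sum and signed-rank tests, and a one-call
  reproduction report;
* **synthetic data** — physically consistent standing trials, strides
  and cohorts with known ground truth, so the whole pipeline is
  testable without laboratory recordings.

## Worked example

```bash
python examples/standing_fbos_extraction.py
```

```
feet used:            both
retained samples:     left 8824, right 8920
fBOS area ratio:      0.206   (true 0.198)
normalised length:    0.593   (true 0.600)
normalised width:     0.334   (true 0.330)
toe inward distance:  0.192 of foot length
heel inward distance: 0.215 of foot length
```

A 60 s synthetic standing trial is generated with a known true fBOS
polygon, written to the plain-TSV trial layout, re-read, and pushed
through the full pipeline. The recovered area ratio (hull area divided
by footprint-hexagon area) lands within ~0.01 of the generated truth:
only a fifth of this footprint can actually bear ≥ 40% body weight.
The toe inward distance says the functional boundary sits ~19% of the
foot length behind the toe marker — the error a footprint-based
margin-of-stability would make in the anterior direction.

`examples/walking_cop_path.py`, `examples/group_templates.py` and
`examples/cohort_statistics.py` demonstrate the walking analysis,
group-template averaging/scaling, and the statistics battery on a
synthetic cohort of 38 young, 14 middle-aged and 34 older adults.

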