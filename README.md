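# carpodyn

Dynamic carpal joint-width analysis for real-time wrist MRI.

Scapholunate ligament (SLL) tears are the most common cause of carpal
instability, and *dynamic* instability patterns — abnormal carpal alignment
that appears only during motion — are invisible to static imaging.
Real-time MRI can film the wrist during continuous radioulnar abduction
(one coronal frame every 95 ms), and the widths of the scapholunate (SL)
and lunotriquetral (LT) joints, tracked as a function of wrist angle,
become quantitative surrogates of ligament status: healthy SL joints stay
near 2 mm across the range of motion, while torn ones widen — and *where*
in the motion cycle they widen distinguishes partial from complete tears.

`carpodyn` implements the full measurement pipeline from segmented label
masks to group statistics, plus a synthetic dynamic wrist phantom that
stands in for patient data:

- **`synthetic_wrist`** — paired (injured / contralateral-control) motion
  series of a 9-bone 2D wrist phantom with per-frame ground-truth masks,
  wrist angles and joint gaps. Gap-versus-angle profiles are enforced
  *exactly* in continuous coordinates before rasterization.
- **`imaging`** — frame preprocessing (Gaussian anti-aliasing + 2×
  bi-quadratic interpolation, 168×168 px @ 1.0 mm → 336×336 px @ 0.5 mm),
  an optional trainable per-pixel neural segmenter, Dice scoring, and
  TIFF/NIfTI series I/O with JSON sidecars.
- **`carpal_geometry`** — smoothed subpixel bone outlines; the proximal-row
  centreline (scaphoid → lunate → triquetrum centroids); SL and LT joint
  widths as distances between the centreline's intersections with the
  facing bone cortices; the wrist angle from minimal-area bounding boxes
  around the distal carpal row and the forearm.
- **`kinematics`** — 5° wrist-angle binning, per-bin mean ± SD profiles,
  intra-individual Δ (injured − control) profiles, and the ≥ 3 mm dynamic
  instability flag.
- **`group_stats`** — subject-blocked (split-plot) two-way ANOVA, Tukey
  posthoc contrasts on the studentized range, and paired-design sample
  size / power via the noncentral *t* distribution.
- **`cli`** — `carpodyn simulate | train | measure | stats | run-all | demo`.

## The measurements

For each frame with label mask *M*:

- **Joint width.** The smoothed outlines of the scaphoid (S), lunate (L)
  and triquetrum (T) are connected by the centreline through their
  centroids. The SL width is ‖p_S − p_L‖ where p_S, p_L are the
  intersections of the S→L centroid segment with the scaphoid's ulnar
  cortex and the lunate's radial cortex; the LT width is built the same
  way on the L→T segment.
- **Wrist angle.** θ = ∠(c_D − c_F, u_F): the signed angle between the
  line joining the centres of the minimal bounding boxes of the distal
  carpal row (hamate, capitate, trapezium, trapezoid) and of the forearm
  (distal radius + ulna), and the forearm box's long axis u_F. Ulnar
  abduction is positive; the ulnar direction is read from the
  ulna-vs-radius centroid offset, so left and right wrists mirror
  automatically.
- **Profiles.** Angles are grouped into 5° bins (centres at multiples of
  5°); per-bin and frame-pooled ("Entire") mean ± SD are tabulated per
  group, Δ profiles are taken against the same subject's contralateral
  wrist, and any bin mean ≥ 3 mm flags dynamic SL instability.

The paired-design sample size solves for the smallest n with

P(|T′_{n−1}(d√n)| > t_{1−α/2, n−1}) ≥ 1 − β,

with effect size d = (mean paired difference)/SD. At α = 0.01, power 0.8,
d = 1.4 (two-tailed) the answer is **n = 10** (power 0.769 at n = 9,
0.844 at n = 10).

## Worked example

Simulate the default paired cohort — 10 patients (6 partial, 4 complete
SLL tears), each with a healthy contralateral control wrist, 300 frames
per wrist — measure every frame from the ground-truth masks, and run the
group statistics:

```bash
carpodyn demo --out demo_out --seed 1
cat demo_out/stats_report.txt
```

```
carpodyn 0.1.0 stats report (alpha=0.01)
SL width, injured vs control (subject-blocked ANOVA): F(1)=18.64, p=4.15e-04  *
LT width, injured vs control (subject-blocked ANOVA): F(1)=0.03, p=8.54e-01
instability flags (>= 3.0 mm): 8 injured wrists flagged
```

The SL width separates injured from control wrists (p ≤ 0.01) while the
LT width does not — the expected phenotype. The group-by-position table
(`demo_out/table_sl_width.csv`, mean ± SD in mm) shows *where* the
separation lives:

```
                 Entire     -20       ...   +0        +5        +10       +20
control_complete 1.97±0.15  1.98±0.11 ...  1.98±0.12  1.94±0.16  1.96±0.19  1.98±0.17
injured_complete 2.90±0.67  2.06±0.15 ...  3.43±0.38  3.69±0.40  3.67±0.37  2.92±0.25
injured_partial  2.88±0.69  2.49±0.68 ...  3.24±0.65  3.19±0.64  2.97±0.67  2.71±0.66
```

Control wrists sit near 2 mm across the whole range of motion; complete
tears peak at +5…+10° ulnar abduction (3.69 mm) while partial tears are
widest near neutral. The ≥ 3 mm rule flagged 8 of 10 injured wrists and
0 of 10 controls in this run. `demo_out/` also contains per-frame
measurement CSVs, Δ profiles (`paired_deltas.csv`), per-wrist flags and a
run manifest that reproduces the run byte-for-byte.

The same pipeline runs on saved mask series (`carpodyn measure masks.tif`)
or from a JSON config (`carpodyn run-all config.json`), optionally through
the trainable segmenter instead of ground-truth masks.

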