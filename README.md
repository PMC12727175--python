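# condylokin

Quantitative symmetry analysis of mandibular condyle motion from real-time
MRI (RT-MRI).

The two temporomandibular joints (TMJs) cannot move independently: healthy
jaw opening and closing is a bilaterally synchronized movement, and a
condyle that starts late, moves less, or peaks later than its counterpart
is a candidate marker of joint dysfunction.  RT-MRI captures both condyles
during motion — one axial plane showing both joints (≈21 ms per frame,
1.41 mm pixels) and two sagittal planes acquired by alternating slices
(≈51 ms per image, 0.36 mm pixels, one joint each).  `condylokin` turns
segmented condyle masks from such acquisitions into per-side centroid
trajectories and computes, per matched opening/closing phase, four
bilateral symmetry parameters:

* **L** — *latency*: |t₀ᴿ − t₀ᴸ| / T̄, the normalized offset between the
  sides' motion onsets, where onset t₀ is the first instant the speed
  reaches 10 % of the phase's peak speed and T̄ is the mean phase duration;
* **VPD** — *velocity peak delay*: |argmaxₜ|vᴿ| − argmaxₜ|vᴸ|| / T̄;
* **MDA** — *maximal difference of amplitudes* (mm):
  |ptp(dᴿ) − ptp(dᴸ)| over the phase, per-side peak-to-peak displacement;
* **MDD** — *maximal displacement difference*:
  maxₜ |dᴿ(t) − dᴸ(t)| with each side referenced to its own phase-start
  position, reported in mm and normalized by the largest motion amplitude
  of the whole series.

Displacements d(t) are scalar projections of the condyle centroid onto
anatomical reference lines — the mid-sagittal line in axial images, the
Frankfurt horizontal line in sagittal images.  The axial and sagittal
tracks are additionally fused into 3D trajectories (AP/ML/CC axes) and
scored by an automatic binary rule (**3DTC**): asymmetric (score 1) when
the per-axis amplitude difference exceeds 1 mm on at least two axes, with
the smaller-amplitude joint flagged as lagging.  A statistics module
provides weighted Cohen's κ and Spearman's ρ with the interpretation band
tables used in this literature.

Because no public RT-MRI corpus of this kind exists, the package ships a
first-class synthetic motion phantom: raised-cosine open/close cycles
(~5 s per phase) with controllable per-side onset latency, velocity-peak
shift, amplitude difference and noise, rendered into mask and image series
with the acquisition's interleaved sagittal timing.  Every analysis stage
is validated against the phantom's analytic ground truth.

## Worked example

Simulate a subject whose left condyle starts 20 % of the phase late and
moves 3 mm less, image it at SNR 20, and run the full pipeline
(segmentation → centroids → smoothing → projection → phases → parameters
→ 3D fusion → score):

```python
from condylokin.pipeline import run_pipeline, validate_config

config = validate_config("""
subject: demo
seed: 1
snr: 20.0
simulation:
  n_cycles: 2
  amplitude_right_mm: 15.0
  amplitude_left_mm: 12.0
  lagging_side: left
  latency_fraction_open: 0.2
  latency_fraction_close: 0.2
""")
report = run_pipeline(config).data

truth = report["ground_truth"]
print(f"ground truth: L={truth['true_latency_norm']:.2f}  "
      f"MDA={truth['true_mda_mm']:.1f} mm  lagging={truth['lagging_side']}")
for plane, res in report["parameters"].items():
    m = res["means"]["opening"]
    print(f"{plane:9s} opening:  L={m['L']:.3f}  VPD={m['VPD']:.3f}  "
          f"MDA={m['MDA_mm']:.2f} mm  MDD={m['MDD_mm']:.2f} mm")
score = report["score_3dtc"]
print(f"3DTC score: {score['value']} (lagging side: {score['lagging']})")
```

prints

```
ground truth: L=0.20  MDA=3.0 mm  lagging=left
axial     opening:  L=0.220  VPD=0.219  MDA=3.22 mm  MDD=5.94 mm
sagittal  opening:  L=0.201  VPD=0.192  MDA=3.00 mm  MDD=5.90 mm
3DTC score: 0 (lagging side: none)
```

The injected latency (0.20) and amplitude difference (3 mm) are recovered
in both planes.  VPD also reads ≈0.2 because delaying a whole phase delays
its velocity peak by the same amount.  The 3DTC score stays 0: the phantom
moves along a single (anteroposterior) axis, so only one of the three axes
shows an amplitude difference, and the rule requires at least two.

The same pipeline is available from the shell:

```bash
condylokin run --config run.yaml --out-dir out/
condylokin simulate --config sim.yaml --out-dir sim/
condylokin track --masks sim/masks_axial.tif --plane axial --out-dir tracks/
condylokin params --tracks tracks/ --out params.csv
condylokin agree --scores scores.csv --rater-a JL1 --rater-b RG --out agree.json
```

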