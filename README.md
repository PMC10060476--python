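# datspect

Automatic semi-quantitative analysis of dopamine-transporter SPECT
(^123^I-FP-CIT), for researchers who study how methodological choices in
the analysis chain — in particular the registration target — affect the
power of the putamen specific binding ratio (SBR) to separate normal from
Parkinson-typical reduced scans.

DAT-SPECT supports the workup of clinically uncertain parkinsonian
syndromes: nigrostriatal degeneration reduces tracer binding in the
putamen. Automatic SBR pipelines map each scan into a standard anatomical
space by matching a template image (affine "stereotactical
normalization"), scale it to distribution-volume-ratio units
(DVR = intensity / 75th percentile of a non-striatal reference region,
SBR = DVR − 1), and read out the putamen either by averaging the hottest
voxels (10 ml) inside an oversized mask or by a tight anatomical ROI.
Using a single normal-uptake template biases the normalization of reduced
scans (their striata get stretched to resemble the template's); this
package implements the alternative in which the optimizer matches the best
**linear combination of eight templates** — normal, moderate deficit
right/left, strong reduction, each with and without scalp signal — and the
cohort-level machinery to quantify what that buys.

At cohort level, the histogram of the minimum putamen SBR (bin width 0.1)
is fitted by a sum of two Gaussians,

    hist(SBR) = A₁ exp(−(SBR − M₁)²/2SD₁²) + A₂ exp(−(SBR − M₂)²/2SD₂²),

and the discriminative power and operating cutoff follow as

    d = (M₂ − M₁) / sqrt((SD₁² + SD₂²)/2),
    c = (SD₂ M₁ + SD₁ M₂) / (SD₁ + SD₂).

Binary classifications (SBR < c ⇒ reduced) from two pipeline variants are
compared by 2×2 cross-tables and Cohen's kappa; stability of d is measured
over random 90% subsamples; the amount of affine stretching is tracked by
DET, the determinant of the transform's linear part.

Because clinical scans cannot ship with the code, the package includes a
first-class digital phantom (`datspect.phantom`): ellipsoidal head anatomy
with bilateral caudate/putamen compartments, optional scalp shell,
point-spread blurring, noise, arbitrary intensity scale, and a known
random affine misalignment — so every stage can be tested against ground
truth. See `docs/methods.md` for the models and all defaults.

## Worked example

```python
import numpy as np
import datspect as ds

spec = ds.PhantomSpec()                      # 2 mm template grid, default anatomy
masks, _ = ds.make_anatomy(spec)             # head/reference/putamen masks
templates, labels = ds.painted_template_set(spec)

rng = np.random.default_rng(0)
truth = ds.sample_subject(ds.CohortMixture(), rng, spec)
scan, _ = ds.simulate_scan(spec, truth, scalp_on=True, rng=rng)

records, norm = ds.quantify_scan(scan, list(templates), masks,
                                 template_mode="multiple", scan_id="demo")
hv = next(r for r in records if r.roi_method == "HV")
print(f"true min SBR       : {truth.sbr_min:.3f}")
print(f"HV SBR min         : {hv.sbr_min:.3f}")
print(f"DET (true / found) : {truth.true_affine.det:.3f} / {norm.transform.det:.3f}")

vals = np.where(rng.random(1702) < 0.45,
                rng.normal(0.58, 0.15, 1702), rng.normal(1.57, 0.32, 1702))
fit = ds.fit_sbr_values(vals)
print(f"effect size d      : {fit.d:.2f}")
print(f"cutoff c           : {fit.c:.3f}")
```

prints

```
true min SBR       : 1.528
HV SBR min         : 1.224
DET (true / found) : 1.041 / 1.042
effect size d      : 3.95
cutoff c           : 0.943
```

The subject is a normal (misaligned, scalp-on) phantom: the recovered DET
matches the simulated stretch to 0.001, and the hottest-voxels SBR sits
~20% below the painted truth — the expected partial-volume under-reading
of a 10 ml average over a blurred structure. The cohort block draws 1702
SBR values from a two-component mixture (reduced fraction 0.45) and
refits them: d ≈ 3.95 means the component means sit almost four pooled
standard deviations apart, and scans below c ≈ 0.94 would be called
reduced.

A `datspect` console script wraps the stages for shell use
(`simulate`, `build-templates`, `normalize`, `quantify`, `cohort-stats`,
`run-experiment`); `datspect run-experiment --config cfg.yaml` runs
simulate → quantify (both template modes) → cohort statistics and writes
a manifest, per-scan results CSV and summary JSON, each stamped with the
config hash and seed.

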