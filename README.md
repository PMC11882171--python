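# t1rr — VFA T1 relaxometry and T1 reduction-rate mapping

`t1rr` measures how strongly the liver takes up a hepatocyte-specific
gadolinium contrast agent (Gd-EOB-DTPA), a proxy for biliary function, by
quantitative T1 relaxometry on a 1.5 T scanner. It is written for MR
physicists and imaging scientists who have dual-flip-angle FLASH/SPGR
acquisitions (two flip angles before contrast, two in the hepatobiliary
phase ~20 min after injection) and want pixel-wise T1 maps and the
**T1 reduction rate**

```
RR% = 100 · (T1_pre − T1_post) / T1_pre
```

rather than absolute T1. The ratio form is the point: flip-angle
miscalibration from transmit-field (B1) inhomogeneity biases each T1
estimate by up to tens of percent, but because the bias is shared by the
pre- and post-contrast measurements it cancels in RR to first order.

## Model

The steady-state spoiled-gradient-echo signal at repetition time TR and
flip angle α for tissue with relaxation time T1 and equilibrium
magnetization M0 is

```
SI(α) = M0 · sin α · (1 − E1) / (1 − cos α · E1),     E1 = exp(−TR/T1).
```

With two acquisitions at distinct flip angles α₁, α₂ (fixed TR), plotting
y = SI/sin α against x = SI/tan α linearizes the equation (DESPOT1); the
slope of the line through the two points is E1, giving the closed-form
per-pixel inversion

```
T1 = −TR / ln(slope),     M0 = (y − slope · x) / (1 − slope).
```

Pixels with a slope outside (0, 1) or T1 outside 1–5000 ms (air, noise,
inflow) are masked invalid. The default protocol is TR = 5 ms with flip
angles 5°/15° pre-contrast and 5°/20° post-contrast, matched to liver T1
before (~500–900 ms) and after (~200–400 ms) contrast; `optimal_fa_pair`
computes the angle pair whose signals both equal 71 % of the Ernst-angle
signal, the precision-optimal choice for a target T1.

The package contains:

- `t1rr.signal_model` — SPGR forward model, dual-angle inversion, Ernst
  angle and flip-angle optimization;
- `t1rr.mapping` — smoothing (Gaussian or boxcar, 4×4 default), T1-map and
  RR-map computation, DICOM/PNG export;
- `t1rr.phantom` — a digital cylindrical QA phantom (12 tube slots with
  certified T1, 20 mm tubes, 208×256 matrix at 1.5×1.5 mm) and an
  abdomen-like fixture, with Rician noise and an optional radial B1 error
  field;
- `t1rr.roi` — circular/free-hand ROI statistics, expected-vs-measured RR
  errors, repeatability reports, reference-tube stability QA;
- `t1rr.cli` — the `t1rr` command (`simulate`, `fit-t1`, `rr-map`,
  `roi-stats`, `report`).

## Worked example

Simulate the RR validation protocol — four certified tube pairs
(657/325, 1264/487, 657/328, 813/500 ms), each in two slots of the
phantom — with an 8 % radial flip-angle error field, run the pipeline,
and measure 10 mm ROIs on every tube:

```python
from t1rr import (make_rr_validation_phantom, render_pair, compute_t1_map,
                  compute_rr_map, phantom_validation_report, RadialB1Field)

pre_spec, post_spec = make_rr_validation_phantom(b1_field=RadialB1Field(0.08))
pre = render_pair(pre_spec, (5, 15), tr=5.0)
post = render_pair(post_spec, (5, 20), tr=5.0)
t1_pre = compute_t1_map(*pre, phase_label="pre")
t1_post = compute_t1_map(*post, phase_label="post")
rr = compute_rr_map(t1_pre, t1_post)
report = phantom_validation_report(t1_pre, t1_post, rr, pre_spec, post_spec)
print(report[["slot", "t1_a", "t1_b", "t1_pre_measured",
              "expected_rr", "measured_rr", "delta_int"]].round(2).to_string(index=False))
```

```
 slot   t1_a  t1_b  t1_pre_measured  expected_rr  measured_rr  delta_int
    1  657.0 325.0           708.93        50.53        50.52          0
    2 1264.0 487.0          1365.71        61.47        61.47          0
    4  657.0 328.0           711.50        50.08        50.06          0
    6  813.0 500.0           881.01        38.50        38.48          0
    7  813.0 500.0           880.51        38.50        38.48          0
    9  657.0 328.0           709.68        50.08        50.06          0
   11 1264.0 487.0          1363.23        61.47        61.47          0
   12  657.0 325.0           708.39        50.53        50.52          0
```

The B1 error inflates every measured T1 (e.g. 709 ms against a certified
657 ms in slot 1, an ~8 % bias), yet the reduction rate is recovered to
within 0.02 percentage points — the first-order cancellation the RR
metric is designed for. The same run from the shell:

```sh
t1rr simulate --out sim --seed 1 --b1
t1rr rr-map --pre-dir sim/pre --post-dir sim/post --out maps \
    --pre-spec sim/pre_spec.yaml --post-spec sim/post_spec.yaml
t1rr report --builtin     # repeatability summary of the bench validation table
```

`t1rr report --builtin` summarizes the bundled bench validation table
(four certified pairs, two slots each, three time points) and prints its
headline figures: `max |delta| = 9 %` and `max within-row range = 3 %` —
the worst-case RR percentage error and the worst spread of that error
across repeated sessions.

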