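# ecdquant

Quantitative regional cerebral blood flow (rCBF) from 99mTc-ECD studies,
for nuclear-medicine physicists and imaging researchers who need to run —
or compare — the two non-invasive quantification schemes used clinically:

* the automatic **brain uptake ratio** method (IBUR): the arterial input
  ROI is detected at the maximum-count pixel of the dynamic chest
  angiogram (the ascending aorta), the aortic peak is separated from the
  pulmonary peak and fitted with a gamma variate
  C(t) = K (t−t0)^α e^{−(t−t0)/β}, and Lassen-linearized regional SPECT
  counts divided by the integrated input give the uptake ratio, converted
  to flow by

      rCBF (ml/100g/min) = 3.23 · BUR + 4.66

* the **Patlak-plot** method (PP): manually placed aortic-arch and
  hemispheric ROIs give input and tissue curves; the slope Ku of
  Cb(t)/Ca(t) versus (∫₀ᵗ Ca dτ)/Ca(t), normalized as the brain perfusion
  index (BPI), is converted by

      mCBF (ml/100g/min) = 2.60 · BPI + 19.8

  and distributed regionally over Lassen-corrected SPECT counts anchored
  at the basal ganglia.

The package also ships a ground-truth **synthetic acquisition simulator**
(dynamic planar series, SPECT volume, 24-segment label template, all with
Poisson noise options) and the **paired comparison statistics** used to
contrast the two methods (regression, Pearson r, paired t / Wilcoxon,
box-plot summary tables with PP/IBUR ratios). See `docs/methods.md` for
the models and all conventions.

## Worked example

```python
from ecdquant import make_ground_truth, simulate_subject
from ecdquant.pipeline import analyze_ibur, analyze_pp

truth = make_ground_truth(true_mcbf=35.0, seed=1)
bundle = simulate_subject(truth, noise="poisson", seed=1)

ib = analyze_ibur(bundle.series, bundle.spect, bundle.template, bundle.config)
pp = analyze_pp(bundle.series, bundle.spect, bundle.template, bundle.config)

print(f"true mCBF (IBUR scale): {bundle.truth.true_mcbf:.1f} ml/100g/min")
print(f"IBUR mCBF estimate:     {ib.regional.mcbf:.1f} ml/100g/min")
print(f"input counts:           {ib.input_counts:.0f} counts*s")
print(f"PP   mCBF estimate:     {pp.regional.mcbf:.1f} ml/100g/min "
      f"(Ku = {pp.ku:.4f} 1/s, BPI = {pp.bpi:.2f})")
```

prints

```
true mCBF (IBUR scale): 35.0 ml/100g/min
IBUR mCBF estimate:     34.4 ml/100g/min
input counts:           8172 counts*s
PP   mCBF estimate:     41.4 ml/100g/min (Ku = 0.0831 1/s, BPI = 8.31)
```

The IBUR estimate recovers the simulated truth to within the Poisson
counting noise (~2% here; exact in the noiseless limit). The PP estimate
is *higher by design*: the two methods sit on different calibration scales
— the Patlak line cannot report below its 19.8 ml/100g/min intercept,
while the uptake-ratio line reaches down to 4.66 — and the simulator
encodes the empirically observed offset between them, so cohort-level
comparisons reproduce the clinical pattern (PP higher and narrower at low
flow) rather than artificial agreement.

A command-line interface mirrors the library:

```sh
ecdquant simulate --n 15 --seed 7 --out cohort/
ecdquant ibur   --series dyn.nii.gz --spect spect.nii.gz \
                --template tpl.nii.gz --config config.yaml --out ibur.csv
ecdquant patlak --series dyn.nii.gz --spect spect.nii.gz \
                --template tpl.nii.gz --config config.yaml --out pp.csv
ecdquant compare --pp pp.csv --ibur ibur.csv --level rcbf --out table.csv
```

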