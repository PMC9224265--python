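# fetpet

Dynamic **¹⁸F-FET PET** biomarker extraction and IDH-stratified diagnostics
for recurrent glioma.

After radiochemotherapy, contrast-enhancing lesions on MRI can be either
**true progression (TP)** or **treatment-related changes (TRC)** such as
radionecrosis and pseudoprogression. Amino-acid PET with
O-(2-[¹⁸F]fluoroethyl)-L-tyrosine (FET) helps separate the two, and the
discriminative value of its biomarkers depends on the tumour's IDH mutation
status. `fetpet` is a tested, end-to-end implementation of this analysis for
physicists and imaging scientists: it extracts the standard static and
dynamic FET biomarkers from 4-D SUV images and evaluates them on patient
cohorts with a non-parametric statistics layer, with a phantom simulator so
every stage is testable without patient data.

## What it computes

**Static biomarkers** (from the 20–40-min summed SUV image):

- SUV<sub>max</sub>: hottest voxel of the lesion;
- SUV<sub>mean,bg</sub>: mean SUV of a crescent-shaped VOI over the
  contralateral, unaffected hemisphere;
- tumour auto-contour: the 26-connected voxel component, seeded at the
  SUV<sub>max</sub> voxel, of `{SUV ≥ 1.6 × SUVmean_bg}`;
- TBR<sub>max</sub> = SUV<sub>max</sub> / SUV<sub>mean,bg</sub> and
  TBR<sub>mean</sub> = SUV<sub>mean,tumor</sub> / SUV<sub>mean,bg</sub>.

**Dynamic biomarkers** (from the 35-frame, 40-min time-activity curve in a
10-mm sphere at the uptake maximum):

- **TTP** (time-to-peak, min), set to the acquisition end for curves without
  an identifiable peak;
- **TAC shape score** ∈ {−1, 0, 1}: early peak (< 22.5 min) with ≥ 5%
  descent → −1; early peak with plateau/smaller descent → 0; continuously
  rising or late-peaking curve → 1.

**Cohort statistics**: empirical ROC with Mann-Whitney AUC and DeLong
variance, DeLong curve comparison, Youden-optimal cut-points with stratified
bootstrap CIs, Wilson score intervals for sensitivity/specificity/accuracy,
Mann-Whitney U tests, χ²/Fisher proportion tests, and a logistic-regression
combiner of TAC score, IDH status and TBR<sub>mean</sub> — all reported
overall and per IDH stratum (IDHm / IDHwt).

## Worked example

Simulate one phantom whose lesion follows descending (early-peak) kinetics
and run the full image pipeline on it:

```sh
fetpet simulate --tac-class descending --grid 48 --out-dir demo_ws
fetpet extract demo_ws/phantom_descending.nii.gz \
               demo_ws/phantom_descending_frames.json
```

which prints (configuration block elided):

```json
{
  "background_hemisphere": "left",
  "patient_id": "phantom_descending",
  "peak_suv": 1.83905342478811,
  "suv_max": 2.4561856389045715,
  "suv_mean_bg": 1.0,
  "suv_mean_tumor": 2.4561856389045715,
  "tac_score": -1,
  "tbr_max": 2.4561856389045715,
  "tbr_mean": 2.4561856389045715,
  "terminal_descent": 0.16519370404630954,
  "ttp_min": 7.5,
  "tumor_volume_ml": 4.416
}
```

The lesion peaks at 7.5 min (the generative kinetics have a closed-form
peak at 7.9 min, inside that 60-s frame) and loses 17% of its peak activity
by the end of the acquisition, so the curve is classed −1 (descending). The
background crescent was placed in the left hemisphere — contralateral to
the lesion — and its mean SUV is exactly the simulated background of 1.0,
so TBRs equal lesion SUVs; the washed-out late-window lesion uptake is 2.46.
The auto-contour recovers the full 4.4-mL lesion.

`fetpet analyze cohort.csv --out-dir report` runs the cohort statistics on
a biomarker table (`patient_id,idh,outcome,sex,tbr_max,tbr_mean,ttp_min,
tac_score`), and `fetpet demo --out-dir demo` produces phantoms for all
three curve classes, a synthetic cohort, and both reports in one command.

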