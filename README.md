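# mpmri

Multiparametric MRI quantification of solid-tumor therapy response, built for
preclinical studies of vascular-targeted treatment (a vascular-disrupting
agent, an antiangiogenic, and their combination) in implanted liver tumors.
The package turns 4D NIfTI series into the imaging biomarkers such studies
report, runs the group statistics on the resulting cohort tables, and ships a
digital phantom and longitudinal cohort generator with known ground truth so
that every stage is testable end to end without any animal data.

## What it computes

**Diffusion (DWI).** Per-voxel apparent diffusion coefficient from the
mono-exponential model over all acquired b-values,

    S(b) = S0 · exp(−b · ADC),

fitted by damped Gauss–Newton least squares initialized from the weighted
log-linear solution (the log-linear estimate is biased under Rician magnitude
noise at high b). Whole-tumor ADC is normalized to same-examination healthy
liver to give the relative ADC, rADC = ADC_tumor / ADC_liver, and the
longitudinal endpoint is the percent change 100·(post − pre)/pre.

**Permeability (DCE-MRI).** Signal is converted to relative enhancement
C_rel(t) = (S(t) − S̄_base)/S̄_base, the arterial input function is taken from
the aorta ROI (measured curve or biexponential model fit), and the
two-parameter Tofts model

    C_t(t) = Ktrans ∫₀ᵗ C_p(τ) · exp(−Ktrans·(t − τ)/v_e) dτ

is fitted by bounded nonlinear least squares for the transfer constant
Ktrans (min⁻¹) and the extravascular extracellular fraction v_e.

**Perfusion (DSC-MRI).** The susceptibility signal drop converts to
ΔR2\*(t) = −ln(S(t)/S̄_base)/TE ∝ concentration. Relative blood volume is the
tracer-dilution integral ratio rBV = ∫C_tissue / ∫C_aif; relative blood flow
is the peak of the flow-scaled residue function F·R(t) recovered by
truncated-SVD deconvolution (threshold 0.2 × largest singular value), and
MTT = rBV/rBF by the central volume theorem.

**Morphometry.** Tumor volume (voxel count × in-plane area × slice extent,
with the slice extent = thickness + gap), its percent change, the relative
viable rim (100 × maximal in-plane rim thickness / maximal tumor diameter)
and the relative necrosis volume (100 × core/tumor volume).

**Statistics.** Per-timepoint Kruskal–Wallis comparisons of the percent-change
endpoints across the four arms with Bonferroni-corrected pairwise rank-sum
post-hoc tests, and stepwise (forward/backward, 0.05/0.10) multiple linear
regression selecting independent predictors of tumor volume change from the
imaging changes.

**Phantom.** `mpmri.phantom` digitizes an ellipsoidal tumor (viable rim around
a necrotic core) in a liver block with an aortic cylinder, simulates all three
acquisitions under the study protocol (10 b-values 0–1000 s/mm²; 80 DCE
frames of 3.7 s and 80 DSC frames of 2 s with the bolus after frame 20; TE
46 ms; 2 mm slices + 0.2 mm gap) with Rician noise, and generates 4-arm ×
5-timepoint cohorts (pre, 4 h, 2 d, 6 d, 12 d) whose effect trajectories
encode the signed treatment dynamics of this tumor model.

## Worked example

```python
from mpmri.io import AcquisitionMeta
from mpmri.phantom import default_geometry, default_truth, \
    simulate_dwi, simulate_dce, simulate_dsc
from mpmri.adc import adc_map, region_adc, radc
from mpmri.dce import to_relative_concentration, extract_aif, fit_tofts
from mpmri.dsc import to_delta_r2star, deconvolve_tsvd
from mpmri.morphometry import morphometry_record

meta = AcquisitionMeta()                       # the study protocol defaults
masks, counts = default_geometry((48, 48, 12), meta)
truth = default_truth(masks, noise_sigma=10.0, seed=1)   # image SNR 100

dwi = simulate_dwi(masks, truth, meta)
amap = adc_map(dwi, mask=masks.region_mask("tumor") | masks.region_mask("liver"))
tumor_adc = region_adc(amap, masks, "tumor")
liver_adc = region_adc(amap, masks, "liver")

dce = simulate_dce(masks, truth, meta)
nb = meta.baseline_frames
tissue = to_relative_concentration(
    dce.data[masks.region_mask("viable_rim")].mean(axis=0), nb, meta.dce_frame_duration)
aif = extract_aif(to_relative_concentration(
    dce.data[masks.region_mask("aorta")].mean(axis=0), nb, meta.dce_frame_duration))
tofts = fit_tofts(tissue, aif)

dsc = simulate_dsc(masks, truth, meta)
t_r2 = to_delta_r2star(dsc.data[masks.region_mask("viable_rim")].mean(axis=0),
                       nb, meta.echo_time, meta.dsc_frame_duration)
a_r2 = to_delta_r2star(dsc.data[masks.region_mask("aorta")].mean(axis=0),
                       nb, meta.echo_time, meta.dsc_frame_duration)
perf = deconvolve_tsvd(t_r2, a_r2, threshold=0.2)
morpho = morphometry_record(masks, meta)
```

Output (the phantom's ground truth in parentheses):

```
tumor ADC  = 1.446e-03 mm^2/s   (truth rim 0.9e-3 / core 2.2e-3)
liver ADC  = 1.100e-03 mm^2/s   (truth 1.1e-3)
rADC       = 1.315
Ktrans     = 0.250 /min          (truth 0.25)
ve         = 0.350               (truth 0.35)
rBV        = 6.07 a.u.           (truth F*MTT = 6.0)
rBF        = 1.51 a.u.           (truth F = 1.5)
MTT        = 4.01 s              (truth 4.0)
tumor vol  = 2137 mm^3
rim %      = 13.7
necrosis % = 42.1
```

The tumor ADC is the count-weighted mean of the low-diffusivity viable rim
and the high-diffusivity necrotic core; Ktrans/v_e and rBV/rBF/MTT recover the
rim's truth values to within a fraction of a percent at this noise level; the
rim percent reflects the 2 mm rim against the 16 mm tumor diameter and the
necrosis percent the (6/8)³ volume ratio of the concentric ellipsoids.

## Command line

```bash
mpmri run --config study.yaml --out runs/exp1    # full reproducible study run
mpmri simulate --out sim/ --seed 7               # one phantom subject
mpmri fit-adc --dwi sim/dwi.nii.gz --sidecar sim/meta.json --out adc.nii.gz
mpmri fit-dce --dce sim/dce.nii.gz --sidecar sim/meta.json --masks sim/masks.nii.gz --out dce.json
mpmri fit-dsc --dsc sim/dsc.nii.gz --sidecar sim/meta.json --masks sim/masks.nii.gz --out dsc.json
mpmri morphometry --masks sim/masks.nii.gz --sidecar sim/meta.json --out morpho.json
mpmri analyze --records runs/exp1/records.csv --out runs/exp1/stats
```

`mpmri run` writes the cohort `records.csv`, the noise-free `truth.csv`, the
statistics tables (`omnibus.csv`, `posthoc.csv`, `stepwise.json`), simulated
series plus fitted maps for the imaged subject subset, and a provenance
`manifest.json` with per-file checksums; rerunning the same config reproduces
every output bit-identically.

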