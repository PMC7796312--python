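# colorfaf

Quantitative analysis of **color fundus autofluorescence** (color-FAF):
blue-light (450 nm excitation) fundus autofluorescence recorded with a
color sensor, so that every pixel splits into a green emission
fluorescence component (GEFC, 500–560 nm — minor fluorophores such as
advanced glycation end products, FAD and collagen) and a red component
(REFC, 560–700 nm — dominated by lipofuscin). The package is aimed at
retinal-imaging researchers studying diabetic retinopathy (DR) and
diabetic macular edema (DME), where foveal GEFC/REFC intensity behaves
as a candidate inflammation/metabolism biomarker.

It provides, as a library plus a `colorfaf` command line:

- **spectral decomposition** — per-pixel GEFC, REFC, intensity
  `(R + G)/2`, green fraction `f = G/(G + R)` and estimated emission
  wavelength `λ(f) = 630 · (530/630)^f` nm, with the *segment graph*
  (λ vs intensity) and *RG graph* (REFC vs GEFC) point sets;
- **ETDRS grid measurement** — the nine sectors of the standard
  1/3/6-mm macular grid in pixel space, and per-sector measurement at
  the largest clean disc inscribed in the sector under a vessel/lesion
  exclusion mask (a deterministic, auditable version of the grader's
  "carefully selected" site);
- **cohort statistics** — pooled/Welch unpaired t-tests (raw or from
  printed mean/SD/n summaries), one-way ANOVA with least-squares means
  and Scheffé pairwise tests, Pearson correlation, and sector-wise
  DME/IRF comparison tables;
- **synthetic data** — fundus-like images with ground-truth sector
  fields, vessels, lesions and exclusion masks, and cohorts with the
  published group structure (18 controls + 193 diabetic eyes, 41 with
  DME), published sector intensity marginals, and a calibrated
  intensity–thickness Gaussian-copula coupling.

## Worked example

Re-derive the headline foveal group comparisons from printed summary
statistics, then measure a synthetic cohort:

```python
from colorfaf import GroupSummary, ttest_from_summary
from colorfaf import CohortSimConfig, generate_cohort, compare_groups_table, pearson

# DM without edema (n=152) vs healthy controls (n=18), printed mean/SD
for name, dm, ctrl in [("GEFC", (17.4, 14.1, 152), (9.1, 6.1, 18)),
                       ("REFC", (18.5, 12.6, 152), (10.0, 6.6, 18))]:
    res = ttest_from_summary(GroupSummary(*dm), GroupSummary(*ctrl), "pooled")
    print(f"foveal {name}: t = {res.t:.3f}, df = {res.df:.0f}, p = {res.p:.3f}")

cohort = generate_cohort(CohortSimConfig(), seed=42)   # 211 eyes
fovea = compare_groups_table(cohort, grouping="dme").query("sector == 'fovea'")
print(fovea[["component", "mean0", "mean1", "p"]].to_string(index=False))
dia = cohort[cohort.group != "control"]
print("r(GEFC, CRT) =", round(pearson(dia.gefc_fovea, dia.thickness_fovea).r, 3))
```

prints

```
foveal GEFC: t = 2.465, df = 168, p = 0.015
foveal REFC: t = 2.812, df = 168, p = 0.006
component     mean0     mean1            p
     GEFC 16.508786 43.387418 4.546401e-19
     REFC 18.614162 43.730106 1.977709e-18
r(GEFC, CRT) = 0.357
```

The two t-tests recover the published DM-vs-control p-values from the
printed summaries alone. In the synthetic cohort, eyes with
center-involving DME show the expected foveal GEFC/REFC elevation
(≈ 43 vs ≈ 17–19 counts, p ≪ 0.001), and foveal intensity correlates
positively with central retinal thickness (r = 0.36 in this 193-eye
draw; the configured population value is 0.37, and single-cohort
estimates scatter around it with SD ≈ 0.07).

The same steps are packaged as numbered drivers under `analysis/`
(`01_image_pipeline.py` … `04_correlation_recovery.py`), which write
small tables to `results/`. The command line mirrors them, e.g.

```bash
colorfaf simulate --kind cohort --seed 5 --out out/
colorfaf cohort-stats --cohort out/cohort.csv --grouping dme --out stats.csv
colorfaf reproduce --seed 1
```

## Documentation

The model, the calibration of the copula coupling, numerical choices
and known limitations are described in [`docs/methods.md`](docs/methods.md).
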