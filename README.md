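# stainslice

Grey-level intensity slicing and computational morphology of pan
cytokeratin immunohistochemistry (IHC) images, with ROC-based prognostic
evaluation against a binary distant-metastasis endpoint.

Pan cytokeratin (AE1/AE3) stains the keratin filaments of epithelial
cells, so in a breast-tumour section it highlights the malignant
epithelial *tumour nests* against the stroma.  In an 8-bit greyscale
digitisation (0 = black = maximal stain, 255 = white = no stain) the
staining intensity spectrum carries information beyond the stained area
itself: how much of the section sits in each intensity band, and how
heterogeneous and complex the pattern of each band is.  `stainslice` is
for image-analysis and biostatistics researchers who want to take such a
section apart intensity-band by intensity-band:

1. **Slice** the 0–255 spectrum into seven discrete narrow ranges
   (0–130, 130–160, 160–180, 180–200, 200–220, 220–240, 240–255), plus
   the specific/non-specific split at the 220 grey level, by whitening
   all out-of-range pixels.
2. **Profile** each slice (and the original) by 33 features: five GLCM
   texture features (ASM, contrast, correlation, IDM, entropy), 23
   monofractal features (differential box-counting dimension D_B, mass
   dimension D_M, "optimal cover" D_X, lacunarity Λ — each with across-grid
   dispersion, extrema and regression diagnostics over 12 repositioned
   grids), and five threshold-limited first-order statistics (area,
   skewness, kurtosis, IntDen, RawIntDen).
3. **Evaluate** per-patient averaged features prognostically: Mann–Whitney
   AUC with DeLong CI and p vs 0.5, AUC folding (max(a, 1−a)), bootstrap
   optimism correction (1000 resamples), chi-square-maximising optimal
   cutoffs, Spearman redundancy screens, stepwise multivariate logistic
   regression (entry/remain p ≤ 0.05), and Hanley–McNeil ROC sample-size
   design.

Because patient image sets of this kind are rarely shareable, the package
includes a calibrated synthetic generator: tumour-nest images whose
seven-range pixel shares reproduce a reported 6/9/10/8/8/29/30 %
composition, and simulated cohorts whose outcome is linked to a latent
image property (nest area fraction) with an analytically chosen AUC, so
the whole pipeline can be exercised and verified end to end.

See `docs/methods.md` for conventions (macro boundary semantics,
box-counting safeguards, moment and variance conventions) and limitations.

## Worked example

```python
import stainslice as ss

# a synthetic pan cytokeratin-like section, 256x256
img = ss.generate_image(ss.NestImageSpec(seed=0))

shares = ss.range_share(img)          # fraction of pixels kept per range
for label, share in shares.items():
    print(f"{label:>8}: {100 * share:5.2f} %")

design = ss.roc_sample_size(auc_alt=0.67, alpha=0.05, power=0.80)
print(design.n_pos, design.n_neg, design.n_total)
```

prints

```
   0-130:  6.50 %
 130-160:  9.43 %
 160-180: 11.00 %
 180-200:  8.66 %
 200-220:  8.57 %
 220-240: 27.45 %
 240-255: 27.68 %
40 40 80
```

The shares sit within ±3 percentage points of the 6/9/10/8/8/29/30 %
calibration target (about 41 % of the frame is covered by nests — the
specific 0–220 staining; the remainder is stroma).  The sample-size line
is the prospective design for detecting a prognostic AUC of 0.67 against
chance at two-sided α = 0.05 and power 0.80: 80 patients, which at a 20 %
metastasis prevalence corresponds to 16 expected positive cases.

The `analysis/` scripts run the full study-shaped workflow
(`01_simulate_cohort.py` → `05_sample_size.py`): simulate 102 patients
(20 metastasis-positive, 5 images each), slice and profile, extract
5100 feature rows, and evaluate.  On the simulated cohort the
specific-staining area recovers its designed folded AUC of 0.8 within
sampling error, the per-range summary tables report mean folded AUCs and
significant-improvement sums, and the stepwise model retains the
effect-bearing feature.  A command-line interface wraps the same library:

```bash
stainslice simulate --patients 20 --out cohort/
stainslice run --manifest cohort/manifest.csv --outdir results/
stainslice slice section.png --outdir slices/   # per-range PNG + mask + overlay
```

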