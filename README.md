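# ftirstress

Chemical fingerprinting of plant heat stress from mid-infrared absorbance
spectra. The package implements, as a tested and reusable pipeline, the
chemometric workflow used to discriminate heat-stressed wheat leaves from
controls by FTIR spectroscopy:

1. **Preprocessing** — each spectrum (400–4000 cm⁻¹, 1 cm⁻¹ grid, 3601
   points) is baseline-corrected by subtracting the straight line through
   its absorbance values at 400 and 4000 cm⁻¹, then total-sum normalized so
   its values sum to 10⁶.
2. **PCA** — centered principal component analysis of the normalized
   spectra (scores, loadings, explained variance).
3. **PCA-LDA** — a class-stratified 60:40 train/test split, then a Fisher
   linear discriminant fitted in a rank-reduced PCA subspace of the
   training spectra (400–3600 cm⁻¹ feature range) and back-projected to
   wavenumber space as an LD1 loading curve. Heat-stressed spectra score
   positive on LD1.
4. **Fm biomarkers** — discriminative wavenumbers are the extrema of the
   LD1 loading curve with |loading| > 0.15. For each target ν, two anchor
   wavenumbers are scanned among spectral landmarks (peaks, minima,
   inflection points) within 150 cm⁻¹ on opposite sides of ν, and the
   anchor-normalized marker

   Fm = (A_target − A_anchor1) / (A_anchor2 − A_anchor1)

   is kept when the two-sided Student's *t*-test between classes gives
   *p* < 10⁻⁴. Fm maps anchor1 to 0 and anchor2 to 1 and is invariant under
   any affine transform of the spectrum — a locally normalized absorbance
   read-out. Markers are evaluated by per-class medians, the heat/control
   median ratio, and the *t*-test, and spectra are diagnosed by majority
   vote across markers.

Because no measured spectra are publicly deposited for the original study,
the package ships a synthetic spectrum generator that emulates the study's
measurement design — 2 classes × 6 plants × 10 KBr-pellet disks × 3 repeat
scans, with one heat-class disk scanned once (180 control + 178 heat
spectra) — including Gaussian absorption bands at the major leaf-band
positions, a broad 2700–3700 cm⁻¹ envelope, implanted class effects at
marker wavenumbers, hierarchical plant/disk/repeat noise, baseline drift,
a detector noise floor, and low-wavenumber "knurl" noise at 405–480 cm⁻¹.
A relative-water-content utility (RWC = 100·(Fw − Dw)/(Tw − Dw)) rounds
out the toolkit.

Intended users: plant physiologists and spectroscopists who want a
reproducible, scriptable version of this workflow for their own FTIR
fingerprinting data, and methodologists studying anchor-normalized
spectral biomarkers on controlled synthetic data.

## Worked example

```python
import ftirstress as ft

# simulate the study design with the default implanted effects
# (1465 up x1.30, 1729 up x1.22, 1251 down x0.75)
raw = ft.simulate_set(ft.study_design(seed=1))
pre = ft.preprocess_set(raw)          # baseline + total-sum normalize
print(pre.class_counts)               # {'control': 180, 'heat': 178}

split = ft.split_set(pre, ratio=0.6, seed=2)
lda = ft.lda_fit(pre, split)          # PCA rank 40, 400-3600 cm^-1
test = pre.select_ids(split.test_ids)
print(ft.accuracy(ft.lda_score(lda, test)))   # 1.0

result = ft.discover_markers(pre, lda)
print(result.table()[["name", "target", "anchor1", "anchor2",
                      "loading", "ratio", "p"]])
```

which prints (seed 1):

```
{'control': 180, 'heat': 178}
1.0
     name  target  anchor1  anchor2   loading     ratio              p
0  Fm1251  1251.0   1311.0   1241.0 -0.225371  0.912978   2.340074e-91
1  Fm1729  1729.0   1797.0   1673.0  0.201359  1.228988   7.498668e-77
2  Fm1465  1465.0   1327.0   1502.0  0.182756  1.312906  1.070514e-107
```

All three implanted effects are recovered at their exact wavenumbers with
the correct direction: the down-marker Fm1251 has a heat/control median
ratio below 1, the up-markers Fm1729 and Fm1465 above 1, and every scan
*p*-value is far below the 10⁻⁴ admission threshold.

The same workflow is available from the shell:

```sh
ftirstress simulate --seed 1 --out spectra.csv --truth-out truth.csv
ftirstress run --seed 1 --outdir results/
ftirstress rwc --in leaf_weights.csv --out rwc.csv
```

`run` writes every intermediate (preprocessed spectra, split, PCA tables,
LD1 loadings and scores, the marker table, per-spectrum verdicts) as CSV
plus a markdown report.

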