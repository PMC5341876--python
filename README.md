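# heterorad

Radiomic quantification of intratumoral pathologic heterogeneity in lung
adenocarcinoma CT.

Invasive lung adenocarcinoma is classified (IASLC/ATS/ERS) into five growth
patterns — lepidic, acinar, papillary, micropapillary, solid — and most
resected tumors are mixtures of several.  A tumor's mixture is summarized two
ways here: by its **pathologic heterogeneity index**, the hazard-ratio-weighted
mean of subtype proportions

```
H = Σ_s  w_s · p_s / 100,        p_s = percentage of subtype s (nearest 5%, Σ p_s = 100)
```

and by its **subtype count group** (one, two, or three-or-four mixed
subtypes).  The package asks how far quantitative image features of the
tumor's 3D CT region of interest reflect that pathologic complexity.

From each tumor ROI, on a non-contrast channel and optionally a dual-energy
iodine-map channel, it extracts a battery of **51 radiomic features**:

| family    | count | features |
|-----------|-------|----------|
| physical  | 4     | volume (cm³), density (g/mL, `(HU+1000)/1000`), mass (g), largest axial diameter (mm) |
| histogram | 7     | skewness, kurtosis (non-excess), HU at the 2.5/25/50/75/97.5th percentiles |
| regional  | 4     | histogram uniformity `Σh²` and entropy `−Σh log₂h`; gray-level and zone-size non-uniformity of the 26-connected size-zone matrix |
| local     | 36    | 12 gray-level co-occurrence statistics (energy, entropy, correlation, contrast, variance, sum mean, inertia, cluster shade/tendency, homogeneity, maximum probability, inverse variance) × voxel distances 1, 2, 3, averaged over the 13 canonical 3D directions |

The statistical layer provides Spearman/Pearson correlation with qualitative
strength bands, Lin's concordance correlation coefficient (CCC) for
inter-reader stability, one-way ANOVA with Tukey(-Kramer) HSD across the
three subtype-count groups, and a bidirectional stepwise-AIC linear model of
the heterogeneity index validated by 10-fold cross-validation.

Because no imaging cohort is distributed, a phantom generator produces
DECT-like tumors with known ground truth: ellipsoidal masks partitioned into
1–4 contiguous compartments whose volume fractions match a sampled subtype
composition, with per-subtype HU distributions ordered along the radiologic
ground-glass → solid spectrum.

## Worked example

```bash
heterorad simulate --n-tumors 89 --seed 5 --out-dir demo
heterorad extract demo/manifest.json --out-dir demo
heterorad correlate demo/features.csv demo/pathology.csv --out-dir demo
heterorad summarize demo/pathology.csv --out-dir demo
```

prints, for the simulate/extract steps,

```
wrote 89 phantoms to demo
wrote 178 rows x 51 features to demo/features.csv
wrote 102 correlation rows to demo/correlations.csv
```

(89 tumors × 2 channels = 178 feature rows; 51 features × 2 channels = 102
correlation rows).  In `demo/correlations.csv` the density row on the
non-contrast channel lands in the strong-to-very-strong band — denser
tumors carry more of the aggressive, heavily-weighted growth patterns — and
the upper HU percentiles behave likewise, while local co-occurrence entropy
tracks the *number* of mixed subtypes rather than the index itself.  The
same cohort's `cohort_summary.json` tabulates predominant-subtype and
subtype-count frequencies.

Python API in one breath:

```python
import heterorad as hr

comp = hr.validate_composition({"lepidic": 40, "solid": 60})
nc, iodine, mask, truth = hr.make_phantom(hr.PhantomSpec(composition=comp, seed=1))
features = hr.extract_features(nc, mask)       # dict of 51 values
print(truth["index"], features["density_gpml"], features["entropy_d1"])
```

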