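# endovesiq

Object-based colocalization analysis of vesicular structures in
multi-channel fluorescence micrographs, with a ground-truth simulator for
validating every stage.

## The problem

Endothelial cells adapt to the fluid shear stress of blood flow, and part
of that adaptation runs through BMP–SMAD signaling compartmentalized in
endocytic vesicles: Caveolin-1-coated structures that mature into EEA1-positive
early endosomes carrying receptor complexes (Endoglin/ALK1) and active
SMAD1. Quantifying this means counting vesicles per field of view, deciding
per vesicle whether it is "positive" for each additional marker, and
comparing those counts between flow conditions (low vs high laminar shear
stress, LSS vs HSS).

`endovesiq` implements that analysis as a reproducible pipeline:

1. **Detection** — in a designated detection channel (e.g. Caveolin-1):
   Gaussian pre-smoothing, white top-hat background subtraction (disk
   structuring element), automatic thresholding (Otsu by default, with a
   robust noise floor), connected-component labeling, and particle
   filtering by area and circularity (4πA/P²).
2. **Classification** — the detected vesicles become a mask; for each
   secondary marker *m*, a vesicle *v* is called *m*-positive when

   ```
   mean_m(v)  ≥  (1 + f) · mean_m(image),      f = 0.15 by default
   ```

   i.e. its mean intensity in the marker channel is at least 15% above the
   whole-image mean of that channel (inclusive boundary).
3. **Screening** — vesicles positive for a base marker set are screened
   for further markers (e.g. SMAD1) with the same rule, yielding nested
   co-positivity flags.
4. **Quantification** — per-field counts and fractions, compared between
   two conditions with an unpaired two-sided t-test (Welch by default;
   pooled-variance and permutation variants available), plus intensity
   line profiles and precision/recall evaluation against simulator ground
   truth.

Because the pipeline is meant to be validated without any microscope, the
`synthetic` module renders fields with known truth: Gaussian-blob vesicles
(σ = radius/2) on a smooth autofluorescent background with shot + read
noise, condition-dependent vesicle density, and per-vesicle secondary-marker
enrichment with a controllable true positive fraction.

## Worked example

Simulate a two-condition experiment at the default presets and compare the
conditions:

```python
from endovesiq import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_fields_per_condition=5, seed=7)
res = run_pipeline(cfg, simulate=True)
print(res.summaries[["field", "condition", "n_vesicles", "n_pos_endoglin",
                     "n_copos_endoglin+smad1"]].to_string(index=False))
comp = res.comparisons["n_copos_endoglin+smad1"]
print(f"\ncopositive vesicles LSS vs HSS: "
      f"t = {comp['statistic']:.2f}, p = {comp['pvalue']:.2e}")
```

prints

```
 field condition  n_vesicles  n_pos_endoglin  n_copos_endoglin+smad1
     0       LSS          56              32                      18
     1       LSS          51              38                      18
     2       LSS          63              35                      14
     3       LSS          47              26                      12
     4       LSS          49              34                      11
     5       HSS          34              18                       3
     6       HSS          30              12                       2
     7       HSS          26              11                       4
     8       HSS          20               8                       6
     9       HSS          30              10                       0
copositive vesicles LSS vs HSS: t = 6.53, p = 3.17e-04
```

Each row is one simulated 256×256 field: `n_vesicles` detected
Caveolin-1 vesicles, of which `n_pos_endoglin` are Endoglin-positive by the
15% rule and `n_copos_endoglin+smad1` additionally carry SMAD1 signal. The
LSS preset is denser and more marker-positive than HSS, and the Welch
t-test on the per-field co-positive counts resolves that contrast
(p ≈ 3×10⁻⁴).

The same pipeline runs from the shell on real or simulated TIFFs:

```bash
endovesiq simulate --out sim/ --seed 1          # fields + ground-truth CSVs
endovesiq run --simulate --out run/ --seed 1    # full bundle
endovesiq classify --image f.tif --config cfg.yaml --out out/
endovesiq profile --image f.tif --channels cav1,endoglin \
    --from 30,4 --to 30,60 --width 3 --n 100 --out profile.csv
endovesiq evaluate --table out/f_vesicles.csv --truth sim/..._truth.csv \
    --max-dist 3.5
```

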