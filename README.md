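# octprofiler

Quantitative characterization of pigmented skin lesions in optical
coherence tomography (OCT) B-scans: dermatoscopy-guided lateral lesion
delimitation, region-of-interest (ROI) extraction with per-A-scan
surface flattening, Beer–Lambert estimation of the total attenuation
coefficient µt, and depth-sectioned gray-level co-occurrence matrix
(GLCM) texture features. The package targets researchers building
image-analysis baselines for melanoma-vs-nevus OCT studies, where the
question is whether optical and textural properties separate lesion
subtypes (compound nevus, intradermal nevus, melanoma in-situ,
superficial spreading melanoma) from adjacent healthy skin.

Patient OCT data in this domain is ethics-restricted, so the package
ships a first-class layered-skin **phantom generator** with known
ground truth (per-column µt map, surface profile, lesion interval). The
whole pipeline is exercised and scored end to end on phantoms: air gap
over an uneven surface, bright entry peak, exponential decay with
region-dependent attenuation, multiplicative speckle, 8-bit
quantization, and a paired dermatoscopy image carrying the white
scan-line marker and a dark lesion blob.

## Model

Each A-scan (column of the B-scan) is modelled by the single-scattering
Beer–Lambert law with round-trip detection:

    I(z) = A · exp(−2 µt z) + C

where µt = µa + µs is the single-pass total attenuation coefficient
(mm⁻¹), z the depth below the tissue entry, A the entry amplitude and C
the dark noise floor (both in arbitrary display units). Depth is
converted from pixels with the in-tissue axial pitch

    Δz = depth_range / n_axial_px / n  =  1.9 mm / 512 / 1.4  ≈ 2.65 µm/px

for skin refractive index n = 1.4 at 1300 nm (3.71 µm/px in air). Each
ROI (100 px ≈ 0.7 mm wide, 150 px ≈ 0.4 mm deep for attenuation, 75 px
≈ 0.2 mm for texture) is summarized by the median and interquartile
range of the per-column µt fits; lesions are compared to adjacent
healthy tissue by the difference of medians. Texture is quantified per
depth section (0–25, 25–50, 50–75 px) by tiling 25×25 px boxes and
computing GLCM contrast, dissimilarity, homogeneity, energy, and
correlation at pixel offset d = 2, averaged over the four axis
directions.

## Worked example

```python
from octprofiler import run_case, scenario_config

result = run_case(scenario_config("SSM-2", seed=17))
print(result.bounds_bscan)
print(result.lesion_attenuation)
print(result.healthy_attenuation)
print(result.median_difference)
```

The `SSM-2` scenario is a phantom with lesion µt = 2.82 mm⁻¹ over
healthy skin at 0.86 mm⁻¹ (a strongly attenuating invasive-melanoma-like
contrast). The run prints:

```
lesion bounds (B-scan cols): [150, 300)          # truth: [150, 300)
lesion   mu_t median 2.84 /mm, IQR 0.48 (n=100)
healthy  mu_t median 0.87 /mm, IQR 0.13 (n=200)
median difference 1.97 /mm                       # configured contrast: 1.96
```

The lesion was localized exactly from the dermatoscopy scan-line band,
and the fitted medians recover the generator's attenuation values
within a few percent despite 22% multiplicative speckle (Gamma shape
k = 20) and 8-bit quantization. `compare_cases` stacks several
`CaseResult` objects into one lesion-vs-healthy comparison table.

The numbered drivers under `analysis/` run the same machinery as
narrative studies (phantom library generation, delimitation scoring,
attenuation comparison, texture sections) and write their tables under
`results/`; a console script `octprofiler` with `simulate`, `delimit`,
`run`, and `compare` subcommands wraps the library for shell use.

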