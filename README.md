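# pbshalo

Tools for characterizing the **nuclear halo** of proton pencil-beam-scanning
(PBS) spots and for predicting **field size factors** (FSFs) from measured
spot profiles.

In PBS delivery every field is a superposition of thousands of near-Gaussian
beam spots. In air, each spot carries a broad, low-intensity envelope — the
halo, produced by large-angle scattering in the beam line — that typical
planning-system beam models (a single Gaussian per spot) ignore. Because a
small field loses a larger fraction of each spot's tails outside its edges,
ignoring the halo makes a planning system overestimate small-field output by
several percent at low beam energies. Quantifying this requires spot images
spanning four decades of intensity, more than film (useful range
0.01–8 Gy) or a scintillator-CCD panel (0–1000 counts) can record in one
shot.

The package implements the complete measurement-analysis chain on synthetic
data with the statistical structure of the real measurements:

- **`pbshalo.synthetic`** — spot models (Gaussian core + Gaussian halo;
  per-energy defaults fitted to published film width tables), and parametric
  detector degradation: dynamic-range clipping, multiplicative noise, and
  the panel's directional low-dose over-response (up to +40%).
- **`pbshalo.pairmag`** — *pair magnification*: registration and stitching
  of exposure series at increasing delivered dose (1×, 20×, 400×) into one
  composite profile valid down to 0.01% of the peak intensity.
- **`pbshalo.radial`** — polar conversion about the spot centre, angular
  masking of the panel artifact, radially averaged profiles, FWHM / FW10% /
  FW1% extraction (σ = FWHM / (2√(2 ln 2))), and film-vs-panel comparison
  tables.
- **`pbshalo.fsf`** — FSF(L) for square fields of side L at 2.5 mm spot
  spacing, normalized to the 10 cm field, from either a measured composite
  kernel or an analytic Gaussian surrogate, with an optional 2 mm-radius
  disc average emulating an ion chamber; closed-form oracle
  FSF(L) = erf(L/(2√2 σ))² / erf(L₀/(2√2 σ))² for the Gaussian case.
- **`pbshalo.io` / `pbshalo.cli`** — TIFF/CSV readers and writers, YAML run
  configuration and the `pbshalo` command with subcommands
  `simulate | compose | analyze | fsf | report`.

## Worked example

```python
import pbshalo as p

model = p.default_spot_model(70, "Z0")        # 70 MeV spot at isocenter
truth = p.make_truth_image(model, 5 * model.outer_sigma)
exposures = p.make_exposure_set(truth=truth, device=p.film_device(), seed=42)
composite = p.compose(exposures, p.register_exposures(exposures))
print(f"dynamic range {p.dynamic_range(composite):.2g}")

profile = p.to_radial(composite, p.find_center(composite))
print({k: round(v, 2) for k, v in p.summarize_widths(profile).items()})
```

```
dynamic range 1.5e+11
{'fwhm_mm': 12.5, 'fw10_mm': 24.12, 'fw1_mm': 36.15, 'sigma_mm': 5.31}
```

The three clipped exposures stitch into a composite spanning far more than
the single-shot range, and the radially averaged widths recover the
published 70 MeV film values (12.5 / 24.1 / 36.1 mm) to within a fraction
of the 0.5 mm radial bin. Feeding the composite and a matched
single-Gaussian surrogate into the FSF calculator:

```python
halo = p.SpotKernel.from_composite(composite)
gauss = p.SpotKernel.from_model(p.SpotModel(p.sigma_from_fwhm(12.5)))
errors = p.percent_error_table(p.fsf_curve(gauss), p.fsf_curve(halo))
print(errors.round(2).head(3))
```

```
          fsf  reference  percent_error
side_mm
20.0     0.94       0.89           5.12
32.0     1.00       0.99           0.68
40.0     1.00       1.00           0.11
```

A single-Gaussian beam model overestimates the 2 cm-field output of this
70 MeV beam by ~5% relative to the halo-included kernel, shrinking to
nothing by the 6 cm field — the clinically relevant signature of the
unmodelled in-air halo.

The same chain is available from the shell, e.g.

```sh
pbshalo simulate --energy 70 --device film --seed 42 --out exp
pbshalo compose --exposures exp/exposure_m1.tif --exposures exp/exposure_m20.tif \
    --exposures exp/exposure_m400.tif --factors 1,20,400 --out composite.tif
pbshalo analyze --composite composite.tif --out widths.csv
pbshalo fsf --kernel composite.tif --out fsf.csv
pbshalo report --seed 5 --out bundle     # full pipeline + manifest
```

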