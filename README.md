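# epival

Validation of ultrasound-based intrafraction prostate-motion monitoring
against fiducial markers on cine portal images.

## The problem

Transperineal ultrasound systems can monitor prostate position
continuously during radiotherapy delivery without implanted hardware,
reporting a 3D translation + rotation estimate at roughly 3 Hz together
with a confidence score *C* ∈ [0, 1].  Before such a system can drive
gating or MLC tracking, its motion estimates need an independent in vivo
check.  The reference standard is the treatment beam itself: implanted
gold markers are visible on cine electronic portal images (EPIs), so the
monitor's prediction of where the markers should be can be compared with
where the beam actually saw them.

`epival` implements that comparison as a reusable, tested pipeline, and
— because patient data of this kind are not public — ships a synthetic
session generator that emulates the full measurement chain: random-walk
prostate motion, a noisy ~3 Hz monitoring trace with a confidence model,
1024×1024 16-bit portal frames with markers rendered inside MLC-shaped
fields, ≤2 mm panel flex, detector noise, and two log clocks separated
by an unknown offset.

## The method

For each treatment field of a fraction:

1. **Image localization.**  The first cine frame of the first segment is
   contrast-enhanced with a Laplacian-of-Gaussian filter (3.5 mm kernel,
   SD 1.0 mm at isocenter scale); up to three marker blobs are detected
   and refined to sub-pixel centroids.  Observer variability is emulated
   by perturbed detection replicates; markers with interobserver
   disagreement > 1.5 mm are excluded, and images with fewer than two
   identifiable markers are dropped.  A marker hidden by the MLC or bony
   anatomy is reconstructed from its CBCT offset relative to the visible
   pair.  Panel flex is measured by a correlation template match of the
   planned MLC aperture and subtracted as a rigid 2D correction.
2. **Monitor localization.**  The monitor and linac logs are
   synchronized through the couch-correction event visible in both; the
   monitored 3D translation at the field's first-segment beam-on time
   (zero-order hold) shifts the initial CBCT marker positions.  Rotation
   estimates are disregarded.
3. **Comparison.**  The predicted markers are projected through the
   divergent beam geometry (SAD 1000 mm, SDD 1600 mm) onto the imager
   and expressed in mm at isocenter scale.  The monitoring error is the
   projected-minus-imaged center-of-mass difference,
   E = (E_u, E_v), with magnitude |E| = √(E_u² + E_v²).

Fractions whose confidence sits persistently below the C < 0.5 warning
threshold during beam-on are excluded wholesale.  Errors are summarized
with nonparametric Bland–Altman limits of agreement (empirical
quantiles), and the toolkit includes the Lilliefors-style KS normality
test, OLS R², and Kruskal–Wallis rank ANOVA used for the secondary
analyses.  A phantom protocol (programmed platform shifts standing in
for the monitor, 5 fields × 6 fractions = 30 images) isolates the
precision of the localization chain itself.

## Worked example

Simulate one 3-field fraction and analyze it:

```bash
cat > cfg.yaml <<EOF
session:
  n_fields: 3
  image_size: 256
  seed: 5
  clock_offset_s: 12.5
EOF
epival simulate --config cfg.yaml --out session/
epival analyze --session session/ --out results/
```

The analyzer logs one line per field and writes
`results_fields.csv`, `results_fractions.csv` and `stats_summary.json`:

```
INFO epival: field 1: E = (0.19, 0.44) mm, |E| = 0.48 mm, C = 0.83
INFO epival: field 2: E = (0.13, -0.18) mm, |E| = 0.22 mm, C = 1.00
INFO epival: field 3: E = (0.41, 0.23) mm, |E| = 0.47 mm, C = 0.89
INFO epival: results written to results (3/3 fields included)
```

Each `E` line is the monitoring error for that field: how far (mm at
isocenter scale, along the two portal-image axes) the monitor-predicted
marker center of mass landed from the image-localized one, with `C` the
monitoring confidence at the first-segment time.  Sub-millimeter values
mean the monitor tracked the (simulated) prostate to within the
localization chain's own precision.

The same machinery runs as a library:

```python
from epival import run_study, study_config_pairs
fields, fractions = run_study(study_config_pairs(seed=1, n_fractions=4,
                                                 n_five_field=4,
                                                 n_outlier_fields=0,
                                                 poor_probe_fraction=None),
                              "scratch/demo")
print(fields[["fraction_id", "field_id", "e_u", "e_v", "e_mag", "excluded"]])
```

## Layout

| Module | Contents |
| --- | --- |
| `epival.geometry` | room/imager frames, divergent projection, centers of mass |
| `epival.motion_sim` | random-walk motion, monitoring oracle, session generator |
| `epival.portal_imaging` | rendering, LoG detection, observer filter, flex correction |
| `epival.log_sync` | log parsing, clock-offset estimation, field-time lookup |
| `epival.validation` | per-field errors, exclusions, studies, phantom protocol |
| `epival.stats` | nonparametric LOA, KS normality, R², Kruskal–Wallis |
| `epival.config` / `epival.cli` | schema-validated configuration and the CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
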