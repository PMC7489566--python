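# collesmetrics

Semi-automatic geometric and texture radiogrammetry for posterior-anterior
(PA) wrist radiographs, aimed at studies of dorsally displaced distal-radius
fractures (Colles' fractures) treated by manipulation under anaesthesia.

Clinical questions about these fractures — is the wrist swollen, is the bone
osteoporotic, did the intervention change the bone texture — are usually
answered by manual measurements that are slow and observer-dependent. This
package automates everything except the placement of three landmarks (base
of the lunate, tip of the radial styloid, centre of the middle-finger
metacarpal). From those it extracts **32 named measurements** per radiograph
in four families, and compares them across the five study groups (control,
pre/post intervention × successful/unsuccessful outcome):

| family | anchored on | measurements |
| --- | --- | --- |
| forearm widths | lunate | 8 widths `W1…W8` at 1 cm spacing → 10 ratios (e.g. `W1 / W4`, `Min width / Max width`) |
| finger radiogrammetry | finger | `Trabecular Area / Total Area`, `Width Finger` |
| bone texture | lunate + styloid | 10 rotation-invariant uniform Local Binary Pattern coefficients `LBP 1…10` |
| intensity profiles | styloid | slope, detrended/raw standard deviation and length of two profile lines at 30° and 45° from the lunate–styloid baseline |

Pre-processing is fully automatic: the forearm inclination is the median
angle of the strongest Hough-transform line peaks over Canny edges of the
image's central third, the image is rotated back so the forearm is vertical,
and collimator artefacts (the exactly-zero regions outside the exposed
field) are detected, dilated and removed. Group differences are tested per
measurement with a two-sample *t*-test (Welch by default) for seven
contrasts (control v patient, pre v post, successful v unsuccessful, and the
four within-pair contrasts).

Because clinical radiographs cannot be redistributed, the package ships a
phantom generator (`collesmetrics.phantom`) that renders synthetic wrist
radiographs with known rotation, width profile, cortical thickness and
landmark positions, so every stage is validated against ground truth.

## Worked example

```python
from collesmetrics import PhantomParams, generate_phantom, run_case

radiograph, truth = generate_phantom(PhantomParams(seed=3))  # true rotation 12°
vector = run_case(radiograph, truth.landmarks)
for name in ("W1 / W4", "Trabecular Area / Total Area", "LBP 4",
             "Std profile 1 adjusted", "Distance profile 1"):
    print(f"{name:32s} {vector[name]:.4f}")
```

prints

```
W1 / W4                          1.0669
Trabecular Area / Total Area     0.6853
LBP 4                            0.1963
Std profile 1 adjusted           10.2082
Distance profile 1               105.0000
```

`W1 / W4` > 1 says the most distal width line is wider than the mid-forearm
reference (the phantom's built-in distal swelling: 320 px v 298 px true).
The trabecular fraction 0.685 recovers the phantom's true 0.68 (17 px
trabecular half-width, 8 px cortical shells). `Distance profile 1` is the
length in pixels of the 30° profile line before it leaves the radius for
the dark inter-bone gap (true geometric distance: 104 px).

For a whole study, `run_study` (or the CLI) produces `measurements.csv`
(one row per case) and `comparisons.csv` (32 measurements × 7 contrast
p-values, significant cells flagged at p < 0.05):

```bash
collesmetrics phantom --seed 1 --out phantom_dir/
collesmetrics measure --image phantom_dir/phantom.png --landmarks phantom_dir/landmarks.csv --pixel-spacing 0.2
collesmetrics study --cases cases.csv --out results/
```

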