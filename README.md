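# fundus-cdr

Automatic glaucoma screening from color fundus photographs: optic disc and
optic cup segmentation, horizontal and vertical cup-to-disc ratios
(HCDR/VCDR), and a multi-grader outlier-filtering evaluation protocol —
plus a synthetic phantom generator that makes the whole pipeline testable
with known ground truth.

Clinically, the cup-to-disc ratio is the standard structural marker of
glaucomatous damage: loss of neuroretinal rim tissue enlarges the cup
relative to the disc. Along an axis, `CDR = cup extent / disc extent`,
where an extent is the inclusive pixel distance between a mask's furthest
two member pixels on that axis. The pipeline:

1. extracts blood vessels from the green channel with a black top-hat
   transform and erases them by diffusion inpainting;
2. localizes the optic nerve head by interval Type-II fuzzy-entropy
   multilevel thresholding (thresholds found with Differential Evolution)
   and segments the disc with a geodesic active contour (a single pass for
   high-quality frames, a re-centered split double pass for low-quality
   ones);
3. segments the cup inside the disc window with a four-loop thresholding
   cascade (thresholds k = 3, 2, 4, 3; contrast enhancement in the first
   two loops) with automatic error detection — a candidate that is too
   small or touches the disc boundary triggers the next loop — and
   approximates the cup boundary with a circular Hough fit;
4. evaluates any panel of markings (six manual graders plus the algorithm
   as a seventh marking) by per-image SD thresholds, iterative outlier
   detection, image-elimination rules, accuracy percentages and pairwise
   agreement matrices.

The intended audience is researchers working on automated optic-nerve-head
analysis who need a complete, reproducible, fully tested reference
implementation of this screening-and-evaluation design.

## Worked example

```sh
# render 5 phantoms with ground truth and simulated graders
fundus-cdr simulate --out-dir demo --n-images 5 --seed 7

# segment them (disc + cup + CDRs per image)
fundus-cdr segment demo/img00?.png --out-dir demo/seg --seed 7
```

The segment step logs one structured line per image and writes
`algorithm_markings.csv` and `status.csv`:

```
INFO image=img000 status=ok path_used=single loop_used=1
...
segmented 5/5 image(s); results in demo/seg
```

```python
>>> import pandas as pd
>>> marks = pd.read_csv("demo/seg/algorithm_markings.csv")
>>> truth = pd.read_csv("demo/truth.csv")
>>> pd.DataFrame({"estimated": marks.set_index("image_id").hcdr.round(3),
...               "truth": truth.set_index("image_id").hcdr.round(3)})
          estimated  truth
image_id
img000        0.579  0.495
img001        0.537  0.495
img002        0.558  0.495
img003        0.537  0.495
img004        0.579  0.495
```

Each row is one phantom: the automated HCDR (cup extent over disc extent
from the segmented masks) against the generator's ground truth; the small
positive bias is the cup boundary landing on the cup-rim intensity ramp
(see `docs/methods.md`). The same marking table, merged with simulated
grader markings, feeds the evaluation protocol:

```sh
fundus-cdr evaluate demo/markings.csv --out-dir demo/report
```

which writes `accuracy_{hcdr,vcdr,final}.csv` (rows: total, removed,
not_localized, tested, accurate, percentage — one column per grader and the
algorithm) and the matching pairwise `agreement_*.csv` matrices.

The library mirrors the CLI: `segment_image`, `segment_disc`, `segment_cup`,
`extract_vessels`, `inpaint`, `de_optimize`, `hcdr`, `vcdr`,
`accuracy_table`, `agreement_matrix`, `generate_phantom`,
`simulate_markings`, with configuration in `fundus_cdr.config.DEFAULTS`
(`fundus-cdr defaults` prints it; `config/defaults.yaml` is that dump).

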