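# endokit

Classical image-analysis pipeline for lower-gastrointestinal endoscopy
frames: enhancement, level-set lesion segmentation, handcrafted texture and
color descriptors, shallow neural-network / SVM classification, and full
diagnostic metric reporting. The package targets the standard 5-class
lower-GI setting (dyed-lifted-polyps, normal-cecum, normal-pylorus, polyps,
ulcerative-colitis) and ships a deterministic phantom generator so the
entire pipeline runs and is tested without any external dataset. Real
endoscopy images (e.g. the public Kvasir collection) can be fed through the
same CLI, but are never required.

It is aimed at researchers building or benchmarking computer-aided
diagnosis pipelines who want a reproducible, fully classical baseline with
every numeric kernel tested against brute-force oracles.

## The pipeline

1. **Enhancement.** The RGB frame is reduced to grayscale by the unweighted
   channel mean, smoothed by a 5×5 averaging filter that replaces each pixel
   with the mean of its 24 neighbors, and sharpened by subtracting a
   discrete Laplacian response: `O = f_avg − ∇²f`.
2. **Segmentation.** A region-based active contour in the Chan–Vese family.
   With inside/outside means `c1, c2` weighted by a smoothed Heaviside
   `Hε(t) = ½(1 + (2/π)·arctan(t/ε))`, the signed pressure force
   `spf(I) = (I − (c1+c2)/2) / max|I − (c1+c2)/2|` drives the level set
   `φ ← φ + dt·spf(I)·(λ|∇φ| + ν)`, regularized by a small Gaussian
   smoothing of φ each step. Evolution stops when the relative mask-area
   change drops below a stop value SV (percent). The final mask is
   hole-filled and restricted to the seed's connected component.
3. **Features.** Circular LBP codes (P=8, R=1, bilinear sampling)
   histogrammed into 203 bins; 13 Haralick GLCM statistics averaged over
   four offsets (0° and 90° at d=1, 45° and 135° at d=√2); a 16-bin fuzzy
   color histogram on a fixed 4×2×2 RGB lattice. Concatenation gives the
   232-wide handcrafted vector; prepending a pluggable deep embedding
   (default width 4096) gives the 4328-wide hybrid vector.
4. **Classification.** A one-hidden-layer network (30 ReLU units, softmax
   output, cross-entropy objective, early stopping on a validation split)
   or a one-vs-one linear SVM.
5. **Evaluation.** Stratified 640/160/200-per-class splitting, 8× training
   augmentation, one-vs-rest accuracy/precision/sensitivity/specificity,
   ROC AUC, pixelwise mask scores (incl. Dice), and size-weighted
   aggregation of per-class accuracies.

## Worked example

```python
from endokit import (PhantomSpec, generate_phantom, enhance, ContourParams,
                     segment, mask_scores, extract_handcrafted,
                     run_phantom_benchmark)

img, truth = generate_phantom(PhantomSpec(klass="polyps", seed=7))
gray = enhance(img).pixels
mask, state = segment(gray, ContourParams(seed=(64, 64), radius=5))
print(f"segmentation: {state.iteration} iterations, {state.stop_reason}")
print(f"Dice vs ground truth: {mask_scores(mask, truth)['dice']:.1f}%")

fv = extract_handcrafted(img, mask=mask)
print(f"handcrafted vector: {len(fv)} values, blocks {fv.blocks}")

result = run_phantom_benchmark(n_per_class=100, seed=1)
print(f"5-class test accuracy: {100 * result['test_accuracy']:.1f}%")
```

prints

```
segmentation: 64 iterations, area change below SV=0.1%
Dice vs ground truth: 89.6%
handcrafted vector: 232 values, blocks ['lbp', 'glcm', 'fch']
5-class test accuracy: 98.0%
```

The segmentation converged by the SV area-change rule; the Dice score
compares the recovered polyp mask against the phantom's analytic ground
truth (the specular highlight painted inside the polyp costs a few points).
The benchmark generates 500 phantoms (100 per class), extracts the
232-feature vector per frame, splits them 320/80/100, trains the network
with early stopping, and scores the held-out test split.

## Command line

Every stage is also a CLI subcommand:

```
endokit simulate --n-per-class 100 --seed 1 --out-dir data/
endokit enhance  --in frame.png --out enhanced.png
endokit segment  --in frame.png --seed 120,160 --radius 5 --out mask.png
endokit features --in data/images --labels data/labels.csv --out features.csv
endokit train    --features features.csv --model mlp --seed 1 --out model.npz
endokit predict  --model model.npz --features features.csv --out preds.csv
endokit evaluate --preds preds.csv --truth data/labels.csv --out report.json
endokit split    --n-per-class 1000 --seed 1 --out split.json
```

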