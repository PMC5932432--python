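# mgmfseg

Segmentation of coronary vessels in 2-D X-ray angiograms by **multiscale
Gaussian matched filtering (MGMF) with neural-network fusion**, plus the
classical thresholding, evaluation and synthetic-phantom machinery needed to
study the method end to end.

Angiograms show contrast-filled vessels as dark tubular structures of varying
caliber on a brighter, unevenly illuminated and noisy background. The package
is aimed at researchers in medical image analysis who want a transparent,
fully reproducible reference implementation of the classic matched-filter
detection pipeline and its multiscale extension — not a clinical tool.

## The method

**Detection.** A Gaussian matched filter approximates the vessel
cross-section with the template

```
G(x, y) = -exp(-x² / 2σ²),   |x| ≤ (T-1)/2,  |y| ≤ (L-1)/2,
```

normalized to zero sum over its support. The template is replicated at κ
evenly spaced orientations over 180°; correlating the image with the bank
and keeping the per-pixel maximum yields the single-scale detection
response. Evaluating the bank at n scales σ₁ < … < σₙ (default
σ ∈ {1.5, 1.6, …, 2.5}, L = 13, T = 15, κ = 12) gives each pixel an
n-vector of responses. A small feed-forward network

```
F(x) = h(W₃ · g(W₂ · g(W₁ · x̃ + b₁) + b₂) + b₃),   g = h = logistic,
```

with two hidden layers (default 3 and 8 neurons, selectable by exhaustive
grid search on training-set A_z) fuses that vector into a vessel-likelihood
score in (0, 1).

**Segmentation.** The gray-scale detection map is binarized by one of ten
classical thresholding methods (Otsu by default; Ridler–Calvard, Kapur,
Pal exponential entropy, Tsai moments, histogram concavity, RATS, Niblack,
Sauvola, White–Rohrer).

**Evaluation.** Detections are scored by the area A_z under the ROC curve
(threshold sweep, trapezoidal Riemann sum); segmentations by pixel accuracy
(TP + TN)/(TP + FP + TN + FN).

Because clinical angiogram databases with expert ground truth are rarely
shareable, the package ships a phantom generator producing angiogram-like
images (smooth random dark vessels of mixed caliber, illumination gradient,
Gaussian noise) with pixel-exact ground truth.

## Worked example

```bash
mgmfseg simulate --n 8 --size 160 --vessels 3 --seed 7 --out data
printf 'training: {epochs: 60, batch_size: 1024}\nn_repeats: 3\nseed: 7\n' > cfg.yaml
mgmfseg experiment --dataset data --config cfg.yaml --out run
```

prints

```
wrote 8 image/mask pairs to data
train A_z = 0.9737, test A_z = 0.9747; report in run/report.json
```

`run/report.json` holds the full picture: the fused detector reaches
A_z = 0.9747 on the four held-out phantoms against 0.9750 for the best
single scale on this small, easy set (on harder mixed-width sets the fusion
pulls ahead — see the test suite), the train/test gap is 0.001, and the
per-method segmentation accuracies on the fused response are

```
ridler_calvard  0.9626
otsu            0.9625
concavity       0.9612
moments         0.9583
rats            0.9548
kapur           0.8690
...
```

with the intraclass-variance family (Otsu, Ridler–Calvard, moments) at the
top, mirroring what is reported on clinical angiograms.

The same steps are available as a library:

```python
from mgmfseg import GMFParams, gmf_response, multiscale_response, segment
from mgmfseg import NetworkArchitecture, TrainingConfig, train, predict_image
from mgmfseg.phantom import PhantomConfig, generate_phantom

image, gt, _ = generate_phantom(PhantomConfig(seed=0))
stack = multiscale_response(image, [1.5, 2.0, 2.5])
model, history = train([stack], [gt], NetworkArchitecture(3, (3, 8)),
                       TrainingConfig(seed=0, epochs=100))
mask = segment(predict_image(model, stack), "otsu")
```

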