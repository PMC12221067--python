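# fasf-tle

MRI-based detection of temporal lobe epilepsy (TLE), implemented as a
modular, fully testable pipeline:

1. **Preprocessing** — skull stripping, multiplicative bias field
   correction, min–max intensity normalization, median filtering.
2. **Fuzzy-AAL segmentation** — fuzzy possibilistic c-means (FPCM) tissue
   clustering followed by affine atlas label transfer onto named
   anatomical regions.
3. **Feature extraction** — local binary pattern (LBP) histograms,
   intensity moments and shape descriptors per region.
4. **DGWO feature selection** — a hybrid dipper-throated / grey-wolf
   metaheuristic that searches binary feature masks by cross-validated
   classification error.
5. **HAETN classification** — a hybrid attention-enhanced transformer
   network (separable-convolution encoder with CBAM, BiLSTM, transformer
   encoder, temporal attention, softmax head), trained with SGD-momentum,
   with Grad-CAM interpretability maps.
6. **Evaluation** — confusion-matrix metrics (accuracy, precision,
   sensitivity, specificity, F1, MCC, NPV, FPR, FNR), ROC/AUC, and
   stratified k-fold cross-validation.

The package ships seeded synthetic generators (multi-tissue brain
phantoms with ground truth, toy atlases, labelled feature tables,
planted-blob slice datasets), so every stage can be validated end to end
without any external data.  It is aimed at researchers who want a
transparent, desk-scale reference implementation of this kind of
segmentation + wrapper-selection + attention-network pipeline.

## The core models

**FPCM.** Every voxel *i* receives a fuzzy membership and a possibilistic
typicality for each tissue cluster *C* (distance `D_iC = |x_i − v_C|`):

```
U_iC = 1 / Σ_K (D_iC / D_iK)^(2/(M−1))        (rows sum to 1)
α_iC = 1 / (1 + (D_iC / η_C)^Q)               (unnormalized)
J    = Σ_i Σ_C [ U_iC^M D_iC² + α_iC^Q D_iC² ]
v_C  = Σ_i (α_iC^Q U_iC^M x_i) / Σ_i (α_iC^Q U_iC^M)
```

Updates alternate until `|ΔJ| < ε`; the voxel label is
`argmax_C (U_iC · α_iC)`.  Typicality makes the centres robust to the
outliers that plain fuzzy c-means must still share across clusters.

**DGWO.** Agents live in `[0,1]^d`; thresholding at 0.5 yields a feature
mask scored by stratified-CV nearest-centroid error.  Each iteration
draws `R ~ U(0,1)`: `R < 0.5` applies the grey-wolf siege step towards
the three current leaders (`a = 2·l·r₁ − l`, `l: 2→0`), otherwise the
dipper-throated flying update
`BS ← c₃·BS + c₄·r₁·(BL_best − BL) + c₅·r₁·(BL_Gbest − BL)`.

**HAETN.** Slice sequences pass per-slice through a depthwise-separable
convolution + CBAM encoder into embeddings, then a BiLSTM, a transformer
encoder block with sinusoidal positional encodings, temporal attention
pooling `v = Σ_t α_t h_t`, and a dense + softmax head.  The network runs
on an in-repo reverse-mode autodiff engine (numpy), which also supplies
the Grad-CAM gradients.

## Worked example

Run the whole pipeline on synthetic data from one config:

```
fasf-tle pipeline --out run/ --config desk.yaml --seed 1
```

with `desk.yaml` holding a width-reduced network for desk-scale training
(the published widths — 64 conv filters, 128 LSTM units, 8 heads, 2048
FFN units — are the package defaults):

```yaml
haetn:
  conv_filters: 8
  lstm_hidden: 8
  attn_heads: 2
  ffn_hidden: 32
  dense_units: 16
  epochs: 15
  batch_size: 8
  learning_rate: 0.1
  max_grad_norm: 0.3
eval:
  k: 3
```

The run prints:

```
INFO fasf_tle: FPCM centres: [0.1924, 0.4729, 0.7581]
INFO fasf_tle: DGWO: 2 features, cv error 0.0000
INFO fasf_tle: HAETN final train accuracy 1.000
INFO fasf_tle: mean accuracy 1.000 +- 0.000
```

Reading the numbers: the phantom's true tissue means are 0.2/0.5/0.8, so
the FPCM centres recover them to ~0.01 despite bias and noise; DGWO finds
exactly the 2 informative features planted among 8 noise columns (zero
cross-validated error); the reduced-width HAETN fits the 40-sequence
planted-blob training set perfectly, and the stratified 3-fold
cross-validation report (written to `run/report.json` with one row per
fold plus mean ± sd) shows perfect held-out accuracy — expected, since
the planted blob is strongly separable by design.  Intermediates
(preprocessed volume, segmentation, region labels, feature table,
selection mask, model checkpoint) are written alongside.

Individual stages are also available as commands (`preprocess`,
`segment`, `label`, `features`, `select`, `train`, `evaluate`,
`gradcam`, `synth`) and as a library:

```python
from fasf_tle import FPCM, make_phantom
vol, truth, bias, mask = make_phantom()
est = FPCM(n_clusters=3).fit(vol.data[mask])
est.cluster_centers_      # sorted ascending: CSF, GM, WM
```

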