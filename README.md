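# polcolor

Depolarization observables and automatic pseudo-coloring for Mueller-matrix
polarimetric images of biological tissue.

Imaging polarimetry measures, at every pixel, a 4×4 real Mueller matrix M
describing how the sample transforms polarized light. Depolarization-related
observables derived from M often separate tissue types (cartilage vs.
collagenous sheath, healthy lamina vs. fungal lesion, raphides vs. cells)
far better than the plain intensity image — but they arrive as six separate
gray-scale channels. `polcolor` computes those observables and fuses them
into a single pseudo-colored RGB image in which each tissue class, defined
by the user through rectangular regions of interest (ROIs), appears in its
own color. It is aimed at biomedical and botanical polarimetry users who
already have per-pixel Mueller images and want contrast-enhanced, per-class
visualizations plus an optional pixel classifier.

## The observables

With the block form `M = m00 [[1, Dᵀ], [P, m]]`, the Components of Purity
(CPs) are

    D   = sqrt(m01² + m02² + m03²) / m00          (diattenuation)
    P   = sqrt(m10² + m20² + m30²) / m00          (polarizance)
    P_S = ||m/m00||_F / sqrt(3)                   (degree of spherical purity)

The Cloude decomposition writes M as a convex sum of four pure
(non-depolarizing) Mueller matrices with weights proportional to the
eigenvalues λ₀ ≥ λ₁ ≥ λ₂ ≥ λ₃ ≥ 0 of the covariance matrix
H(M) = (1/4) Σ_ab m_ab (σ_a ⊗ σ_b*). Normalizing λ̂ᵢ = λᵢ/Σλ gives the
Indices of Polarimetric Purity (IPPs)

    P₁ = λ̂₀ − λ̂₁,   P₂ = λ̂₀ + λ̂₁ − 2λ̂₂,   P₃ = λ̂₀ + λ̂₁ + λ̂₂ − 3λ̂₃,

with 0 ≤ P₁ ≤ P₂ ≤ P₃ ≤ 1. Both triplets are tied together by the
depolarization index

    P_Δ = sqrt(D² + P² + 3P_S²)/√3 = sqrt(2P₁² + (2/3)P₂² + (1/3)P₃²)/√3,

which is 1 for a pure element and 0 for the ideal depolarizer diag(1,0,0,0).

## The pseudo-coloring methods

Each class i gets an RGB color C^i and per-observable ROI statistics
(means m_j^i, standard deviations σ_j^i) over a chosen triplet
(IPP = (P₁,P₂,P₃) or CP = (P,D,P_S)).

* **Euclidean** (exactly two classes): per-pixel normalized distances
  dⁱ = sqrt(Σ_j ((m_j^i − p_j)/(m_j¹ − m_j²))²) give color weights
  ℜⁱ = 1 − dⁱ/(d¹ + d²), which sum to 1; the pixel color is
  ℜ¹C¹ + ℜ²C². Pixels belonging to neither class end up an even mix —
  this method enhances contrast, it does not classify.
* **Normal** (any number of classes): each class contributes
  Pⁱ = Π_j exp(−((p_j − m_j^i)/σ_j^i)²) of its color; pixels far from every
  class come out black. The membership map also supports an argmax
  classification export.

## Worked example

Generate a synthetic two-class scene (top half a pure identity matrix,
bottom half the partial depolarizer diag(1, 0.4, 0.4, 0.4), 0.5 % additive
element noise), then estimate class statistics from one ROI per class and
render both pseudo-colorings:

```bash
polcolor simulate -o scene.tif -a 1.0 -a 0.4 --noise-sd 0.005 --seed 7 \
         --height 128 --width 128
```

```python
import numpy as np
import polcolor as pc
from polcolor import io

stack = pc.compute_observables(io.read_mueller("scene.tif"))
pure  = pc.roi_statistics(stack, pc.ROISpec("pure", [(8, 8, 56, 56)]),
                          "ipp", color=pc.COLOR_PRESETS["yellow"])
depol = pc.roi_statistics(stack, pc.ROISpec("depolarizing", [(8, 72, 56, 120)]),
                          "ipp", color=pc.COLOR_PRESETS["blue"])
print(np.round(pure.means, 3), np.round(depol.means, 3))

rgb = pc.euclidean_pseudocolor(stack, pure, depol, "ipp")
print(np.round(rgb[8, 8], 3), np.round(rgb[120, 8], 3))

_, probs = pc.normal_pseudocolor(stack, [pure, depol], "ipp")
truth = np.where(np.arange(128)[:, None] < 64, 0, 1)
print(np.mean(np.argmax(probs, -1) == truth))
```

prints

```
[0.99  0.998 1.   ] [0.395 0.405 0.419]
[0.997 0.997 0.003] [0.005 0.005 0.995]
1.0
```

The ROI means recover the ground-truth IPPs of the two classes — (1, 1, 1)
for the pure half, (0.4, 0.4, 0.4) for the depolarizer — up to the small
noise-induced bias of the eigenvalue statistics. In the Euclidean rendering
a pixel inside the pure region is essentially the class color yellow
[1, 1, 0] and a depolarizing pixel essentially blue [0, 0, 1]; the Normal
membership argmax labels every pixel correctly on this well-separated
scene. The same pipeline is available from the shell
(`polcolor observables`, `polcolor pseudocolor --method euclidean|normal
--classes rois.json`, `polcolor validate`).

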