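# mwiseg — tissue-type segmentation and evaluation of microwave breast images

Microwave tomography reconstructs the complex permittivity ϵ(r) of the
breast over a grid of model elements by solving a severely ill-posed
inverse scattering problem. The resulting images are low-resolution, may
carry peripheral artefacts, and the interfaces between tissue types are
often blurred — yet evaluating a reconstruction algorithm requires
asking, per tissue, how well geometry and dielectric properties were
recovered. `mwiseg` is a toolkit for researchers developing such
reconstruction algorithms. It partitions a reconstructed image into
tissue types **without** assuming the dielectric ranges that characterize
each tissue and **without** pre-selecting a cluster count, then scores
the result against a ground-truth model with region and distance
metrics.

## The method

Given a scalar component image ℐ (Re{ϵ}, the loss magnitude |Im{ϵ}|, or
|ϵ|; ϵ is recovered from a contrast profile via ϵ = ϵ_b·(χ+1)):

1. **Region of interest.** The imaging-domain boundary ∂𝒟 is contracted
   uniformly inward (default 3.5 mm) to ∂ℛ, excluding peripheral
   artefacts; elements outside ℛ get a sentinel value of −100 so the
   background always forms the lowest cluster.
2. **Iterative clustering.** k-means (Lloyd, k-means++ initialization,
   best of d = 10 restarts) partitions the values into k clusters,
   relabeled so centroids ascend; k starts at 3. At each k the
   provisional tumor region is the top cluster, T̂ = c_max(k), and its
   complement within the ROI is T̂ᶜ = c₂ ∪ … ∪ c_max(k)−1.
3. **Statistical termination.** For k > 3, two two-sample
   Kolmogorov–Smirnov tests compare the value samples under T̂ and T̂ᶜ
   with the previous iteration's samples. While either null hypothesis
   ("same distribution") is rejected at the 1 % level, k is incremented
   and the image re-clustered; the first time neither rejects, the
   refinement stops.
4. **Tissue mapping.** Clusters map to tissues by ascending value:
   c₁ → background, c₂ → fatty, c₃–c₄ → transition,
   c₅…c_max(k)−1 → fibroglandular (Ĝ), c_max(k) → malignant (with a
   special three-tissue mapping if the loop stopped after a single
   refinement, max(k) = 4).
5. **Evaluation.** Reference and reconstructed masks are compared with
   Fidelity (normalized mask cross-correlation), xcorrDiel (the same on
   masked property values), Dice, ratio of tumor detected (RD), artefact
   rejection (AR, negative when false positives exceed the reference
   tumor area), and the average Hausdorff distance H_A between
   centroid-aligned boundary contours, reported per glandular region and
   per tumor. A threshold baseline (tumor = elements above 95/90/85/80 %
   of the interior maximum) is included to expose the
   sensitivity/specificity trade-off fixed thresholds suffer from.

A synthetic phantom generator supplies ground-truth breast images —
skin ring, fatty interior, blobby fibroglandular region with a
transition shell, tumors — with ordered, heterogeneous tissue value
distributions, plus a degradation operator (in-breast blur, noise,
multiplicative bias, peripheral artefacts) emulating the range of
reconstruction quality an inverse solver produces.

## Worked example

```python
from mwiseg import (PhantomSpec, DegradationSpec, SegmentationParams,
                    generate_phantom, degrade, contract_roi,
                    segment_components, component_images, evaluate)

truth = generate_phantom(PhantomSpec(seed=0))
recon = degrade(truth, DegradationSpec(blur_sigma_mm=1.0, noise_sd=0.3, seed=1))

roi = contract_roi(truth.domain_boundary_mask, distance_mm=3.5)
results = segment_components(recon, roi, SegmentationParams(seed=2))

seg, history = results["real"]
print(f"converged at k = {history.final_k} "
      f"after {len(history.records) - 1} refinement iterations")

ref_seg = truth.reference_segmentation()
ref_img = component_images(truth.image)["real"]
rec_img = component_images(recon)["real"]
report = evaluate(ref_seg, seg, ref_img, rec_img, pixel_spacing_mm=1.0)
for region, row in report.regions.items():
    print(region, {k: round(v, 3) for k, v in row.items() if v is not None})
```

prints

```
converged at k = 6 after 3 refinement iterations
glandular {'fidelity': 0.994, 'xcorr_diel': 0.991, 'dice': 0.994, 'rd': 0.989, 'ar': 1.0, 'hausdorff_mm': 0.118}
tumor_1 {'fidelity': 0.987, 'xcorr_diel': 0.989, 'dice': 0.987, 'rd': 1.0, 'ar': 0.973, 'hausdorff_mm': 0.141}
```

The KS termination settled on six clusters for this mildly degraded
image. The glandular region is recovered nearly perfectly (Dice 0.994,
boundary within ~0.1 mm on average); the tumor is fully detected
(RD = 1.0) with a small amount of surrounding tissue misattributed to it
(AR = 0.973).

The same pipeline is available from the shell:

```bash
mwiseg phantom --seed 0 --blur-sigma-mm 1 --noise-sd 0.3 --out work
mwiseg segment --input work/recon/image_re.csv,work/recon/image_im.csv \
               --domain-mask work/domain_mask.png --seed 2 --out work/recon
mwiseg metrics --ref work/truth --rec work/recon --out work/report.json
mwiseg threshold --input work/recon/image_re.csv --roi work/recon/roi_mask.png \
                 --ref work/tumor_mask.png --out work/sweep.csv
```

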