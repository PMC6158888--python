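# halopet

Adaptive FDG-PET tumor segmentation by the **peritumoral halo layer (PHL)**
method, with the fixed-threshold comparators it is validated against, a
digital phantom generator, and the agreement statistics used in that
validation.

## The problem

Delineating a tumor on an FDG-PET image requires choosing an SUV threshold.
The two workstation standards — a fixed absolute cutoff (SUV 2.5) and a
fixed percentage of the lesion's SUVmax (40%) — are known to be biased:
a fixed SUV cutoff swallows more and more partial-volume blur as SUVmax
grows, while a fixed percentage threshold balloons for faint lesions. For
elongated esophageal tumors, where the clinically relevant quantity is the
craniocaudal *metabolic tumor length* (ML), these biases translate directly
into length errors.

The halo-layer method derives the threshold adaptively from the image
itself. Display the lesion with the PET window bottom at SUV 0 and the top
just above SUVmax (rounded up to the next 0.1), quantized into ten equal
color layers — each layer then spans 10% of SUVmax. Between the tumoral
uptake and the background activity there is a distinct decile band, the
peritumoral halo layer, recognizable by an **abrupt increase in layer
thickness**. The tumor threshold is the percentage at the halo's inner
edge: a halo occupying the 20–30% layer gives a 30%-of-SUVmax threshold.
Because the background occupies higher deciles when SUVmax is low, the
percent threshold falls as SUVmax rises (and the absolute SUV threshold
rises) — the behaviour an accurate adaptive scheme must have.

`halopet` turns this visual workstation procedure into a deterministic
algorithm:

1. **Decile quantization** — `label(v) = clamp(floor(10·v/top), 0, 9)` with
   `top = (floor(10·SUVmax)+1)/10`.
2. **Band profiling** — per-decile band volume, interface areas (voxel-face
   counting with the 2/3 staircase correction), and thickness
   `t_k = V_k / mean(A_inner, A_outer)` inside a lesion shell.
3. **Halo detection** — locate the background decile `b` from an annulus
   outside the lesion shell; walk inward from band `b+1` while a band is at
   least ρ (default 2.0) times thicker than the next inner band; the
   innermost such band `k` sets the threshold `10·(k+1)%`. If no band shows
   the abrupt increase, the band adjacent to the background is the halo
   (its canonical position).
4. **Segmentation** — the 26-connected component above the threshold that
   contains the seed; from it ML (craniocaudal extent), MTV, SUVmean,
   TLG = SUVmean·MTV, and a homogeneous/heterogeneous uptake-pattern proxy.

## Worked example

```python
from halopet import (PhantomSpec, generate_phantom, roi_from_truth,
                     segment_phl, lesion_metrics)

spec = PhantomSpec(true_length_mm=40, peak_suv=10.0, noise_sd=0.0)
vol, truth = generate_phantom(spec)          # 2.65 mm voxels, 7 mm PSF
roi = roi_from_truth(vol, truth)
result, mask, labels = segment_phl(vol, roi)
metrics = lesion_metrics(vol, mask, labels)
```

prints (via the fields of `result` and `metrics`):

```
SUVmax            : 9.974
window top        : 10.0
background layer  : 1
halo layer        : 2
tumor threshold   : 30% of SUVmax = 3.00 SUV
detection mode    : fallback_adjacent
ML_PHL            : 4.505 cm   (truth 3.975 cm)
MTV_PHL           : 15.58 mL
SUVmean / TLG     : 6.21 / 96.8
pattern           : homogeneous
```

The background sits in the 10–20% layer (layer 1), so the halo is the
20–30% band and the threshold is 30% of SUVmax — the canonical halo
geometry. The measured length overshoots the ground truth by two voxels
because a 30% threshold lies below the partial-volume edge level of a
blurred plateau; see `docs/methods.md` for what the phantom does and does
not model.

The same pipeline is scriptable from the shell:

```bash
halopet phantom --n 30 --noise-sd 0.15 --seed 1 --outdir phantoms/
halopet segment phantoms/phantom_000.nii.gz --roi roi.json --outdir out/
halopet evaluate out/phantom_000_metrics.csv --truth phantoms/manifest.csv
```

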