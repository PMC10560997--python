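"""Generate long-tailed segmentation phantoms and check their composition.

Builds a liver-tumour-style dataset (organ 1:400, lesion 1:1400 vs
background) and the desk-scale default (lesion 1:100), then prints the
pooled per-class pixel fractions — the dataset-level contract the generator
enforces even though single small images cannot contain a 1:1400 class.
"""

from uqgan import (desk_spec, generate_segmentation_dataset, lits_like_spec,
                   pooled_class_fractions)

for name, spec in [("lits-like", lits_like_spec()), ("desk", desk_spec())]:
    ds = generate_segmentation_dataset(spec, 200, seed=7)
    fr = pooled_class_fractions(ds, spec.n_classes)
    print(f"{name}: {len(ds)} images of {spec.image_size}")
    for cls, target, actual in zip(spec.class_names, spec.target_ratios, fr):
        print(f"  {cls:12s} target {target:.6f}  pooled {actual:.6f}  "
              f"(1:{fr[0] / actual:.0f} vs background)")

# pooled fractions track the targets; e.g. the lits-like lesion class sits
# near 1:1400 relative to background over the dataset as a whole.
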