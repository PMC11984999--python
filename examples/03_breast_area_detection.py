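"""Bootstrap and train the breast-area detector, then clean an image.

Pipeline: K-means candidate masks -> quality filter -> 5x fake-label
augmentation -> UNet training -> mask-apply + peripheral crop. Scaled down
(24 source images at 64x64, a few epochs) so it runs in about a minute.
"""

import numpy as np

from fedmammo import (
    AugmentationConfig,
    HospitalProfile,
    PhantomSpec,
    build_auld,
    clean_and_crop,
    dice_iou,
    generate_phantom,
    predict_mask,
    preprocess,
)
from fedmammo.segmenter import SegTrainConfig, train_unet

profile = HospitalProfile("H1", intensity_range=(0, 4095), label_prob=0.7)
images, truth = [], []
for i in range(24):
    rec = generate_phantom(PhantomSpec(image_size=(64, 64), birads=1 + i % 5, seed=i), profile)
    pre = preprocess(rec, target_size=(64, 64))
    images.append(pre.pixels)
    truth.append(pre.mask)

auld = build_auld(images, k=2, cfg=AugmentationConfig(n_variants=5, seed=0))
print(f"bootstrap corpus: {len(auld.samples)} samples from "
      f"{len(images) - len(auld.rejections)} accepted sources (x5 augmentation)")

n_tr = 80
cfg = SegTrainConfig(n_train=n_tr, n_val=len(auld.samples) - n_tr, epochs=4,
                     seed=0, base_channels=4, depth=3)
model, history = train_unet(auld.samples[:n_tr], auld.samples[n_tr:], cfg)
print(f"validation Dice by epoch: {[round(h['val_dice'], 3) for h in history]}")

# apply to a fresh labeled phantom
rec = generate_phantom(PhantomSpec(image_size=(64, 64), birads=3, seed=999), profile)
pre = preprocess(rec, target_size=(64, 64))
mask = predict_mask(model, pre.pixels)
print(f"held-out Dice vs ground truth: {dice_iou(mask, pre.mask).dice:.3f}")
cleaned = clean_and_crop(pre.pixels, mask, margin=2, out_size=(64, 64))
print(f"cleaned image {cleaned.shape}; background zeroed: "
      f"{(cleaned == 0).mean():.0%} of pixels (printed label removed)")
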