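"""Train the stand-in severity grader and extract lesion descriptors.

The grader is the pipeline's workhorse: it scores severity (the
severity loss), provides feature maps (the perceptual loss and the FID
embedding), and its input gradient drives saliency-based lesion
extraction.
"""

import numpy as np

from fundusgan import SynthConfig, extract, generate_sample, predict_grade, train_grader

config = SynthConfig(side=64, n_samples=400, seed=7)
data = [generate_sample(config, i) for i in range(config.n_samples)]

grader, report = train_grader(data, epochs=30, seed=7, holdout_fraction=0.25)
print(f"held-out within-one accuracy: {report['within_one_accuracy']:.3f} "
      f"(mae {report['mae']:.3f}, n={report['n_holdout']})")

sample = next(s for s in data if s.grade >= 3)
print(f"true grade {sample.grade}, predicted {predict_grade(grader, sample.image):.2f}")

# lesion descriptors: grade saliency -> Gaussian smoothing at two scales
# -> per-image quantile binarization inside the field of view
desc = extract(grader, sample.image, fov=sample.fov_mask().astype(bool))
truth = sample.lesion_mask_fine.astype(bool)
overlap = (desc.fine.astype(bool) & truth).sum()
print(f"fine mask: {int(desc.fine.sum())} px, {overlap} overlapping the "
      f"{int(truth.sum())} true fine-lesion px")
print(f"coarse mask: {int(desc.coarse.sum())} px; saliency max "
      f"{desc.saliency.max():.4f}")

# the stacked descriptor is the D(x) conditioning input of the generator
print("descriptor tensor shape:", desc.stack().shape)
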