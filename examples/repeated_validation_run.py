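"""Repeated random-split validation of a segmentation backend.

Splits 12 synthetic tiles 60/20/20 into train/test/left-out sets,
repeats 10 times with incremented seeds, and prints the per-run metric
table plus the arithmetic-mean row — the structure used to flag
overfitting or selection bias.  With the perfect colour-rule oracle
every entry is 100.
"""

from skinquant import SplitSpec, SynthParams, generate_section
from skinquant.evaluation import repeated_validation
from skinquant.segmentation import ColorRuleOracle

dataset = []
for i in range(12):
    s = generate_section(SynthParams(seed=i, width=96, height=96, n_cells=5,
                                     noise_std=0.0))
    dataset.append((s.tile, s.tissue))

report = repeated_validation(
    dataset, lambda pairs, seed: ColorRuleOracle("tissue"),
    SplitSpec(fractions=(0.6, 0.2, 0.2), seed=0), k=10,
    classes=[1, 2, 3, 4], tolerance=0)

header = ["GlobalAccuracy", "MeanAccuracy", "MeanIoU", "WeightedIoU",
          "MeanBFScore"]
print("run  " + "  ".join(f"{h:>14s}" for h in header))
for i, row in enumerate(report.folds, start=1):
    print(f"{i:3d}  " + "  ".join(f"{row.as_dict()[h]:14.2f}" for h in header))
print("avg  " + "  ".join(f"{report.average.as_dict()[h]:14.2f}"
                          for h in header))
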