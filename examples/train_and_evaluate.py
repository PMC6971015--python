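"""Small leave-one-bulb-out benchmark comparing the three regressors.

Simulates 6 bulbs x 15 poses, then for each regressor trains on five
bulbs and tests on the held-out one (every fold), reporting the median
held-out 2D angle error. The neural network and kernel ELM should beat
kernel SVR by a wide margin. A full-size run (20 bulbs x 50 poses, with
multi-pass re-imaging and the 30-degree success criterion) is what
scripts/acceptance.py performs.
"""

import time

import numpy as np

from bulbdir.phantom import make_dataset
from bulbdir.pipeline import leave_one_out_2d_errors, triplet_features

t0 = time.perf_counter()
dataset = make_dataset(6, 15, seed=1, size=96, voxel_size=0.667,
                       n_pixels=128, pixel_size=0.7)
print(f"simulated {len(dataset.triplets)} triplets "
      f"({3 * len(dataset.triplets)} radiographs) in {time.perf_counter() - t0:.0f}s")

cache = {id(t): triplet_features(t) for t in dataset.triplets}
for kind in ("ann", "elm", "svr"):
    t0 = time.perf_counter()
    errs = leave_one_out_2d_errors(dataset, kind, seed=2, features_cache=cache)
    print(f"{kind}: median held-out 2D error {np.median(errs):6.2f} deg "
          f"(mean {errs.mean():6.2f}) in {time.perf_counter() - t0:.0f}s")
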