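"""Serial feature fusion and reduction accounting.

Builds four small feature blocks named after the benchmark extractor slots
(FV1..FV4), fuses the standard combinations, and shows the reduction
percentage a selector report would carry.
"""

import numpy as np

from lesionselect import FeatureBlock, fuse, reduction_percentage, standard_combinations

rng = np.random.default_rng(0)
widths = {"FV1": 2, "FV2": 16, "FV3": 10, "FV4": 20}
blocks = [
    FeatureBlock(name=n, values=rng.normal(size=(12, w)), source_tag=f"emulated/{n}")
    for n, w in widths.items()
]

for fused in standard_combinations(blocks):
    print(f"{fused.combination_id:<18} fused width {fused.d_fused}")

pair = fuse(blocks[1:3])
print(
    f"\nkeeping 9 of {pair.d_fused} fused columns -> "
    f"reduction {reduction_percentage(pair.d_fused, 9)}%"
)
# The reduction percentage is 100·(1 − kept/input), rounded half away from
# zero — the single summary number reported per selection run.
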