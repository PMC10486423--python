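"""Published reference figures for the dermoscopy fusion/selection benchmarks.

These constants record the printed results of the PH2 / ISIC-MSK / ISIC-UDA
experiments that this toolkit's pipeline models: the widths of the four deep
feature blocks, the five serial-fusion combinations, the per-dataset
input/output dimensions with their printed reduction percentages, the
per-combination average reductions, and one representative classifier metric
row.  They serve as arithmetic cross-checks for the fusion accounting and the
metric identities — the toolkit never needs the underlying images.
"""

from __future__ import annotations

# Widths of the four deep-feature blocks (fully-connected / average-pooling
# layer outputs of DarkNet53, InceptionV3, InceptionResNetV2, DenseNet201).
EXTRACTOR_WIDTHS: dict[str, int] = {"FV1": 2, "FV2": 1536, "FV3": 1026, "FV4": 1920}

# The five serial-fusion combinations, in reporting order.
STANDARD_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("FV2", "FV3"),
    ("FV3", "FV4"),
    ("FV2", "FV4"),
    ("FV2", "FV3", "FV4"),
    ("FV1", "FV2", "FV3", "FV4"),
)

# Per-dataset training-set sizes under the 70:30 hold-out split.
TRAIN_SIZES: dict[str, int] = {"PH2": 140, "ISIC-MSK": 201, "ISIC-UDA": 271}

# (dataset, combination id, input dim, output dim, printed reduction %).
PUBLISHED_REDUCTIONS: tuple[tuple[str, str, int, int, int], ...] = (
    ("PH2", "FV2-FV3", 2562, 948, 63),
    ("PH2", "FV3-FV4", 2946, 884, 70),
    ("PH2", "FV2-FV4", 3456, 380, 89),
    ("PH2", "FV2-FV3-FV4", 4482, 583, 87),
    ("PH2", "FV1-FV2-FV3-FV4", 4484, 628, 88),
    ("ISIC-MSK", "FV2-FV3", 2562, 589, 77),
    ("ISIC-MSK", "FV3-FV4", 2946, 295, 90),
    ("ISIC-MSK", "FV2-FV4", 3456, 242, 93),
    ("ISIC-MSK", "FV2-FV3-FV4", 4482, 403, 91),
    ("ISIC-MSK", "FV1-FV2-FV3-FV4", 4484, 179, 96),
    ("ISIC-UDA", "FV2-FV3", 2562, 436, 83),
    ("ISIC-UDA", "FV3-FV4", 2946, 383, 87),
    ("ISIC-UDA", "FV2-FV4", 3456, 346, 90),
    ("ISIC-UDA", "FV2-FV3-FV4", 4482, 538, 88),
    ("ISIC-UDA", "FV1-FV2-FV3-FV4", 4484, 448, 90),
)

# Rows whose printed percentage disagrees with the arithmetic on their own
# printed dimensions (100·(1−628/4484) rounds to 86, not the printed 88).
KNOWN_INCONSISTENT_ROWS: frozenset[tuple[str, str]] = frozenset(
    {("PH2", "FV1-FV2-FV3-FV4")}
)

# Printed per-combination average reduction percentages (mean over the three
# datasets).  Two of these were truncated rather than rounded in print: the
# exact means for FV2-FV4 and FV2-FV3-FV4 are 90.67 and 88.67.
PUBLISHED_MEAN_REDUCTIONS: dict[str, float] = {
    "FV2-FV3": 74.33,
    "FV3-FV4": 82.33,
    "FV2-FV4": 90.66,
    "FV2-FV3-FV4": 88.66,
    "FV1-FV2-FV3-FV4": 91.33,
}

# One representative published metric row (linear SVM on PH2): accuracy %,
# sensitivity, specificity, FNR, FPR, F1.  Used to check the FNR = 1 − TPR
# identity against printed values.
LINEAR_SVM_PH2_ROW: dict[str, float] = {
    "accuracy_pct": 88.13,
    "sensitivity": 0.833,
    "specificity": 0.941,
    "fnr": 0.167,
    "fpr": 0.058,
    "f1": 0.888,
}
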