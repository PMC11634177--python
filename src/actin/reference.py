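"""Published per-cell-line benchmark metrics of the original ACTIN release.

The original models were trained on LINCS L1000 per-cell-line perturbation
data; their reported test sample sizes (perturbation instances) and
up/down-regulation AUCs are bundled here so the weighted "ACTIN-ALL"
aggregation can be computed and checked without access to that corpus.
Each row: cell line -> (sample_size, roc_auc_down, pr_auc_down, roc_auc_up,
pr_auc_up).
"""

from __future__ import annotations

CELL_LINE_METRICS: dict[str, tuple[int, float, float, float, float]] = {
    "VCAP":   (349, 0.7623, 0.8550, 0.7191, 0.5101),
    "PC3":    (601, 0.7721, 0.8689, 0.7612, 0.5895),
    "YAPC":   (140, 0.7651, 0.8378, 0.7318, 0.5464),
    "MCF7":   (758, 0.7939, 0.8782, 0.7758, 0.6123),
    "HT29":   (385, 0.7536, 0.8397, 0.7195, 0.5684),
    "HELA":   (172, 0.7306, 0.8337, 0.6782, 0.4739),
    "HCC515": (299, 0.7189, 0.8269, 0.7021, 0.5416),
    "HA1E":   (480, 0.7646, 0.8457, 0.7423, 0.5906),
    "A549":   (285, 0.7548, 0.8881, 0.7074, 0.5024),
    "A375":   (492, 0.7963, 0.8704, 0.7687, 0.6228),
}

#: Reported weighted "ACTIN-ALL" row for the four metric columns.
ACTIN_ALL_REPORTED = {
    "roc_auc_down": 0.7684,
    "pr_auc_down": 0.8596,
    "roc_auc_up": 0.7419,
    "pr_auc_up": 0.5727,
}


def metric_columns():
    """(sample_sizes, {metric_name: values}) in a fixed cell-line order."""
    order = list(CELL_LINE_METRICS)
    sizes = [CELL_LINE_METRICS[c][0] for c in order]
    cols = {
        "roc_auc_down": [CELL_LINE_METRICS[c][1] for c in order],
        "pr_auc_down": [CELL_LINE_METRICS[c][2] for c in order],
        "roc_auc_up": [CELL_LINE_METRICS[c][3] for c in order],
        "pr_auc_up": [CELL_LINE_METRICS[c][4] for c in order],
    }
    return sizes, cols
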