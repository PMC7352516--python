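"""Published per-feature AUC/p values used as worked arithmetic inputs.

A compact excerpt of a reference prognostic table (feature x grey-level
range, AUCs with significance at p <= 0.05) against which the range-summary
improvement rule is checked cell by cell.  ``None`` marks values that were
not reported.  Stored as (auc, significant) pairs.
"""

import numpy as np
import pandas as pd

# columns used by the worked cells; "0-255" is the original-image baseline
_GLCM = {
    #            0-255          160-180
    "asm":        ((0.77, True), (0.68, True)),
    "contrast":   ((0.39, False), (0.31, True)),
    "correlation": ((0.60, False), (0.71, True)),
    "idm":        ((0.75, True), (0.68, True)),
    "entropy":    ((0.28, True), (0.32, True)),
}
_FRACTAL = {
    #            0-255          200-220
    "d_b":       ((0.37, False), (0.35, True)),
    "se_d_b":    ((0.49, False), (0.55, False)),
    "lam":       ((0.70, True), (0.65, True)),
}
_FIRST_ORDER_180_200 = {
    #            0-255          180-200
    "area":      ((None, False), (0.40, False)),
    "mean":      ((0.36, True), (0.35, True)),
    "kurtosis":  ((0.67, True), (0.59, False)),
}
_FIRST_ORDER_240_255 = {
    #            0-255          240-255
    "area":      ((None, False), (0.61, False)),
    "mean":      ((0.36, True), (0.68, True)),
    "kurtosis":  ((0.67, True), (0.69, True)),
}


def _frames(data: dict, range_label: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(auc_table, p_table) for one family block; p encodes the star flag."""
    auc = {}
    p = {}
    for feat, ((a0, s0), (a1, s1)) in data.items():
        auc[feat] = {"0-255": np.nan if a0 is None else a0, range_label: a1}
        p[feat] = {"0-255": 0.01 if s0 else 0.5, range_label: 0.01 if s1 else 0.5}
    return pd.DataFrame(auc).T, pd.DataFrame(p).T


#: (family, range_label, auc_table, p_table, expected improvement sum)
WORKED_IMPROVEMENT_CELLS = [
    ("glcm", "160-180", *_frames(_GLCM, "160-180"), 0.19),
    ("fractal", "200-220", *_frames(_FRACTAL, "200-220"), 0.02),
    ("first_order", "180-200", *_frames(_FIRST_ORDER_180_200, "180-200"), 0.01),
    ("first_order", "240-255", *_frames(_FIRST_ORDER_240_255, "240-255"), 0.06),
]
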