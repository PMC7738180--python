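"""Hemispheric lateralization indices and their across-subject association.

The lateralization index (LI) of a thresholded contrast map is
``(n_L - n_R) / (n_L + n_R)`` where ``n_H`` counts suprathreshold (FDR
q < 0.05) vertices in hemisphere H: +1 is fully left-lateralized, -1 fully
right.  A magnitude-weighted variant (summed |statistic| instead of counts)
is available by flag.  Group inference is a one-sample t against 0; the
code-language association is the OLS R^2 across subjects with its F-test p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import BinaryActivationMap, VertexMap

__all__ = [
    "LateralityResult",
    "lateralization_index",
    "li_group_test",
    "li_association",
    "li_table",
]


@dataclass
class LateralityResult:
    contrast: str
    per_subject: np.ndarray
    mean: float
    t: float
    p: float
    df: int


def lateralization_index(m: BinaryActivationMap | VertexMap, weighted: bool = False) -> float:
    """LI = (left - right) / (left + right) suprathreshold activation.

    With ``weighted=False`` (default) activation is the suprathreshold vertex
    count of a binary map; with ``weighted=True`` it is the summed absolute
    statistic of a vertex map.
    """
    if weighted:
        left = float(np.abs(m.hemi("L")).sum())
        right = float(np.abs(m.hemi("R")).sum())
    else:
        if not isinstance(m, BinaryActivationMap):
            raise TypeError("count-based LI requires a thresholded (binary) map")
        left = float(m.hemi("L").sum())
        right = float(m.hemi("R").sum())
    if m.hemi("L").size == 0 or m.hemi("R").size == 0:
        raise ValueError("both hemispheres must be represented")
    total = left + right
    if total == 0:
        raise ValueError("LI undefined: no suprathreshold activation in either hemisphere")
    return (left - right) / total


def li_group_test(lis: np.ndarray, contrast: str = "") -> LateralityResult:
    """Two-sided one-sample t-test of subject LIs against 0 (df = n - 1)."""
    lis = np.asarray(lis, dtype=float)
    if lis.size < 2:
        raise ValueError("need at least two subjects")
    if np.allclose(lis, lis[0]) and not np.allclose(lis, 0):
        raise ValueError("zero variance across subjects")
    if np.allclose(lis, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(lis, 0.0)
    return LateralityResult(contrast=contrast, per_subject=lis, mean=float(lis.mean()),
                            t=float(t), p=float(p), df=lis.size - 1)


def li_association(lis_code: np.ndarray, lis_language: np.ndarray) -> tuple[float, float]:
    """OLS R^2 (and F-test p) of code LIs regressed on language LIs across subjects."""
    x = np.asarray(lis_language, dtype=float)
    y = np.asarray(lis_code, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one of the LI vectors")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def li_table(binary_maps: dict[str, dict[str, BinaryActivationMap]]) -> pd.DataFrame:
    """Tidy LI table from ``{subject: {contrast: binary map}}``: one row per cell."""
    rows = []
    for subject, maps in binary_maps.items():
        for contrast, m in maps.items():
            n_l, n_r = int(m.hemi("L").sum()), int(m.hemi("R").sum())
            rows.append(
                {
                    "subject": subject,
                    "contrast": contrast,
                    "n_L": n_l,
                    "n_R": n_r,
                    "LI": lateralization_index(m),
                }
            )
    return pd.DataFrame(rows)
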