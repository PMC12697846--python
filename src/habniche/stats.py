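"""Small statistical helpers shared by the comparison modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def paired_t(a, b) -> tuple[float, float]:
    """Paired t-test robust to degenerate input.

    Identical vectors (all differences zero) are reported as no difference
    (t=0, p=1).  Fewer than 3 pairs gives NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3:
        return float("nan"), float("nan")
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0
    if np.ptp(d) == 0:  # constant nonzero difference: overwhelming evidence
        return np.inf if d[0] > 0 else -np.inf, 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def compact_letter_display(
    levels: list, significant: set[tuple]
) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered pairs of levels judged different; levels
    sharing a letter are not significantly different.
    """
    sets: list[set] = [set(levels)]
    for a, b in significant:
        nxt = []
        for s in sets:
            if a in s and b in s:
                nxt.append(s - {a})
                nxt.append(s - {b})
            else:
                nxt.append(s)
        # absorb subsets
        nxt = [s for s in nxt if s]
        sets = [
            s for i, s in enumerate(nxt)
            if not any(s < t or (s == t and i > j) for j, t in enumerate(nxt))
        ]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {lv: "" for lv in levels}
    ordered = sorted(sets, key=lambda s: min(levels.index(x) for x in s))
    for letter, s in zip(letters, ordered):
        for lv in s:
            out[lv] += letter
    return {lv: "".join(sorted(v)) for lv, v in out.items()}
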