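"""Cross-platform validation: array log-ratios vs bisulphite percent methylation.

HELP log2(HpaII/MspI) ratios and bisulphite percent-methylation values
measure the same quantity with opposite polarity (high ratio =
hypomethylated = low percent), so agreement shows up as a strongly
negative Pearson correlation across loci.  Site-level group differences
in percent methylation are tested with an unpaired t-test (default) or
an exact Mann-Whitney test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["platform_concordance", "site_difference_test"]


def platform_concordance(paired: pd.DataFrame) -> dict:
    """Pearson correlation between log-ratio and percent across loci.

    ``paired`` needs columns ``log_ratio`` and ``percent`` (one row per
    locus, e.g. sample-averaged); >= 3 complete rows required.  Returns
    the correlation (expected negative), its p-value, the least-squares
    line, and per-locus residuals from that line.
    """
    df = paired.dropna(subset=["log_ratio", "percent"])
    if len(df) < 3:
        raise ValueError("need >= 3 loci with both measurements")
    x = df["log_ratio"].to_numpy(dtype=float)
    y = df["percent"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis: correlation undefined")
    lin = sps.linregress(x, y)
    residuals = y - (lin.intercept + lin.slope * x)
    return {
        "r": float(lin.rvalue),
        "p": float(lin.pvalue),
        "slope": float(lin.slope),
        "intercept": float(lin.intercept),
        "residuals": pd.Series(residuals, index=df.index, name="residual"),
        "n": int(len(df)),
    }


def site_difference_test(
    case_percents,
    control_percents,
    method: str = "t",
) -> dict:
    """Group difference in percent methylation at one site.

    Returns mean(case) - mean(control) in percentage points and a
    two-sided p-value from an unpaired t-test (``method='t'``), an exact
    Mann-Whitney test (``'mannwhitney'``), or ``'both'``.  Identical
    constant groups give difference 0, p = 1.
    """
    case = np.asarray(case_percents, dtype=float)
    ctrl = np.asarray(control_percents, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 values per group")
    if method not in ("t", "mannwhitney", "both"):
        raise ValueError("method must be 't', 'mannwhitney' or 'both'")
    diff = float(case.mean() - ctrl.mean())
    out: dict = {"difference": diff, "n_case": case.size, "n_control": ctrl.size}

    degenerate = np.ptp(case) == 0 and np.ptp(ctrl) == 0 and case[0] == ctrl[0]
    if method in ("t", "both"):
        if degenerate:
            out["p_t"] = 1.0
        else:
            out["p_t"] = float(sps.ttest_ind(case, ctrl, equal_var=True).pvalue)
    if method in ("mannwhitney", "both"):
        if degenerate:
            out["p_mannwhitney"] = 1.0
        else:
            out["p_mannwhitney"] = float(
                sps.mannwhitneyu(case, ctrl, alternative="two-sided", method="exact").pvalue
            )
    out["p"] = out.get("p_t", out.get("p_mannwhitney"))
    return out
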