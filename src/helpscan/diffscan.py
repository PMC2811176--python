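"""Per-locus differential-methylation scan with permutation calibration.

The scan runs a paired t-test per locus over matched case/control pairs
of log2(HpaII/MspI) ratios, calls methylation states against the zero
threshold, builds a permutation null by relabeling, picks a round
significance threshold below the permutation floor, and ranks loci by a
fold-change-weighted score.

The ranking score |mean paired difference| / (sd of paired differences +
s0) deliberately weights the mean shift more heavily than the t statistic
does: s0 (default: the median paired-difference SD across loci) damps the
score of loci whose tiny variance would otherwise dominate.  Scores are
used only to order loci, never as probabilities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_model import MethylationMatrix, SampleTable

__all__ = [
    "RankingConfig",
    "PermutationNull",
    "call_state",
    "paired_t_scan",
    "unpaired_t_scan",
    "rank_scores",
    "permutation_null",
    "perm_locus_pvalues",
    "significance_threshold",
    "select_candidates",
]

STATE_METHYLATED = "methylated"
STATE_HYPOMETHYLATED = "hypomethylated"
STATE_BOUNDARY = "boundary"


def call_state(ratio: float):
    """Methylation state from a log2(HpaII/MspI) ratio, zero-threshold rule.

    Below zero the HpaII representation is depleted (fragment methylated);
    above zero it is enriched (hypomethylated).  Exactly zero is a
    boundary call, excluded from state-change summaries.  Missing ratios
    yield a missing state (None).
    """
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return None
    if ratio < 0:
        return STATE_METHYLATED
    if ratio > 0:
        return STATE_HYPOMETHYLATED
    return STATE_BOUNDARY


def _paired_diffs(matrix: MethylationMatrix, samples: SampleTable) -> tuple[np.ndarray, list[str], list[str]]:
    samples.check_against_matrix(matrix)
    pairs = samples.pairs()
    case_ids = [c for c, _ in pairs]
    ctrl_ids = [c for _, c in pairs]
    case = matrix.values[case_ids].to_numpy(dtype=float)
    ctrl = matrix.values[ctrl_ids].to_numpy(dtype=float)
    return case - ctrl, case_ids, ctrl_ids


def _t_from_diffs(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t over a loci x pairs difference matrix.

    Returns (t, p, mean_diff, sd_diff, k_complete).  Loci with < 2
    complete pairs get NaN t/p; zero-variance loci with nonzero mean get
    NaN p (flagged upstream) since the t reference is undefined, while
    all-zero differences give t = 0, p = 1.
    """
    complete = ~np.isnan(diffs)
    k = complete.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(complete, diffs, np.nan), axis=1)
        sd = np.nanstd(np.where(complete, diffs, np.nan), axis=1, ddof=1)
    t = np.full(diffs.shape[0], np.nan)
    p = np.full(diffs.shape[0], np.nan)
    ok = (k >= 2) & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(k[ok]))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), k[ok] - 1)
    # two-sided p can round to 0 in double precision only for |t| beyond
    # any realistic scan; clamp to the smallest positive float so p in (0, 1]
    p[ok] = np.maximum(p[ok], np.finfo(float).tiny)
    zero = (k >= 2) & (sd == 0) & (mean == 0)
    t[zero] = 0.0
    p[zero] = 1.0
    mean[k < 2] = np.nan
    sd[k < 2] = np.nan
    return t, p, mean, sd, k


def paired_t_scan(matrix: MethylationMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-locus paired t-test of case minus matched-control differences.

    Returns a LocusStats DataFrame indexed by locus key with columns
    ``mean_case, mean_control, difference, sd_paired_diff, t, p,
    n_complete_pairs, degenerate, state_case, state_control``.  The test
    statistic is mean(diff) / (sd(diff)/sqrt(k)) over the k complete
    pairs, referred to a t distribution with k-1 degrees of freedom
    (two-sided).
    """
    diffs, case_ids, ctrl_ids = _paired_diffs(matrix, samples)
    t, p, mean_d, sd_d, k = _t_from_diffs(diffs)
    mean_case = matrix.values[case_ids].mean(axis=1, skipna=True).to_numpy()
    mean_ctrl = matrix.values[ctrl_ids].mean(axis=1, skipna=True).to_numpy()
    degenerate = (k >= 2) & (sd_d == 0) & (mean_d != 0)
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "difference": mean_case - mean_ctrl,
            "sd_paired_diff": sd_d,
            "t": t,
            "p": p,
            "n_complete_pairs": k.astype(int),
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    out["state_case"] = [call_state(v) for v in mean_case]
    out["state_control"] = [call_state(v) for v in mean_ctrl]
    return out


def unpaired_t_scan(matrix: MethylationMatrix, case_ids: list[str], ctrl_ids: list[str]) -> pd.DataFrame:
    """Per-locus two-sided equal-variance two-sample t-test (no pairing)."""
    case = matrix.values[list(case_ids)].to_numpy(dtype=float)
    ctrl = matrix.values[list(ctrl_ids)].to_numpy(dtype=float)
    res = sps.ttest_ind(case, ctrl, axis=1, equal_var=True, nan_policy="omit")
    return pd.DataFrame(
        {
            "t": np.asarray(res.statistic, dtype=float),
            "p": np.maximum(np.asarray(res.pvalue, dtype=float), np.finfo(float).tiny),
            "difference": np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1),
        },
        index=matrix.values.index,
    )


@dataclass
class RankingConfig:
    """Configuration of the fold-change-weighted ranking statistic.

    ``s0`` is the non-negative stabilization constant in log2 units; if
    None it defaults to the median ``sd_paired_diff`` over all loci.  The
    ``sam_like`` variant is the canonical score.
    """

    s0: float | None = None
    variant: str = "sam_like"

    def __post_init__(self) -> None:
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.variant != "sam_like":
            raise ValueError(f"unknown ranking variant: {self.variant!r}")


def rank_scores(
    matrix: MethylationMatrix,
    samples: SampleTable,
    config: RankingConfig | None = None,
) -> pd.Series:
    """Fold-change-weighted rank score per locus.

    score = |mean paired difference| / (sd_paired_diff + s0).  With both
    the spread and s0 zero the score is +inf (the locus ranks first).
    Rank-only: never interpret as a probability.
    """
    config = config or RankingConfig()
    diffs, _, _ = _paired_diffs(matrix, samples)
    _, _, mean_d, sd_d, _ = _t_from_diffs(diffs)
    s0 = config.s0
    if s0 is None:
        s0 = float(np.nanmedian(sd_d))
    denom = sd_d + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs(mean_d) / denom
    score[(denom == 0)] = np.inf
    score[(denom == 0) & (mean_d == 0)] = 0.0
    score[np.abs(mean_d) == 0] = 0.0
    return pd.Series(score, index=matrix.values.index, name="rank_score")


@dataclass
class PermutationNull:
    """Null distribution of the scan under relabeled group assignments."""

    scheme: str
    n_perm: int
    seed: int | None
    min_p: np.ndarray  # per-permutation minimum p over loci
    p_matrix: np.ndarray | None = None  # (n_perm, n_loci) when retained
    exhaustive: bool = False
    abs_t_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.p_matrix is not None:
            if not np.allclose(self.min_p, np.nanmin(self.p_matrix, axis=1)):
                raise ValueError("min_p inconsistent with p_matrix")

    @property
    def overall_min_p(self) -> float:
        return float(np.nanmin(self.min_p))


def _sign_patterns_exhaustive(k: int) -> np.ndarray:
    """All 2^k - 1 non-identity within-pair sign flips (identity = all +1)."""
    pats = np.array(list(itertools.product([1.0, -1.0], repeat=k)))
    keep = ~(pats == 1.0).all(axis=1)
    return pats[keep]


def permutation_null(
    matrix: MethylationMatrix,
    samples: SampleTable,
    n_perm: int,
    scheme: str = "within_pair_flip",
    seed: int = 0,
    keep_pvectors: bool = True,
) -> PermutationNull:
    """Build the permutation null of the per-locus scan.

    ``within_pair_flip`` independently swaps the case/control labels
    within each pair (equivalently flips the sign of that pair's
    difference); when 2^k <= n_perm all 2^k - 1 non-identity sign
    patterns are enumerated instead of sampled.  ``full_relabel``
    shuffles group labels across all samples preserving group sizes and
    re-runs an unpaired equal-variance t scan.  Each permutation's
    p-vector minimum is recorded; full p vectors are retained when
    ``keep_pvectors``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("within_pair_flip", "full_relabel"):
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    rng = np.random.default_rng(seed)

    if scheme == "within_pair_flip":
        diffs, _, _ = _paired_diffs(matrix, samples)
        k = diffs.shape[1]
        exhaustive = 2**k - 1 <= n_perm
        if exhaustive and k > 20:
            raise ValueError("exhaustive enumeration with k > 20 pairs: use sampling")
        if exhaustive:
            signs = _sign_patterns_exhaustive(k)
        else:
            # the identity and the global negation are excluded from
            # sampling: for a two-sided statistic the all-flipped pattern
            # reproduces the observed |t| exactly and carries no null
            # information
            signs = rng.choice([1.0, -1.0], size=(n_perm, k))
            degenerate = (signs == signs[:, :1]).all(axis=1)
            while degenerate.any():
                signs[degenerate] = rng.choice([1.0, -1.0], size=(int(degenerate.sum()), k))
                degenerate = (signs == signs[:, :1]).all(axis=1)
        pvecs = np.empty((signs.shape[0], diffs.shape[0]))
        tvecs = np.empty_like(pvecs)
        for i, s in enumerate(signs):
            t, p, _, _, _ = _t_from_diffs(diffs * s)
            pvecs[i] = p
            tvecs[i] = np.abs(t)
    else:
        all_ids = np.array(samples.sample_ids)
        n_case = len(samples.group_samples("case"))
        observed = set(samples.group_samples("case"))
        exhaustive = False
        pvecs_list, tvecs_list = [], []
        drawn = 0
        all_sample_set = set(all_ids)
        while drawn < n_perm:
            perm = rng.permutation(all_ids)
            pseudo_case = set(perm[:n_case])
            # skip the observed labeling and its complement: both reproduce
            # the observed two-sided statistics
            if pseudo_case == observed or pseudo_case == all_sample_set - observed:
                continue
            res = unpaired_t_scan(matrix, list(perm[:n_case]), list(perm[n_case:]))
            pvecs_list.append(res["p"].to_numpy())
            tvecs_list.append(np.abs(res["t"].to_numpy()))
            drawn += 1
        pvecs = np.array(pvecs_list)
        tvecs = np.array(tvecs_list)

    min_p = np.nanmin(pvecs, axis=1)
    return PermutationNull(
        scheme=scheme,
        n_perm=pvecs.shape[0],
        seed=seed,
        min_p=min_p,
        p_matrix=pvecs if keep_pvectors else None,
        exhaustive=exhaustive,
        abs_t_matrix=tvecs if keep_pvectors else None,
    )


def perm_locus_pvalues(observed: pd.DataFrame, null: PermutationNull) -> pd.Series:
    """Per-locus permutation p-value: fraction of permuted |t| >= observed |t|.

    The identity labeling counts as one permutation (it always attains its
    own |t|), so p = (1 + #{null perms with |t_perm| >= |t_obs|}) /
    (n_perm + 1); for an exhaustive within-pair null this is the exact
    all-pattern fraction over 2^k sign assignments.
    """
    if null.abs_t_matrix is None:
        raise ValueError("permutation null was built without retained statistics")
    t_obs = np.abs(observed["t"].to_numpy())
    count = (null.abs_t_matrix >= t_obs[None, :]).sum(axis=0)
    p = (1.0 + count) / (null.n_perm + 1.0)
    return pd.Series(p, index=observed.index, name="perm_p")


def _threshold_ladder(floor: float):
    """Yield 5*10^-k, 10^-k for k = 1, 2, ... down past ``floor``."""
    k = 1
    while True:
        for v in (5.0 * 10.0**-k, 10.0**-k):
            yield v
        if 10.0**-k < floor:
            return
        k += 1


def significance_threshold(observed: pd.DataFrame, null: PermutationNull) -> tuple[float, float]:
    """Largest round threshold strictly below the permutation minimum p.

    The ladder is {5*10^-k, 10^-k}; the returned alpha_star is the
    calibrated genome-wide significance cut: no locus in any permuted
    dataset reached a p-value below it.  Returns (alpha_star,
    permutation minimum p).

    Note: an *exhaustive* within-pair null contains the global sign flip,
    whose two-sided p-vector equals the observed one, so its minimum ties
    the observed minimum and the resulting threshold excludes every
    locus.  Calibrate on a sampled null (which excludes sign-equivalent
    patterns) or on ``full_relabel``; exhaustive nulls are meant for
    per-locus permutation p-values.
    """
    if null.n_perm < 1 or null.min_p.size == 0:
        raise ValueError("empty permutation null")
    floor = null.overall_min_p
    if not np.isfinite(floor) or floor <= 0:
        raise ValueError(f"invalid permutation minimum p: {floor}")
    alpha_star = None
    for v in _threshold_ladder(floor):
        if v < floor:
            alpha_star = v
            break
    if alpha_star is None:  # pragma: no cover - ladder generator runs past floor
        raise RuntimeError("threshold ladder exhausted")
    return alpha_star, floor


_HIST_BINS = np.linspace(0.0, 1.0, 21)  # fixed 0.05-wide p-value bins


def select_candidates(
    stats: pd.DataFrame,
    alpha_star: float,
    moderate_alpha: float,
) -> dict:
    """Two-tier candidate selection plus p-value histogram counts.

    Significant tier: p < alpha_star; moderate tier: alpha_star <= p <
    moderate_alpha.  Candidates sort by p ascending then |difference|
    descending.  Histogram counts use fixed 0.05-wide bins over [0, 1].
    """
    if moderate_alpha <= alpha_star:
        raise ValueError("moderate_alpha must exceed alpha_star")
    valid = stats.dropna(subset=["p"])
    order = valid.assign(_absdiff=valid["difference"].abs()).sort_values(
        ["p", "_absdiff"], ascending=[True, False]
    ).drop(columns="_absdiff")
    significant = order[order["p"] < alpha_star]
    moderate = order[(order["p"] >= alpha_star) & (order["p"] < moderate_alpha)]
    counts, edges = np.histogram(valid["p"].to_numpy(), bins=_HIST_BINS)
    return {
        "significant": significant,
        "moderate": moderate,
        "histogram": pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}),
        "alpha_star": alpha_star,
        "moderate_alpha": moderate_alpha,
    }
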