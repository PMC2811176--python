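"""Synthetic matched-cohort generator for HELP-style methylation matrices.

Emulates the statistical structure the downstream scan assumes: a bimodal
baseline of log2(HpaII/MspI) ratios (methylated fragments around -2,
hypomethylated around +2), a small planted fraction of differential loci
whose per-locus case shift is drawn Normal(0.60, 0.20) log2 units with a
random sign, and independent within-group noise of SD 0.32 on every
measurement.  Ground truth (which loci are differential and by how much)
is returned alongside the matrix so recovery can be asserted exactly.

What this emulates and what it does not: the generator reproduces the
marginal ratio distribution, the matched 5-vs-5 (or k-vs-k) design, the
effect-size distribution and noise level of a real cohort; it does not
model probe-level intensities, dye bias, fragment-length effects, or
spatial correlation along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AnnotationTrack,
    GeneModel,
    GenomicInterval,
    MethylationMatrix,
    SampleTable,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_cohort",
    "simulate_annotation_tracks",
    "simulate_bisulphite",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: per-locus case/control mean
    shifts ~ Normal(0.60, 0.20) log2 units among differential loci,
    within-group noise SD 0.32, and a two-component baseline mixture at
    -2.0 (methylated) / +2.0 (hypomethylated).
    """

    n_loci: int = 10_000
    n_pairs: int = 5
    frac_differential: float = 0.01
    effect_mean: float = 0.60
    effect_sd_across_loci: float = 0.20
    noise_sd: float = 0.32
    baseline_means: tuple[float, float] = (-2.0, 2.0)
    baseline_sds: tuple[float, float] = (0.6, 0.6)
    baseline_weight: float = 0.5  # probability of the methylated (first) component
    gender_effect: bool = False
    n_gender_loci: int = 0
    gender_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        for name in ("effect_sd_across_loci", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(sd <= 0 for sd in self.baseline_sds):
            raise ValueError("baseline_sds must be > 0")
        if not 0.0 <= self.baseline_weight <= 1.0:
            raise ValueError("baseline_weight must be in [0, 1]")
        if self.gender_effect and self.n_gender_loci < 1:
            raise ValueError("n_gender_loci must be >= 1 when gender_effect is set")
        if self.n_gender_loci > self.n_loci:
            raise ValueError("n_gender_loci must not exceed n_loci")


@dataclass
class TruthTable:
    """Ground truth for a simulated cohort (one row per locus)."""

    table: pd.DataFrame  # index: locus key; columns: is_differential, true_shift, is_gender

    @property
    def differential_loci(self) -> list[str]:
        return list(self.table.index[self.table["is_differential"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="locus", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", index_col="locus")
        df["is_differential"] = df["is_differential"].astype(bool)
        df["is_gender"] = df["is_gender"].astype(bool)
        return cls(df)


_FRAGMENT_LEN = 500
_FRAGMENT_GAP = 1500


def _locus_keys(n_loci: int, n_gender: int) -> tuple[list[str], np.ndarray]:
    """Lay loci along chr1 (autosomal) and chrX (gender-linked), spaced apart."""
    keys = []
    is_gender = np.zeros(n_loci, dtype=bool)
    n_auto = n_loci - n_gender
    for i in range(n_auto):
        start = 10_000 + i * (_FRAGMENT_LEN + _FRAGMENT_GAP)
        keys.append(GenomicInterval("chr1", start, start + _FRAGMENT_LEN).to_key())
    for j in range(n_gender):
        start = 10_000 + j * (_FRAGMENT_LEN + _FRAGMENT_GAP)
        keys.append(GenomicInterval("chrX", start, start + _FRAGMENT_LEN).to_key())
        is_gender[n_auto + j] = True
    return keys, is_gender


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, SampleTable, TruthTable]:
    """Generate a matched case/control ratio matrix with known ground truth.

    Per locus a baseline is drawn from the two-component mixture; for the
    planted differential fraction a signed shift ~ Normal(effect_mean,
    effect_sd_across_loci) (sign +/- with probability 1/2) is added to the
    case samples only; every cell then receives independent
    Normal(0, noise_sd) measurement noise.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_loci, config.n_pairs
    n_gender = config.n_gender_loci if config.gender_effect else 0
    keys, is_gender = _locus_keys(n, n_gender)

    # baseline mixture
    comp = rng.random(n) < config.baseline_weight
    baseline = np.where(
        comp,
        rng.normal(config.baseline_means[0], config.baseline_sds[0], size=n),
        rng.normal(config.baseline_means[1], config.baseline_sds[1], size=n),
    )

    # planted differential loci (autosomal only)
    auto_idx = np.flatnonzero(~is_gender)
    n_diff = int(round(config.frac_differential * len(auto_idx)))
    diff_idx = rng.choice(auto_idx, size=n_diff, replace=False) if n_diff else np.array([], int)
    shift = np.zeros(n)
    if n_diff:
        magnitude = rng.normal(config.effect_mean, config.effect_sd_across_loci, size=n_diff)
        sign = rng.choice([-1.0, 1.0], size=n_diff)
        shift[diff_idx] = sign * magnitude

    case_ids = [f"case_{i + 1}" for i in range(k)]
    ctrl_ids = [f"ctrl_{i + 1}" for i in range(k)]
    genders = [("M" if i % 2 == 0 else "F") for i in range(k)]

    # signal per (locus, sample): baseline + case-only shift (+ gender shift)
    cols = {}
    for i, sid in enumerate(case_ids):
        mean = baseline + shift
        if n_gender and genders[i] == "M":
            mean = mean + np.where(is_gender, config.gender_shift, 0.0)
        cols[sid] = mean + rng.normal(0.0, config.noise_sd, size=n)
    for i, sid in enumerate(ctrl_ids):
        mean = baseline.copy()
        if n_gender and genders[i] == "M":
            mean = mean + np.where(is_gender, config.gender_shift, 0.0)
        cols[sid] = mean + rng.normal(0.0, config.noise_sd, size=n)

    values = pd.DataFrame(cols, index=pd.Index(keys, name="locus"))
    matrix = MethylationMatrix(values)

    records = pd.DataFrame(
        {
            "sample_id": case_ids + ctrl_ids,
            "group": ["case"] * k + ["control"] * k,
            "pair_id": [f"P{i + 1:02d}" for i in range(k)] * 2,
            "gender": genders + genders,
            "ethnicity": ["synthetic"] * (2 * k),
        }
    )
    samples = SampleTable(records)

    truth = pd.DataFrame(
        {
            "is_differential": shift != 0.0,
            "true_shift": shift,
            "is_gender": is_gender,
        },
        index=values.index,
    )
    return matrix, samples, TruthTable(truth)


def simulate_annotation_tracks(
    config: SimulationConfig,
    truth: TruthTable,
    kinds: Sequence[str] = ("CpG_island", "CG_cluster", "conserved", "repeat_RT"),
    frac_per_kind: float = 0.2,
) -> tuple[list[AnnotationTrack], list[GeneModel], dict[str, dict[str, bool]]]:
    """Build toy annotation tracks and gene models over the simulated loci.

    For each requested feature kind, a deterministic subset of loci gets a
    covering interval, so the true overlap map is known by construction.
    Gene models are planted so some loci fall in the 10 kb promoter window
    (TSS downstream of the locus on +, upstream on -) and some inside gene
    bodies.  Returns (tracks, genes, planted_map) where
    ``planted_map[kind][locus]`` is the intended overlap flag.
    """
    if not kinds:
        return [], [], {}
    rng = np.random.default_rng(config.seed + 1)
    loci = list(truth.table.index)
    intervals = {k: GenomicInterval.from_key(k) for k in loci}
    tracks: list[AnnotationTrack] = []
    planted: dict[str, dict[str, bool]] = {}
    for j, kind in enumerate(kinds):
        chosen = set(rng.choice(len(loci), size=max(1, int(frac_per_kind * len(loci))), replace=False))
        ivs = []
        flags = {}
        for i, key in enumerate(loci):
            hit = i in chosen
            flags[key] = hit
            if hit:
                iv = intervals[key]
                # cover the middle of the fragment; stays clear of neighbours
                ivs.append(GenomicInterval(iv.chrom, iv.start + 10, iv.end - 10))
        tracks.append(AnnotationTrack(f"synthetic_{kind}", kind, ivs))
        planted[kind] = flags

    genes: list[GeneModel] = []
    # promoter-planted genes: TSS 5 kb downstream of the locus end on + strand
    n_pro = min(5, len(loci))
    for i in range(n_pro):
        iv = intervals[loci[i]]
        tss = iv.end + 5_000
        genes.append(
            GeneModel(f"PROG{i + 1}", f"NM_9{i:04d}", GenomicInterval(iv.chrom, tss, tss + 2_000, "+"))
        )
    # body-planted genes: body covering the locus
    n_gb = min(5, max(0, len(loci) - n_pro))
    for i in range(n_gb):
        iv = intervals[loci[n_pro + i]]
        genes.append(
            GeneModel(
                f"BODYG{i + 1}", f"NM_8{i:04d}",
                GenomicInterval(iv.chrom, max(0, iv.start - 200), iv.end + 200, "+"),
            )
        )
    return tracks, genes, planted


def simulate_bisulphite(
    matrix: MethylationMatrix,
    link_midpoint: float = 0.0,
    link_slope: float = -1.0,
    noise_sd_percent: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Map log-ratios to percent methylation through a decreasing logistic link.

    percent = 100 * logistic(link_slope * (ratio - link_midpoint)) + noise,
    clamped to [0, 100].  The link is monotone decreasing in the ratio
    (high ratio = hypomethylated = low percent), matching the polarity of
    bisulphite readouts against HELP ratios.  Returns a loci x samples
    DataFrame of percentages.
    """
    if link_slope >= 0:
        raise ValueError("link_slope must be negative (ratio and percent are inversely related)")
    rng = np.random.default_rng(seed)
    ratios = matrix.values.to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        percent = 100.0 / (1.0 + np.exp(-link_slope * (ratios - link_midpoint)))
    if noise_sd_percent > 0:
        percent = percent + rng.normal(0.0, noise_sd_percent, size=percent.shape)
    percent = np.clip(percent, 0.0, 100.0)
    percent[np.isnan(ratios)] = np.nan
    return pd.DataFrame(percent, index=matrix.values.index, columns=matrix.values.columns)
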