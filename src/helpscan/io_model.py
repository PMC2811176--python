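"""Core data types and I/O for HELP-assay methylation analyses.

The central object is a loci x samples matrix of log2(HpaII/MspI) ratios,
where each locus is a genomic fragment (an interval on an assembly) and
each sample contributes one ratio per locus.  Low ratios indicate a
methylated fragment (HpaII could not cut), high ratios a hypomethylated
one.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open, the BED convention.
Human-readable locus keys of the form ``chr2:235526053-235526128`` are
1-based *inclusive* (the convention of genome-browser positions) and are
converted at the I/O boundary: a printed key ``chrom:a-b`` maps to the
internal interval ``(a-1, b)`` and serializes back to the identical text.

File formats
------------
* ratio matrix: TSV, header row of sample IDs, first column the locus key;
  missing values written as ``NA``.
* annotation tracks: BED3+ (already 0-based half-open, loaded verbatim).
* gene models: 6-column TSV ``symbol  transcript  chrom  start  end  strand``
  with 0-based half-open body coordinates.
* sample sheets: TSV with columns ``sample_id  group  pair_id  gender
  ethnicity``; ``group`` is ``case`` or ``control``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "MethylationMatrix",
    "SampleTable",
    "AnnotationTrack",
    "GeneModel",
    "FEATURE_KINDS",
    "MISSING_TOKEN",
    "read_ratio_matrix",
    "write_ratio_matrix",
    "read_intervals",
    "write_intervals",
    "read_gene_models",
    "write_gene_models",
    "read_sample_table",
    "write_sample_table",
]

MISSING_TOKEN = "NA"

FEATURE_KINDS = frozenset(
    {"CpG_island", "CG_cluster", "conserved", "repeat_RT", "repeat_LT", "other"}
)

_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome.

    ``strand`` is ``+``, ``-`` or ``.`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require start < end (0-based half-open)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open intersection of at least 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_key(cls, key: str, strand: str = ".") -> "GenomicInterval":
        """Parse a 1-based inclusive ``chrom:a-b`` locus key."""
        m = _KEY_RE.match(key.strip())
        if m is None:
            raise ValueError(f"malformed locus key: {key!r}")
        start = int(m.group("start")) - 1
        end = int(m.group("end"))
        return cls(m.group("chrom"), start, end, strand)

    def to_key(self) -> str:
        """Serialize back to the 1-based inclusive text form."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class MethylationMatrix:
    """Loci x samples table of log2(HpaII/MspI) ratios.

    ``values`` is a DataFrame indexed by locus key with one column per
    sample; missing ratios are NaN.  ``intervals`` maps each locus key to
    its genomic interval and is kept in the row order of ``values``.
    """

    values: pd.DataFrame
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate locus key: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        self.values.index.name = "locus"
        if not self.intervals:
            self.intervals = {k: GenomicInterval.from_key(k) for k in idx}
        elif set(self.intervals) != set(idx):
            raise ValueError("intervals do not match locus keys")

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(sample_ids)].copy(), dict(self.intervals))

    def drop_incomplete_loci(self) -> tuple["MethylationMatrix", int]:
        """Drop loci with any missing value; return (matrix, n_dropped)."""
        keep = self.values.notna().all(axis=1)
        dropped = int((~keep).sum())
        vals = self.values.loc[keep]
        ivals = {k: self.intervals[k] for k in vals.index}
        return MethylationMatrix(vals, ivals), dropped


@dataclass
class SampleTable:
    """Per-sample metadata encoding the matched case/control design."""

    records: pd.DataFrame  # columns: sample_id, group, pair_id, gender, ethnicity

    REQUIRED = ("sample_id", "group", "pair_id", "gender", "ethnicity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = self.records
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        bad_group = set(df["group"]) - {"case", "control"}
        if bad_group:
            raise ValueError(f"group labels must be case/control, got {sorted(bad_group)}")
        for pid, grp in df.groupby("pair_id"):
            groups = sorted(grp["group"])
            if groups != ["case", "control"]:
                raise ValueError(
                    f"pair {pid!r} must contain exactly one case and one control, "
                    f"got {list(grp['group'])}"
                )

    @property
    def n_pairs(self) -> int:
        return self.records["pair_id"].nunique()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """Ordered (case_id, control_id) tuples, sorted by pair_id."""
        out = []
        for pid, grp in sorted(self.records.groupby("pair_id"), key=lambda kv: str(kv[0])):
            case = grp.loc[grp["group"] == "case", "sample_id"].iloc[0]
            ctrl = grp.loc[grp["group"] == "control", "sample_id"].iloc[0]
            out.append((case, ctrl))
        return out

    def group_samples(self, group: str) -> list[str]:
        return list(self.records.loc[self.records["group"] == group, "sample_id"])

    def check_against_matrix(self, matrix: MethylationMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.samples)
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)}")


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals of one feature kind (e.g. CpG islands)."""

    name: str
    feature_kind: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(
                f"feature_kind {self.feature_kind!r} not in {sorted(FEATURE_KINDS)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript with a strand-aware transcription start site.

    On the + strand the TSS is the body start; on the - strand it is
    ``end - 1`` (the last base of the half-open body interval).
    """

    symbol: str
    transcript: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol}: strand must be '+' or '-'")

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_ratio_matrix(path: str | Path) -> MethylationMatrix:
    """Read a TSV ratio matrix (header = sample IDs, column 1 = locus keys).

    Locus keys are 1-based inclusive ``chrom:a-b`` text and are converted
    to internal 0-based half-open intervals.  Cells equal to ``NA`` become
    missing; any other non-numeric cell raises with its row and column.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate locus key in {path.name}: {dup!r}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell in {path.name} at locus {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        values[col] = converted
    intervals = {k: GenomicInterval.from_key(k) for k in values.index}
    return MethylationMatrix(values, intervals)


def write_ratio_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write a ratio matrix as TSV with ``NA`` for missing cells."""
    matrix.values.to_csv(
        Path(path), sep="\t", na_rep=MISSING_TOKEN, index_label="locus",
        lineterminator="\n",
    )


def read_intervals(path: str | Path, feature_kind: str, name: str | None = None) -> AnnotationTrack:
    """Read a BED3+ file into an AnnotationTrack (coordinates loaded verbatim)."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return AnnotationTrack(name or path.stem, feature_kind, intervals)


def write_intervals(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a 6-column TSV of gene models (symbol, transcript, chrom, start, end, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            symbol, transcript, chrom, start, end, strand = fields[:6]
            genes.append(
                GeneModel(symbol, transcript, GenomicInterval(chrom, int(start), int(end), strand))
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            fh.write(f"{g.symbol}\t{g.transcript}\t{b.chrom}\t{b.start}\t{b.end}\t{b.strand}\n")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.records.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")
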