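"""Genomic coordinate primitives and plain-text interval I/O.

Coordinates are 0-based, half-open throughout (BED dialect). Read
collections are kept as pandas DataFrames with columns ``chrom``,
``five_prime`` and ``strand`` — the 5′ position is the unit of evidence
coming out of the aligner; everything downstream (extension, dyads) is
derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "five_prime", "strand"]


class ChromSizes:
    """Ordered chromosome name -> length table.

    Lengths must be at least 10 kb: windows, flanks and read extension all
    assume chromosomes large relative to a nucleosome footprint.
    """

    MIN_LENGTH = 10_000

    def __init__(self, sizes: dict[str, int]):
        if not sizes:
            raise ValueError("at least one chromosome required")
        if len(set(sizes)) != len(sizes):
            raise ValueError("chromosome names must be unique")
        for name, length in sizes.items():
            if int(length) < self.MIN_LENGTH:
                raise ValueError(
                    f"chromosome {name!r} length {length} < {self.MIN_LENGTH}"
                )
        self._sizes = {str(k): int(v) for k, v in sizes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    @classmethod
    def read(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass
class FeatureSet:
    """A named set of labelled genomic intervals.

    ``intervals`` is a DataFrame with at least chrom/start/end; optional
    ``strand``, ``name`` and arbitrary attribute columns ride along. Used
    for peaks, histone-mark domains, repeats and transcript spans alike.
    """

    name: str
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not self.name:
            raise ValueError("FeatureSet name must be non-empty")
        if len(self.intervals):
            for col in ("chrom", "start", "end"):
                if col not in self.intervals.columns:
                    raise ValueError(f"intervals missing column {col!r}")
            if (self.intervals["start"] >= self.intervals["end"]).any():
                raise ValueError("all intervals must satisfy start < end")
        self.intervals = self.intervals.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> pd.DataFrame:
        mid = (
            self.intervals["start"]
            + (self.intervals["end"] - self.intervals["start"]) // 2
        )
        out = self.intervals[["chrom"]].copy()
        out["pos"] = mid.astype(int)
        if "strand" in self.intervals.columns:
            out["strand"] = self.intervals["strand"]
        else:
            out["strand"] = "."
        return out

    @classmethod
    def read_bed(cls, path, name: str | None = None) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
        df.columns = cols + list(df.columns[len(cols):])
        return cls(name or str(path), df)

    def write_bed(self, path) -> None:
        df = self.intervals.copy()
        if "name" not in df.columns:
            df["name"] = [f"{self.name}_{i}" for i in range(len(df))]
        if "score" not in df.columns:
            df["score"] = 0
        if "strand" not in df.columns:
            df["strand"] = "."
        df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def validate_reads(reads: pd.DataFrame, chroms: ChromSizes | None = None) -> pd.DataFrame:
    """Check a read table's schema and (optionally) coordinate bounds."""
    for col in READ_COLUMNS:
        if col not in reads.columns:
            raise ValueError(f"read table missing column {col!r}")
    if len(reads) and not reads["strand"].isin(["+", "-"]).all():
        raise ValueError("read strand must be '+' or '-'")
    if chroms is not None and len(reads):
        unknown = set(reads["chrom"].unique()) - set(chroms.names)
        if unknown:
            raise ValueError(f"reads on chromosomes absent from genome: {sorted(unknown)}")
    return reads


def read_reads_bed(path) -> pd.DataFrame:
    """Load a BED6 read file: each record anchors a read at its 5′ end.

    For plus-strand records the 5′ end is the BED start; for minus-strand
    records it is end-1.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if len(df) == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    five = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = pd.DataFrame(
        {"chrom": df["chrom"], "five_prime": five.astype(int), "strand": df["strand"]}
    )
    return validate_reads(out)


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    """Write reads as 1-bp BED6 records anchored at the 5′ end."""
    validate_reads(reads)
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(
            zip(reads["chrom"], reads["five_prime"], reads["strand"])
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tread_{i}\t0\t{strand}\n")
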