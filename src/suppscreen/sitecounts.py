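"""Per-site, per-sample base counts — the caller's sole evidence.

Counts are post-quality-filter by definition (base quality ≥ 30 upstream);
a quality-binned reader is provided for inputs that still carry a quality
column.  Allele frequency uses total site depth (all four bases) as the
denominator, and a site with zero depth has AF 0 for every allele.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "COUNT_COLUMNS",
    "BaseCountMatrix",
    "GroupDesign",
    "allele_frequency",
    "read_counts",
    "read_quality_binned_counts",
    "write_counts",
]

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["nA", "nC", "nG", "nT"]
_ALL_COLUMNS = ["contig", "pos", "ref", "sample", *COUNT_COLUMNS]

ROLE_SUPPRESSOR = "suppressor"
ROLE_CONTROL = "control"


@dataclass
class GroupDesign:
    """Sample-group design for one experiment: who is a suppressor, who a control."""

    experiment_id: str
    roles: dict[str, str]
    preset: str = "batch95"

    def __post_init__(self) -> None:
        bad = {s: r for s, r in self.roles.items() if r not in (ROLE_SUPPRESSOR, ROLE_CONTROL)}
        if bad:
            raise ValueError(f"invalid roles: {bad}")
        if not self.controls:
            raise ValueError(f"experiment {self.experiment_id!r} has no control sample")

    @property
    def samples(self) -> list[str]:
        return list(self.roles)

    @property
    def suppressors(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == ROLE_SUPPRESSOR]

    @property
    def controls(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == ROLE_CONTROL]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# experiment={self.experiment_id}\tpreset={self.preset}\n")
            fh.write("sample\trole\n")
            for s, r in self.roles.items():
                fh.write(f"{s}\t{r}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupDesign":
        experiment_id, preset = "experiment", "batch95"
        rows: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line.lstrip("# ").split("\t"):
                        if tok.startswith("experiment="):
                            experiment_id = tok.split("=", 1)[1]
                        elif tok.startswith("preset="):
                            preset = tok.split("=", 1)[1]
                    continue
                if not line or line == "sample\trole":
                    continue
                sample, role = line.split("\t")
                rows[sample] = role
        return cls(experiment_id, rows, preset)


class BaseCountMatrix:
    """Ordered per-(contig, pos, sample) A/C/G/T counts after quality filtering.

    Backed by a pandas DataFrame with columns
    ``contig, pos, ref, sample, nA, nC, nG, nT``.  Records are sorted by
    (contig, pos, sample) and the key (contig, pos, sample) is unique.
    Only sites with non-reference evidence (or otherwise of interest) need
    be present: an absent record means homozygous reference / no evidence.
    """

    def __init__(self, records: pd.DataFrame, validate: bool = True,
                 presorted: bool = False):
        missing = [c for c in _ALL_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if presorted:
            # trusted construction path (simulator): no copies, no re-sort
            self.records = records
            return
        df = records[_ALL_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        for c in COUNT_COLUMNS:
            df[c] = df[c].astype(np.int64)
        df = df.sort_values(["contig", "pos", "sample"], kind="mergesort").reset_index(drop=True)
        if validate:
            self._validate(df)
        self.records = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        neg = df[(df[COUNT_COLUMNS] < 0).any(axis=1)]
        if not neg.empty:
            r = neg.iloc[0]
            raise ValueError(
                f"negative count at {r['contig']}:{r['pos']} sample {r['sample']}"
            )
        bad_ref = ~df["ref"].isin(BASES)
        if bad_ref.any():
            r = df[bad_ref].iloc[0]
            raise ValueError(f"invalid ref base {r['ref']!r} at {r['contig']}:{r['pos']}")
        if df["pos"].le(0).any():
            raise ValueError("positions must be 1-based (found pos <= 0)")
        dup = df.duplicated(subset=["contig", "pos", "sample"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(
                f"duplicate record for {r['contig']}:{r['pos']} sample {r['sample']}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    def depth(self) -> pd.Series:
        return self.records[COUNT_COLUMNS].sum(axis=1)

    def subset_positions(self, keys: pd.DataFrame) -> "BaseCountMatrix":
        """Records at the (contig, pos) pairs in ``keys``."""
        merged = self.records.merge(keys[["contig", "pos"]].drop_duplicates(),
                                    on=["contig", "pos"], how="inner")
        return BaseCountMatrix(merged, validate=False)

    def write_tsv(self, path: str | Path, header_comments: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.records.to_csv(fh, sep="\t", index=False)


def allele_frequency(record: Mapping, allele: str) -> float:
    """Fraction of post-filter bases supporting ``allele`` at one (site, sample).

    Depth 0 yields AF 0 (uncovered sites never generate calls).
    """
    if allele not in BASES:
        raise ValueError(f"allele must be one of {BASES}, got {allele!r}")
    depth = sum(int(record[c]) for c in COUNT_COLUMNS)
    if depth == 0:
        return 0.0
    return int(record[f"n{allele}"]) / depth


def read_counts(path: str | Path, design: GroupDesign | None = None) -> BaseCountMatrix:
    """Read a count TSV (columns contig, pos, ref, sample, nA, nC, nG, nT).

    Validation errors name the offending line; if a design is given, samples
    not in the design are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"contig": str, "ref": str, "sample": str})
    missing = [c for c in _ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # line numbers for error messages: header + 1-based data rows (comments
    # shift them, but plain files are the common case)
    for c in COUNT_COLUMNS:
        if not pd.api.types.is_integer_dtype(df[c]):
            bad = pd.to_numeric(df[c], errors="coerce")
            idx = bad[bad.isna()].index
            if len(idx):
                raise ValueError(f"{path}: non-numeric count on data line {idx[0] + 2}")
            df[c] = bad.astype(np.int64)
    neg = (df[COUNT_COLUMNS] < 0).any(axis=1)
    if neg.any():
        raise ValueError(f"{path}: negative count on data line {neg.idxmax() + 2}")
    dup = df.duplicated(subset=["contig", "pos", "sample"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (contig, pos, sample) key "
            f"({r['contig']}, {r['pos']}, {r['sample']}) on data line {dup.idxmax() + 2}"
        )
    if design is not None:
        unknown = sorted(set(df["sample"]) - set(design.samples))
        if unknown:
            raise ValueError(f"{path}: samples not in design: {unknown}")
    return BaseCountMatrix(df)


def write_counts(matrix: BaseCountMatrix, path: str | Path,
                 header_comments: Iterable[str] = ()) -> None:
    matrix.write_tsv(path, header_comments)


def read_quality_binned_counts(path: str | Path, min_base_quality: int = 30,
                               design: GroupDesign | None = None) -> BaseCountMatrix:
    """Read a quality-binned count TSV and apply the base-quality filter at load.

    Expected columns: contig, pos, ref, sample, qual_bin, nA, nC, nG, nT.
    Bins with ``qual_bin < min_base_quality`` are dropped; remaining bins are
    summed per (contig, pos, sample).
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"contig": str, "ref": str, "sample": str})
    if "qual_bin" not in df.columns:
        raise ValueError(f"{path}: quality-binned input requires a 'qual_bin' column")
    df = df[df["qual_bin"] >= min_base_quality]
    agg = (
        df.groupby(["contig", "pos", "ref", "sample"], as_index=False)[COUNT_COLUMNS].sum()
    )
    if design is not None:
        unknown = sorted(set(agg["sample"]) - set(design.samples))
        if unknown:
            raise ValueError(f"{path}: samples not in design: {unknown}")
    return BaseCountMatrix(agg)
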