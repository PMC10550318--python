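"""Tables, sequences and normalization.

Readers/writers for the plain-text formats the pipeline consumes (counts TSV,
sample sheet CSV, gene table TSV, region FASTA, GMT, ChIP TSV), plus the two
normalizations every downstream stage relies on: transcripts-per-million and
median-of-ratios size factors.

Conventions
-----------
* Count matrices are genes x samples with a header row of sample ids and the
  gene id in the first column.  All tables are UTF-8, tab-delimited unless the
  file extension is ``.csv``.
* Timepoint units (minutes for the mitotic depletion course, hours for the
  meiotic course) are carried explicitly on the sample sheet and never coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGIONS = ("upstream", "orf", "downstream")


class ParseError(ValueError):
    """A file failed validation; the message names the file and the problem."""


class DegenerateSampleError(ValueError):
    """A sample carries no usable signal (e.g. all-zero counts)."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

class CountMatrix:
    """Integer gene x sample count matrix.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample ids)
    and enforces the invariants: non-negative integers, unique ids.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ParseError("duplicate gene ids in count matrix")
        if values.columns.has_duplicates:
            raise ParseError("duplicate sample ids in count matrix")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ParseError("non-integer counts in count matrix")
            values = values.round().astype(np.int64)
        if (values.to_numpy() < 0).any():
            raise ParseError("negative counts in count matrix")
        self.values = values.astype(np.int64)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[:, list(sample_ids)])

    def __eq__(self, other) -> bool:  # round-trip tests
        return isinstance(other, CountMatrix) and self.values.equals(other.values)

    def __repr__(self) -> str:
        return f"CountMatrix({self.values.shape[0]} genes x {self.values.shape[1]} samples)"


class SampleSheet:
    """Sample metadata: condition, timepoint (with explicit unit), replicate."""

    REQUIRED = ("sample_id", "condition", "timepoint", "replicate")

    def __init__(self, table: pd.DataFrame, time_unit: str = "minutes"):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ParseError(f"sample sheet missing column(s): {', '.join(missing)}")
        if table["sample_id"].duplicated().any():
            raise ParseError("duplicate sample ids in sample sheet")
        self.table = table.reset_index(drop=True)
        self.time_unit = time_unit

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.table["timepoint"].unique())

    def samples_for(self, condition=None, timepoint=None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if timepoint is not None:
            mask &= self.table["timepoint"] == timepoint
        return list(self.table.loc[mask, "sample_id"])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SampleSheet)
            and self.time_unit == other.time_unit
            and self.table.equals(other.table)
        )


@dataclass
class ChipScoreTable:
    """Per-gene replicate ChIP peak scores plus the reference gene id.

    The curation ratio downstream is mean(scores of gene) / mean(scores of the
    reference gene), mirroring normalization against a canonical bound target.
    """

    scores: pd.DataFrame  # index gene_id, columns rep1..repN
    reference_gene: str

    def __post_init__(self):
        if self.scores.shape[1] < 1:
            raise ParseError("ChIP table needs at least one replicate column")
        if self.reference_gene not in self.scores.index:
            raise ParseError(f"reference gene {self.reference_gene!r} absent from ChIP table")

    def ratio(self, gene: str) -> float:
        ref = float(self.scores.loc[self.reference_gene].mean())
        return float(self.scores.loc[gene].mean()) / ref


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_tpm(counts: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and gene lengths (bp).

    TPM_gj = (c_gj / len_g) / sum_g (c_gj / len_g) * 1e6, so each column sums
    to one million.  Gene length is the annotated length in bp; no effective
    (fragment-corrected) length is modelled.
    """
    lengths = lengths.reindex(counts.genes)
    if lengths.isna().any():
        missing = list(counts.genes[lengths.isna()])[:5]
        raise ParseError(f"genes missing lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ParseError("gene with non-positive length in annotation")
    rate = counts.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise DegenerateSampleError(f"all-zero sample(s): {bad}")
    return rate.div(denom, axis=1) * 1e6


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes containing a zero in any sample are excluded from the median (their
    geometric mean across samples is zero, so the ratio is undefined).
    """
    x = counts.values.to_numpy(dtype=float)
    keep = (x > 0).all(axis=1)
    if not keep.any():
        raise DegenerateSampleError("no gene has nonzero counts in every sample")
    kept = x[keep]
    geo = np.exp(np.log(kept).mean(axis=1, keepdims=True))
    s = np.median(kept / geo, axis=0)
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=counts.samples, name="size_factor")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message plumbing
        raise ParseError(f"{path}: cannot parse counts table ({exc})") from exc
    try:
        return CountMatrix(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts(counts: CountMatrix, path) -> None:
    counts.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path, time_unit: str = "minutes") -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path)
    try:
        return SampleSheet(df, time_unit=time_unit)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, length_bp and optional extra columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ParseError(f"{path}: gene table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in gene table")
    return df.set_index("gene_id")


def write_gene_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_chip_table(path, reference_gene: str) -> ChipScoreTable:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: ChIP table missing gene_id column")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in ChIP table")
    return ChipScoreTable(df.set_index("gene_id"), reference_gene)


def write_chip_table(chip: ChipScoreTable, path) -> None:
    chip.scores.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA regions and GMT gene sets
# ---------------------------------------------------------------------------

def read_fasta_regions(path) -> dict[str, dict[str, str]]:
    """Parse region FASTA with headers ``geneID|region`` into a nested map."""
    regions: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(f"{path}: FASTA header {rec.id!r} lacks 'geneID|region' form")
        gene, region = rec.id.split("|", 1)
        if region not in REGIONS:
            raise ParseError(f"{path}: unknown region {region!r} in header {rec.id!r}")
        regions.setdefault(gene, {})[region] = str(rec.seq).upper()
    return regions


def write_fasta_regions(regions: Mapping[str, Mapping[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{gene}|{region}", description="")
        for gene, per_region in regions.items()
        for region, seq in per_region.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
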