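"""Readers and writers for the genomic and tabular formats the pipeline touches.

Coordinate convention: 0-based half-open ([start, end)) everywhere, BED-style.
A TSS is stored as a 0-based point (the first transcribed base). Inputs in a
1-based inclusive dialect must be shifted by the caller (``start - 1``).
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "CoverageRecord",
    "TssRecord",
    "EnhancerLink",
    "ExpressionTable",
    "DETable",
    "RunConfig",
    "read_peaks",
    "read_coverage",
    "read_tables",
    "read_sequences",
    "write_peaks",
    "write_coverage",
    "write_table",
    "write_sequences",
    "load_config",
    "save_config",
]

VALID_STRANDS = {"+", "-", "."}
FASTA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class PeakRecord:
    """A called binding peak with a significance-derived signal.

    ``signal`` is the -log10 q-value (ChIP-seq conservative peaks) or an
    analogous -log10 p style score (calling cards / ChIP-exo inputs).
    """

    interval: GenomicInterval
    signal: float
    name: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative peak signal: {self.signal}")
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < len(self.interval):
                raise ValueError(
                    f"summit offset {self.summit_offset} outside peak of "
                    f"length {len(self.interval)}"
                )

    @property
    def anchor(self) -> int:
        """Genomic position representing the peak: summit if known, else midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class CoverageRecord:
    """A constant-value stretch of a per-bp coverage track (fold-change)."""

    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("coverage value must be finite")


@dataclass(frozen=True)
class TssRecord:
    """The 5'-most transcription start site of a gene (0-based point)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")


@dataclass(frozen=True)
class EnhancerLink:
    """An enhancer interval linked to a target gene (GeneHancer-style)."""

    gene_id: str
    enhancer: GenomicInterval
    evidence_tier: str = "double elite"


@dataclass
class ExpressionTable:
    """Gene x sample matrix of non-negative preperturbation expression values."""

    values: pd.DataFrame  # index gene_id, columns sample names
    scale_tag: str = "linear"  # {"linear", "log"}

    def __post_init__(self) -> None:
        if self.scale_tag not in {"linear", "log"}:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values on linear scale")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DETable:
    """Per-gene differential-expression summary for one TF perturbation.

    ``padj`` may be absent (all-NaN) for datasets without replicates, which
    triggers the fold-change-only labeling rule explicitly.
    """

    table: pd.DataFrame  # index gene_id; columns log2fc, padj[, shrunken_lfc]

    def __post_init__(self) -> None:
        if "log2fc" not in self.table.columns:
            raise ValueError("DE table missing required column 'log2fc'")
        if "padj" in self.table.columns:
            padj = self.table["padj"].dropna()
            if ((padj < 0) | (padj > 1)).any():
                raise ValueError("padj values outside [0, 1]")

    @property
    def has_padj(self) -> bool:
        return "padj" in self.table.columns and self.table["padj"].notna().any()

    @property
    def has_shrunken(self) -> bool:
        return "shrunken_lfc" in self.table.columns


@dataclass
class RunConfig:
    """End-to-end run settings; thresholds default to the published cutoffs."""

    mode: str = "yeast"  # {"yeast", "human"}
    fold_count: int = 10
    permutation_count: int = 35
    seed: int = 0
    feature_subset: str = "full"
    enhancer_scheme: str = "aggregated"  # {"binned", "aggregated", "none"}
    padj_max: float = 0.05
    lfc_min: float = 0.5
    significance_p: float = 1e-3
    responder_floor: float = 0.01
    n_boost_rounds: int = 300
    max_depth: int = 6

    def __post_init__(self) -> None:
        if self.fold_count < 2:
            raise ValueError("fold_count must be >= 2")
        if self.permutation_count < 1:
            raise ValueError("permutation_count must be >= 1")
        if self.mode not in {"yeast", "human"}:
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Peaks (narrowPeak / generic TSV)
# ---------------------------------------------------------------------------

def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer {what}: {text!r}") from exc


def read_peaks(path: str | os.PathLike, dialect: str = "narrowPeak") -> list[PeakRecord]:
    """Read binding peaks.

    ``narrowPeak`` is BED6+4: the qValue (column 9, 0-based index 8) is the
    signal and column 10 the summit offset, with -1 meaning "no summit".
    ``tsv`` expects a header with columns chrom, start, end, signal and
    optional name, strand, summit_offset.
    """
    records: list[PeakRecord] = []
    if dialect == "narrowPeak":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(
                        f"line {lineno}: narrowPeak needs 10 columns, got {len(fields)}"
                    )
                chrom = fields[0]
                start = _parse_int(fields[1], "start", lineno)
                end = _parse_int(fields[2], "end", lineno)
                if start < 0:
                    raise ValueError(f"line {lineno}: negative start coordinate")
                strand = fields[5] if fields[5] in VALID_STRANDS else "."
                try:
                    signal = float(fields[8])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-numeric qValue") from exc
                summit = _parse_int(fields[9], "summit", lineno)
                records.append(
                    PeakRecord(
                        interval=GenomicInterval(chrom, start, end, strand),
                        signal=signal,
                        name=fields[3],
                        summit_offset=None if summit == -1 else summit,
                    )
                )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        for col in ("chrom", "start", "end", "signal"):
            if col not in df.columns:
                raise ValueError(f"peak tsv missing required column {col!r}")
        for row in df.itertuples(index=False):
            summit = getattr(row, "summit_offset", None)
            if summit is not None and (pd.isna(summit) or int(summit) == -1):
                summit = None
            records.append(
                PeakRecord(
                    interval=GenomicInterval(
                        str(row.chrom), int(row.start), int(row.end),
                        getattr(row, "strand", "."),
                    ),
                    signal=float(row.signal),
                    name=str(getattr(row, "name", ".")),
                    summit_offset=None if summit is None else int(summit),
                )
            )
    else:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    return records


def write_peaks(records: list[PeakRecord], path: str | os.PathLike) -> None:
    """Write peaks as narrowPeak (signalValue/pValue columns set to 0)."""
    with open(path, "w") as fh:
        for rec in records:
            summit = -1 if rec.summit_offset is None else rec.summit_offset
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}\t"
                f"{rec.name}\t0\t{rec.interval.strand}\t0\t0\t"
                f"{rec.signal!r}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# Coverage (bedGraph)
# ---------------------------------------------------------------------------

def read_coverage(path: str | os.PathLike, dialect: str = "bedGraph") -> list[CoverageRecord]:
    """Read a 4-column bedGraph track, returned sorted by (chrom, start).

    Overlapping intervals within the track are an error: a coverage track is a
    per-bp function, so overlaps would double-count signal.
    """
    if dialect != "bedGraph":
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    records: list[CoverageRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric value {fields[3]!r}") from exc
            records.append(
                CoverageRecord(
                    GenomicInterval(
                        fields[0],
                        _parse_int(fields[1], "start", lineno),
                        _parse_int(fields[2], "end", lineno),
                    ),
                    value,
                )
            )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    prev: CoverageRecord | None = None
    for rec in records:
        if (
            prev is not None
            and rec.interval.chrom == prev.interval.chrom
            and rec.interval.start < prev.interval.end
        ):
            raise ValueError(
                f"overlapping coverage intervals: {prev.interval} and {rec.interval}"
            )
        prev = rec
    return records


def write_coverage(records: list[CoverageRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t"
                f"{rec.interval.end}\t{rec.value!r}\n"
            )


# ---------------------------------------------------------------------------
# Typed tables (TSV with headers)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "tss": ("gene_id", "chrom", "tss", "strand"),
    "enhancer_links": ("gene_id", "chrom", "start", "end", "tier"),
    "expression": ("gene_id",),
    "de": ("gene_id", "log2fc"),
}


def read_tables(path: str | os.PathLike, kind: str):
    """Read one of the typed TSV tables.

    kind: ``tss`` -> list[TssRecord]; ``enhancer_links`` -> list[EnhancerLink];
    ``expression`` -> ExpressionTable (scale from a ``#scale=`` comment line,
    default linear); ``de`` -> DETable. Unknown extra columns are ignored.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    scale_tag = "linear"
    with open(path) as fh:
        head = fh.readline()
        if head.startswith("#scale="):
            scale_tag = head.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing required column(s): {', '.join(missing)}")

    if kind == "tss":
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id in tss table: {dup.iloc[0]!r}")
        return [
            TssRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples(index=False)
        ]
    if kind == "enhancer_links":
        return [
            EnhancerLink(
                str(r.gene_id),
                GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                str(r.tier),
            )
            for r in df.itertuples(index=False)
        ]
    if kind == "expression":
        df = df.set_index("gene_id")
        return ExpressionTable(values=df.astype(float), scale_tag=scale_tag)
    # de
    df = df.set_index("gene_id")
    keep = [c for c in ("log2fc", "padj", "shrunken_lfc") if c in df.columns]
    return DETable(table=df[keep].astype(float))


def write_table(obj, path: str | os.PathLike, kind: str) -> None:
    """Inverse of :func:`read_tables` for each table kind."""
    if kind == "tss":
        df = pd.DataFrame(
            [(r.gene_id, r.chrom, r.tss, r.strand) for r in obj],
            columns=["gene_id", "chrom", "tss", "strand"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif kind == "enhancer_links":
        df = pd.DataFrame(
            [
                (r.gene_id, r.enhancer.chrom, r.enhancer.start, r.enhancer.end, r.evidence_tier)
                for r in obj
            ],
            columns=["gene_id", "chrom", "start", "end", "tier"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif kind == "expression":
        with open(path, "w") as fh:
            fh.write(f"#scale={obj.scale_tag}\n")
            obj.values.to_csv(fh, sep="\t", index_label="gene_id")
    elif kind == "de":
        obj.table.to_csv(path, sep="\t", index_label="gene_id")
    else:
        raise ValueError(f"unknown table kind {kind!r}")


# ---------------------------------------------------------------------------
# Sequences (FASTA)
# ---------------------------------------------------------------------------

def read_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA of regulatory sequences into {region_id: uppercase seq}.

    Only A, C, G, T, N are accepted; anything else is an error.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            seq = str(record.seq).upper()
            bad = set(seq) - FASTA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {record.id!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            seqs[record.id] = seq
    return seqs


def write_sequences(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Config (YAML)
# ---------------------------------------------------------------------------

def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
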