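"""Assemble the feature matrix and labels from on-disk inputs.

This is the glue between the format readers, the region schemes, and the
feature mappers: it reads a dataset directory (TSS table, expression table,
promoter FASTA, enhancer links, per-TF peaks, coverage tracks, per-TF DE
tables), builds per-gene regions, and produces the rectangular
(TF, gene) x feature matrix plus response labels.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .features import (
    DINUCLEOTIDES,
    FeatureMatrix,
    assemble_feature_matrix,
    compute_gex_level,
    compute_gex_variation,
    dinucleotide_freqs,
    map_coverage_to_bins,
    map_peaks_to_bins,
)
from .io_formats import CoverageRecord, PeakRecord, RunConfig
from .labels import ResponseLabels, labels_from_de_tables
from .regions import BinScheme, GeneRegions, build_regions, scheme_for

__all__ = ["Dataset", "load_dataset", "build_gene_regions", "build_feature_matrix"]


@dataclass
class Dataset:
    """All parsed inputs of one run."""

    tss: list
    expression: iof.ExpressionTable
    sequences: dict[str, str]
    enhancer_links: list
    coverage: dict[str, list[CoverageRecord]]  # track name -> records
    peaks: dict[str, list[PeakRecord]]  # tf -> records
    de: dict[str, iof.DETable]  # tf -> table
    chrom_length: int


def load_dataset(root: str | Path, chrom_length: int | None = None) -> Dataset:
    """Read a dataset directory written by the generator (or hand-assembled).

    Layout: tss.tsv, expression.tsv, promoters.fasta, enhancers.tsv,
    atac.bedGraph, coverage/*.bedGraph, peaks/*.narrowPeak, de/*.tsv.
    """
    root = Path(root)
    tss = iof.read_tables(root / "tss.tsv", kind="tss")
    coverage = {"atac": iof.read_coverage(root / "atac.bedGraph")}
    for p in sorted((root / "coverage").glob("*.bedGraph")):
        coverage[p.stem] = iof.read_coverage(p)
    peaks = {
        p.stem: iof.read_peaks(p) for p in sorted((root / "peaks").glob("*.narrowPeak"))
    }
    de = {p.stem: iof.read_tables(p, kind="de") for p in sorted((root / "de").glob("*.tsv"))}
    if chrom_length is None:
        chrom_length = max(r.tss for r in tss) + 1_000_000
    return Dataset(
        tss=tss,
        expression=iof.read_tables(root / "expression.tsv", kind="expression"),
        sequences=iof.read_sequences(root / "promoters.fasta"),
        enhancer_links=iof.read_tables(root / "enhancers.tsv", kind="enhancer_links"),
        coverage=coverage,
        peaks=peaks,
        de=de,
        chrom_length=chrom_length,
    )


def build_gene_regions(data: Dataset, scheme: BinScheme) -> dict[str, GeneRegions]:
    links_by_gene: dict[str, list] = {}
    for link in data.enhancer_links:
        links_by_gene.setdefault(link.gene_id, []).append(link)
    return {
        rec.gene_id: build_regions(
            rec, links_by_gene.get(rec.gene_id, []), scheme, data.chrom_length
        )
        for rec in data.tss
    }


class _SortedTrack:
    """Binary-search index over sorted records for fast window queries."""

    def __init__(self, records, max_len: int):
        self.records = sorted(records, key=lambda r: r.interval.start)
        self.starts = [r.interval.start for r in self.records]
        self.max_len = max_len

    def overlapping(self, start: int, end: int):
        lo = bisect.bisect_left(self.starts, start - self.max_len)
        hi = bisect.bisect_right(self.starts, end)
        return [
            r for r in self.records[lo:hi]
            if r.interval.end > start and r.interval.start < end
        ]


def _gene_window(regions: GeneRegions, reach: int) -> tuple[int, int]:
    promoter = regions.promoter_interval
    start = promoter.start if promoter else regions.tss.tss
    end = promoter.end if promoter else regions.tss.tss + 1
    if regions.enhancer_members:
        start, end = start - reach - 2000, end + reach + 2000
    return max(0, start), end


def _dinuc_features(
    regions: GeneRegions, seq: str | None, scheme: BinScheme
) -> pd.Series:
    """Per-promoter-bin dinucleotide frequencies from the promoter sequence.

    The FASTA sequence is the promoter window 5'->3' in gene orientation, so
    bin i corresponds to seq[i*w:(i+1)*w].
    """
    w = scheme.bin_width
    out: dict[str, float] = {}
    for i, ((a, b), _) in enumerate(regions.promoter_bins):
        piece = "" if seq is None else seq[i * w : (i + 1) * w]
        freqs = dinucleotide_freqs(piece) if len(piece) >= 2 else pd.Series(
            0.0, index=DINUCLEOTIDES
        )
        for d in DINUCLEOTIDES:
            out[f"dinuc_{d}:prom_{a}:{b}"] = float(freqs[d])
    return pd.Series(out)


def build_feature_matrix(
    data: Dataset,
    config: RunConfig,
    regions_by_gene: dict[str, GeneRegions] | None = None,
) -> FeatureMatrix:
    """The full rectangular feature matrix for every (TF, gene) pair."""
    scheme = scheme_for(config.mode, config.enhancer_scheme)
    if regions_by_gene is None:
        regions_by_gene = build_gene_regions(data, scheme)
    genes = [rec.gene_id for rec in data.tss]
    reach = scheme.enhancer_reach if scheme.enhancer_scheme != "none" else 0

    # gene-centric positional tracks (coverage)
    cov_tracks = {
        name: _SortedTrack(recs, max(len(r.interval) for r in recs) if recs else 1)
        for name, recs in data.coverage.items()
    }
    gene_rows = []
    for gene in genes:
        regions = regions_by_gene[gene]
        row: dict[str, float] = {}
        w0, w1 = _gene_window(regions, reach)
        for name, track in cov_tracks.items():
            sums = map_coverage_to_bins(track.overlapping(w0, w1), regions)
            for label, val in sums.items():
                row[f"{name}:{label}"] = float(val)
        row.update(_dinuc_features(regions, data.sequences.get(gene), scheme))
        gene_rows.append(row)
    gene_features = pd.DataFrame(gene_rows, index=pd.Index(genes, name="gene"))

    # positionless gene-expression features
    level = compute_gex_level(data.expression)
    variation = compute_gex_variation(data.expression)
    gene_features["gex_level:gene"] = level.reindex(genes).to_numpy()
    gene_features["gex_var:gene"] = variation.reindex(genes).to_numpy()

    # per-TF binding features
    tf_list = sorted(data.de)
    tf_binding = {}
    for tf in tf_list:
        track = _SortedTrack(
            data.peaks.get(tf, []),
            max((len(p.interval) for p in data.peaks.get(tf, [])), default=1),
        )
        rows = []
        for gene in genes:
            regions = regions_by_gene[gene]
            w0, w1 = _gene_window(regions, reach)
            sums = map_peaks_to_bins(track.overlapping(w0, w1), regions)
            rows.append({f"tf_binding:{label}": float(v) for label, v in sums.items()})
        tf_binding[tf] = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))

    return assemble_feature_matrix(gene_features, tf_binding, tf_list, mode=config.mode)


def build_labels(data: Dataset, config: RunConfig, rule: str = "de") -> ResponseLabels:
    return labels_from_de_tables(
        data.de, rule=rule, padj_max=config.padj_max, lfc_min=config.lfc_min
    )
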