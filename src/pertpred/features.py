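"""Build the rectangular per-(TF, gene) feature matrix.

Each signal track contributes one feature per positional bin of the region
scheme. Peaks contribute their whole signal to the single bin containing
their summit (or midpoint when no summit was called); coverage tracks
contribute base-pair-weighted sums (value x overlap bp). Sequence features
are overlapping-dinucleotide frequencies computed per promoter bin.
Gene-expression features are positionless: the median log expression level
and the expression-variation residual (coefficient of variation after
removing its LOESS-estimated dependence on level).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import CoverageRecord, ExpressionTable, PeakRecord
from .regions import GeneRegions

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "map_peaks_to_bins",
    "map_coverage_to_bins",
    "dinucleotide_freqs",
    "compute_gex_level",
    "compute_gex_variation",
    "assemble_feature_matrix",
    "select_feature_subset",
    "feature_class_of",
    "FEATURE_SUBSETS",
]

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

#: Recognised feature-subset ablations (mirror the published model contrasts).
FEATURE_SUBSETS = (
    "full",
    "no_binding",
    "no_gex",
    "no_hm",
    "binding_only",
    "gex_only",
    "prom_only",
    "gene_body_2kb",
)

GEX_COLUMNS = ("gex_level:gene", "gex_var:gene")


@dataclass
class FeatureMatrix:
    """Instances are (tf_id, gene_id) pairs; columns are '<track>:<bin>' names.

    All columns except the ``tf_binding`` ones are gene-centric: for a fixed
    gene they are identical across TFs.
    """

    values: pd.DataFrame  # MultiIndex (tf, gene) rows
    mode: str = "yeast"

    @property
    def tfs(self) -> list[str]:
        return list(self.values.index.get_level_values("tf").unique())

    @property
    def genes(self) -> list[str]:
        return list(self.values.index.get_level_values("gene").unique())

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.values.xs(tf, level="tf")


def feature_class_of(column: str, pool_dinuc: bool = True) -> str:
    """Map a column name to its feature class (track label; dinucs pooled)."""
    track = column.split(":", 1)[0]
    if pool_dinuc and track.startswith("dinuc_"):
        return "dinuc"
    return track


def _positional_spans(regions: GeneRegions) -> list[tuple[str, object]]:
    """(feature label, span) pairs; span is a GenomicInterval, a list of
    member intervals (enhancer features), or None (clipped-away bin)."""
    out: list[tuple[str, object]] = []
    for (a, b), iv in regions.promoter_bins:
        out.append((f"prom_{a}:{b}", iv))
    for label, members in regions.enhancer_members.items():
        out.append((label, members))
    return out


def map_peaks_to_bins(peaks: list[PeakRecord], regions: GeneRegions) -> pd.Series:
    """Sum peak signals into positional features by summit/midpoint containment.

    Promoter bins capture any peak anchored inside them; enhancer features
    capture only peaks anchored inside one of their member enhancers (signal
    outside annotated enhancers is not counted there). Peaks anchored
    nowhere are ignored.
    """
    spans = _positional_spans(regions)
    sums = pd.Series(0.0, index=[label for label, _ in spans])
    for peak in peaks:
        pos = peak.anchor
        chrom = peak.interval.chrom
        for label, span in spans:
            if span is None:
                continue
            if isinstance(span, list):
                if any(m.contains(chrom, pos) for m in span):
                    sums[label] += peak.signal
                    break
            elif span.contains(chrom, pos):
                sums[label] += peak.signal
                break
    return sums


def map_coverage_to_bins(cov: list[CoverageRecord], regions: GeneRegions) -> pd.Series:
    """Base-pair-weighted sums of a coverage track over positional features."""
    spans = _positional_spans(regions)
    sums = pd.Series(0.0, index=[label for label, _ in spans])
    for rec in cov:
        for label, span in spans:
            if span is None:
                continue
            if isinstance(span, list):
                bp = sum(rec.interval.overlap(m) for m in span)
            else:
                bp = rec.interval.overlap(span)
            if bp:
                sums[label] += rec.value * bp
    return sums


def dinucleotide_freqs(seq: str) -> pd.Series:
    """Overlapping dinucleotide frequencies of ``seq``.

    Windows containing N are excluded from both numerator and denominator.
    Degenerate input (length < 2 or no valid window) yields all zeros.
    """
    counts = pd.Series(0.0, index=DINUCLEOTIDES)
    seq = seq.upper()
    valid = 0
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if "N" in d:
            continue
        counts[d] += 1
        valid += 1
    if valid == 0:
        logger.warning("no valid dinucleotide window in sequence of length %d", len(seq))
        return counts
    return counts / valid


def compute_gex_level(expr: ExpressionTable) -> pd.Series:
    """Median log expression per gene.

    Linear-scale inputs are transformed as log2(x + 1); log-scale inputs are
    used as-is.
    """
    if expr.scale_tag == "linear":
        values = np.log2(expr.values + 1.0)
    else:
        values = expr.values
    return values.median(axis=1)


def compute_gex_variation(expr: ExpressionTable, span: float = 0.75) -> pd.Series:
    """Expression-variation feature: LOESS residual of CV on level.

    The coefficient of variation (sd/mean, linear scale) depends strongly on
    expression level; a locally linear LOESS fit of CV on the median log
    level is subtracted so the residual captures level-independent
    variability. Genes with zero mean get residual 0 with a warning.
    """
    if expr.n_samples < 2:
        raise ValueError("expression variation requires >= 2 samples")
    if expr.scale_tag == "linear":
        linear = expr.values
    else:
        linear = np.exp2(expr.values) - 1.0
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    level = compute_gex_level(expr)

    cv = pd.Series(0.0, index=mean.index)
    ok = mean > 0
    cv[ok] = sd[ok] / mean[ok]
    if (~ok).any():
        warnings.warn(
            f"{(~ok).sum()} gene(s) with zero mean expression: variation set to 0",
            stacklevel=2,
        )
    fitted = pd.Series(
        lowess(cv[ok].to_numpy(), level[ok].to_numpy(), frac=span,
               return_sorted=False),
        index=cv[ok].index,
    )
    residual = pd.Series(0.0, index=cv.index)
    residual[ok] = cv[ok] - fitted
    return residual


def assemble_feature_matrix(
    gene_features: pd.DataFrame,
    tf_binding: dict[str, pd.DataFrame],
    tf_list: list[str],
    mode: str = "yeast",
) -> FeatureMatrix:
    """Stack gene-centric and per-TF binding features into one matrix.

    ``gene_features``: genes x non-binding columns (identical across TFs).
    ``tf_binding``: tf -> genes x tf_binding columns. The result has
    len(tf_list) * n_genes rows in deterministic (tf, then gene) order.
    """
    genes = list(gene_features.index)
    blocks = []
    for tf in tf_list:
        if tf not in tf_binding:
            raise ValueError(f"missing tf_binding features for TF {tf!r}")
        bind = tf_binding[tf]
        missing = set(genes) - set(bind.index)
        if missing:
            raise ValueError(
                f"gene {sorted(missing)[0]!r} missing track 'tf_binding' for TF {tf!r}"
            )
        block = pd.concat([bind.loc[genes], gene_features], axis=1)
        block.index = pd.MultiIndex.from_product([[tf], genes], names=["tf", "gene"])
        blocks.append(block)
    values = pd.concat(blocks, axis=0)
    if values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        raise ValueError(f"gene missing values in track {col.split(':')[0]!r}")
    return FeatureMatrix(values=values, mode=mode)


def _bin_label(column: str) -> str:
    return column.split(":", 1)[1]


def _subset_columns(columns: list[str], subset: str) -> list[str]:
    def cls(c: str) -> str:
        return feature_class_of(c, pool_dinuc=False)

    def is_hm(c: str) -> bool:
        return cls(c).startswith(("H2", "H3", "H4"))

    if subset == "full":
        return columns
    if subset == "no_binding":
        return [c for c in columns if cls(c) != "tf_binding"]
    if subset == "no_gex":
        return [c for c in columns if c not in GEX_COLUMNS]
    if subset == "no_hm":
        return [c for c in columns if not is_hm(c)]
    if subset == "binding_only":
        return [c for c in columns if cls(c) == "tf_binding"]
    if subset == "gex_only":
        return [c for c in columns if c in GEX_COLUMNS]
    if subset == "prom_only":
        return [c for c in columns if not _bin_label(c).startswith("enh_")]
    if subset == "gene_body_2kb":
        kept = []
        for c in columns:
            label = _bin_label(c)
            if label.startswith("enh_"):
                continue
            if label.startswith("prom_"):
                upstream_bound = int(label[len("prom_"):].split(":")[0])
                if upstream_bound < 0:
                    continue
            kept.append(c)
        return kept
    raise ValueError(f"unknown feature subset {subset!r}")


def select_feature_subset(matrix: FeatureMatrix, subset: str) -> FeatureMatrix:
    """Drop named column groups, mirroring the published ablation contrasts.

    ``prom_only`` removes enhancer features; ``gene_body_2kb`` additionally
    removes promoter bins upstream of the TSS, leaving gene-body positional
    features plus the positionless gene features.
    """
    kept = _subset_columns(list(matrix.values.columns), subset)
    return FeatureMatrix(values=matrix.values[kept].copy(), mode=matrix.mode)
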