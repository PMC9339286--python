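"""Binary responsiveness labels and bound-gene sets.

Three labeling rules cover the three kinds of perturbation-response
evidence: replicate differential-expression tables (adjusted p and log2
fold-change, both thresholds strict), fold-change only (datasets without
replicates), and shrunken fold-changes where any nonzero value counts as a
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DETable, PeakRecord
from .regions import GeneRegions

__all__ = [
    "ResponseLabels",
    "BoundSet",
    "call_responsive_de",
    "call_responsive_fc_only",
    "call_responsive_nonzero",
    "bound_gene_set",
    "labels_from_de_tables",
]


@dataclass
class ResponseLabels:
    """Responsive flags per (tf, gene), plus per-TF summaries.

    ``perturbation_efficacy``: |log2FC| of the perturbed TF's own gene in its
    DE table (NaN when that gene is absent) — a measure of how strong the
    perturbation itself was.
    """

    responsive: pd.Series  # MultiIndex (tf, gene) -> {0, 1}
    perturbation_efficacy: dict[str, float] = field(default_factory=dict)

    @property
    def tfs(self) -> list[str]:
        return list(self.responsive.index.get_level_values("tf").unique())

    def for_tf(self, tf: str) -> pd.Series:
        return self.responsive.xs(tf, level="tf")

    def response_fraction(self, tf: str) -> float:
        y = self.for_tf(tf)
        return float(y.mean())

    def response_fractions(self) -> pd.Series:
        return pd.Series({tf: self.response_fraction(tf) for tf in self.tfs})


@dataclass
class BoundSet:
    """Per TF, the genes with a significant binding signal in their promoter."""

    genes_by_tf: dict[str, set[str]]

    def __getitem__(self, tf: str) -> set[str]:
        return self.genes_by_tf[tf]


def _as_series(mask: pd.Series) -> pd.Series:
    return mask.astype(int)


def call_responsive_de(de: DETable, padj_max: float = 0.05, lfc_min: float = 0.5
                       ) -> pd.Series:
    """Responsive iff padj < padj_max AND |log2fc| > lfc_min (both strict)."""
    if not de.has_padj:
        raise ValueError(
            "DE table has no adjusted p-values; use call_responsive_fc_only"
        )
    t = de.table
    mask = (t["padj"] < padj_max) & (t["log2fc"].abs() > lfc_min)
    mask &= t["padj"].notna()
    return _as_series(mask)


def call_responsive_fc_only(de: DETable, lfc_min: float = 0.5) -> pd.Series:
    """Responsive iff |log2fc| > lfc_min; for datasets without replicates."""
    return _as_series(de.table["log2fc"].abs() > lfc_min)


def call_responsive_nonzero(de: DETable) -> pd.Series:
    """Responsive iff the shrunken log2 fold-change is nonzero.

    Shrinkage already pulls non-signals to exactly zero, so any surviving
    value is evidence of a response.
    """
    if not de.has_shrunken:
        raise ValueError("DE table has no 'shrunken_lfc' column")
    return _as_series(de.table["shrunken_lfc"] != 0.0)


def labels_from_de_tables(
    de_by_tf: dict[str, DETable],
    rule: str = "de",
    padj_max: float = 0.05,
    lfc_min: float = 0.5,
) -> ResponseLabels:
    """Apply one labeling rule per TF and record perturbation efficacy.

    rule: "de" (padj + lfc), "fc_only", or "nonzero".
    """
    pieces = {}
    efficacy = {}
    for tf, de in de_by_tf.items():
        if rule == "de":
            y = call_responsive_de(de, padj_max=padj_max, lfc_min=lfc_min)
        elif rule == "fc_only":
            y = call_responsive_fc_only(de, lfc_min=lfc_min)
        elif rule == "nonzero":
            y = call_responsive_nonzero(de)
        else:
            raise ValueError(f"unknown labeling rule {rule!r}")
        pieces[tf] = y
        if tf in de.table.index:
            efficacy[tf] = float(abs(de.table.loc[tf, "log2fc"]))
        else:
            efficacy[tf] = float("nan")
    responsive = pd.concat(pieces, names=["tf", "gene"])
    return ResponseLabels(responsive=responsive, perturbation_efficacy=efficacy)


def bound_gene_set(
    peaks_by_tf: dict[str, list[PeakRecord]],
    regions_by_gene: dict[str, GeneRegions],
    min_signal: float,
) -> BoundSet:
    """Genes with >= 1 peak of signal >= min_signal anchored in their promoter.

    Only the promoter window counts: a gene bound exclusively in an enhancer
    is not in the bound set.
    """
    out: dict[str, set[str]] = {}
    for tf, peaks in peaks_by_tf.items():
        bound: set[str] = set()
        for gene, regions in regions_by_gene.items():
            promoter = regions.promoter_interval
            if promoter is None:
                continue
            for peak in peaks:
                if peak.signal >= min_signal and promoter.contains(
                    peak.interval.chrom, peak.anchor
                ):
                    bound.add(gene)
                    break
        out[tf] = bound
    return BoundSet(genes_by_tf=out)
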