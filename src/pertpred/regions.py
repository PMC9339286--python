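"""Strand-aware cis-regulatory region schemes.

A gene's regulatory territory is described relative to its 5'-most TSS.
The promoter window [upstream, downstream) is tiled with fixed-width bins,
ordered 5'->3' in gene orientation. For the human scheme, enhancers linked
to the gene are either assigned to growing distance bins on each side of the
promoter (widths 1, 2, 3, ... kb) or pooled into two aggregate windows
(everything within reach upstream / downstream of the promoter edge).

Relative coordinates: position r means "r bp downstream of the TSS in gene
orientation" (negative = upstream). A relative window [a, b) maps to genomic
[tss + a, tss + b) on the plus strand and to its mirror image
[tss - b, tss - a) on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import EnhancerLink, GenomicInterval, TssRecord

__all__ = [
    "BinScheme",
    "GeneRegions",
    "build_regions",
    "count_features",
    "classify_alt_tss",
    "YEAST_SCHEME",
    "HUMAN_BINNED_SCHEME",
    "HUMAN_AGGREGATED_SCHEME",
]


@dataclass(frozen=True)
class BinScheme:
    """Parameters of a region scheme.

    Defaults follow the published designs: yeast promoter (-1000, +500) in
    fifteen 100-bp bins; human promoter (-2000, +2000) in forty 100-bp bins
    with 32 enhancer bins per side of widths 1, 2, 3, ... kb, truncated at a
    hard 500 kb reach from the promoter edge.
    """

    mode: str = "yeast"  # {"yeast", "human"}
    promoter_bounds: tuple[int, int] = (-1000, 500)
    bin_width: int = 100
    enhancer_scheme: str = "none"  # {"binned", "aggregated", "none"}
    enhancer_bin_count: int = 32
    enhancer_reach: int = 500_000

    def __post_init__(self) -> None:
        up, down = self.promoter_bounds
        if down <= up:
            raise ValueError("promoter_bounds must satisfy downstream > upstream")
        if (down - up) % self.bin_width:
            raise ValueError("promoter window must be a whole number of bins")
        if self.enhancer_scheme not in {"binned", "aggregated", "none"}:
            raise ValueError(f"unknown enhancer scheme {self.enhancer_scheme!r}")

    @property
    def n_promoter_bins(self) -> int:
        up, down = self.promoter_bounds
        return (down - up) // self.bin_width

    def promoter_bin_bounds(self) -> list[tuple[int, int]]:
        """Relative [a, b) bounds of each promoter bin, ordered 5'->3'."""
        up, _ = self.promoter_bounds
        w = self.bin_width
        return [(up + i * w, up + (i + 1) * w) for i in range(self.n_promoter_bins)]

    def enhancer_bin_edges(self) -> list[int]:
        """Cumulative distances (bp from the promoter edge) bounding each
        enhancer bin: bin k covers (edges[k-1], edges[k]]. Widths grow by
        1 kb per bin; the last bin is truncated at ``enhancer_reach``."""
        edges = [0]
        for k in range(1, self.enhancer_bin_count + 1):
            edges.append(min(edges[-1] + 1000 * k, self.enhancer_reach))
        return edges


YEAST_SCHEME = BinScheme()
HUMAN_BINNED_SCHEME = BinScheme(
    mode="human", promoter_bounds=(-2000, 2000), enhancer_scheme="binned"
)
HUMAN_AGGREGATED_SCHEME = BinScheme(
    mode="human", promoter_bounds=(-2000, 2000), enhancer_scheme="aggregated"
)


def scheme_for(mode: str, enhancer_scheme: str = "aggregated") -> BinScheme:
    """The default scheme for an organism mode."""
    if mode == "yeast":
        return YEAST_SCHEME
    if mode == "human":
        return BinScheme(mode="human", promoter_bounds=(-2000, 2000),
                         enhancer_scheme=enhancer_scheme)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class GeneRegions:
    """Realized regulatory regions of one gene under a scheme.

    ``promoter_bins``: ordered [(relative_bounds, genomic interval or None)],
    None when the bin is entirely clipped off the chromosome.
    ``enhancer_members``: feature label -> list of member enhancer intervals.
    Feature labels are e.g. ``"up12"``/``"dn3"`` (binned) or ``"up_agg"`` /
    ``"dn_agg"`` (aggregated).
    """

    gene_id: str
    tss: TssRecord
    scheme: BinScheme
    promoter_bins: list[tuple[tuple[int, int], GenomicInterval | None]]
    enhancer_members: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def promoter_interval(self) -> GenomicInterval | None:
        """The full (clipped) promoter window as one genomic interval."""
        spans = [iv for _, iv in self.promoter_bins if iv is not None]
        if not spans:
            return None
        return GenomicInterval(
            self.tss.chrom, min(s.start for s in spans), max(s.end for s in spans),
            self.tss.strand,
        )

    def relative_to_genomic(self, a: int, b: int) -> tuple[int, int]:
        """Map a relative window [a, b) to an (unclipped) genomic [start, end)."""
        if self.tss.strand == "-":
            return self.tss.tss - b, self.tss.tss - a
        return self.tss.tss + a, self.tss.tss + b

    def positional_feature_labels(self) -> list[str]:
        labels = [f"prom_{a}:{b}" for (a, b), _ in self.promoter_bins]
        labels.extend(self.enhancer_members.keys())
        return labels


def _clip(chrom: str, start: int, end: int, strand: str, chrom_length: int
          ) -> GenomicInterval | None:
    start = max(0, start)
    end = min(chrom_length, end)
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end, strand)


def _enhancer_feature_labels(scheme: BinScheme) -> list[str]:
    if scheme.enhancer_scheme == "aggregated":
        return ["enh_up_agg", "enh_dn_agg"]
    if scheme.enhancer_scheme == "binned":
        n = scheme.enhancer_bin_count
        return [f"enh_up{k}" for k in range(1, n + 1)] + [
            f"enh_dn{k}" for k in range(1, n + 1)
        ]
    return []


def build_regions(
    tss: TssRecord,
    links: list[EnhancerLink],
    scheme: BinScheme,
    chrom_length: int,
) -> GeneRegions:
    """Construct the regulatory regions for one gene.

    Promoter bins are mapped by strand and clipped at chromosome bounds
    (clipped bins keep their identity with a reduced span, so the feature
    matrix stays rectangular). Each enhancer link is assigned to exactly one
    enhancer feature by the distance of its midpoint from the nearest
    promoter edge, in gene orientation; midpoints beyond ``enhancer_reach``
    (or inside the promoter) contribute to no enhancer feature — signal
    inside the promoter is already captured by the promoter bins.
    """
    if chrom_length < tss.tss:
        raise ValueError(
            f"TSS of {tss.gene_id} at {tss.tss} beyond chromosome length {chrom_length}"
        )
    minus = tss.strand == "-"
    promoter_bins: list[tuple[tuple[int, int], GenomicInterval | None]] = []
    for a, b in scheme.promoter_bin_bounds():
        if minus:
            g0, g1 = tss.tss - b, tss.tss - a
        else:
            g0, g1 = tss.tss + a, tss.tss + b
        promoter_bins.append(((a, b), _clip(tss.chrom, g0, g1, tss.strand, chrom_length)))

    regions = GeneRegions(tss.gene_id, tss, scheme, promoter_bins)
    labels = _enhancer_feature_labels(scheme)
    regions.enhancer_members = {lab: [] for lab in labels}
    if not labels:
        return regions

    up_rel, down_rel = scheme.promoter_bounds
    edges = scheme.enhancer_bin_edges()
    for link in links:
        if link.enhancer.chrom != tss.chrom:
            raise ValueError(
                f"enhancer for {tss.gene_id} on {link.enhancer.chrom}, "
                f"gene TSS on {tss.chrom}"
            )
        mid = link.enhancer.midpoint
        # relative coordinate of the midpoint in gene orientation
        r = (tss.tss - mid) if minus else (mid - tss.tss)
        if up_rel <= r < down_rel:
            continue  # inside the promoter window
        if r < up_rel:
            side, dist = "up", up_rel - r
        else:
            side, dist = "dn", r - down_rel + 1
        if dist > scheme.enhancer_reach:
            continue
        if scheme.enhancer_scheme == "aggregated":
            label = f"enh_{side}_agg"
        else:
            k = next(i for i in range(1, len(edges)) if dist <= edges[i])
            label = f"enh_{side}{k}"
        regions.enhancer_members[label].append(link.enhancer)
    return regions


def count_features(regions: GeneRegions, scheme: BinScheme) -> int:
    """Number of positional features per signal track under this scheme."""
    n = len(regions.promoter_bins)
    if scheme.enhancer_scheme == "aggregated":
        n += 2
    elif scheme.enhancer_scheme == "binned":
        n += 2 * scheme.enhancer_bin_count
    return n


def classify_alt_tss(
    primary: TssRecord, alt_positions: list[int], window: int = 2000
) -> list[EnhancerLink]:
    """Turn alternative TSS positions into enhancer-style links.

    Alternative TSSs within ``window`` bp of the 5'-most TSS are considered
    part of the 5' promoter (no link emitted); those further away become
    promoter-sized (2*window) intervals tagged ``alt_promoter`` and are
    treated like enhancers downstream.
    """
    links = []
    for pos in alt_positions:
        if abs(pos - primary.tss) <= window:
            continue
        links.append(
            EnhancerLink(
                primary.gene_id,
                GenomicInterval(primary.chrom, max(0, pos - window), pos + window),
                evidence_tier="alt_promoter",
            )
        )
    return links
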