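"""File-backed synthetic datasets with planted effect structure.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — proximally enriched TF binding peaks with
significance-derived signals, lognormal preperturbation expression with
level-dependent variability, gene-body histone-mark coverage correlated
with expression, GeneHancer-style enhancer links — and plants a known
response model so recovery can be tested end to end:

    logit P(responsive | tf, gene) = b0 + b_bind * x_bind
                                     + b_gex * z(level) + b_var * z(variation)
                                     + b_hm * z(downstream HM)

``yeastlike`` makes binding the dominant driver (peaks ~150 bp upstream of
the TSS); ``humanlike`` sets b_bind = 0 with decoy peaks, so the
gene-centric expression features dominate — mirroring the organism contrast
the pipeline is meant to expose. Baseline b0 values put the median per-TF
response fraction in the 2-7% range typical of real perturbation compendia.

DE tables are generated directly from the sampled labels (padj and log2FC
drawn on the correct side of the thresholds), since labels — not
differential-expression inference — are what the pipeline consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    CoverageRecord,
    DETable,
    EnhancerLink,
    ExpressionTable,
    GenomicInterval,
    PeakRecord,
    TssRecord,
)

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset",
           "summarize_truth", "YEASTLIKE", "HUMANLIKE"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the preset defaults are the study conditions."""

    preset: str = "yeastlike"  # {"yeastlike", "humanlike"}
    n_genes: int = 1000
    n_tfs: int = 10
    n_samples: int = 10  # preperturbation replicates
    # effect weights (b0, b_bind, b_gex, b_var, b_hm) on the logit scale
    beta: tuple[float, float, float, float, float] = (-3.90, 2.0, 0.5, 0.4, 0.3)
    # binding model
    bound_fraction: float = 0.12
    summit_offset_mean: float = -150.0  # bp relative to TSS (upstream)
    summit_offset_sd: float = 80.0
    signal_min: float = 2.0
    signal_scale: float = 3.0  # exponential scale above signal_min
    decoy_peaks: bool = False  # peaks placed independently of responses
    # expression model
    expr_meanlog: float = 5.0  # log2 scale
    expr_sdlog: float = 2.0
    cv_base: float = 0.05
    cv_amplitude: float = 0.4
    cv_decay: float = 0.25  # per log2 unit of level
    var_sd: float = 0.4  # sd of the latent log-CV residual
    # histone-mark model
    hm_marks: tuple[str, ...] = ("H3K4me3", "H3K79me1", "H3K4me1")
    hm_expr_corr: float = 0.6
    hm_upstream_factor: float = 0.3  # downstream bias of gene-body marks
    indirect_fraction: float = 0.05  # responsive-but-unbound rate
    gene_spacing: int = 6000
    enhancers_per_gene_max: int = 0
    enhancer_reach: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0, 1]")
        if self.beta[1] != 0 and self.bound_fraction == 0 and not self.decoy_peaks:
            raise ValueError("b_bind != 0 requires a nonzero bound fraction")

    @property
    def mode(self) -> str:
        return "yeast" if self.preset == "yeastlike" else "human"


YEASTLIKE = SimConfig()
HUMANLIKE = SimConfig(
    preset="humanlike",
    n_genes=800,
    n_tfs=8,
    beta=(-3.35, 0.0, 1.0, 0.6, 0.2),
    bound_fraction=0.08,
    decoy_peaks=True,
    hm_marks=("H3K4me3", "H3K4me1", "H3K27ac"),
    gene_spacing=50_000,
    enhancers_per_gene_max=5,
)


@dataclass
class SimTruth:
    """The planted structure behind one simulated dataset."""

    config: SimConfig
    response_prob: pd.DataFrame  # tf x gene
    labels: pd.DataFrame  # tf x gene in {0,1}
    bound: dict[str, set[str]]
    gene_latents: pd.DataFrame  # per gene: z_level, z_var, z_hm


@dataclass
class SimDataset:
    truth: SimTruth
    paths: dict[str, object]  # logical name -> path or {key: path}
    out_dir: Path


def _promoter_window(cfg: SimConfig) -> tuple[int, int]:
    return (-1000, 500) if cfg.preset == "yeastlike" else (-2000, 2000)


def _rel_to_genomic(tss: int, strand: str, r: int) -> int:
    return tss + r if strand == "+" else tss - r - 1


def simulate_dataset(cfg: SimConfig, out_dir: str | os.PathLike) -> SimDataset:
    """Generate all input files plus the planted truth, deterministically.

    Writes: tss.tsv, expression.tsv, promoters.fasta, enhancers.tsv,
    atac.bedGraph, coverage/<mark>.bedGraph, peaks/<tf>.narrowPeak,
    de/<tf>.tsv. The same seed yields byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "de").mkdir(exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)

    chrom = "chrS" if cfg.preset == "yeastlike" else "chrH"
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tf_list = genes[: cfg.n_tfs]
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    tss_pos = (np.arange(cfg.n_genes) + 1) * cfg.gene_spacing
    chrom_length = int((cfg.n_genes + 2) * cfg.gene_spacing)
    tss_records = [
        TssRecord(g, chrom, int(p), s) for g, p, s in zip(genes, tss_pos, strands)
    ]
    up, down = _promoter_window(cfg)

    # --- expression: lognormal levels, CV a declining function of level ----
    mu = rng.normal(cfg.expr_meanlog, cfg.expr_sdlog, size=cfg.n_genes)
    z_level = (mu - cfg.expr_meanlog) / cfg.expr_sdlog
    z_var = rng.normal(size=cfg.n_genes)
    cv = (cfg.cv_base + cfg.cv_amplitude * np.exp(-cfg.cv_decay * np.clip(mu, 0, None))
          ) * np.exp(cfg.var_sd * z_var)
    sigma_ln = np.sqrt(np.log1p(cv**2))  # lognormal sigma giving that CV
    samples = np.exp2(mu)[:, None] * np.exp(
        rng.normal(size=(cfg.n_genes, cfg.n_samples)) * sigma_ln[:, None]
        - 0.5 * sigma_ln[:, None] ** 2
    )
    expr = ExpressionTable(
        values=pd.DataFrame(
            samples, index=pd.Index(genes, name="gene_id"),
            columns=[f"s{j:02d}" for j in range(cfg.n_samples)],
        ),
        scale_tag="linear",
    )

    # --- histone marks: gene-body coverage correlated with expression ------
    rho = cfg.hm_expr_corr
    z_hm_by_mark = {}
    coverage_by_mark: dict[str, list[CoverageRecord]] = {}
    for mark in cfg.hm_marks:
        eta = rng.normal(size=cfg.n_genes)
        z_hm = rho * z_level + np.sqrt(1 - rho**2) * eta
        z_hm_by_mark[mark] = z_hm
        records = []
        for i, rec in enumerate(tss_records):
            dn_val = float(np.exp(0.5 * z_hm[i]))
            up_val = dn_val * cfg.hm_upstream_factor * float(rng.uniform(0.5, 1.5))
            # upstream segment covers [up, 0), downstream [0, down) in gene
            # orientation; mapped to genomic, possibly swapped on minus strand
            for (a, b), val in ((( up, 0), up_val), ((0, down), dn_val)):
                if rec.strand == "-":
                    g0, g1 = rec.tss - b, rec.tss - a
                else:
                    g0, g1 = rec.tss + a, rec.tss + b
                records.append(
                    CoverageRecord(GenomicInterval(chrom, max(0, g0), g1), round(val, 6))
                )
        records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
        coverage_by_mark[mark] = records
    hm_driver = cfg.hm_marks[0]
    z_hm_driver = z_hm_by_mark[hm_driver]

    # --- chromatin accessibility: level-correlated, no planted effect ------
    z_atac = 0.5 * z_level + np.sqrt(1 - 0.25) * rng.normal(size=cfg.n_genes)
    atac_records = []
    for i, rec in enumerate(tss_records):
        g0, g1 = (rec.tss - down, rec.tss - up) if rec.strand == "-" else (
            rec.tss + up, rec.tss + down)
        atac_records.append(
            CoverageRecord(
                GenomicInterval(chrom, max(0, g0), g1),
                round(float(np.exp(0.4 * z_atac[i])), 6),
            )
        )
    atac_records.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    # --- promoter sequences (no planted sequence effect) -------------------
    seqs = {}
    for rec in tss_records:
        gc = rng.uniform(0.35, 0.50)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seqs[rec.gene_id] = "".join(
            rng.choice(list("ACGT"), size=down - up, p=probs)
        )

    # --- enhancer links (human preset) -------------------------------------
    links: list[EnhancerLink] = []
    if cfg.enhancers_per_gene_max > 0:
        for rec in tss_records:
            for _ in range(int(rng.integers(0, cfg.enhancers_per_gene_max + 1))):
                offset = int(rng.integers(3000, cfg.enhancer_reach))
                side = 1 if rng.random() < 0.5 else -1
                mid = rec.tss + side * offset
                half = int(rng.integers(250, 1000))
                start, end = max(0, mid - half), min(chrom_length, mid + half)
                if end - start < 100:
                    continue
                links.append(
                    EnhancerLink(rec.gene_id, GenomicInterval(chrom, start, end))
                )

    # --- TF binding peaks ---------------------------------------------------
    peaks_by_tf: dict[str, list[PeakRecord]] = {}
    bound: dict[str, set[str]] = {}
    x_bind = pd.DataFrame(0.0, index=tf_list, columns=genes)
    for tf in tf_list:
        n_bound = int(round(cfg.bound_fraction * cfg.n_genes))
        bound_idx = rng.choice(cfg.n_genes, size=n_bound, replace=False)
        bound[tf] = {genes[i] for i in bound_idx}
        peaks: list[PeakRecord] = []
        for i in sorted(bound_idx):
            rec = tss_records[i]
            signal = float(cfg.signal_min + rng.exponential(cfg.signal_scale))
            if cfg.decoy_peaks:
                # binding uninformative: place the peak anywhere within 50 kb
                summit = rec.tss + int(rng.integers(-50_000, 50_000))
            else:
                r = int(np.clip(rng.normal(cfg.summit_offset_mean,
                                           cfg.summit_offset_sd), up, down - 1))
                summit = _rel_to_genomic(rec.tss, rec.strand, r)
            summit = int(np.clip(summit, 100, chrom_length - 100))
            start, end = summit - 100, summit + 100
            peaks.append(
                PeakRecord(
                    GenomicInterval(chrom, start, end),
                    signal=round(signal, 4),
                    name=f"{tf}_p{len(peaks)}",
                    summit_offset=summit - start,
                )
            )
            if not cfg.decoy_peaks:
                # planted driver: proximal binding signal, scaled
                x_bind.loc[tf, rec.gene_id] += signal / 5.0
        peaks_by_tf[tf] = peaks

    # --- planted response model --------------------------------------------
    b0, b_bind, b_gex, b_var, b_hm = cfg.beta
    logit = (
        b0
        + b_gex * z_level[None, :]
        + b_var * z_var[None, :]
        + b_hm * z_hm_driver[None, :]
    ) + b_bind * x_bind.to_numpy()
    if cfg.indirect_fraction > 0 and b_bind != 0:
        typical = (cfg.signal_min + cfg.signal_scale) / 5.0
        indirect = rng.random((cfg.n_tfs, cfg.n_genes)) < cfg.indirect_fraction
        indirect &= x_bind.to_numpy() == 0
        logit = logit + b_bind * typical * indirect
    prob = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random((cfg.n_tfs, cfg.n_genes)) < prob).astype(int)
    labels_df = pd.DataFrame(y, index=tf_list, columns=genes)
    # a TF's own gene always responds to its own (strong) perturbation
    for tf in tf_list:
        labels_df.loc[tf, tf] = 1

    # --- DE tables consistent with the sampled labels ----------------------
    de_by_tf: dict[str, DETable] = {}
    for tf in tf_list:
        lab = labels_df.loc[tf]
        padj = np.empty(cfg.n_genes)
        lfc = np.empty(cfg.n_genes)
        for j in range(cfg.n_genes):
            if lab.iloc[j]:
                padj[j] = rng.uniform(1e-6, 0.049)
                lfc[j] = (0.51 + rng.exponential(0.6)) * (1 if rng.random() < 0.5 else -1)
            elif rng.random() < 0.7:
                padj[j] = rng.uniform(0.06, 1.0)
                lfc[j] = rng.normal(0, 0.3)
            else:  # significant p but sub-threshold fold-change
                padj[j] = rng.uniform(1e-4, 0.049)
                lfc[j] = rng.uniform(-0.499, 0.499)
        table = pd.DataFrame(
            {"log2fc": np.round(lfc, 6), "padj": np.round(padj, 8)},
            index=pd.Index(genes, name="gene_id"),
        )
        # the perturbed TF's own gene shows a large fold-change (efficacy)
        table.loc[tf, "log2fc"] = round(
            float((1.5 + abs(rng.normal())) * (1 if rng.random() < 0.5 else -1)), 6
        )
        table.loc[tf, "padj"] = 1e-8
        table["shrunken_lfc"] = np.where(lab.to_numpy() == 1, table["log2fc"], 0.0)
        de_by_tf[tf] = DETable(table=table)

    # --- write everything ---------------------------------------------------
    paths: dict[str, object] = {}
    iof.write_table(tss_records, out / "tss.tsv", kind="tss")
    paths["tss"] = out / "tss.tsv"
    iof.write_table(expr, out / "expression.tsv", kind="expression")
    paths["expression"] = out / "expression.tsv"
    iof.write_sequences(seqs, out / "promoters.fasta")
    paths["promoters"] = out / "promoters.fasta"
    iof.write_table(links, out / "enhancers.tsv", kind="enhancer_links")
    paths["enhancers"] = out / "enhancers.tsv"
    iof.write_coverage(atac_records, out / "atac.bedGraph")
    cov_paths = {"atac": out / "atac.bedGraph"}
    for mark, records in coverage_by_mark.items():
        p = out / "coverage" / f"{mark}.bedGraph"
        iof.write_coverage(records, p)
        cov_paths[mark] = p
    paths["coverage"] = cov_paths
    peak_paths = {}
    for tf, peaks in peaks_by_tf.items():
        p = out / "peaks" / f"{tf}.narrowPeak"
        iof.write_peaks(peaks, p)
        peak_paths[tf] = p
    paths["peaks"] = peak_paths
    de_paths = {}
    for tf, de in de_by_tf.items():
        p = out / "de" / f"{tf}.tsv"
        iof.write_table(de, p, kind="de")
        de_paths[tf] = p
    paths["de"] = de_paths
    paths["chrom_length"] = chrom_length

    truth = SimTruth(
        config=cfg,
        response_prob=pd.DataFrame(prob, index=tf_list, columns=genes),
        labels=labels_df,
        bound=bound,
        gene_latents=pd.DataFrame(
            {"z_level": z_level, "z_var": z_var, "z_hm": z_hm_driver},
            index=pd.Index(genes, name="gene_id"),
        ),
    )
    return SimDataset(truth=truth, paths=paths, out_dir=out)


def summarize_truth(truth: SimTruth) -> pd.DataFrame:
    """Per-TF response fractions and bound/responsive overlap counts."""
    rows = {}
    for tf in truth.labels.index:
        lab = truth.labels.loc[tf]
        bound = truth.bound.get(tf, set())
        in_bound = lab.index.isin(bound)
        rows[tf] = {
            "response_fraction": float(lab.mean()),
            "n_responsive": int(lab.sum()),
            "n_bound": int(in_bound.sum()),
            "n_bound_responsive": int(lab[in_bound].sum()),
            "p_resp_given_bound": float(lab[in_bound].mean()) if in_bound.any() else np.nan,
            "p_resp_given_unbound": float(lab[~in_bound].mean()),
        }
    return pd.DataFrame(rows).T
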