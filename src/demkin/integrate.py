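"""Methylome-transcriptome integration.

Probe-level expression is collapsed to one row per gene by keeping the
probe with the largest across-sample interquartile range; paired
differential expression reuses the moderated paired test on log2
intensities; per-gene promoter / gene-body beta averages feed a gene-wise
Spearman screen of per-patient methylation change against per-patient
RNA log2 fold change.  "Anti-correlated" means the rank correlation is
negative (expression rises as promoter methylation falls) with a one-sided
Fisher-z normal p-value below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    BODY_CATEGORIES,
    PROMOTER_CATEGORIES,
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    PairedDesign,
)
from .diffmeth import bh_adjust, moderated_paired_test

logger = logging.getLogger(__name__)

_RHO_CLAMP = 1.0 - 1e-12


def collapse_probes_by_iqr(
    expr: ExpressionMatrix, probe_to_gene: dict | pd.Series
) -> ExpressionMatrix:
    """One row per gene: the probe with the largest across-sample IQR.

    Unmapped probes are dropped (count logged).  IQR ties break to the
    lexicographically smallest probe id.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("probe_to_gene mapping is empty")
    df = expr.data
    mapped = df.index.intersection(mapping.index)
    n_unmapped = len(df.index) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes_by_iqr: dropping %d unmapped probes", n_unmapped)
    if not len(mapped):
        raise ValueError("no probe maps to a gene")
    sub = df.loc[mapped]
    q75, q25 = np.percentile(sub.to_numpy(), [75, 25], axis=1)
    choice = pd.DataFrame(
        {"gene": mapping.loc[mapped].to_numpy(), "iqr": q75 - q25, "probe": mapped}
    )
    choice = choice.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    best = choice.drop_duplicates("gene")
    out = sub.loc[best["probe"]]
    out.index = pd.Index(best["gene"].to_numpy(), name="id")
    return ExpressionMatrix(out)


@dataclass
class DEGResults:
    """Paired differential-expression results."""

    table: pd.DataFrame           # per gene: mean_log2fc, mod_t, p, adj_p
    log2fc: pd.DataFrame          # gene x patient per-patient log2 fold changes
    design: PairedDesign
    alpha: float

    def significant_genes(self) -> set[str]:
        return set(self.table.index[(self.table["adj_p"] < self.alpha).to_numpy()])


def paired_deg(
    expr: ExpressionMatrix, design: PairedDesign, alpha: float = 0.05
) -> DEGResults:
    """Moderated paired differential expression on log2 intensities."""
    data = expr.data
    fc = pd.DataFrame(
        data[list(design.t1_samples)].to_numpy() - data[list(design.t0_samples)].to_numpy(),
        index=data.index,
        columns=list(design.patients),
    )
    if np.allclose(fc.to_numpy(), 0.0):
        # identical timepoints: nothing to test, no DEG by construction
        table = pd.DataFrame(
            {"mean_log2fc": 0.0, "mod_t": 0.0, "p": 1.0}, index=data.index
        )
        table["adj_p"] = 1.0
        return DEGResults(table=table, log2fc=fc, design=design, alpha=alpha)
    table = moderated_paired_test(data, design)
    table = table.rename(columns={"mean_diff": "mean_log2fc"})
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return DEGResults(table=table, log2fc=fc, design=design, alpha=alpha)


@dataclass
class GeneRegionBeta:
    """Per-gene mean beta over promoter and gene-body CpGs.

    Genes with zero CpGs in a region carry NaN (absent), never 0, and are
    excluded from that region's screen.  A CpG carrying both promoter and
    body categories contributes to both regions.
    """

    promoter: pd.DataFrame   # gene x sample
    body: pd.DataFrame       # gene x sample
    n_cpgs: pd.DataFrame     # gene x {promoter, body}

    def region(self, which: str) -> pd.DataFrame:
        if which not in ("promoter", "body"):
            raise ValueError("region must be 'promoter' or 'body'")
        return getattr(self, which)


def gene_region_beta(beta: BetaMatrix, annot: CpGAnnotation) -> GeneRegionBeta:
    """Unweighted mean beta per (gene, region, sample).

    Genes are the ``nearest_gene`` assignment of each CpG; promoter =
    TSS1500/TSS200/5'UTR, body = 1stExon/ExonBnd/Body/3'UTR.
    """
    sub = annot.for_cpgs(beta.cpg_ids)
    genes = sub.table["nearest_gene"]
    frames = {}
    counts = {}
    for name, cats in (("promoter", PROMOTER_CATEGORIES), ("body", BODY_CATEGORIES)):
        mask = sub.region_mask(cats).to_numpy()
        vals = beta.data.loc[mask]
        grp = vals.groupby(genes[mask].to_numpy())
        frames[name] = grp.mean()
        counts[name] = grp.size()
    all_genes = frames["promoter"].index.union(frames["body"].index)
    n = pd.DataFrame(
        {
            "promoter": counts["promoter"].reindex(all_genes, fill_value=0),
            "body": counts["body"].reindex(all_genes, fill_value=0),
        }
    )
    return GeneRegionBeta(
        promoter=frames["promoter"].reindex(all_genes),
        body=frames["body"].reindex(all_genes),
        n_cpgs=n.astype(int),
    )


def fisher_z_p(rho: float, n: int, alternative: str = "less") -> float:
    """Normal-approximation p for a correlation via the Fisher z transform.

    z = atanh(rho) * sqrt(n - 3); ``alternative="less"`` gives the
    anti-correlation (lower) tail.  rho is clamped away from +-1 so a
    perfect correlation yields a finite, extreme z.
    """
    if n < 4:
        raise ValueError("Fisher z requires n >= 4")
    z = np.arctanh(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)) * np.sqrt(n - 3)
    if alternative == "less":
        return float(stats.norm.cdf(z))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "two-sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class CorrelationScreenResult:
    """Gene x region Spearman screen results.

    ``table`` has one row per (gene, region) with rho, n, p and the
    anti-correlation call; ``pairs`` retains the per-patient
    (delta beta, log2FC) points for audit.
    """

    table: pd.DataFrame
    pairs: dict
    alpha: float
    two_sided: bool

    def called_genes(self, region: str | None = None) -> set[str]:
        t = self.table
        if region is not None:
            t = t[t["region"] == region]
        return set(t.loc[t["anti_correlated_call"], "gene_id"])

    def summary(self) -> str:
        t = self.table
        by_region = t.groupby("region")["anti_correlated_call"].sum().to_dict()
        return (
            "Methylation-expression anti-correlation screen\n"
            f"  genes x regions tested: {len(t)}   alpha: {self.alpha:g}"
            f"   {'two-sided' if self.two_sided else 'one-sided (anti-correlation)'}\n"
            f"  anti-correlated calls: {int(t['anti_correlated_call'].sum())} "
            f"({', '.join(f'{k}: {int(v)}' for k, v in sorted(by_region.items()))})\n"
            f"  distinct genes called: {len(self.called_genes())}"
        )


class AntiCorrelationScreen:
    """Gene-wise Spearman screen of methylation change vs expression change.

    For each gene and region, x = per-patient RNA log2 fold change and
    y = per-patient region mean delta beta (same contrast); rho is the
    average-rank Spearman correlation across patients and p the one-sided
    Fisher-z normal tail for anti-correlation.  Genes with an undefined
    correlation (zero-variance vector) are flagged, never called.
    """

    def __init__(
        self,
        region_beta: GeneRegionBeta,
        log2fc: pd.DataFrame,
        design: PairedDesign,
        min_patients: int = 5,
    ):
        if design.n < min_patients:
            raise ValueError(
                f"screen requires >= {min_patients} patients, got {design.n}"
            )
        self.region_beta = region_beta
        self.log2fc = log2fc
        self.design = design

    def fit(self, alpha: float = 0.05, two_sided: bool = False) -> CorrelationScreenResult:
        design = self.design
        rows = []
        pairs = {}
        for region in ("promoter", "body"):
            rb = self.region_beta.region(region)
            genes = rb.index.intersection(self.log2fc.index)
            if not len(genes):
                continue
            delta = (
                rb.loc[genes, list(design.t1_samples)].to_numpy()
                - rb.loc[genes, list(design.t0_samples)].to_numpy()
            )
            fc = self.log2fc.loc[genes, list(design.patients)].to_numpy()
            for i, gene in enumerate(genes):
                y = delta[i]
                x = fc[i]
                if np.isnan(y).any():
                    continue  # gene has no CpGs in this region
                flagged = (np.ptp(x) == 0.0) or (np.ptp(y) == 0.0)
                if flagged:
                    rho, p, call = np.nan, np.nan, False
                else:
                    rho = float(stats.spearmanr(x, y).statistic)
                    p = fisher_z_p(
                        rho, design.n, "two-sided" if two_sided else "less"
                    )
                    call = (p < alpha) and (rho < 0)
                rows.append(
                    {
                        "gene_id": gene,
                        "region": region,
                        "rho": rho,
                        "n": design.n,
                        "p": p,
                        "anti_correlated_call": call,
                        "undefined": flagged,
                    }
                )
                pairs[(gene, region)] = list(zip(y.tolist(), x.tolist()))
        table = pd.DataFrame(rows)
        return CorrelationScreenResult(
            table=table, pairs=pairs, alpha=alpha, two_sided=two_sided
        )


def anti_correlation_screen(
    region_beta: GeneRegionBeta,
    log2fc: pd.DataFrame,
    design: PairedDesign,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> CorrelationScreenResult:
    """Functional wrapper around :class:`AntiCorrelationScreen`."""
    return AntiCorrelationScreen(region_beta, log2fc, design).fit(
        alpha=alpha, two_sided=two_sided
    )
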