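"""Biomarker region selection at the optimized entropy parameters.

A region is a biomarker for the epileptogenic hemisphere when its
entropy values differ between the left- and right-positive groups at a
stricter threshold (default p < .01) than the screening level used
during parameter optimization (p < .05).  P-values are uncorrected by
default, so that the default pipeline reproduces the single-threshold
procedure typical of small-cohort neuroimaging studies; a
Benjamini-Hochberg FDR option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mselat.mse import EntropyMatrix, MseParams
from mselat.optimize import auc, region_pvalues, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["BiomarkerSet", "select_biomarkers", "biomarker_report"]


@dataclass
class BiomarkerSet:
    """Regions surviving the intergroup test at the optimized params."""

    region_indices: list[int]
    region_names: list[str]
    pvalues: np.ndarray
    aucs: np.ndarray
    params: MseParams
    alpha_final: float = 0.01

    def __post_init__(self) -> None:
        self.region_indices = [int(i) for i in self.region_indices]
        if self.region_indices != sorted(set(self.region_indices)):
            raise ValueError("region_indices must be unique and sorted")
        n = len(self.region_indices)
        if not (len(self.region_names) == n == len(self.pvalues) == len(self.aucs)):
            raise ValueError("names, pvalues and aucs must align with indices")
        if any(p >= self.alpha_final for p in np.asarray(self.pvalues)):
            raise ValueError("every biomarker p-value must be < alpha_final")

    def __len__(self) -> int:
        return len(self.region_indices)


def select_biomarkers(
    mat: EntropyMatrix,
    labels,
    alpha_final: float = 0.01,
    region_names: list[str] | None = None,
    fdr: bool = False,
    welch: bool = False,
) -> BiomarkerSet:
    """Regions with intergroup t-test p < ``alpha_final``.

    ``fdr=True`` applies Benjamini-Hochberg to the defined p-values and
    thresholds the adjusted values instead (off by default).  An empty
    set is a legitimate result.
    """
    if region_names is None:
        region_names = [f"ROI{g + 1:03d}" for g in range(mat.n_regions)]
    pvals = region_pvalues(mat, labels, welch=welch)
    crit = pvals.copy()
    if fdr:
        defined = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        adj[defined] = multipletests(pvals[defined], method="fdr_bh")[1]
        crit = adj
    with np.errstate(invalid="ignore"):
        hits = np.where(~np.isnan(crit) & (crit < alpha_final))[0]
    aucs = np.array([auc(mat.values[:, g], labels) for g in hits])
    logger.info(
        "select_biomarkers: %d/%d regions at alpha=%g (fdr=%s)",
        hits.size, mat.n_regions, alpha_final, fdr,
    )
    return BiomarkerSet(
        region_indices=[int(g) for g in hits],
        region_names=[region_names[g] for g in hits],
        pvalues=crit[hits],
        aucs=aucs,
        params=mat.params,
        alpha_final=alpha_final,
    )


def biomarker_report(bs: BiomarkerSet, mat: EntropyMatrix, labels) -> pd.DataFrame:
    """Per-biomarker summary table with serialized ROC curves.

    One row per biomarker: region name, p-value, AUC, per-group means
    and sds of the entropy values, and the ROC polyline as a
    "fpr:tpr;..." string ready for TSV output.
    """
    labels = np.asarray(labels)
    if len(bs) == 0:
        logger.warning("biomarker_report: empty biomarker set")
        return pd.DataFrame(
            columns=["region", "index", "pvalue", "auc",
                     "mean_group1", "sd_group1", "mean_group0", "sd_group0", "roc"]
        )
    rows = []
    for name, idx, p, a in zip(bs.region_names, bs.region_indices, bs.pvalues, bs.aucs):
        v = mat.values[:, idx]
        g1 = v[labels == 1]
        g0 = v[labels == 0]
        curve = roc_curve(v[~np.isnan(v)], labels[~np.isnan(v)])
        rows.append(
            {
                "region": name,
                "index": idx,
                "pvalue": p,
                "auc": a,
                "mean_group1": np.nanmean(g1),
                "sd_group1": np.nanstd(g1, ddof=1),
                "mean_group0": np.nanmean(g0),
                "sd_group0": np.nanstd(g0, ddof=1),
                "roc": ";".join(f"{fpr:.6g}:{tpr:.6g}" for fpr, tpr in curve),
            }
        )
    return pd.DataFrame(rows)
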