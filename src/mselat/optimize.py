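"""Data-driven selection of the entropy parameters (m, r, tau).

The three MSE parameters interact, so they are selected in stages on
the cohort itself:

1. ``m`` — for every grid point (m, tau, r) count the regions whose
   entropy differs significantly between groups (two-sample t-test,
   p < alpha); pick the ``m`` with the larger grand-mean count over the
   (tau, r) grid.
2. ``r`` — at the selected ``m`` and the candidate scales (the scales
   with the highest significance counts), compute each region's ROC/AUC
   for group separation and pick the ``r`` that maximizes the mean of
   the top-k region AUCs.
3. ``tau`` — same AUC scoring with ``r`` now fixed, over all scales.

For ranking, AUCs are *folded* as max(AUC, 1 - AUC): a region whose
entropy is consistently lower in the positive group is just as useful a
separator.  Reported tables keep the raw, unfolded orientation
(positive class = label 1, decision rule "entropy >= threshold").
Ties in every argmax are broken toward the smaller parameter value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mselat.mse import EntropyMatrix, MseParams, entropy_table

logger = logging.getLogger(__name__)

__all__ = [
    "ParamGrid",
    "ParamSearchResult",
    "region_pvalues",
    "significance_count",
    "select_m",
    "roc_curve",
    "auc",
    "select_r",
    "select_tau",
    "optimize_all",
]

_DEFAULT_R_GRID = tuple(round(0.30 + 0.02 * i, 2) for i in range(16))


@dataclass(frozen=True)
class ParamGrid:
    """Search grids and thresholds of the three-stage optimization."""

    m_values: tuple[int, ...] = (1, 2)
    r_values: tuple[float, ...] = _DEFAULT_R_GRID
    tau_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    alpha_screen: float = 0.05
    top_k: int = 2
    n_tau_candidates: int = 2
    welch: bool = False

    def __post_init__(self) -> None:
        for name in ("m_values", "r_values", "tau_values"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be sorted ascending")
        if not 0 < self.alpha_screen < 1:
            raise ValueError(f"alpha_screen must be in (0,1), got {self.alpha_screen}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.n_tau_candidates < 1:
            raise ValueError("n_tau_candidates must be >= 1")


@dataclass
class ParamSearchResult:
    """Audit-friendly result of the full three-stage search."""

    sig_counts: np.ndarray  # [m x tau x r] significant-region counts
    auc_table_r: np.ndarray  # [region x r] at selected m, averaged over tau candidates
    auc_table_tau: np.ndarray  # [region x tau] at selected (m, r)
    selected: MseParams
    tau_candidates: tuple[int, ...]
    grid: ParamGrid
    audit: list[str] = field(default_factory=list)


def _two_class(values: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def region_pvalues(mat: EntropyMatrix | np.ndarray, labels, welch: bool = False) -> np.ndarray:
    """Two-sided two-sample t-test p-value per region.

    Pooled-variance Student's t by default (``welch=True`` switches to
    Welch).  Masked (undefined) entropy values are dropped per region; a
    region left with fewer than two defined values in either class gets
    a NaN p-value and is excluded from downstream counts.
    """
    values = mat.values if isinstance(mat, EntropyMatrix) else np.asarray(mat, float)
    pos, neg = _two_class(values, labels)
    n_regions = values.shape[1]
    if not np.isnan(values).any():
        # fully defined: one vectorized call over regions
        return np.asarray(
            stats.ttest_ind(pos, neg, axis=0, equal_var=not welch).pvalue, dtype=float
        )
    pvals = np.full(n_regions, np.nan)
    for g in range(n_regions):
        a = pos[:, g][~np.isnan(pos[:, g])]
        b = neg[:, g][~np.isnan(neg[:, g])]
        if a.size < 2 or b.size < 2:
            logger.warning("region %d: too few defined values for t-test", g)
            continue
        if a.size < pos.shape[0] or b.size < neg.shape[0]:
            logger.info(
                "region %d: dropped %d masked values before t-test",
                g,
                (pos.shape[0] - a.size) + (neg.shape[0] - b.size),
            )
        pvals[g] = stats.ttest_ind(a, b, equal_var=not welch).pvalue
    return pvals


def significance_count(pvals: np.ndarray, alpha: float) -> int:
    """Number of defined p-values strictly below ``alpha``."""
    pvals = np.asarray(pvals, dtype=float)
    return int(np.sum(pvals[~np.isnan(pvals)] < alpha))


def _sig_count_table(table: np.ndarray, labels, alpha: float, welch: bool) -> np.ndarray:
    """Significance counts for every (m, tau, r) layer of an entropy table."""
    n_m, n_tau, n_r = table.shape[:3]
    counts = np.zeros((n_m, n_tau, n_r), dtype=int)
    for mi in range(n_m):
        for ti in range(n_tau):
            for ri in range(n_r):
                pv = region_pvalues(table[mi, ti, ri], labels, welch=welch)
                counts[mi, ti, ri] = significance_count(pv, alpha)
    return counts


def select_m(ds, grid: ParamGrid) -> tuple[int, np.ndarray]:
    """Pick the embedding dimension by grand-mean significance count.

    Computes the [m x tau x r] table of region counts with intergroup
    p < ``alpha_screen`` and returns the ``m`` whose mean count over the
    (tau, r) grid is largest (ties toward the smaller ``m``).
    """
    table = entropy_table(ds, list(grid.m_values), list(grid.r_values), list(grid.tau_values))
    counts = _sig_count_table(table, ds.labels, grid.alpha_screen, grid.welch)
    means = counts.reshape(len(grid.m_values), -1).mean(axis=1)
    m_star = int(grid.m_values[int(np.argmax(means))])  # argmax keeps first (smallest m) on ties
    logger.info("select_m: grand-mean counts %s -> m=%d", dict(zip(grid.m_values, means)), m_star)
    return m_star, counts


def roc_curve(values, labels) -> np.ndarray:
    """ROC points (fpr, tpr) for the rule "value >= threshold -> class 1".

    The curve is not orientation-corrected: a region whose entropy runs
    lower in the positive group yields a curve below the diagonal (and
    AUC < 0.5).  Includes the (0,0) and (1,1) endpoints.
    """
    values = np.asarray(values, dtype=float)
    pos, neg = _two_class(values, labels)
    thresholds = np.unique(values)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.array(points)


def auc(values, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney pair probability.

    Equals (#{positive > negative} + 0.5 * #{ties}) / (n_pos * n_neg);
    masked (NaN) values are dropped before pairing.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    pos, neg = _two_class(values[keep], labels[keep])
    diff = pos[:, None] - neg[None, :]
    wins = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(wins / (pos.size * neg.size))


def _auc_table(table_slice: np.ndarray, labels) -> np.ndarray:
    """Per-region AUC for each layer of a [k, subject, region] stack."""
    k, _, n_regions = table_slice.shape
    out = np.empty((n_regions, k))
    for i in range(k):
        for g in range(n_regions):
            out[g, i] = auc(table_slice[i, :, g], labels)
    return out


def _topk_folded_score(auc_col: np.ndarray, top_k: int) -> float:
    folded = np.maximum(auc_col, 1.0 - auc_col)
    k = min(top_k, folded.size)
    return float(np.sort(folded)[-k:].mean())


def select_r(
    ds,
    m: int,
    tau_candidates,
    r_values,
    top_k: int = 2,
    table: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the similarity factor by top-k folded region AUC.

    For each candidate scale and each ``r``, per-region AUCs of the
    entropy values are computed; ``r*`` maximizes the mean over
    candidate scales of the mean of the ``top_k`` largest folded AUCs
    (ties toward smaller ``r``).  Returns the [region x r] AUC table
    (unfolded, averaged over the candidate scales).
    """
    r_values = list(r_values)
    tau_candidates = list(tau_candidates)
    if table is None:
        table = entropy_table(ds, [m], r_values, tau_candidates)[0]  # [tau, r, subj, region]
    n_regions = table.shape[-1]
    aucs = np.empty((len(tau_candidates), n_regions, len(r_values)))
    for ti in range(len(tau_candidates)):
        aucs[ti] = _auc_table(table[ti], ds.labels)
    scores = [
        float(np.mean([_topk_folded_score(aucs[ti, :, ri], top_k) for ti in range(len(tau_candidates))]))
        for ri in range(len(r_values))
    ]
    r_star = float(r_values[int(np.argmax(scores))])
    logger.info("select_r: scores %s -> r=%.2f", dict(zip(r_values, np.round(scores, 4))), r_star)
    return r_star, aucs.mean(axis=0)


def select_tau(
    ds,
    m: int,
    r: float,
    tau_values,
    top_k: int = 2,
    table: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the scale factor by top-k folded region AUC at fixed (m, r)."""
    tau_values = list(tau_values)
    if table is None:
        table = entropy_table(ds, [m], [r], tau_values)[0, :, 0]  # [tau, subj, region]
    aucs = _auc_table(table, ds.labels)  # [region x tau]
    scores = [_topk_folded_score(aucs[:, ti], top_k) for ti in range(len(tau_values))]
    tau_star = int(tau_values[int(np.argmax(scores))])
    logger.info("select_tau: scores %s -> tau=%d", dict(zip(tau_values, np.round(scores, 4))), tau_star)
    return tau_star, aucs


def optimize_all(ds, grid: ParamGrid | None = None) -> ParamSearchResult:
    """Run the full three-stage (m, r, tau) selection.

    The candidate scales passed to the ``r`` stage are the
    ``n_tau_candidates`` scales with the highest mean significance count
    at the selected ``m`` (ties toward smaller tau).  Deterministic
    given the dataset.  The entropy grid is computed once and shared by
    all three stages (the r and tau stages only need slices of it).
    """
    grid = grid or ParamGrid()
    audit: list[str] = []
    table = entropy_table(ds, list(grid.m_values), list(grid.r_values), list(grid.tau_values))
    counts = _sig_count_table(table, ds.labels, grid.alpha_screen, grid.welch)
    means = counts.reshape(len(grid.m_values), -1).mean(axis=1)
    m_star = int(grid.m_values[int(np.argmax(means))])
    mi = grid.m_values.index(m_star)
    audit.append(
        f"stage m: grand-mean significant-region counts "
        f"{ {m: round(float(v), 3) for m, v in zip(grid.m_values, means)} } -> m={m_star}"
    )
    # candidate scales: highest mean counts over r at the selected m
    tau_mean_counts = counts[mi].mean(axis=1)
    order = np.argsort(-tau_mean_counts, kind="stable")  # stable keeps smaller tau first on ties
    n_cand = min(grid.n_tau_candidates, len(grid.tau_values))
    tau_candidates = tuple(sorted(int(grid.tau_values[i]) for i in order[:n_cand]))
    audit.append(
        f"stage m: mean counts by tau "
        f"{ {t: round(float(v), 3) for t, v in zip(grid.tau_values, tau_mean_counts)} } "
        f"-> candidate scales {tau_candidates}"
    )
    cand_ti = [grid.tau_values.index(t) for t in tau_candidates]
    r_star, auc_table_r = select_r(
        ds, m_star, tau_candidates, grid.r_values, grid.top_k,
        table=table[mi][cand_ti],
    )
    ri = grid.r_values.index(r_star)
    tau_star, auc_table_tau = select_tau(
        ds, m_star, r_star, grid.tau_values, grid.top_k,
        table=table[mi, :, ri],
    )
    audit.append(f"stage r: top-{grid.top_k} folded-AUC argmax over candidates {tau_candidates} -> r={r_star}")
    audit.append(f"stage tau: top-{grid.top_k} folded-AUC argmax at (m={m_star}, r={r_star}) -> tau={tau_star}")
    selected = MseParams(m=m_star, r=r_star, tau=tau_star)
    for line in audit:
        logger.info("optimize_all: %s", line)
    return ParamSearchResult(
        sig_counts=counts,
        auc_table_r=auc_table_r,
        auc_table_tau=auc_table_tau,
        selected=selected,
        tau_candidates=tau_candidates,
        grid=grid,
        audit=audit,
    )
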