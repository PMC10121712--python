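"""Nucleus- and gene-level quality control.

The cascade mirrors common droplet snRNA-seq practice: a per-subject
barcode-rank threshold separates nucleus-containing droplets from
ambient barcodes, a per-subject two-group split on the mitochondrial
fraction removes the high-contamination component, externally supplied
doublet flags are honored, and genes detected in too few nuclei are
dropped. A stage-by-stage accounting report is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CountMatrix

QC_STAGES = ["input", "barcode_rank", "mito_filter", "doublet_removal", "gene_filter"]


@dataclass
class QCConfig:
    smoothing_window: int = 5
    fallback_threshold: float = 0.0
    min_slope: float = 2.0
    rank_min: int = 1
    mito_hard_cap: float | None = 0.10
    mito_epsilon: float = 0.05
    min_gene_nuclei: int = 10
    subject_thresholds: dict[str, float] = field(default_factory=dict)


@dataclass
class QCReport:
    """Per-stage accounting: nuclei retained and mean quality metrics."""

    table: pd.DataFrame

    def nuclei_counts(self) -> np.ndarray:
        return self.table["n_nuclei"].to_numpy()


def barcode_rank_threshold(
    umi_per_barcode: np.ndarray,
    smoothing_window: int = 5,
    fallback: float = 0.0,
    min_slope: float = 2.0,
    rank_min: int = 1,
    rank_max: int | None = None,
) -> float:
    """UMI threshold at the knee of the barcode-rank distribution.

    Barcodes are sorted by descending UMI; on the (log10 rank, log10 UMI)
    curve the discrete slope over ``smoothing_window`` ranks is computed
    and the threshold is placed at the steepest drop (geometric mean of
    the UMI values bracketing it). If no drop is steeper than
    ``min_slope`` in magnitude, ``fallback`` is returned.

    The search is restricted to ranks in ``[rank_min, rank_max]``
    (default: the top half of barcodes). Deep in the ambient tail,
    runs of tied integer UMI values produce arbitrarily steep log-log
    steps because log-rank increments shrink with rank, so an
    unrestricted search would lock onto the tail rather than the knee.
    """
    umi = np.asarray(umi_per_barcode, dtype=float)
    if umi.size == 0:
        raise ValueError("empty barcode list")
    order = np.sort(umi)[::-1]
    n = order.size
    w = max(int(smoothing_window), 1)
    if n <= w:
        return fallback
    ranks = np.arange(1, n + 1, dtype=float)
    ly = np.log10(np.maximum(order, 1e-12))
    lr = np.log10(ranks)
    i0 = np.arange(0, n - w)
    slope = (ly[i0 + w] - ly[i0]) / (lr[i0 + w] - lr[i0])
    lo = max(rank_min - 1, 0)
    hi = min(n // 2 if rank_max is None else rank_max, n - w)
    if hi <= lo:
        return fallback
    window = slope[lo:hi]
    i_star = lo + int(np.argmin(window))
    if -window[i_star - lo] < min_slope:
        return fallback
    return float(np.sqrt(order[i_star] * order[i_star + w]))


def dynamic_mito_filter(pct_mito: np.ndarray, epsilon: float = 0.05) -> np.ndarray:
    """Keep mask after a deterministic 1-D two-means split.

    Centroids start at the minimum and maximum and iterate to
    convergence; every member of the higher-mean group is removed. If
    the converged centroids differ by less than ``epsilon`` the split is
    considered spurious and everything is kept.
    """
    x = np.asarray(pct_mito, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("pct_mito values must be in [0, 1]")
    n = x.size
    if n <= 1:
        return np.ones(n, dtype=bool)
    c_lo, c_hi = float(x.min()), float(x.max())
    if c_hi - c_lo < 1e-15:
        return np.ones(n, dtype=bool)
    for _ in range(100):
        hi_group = np.abs(x - c_hi) < np.abs(x - c_lo)
        if not hi_group.any() or hi_group.all():
            break
        new_lo, new_hi = x[~hi_group].mean(), x[hi_group].mean()
        if abs(new_lo - c_lo) < 1e-12 and abs(new_hi - c_hi) < 1e-12:
            break
        c_lo, c_hi = new_lo, new_hi
    if c_hi - c_lo < epsilon:
        return np.ones(n, dtype=bool)
    return ~hi_group


def gene_presence_filter(counts, min_nuclei: int = 10) -> np.ndarray:
    """Gene keep mask: detected (nonzero) in at least ``min_nuclei`` nuclei."""
    if sparse.issparse(counts):
        n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    else:
        n_detected = (np.asarray(counts) > 0).sum(axis=0)
    return n_detected >= min_nuclei


def _stage_metrics(stage: str, cm: CountMatrix, keep: np.ndarray) -> dict:
    if keep.sum() == 0:
        return {
            "stage": stage, "n_nuclei": 0, "mean_genes": np.nan,
            "mean_umi": np.nan, "mean_pct_mito": np.nan,
        }
    return {
        "stage": stage,
        "n_nuclei": int(keep.sum()),
        "mean_genes": float(cm.genes_per_nucleus()[keep].mean()),
        "mean_umi": float(cm.umi_per_nucleus()[keep].mean()),
        "mean_pct_mito": float(cm.pct_mito()[keep].mean()),
    }


def apply_qc(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    config: QCConfig | None = None,
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Run the full cascade; filtering is per subject, gene filter global.

    Stage order: barcode-rank threshold, mitochondrial filter (optional
    hard cap then the dynamic two-group split), doublet-flag removal,
    gene presence filter. Subjects are processed independently, so
    subject order cannot change the result.
    """
    config = config or QCConfig()
    meta = metadata.set_index("barcode").loc[cm.barcodes].reset_index()
    if len(meta) != cm.n_nuclei:
        raise ValueError("metadata does not cover all barcodes")

    umi = cm.umi_per_nucleus()
    pct = cm.pct_mito()
    subjects = meta["subject_id"].to_numpy()
    rows = [_stage_metrics("input", cm, np.ones(cm.n_nuclei, bool))]

    keep = np.ones(cm.n_nuclei, dtype=bool)
    for subj in pd.unique(subjects):
        idx = np.flatnonzero(subjects == subj)
        if subj in config.subject_thresholds:
            thr = config.subject_thresholds[subj]
        elif idx.size >= 100:
            thr = barcode_rank_threshold(
                umi[idx],
                smoothing_window=config.smoothing_window,
                fallback=config.fallback_threshold,
                min_slope=config.min_slope,
                rank_min=config.rank_min,
            )
        else:
            thr = config.fallback_threshold
        keep[idx] &= umi[idx] >= thr
    rows.append(_stage_metrics("barcode_rank", cm, keep))

    for subj in pd.unique(subjects):
        idx = np.flatnonzero((subjects == subj) & keep)
        if idx.size == 0:
            continue
        sub_keep = np.ones(idx.size, bool)
        if config.mito_hard_cap is not None:
            sub_keep &= pct[idx] <= config.mito_hard_cap
        live = idx[sub_keep]
        if live.size:
            dyn = dynamic_mito_filter(pct[live], epsilon=config.mito_epsilon)
            drop = live[~dyn]
            keep[drop] = False
        keep[idx[~sub_keep]] = False
    rows.append(_stage_metrics("mito_filter", cm, keep))

    keep &= ~meta["doublet"].to_numpy(dtype=bool)
    rows.append(_stage_metrics("doublet_removal", cm, keep))

    cm_nuc = cm.subset(nuclei=keep)
    gene_keep = gene_presence_filter(cm_nuc.values, config.min_gene_nuclei)
    cm_out = cm_nuc.subset(genes=gene_keep)
    rows.append(_stage_metrics("gene_filter", cm_out, np.ones(cm_out.n_nuclei, bool)))

    meta_out = meta[keep].reset_index(drop=True).copy()
    meta_out["n_umi"] = cm_out.umi_per_nucleus()
    meta_out["n_genes"] = cm_out.genes_per_nucleus()
    meta_out["pct_mito"] = cm_out.pct_mito()
    report = QCReport(table=pd.DataFrame(rows))
    if not np.all(np.diff(report.nuclei_counts()) <= 0):
        raise AssertionError("QC stage nuclei counts must be non-increasing")
    return cm_out, meta_out, report
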