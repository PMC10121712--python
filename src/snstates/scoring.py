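"""Gene-signature module scores and overlap statistics.

A module score for a nucleus is the mean expression of the signature
genes minus the mean of expression-bin-matched control genes: genes are
binned by their dataset-average expression and each signature gene
draws ``n_ctrl`` controls from its own bin, so the score is centred at
zero for a random gene set and invariant to adding a constant to the
whole matrix. Signature/marker overlaps use the upper-tail
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .de import bh_correct
from .replication import OverlapTest, hypergeom_overlap

DEFAULT_MHC1_GENES = ("HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "B2M")


@dataclass
class GeneSet:
    name: str
    up_genes: list[str]
    down_genes: list[str] | None = None
    provenance: str = ""

    def restricted_to(self, universe: list[str]) -> "GeneSet":
        uni = set(universe)
        up = [g for g in self.up_genes if g in uni]
        if not up:
            raise ValueError(
                f"gene set {self.name!r} has no up-regulated genes in the matrix"
            )
        down = [g for g in self.down_genes if g in uni] if self.down_genes else None
        return GeneSet(self.name, up, down, self.provenance)


def _as_dense(expression) -> np.ndarray:
    return np.asarray(
        expression.todense() if sparse.issparse(expression) else expression, dtype=float
    )


def module_score(
    expression,
    gene_names: list[str],
    gene_set: GeneSet | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-nucleus signature score with bin-matched control genes."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = gene_set.up_genes if isinstance(gene_set, GeneSet) else list(gene_set)
    expr = _as_dense(expression)
    name_idx = {g: i for i, g in enumerate(gene_names)}
    set_idx = [name_idx[g] for g in genes if g in name_idx]
    if not set_idx:
        raise ValueError("no signature genes present in the matrix")
    avg = expr.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(gene_names), dtype=int)
    bins[order] = np.arange(len(gene_names)) * n_bins // len(gene_names)
    rng = np.random.default_rng(seed)
    in_set = np.zeros(len(gene_names), bool)
    in_set[set_idx] = True
    ctrl_idx: list[int] = []
    for gi in sorted(set_idx):
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:  # bin holds only signature genes; fall back to all
            pool = np.flatnonzero(~in_set)
        take = min(n_ctrl, pool.size)
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    return expr[:, sorted(set_idx)].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)


def score_group_test(
    scores: np.ndarray,
    cluster_labels,
    subject_ids=None,
    mode: str = "subject-random",
) -> pd.DataFrame:
    """All pairwise cluster differences in mean module score.

    ``mode='fixed-only'`` fits a Gaussian linear model per pair;
    ``mode='subject-random'`` adds a subject random intercept (Gaussian
    mixed model), guarding against pseudoreplication of nuclei from the
    same donor. BH correction across the pairwise family.
    """
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(cluster_labels)
    levels = sorted(pd.unique(clusters).tolist())
    if mode == "subject-random" and subject_ids is None:
        raise ValueError("subject-random mode requires subject_ids")
    subjects = np.asarray(subject_ids) if subject_ids is not None else None
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            sel = np.isin(clusters, [a, b])
            y = scores[sel]
            x = (clusters[sel] == b).astype(float)
            X = np.column_stack([np.ones_like(x), x])
            if np.ptp(y) == 0:
                diff, se, p = float(y[x == 1].mean() - y[x == 0].mean()), 0.0, 1.0
            elif mode == "fixed-only":
                fit = sm.OLS(y, X).fit()
                diff, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            elif mode == "subject-random":
                grp = subjects[sel]
                if len(np.unique(grp)) < 2:
                    fit = sm.OLS(y, X).fit()
                    diff, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
                else:
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mdl = sm.MixedLM(y, X, groups=grp).fit(reml=True, method="lbfgs")
                    diff, se = mdl.params[1], mdl.bse[1]
                    p = 2 * stats.norm.sf(abs(diff / se)) if np.isfinite(se) and se > 0 else np.nan
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append({"cluster_a": a, "cluster_b": b, "difference": diff, "se": se, "p": p})
    out = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "difference", "se", "p"])
    out["q"] = bh_correct(out["p"]) if len(out) else []
    return out


def signature_from_de(
    de_result: pd.DataFrame,
    estimate_cutoff: float = 0.25,
    q_cutoff: float = 0.05,
    direction: str = "up",
    name: str = "signature",
) -> GeneSet:
    """Signature genes from a DE table: q below cutoff and estimate
    strictly beyond +-``estimate_cutoff``."""
    sig = de_result[de_result["q"] < q_cutoff]
    if direction == "up":
        genes = sig.loc[sig["estimate"] > estimate_cutoff, "gene"].tolist()
    elif direction == "down":
        genes = sig.loc[sig["estimate"] < -estimate_cutoff, "gene"].tolist()
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if not genes:
        raise ValueError(
            "no genes pass the signature thresholds; relax estimate_cutoff/q_cutoff"
        )
    return GeneSet(name=name, up_genes=genes, provenance="derived from DE result")


def marker_overlap_test(
    query_genes: list[str], reference_genes: list[str], universe_size: int
) -> OverlapTest:
    """Upper-tail hypergeometric overlap of two gene sets."""
    q, r = set(query_genes), set(reference_genes)
    return hypergeom_overlap(universe_size, len(q), len(r), len(q & r))


def overlap_panel(
    query_genes: list[str],
    references: dict[str, list[str]],
    universe_size: int,
) -> pd.DataFrame:
    """Overlap of one query set against a panel of published signatures,
    BH-corrected across the panel."""
    rows = []
    for name, ref in references.items():
        ot = marker_overlap_test(query_genes, ref, universe_size)
        rows.append(
            {
                "reference": name, "M": ot.M, "n": ot.n, "N": ot.N, "k": ot.k,
                "p_tail": ot.p_tail, "p_point": ot.p_point,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_correct(out["p_tail"]) if len(out) else []
    return out


def apoe_mhc1_scores(
    expression,
    gene_names: list[str],
    apoe_gene: str = "APOE",
    mhc1_genes: tuple[str, ...] = DEFAULT_MHC1_GENES,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """APOE-high flags and the summed MHC-I score per nucleus.

    A nucleus is APOE-high when its APOE expression exceeds the mean by
    more than two standard deviations of the analyzed nuclei; the MHC-I
    score sums the six class-I genes. Returns the per-nucleus table and
    the Pearson (r, p) between APOE and MHC-I expression.
    """
    expr = _as_dense(expression)
    name_idx = {g: i for i, g in enumerate(gene_names)}
    if apoe_gene not in name_idx:
        raise ValueError(f"{apoe_gene!r} absent from the matrix")
    present = [g for g in mhc1_genes if g in name_idx]
    if not present:
        raise ValueError("no MHC-I genes present in the matrix")
    apoe = expr[:, name_idx[apoe_gene]]
    sd = apoe.std()
    high = apoe > apoe.mean() + 2 * sd if sd > 0 else np.zeros(len(apoe), bool)
    mhc1 = expr[:, [name_idx[g] for g in present]].sum(axis=1)
    if apoe.std() > 0 and mhc1.std() > 0:
        r, p = stats.pearsonr(apoe, mhc1)
    else:
        r, p = np.nan, np.nan
    table = pd.DataFrame({"apoe": apoe, "apoe_high": high, "mhc1_score": mhc1})
    return table, (float(r), float(p))
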