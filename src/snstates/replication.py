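"""Hypergeometric replication machinery.

Concordance between two cohorts is quantified with exact hypergeometric
overlap tests computed in log space (log-gamma combinatorics via
scipy), stable down to p ~ 1e-300. Both the point probability P(X = k)
and the conventional upper tail P(X >= k) are reported. A regulon
replication pipeline applies the TF intersection, per-regulon target
overlaps, BH correction and a strict >2-intersecting-targets filter;
2x2 DEG concordance uses Fisher's exact test with a conditional-MLE
odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .de import bh_correct, estimate_to_log2fc


@dataclass
class OverlapTest:
    """Hypergeometric overlap of an n-set and an N-set in an M universe."""

    M: int
    n: int
    N: int
    k: int
    p_point: float
    p_tail: float


@dataclass
class Regulon:
    """A transcription factor and its inferred target genes."""

    tf: str
    targets: list[str]
    cohort: str = ""

    def __post_init__(self) -> None:
        # targets unique, TF never counted among its own targets
        seen = []
        for t in self.targets:
            if t != self.tf and t not in seen:
                seen.append(t)
        self.targets = seen


def hypergeom_overlap(M: int, n: int, N: int, k: int) -> OverlapTest:
    """Exact overlap test; raises on parameters outside the support."""
    for name, v in [("M", M), ("n", n), ("N", N), ("k", k)]:
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if n > M or N > M:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(n, N) or k < max(0, n + N - M):
        raise ValueError(
            f"k={k} outside the hypergeometric support [{max(0, n + N - M)}, {min(n, N)}]"
        )
    dist = stats.hypergeom(M, n, N)
    p_point = float(np.exp(dist.logpmf(k)))
    p_tail = float(dist.sf(k - 1))
    return OverlapTest(M=M, n=n, N=N, k=k, p_point=p_point, p_tail=min(p_tail, 1.0))


@dataclass
class RegulonReplication:
    tf_concordance: OverlapTest
    table: pd.DataFrame


def regulon_replication(
    discovery: list[Regulon],
    replication: list[Regulon],
    de_gene_list: list[str],
    gene_universe_size: int,
    tf_universe_size: int | None = None,
    min_intersecting_targets: int = 3,
    exclude_tf_from_targets: bool = True,
) -> RegulonReplication:
    """Cross-cohort regulon replication.

    Steps: intersect the TF lists; test overall TF concordance
    (universe = ``tf_universe_size``, default the union of TFs); keep
    TFs that are themselves differentially expressed; test each kept
    regulon's target overlap in the ``gene_universe_size`` universe; BH
    at 0.05; drop regulons with fewer than ``min_intersecting_targets``
    shared targets (strict >2 by default). Output ordering is by TF
    name, so regulon input order cannot matter.
    """
    disc = {r.tf: r for r in discovery}
    repl = {r.tf: r for r in replication}
    shared_tfs = sorted(set(disc) & set(repl))
    M_tf = tf_universe_size if tf_universe_size is not None else len(set(disc) | set(repl))
    overall = hypergeom_overlap(M_tf, len(disc), len(repl), len(shared_tfs))

    de_set = set(de_gene_list)
    rows = []
    for tf in shared_tfs:
        if tf not in de_set:
            continue
        t_disc = set(disc[tf].targets)
        t_repl = set(repl[tf].targets)
        if exclude_tf_from_targets:
            t_disc.discard(tf)
            t_repl.discard(tf)
        k = len(t_disc & t_repl)
        ot = hypergeom_overlap(gene_universe_size, len(t_disc), len(t_repl), k)
        rows.append(
            {
                "tf": tf,
                "n_discovery_targets": len(t_disc),
                "n_replication_targets": len(t_repl),
                "k_intersecting": k,
                "p_tail": ot.p_tail,
                "p_point": ot.p_point,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "tf", "n_discovery_targets", "n_replication_targets",
            "k_intersecting", "p_tail", "p_point",
        ],
    )
    if len(table):
        table["q"] = bh_correct(table["p_tail"])
        table["replicated"] = (table["q"] < 0.05) & (
            table["k_intersecting"] >= min_intersecting_targets
        )
        table = table[table["replicated"]].drop(columns="replicated").reset_index(drop=True)
    else:
        table["q"] = []
    return RegulonReplication(tf_concordance=overall, table=table)


def _conditional_mle_or(table: np.ndarray) -> float:
    """Conditional maximum-likelihood odds ratio (as in R's fisher.test)."""
    a, b = table[0]
    c, d = table[1]
    M, n, N = a + b + c + d, a + b, a + c
    lo, hi = max(0, n + N - M), min(n, N)
    if a == hi:
        return np.inf
    if a == lo:
        return 0.0

    def mean_minus_a(log_or):
        dist = stats.nchypergeom_fisher(M, n, N, np.exp(log_or))
        return dist.mean() - a

    log_or = optimize.brentq(mean_minus_a, -50, 50)
    return float(np.exp(log_or))


def deg_concordance(table) -> tuple[float, float]:
    """Fisher exact test of a 2x2 DE-called concordance table.

    Returns ``(odds_ratio, two_sided_p)``; the odds ratio is the
    conditional MLE (inf/0 at the boundary). A table with a zero margin
    has no defined association: OR is NaN and p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return _conditional_mle_or(t), float(p)


def calls_to_table(calls_a, calls_b) -> np.ndarray:
    """2x2 table from two aligned boolean DE-call vectors."""
    a = np.asarray(calls_a, bool)
    b = np.asarray(calls_b, bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must align")
    return np.array(
        [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]],
        dtype=np.int64,
    )


def summarize_gwas_genes(
    de_tables: pd.DataFrame,
    state_sizes: pd.DataFrame,
    expression_means: pd.DataFrame,
    gene_list: list[str] | None = None,
    sig_column: str = "q",
    sig_cutoff: float = 0.05,
    min_state_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-(gene, cell type) summary of cell-state DE for GWAS genes.

    ``de_tables`` needs columns gene, cell_type, cell_state, contrast
    (``state_vs_rest`` or ``state_vs_state``), estimate and the
    significance column. Hits against states holding less than
    ``min_state_fraction`` of the cell type's nuclei are excluded;
    negative-estimate hits are dropped for one-vs-rest contrasts only.
    Estimates are converted to log2FC and the maximum absolute value per
    (gene, cell type) is reported with the cell type's log10 mean
    expression.
    """
    df = de_tables.copy()
    if gene_list is not None:
        df = df[df["gene"].isin(gene_list)]
    sizes = state_sizes.set_index(["cell_type", "cell_state"])["fraction"]
    frac = df.set_index(["cell_type", "cell_state"]).index.map(sizes)
    df = df[np.asarray(frac) >= min_state_fraction]
    df = df[df[sig_column] < sig_cutoff]
    one_vs_rest_neg = (df["contrast"] == "state_vs_rest") & (df["estimate"] < 0)
    df = df[~one_vs_rest_neg]
    if not len(df):
        return pd.DataFrame(
            columns=["gene", "cell_type", "max_abs_log2fc", "log10_mean_expression"]
        )
    df = df.assign(abs_log2fc=np.abs(estimate_to_log2fc(df["estimate"].to_numpy())))
    out = (
        df.groupby(["gene", "cell_type"])["abs_log2fc"].max().rename("max_abs_log2fc").reset_index()
    )
    expr = expression_means.set_index(["gene", "cell_type"])["mean_expression"]
    mean_e = out.set_index(["gene", "cell_type"]).index.map(expr)
    with np.errstate(divide="ignore"):
        out["log10_mean_expression"] = np.log10(np.asarray(mean_e, dtype=float))
    return out
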