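"""Cell-state analysis: normalization, clustering, neuron classes and
differential cell-state proportions.

The abundance statistic regresses cube-root-transformed per-subject
state proportions on a genotype/disease predictor with sex, age of
death and AD status as covariates, fitted by ordinary least squares —
the same estimator as a Gaussian ``glm``. Proportions for a subject are
``n(state) / n(cell type)`` and subjects below a per-cell-type minimum
nucleus count are excluded outright (strict ``>`` rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import CountMatrix

DEFAULT_MIN_NUCLEI = {
    "astrocytes": 50,
    "microglia": 50,
    "excitatory_neurons": 60,
    "inhibitory_neurons": 60,
    "oligodendrocytes": 60,
    "opcs": 66,
}


def normalize_counts(
    counts, dispersion: float | np.ndarray | None = None, clip: float | None = None
) -> np.ndarray:
    """Per-gene Pearson residuals of an NB depth model.

    The expected count is ``mu_ij = t_i * p_j`` (depth times the pooled
    gene fraction); residuals are ``(x - mu) / sqrt(mu + a_j mu^2)``
    with a per-gene dispersion estimated by method of moments unless
    given, clipped at +-sqrt(n). All-zero genes get residual 0.
    """
    X = counts.values if isinstance(counts, CountMatrix) else counts
    X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)
    n, g = X.shape
    depth = X.sum(axis=1)
    gene_tot = X.sum(axis=0)
    grand = depth.sum()
    if grand == 0:
        return np.zeros_like(X)
    mu = np.outer(depth, gene_tot / grand)
    if dispersion is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            num = ((X - mu) ** 2 - mu).sum(axis=0)
            den = (mu**2).sum(axis=0)
            alpha = np.where(den > 0, np.clip(num / np.maximum(den, 1e-300), 0.0, 100.0), 0.0)
    else:
        alpha = np.broadcast_to(np.atleast_1d(np.asarray(dispersion, float)), (g,))
    var = mu + alpha[None, :] * mu**2
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(var > 0, (X - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    cap = np.sqrt(n) if clip is None else clip
    return np.clip(res, -cap, cap)


def embed_and_cluster(
    normalized: np.ndarray,
    n_components: int = 10,
    k: int | None = None,
    resolution: float | None = None,
    n_top_genes: int = 2000,
    method: str = "kmeans",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA on the most variable genes, then clustering.

    ``method='kmeans'`` (default) needs ``k``; ``method='leiden'`` uses
    graph community detection at the given ``resolution`` when the
    igraph/leidenalg stack is importable. Deterministic under a fixed
    seed. Returns ``(labels, embedding)``.
    """
    Z = np.asarray(normalized, dtype=float)
    n, g = Z.shape
    if g > n_top_genes:
        order = np.argsort(Z.var(axis=0))[::-1][:n_top_genes]
        Z = Z[:, order]
    n_components = min(n_components, min(Z.shape) - 1) or 1
    emb = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
    if method == "kmeans":
        if k is None:
            raise ValueError("kmeans clustering requires k")
        if k == 1:
            return np.zeros(n, dtype=int), emb
        km = KMeans(n_clusters=min(k, n), n_init=10, random_state=seed)
        return km.fit_predict(emb), emb
    if method == "leiden":
        labels = _leiden(emb, resolution or 1.0, seed)
        return labels, emb
    raise ValueError(f"unknown clustering method {method!r}")


def _leiden(emb: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=min(15, n - 1)).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i] if i != j}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def classify_neuron_states(
    expression: np.ndarray,
    gene_names: list[str],
    cluster_labels,
    sample_labels,
    markers: dict[str, str] | None = None,
) -> dict:
    """Assign neuronal clusters to excitatory/inhibitory classes.

    Marker expression is log2(x+1)-transformed, averaged within
    (sample, cluster), then averaged over samples; each cluster takes
    the class of its higher-scoring marker, with exact ties flagged
    ``ambiguous``.
    """
    markers = markers or {"SLC17A7": "EN", "GAD1": "IN"}
    expression = np.asarray(
        expression.todense() if sparse.issparse(expression) else expression, dtype=float
    )
    name_idx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in markers if g not in name_idx]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    df = pd.DataFrame(
        {
            "cluster": np.asarray(cluster_labels),
            "sample": np.asarray(sample_labels),
        }
    )
    for gene in markers:
        df[gene] = np.log2(expression[:, name_idx[gene]] + 1.0)
    per_sample = df.groupby(["cluster", "sample"])[list(markers)].mean()
    per_cluster = per_sample.groupby(level="cluster").mean()
    out = {}
    for cluster, row in per_cluster.iterrows():
        scores = {markers[g]: row[g] for g in markers}
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        out[cluster] = "ambiguous" if ranked[0][1] == ranked[1][1] else ranked[0][0]
    return out


def compute_proportions(
    metadata: pd.DataFrame,
    min_nuclei: dict[str, int] | int | None = None,
) -> pd.DataFrame:
    """Per-subject cell-state proportions within each cell type.

    Subjects contributing no more than the cell-type minimum (strict
    ``>`` to be included) are dropped from that cell type entirely.
    """
    thresholds = dict(DEFAULT_MIN_NUCLEI)
    if isinstance(min_nuclei, int):
        thresholds = {}
        default_thr = min_nuclei
    else:
        thresholds.update(min_nuclei or {})
        default_thr = 60
    rows = []
    for (subj, ct), grp in metadata.groupby(["subject_id", "cell_type"], sort=True):
        thr = thresholds.get(ct, default_thr)
        total = len(grp)
        if total <= thr:
            continue
        for state, n in grp.groupby("cell_state")["barcode"].count().items():
            prop = n / total
            rows.append(
                {
                    "subject_id": subj,
                    "cell_type": ct,
                    "cell_state": state,
                    "n_state_nuclei": int(n),
                    "n_celltype_nuclei": int(total),
                    "proportion": prop,
                    "cuberoot_proportion": prop ** (1.0 / 3.0),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "cell_type", "cell_state", "n_state_nuclei",
            "n_celltype_nuclei", "proportion", "cuberoot_proportion",
        ],
    )


@dataclass
class ProportionModelSpec:
    """Design of the transformed-proportion regression.

    ``predictor`` is a column of the subject table (numeric dose or a
    binary/boolean status); ``covariates`` are additional columns;
    ``subject_filter`` is an optional pandas query string applied to the
    subject table first (e.g. restricting the genetic analyses to
    sporadic-AD samples).
    """

    predictor: str
    covariates: tuple[str, ...] = ("sex",)
    subject_filter: str | None = None


def _encode(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy(float)
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(float)
    levels = sorted(col.unique())
    if len(levels) > 2:
        raise ValueError(
            f"column {col.name!r} has {len(levels)} levels; encode it numerically"
        )
    return (col == levels[-1]).to_numpy(float)


def fit_proportion_model(
    proportions: pd.DataFrame,
    subject_table: pd.DataFrame,
    spec: ProportionModelSpec,
) -> pd.DataFrame:
    """OLS of cube-root proportion on the design, one fit per state.

    Returns the predictor's coefficient, SE and two-sided p per
    (cell type, cell state). Raises on a rank-deficient design, naming
    the aliased columns.
    """
    subj = subject_table.drop_duplicates("subject_id").set_index("subject_id")
    if spec.subject_filter:
        subj = subj.query(spec.subject_filter)
    rows = []
    for (ct, state), grp in proportions.groupby(["cell_type", "cell_state"], sort=True):
        grp = grp[grp["subject_id"].isin(subj.index)]
        if len(grp) < 3:
            continue
        sub = subj.loc[grp["subject_id"]]
        cols = [spec.predictor, *spec.covariates]
        mats, names = [np.ones(len(grp))], ["intercept"]
        for c in cols:
            v = _encode(sub[c])
            if np.ptp(v) > 0:
                mats.append(v)
                names.append(c)
        X = np.column_stack(mats)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            aliased = _aliased_columns(X, names)
            raise ValueError(f"rank-deficient design for {ct}/{state}: aliased {aliased}")
        if spec.predictor not in names:
            continue  # predictor constant within the filtered subjects
        fit = sm.OLS(grp["cuberoot_proportion"].to_numpy(), X).fit()
        j = names.index(spec.predictor)
        rows.append(
            {
                "cell_type": ct,
                "cell_state": state,
                "coef": fit.params[j],
                "se": fit.bse[j],
                "p": fit.pvalues[j],
                "n_subjects": int(len(grp)),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_type", "cell_state", "coef", "se", "p", "n_subjects"]
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            aliased.append(names[j])
    return aliased


def meta_analyze_proportions(results: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Stouffer combination of proportion-model results across cohorts.

    Each input is ``(effect, two_sided_p, n_subjects)``. Two-sided p
    values are converted to z-scores signed by the effect direction
    (a zero effect contributes z = 0), weighted by sqrt(n) and combined
    as ``z = sum(w z) / sqrt(sum w^2)``. Returns the combined z and its
    two-sided p, so exactly opposed effects cancel to z = 0, p = 1.
    """
    if not results:
        raise ValueError("no results to combine")
    zs, ws = [], []
    for effect, p, n in results:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        z = stats.norm.isf(p / 2.0)
        zs.append(float(np.sign(effect)) * z)
        ws.append(np.sqrt(n))
    zs, ws = np.asarray(zs), np.asarray(ws)
    z_comb = float((ws * zs).sum() / np.sqrt((ws**2).sum()))
    return z_comb, float(2 * stats.norm.sf(abs(z_comb)))
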