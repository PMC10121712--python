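"""Reference-to-query label transfer by over-clustering a joint embedding.

Both datasets are standardized per gene over their shared genes,
embedded together with PCA, then shattered into many fine clusters.
Each fine cluster takes the modal label of its reference members
("majority vote"); the label is handed to the query nuclei in the same
fine cluster, with purity, tie and empty-reference flags reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class TransferResult:
    """Per-nucleus assignments and per-fine-cluster vote summaries."""

    assignments: pd.DataFrame  # query nuclei: label, fine cluster, purity
    clusters: pd.DataFrame  # fine clusters: size, n_reference, label, flags


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


def joint_embed(
    reference,
    query,
    reference_genes: list[str],
    query_genes: list[str],
    n_components: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared-gene standardization followed by joint PCA.

    Each dataset is z-scored per gene independently, which removes
    constant per-gene batch offsets before the common embedding.
    Returns (reference embedding, query embedding).
    """
    shared = [g for g in reference_genes if g in set(query_genes)]
    if not shared:
        raise ValueError("reference and query share no genes")
    r_idx = [reference_genes.index(g) for g in shared]
    q_idx = [query_genes.index(g) for g in shared]
    R = _dense(reference)[:, r_idx]
    Q = _dense(query)[:, q_idx]

    def standardize(X):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    stacked = np.vstack([standardize(R), standardize(Q)])
    n_comp = min(n_components, min(stacked.shape) - 1) or 1
    emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(stacked)
    return emb[: len(R)], emb[len(R) :]


def overcluster(
    embedding: np.ndarray, target_fineness: int, seed: int = 0
) -> np.ndarray:
    """Shatter an embedding into at least ``target_fineness`` clusters.

    Centroid clustering with k = target_fineness (clamped, with a
    warning, to the number of points); deterministic under the seed.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if target_fineness < 1:
        raise ValueError("target_fineness must be >= 1")
    k = target_fineness
    if k > n:
        import warnings

        warnings.warn(
            f"target_fineness {k} exceeds the {n} available nuclei; clamping", stacklevel=2
        )
        k = n
    if k == 1:
        return np.zeros(n, dtype=int)
    # duplicate points must co-cluster: cluster the unique rows
    uniq, inverse = np.unique(emb, axis=0, return_inverse=True)
    k = min(k, len(uniq))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels_uniq = km.fit_predict(uniq)
    return labels_uniq[inverse]


def majority_transfer(
    fine_clusters: np.ndarray,
    is_reference: np.ndarray,
    reference_labels,
    embedding: np.ndarray | None = None,
    empty_policy: str = "nearest",
) -> TransferResult:
    """Modal reference label per fine cluster, handed to query members.

    Ties break to the lexicographically smallest label and are flagged.
    Fine clusters without reference members take the label of the
    nearest labeled fine-cluster centroid (``empty_policy='nearest'``,
    requires the embedding) or stay ``unlabeled``.
    """
    fine = np.asarray(fine_clusters)
    ref_mask = np.asarray(is_reference, bool)
    if fine.shape[0] != ref_mask.shape[0]:
        raise ValueError("fine_clusters and is_reference must align")
    if not ref_mask.any():
        raise ValueError("at least one reference nucleus is required")
    labels = np.asarray(reference_labels)
    if labels.shape[0] != int(ref_mask.sum()):
        raise ValueError("reference_labels must align with reference nuclei")
    ref_label_full = np.empty(fine.shape[0], dtype=object)
    ref_label_full[ref_mask] = labels

    cluster_rows = []
    cluster_label: dict = {}
    cluster_purity: dict = {}
    for c in np.unique(fine):
        members = fine == c
        ref_members = members & ref_mask
        n_ref = int(ref_members.sum())
        tie = False
        if n_ref:
            vals, counts = np.unique(ref_label_full[ref_members].astype(str), return_counts=True)
            top = counts.max()
            winners = sorted(vals[counts == top])
            label = winners[0]
            tie = len(winners) > 1
            purity = top / n_ref
        else:
            label = None
            purity = np.nan
        cluster_rows.append(
            {
                "fine_cluster": c,
                "size": int(members.sum()),
                "n_reference": n_ref,
                "label": label,
                "tie": tie,
                "empty_reference": n_ref == 0,
                "purity": purity,
            }
        )
        cluster_label[c] = label
        cluster_purity[c] = purity
    clusters = pd.DataFrame(cluster_rows)

    empties = clusters.loc[clusters["empty_reference"], "fine_cluster"]
    if len(empties):
        if empty_policy == "nearest":
            if embedding is None:
                raise ValueError("empty_policy='nearest' requires the embedding")
            emb = np.asarray(embedding, dtype=float)
            centroids = {
                c: emb[fine == c].mean(axis=0) for c in np.unique(fine)
            }
            labeled = [c for c in centroids if cluster_label[c] is not None]
            for c in empties:
                dists = {d: np.linalg.norm(centroids[c] - centroids[d]) for d in labeled}
                nearest = min(sorted(dists), key=lambda d: dists[d])
                cluster_label[c] = cluster_label[nearest]
                clusters.loc[clusters["fine_cluster"] == c, "label"] = cluster_label[nearest]
        elif empty_policy == "unlabeled":
            for c in empties:
                cluster_label[c] = "unlabeled"
                clusters.loc[clusters["fine_cluster"] == c, "label"] = "unlabeled"
        else:
            raise ValueError(f"unknown empty_policy {empty_policy!r}")

    query_fine = fine[~ref_mask]
    assignments = pd.DataFrame(
        {
            "fine_cluster": query_fine,
            "label": [cluster_label[c] for c in query_fine],
            "purity": [cluster_purity[c] for c in query_fine],
        }
    )
    return TransferResult(assignments=assignments, clusters=clusters)


def transfer_labels(
    reference,
    query,
    reference_genes: list[str],
    query_genes: list[str],
    reference_labels,
    target_fineness: int = 147,
    n_components: int = 10,
    seed: int = 0,
    empty_policy: str = "nearest",
) -> TransferResult:
    """End-to-end transfer: joint embedding, over-clustering, majority vote."""
    emb_ref, emb_query = joint_embed(
        reference, query, reference_genes, query_genes, n_components=n_components
    )
    emb = np.vstack([emb_ref, emb_query])
    fine = overcluster(emb, target_fineness, seed=seed)
    is_ref = np.zeros(len(emb), bool)
    is_ref[: len(emb_ref)] = True
    return majority_transfer(
        fine, is_ref, reference_labels, embedding=emb, empty_policy=empty_policy
    )
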