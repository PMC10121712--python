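"""Synthetic single-nucleus cohort generator.

Builds seeded cohorts with the statistical structure the downstream
analyses assume: several subjects, each contributing nuclei of multiple
cell types with distinct transcriptional states; negative-binomial (or
zero-inflated NB) counts whose log-scale gene means combine a gene
baseline, state and genotype-group effects, a per-subject random
intercept, and a per-nucleus depth factor; a two-component mitochondrial
contamination model; optional ambient low-UMI barcodes and doublets.

Ground-truth tables (state memberships, planted proportions, planted
fold-changes) are returned alongside the counts so parameter-recovery
tests can score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CountMatrix


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CellTypeSpec:
    """One cell type: its name, number of states and state composition.

    ``base_proportions`` are the control-group state proportions and must
    sum to 1; ``fraction`` is the share of a subject's nuclei that belong
    to this cell type (fractions are normalized across cell types).
    """

    name: str
    n_states: int
    base_proportions: tuple[float, ...] | None = None
    fraction: float = 1.0

    def proportions(self) -> np.ndarray:
        if self.base_proportions is None:
            return np.full(self.n_states, 1.0 / self.n_states)
        p = np.asarray(self.base_proportions, dtype=float)
        if len(p) != self.n_states:
            raise ConfigError(
                f"cell type {self.name}: {len(p)} proportions for {self.n_states} states"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError(f"cell type {self.name}: base proportions must be >=0 and sum to 1")
        return p


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Effects are planted on the scales the downstream models estimate:
    ``proportion_effects`` maps ``(group, cell_type, state_index)`` to an
    additive shift of the cube-root state proportion, and ``de_effects``
    maps ``(level, gene_index)`` to a natural-log shift of the gene mean,
    where ``level`` is either a genotype group name or a state label of
    the form ``"<cell_type>.<state_index>"``.
    """

    n_subjects: int = 10
    nuclei_per_subject: int | tuple[int, int] = 200
    n_batches: int = 2
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [CellTypeSpec("microglia", 3)]
    )
    genotype_groups: dict[str, str] | None = None  # subject -> group label
    proportion_effects: dict[tuple[str, str, int], float] = field(default_factory=dict)
    de_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    n_genes: int = 300
    n_mito_genes: int = 5
    mean_umi: float = 1000.0
    nb_dispersion: float | np.ndarray = 0.5
    subject_re_sd: float = 0.3
    zero_inflation: float = 0.0
    depth_log_sd: float = 0.25
    ambient_barcodes: int = 0
    ambient_umi_scale: float = 25.0
    doublet_rate: float = 0.0
    mito_low_mean: float = 0.02
    mito_high_mean: float = 0.25
    mito_high_fraction: float = 0.0
    mito_concentration: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        for name, val in [
            ("zero_inflation", self.zero_inflation),
            ("doublet_rate", self.doublet_rate),
            ("mito_high_fraction", self.mito_high_fraction),
            ("mito_low_mean", self.mito_low_mean),
            ("mito_high_mean", self.mito_high_mean),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        disp = np.atleast_1d(np.asarray(self.nb_dispersion, dtype=float))
        if np.any(disp <= 0):
            raise ConfigError("nb_dispersion must be > 0")
        if self.subject_re_sd < 0:
            raise ConfigError("subject_re_sd must be >= 0")
        if self.n_subjects < 1 or self.n_genes < 1:
            raise ConfigError("n_subjects and n_genes must be >= 1")
        if self.n_mito_genes >= self.n_genes:
            raise ConfigError("n_mito_genes must be smaller than n_genes")
        for ct in self.cell_types:
            ct.proportions()

    def subjects(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_subjects)]

    def groups(self) -> dict[str, str]:
        if self.genotype_groups is not None:
            return dict(self.genotype_groups)
        subs = self.subjects()
        half = len(subs) // 2
        return {s: ("control" if i < half else "sAD") for i, s in enumerate(subs)}


@dataclass
class TruthTables:
    """Ground truth for a generated cohort.

    ``nuclei`` has one row per simulated nucleus (true state, doublet
    flag, mitochondrial component); ``proportions`` carries the planted
    per-(subject, cell type, state) probabilities and realized counts;
    ``de`` lists every planted expression effect with its log2 fold-change.
    """

    nuclei: pd.DataFrame
    proportions: pd.DataFrame
    de: pd.DataFrame


def _state_probs(cfg: CohortConfig, ct: CellTypeSpec, group: str) -> np.ndarray:
    """Group-specific state proportions: cube-root shift, cube, renormalize."""
    base = ct.proportions()
    cuberoot = np.cbrt(base)
    for s in range(ct.n_states):
        shift = cfg.proportion_effects.get((group, ct.name, s), 0.0)
        cuberoot[s] = max(cuberoot[s] + shift, 0.0)
    p = cuberoot**3
    tot = p.sum()
    if tot <= 0:
        raise ConfigError(f"proportion effects remove all states of {ct.name} in group {group}")
    return p / tot


def _gene_effects(cfg: CohortConfig, level: str) -> np.ndarray:
    eff = np.zeros(cfg.n_genes)
    for (lvl, g), val in cfg.de_effects.items():
        if lvl == level:
            if not 0 <= g < cfg.n_genes:
                raise ConfigError(f"de_effects gene index {g} out of range")
            eff[g] += val
    return eff


def generate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, pd.DataFrame, TruthTables]:
    """Simulate one cohort.

    Returns the raw count matrix (nuclei x genes), a per-nucleus metadata
    table and the ground-truth tables. Identical config and seed give
    bit-identical output. Stages draw from independent substreams of the
    single seed so, e.g., adding doublets does not perturb the base counts.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(6)
    rng_assign = np.random.default_rng(ss[0])
    rng_counts = np.random.default_rng(ss[1])
    rng_mito = np.random.default_rng(ss[2])
    rng_meta = np.random.default_rng(ss[3])
    rng_doublet = np.random.default_rng(ss[4])
    rng_ambient = np.random.default_rng(ss[5])

    subjects = config.subjects()
    groups = config.groups()
    n_mito = config.n_mito_genes
    gene_ids = [f"ENSG{j:08d}" for j in range(config.n_genes)]
    gene_names = [f"MT-G{j}" if j < n_mito else f"GENE{j}" for j in range(config.n_genes)]

    # gene baselines: expected per-nucleus totals sum to mean_umi; the
    # mitochondrial share is reassigned per nucleus below
    base_weight = rng_counts.gamma(0.8, 1.0, size=config.n_genes) + 1e-3
    base_weight[:n_mito] = base_weight[:n_mito].mean() if n_mito else 0.0
    nonmito = base_weight[n_mito:].sum()
    base_mean = base_weight * (config.mean_umi / (nonmito + base_weight[:n_mito].sum()))

    subject_b = rng_counts.normal(0.0, config.subject_re_sd, size=config.n_subjects)

    ct_frac = np.array([ct.fraction for ct in config.cell_types], dtype=float)
    ct_frac = ct_frac / ct_frac.sum()

    rows = []  # per-nucleus truth rows
    prop_rows = []
    counts_blocks = []
    lo_hi = (
        (config.nuclei_per_subject, config.nuclei_per_subject)
        if isinstance(config.nuclei_per_subject, int)
        else tuple(config.nuclei_per_subject)
    )
    for si, subj in enumerate(subjects):
        n_nuc = int(lo_hi[0]) if lo_hi[0] == lo_hi[1] else int(
            rng_assign.integers(lo_hi[0], lo_hi[1] + 1)
        )
        n_per_ct = rng_assign.multinomial(n_nuc, ct_frac)
        group = groups[subj]
        for ct, n_ct in zip(config.cell_types, n_per_ct):
            probs = _state_probs(config, ct, group)
            n_per_state = rng_assign.multinomial(n_ct, probs)
            for s, (n_s, p_s) in enumerate(zip(n_per_state, probs)):
                prop_rows.append(
                    {
                        "subject_id": subj,
                        "cell_type": ct.name,
                        "state": s,
                        "true_proportion": p_s,
                        "n_nuclei": int(n_s),
                    }
                )
                if n_s == 0:
                    continue
                level = f"{ct.name}.{s}"
                log_mu = (
                    np.log(base_mean + 1e-300)
                    + _gene_effects(config, level)
                    + _gene_effects(config, group)
                    + subject_b[si]
                )
                depth = rng_counts.normal(0.0, config.depth_log_sd, size=n_s)
                mu = np.exp(log_mu[None, :] + depth[:, None])
                # mitochondrial fraction: two-component Beta model
                high = rng_mito.random(n_s) < config.mito_high_fraction
                f_mean = np.where(high, config.mito_high_mean, config.mito_low_mean)
                c = config.mito_concentration
                frac = rng_mito.beta(f_mean * c, (1 - f_mean) * c)
                if n_mito:
                    nonmito_tot = mu[:, n_mito:].sum(axis=1)
                    mu[:, :n_mito] = (frac * nonmito_tot / (1 - frac) / n_mito)[:, None]
                disp = np.broadcast_to(
                    np.atleast_1d(np.asarray(config.nb_dispersion, float)), (config.n_genes,)
                )
                r = 1.0 / disp
                lam = rng_counts.gamma(r[None, :], mu / r[None, :])
                block = rng_counts.poisson(lam)
                if config.zero_inflation > 0:
                    keep = rng_counts.random(block.shape) >= config.zero_inflation
                    block = block * keep
                counts_blocks.append(block)
                for i in range(n_s):
                    rows.append(
                        {
                            "subject_id": subj,
                            "cell_type": ct.name,
                            "cell_state": level,
                            "mito_component": "high" if high[i] else "low",
                            "doublet": False,
                        }
                    )

    counts = np.vstack(counts_blocks) if counts_blocks else np.zeros((0, config.n_genes), int)
    truth_nuc = pd.DataFrame(rows)
    n_total = len(truth_nuc)
    barcodes = [
        f"{truth_nuc.subject_id.iat[i]}-{i:06d}" for i in range(n_total)
    ]
    truth_nuc.insert(0, "barcode", barcodes)

    meta = _build_metadata(config, truth_nuc, counts, n_mito, rng_meta)

    if config.doublet_rate > 0:
        counts, meta, truth_nuc = _append_doublets(
            counts, meta, truth_nuc, config.doublet_rate, rng_doublet, n_mito
        )

    if config.ambient_barcodes > 0:
        counts, meta, truth_nuc = _append_ambient(
            config, counts, meta, truth_nuc, base_mean, n_mito, rng_ambient
        )

    cm = CountMatrix(
        values=sparse.csr_matrix(counts.astype(np.int64)),
        gene_ids=gene_ids,
        gene_names=gene_names,
        barcodes=list(meta["barcode"]),
    )
    truth_de = pd.DataFrame(
        [
            {
                "level": lvl,
                "gene": gene_names[g],
                "estimate": val,
                "true_log2fc": val * np.log2(np.e),
            }
            for (lvl, g), val in sorted(config.de_effects.items())
        ],
        columns=["level", "gene", "estimate", "true_log2fc"],
    )
    truth_prop = pd.DataFrame(prop_rows)
    return cm, meta, TruthTables(nuclei=truth_nuc, proportions=truth_prop, de=truth_de)


def _build_metadata(cfg, truth_nuc, counts, n_mito, rng) -> pd.DataFrame:
    groups = cfg.groups()
    subjects = cfg.subjects()
    sex = {s: ("M" if rng.random() < 0.5 else "F") for s in subjects}
    aod = {s: float(np.round(rng.normal(80.0, 8.0), 1)) for s in subjects}
    batch = {s: f"B{i % cfg.n_batches}" for i, s in enumerate(subjects)}
    tot = counts.sum(axis=1)
    mito = counts[:, :n_mito].sum(axis=1) if n_mito else np.zeros(len(counts))
    meta = pd.DataFrame(
        {
            "barcode": truth_nuc["barcode"].to_numpy(),
            "subject_id": truth_nuc["subject_id"].to_numpy(),
            "batch_id": truth_nuc["subject_id"].map(batch).to_numpy(),
            "sex": truth_nuc["subject_id"].map(sex).to_numpy(),
            "aod": truth_nuc["subject_id"].map(aod).to_numpy(),
            "genotype_group": truth_nuc["subject_id"].map(groups).to_numpy(),
            "ms4a_genotype": 0,
            "apoe_e4": False,
            "cell_type": truth_nuc["cell_type"].to_numpy(),
            "cell_state": truth_nuc["cell_state"].to_numpy(),
            "n_umi": tot,
            "n_genes": (counts > 0).sum(axis=1),
            "pct_mito": np.where(tot > 0, mito / np.maximum(tot, 1), 0.0),
            "doublet": False,
        }
    )
    return meta


def generate_barcode_rank_profile(
    n_cells: int,
    n_ambient: int,
    cell_umi_scale: float = 5000.0,
    ambient_umi_scale: float = 50.0,
    cell_log_sd: float = 0.3,
    ambient_log_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """UMI totals for a mixture of real cells and ambient barcodes.

    Both populations are log-normal; returns (umi_counts, is_cell flags)
    in generation order. Used as a fixture with a planted answer for
    barcode-rank knee detection.
    """
    if n_cells < 0 or n_ambient < 0:
        raise ConfigError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    cells = np.exp(rng.normal(np.log(cell_umi_scale), cell_log_sd, size=n_cells))
    amb = np.exp(rng.normal(np.log(ambient_umi_scale), ambient_log_sd, size=n_ambient))
    umi = np.maximum(np.concatenate([cells, amb]).round().astype(np.int64), 1)
    flags = np.concatenate([np.ones(n_cells, bool), np.zeros(n_ambient, bool)])
    return umi, flags


def inject_doublets(
    counts: np.ndarray | sparse.spmatrix,
    metadata: pd.DataFrame,
    rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Append synthetic doublets: element-wise sums of random nucleus pairs.

    ``round(rate * n)`` doublets are appended and flagged in the metadata;
    ``rate=0`` returns the inputs unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("doublet rate must be in [0, 1]")
    dense = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
    if rate == 0.0:
        return dense, metadata
    rng = np.random.default_rng(seed)
    n = dense.shape[0]
    k = int(round(rate * n))
    pairs = np.array([rng.choice(n, size=2, replace=False) for _ in range(k)])
    extra = dense[pairs[:, 0]] + dense[pairs[:, 1]]
    rows = metadata.iloc[pairs[:, 0]].copy().reset_index(drop=True)
    rows["barcode"] = [f"DBL-{i:06d}" for i in range(k)]
    rows["doublet"] = True
    rows["n_umi"] = extra.sum(axis=1)
    rows["n_genes"] = (extra > 0).sum(axis=1)
    out_meta = pd.concat([metadata, rows], ignore_index=True)
    return np.vstack([dense, extra]), out_meta


def _append_doublets(counts, meta, truth, rate, rng, n_mito):
    new_counts, new_meta = inject_doublets(counts, meta, rate, seed=int(rng.integers(2**31)))
    k = len(new_meta) - len(meta)
    extra_truth = truth.iloc[:0].copy()
    if k:
        extra_truth = new_meta.iloc[-k:][["barcode", "subject_id", "cell_type", "cell_state"]].copy()
        extra_truth["mito_component"] = "low"
        extra_truth["doublet"] = True
    new_truth = pd.concat([truth, extra_truth], ignore_index=True)
    mito = new_counts[:, :n_mito].sum(axis=1) if n_mito else np.zeros(len(new_counts))
    tot = new_counts.sum(axis=1)
    new_meta = new_meta.copy()
    new_meta["pct_mito"] = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
    return new_counts, new_meta, new_truth


def _append_ambient(cfg, counts, meta, truth, base_mean, n_mito, rng):
    """Low-UMI ambient barcodes drawn from the pooled expression profile."""
    k = cfg.ambient_barcodes
    probs = base_mean / base_mean.sum()
    depth = np.maximum(
        np.exp(rng.normal(np.log(cfg.ambient_umi_scale), 0.5, size=k)).round(), 1
    ).astype(int)
    block = np.vstack([rng.multinomial(d, probs) for d in depth])
    subs = rng.choice(cfg.subjects(), size=k)
    barcodes = [f"AMB-{i:06d}" for i in range(k)]
    tot = block.sum(axis=1)
    mito = block[:, :n_mito].sum(axis=1) if n_mito else np.zeros(k)
    groups = cfg.groups()
    first = meta.iloc[0] if len(meta) else None
    amb_meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "subject_id": subs,
            "batch_id": [meta[meta.subject_id == s].batch_id.iat[0] if (meta.subject_id == s).any() else "B0" for s in subs],
            "sex": [meta[meta.subject_id == s].sex.iat[0] if (meta.subject_id == s).any() else "F" for s in subs],
            "aod": [meta[meta.subject_id == s].aod.iat[0] if (meta.subject_id == s).any() else 80.0 for s in subs],
            "genotype_group": [groups[s] for s in subs],
            "ms4a_genotype": 0,
            "apoe_e4": False,
            "cell_type": "ambient",
            "cell_state": "ambient",
            "n_umi": tot,
            "n_genes": (block > 0).sum(axis=1),
            "pct_mito": np.where(tot > 0, mito / np.maximum(tot, 1), 0.0),
            "doublet": False,
        }
    )
    amb_truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "subject_id": subs,
            "cell_type": "ambient",
            "cell_state": "ambient",
            "mito_component": "low",
            "doublet": False,
        }
    )
    return (
        np.vstack([counts, block]),
        pd.concat([meta, amb_meta], ignore_index=True),
        pd.concat([truth, amb_truth], ignore_index=True),
    )
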