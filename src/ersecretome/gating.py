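"""Marker-ratio gating, population composition and differential expression.

The screen identifies endoplasmic-reticulum-stressed endothelial cells as
those whose depth-normalized expression of every marker gene (canonically
the ER chaperone transcripts Hspa5/BiP and Manf) exceeds the dataset mean
of that marker by a log2 ratio above a threshold (default 1, i.e. more
than 2x the mean).  Candidate secreted factors are genes preferentially
expressed in the gated population (>1.5-fold, rank-sum p < 0.05, mean
normalized expression > 0.1 in the gated population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

logger = logging.getLogger("ersecretome")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_expression(adata: ad.AnnData) -> ad.AnnData:
    """Depth-normalize counts: per-cell totals rescaled to the median depth.

    No log transform is applied.  All-zero cells are dropped with a warning.
    Returns a new AnnData with float X; the raw counts are left untouched.
    """
    depths = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = depths > 0
    if not keep.all():
        logger.warning("normalize_expression: dropping %d all-zero cells", int((~keep).sum()))
    out = adata[keep].copy()
    depths = depths[keep]
    median_depth = float(np.median(depths))
    scale = median_depth / depths
    X = out.X
    if sp.issparse(X):
        X = sp.diags(scale) @ X.astype(float)
        X = sp.csr_matrix(X)
    else:
        X = np.asarray(X, dtype=float) * scale[:, None]
    out.X = X
    out.uns["median_depth"] = median_depth
    return out


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

@dataclass
class GateResult:
    """Per-cell membership in the marker-gated subpopulation."""

    membership: pd.Series  # boolean, indexed by barcode
    markers: list[str]
    threshold: float
    composition: pd.DataFrame  # condition, cluster, n_total, n_gated, pct

    @property
    def n_gated(self) -> int:
        return int(self.membership.sum())


def gate_er_stress_cells(
    adata: ad.AnnData,
    markers: list[str],
    threshold: float = 1.0,
    pseudocount: float = 0.01,
) -> GateResult:
    """Gate cells with elevated expression of every marker gene.

    A cell is a member iff for every marker
    ``log2((x_cell + eps) / (mean_dataset + eps)) > threshold`` where x is
    depth-normalized expression and the mean is over all cells.
    """
    missing = [m for m in markers if m not in adata.var_names]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")

    idx = [adata.var_names.get_loc(m) for m in markers]
    X = _dense(adata.X[:, idx])
    means = X.mean(axis=0)
    ratios = np.log2((X + pseudocount) / (means[None, :] + pseudocount))
    member = (ratios > threshold).all(axis=1)
    membership = pd.Series(member, index=adata.obs_names, name="member")

    comp = _composition(adata.obs, membership)
    logger.info(
        "gate_er_stress_cells: %d / %d cells pass (markers=%s, threshold=%g)",
        int(member.sum()), adata.n_obs, markers, threshold,
    )
    return GateResult(membership=membership, markers=list(markers),
                      threshold=threshold, composition=comp)


def _composition(obs: pd.DataFrame, membership: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "condition": obs["condition"].values,
            "cluster": obs["cluster"].values if "cluster" in obs else pd.NA,
            "member": membership.values,
        }
    )
    grouped = (
        df.groupby(["condition", "cluster"], dropna=False, observed=True)
        .agg(n_total=("member", "size"), n_gated=("member", "sum"))
        .reset_index()
    )
    grouped["pct"] = [
        summarize_population(g, t) for g, t in zip(grouped["n_gated"], grouped["n_total"])
    ]
    return grouped


def summarize_population(n_gated: int, n_total: int) -> float:
    """Percentage of gated cells, reported to one decimal place.

    Returns NaN when the total is zero.
    """
    if n_gated > n_total:
        raise ValueError("gated count exceeds total")
    if n_total == 0:
        logger.warning("summarize_population: zero total, percentage undefined")
        return float("nan")
    return round(100.0 * n_gated / n_total, 1)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _ranksum_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (midranks, tie-corrected
    normal approximation).  Columns constant across both groups get p = 1."""
    res = st.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(np.vstack([A, B]), axis=0) == 0
    p[constant] = 1.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def differential_expression(
    adata: ad.AnnData,
    group_a: np.ndarray,
    group_b: np.ndarray,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene rank-sum comparison of group b versus group a.

    ``group_a``/``group_b`` are boolean masks or barcode lists over the
    normalized matrix.  Fold change is ``(mean_b + eps) / (mean_a + eps)``.
    """
    mask_a = _as_mask(adata, group_a)
    mask_b = _as_mask(adata, group_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be nonempty")
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")

    A = _dense(adata.X[mask_a])
    B = _dense(adata.X[mask_b])
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    pvals = _ranksum_pvalues(A, B)
    de = pd.DataFrame(
        {
            "gene": adata.var_names,
            "mean_expr_a": mean_a,
            "mean_expr_b": mean_b,
            "fold_change": fold,
            "p_value": pvals,
        }
    ).set_index("gene")
    return de


def _as_mask(adata: ad.AnnData, group) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.shape[0] != adata.n_obs:
            raise ValueError("boolean mask length mismatch")
        return group
    return adata.obs_names.isin(group)


def filter_candidates(
    de: pd.DataFrame,
    fold_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_expression: float = 0.1,
) -> list[str]:
    """Candidate genes: fold > threshold, p < threshold and mean expression
    in the target (b) population above the floor.  Annotates the table with
    a ``passes_filters`` column in place and logs the funnel."""
    passes = (
        (de["fold_change"] > fold_threshold)
        & (de["p_value"] < p_threshold)
        & (de["mean_expr_b"] > min_expression)
    )
    de["passes_filters"] = passes
    logger.info(
        "filter_candidates: %d / %d genes retained (fold>%g, p<%g, expr>%g)",
        int(passes.sum()), len(de), fold_threshold, p_threshold, min_expression,
    )
    return de.index[passes].tolist()


# ---------------------------------------------------------------------------
# snRNA-seq style balanced comparison
# ---------------------------------------------------------------------------

def balanced_subsample(
    adata: ad.AnnData,
    group_label: str = "condition",
    target_size: int | None = None,
    seed: int = 0,
) -> ad.AnnData:
    """Uniformly subsample every group to the same size without replacement.

    When ``target_size`` is omitted it defaults to the smallest group size.
    """
    groups = adata.obs[group_label]
    sizes = groups.value_counts()
    if target_size is None:
        target_size = int(sizes.min())
    for name, size in sizes.items():
        if size < target_size:
            raise ValueError(f"group {name!r} has {size} cells < target {target_size}")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for name in sizes.index:
        members = np.flatnonzero((groups == name).values)
        keep.append(rng.choice(members, size=target_size, replace=False))
    order = np.sort(np.concatenate(keep))
    logger.info(
        "balanced_subsample: %d groups x %d cells each", len(sizes), target_size
    )
    return adata[order].copy()


def groupwise_rank_test(
    adata: ad.AnnData,
    gene: str,
    group_label: str = "condition",
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of one gene across groups.

    Uses exact enumeration for small tie-free comparisons (both groups
    <= 25) and the midrank normal approximation otherwise.  Groups that are
    jointly constant get p = 1 by convention.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent")
    values = _dense(adata.X[:, [adata.var_names.get_loc(gene)]]).ravel()
    labels = adata.obs[group_label]
    names = [n for n in pd.unique(labels)]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x = values[(labels == a).values]
            y = values[(labels == b).values]
            if len(x) == 0 or len(y) == 0:
                raise ValueError(f"empty group in pair ({a}, {b})")
            rows.append({"group_a": a, "group_b": b, "p_value": rank_test_pair(x, y)})
    return pd.DataFrame(rows)


def rank_test_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p for one pair of samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        logger.info("rank_test_pair: constant values in both groups, p = 1")
        return 1.0
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (max(len(x), len(y)) <= 25 and no_ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
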