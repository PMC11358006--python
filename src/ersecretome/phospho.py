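"""Phosphoproteomic processing and substrate-motif kinase-activity inference.

The processing chain mirrors the standard Perseus-style workflow: drop
sites with localization probability below 0.75, keep sites quantified in
all four replicates of at least one (condition, timepoint) group, impute
remaining missing values from a downshifted normal distribution (width 0.3,
downshift 1.8 standard deviations, per sample column), then ANOVA across
groups, PCA over samples and Ward/Euclidean clustering of responsive
sites.

Kinase activity is inferred KSEA-style: per stimulation timepoint, a 2x2
Fisher exact test asks whether sites matching a kinase's substrate
recognition motif are over-represented among regulated sites (two-sided
unpaired Welch t-test p < 0.05, stimulus vs control), with
Benjamini-Hochberg correction across kinases; significant kinases are
summarized by the arithmetic mean log2 regulation of their qualifying
targets (motif-positive, localization probability > 0.75, t-test p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ersecretome.io import PhosphoSiteTable

logger = logging.getLogger("ersecretome")

FLANK_LENGTH = 15
CENTER = 7  # 0-based index of the phosphoresidue in the 15-mer
PAD = "_"


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_sites(
    table: PhosphoSiteTable,
    loc_prob_threshold: float = 0.75,
    required_replicates: int = 4,
) -> PhosphoSiteTable:
    """Keep sites with confident localization that are complete in at least
    one (condition, timepoint) group.

    A site passes iff loc_prob >= threshold and all ``required_replicates``
    intensities of some group are measured.
    """
    loc_ok = table.sites["loc_prob"] >= loc_prob_threshold
    groups = table.groups()
    complete = np.zeros(table.n_sites, dtype=bool)
    measured = table.intensity.notna()
    for samples in groups.values():
        if len(samples) >= required_replicates:
            complete |= measured[samples].sum(axis=1).values >= len(samples)
    keep = loc_ok.values & complete
    logger.info(
        "filter_sites: %d -> %d sites (loc_prob >= %g: %d; complete in a group: %d)",
        table.n_sites, int(keep.sum()), loc_prob_threshold,
        int(loc_ok.sum()), int(complete.sum()),
    )
    return table.subset(table.sites.index[keep])


# ---------------------------------------------------------------------------
# downshifted-normal imputation
# ---------------------------------------------------------------------------

def impute_missing(
    table: PhosphoSiteTable,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> PhosphoSiteTable:
    """Impute missing log2 intensities from a downshifted normal, per column.

    For each sample column with measured mean mu and sample standard
    deviation sigma, each missing entry is an independent draw from
    Normal(mu - downshift*sigma, (width*sigma)^2).  Measured entries are
    never altered.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    values = out.intensity.to_numpy(float)
    for j, sample in enumerate(out.intensity.columns):
        col = values[:, j]
        missing = np.isnan(col)
        observed = col[~missing]
        if missing.any():
            if len(observed) < 2:
                raise ValueError(
                    f"column {sample!r} has {len(observed)} measured values; "
                    "imputation needs at least 2"
                )
            mu = observed.mean()
            sigma = observed.std(ddof=1)
            col[missing] = rng.normal(mu - downshift * sigma, width * sigma, missing.sum())
    out.intensity = pd.DataFrame(values, index=out.intensity.index, columns=out.intensity.columns)
    return out


# ---------------------------------------------------------------------------
# responsive sites / PCA / clustering
# ---------------------------------------------------------------------------

def responsive_sites(table: PhosphoSiteTable, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across (condition, timepoint) groups, per site.

    Returns a DataFrame (site_id index) with the F statistic, p value and
    a boolean ``responsive`` (p < alpha).  Sites with zero within-group
    variance everywhere get p = 0 if group means differ else 1.
    """
    groups = table.groups()
    if len(groups) < 2:
        raise ValueError("need at least two (condition, timepoint) groups")
    arrays = [table.intensity[samples].to_numpy(float) for samples in groups.values()]
    if any(a.shape[1] < 2 for a in arrays):
        raise ValueError("every group needs at least 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat, pval = st.f_oneway(*arrays, axis=1)
    # degenerate: no within-group variance anywhere
    within = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    means = np.stack([a.mean(axis=1) for a in arrays])
    degenerate = within == 0
    if degenerate.any():
        differ = np.ptp(means, axis=0) > 0
        pval = np.where(degenerate, np.where(differ, 0.0, 1.0), pval)
        logger.info("responsive_sites: %d degenerate zero-variance sites", int(degenerate.sum()))
    out = pd.DataFrame(
        {"F": fstat, "p_value": pval, "responsive": pval < alpha},
        index=table.sites.index,
    )
    logger.info(
        "responsive_sites: %d / %d responsive at alpha=%g",
        int(out["responsive"].sum()), len(out), alpha,
    )
    return out


def project_pca(intensity: pd.DataFrame, n_components: int = 2):
    """PCA of samples over sites (columns = samples observations).

    Returns (scores DataFrame indexed by sample, explained_variance array
    over all principal axes).  The requested component count is truncated
    to the rank with a warning.
    """
    X = intensity.to_numpy(float).T  # samples x sites
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    max_rank = min(X.shape[0] - 1, X.shape[1]) or 1
    if n_components > max_rank:
        logger.warning("project_pca: truncating n_components %d -> rank %d", n_components, max_rank)
        n_components = max_rank
    pca = PCA(n_components=max_rank)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(max_rank)]
    frame = pd.DataFrame(scores[:, :n_components], index=intensity.columns, columns=cols[:n_components])
    return frame, pca.explained_variance_


def cluster_sites(intensity: pd.DataFrame):
    """Ward-linkage / Euclidean agglomerative clustering of sites.

    Returns (linkage matrix, leaf order as site ids).  Ties break by input
    order (scipy's deterministic behaviour), so leaf order is reproducible.
    """
    if len(intensity) < 2:
        raise ValueError("need at least two sites to cluster")
    Z = sch.linkage(intensity.to_numpy(float), method="ward", metric="euclidean")
    leaves = sch.leaves_list(Z)
    return Z, [intensity.index[i] for i in leaves]


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(Z)

    def build(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.left, node.right
        return (
            f"({build(left)}:{node.dist - left.dist:.6g},"
            f"{build(right)}:{node.dist - right.dist:.6g})"
        )

    return build(tree) + ";"


# ---------------------------------------------------------------------------
# kinase motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinaseMotif:
    """Position-constrained substrate recognition motif over the +-7 flank.

    ``constraints`` maps an offset in -7..+7 (excluding 0) to the set of
    residues allowed there; ``center`` is the set of allowed
    phosphoacceptor residues.
    """

    kinase: str
    constraints: dict[int, frozenset]
    center: frozenset = frozenset("ST")

    def __post_init__(self):
        for off in self.constraints:
            if not (-7 <= off <= 7) or off == 0:
                raise ValueError(f"{self.kinase}: offset {off} outside -7..+7")


def match_motif(flank: str, motif: KinaseMotif) -> bool:
    """True iff the 15-mer satisfies every positional constraint.

    '_' padding never satisfies a constraint; the center residue must be an
    allowed phosphoacceptor.
    """
    if len(flank) != FLANK_LENGTH:
        raise ValueError(f"flank must be {FLANK_LENGTH} residues, got {len(flank)}")
    if flank[CENTER] not in motif.center:
        return False
    for offset, allowed in motif.constraints.items():
        residue = flank[CENTER + offset]
        if residue == PAD or residue not in allowed:
            return False
    return True


def _m(kinase: str, center: str, **offsets) -> KinaseMotif:
    constraints = {int(k.replace("m", "-").replace("p", "")): frozenset(v) for k, v in offsets.items()}
    return KinaseMotif(kinase, constraints, frozenset(center))


# Literature-style linear motifs (illustrative registry, overridable via TSV).
DEFAULT_MOTIFS: list[KinaseMotif] = [
    _m("AKT", "ST", m5="R", m3="R"),                 # R-x-R-x-x-[ST]
    _m("AMPK", "ST", m5="LM", m3="R"),               # [LM]-x-R-x-x-[ST]
    _m("PKA", "ST", m3="R", m2="R"),                 # R-R-x-[ST]
    _m("CK2", "ST", p1="DE", p3="DE"),               # [ST]-x-x-[DE] acidophilic
    _m("CDK1", "ST", p1="P", p3="KR"),               # [ST]-P-x-[KR]
    _m("ERK1", "ST", m2="P", p1="P"),                # P-x-[ST]-P proline-directed
    _m("GSK3", "ST", p4="ST", p1="P"),               # [ST]-P-x-x-[ST] primed
    _m("CAMK2", "ST", m3="R", p2="DE"),              # R-x-x-[ST]-x-[DE]
    _m("PLK1", "ST", m2="DE", p1="FLMIV"),           # [DE]-x-[ST]-[hydrophobic]
    _m("SRC", "Y", m3="DE", p1="DE"),                # acidic-flanked Tyr
]


def load_motifs(path) -> list[KinaseMotif]:
    """Load motifs from a TSV with columns kinase, offset, allowed, center.

    One row per positional constraint; ``center`` (allowed phosphoacceptor
    residues) may be given on any row of the kinase and defaults to "ST".
    """
    df = pd.read_csv(path, sep="\t")
    motifs = []
    for kinase, rows in df.groupby("kinase", sort=False):
        constraints = {
            int(r.offset): frozenset(str(r.allowed)) for r in rows.itertuples() if int(r.offset) != 0
        }
        center = "ST"
        if "center" in rows.columns:
            declared = rows["center"].dropna()
            if len(declared):
                center = str(declared.iloc[0])
        motifs.append(KinaseMotif(str(kinase), constraints, frozenset(center)))
    return motifs


# ---------------------------------------------------------------------------
# kinase-activity inference
# ---------------------------------------------------------------------------

@dataclass
class KinaseActivityResult:
    kinase: str
    condition: str
    timepoint: int
    contingency: tuple[int, int, int, int]  # a,b,c,d
    fisher_p: float
    fdr: float
    significant: bool
    targets: list[str]
    mean_regulation: float  # NaN when no qualifying targets


def site_regulation(
    table: PhosphoSiteTable,
    condition: str,
    timepoint: int,
    control: str = "control",
) -> pd.DataFrame:
    """Per-site log2 regulation and Welch t-test p, stimulus vs control."""
    groups = table.groups()
    key_s, key_c = (condition, timepoint), (control, timepoint)
    if key_s not in groups or key_c not in groups:
        raise ValueError(f"missing group {key_s} or {key_c} in design")
    S = table.intensity[groups[key_s]].to_numpy(float)
    C = table.intensity[groups[key_c]].to_numpy(float)
    if np.isnan(S).any() or np.isnan(C).any():
        raise ValueError("regulation requires a fully imputed table")
    regulation = S.mean(axis=1) - C.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = st.ttest_ind(S, C, axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    return pd.DataFrame(
        {"regulation": regulation, "t_p_value": pval}, index=table.sites.index
    )


def infer_kinase_activity(
    table: PhosphoSiteTable,
    motifs: list[KinaseMotif],
    condition: str,
    timepoint: int,
    control: str = "control",
    fdr_threshold: float = 0.02,
    target_p_threshold: float = 0.05,
    loc_prob_threshold: float = 0.75,
    min_substrates: int = 5,
    alternative: str = "two-sided",
) -> list[KinaseActivityResult]:
    """Substrate-motif kinase-activity inference for one stimulus/timepoint.

    Builds, per kinase, the 2x2 table {motif match} x {regulated} over all
    sites in the (filtered, imputed) table, tests it with a Fisher exact
    test, adjusts across kinases by Benjamini-Hochberg, and summarizes each
    significant kinase by the arithmetic mean regulation of its qualifying
    targets.  Kinases matching fewer than ``min_substrates`` sites are
    excluded from testing (logged).
    """
    reg = site_regulation(table, condition, timepoint, control)
    regulated = (reg["t_p_value"] < target_p_threshold).to_numpy()
    flanks = table.sites["flank"].tolist()
    loc_prob = table.sites["loc_prob"].to_numpy(float)
    n_sites = len(flanks)

    tested: list[tuple[KinaseMotif, np.ndarray]] = []
    for motif in motifs:
        matches = np.fromiter((match_motif(f, motif) for f in flanks), bool, count=n_sites)
        if matches.sum() < min_substrates:
            logger.info(
                "infer_kinase_activity: %s matches %d < %d sites, excluded",
                motif.kinase, int(matches.sum()), min_substrates,
            )
            continue
        tested.append((motif, matches))
    if not tested:
        return []

    pvals = []
    tables = []
    for motif, matches in tested:
        a = int((matches & regulated).sum())
        b = int((matches & ~regulated).sum())
        c = int((~matches & regulated).sum())
        d = int((~matches & ~regulated).sum())
        _, p = st.fisher_exact([[a, b], [c, d]], alternative=alternative)
        pvals.append(float(p))
        tables.append((a, b, c, d))
    reject, fdr, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")

    results = []
    for (motif, matches), table2x2, p, q, sig in zip(tested, tables, pvals, fdr, reject):
        target_mask = matches & regulated & (loc_prob > loc_prob_threshold)
        targets = [table.sites.index[i] for i in np.flatnonzero(target_mask)]
        mean_reg = float(reg["regulation"].to_numpy()[target_mask].mean()) if targets else float("nan")
        results.append(
            KinaseActivityResult(
                kinase=motif.kinase,
                condition=condition,
                timepoint=timepoint,
                contingency=table2x2,
                fisher_p=p,
                fdr=float(q),
                significant=bool(sig),
                targets=targets,
                mean_regulation=mean_reg,
            )
        )
    n_sig = sum(r.significant for r in results)
    logger.info(
        "infer_kinase_activity: %s %dmin: %d kinases tested, %d significant at FDR<%g",
        condition, timepoint, len(results), n_sig, fdr_threshold,
    )
    return results


def activity_to_frame(results: list[KinaseActivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        a, b, c, d = r.contingency
        rows.append(
            {
                "kinase": r.kinase, "condition": r.condition, "timepoint": r.timepoint,
                "a": a, "b": b, "c": c, "d": d,
                "fisher_p": r.fisher_p, "fdr": r.fdr, "significant": r.significant,
                "n_targets": len(r.targets), "mean_regulation": r.mean_regulation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recombinant-protein purity
# ---------------------------------------------------------------------------

def protein_purity(peptides: pd.DataFrame) -> float:
    """Percent purity from unique-peptide intensities.

    ``peptides`` has columns ``intensity`` and boolean ``is_target``;
    purity = 100 * target intensity / total intensity.  Returns NaN when
    the total is zero.
    """
    total = float(peptides["intensity"].sum())
    if total <= 0:
        logger.warning("protein_purity: zero total intensity")
        return float("nan")
    target = float(peptides.loc[peptides["is_target"], "intensity"].sum())
    return 100.0 * target / total
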