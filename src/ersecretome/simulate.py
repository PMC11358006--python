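"""Seed-deterministic generators for every input the pipeline consumes.

Each generator returns both the data and a ground-truth object, so
recovery tests downstream consume planted truth rather than re-deriving
it.  What the generators emulate, and which features of real data they do
not, is documented in docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ersecretome.io import PhosphoSiteTable, ProteinRecord
from ersecretome.phospho import DEFAULT_MOTIFS, KinaseMotif, match_motif

logger = logging.getLogger("ersecretome")

# Swiss-Prot-average amino-acid frequencies (percent).
BACKGROUND_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.46, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.65, "T": 5.36, "W": 1.10,
    "Y": 2.92, "V": 6.85,
}
_AA = np.array(list(BACKGROUND_AA_FREQ))
_AA_P = np.array(list(BACKGROUND_AA_FREQ.values()))
_AA_P = _AA_P / _AA_P.sum()

# Transmembrane-core composition: strongly hydrophobic, Leu/Ile/Val-rich.
_TM_AA = np.array(list("ILVFAM"))
_TM_P = np.array([0.30, 0.22, 0.22, 0.12, 0.08, 0.06])


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class ScSimTruth:
    subpop_mask: np.ndarray  # per-cell boolean
    marker_genes: list[str]
    marker_effect: float
    enriched_genes: list[str]
    enriched_fold: float
    dispersion: float
    depth_range: tuple[int, int]

    @property
    def subpop_fraction(self) -> float:
        return float(self.subpop_mask.mean())


def _gene_dispersion(mu: np.ndarray, dispersion: float, mu0: float = 10.0,
                     phi_min: float = 0.005) -> np.ndarray:
    """Mean-dependent NB dispersion: phi = max(phi_min, dispersion * mu0/mu).

    Mirrors the empirical mean-dispersion trend of droplet scRNA-seq, where
    abundant transcripts (chaperones like Hspa5) have far lower relative
    noise than low-expressed genes.
    """
    return np.maximum(phi_min, dispersion * mu0 / np.maximum(mu, 1e-9))


def simulate_sc_counts(
    n_cells: int = 3000,
    n_genes: int = 2000,
    subpop_fraction: float = 0.094,
    marker_effect: float = 4.0,
    enriched_gene_count: int = 60,
    enriched_fold: float = 3.0,
    dispersion: float = 0.05,
    depth_range: tuple[int, int] = (2000, 8000),
    n_clusters: int = 17,
    condition_label: str = "MI",
    exact_fraction: bool = True,
    seed: int = 0,
) -> tuple[ad.AnnData, ScSimTruth]:
    """Negative-binomial cell-by-gene counts with a planted ER-stressed
    subpopulation.

    Two marker genes (abundant chaperone-like transcripts) and a block of
    ``enriched_gene_count`` secreted-factor-like genes have their means
    multiplied by ``marker_effect`` / ``enriched_fold`` in the planted
    subpopulation.  Per-cell depth is uniform in ``depth_range``; cluster
    labels place the subpopulation predominantly in one of ``n_clusters``
    clusters.  With ``exact_fraction`` the subpopulation size is exactly
    ``round(subpop_fraction * n_cells)``; otherwise Bernoulli.
    """
    rng = np.random.default_rng(seed)
    if not (0 < subpop_fraction < 1):
        raise ValueError("subpop_fraction must be in (0,1)")
    if n_genes < 2 + enriched_gene_count:
        raise ValueError("n_genes must exceed marker + enriched gene count")

    markers = ["Hspa5", "Manf"]
    enriched = [f"SEC{i:04d}" for i in range(enriched_gene_count)]
    background = [f"G{i:05d}" for i in range(n_genes - 2 - enriched_gene_count)]
    genes = markers + enriched + background

    # relative abundances: markers abundant; enriched genes moderately
    # expressed; background log-normal
    rel = np.empty(n_genes)
    rel[0:2] = 0.02  # ~100 counts at a 5000-count median depth
    rel[2 : 2 + enriched_gene_count] = 10 ** rng.normal(-3.0, 0.3, enriched_gene_count)
    rel[2 + enriched_gene_count :] = 10 ** rng.normal(-3.6, 0.8, len(background))
    rel = rel / rel.sum()

    n_sub = int(round(subpop_fraction * n_cells))
    if n_sub < 10:
        logger.warning("simulate_sc_counts: only %d subpopulation cells; tests underpowered", n_sub)
    mask = np.zeros(n_cells, dtype=bool)
    if exact_fraction:
        mask[rng.choice(n_cells, size=n_sub, replace=False)] = True
    else:
        mask = rng.random(n_cells) < subpop_fraction

    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_cells).astype(float)
    fold = np.ones((n_cells, n_genes))
    fold[np.ix_(mask, np.arange(2))] = marker_effect
    fold[np.ix_(mask, np.arange(2, 2 + enriched_gene_count))] = enriched_fold

    mu = depths[:, None] * rel[None, :] * fold
    mu_med = np.median(depths) * rel  # per-gene typical mean for dispersion
    phi = _gene_dispersion(mu_med, dispersion)
    r = 1.0 / phi
    lam = rng.gamma(shape=r[None, :], scale=mu / r[None, :])
    counts = rng.poisson(lam).astype(np.int32)

    clusters = rng.integers(1, n_clusters + 1, size=n_cells)
    stress_cluster = n_clusters
    concentrate = mask & (rng.random(n_cells) < 0.8)
    clusters[concentrate] = stress_cluster

    obs = pd.DataFrame(
        {
            "condition": condition_label,
            "cluster": pd.array(clusters, dtype="Int64"),
        },
        index=pd.Index([f"CELL{i:06d}" for i in range(n_cells)], name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = ScSimTruth(
        subpop_mask=mask, marker_genes=markers, marker_effect=marker_effect,
        enriched_genes=enriched, enriched_fold=enriched_fold,
        dispersion=dispersion, depth_range=depth_range,
    )
    logger.info(
        "simulate_sc_counts: %d cells x %d genes, %d planted subpopulation cells (%.1f%%)",
        n_cells, n_genes, n_sub, 100 * n_sub / n_cells,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# protein sequences
# ---------------------------------------------------------------------------

def _background_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def _signal_peptide(rng: np.random.Generator) -> str:
    """Construct a signal peptide satisfying the tripartite criteria."""
    n_extra = rng.integers(0, 4)
    n_region = "M" + "".join(rng.choice(list("KRNQST"), size=n_extra))
    h_len = rng.integers(8, 13)
    h_region = "".join(rng.choice(list("AILMFVW"), size=h_len))
    spacer = "".join(rng.choice(list("PQNG"), size=4))
    c_region = spacer + "A" + rng.choice(list("QNH")) + "A"
    return n_region + h_region + c_region


def simulate_proteins(
    n_with_sp: int = 200,
    n_without_sp: int = 200,
    n_with_tm: int = 100,
    ers_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Protein sequences with planted signal peptides, internal TM helices
    and C-terminal ER-retention tetrapeptides, plus a truth table.

    Signal peptides are built to satisfy the tripartite heuristic
    (verified at construction).  TM cores are internal 21-mers of strongly
    hydrophobic residues planted at least 40 residues into the mature
    chain, distributed across SP-positive and SP-negative records.  An
    ``ers_fraction`` of records ends in a motif from {KDEL, REDL, RDEL}.
    """
    from ersecretome.triage import detect_signal_peptide  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    n_total = n_with_sp + n_without_sp
    tm_flags = np.zeros(n_total, dtype=bool)
    if n_with_tm:
        tm_flags[rng.choice(n_total, size=min(n_with_tm, n_total), replace=False)] = True
    ers_flags = rng.random(n_total) < ers_fraction
    ers_choices = np.array(["KDEL", "REDL", "RDEL"])

    records, rows = [], []
    for i in range(n_total):
        has_sp = i < n_with_sp
        mature_len = int(rng.integers(120, 400))
        body = _background_seq(rng, mature_len)
        if tm_flags[i]:
            core = "".join(rng.choice(_TM_AA, size=21, p=_TM_P))
            pos = int(rng.integers(40, mature_len - 30))
            body = body[:pos] + core + body[pos + 21 :]
        if has_sp:
            for _ in range(100):
                sp_seq = _signal_peptide(rng)
                seq = sp_seq + body
                if detect_signal_peptide(ProteinRecord("tmp", seq)).positive:
                    break
            else:  # pragma: no cover - construction essentially always succeeds
                raise RuntimeError("failed to construct a detectable signal peptide")
        else:
            seq = "M" + body
        motif = ""
        if ers_flags[i]:
            motif = str(rng.choice(ers_choices))
            seq = seq[:-4] + motif
        rec = ProteinRecord(f"P{i:04d}", seq)
        records.append(rec)
        rows.append(
            {"id": rec.id, "has_sp": has_sp, "has_tm": bool(tm_flags[i]), "ers_motif": motif}
        )
    truth = pd.DataFrame(rows).set_index("id")
    logger.info(
        "simulate_proteins: %d records (%d SP+, %d TM+, %d with ER motif)",
        n_total, n_with_sp, int(tm_flags.sum()), int(ers_flags.sum()),
    )
    return records, truth


# ---------------------------------------------------------------------------
# phosphosite tables
# ---------------------------------------------------------------------------

@dataclass
class PhosphoSimTruth:
    active_kinases: dict  # (condition, timepoint) -> list of kinase names
    effect: float
    target_sites: dict  # kinase -> list of site ids (motif-positive, shifted)
    missing_midpoint: float
    missing_steepness: float


_PHOSPHO_CENTER = np.array(list("STY"))
_PHOSPHO_CENTER_P = np.array([0.86, 0.12, 0.02])  # phosphoproteome S/T/Y shares


def _random_flank(rng: np.random.Generator) -> str:
    left = "".join(rng.choice(_AA, size=7, p=_AA_P))
    right = "".join(rng.choice(_AA, size=7, p=_AA_P))
    center = str(rng.choice(_PHOSPHO_CENTER, p=_PHOSPHO_CENTER_P))
    return left + center + right


def _motif_flank(
    rng: np.random.Generator,
    motif: KinaseMotif,
    exclude: list[KinaseMotif] = (),
    max_tries: int = 10**4,
) -> str:
    """A flank matching ``motif`` and none of the ``exclude`` motifs.

    Cross-matching is resampled away so that each kinase's motif-positive
    site count in the generated table is exactly the requested one."""
    for _ in range(max_tries):
        flank = list(_random_flank(rng))
        center_allowed = sorted(motif.center)
        flank[7] = str(rng.choice(center_allowed))
        for off, allowed in motif.constraints.items():
            flank[7 + off] = str(rng.choice(sorted(allowed)))
        joined = "".join(flank)
        if not any(match_motif(joined, m) for m in exclude):
            return joined
    raise RuntimeError(f"motif {motif.kinase}: could not avoid cross-matches")


def default_design(replicates: int = 4) -> pd.DataFrame:
    """The study design: 4 replicates x {control, CRELD2, VEGFA} x {5,15} min."""
    rows = []
    for cond in ("control", "CRELD2", "VEGFA"):
        for tp in (5, 15):
            for r in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": f"{cond}_{tp}min_R{r}",
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_phospho(
    n_sites: int = 500,
    motifs: list[KinaseMotif] | None = None,
    active_kinases: dict | None = None,
    n_motif_positive: int = 30,
    effect: float = 1.5,
    replicates: int = 4,
    missing_rate: float = 0.1,
    noise_sd: float = 0.3,
    base_mean: float = 23.0,
    base_sd: float = 1.5,
    seed: int = 0,
) -> tuple[PhosphoSiteTable, PhosphoSimTruth]:
    """Phosphosite table with kinase-motif-driven regulation and
    intensity-dependent (left-censoring-like) missingness.

    ``active_kinases`` maps (condition, timepoint) to kinase names from the
    motif registry; each active kinase gets exactly ``n_motif_positive``
    motif-matching sites (verified via match_motif; accidental matches
    among the remaining sites are resampled away) whose intensities are
    shifted by ``effect`` log2 units in the corresponding group.
    Missingness probability decreases logistically with intensity, with
    the midpoint placed so the expected missing fraction equals
    ``missing_rate``.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    if active_kinases is None:
        active_kinases = {("CRELD2", 5): ["AMPK"]}
    rng = np.random.default_rng(seed)
    by_name = {m.kinase: m for m in motifs}
    active_names = sorted({k for ks in active_kinases.values() for k in ks})
    for name in active_names:
        if name not in by_name:
            raise ValueError(f"active kinase {name!r} not in motif registry")

    # assign target blocks
    target_sites: dict[str, list[str]] = {name: [] for name in active_names}
    flanks: list[str] = []
    site_ids = [f"site{i:04d}" for i in range(n_sites)]
    owner = np.full(n_sites, "", dtype=object)
    cursor = 0
    for name in active_names:
        if n_motif_positive < 10:
            raise ValueError("need >= 10 motif-positive sites per active kinase")
        for _ in range(n_motif_positive):
            owner[cursor] = name
            target_sites[name].append(site_ids[cursor])
            cursor += 1
    if cursor > n_sites:
        raise ValueError("more planted targets than sites")

    active_motifs = [by_name[n] for n in active_names]
    for i in range(n_sites):
        if owner[i]:
            others = [m for m in motifs if m.kinase != owner[i]]
            flanks.append(_motif_flank(rng, by_name[owner[i]], exclude=others))
        else:
            for attempt in range(10**6):
                f = _random_flank(rng)
                if not any(match_motif(f, m) for m in active_motifs):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a non-matching flank")
            flanks.append(f)

    design = default_design(replicates)
    groups: dict[tuple[str, int], list[str]] = {}
    for sample, row in design.iterrows():
        groups.setdefault((row["condition"], int(row["timepoint"])), []).append(sample)

    base = rng.normal(base_mean, base_sd, n_sites)
    intensity = np.empty((n_sites, len(design)))
    col_of = {s: j for j, s in enumerate(design.index)}
    for key, samples in groups.items():
        shift = np.zeros(n_sites)
        for name in active_kinases.get(key, []):
            idx = [site_ids.index(s) for s in target_sites[name]]
            shift[idx] += effect
        for s in samples:
            intensity[:, col_of[s]] = base + shift + rng.normal(0.0, noise_sd, n_sites)

    # intensity-dependent missingness: p(x) = missing_max / (1 + exp((x-c)/s))
    steepness = 1.0
    flat = intensity.ravel()
    if missing_rate > 0:
        lo, hi = flat.min() - 10, flat.max() + 10
        for _ in range(80):  # bisect midpoint so mean p == missing_rate
            c = 0.5 * (lo + hi)
            p = 1.0 / (1.0 + np.exp((flat - c) / steepness))
            if p.mean() > missing_rate:
                hi = c
            else:
                lo = c
        midpoint = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp((intensity - midpoint) / steepness))
        missing = rng.random(intensity.shape) < p
        intensity = np.where(missing, np.nan, intensity)
    else:
        midpoint = -np.inf

    loc_prob = np.where(
        rng.random(n_sites) < 0.85,
        rng.uniform(0.76, 1.0, n_sites),
        rng.uniform(0.30, 0.75, n_sites),
    )
    residues = np.array([f[7] for f in flanks])
    sites = pd.DataFrame(
        {
            "protein_id": [f"PROT{i % 200:03d}" for i in range(n_sites)],
            "residue": residues,
            "position": rng.integers(8, 800, n_sites),
            "loc_prob": loc_prob,
            "flank": flanks,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    table = PhosphoSiteTable(
        sites,
        pd.DataFrame(intensity, index=sites.index, columns=design.index),
        design,
    )
    truth = PhosphoSimTruth(
        active_kinases=dict(active_kinases), effect=effect, target_sites=target_sites,
        missing_midpoint=float(midpoint), missing_steepness=steepness,
    )
    logger.info(
        "simulate_phospho: %d sites x %d samples, active kinases %s, %.1f%% missing",
        n_sites, len(design), active_names,
        100 * float(np.isnan(intensity).mean()),
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct(
    genes: list[str],
    conditions: list[str],
    true_folds: dict,
    reference_gene: str = "GAPDH",
    control_condition: str = "control",
    baseline_ct: float = 24.0,
    ct_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table with planted fold changes: Ct = baseline - log2(fold) + noise.

    ``true_folds`` maps (gene, condition) to the planted linear fold versus
    the control; the reference gene is constant (fold 1) everywhere.
    """
    rng = np.random.default_rng(seed)
    for cond in conditions:
        if true_folds.get((reference_gene, cond), 1.0) != 1.0:
            raise ValueError("reference gene must have fold 1 in every condition")
    rows = []
    for gene in genes:
        base = baseline_ct if gene == reference_gene else baseline_ct + rng.uniform(-2, 4)
        for cond in conditions:
            fold = 1.0 if gene == reference_gene else float(true_folds.get((gene, cond), 1.0))
            for rep in range(1, replicates + 1):
                ct = base - np.log2(fold) + rng.normal(0.0, ct_sd)
                rows.append({"gene": gene, "condition": cond, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)
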