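"""Readers and writers for the formats the pipeline touches.

Count matrices use the 10x-style MatrixMarket triplet (``matrix.mtx`` with
genes as rows and cells as columns, plus ``barcodes.tsv`` and
``features.tsv``) with a separate tab-separated cell-metadata table keyed
by barcode.  Phosphosite tables are MaxQuant-"Phospho (STY)Sites"-like TSVs
with one intensity column per sample; zero or empty intensities mean
missing and intensities are log2-transformed on load.  Protein sequences
are plain FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from ersecretome.config import ConfigError

logger = logging.getLogger("ersecretome")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PAD_SYMBOL = "_"

PHOSPHO_REQUIRED_COLUMNS = ("site_id", "protein_id", "residue", "position", "loc_prob", "flank")


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    metadata_path: str | Path,
) -> ad.AnnData:
    """Load an MTX triplet plus cell metadata into an AnnData (cells x genes).

    The metadata table must be tab-separated with a ``barcode`` column and
    ``condition`` / ``cluster`` columns; unknown clusters may be empty.
    """
    mat = scipy.io.mmread(str(matrix_path))  # genes x cells
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
    features = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str).tolist()
    n_genes, n_cells = mat.shape
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares {n_cells} cells"
        )
    if len(features) != n_genes:
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix declares {n_genes} genes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate barcodes")

    counts = sp.csr_matrix(mat.T)
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative counts")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"barcode": str})
    if "barcode" not in meta.columns or "condition" not in meta.columns:
        raise FormatError(f"{metadata_path}: needs 'barcode' and 'condition' columns")
    meta = meta.set_index("barcode")
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise FormatError(f"{metadata_path}: no metadata for barcodes {missing[:5]} ...")
    meta = meta.loc[barcodes]

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["condition"] = meta["condition"].values
    if "cluster" in meta.columns:
        obs["cluster"] = pd.array(meta["cluster"].values, dtype="Int64")
    else:
        obs["cluster"] = pd.array([pd.NA] * len(barcodes), dtype="Int64")

    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene")))
    zero_genes = int((np.asarray(counts.sum(axis=0)).ravel() == 0).sum())
    if zero_genes:
        logger.warning("read_count_matrix: %d all-zero genes retained", zero_genes)
    logger.info("read_count_matrix: %d cells x %d genes", adata.n_obs, adata.n_vars)
    return adata


def write_count_matrix(adata: ad.AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write the 10x-style triplet plus cell metadata; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "metadata": out / "cell_metadata.tsv",
    }
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(X.T), field="integer")
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], header=False, index=False, sep="\t")
    pd.Series(adata.var_names).to_csv(paths["features"], header=False, index=False, sep="\t")
    meta = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "condition": adata.obs["condition"].values,
            "cluster": adata.obs["cluster"].values if "cluster" in adata.obs else pd.NA,
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# phosphosite tables
# ---------------------------------------------------------------------------

class PhosphoSiteTable:
    """Site x sample log2 intensities with site annotation and sample design.

    Attributes
    ----------
    sites : DataFrame indexed by site_id with protein_id, residue, position,
        loc_prob and the +-7 flanking 15-mer ('_'-padded at termini).
    intensity : DataFrame (site x sample) of log2 intensities, NaN = missing.
    design : DataFrame indexed by sample with condition, timepoint, replicate.
    """

    def __init__(self, sites: pd.DataFrame, intensity: pd.DataFrame, design: pd.DataFrame):
        if not sites.index.equals(intensity.index):
            raise ValueError("sites and intensity must share the site index")
        if list(intensity.columns) != list(design.index):
            raise ValueError("intensity columns must match design samples")
        bad = sites.loc[~sites["residue"].isin(["S", "T", "Y"])]
        if len(bad):
            raise FormatError(f"non-STY residues at sites {list(bad.index[:5])}")
        centers = sites["flank"].str[7]
        mismatch = sites.index[centers != sites["residue"]]
        if len(mismatch):
            raise FormatError(f"flank center does not match residue at {list(mismatch[:5])}")
        self.sites = sites
        self.intensity = intensity
        self.design = design

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def groups(self) -> dict[tuple[str, int], list[str]]:
        """Samples per (condition, timepoint) group, in design order."""
        out: dict[tuple[str, int], list[str]] = {}
        for sample, row in self.design.iterrows():
            out.setdefault((row["condition"], int(row["timepoint"])), []).append(sample)
        return out

    def copy(self) -> "PhosphoSiteTable":
        return PhosphoSiteTable(self.sites.copy(), self.intensity.copy(), self.design.copy())

    def subset(self, site_ids) -> "PhosphoSiteTable":
        return PhosphoSiteTable(
            self.sites.loc[site_ids], self.intensity.loc[site_ids], self.design
        )


def _pad_flank(flank: str, position: int) -> str:
    """Pad a terminus-truncated flank with '_' so the phosphoresidue sits at
    the center of the 15-mer; ``position`` is the 1-based site position."""
    flank = flank.strip()
    if len(flank) > 15:
        raise FormatError(f"flank longer than 15: {flank!r}")
    if len(flank) < 15:
        pad_left = 7 - min(7, position - 1)
        flank = PAD_SYMBOL * pad_left + flank
        flank = flank.ljust(15, PAD_SYMBOL)
    return flank


def read_phospho_table(path: str | Path, design: pd.DataFrame) -> PhosphoSiteTable:
    """Read a MaxQuant-like phosphosite TSV against a sample design.

    ``design`` is indexed by sample name with columns condition, timepoint,
    replicate.  Intensity columns in the file are named ``Intensity_<sample>``
    (bare sample names are also accepted); every intensity column must be in
    the design.  Intensities are log2-transformed; zero/empty become NaN.
    """
    df = pd.read_csv(path, sep="\t")
    for col in PHOSPHO_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    intensity_cols = [c for c in df.columns if c not in PHOSPHO_REQUIRED_COLUMNS]
    sample_names = []
    for col in intensity_cols:
        name = col[len("Intensity_"):] if col.startswith("Intensity_") else col
        if name not in design.index:
            raise ConfigError(f"{path}: sample {name!r} (column {col!r}) absent from design")
        sample_names.append(name)
    missing_design = [s for s in design.index if s not in sample_names]
    if missing_design:
        raise ConfigError(f"{path}: design samples without intensity columns: {missing_design}")

    sites = df[list(PHOSPHO_REQUIRED_COLUMNS)].copy()
    sites["flank"] = [
        _pad_flank(f, int(p)) for f, p in zip(sites["flank"], sites["position"])
    ]
    sites = sites.set_index("site_id")
    if sites.index.duplicated().any():
        raise FormatError(f"{path}: duplicate site ids")

    raw = df[intensity_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.nanmin(raw, initial=0.0) < 0:
        raise FormatError(f"{path}: negative intensity")
    with np.errstate(divide="ignore"):
        logged = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    intensity = pd.DataFrame(logged, index=sites.index, columns=sample_names)
    intensity = intensity[list(design.index)]
    logger.info("read_phospho_table: %d sites x %d samples", len(sites), len(design))
    return PhosphoSiteTable(sites, intensity, design)


def write_phospho_table(table: PhosphoSiteTable, path: str | Path) -> None:
    """Write a phosphosite table back to TSV (linear-scale intensities)."""
    out = table.sites.reset_index()
    linear = np.power(2.0, table.intensity.to_numpy(float))
    linear[~np.isfinite(linear)] = 0.0
    for i, sample in enumerate(table.intensity.columns):
        out[f"Intensity_{sample}"] = linear[:, i]
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    for col in ("sample", "condition", "timepoint", "replicate"):
        if col not in design.columns:
            raise FormatError(f"{path}: design needs column {col!r}")
    return design.set_index("sample")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class ProteinRecord:
    """An identifier plus a one-letter amino-acid sequence ('X' permitted)."""

    __slots__ = ("id", "sequence")

    def __init__(self, id: str, sequence: str):
        if not sequence:
            raise FormatError(f"{id}: empty sequence")
        for pos, char in enumerate(sequence, start=1):
            if char not in AA_ALPHABET:
                raise FormatError(f"{id}: invalid residue {char!r} at position {pos}")
        self.id = id
        self.sequence = sequence

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProteinRecord({self.id!r}, len={len(self.sequence)})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinRecord)
            and self.id == other.id
            and self.sequence == other.sequence
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    if not records:
        logger.warning("read_fasta: %s contains no records", path)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns gene, condition, replicate, ct."""
    df = pd.read_csv(path)
    for col in ("gene", "condition", "replicate", "ct"):
        if col not in df.columns:
            raise FormatError(f"{path}: Ct table needs column {col!r}")
    if (df["ct"] <= 0).any():
        raise FormatError(f"{path}: non-positive Ct values")
    return df
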