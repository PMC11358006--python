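"""Sequence-based secreted-protein triage.

A protein is a classical-secretion candidate when it carries an N-terminal
signal peptide but no transmembrane domain.  The signal-peptide call is a
deterministic tripartite heuristic (charged n-region, hydrophobic h-region,
von Heijne (-3,-1) c-region) and transmembrane segments are detected by a
Kyte-Doolittle sliding-window hydropathy scan.  Both are stand-ins for
dedicated predictors; an annotation-table bypass lets callers inject
external signal-peptide/TM calls per gene.  C-terminal ER-retention
tetrapeptides (canonical KDEL plus noncanonical variants such as REDL and
RDEL) are scanned separately because the retention motif governs whether a
signal-peptide-bearing protein is actually released.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ersecretome.io import ProteinRecord

logger = logging.getLogger("ersecretome")

# Kyte-Doolittle hydropathy; 'X' (unknown) contributes 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

HYDROPHOBIC = frozenset("AILMFVWC")
SMALL = frozenset("AGSTC")  # permitted at the (-3,-1) cleavage positions
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

DEFAULT_ER_MOTIFS = ("KDEL", "HDEL", "RDEL", "REDL", "ADEL", "DDEL")
CANONICAL_ER_MOTIF = "KDEL"


@dataclass
class SignalPeptideCall:
    positive: bool
    score: float  # fraction of the three criteria met
    cleavage_position: int | None  # 1-based residue after which cleavage occurs
    reason: str = ""


@dataclass
class TMSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float


@dataclass
class MotifCall:
    motif: str | None
    canonical: bool


@dataclass
class TriageVerdict:
    id: str
    signal_peptide: SignalPeptideCall | None
    tm_segments: list[TMSegment] | None
    ers_motif: MotifCall | None
    secreted_candidate: bool | None
    source: str  # heuristic | annotation | unresolvable


# ---------------------------------------------------------------------------
# signal peptide
# ---------------------------------------------------------------------------

def detect_signal_peptide(record: ProteinRecord) -> SignalPeptideCall:
    """Tripartite signal-peptide heuristic over the first ~40 residues.

    Criteria (all required for a positive call; score = fraction met):

    * n-region: net charge (K/R minus D/E) >= 0 in the first 5 residues;
    * h-region: some window of 8 starting within residues 2-15 contains at
      least 6 hydrophobic residues (A,I,L,M,F,V,W,C);
    * c-region: small residues (A,G,S,T,C) at positions -3 and -1 relative
      to a candidate cleavage site located 5-10 residues after the h-region.
    """
    seq = record.sequence
    if len(seq) < 15:
        return SignalPeptideCall(False, 0.0, None, reason="too short")

    head = seq[:5]
    n_ok = sum(c in POSITIVE for c in head) - sum(c in NEGATIVE for c in head) >= 0

    h_start = None
    for s in range(1, 15):  # 0-based start, i.e. residues 2..15
        window = seq[s : s + 8]
        if len(window) == 8 and sum(c in HYDROPHOBIC for c in window) >= 6:
            h_start = s
            break
    h_ok = h_start is not None

    c_ok = False
    cleavage = None
    if h_ok:
        h_end = h_start + 8  # 0-based index just past the h-region
        for offset in range(5, 11):
            cut = h_end + offset  # cleavage after residue number `cut` (1-based)
            if cut <= len(seq) and cut - 3 >= 0:
                if seq[cut - 3] in SMALL and seq[cut - 1] in SMALL:
                    c_ok = True
                    cleavage = cut
                    break

    score = (n_ok + h_ok + c_ok) / 3.0
    return SignalPeptideCall(bool(n_ok and h_ok and c_ok), score, cleavage)


# ---------------------------------------------------------------------------
# transmembrane segments
# ---------------------------------------------------------------------------

def hydropathy_profile(record: ProteinRecord, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy (one value per window
    center, in sequence order)."""
    values = np.array([KYTE_DOOLITTLE[c] for c in record.sequence])
    if len(values) < window:
        return np.empty(0)
    return np.convolve(values, np.full(window, 1.0 / window), mode="valid")


def detect_tm_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
) -> list[TMSegment]:
    """Kyte-Doolittle sliding-window scan for transmembrane segments.

    Maximal runs of window centers with mean hydropathy above the threshold
    become segments (reported as the 1-based span of those centers); runs
    spanning fewer than ``min_length`` residues are discarded.
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be odd and >= 7")
    seq = record.sequence
    if len(seq) < window:
        logger.warning("detect_tm_segments: %s shorter than window", record.id)
        return []
    values = np.array([KYTE_DOOLITTLE[c] for c in seq])
    means = np.convolve(values, np.full(window, 1.0 / window), mode="valid")
    half = window // 2
    above = means > threshold
    segments: list[TMSegment] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i >= min_length:
                segments.append(
                    TMSegment(
                        start=i + half + 1,
                        end=j - 1 + half + 1,
                        mean_hydropathy=float(means[i:j].mean()),
                    )
                )
            i = j
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# ER-retention motif
# ---------------------------------------------------------------------------

def detect_er_retention_motif(
    record: ProteinRecord,
    motif_set: tuple[str, ...] = DEFAULT_ER_MOTIFS,
) -> MotifCall:
    """Call the C-terminal tetrapeptide iff it is in the motif set."""
    if len(record.sequence) < 4:
        return MotifCall(None, False)
    tail = record.sequence[-4:]
    if tail in motif_set:
        return MotifCall(tail, tail == CANONICAL_ER_MOTIF)
    return MotifCall(None, False)


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

def triage_secretome(
    records: list[ProteinRecord],
    candidates: list[str] | None = None,
    annotations: pd.DataFrame | None = None,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    tm_min_length: int = 15,
    signal_anchor_region: int = 30,
    motif_set: tuple[str, ...] = DEFAULT_ER_MOTIFS,
) -> list[TriageVerdict]:
    """Classify candidates as secreted (signal peptide, no TM domain).

    ``annotations``, when given, is a table with columns ``gene``,
    ``signal_peptide`` (0/1) and ``n_tm_domains`` that overrides the
    heuristics for listed genes (source = "annotation").  TM segments fully
    inside the first ``signal_anchor_region`` residues of a signal-peptide-
    positive protein do not count against it (h-region vs signal-anchor
    ambiguity).  Candidates without a sequence or annotation are reported
    as unresolvable, never dropped.
    """
    by_id = {}
    for rec in records:
        if rec.id in by_id:
            raise ValueError(f"multiple records for {rec.id!r}")
        by_id[rec.id] = rec
    if candidates is None:
        candidates = [rec.id for rec in records]
    ann = None
    if annotations is not None:
        ann = annotations.set_index("gene")

    verdicts: list[TriageVerdict] = []
    for gene in candidates:
        if ann is not None and gene in ann.index:
            row = ann.loc[gene]
            sp_pos = bool(int(row["signal_peptide"]))
            n_tm = int(row["n_tm_domains"])
            rec = by_id.get(gene)
            ers = detect_er_retention_motif(rec, motif_set) if rec else MotifCall(None, False)
            verdicts.append(
                TriageVerdict(
                    id=gene,
                    signal_peptide=SignalPeptideCall(sp_pos, float(sp_pos), None),
                    tm_segments=[TMSegment(0, 0, float("nan"))] * n_tm,
                    ers_motif=ers,
                    secreted_candidate=sp_pos and n_tm == 0,
                    source="annotation",
                )
            )
            continue
        rec = by_id.get(gene)
        if rec is None:
            logger.warning("triage_secretome: no sequence or annotation for %s", gene)
            verdicts.append(TriageVerdict(gene, None, None, None, None, "unresolvable"))
            continue
        sp = detect_signal_peptide(rec)
        tm = detect_tm_segments(rec, tm_window, tm_threshold, tm_min_length)
        if sp.positive:
            kept = [seg for seg in tm if seg.end > signal_anchor_region]
            if len(kept) < len(tm):
                logger.info(
                    "triage_secretome: %s: ignoring %d N-terminal segment(s) as signal anchor",
                    gene, len(tm) - len(kept),
                )
            tm = kept
        ers = detect_er_retention_motif(rec, motif_set)
        verdicts.append(
            TriageVerdict(
                id=gene,
                signal_peptide=sp,
                tm_segments=tm,
                ers_motif=ers,
                secreted_candidate=sp.positive and len(tm) == 0,
                source="heuristic",
            )
        )
    n_in = len(candidates)
    n_out = sum(1 for v in verdicts if v.secreted_candidate)
    logger.info("triage_secretome: %d candidates -> %d secreted", n_in, n_out)
    return verdicts


def verdicts_to_frame(verdicts: list[TriageVerdict]) -> pd.DataFrame:
    """Tidy CSV-ready view of a triage run."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "id": v.id,
                "sp": None if v.signal_peptide is None else v.signal_peptide.positive,
                "sp_score": None if v.signal_peptide is None else v.signal_peptide.score,
                "n_tm": None if v.tm_segments is None else len(v.tm_segments),
                "ers_motif": None if v.ers_motif is None else v.ers_motif.motif,
                "canonical": None if v.ers_motif is None else v.ers_motif.canonical,
                "secreted_candidate": v.secreted_candidate,
                "source": v.source,
            }
        )
    return pd.DataFrame(rows)
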