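"""Triage candidate proteins for classical secretion.

Reads the simulated candidate FASTA, applies the signal-peptide heuristic,
the Kyte-Doolittle transmembrane scan and the C-terminal ER-retention-motif
scan, writes the verdict table, and scores the calls against the planted
truth (the funnel mirrors the screen's transcripts -> secreted-candidates
step).

Usage: python analysis/03_triage_candidates.py [--sim scratch/sim] [--out results]
"""

import argparse
import logging
import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from ersecretome.io import read_fasta
from ersecretome.triage import triage_secretome, verdicts_to_frame

logging.basicConfig(level=logging.INFO, format="%(asctime)s %(levelname)s %(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=REPO / "scratch" / "sim")
    parser.add_argument("--out", type=Path, default=REPO / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = read_fasta(args.sim / "proteins.fasta")
    truth = pd.read_csv(args.sim / "proteins_truth.tsv", sep="\t").set_index("id")

    verdicts = triage_secretome(records)
    frame = verdicts_to_frame(verdicts).set_index("id")
    frame.to_csv(args.out / "triage.csv")

    n_secreted = int(frame["secreted_candidate"].sum())
    print(f"funnel: {len(records)} candidates -> {n_secreted} secreted "
          f"(signal peptide, no TM domain)")

    merged = frame.join(truth, rsuffix="_true")
    for task, pred_col, true_col in (
        ("signal peptide", "sp", "has_sp"),
        ("TM domain", None, "has_tm"),
    ):
        pred = merged[pred_col].astype(bool) if pred_col else merged["n_tm"] > 0
        true = merged[true_col].astype(bool)
        sens = (pred & true).sum() / true.sum()
        spec = (~pred & ~true).sum() / (~true).sum()
        print(f"{task}: sensitivity {sens:.3f}, specificity {spec:.3f}")

    motifs = frame[frame["ers_motif"].notna()]
    truth_motifs = truth[truth["ers_motif"].fillna("") != ""]
    print(f"ER-retention motifs: called {len(motifs)}, planted {len(truth_motifs)}; "
          f"canonical (KDEL): {int(motifs['canonical'].sum())}")


if __name__ == "__main__":
    main()
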