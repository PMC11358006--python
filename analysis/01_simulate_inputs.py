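"""Generate the full synthetic input set with known ground truth.

Writes, under scratch/sim/: the single-cell count-matrix triplets for a
sham-like condition (3.2% planted ER-stressed fraction) and an MI-like
condition (9.4%), the candidate-protein FASTA with its truth table, the
phosphosite table with design and truth, and a qPCR Ct table with planted
fold changes.  Downstream drivers (02-05) consume these files.

Usage: python analysis/01_simulate_inputs.py [--seed 1] [--out scratch/sim]
"""

import argparse
import json
import logging
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from ersecretome.io import write_count_matrix, write_fasta, write_phospho_table
from ersecretome.simulate import (
    simulate_ct,
    simulate_phospho,
    simulate_proteins,
    simulate_sc_counts,
)

logging.basicConfig(level=logging.INFO, format="%(asctime)s %(levelname)s %(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=REPO / "scratch" / "sim")
    parser.add_argument("--full-scale", action="store_true",
                        help="11,743 cells as in the source screen instead of 3,000")
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    n_cells = 11743 if args.full_scale else 3000

    # single-cell matrices: sham-like (3.2%) and MI-like (9.4%) conditions
    truth_summary = {}
    for cond, frac, sub in (("sham", 0.032, 0), ("MI", 0.094, 1)):
        adata, truth = simulate_sc_counts(
            n_cells=n_cells, subpop_fraction=frac, condition_label=cond,
            seed=args.seed + sub,
        )
        write_count_matrix(adata, out / f"sc_{cond}")
        truth_summary[cond] = {
            "n_cells": int(adata.n_obs),
            "planted_subpop": int(truth.subpop_mask.sum()),
            "markers": truth.marker_genes,
            "enriched_genes": truth.enriched_genes,
        }
        print(f"{cond}: {adata.n_obs} cells, planted {truth.subpop_mask.sum()} "
              f"({100 * truth.subpop_mask.mean():.1f}%)")

    # candidate proteins
    records, ptruth = simulate_proteins(200, 200, 100, ers_fraction=0.1, seed=args.seed)
    write_fasta(records, out / "proteins.fasta")
    ptruth.to_csv(out / "proteins_truth.tsv", sep="\t")
    print(f"proteins: {len(records)} records "
          f"({int(ptruth['has_sp'].sum())} SP+, {int(ptruth['has_tm'].sum())} TM+)")

    # phosphosites
    table, phtruth = simulate_phospho(seed=args.seed)
    write_phospho_table(table, out / "phosphosites.tsv")
    table.design.to_csv(out / "design.tsv", sep="\t")
    with open(out / "phospho_truth.json", "w") as fh:
        json.dump(
            {
                "active_kinases": {f"{c}_{t}": ks for (c, t), ks in
                                   phtruth.active_kinases.items()},
                "effect_log2": phtruth.effect,
                "target_sites": phtruth.target_sites,
            },
            fh, indent=2,
        )
    print(f"phospho: {table.n_sites} sites x {len(table.design)} samples, "
          f"active {phtruth.active_kinases}")

    # qPCR screen of three candidate genes against GAPDH
    folds = {("CRELD2", "Tg"): 6.0, ("CRELD2", "Tm"): 4.0,
             ("CAND1", "Tg"): 2.5, ("CAND1", "Tm"): 0.8,
             ("CAND2", "Tg"): 1.0, ("CAND2", "Tm"): 1.1}
    ct = simulate_ct(["GAPDH", "CRELD2", "CAND1", "CAND2"],
                     ["control", "Tg", "Tm"], folds, replicates=3, seed=args.seed)
    ct.to_csv(out / "ct_table.csv", index=False)
    with open(out / "ct_truth.json", "w") as fh:
        json.dump({f"{g}_{c}": v for (g, c), v in folds.items()}, fh, indent=2)
    print(f"qPCR: {len(ct)} wells, planted folds for CRELD2/CAND1/CAND2")

    with open(out / "sc_truth.json", "w") as fh:
        json.dump(truth_summary, fh, indent=2)
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
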