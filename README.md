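# ersecretome

A tested re-implementation of the computational discovery path behind an
ER-stress endothelial secretome screen: marker-ratio gating of stressed
endothelial cells in single-cell count matrices, sequence-based triage of
candidate secreted proteins, and substrate-motif kinase-activity inference
over phosphoproteomic intensity tables — together with seed-deterministic
synthetic-data generators that produce every input with known ground
truth, so the whole pipeline is testable without any external download.

It is aimed at computational biologists who want the individual stages
(gating, secretome triage, Perseus-style imputation, KSEA-style
enrichment, ddCt, 4PL fitting) as reusable, tested library functions
rather than spreadsheet or point-and-click steps.

## What it computes

**Marker-ratio gating.** Cells are depth-normalized to the median library
size; a cell belongs to the ER-stressed subpopulation iff, for *every*
marker gene m (canonically the chaperone transcripts *Hspa5* and *Manf*),

    log2((x_cm + ε) / (x̄_m + ε)) > t,      t = 1 by default,

where x_cm is the cell's normalized expression and x̄_m the dataset mean.
Population composition is summarized per condition and cluster as
100·gated/total, one decimal. Candidate genes are those preferentially
expressed in the gated population: rank-sum p < 0.05, fold change > 1.5,
mean normalized expression in the gated population > 0.1.

**Secretome triage.** A protein is a classical-secretion candidate iff it
has an N-terminal signal peptide and no transmembrane domain. The signal
peptide is called by a deterministic tripartite heuristic (charged
n-region, ≥6/8-hydrophobic h-region in residues 2–15, von Heijne (−3,−1)
c-region); TM segments come from a 19-residue Kyte–Doolittle window at
threshold 1.6. C-terminal ER-retention tetrapeptides (KDEL canonical;
REDL/RDEL/HDEL/ADEL/DDEL noncanonical) are scanned separately. An
annotation table can bypass the heuristics with external predictor
output per gene.

**Phospho / kinase inference.** Sites with localization probability < 0.75
or without one complete 4-replicate group are dropped; missing log2
intensities are imputed per sample column from N(μ − 1.8σ, (0.3σ)²).
Per stimulus and timepoint, sites are "regulated" by a two-sided Welch
t-test (p < 0.05) against control; per kinase, a 2×2 Fisher exact test of
{motif match} × {regulated} is BH-adjusted across kinases (FDR < 0.02),
and significant kinases are summarized by the arithmetic mean log2
regulation of their qualifying targets (motif-positive, localization
probability > 0.75, t-test p < 0.05).

**Assay metrics.** 2^−ΔΔCt fold changes against a reference gene and
control condition; two-arm inducibility quadrant calls; 4PL dose-response
r(d) = bottom + (top−bottom)/(1+(EC50/d)^h) with multi-start least
squares; scratch recovery 100·(A₀−A₁₆)/A₀; fractional area change
100·(LVEDA−LVESA)/LVEDA; heparinase-release difference per mg tissue;
recombinant purity from unique-peptide intensities.

## Worked example

The numbered drivers under `analysis/` run the full path on simulated
inputs (written to `scratch/sim/`, results to `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_gate_and_screen.py
python analysis/03_triage_candidates.py
python analysis/04_phospho_kinase.py
python analysis/05_assay_metrics.py
```

which prints, among other things:

```
sham: gated 96/3000 = 3.2% (planted 96 = 3.2%)
MI: gated 276/3000 = 9.2% (planted 282 = 9.4%)
DE funnel: 2000 genes -> 65 candidates; 60/60 planted enriched genes recovered
funnel: 400 candidates -> 156 secreted (signal peptide, no TM domain)
signal peptide: sensitivity 1.000, specificity 0.945
significant kinase calls (FDR<0.02):
  AMPK @ CRELD2 5 min: FDR 1.03e-26, mean regulation +1.53 log2 (24 targets)
  CRELD2: Tg 5.79 (6.0), Tm 3.98 (4.0) -> induced
4PL: EC50 12.04 (true 12.0), hill 1.27 (true 1.2)
```

Reading: the gate recovers the planted stressed fractions (3.2% of the
sham-like and 9.4% of the MI-like matrix) to within sampling noise; the
differential-expression filter recovers all 60 planted enriched genes;
the triage heuristics separate planted signal peptides and TM helices at
≥0.9 sensitivity/specificity; the single planted active kinase (AMPK-like
motif, +1.5 log2 shift at 5 min) is the unique FDR < 0.02 call with the
correct sign and magnitude; and ddCt/4PL recover their planted parameters.

Equivalent calls are available as library functions, e.g.:

```python
from ersecretome.simulate import simulate_sc_counts
from ersecretome.gating import normalize_expression, gate_er_stress_cells

adata, truth = simulate_sc_counts(seed=1)
gate = gate_er_stress_cells(normalize_expression(adata), truth.marker_genes)
```

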