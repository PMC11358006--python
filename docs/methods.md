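# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design decisions taken where the choices were
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Single-cell gating and screen

Counts are depth-normalized by rescaling each cell's totals to the median
library size; no log transform is applied at this stage, because the gate
operates on ratios. A cell is gated into the ER-stressed subpopulation
iff, for every marker gene, log2((x + ε)/(x̄ + ε)) > t with ε = 0.01 and
t = 1 by default. The denominator is the *dataset-wide mean* normalized
expression of the marker: the gate is a per-cell decision against a global
reference, which keeps zero-expressing cells out (with ε preventing −∞)
and makes the threshold interpretable as "more than 2^t times the average
cell". Raising t can only shrink the membership (tested property).

Differential expression between the gated population and the rest uses a
two-sided Wilcoxon rank-sum test per gene on normalized expression, with
midranks and the tie-corrected normal approximation; for small tie-free
comparisons (both groups ≤ 25) the exact null distribution is enumerated.
No multiple-testing correction is applied to the screen — the candidate
filter is deliberately a raw p < 0.05 combined with fold > 1.5 and a mean
normalized expression > 0.1 floor in the gated (target) population, since
the downstream sequence triage and inducibility screens act as the real
specificity filters. Fold changes are ε-regularized ratios of group means
(b vs a), so a gene absent from both groups has fold 1 and p 1.

The balanced-subsample comparison (for public snRNA-seq-style reanalyses)
draws each condition down to the smallest group size — or an explicit
target — uniformly without replacement, reproducibly under a seed, then
compares a gene across groups by pairwise rank-sum tests.

Cluster labels are taken as input; clustering and embedding are upstream
concerns out of scope here.

## Secretome triage

The signal-peptide call is a deterministic tripartite heuristic over the
N-terminal 40 residues: (i) net charge (K/R minus D/E) ≥ 0 in the first 5
residues; (ii) an 8-residue window starting within residues 2–15 with ≥ 6
hydrophobic residues {A,I,L,M,F,V,W,C}; (iii) small residues {A,G,S,T,C}
at −3 and −1 of a candidate cleavage site 5–10 residues after the
h-region (the classical (−3,−1) rule). The score is the fraction of
criteria met; the call requires all three. This is an intentionally simple
stand-in for a dedicated predictor; the triage accepts an annotation table
(gene, signal_peptide, n_tm_domains) that overrides the heuristics so
external predictor output can be injected verbatim.

TM segments are maximal runs of 19-residue Kyte–Doolittle window centers
with mean hydropathy above 1.6; runs spanning fewer than 15 residues are
discarded. The run-of-centers length rule matters: counting the full
window extent would make any single crossing a 19-residue "segment" and
floods background sequences with false calls (~27% measured), whereas the
center-run rule keeps the background false-positive rate at ~0.2% while
detecting planted 21-residue hydrophobic cores at ≥ 0.99 sensitivity.
'X' contributes hydropathy 0. A TM segment contained in the first 30
residues of a signal-peptide-positive protein is ignored (the h-region of
a signal peptide is locally indistinguishable from a signal anchor); the
exemption is logged when applied.

A protein is a secreted candidate iff signal-peptide-positive with no
remaining TM segment. The C-terminal tetrapeptide is called an
ER-retention motif iff it is in the configured set, default
{KDEL, HDEL, RDEL, REDL, ADEL, DDEL} with KDEL flagged canonical. Both
REDL and RDEL appear in the default set deliberately: both spellings occur
in the KDEL-variant literature for noncanonical retention signals.

## Phosphoproteomics

Site filtering keeps sites with localization probability ≥ 0.75 that are
quantified in all four replicates of at least one (condition, timepoint)
group. Imputation is the standard downshifted-normal scheme applied per
sample column: with measured mean μ and sample standard deviation σ,
missing entries are drawn i.i.d. from N(μ − 1.8σ, (0.3σ)²). Width 0.3 and
downshift 1.8 are the package defaults; measured values are never touched,
and the draw is reproducible under a seed. This models missingness as
left-censoring of low-abundance ions, which is also exactly the mechanism
the phospho generator plants (see below).

Responsive sites are one-way ANOVA across all (condition, timepoint)
groups at α = 0.05. Degenerate sites with zero within-group variance
everywhere get p = 0 if group means differ and p = 1 otherwise (logged).
Sample-level structure is summarized by column-centered PCA over
responsive sites, and responsive sites are clustered by Ward linkage on
Euclidean distances with scipy's deterministic tie-breaking; the
dendrogram is exportable as Newick.

Kinase-activity inference is KSEA-style. Per stimulus condition and
timepoint: a site is *regulated* iff a two-sided Welch t-test against the
control group at that timepoint gives p < 0.05 (Welch, because 4-replicate
groups after imputation have no reason to share variance; undirected,
because the enrichment is categorical — direction enters through the mean
regulation's sign). Per kinase, the 2×2 table {motif match} × {regulated}
over all surviving sites is tested with a two-sided Fisher exact test;
p-values are Benjamini–Hochberg-adjusted across the kinases tested within
that (stimulus, timepoint) family, significant at FDR < 0.02. For a
significant kinase, targets are the sites that are motif-positive with
localization probability > 0.75 and t-test p < 0.05, and the reported
activity is the arithmetic mean of their log2 regulations (stimulated
minus control means). Kinases matching fewer than 5 sites are excluded
from testing — the usual minimum-substrate-set requirement in
substrate-based inference; near-empty motif rows otherwise yield
degenerate tables whose "significance" is meaningless. The minimum, the
Fisher sidedness and all thresholds are configurable.

The built-in motif registry holds ten literature-style linear motifs
(AKT R-x-R-x-x-[ST], AMPK [LM]-x-R-x-x-[ST], PKA R-R-x-[ST], CK2
[ST]-x-x-[DE], CDK1 [ST]-P-x-[KR], ERK1 P-x-[ST]-P, GSK3, CAMK2, PLK1,
SRC). It is illustrative, not a database copy, and can be replaced from a
TSV (kinase, offset, allowed, center). Matching is exact positional set
membership over the ±7 flank with '_' padding never satisfying a
constraint.

## Assay metrics

ΔΔCt uses replicate-mean Ct per (gene, condition) — unpaired plate design
— with ΔCt against the reference gene, ΔΔCt against the control
condition, fold = 2^−ΔΔCt, assuming doubling efficiency. Conditions
missing the reference are reported missing, never silently dropped.
Adding a constant to every well leaves all folds unchanged (tested).

The inducibility call classifies a gene from its fold changes under two
independent ER-stress inducers: induced iff both ≥ T, repressed iff both
≤ 1/T, partial iff exactly one ≥ T, else unchanged. The default T = 2 is
a package decision — the underlying screen marks only the no-change lines
at ratio 1 and states no numeric cutoff — and is configurable.

The 4PL model r(d) = bottom + (top−bottom)/(1+(EC50/d)^h) is fitted by
least squares on log10 dose for conditioning, with multi-start
initialization (5 EC50 grid points × Hill slopes ±{0.5,1,2}) and
Levenberg–Marquardt refinement at tight tolerances. Decreasing curves are
returned in canonical order (bottom ≤ top, negated Hill). A flat response
raises a convergence error instead of returning a spurious EC50. On
noise-free curves across hill ∈ {0.5,1,2} × EC50 ∈ {0.1,1,10} the EC50
relative error is below 1e-5 (in practice ~1e-15).

Scratch recovery, fractional area change, heparinase release and purity
are the closed forms given in the README; negative recovery/release are
returned with warnings rather than clipped, since they are legitimate
noise outcomes.

## Synthetic data: what is and is not emulated

All generators are seed-deterministic and emit a truth object; every
downstream recovery test consumes that truth rather than re-deriving it.

**Single-cell counts.** Negative-binomial counts with per-cell depth
uniform in 2,000–8,000 and a mean-dependent dispersion trend
φ_g = max(0.005, φ·μ₀/μ_g) with μ₀ = 10 and φ = 0.05 — the empirical
scRNA-seq pattern in which abundant transcripts have much lower relative
noise than rare ones. The two marker genes are modeled as abundant
chaperone-like transcripts (~100 counts at median depth); the planted
subpopulation (default 9.4% of cells, exact count) multiplies marker
means by 4 and a 60-gene enriched block by 3. Cluster labels place ~80%
of the subpopulation in one of 17 clusters. Default scale is 3,000 cells
× 2,000 genes, chosen so a full pipeline run and its 20-seed recovery
suite complete comfortably on a laptop; the 11,743-cell scale of the
source screen is available behind `--full-scale`. Not emulated:
co-expression structure, batch effects, doublets, ambient RNA — so
passing recovery tests demonstrate correctness of the gate's arithmetic
under realistic count noise, not robustness to those artifacts.

**Proteins.** Background composition uses Swiss-Prot-average amino-acid
frequencies. Planted signal peptides are built from the same tripartite
grammar the detector checks (and verified detectable at construction), so
signal-peptide *sensitivity* on this benchmark is by construction and the
informative number is the *specificity* on background sequences (~0.94).
Planted TM cores are internal 21-mers drawn from {I,L,V,F,A,M} weighted
toward Leu/Ile/Val, as in real TM helices. An `ers_fraction` of records
ends in KDEL/REDL/RDEL.

**Phosphosites.** The study design (4 replicates × {control, CRELD2,
VEGFA} × {5, 15} min) with site base intensities N(23, 1.5²) log2 units
and replicate noise sd 0.3. Each active kinase gets exactly its requested
number of motif-positive sites; target flanks are resampled until they
match *only* their designated kinase's motif across the registry, and
background flanks until they match no active kinase — so the planted
contingency tables are exactly controlled. Missingness is applied with
probability logistic-decreasing in intensity (midpoint solved by
bisection so the expected missing fraction hits the requested rate,
default 10%), i.e. the left-censoring the downshifted imputation assumes.
Localization probabilities are a spike above 0.75 (85%) with a tail
below. Not emulated: peptide-level identification, shared peptides,
TMT-style ratio compression.

**Ct tables.** Ct = baseline − log2(fold) + N(0, sd) with the reference
gene flat; recovering the planted fold is a log2 identity plus noise.

## Numerical choices and degenerate inputs

- Pseudocount ε = 0.01 in gating ratios and DE folds.
- Rank tests: midranks with tie-corrected normal approximation; exact
  enumeration only for tie-free groups ≤ 25; jointly constant groups
  give p = 1 by convention.
- All-zero cells are dropped at normalization (warning); all-zero genes
  are retained and logged at load.
- Imputation requires ≥ 2 measured values per column (σ undefined below
  that) and errors out rather than guessing.
- Fisher p-values use the exhaustively verified two-tail hypergeometric
  definition (sum of all table probabilities ≤ that of the observed
  table, with a 1+1e-9 relative guard against float ties).
- PCA components are truncated to the matrix rank with a warning.
- Ward clustering inherits scipy's deterministic input-order tie-break;
  leaf order is therefore reproducible for identical input order.

## Known limitations

- The triage heuristics approximate, not reproduce, dedicated
  signal-peptide/TM predictors; exact replication of an external screen's
  candidate list requires the annotation-table bypass.
- The rank-sum DE stand-in will not reproduce gene counts from screens
  performed with other (unpublished) test implementations.
- The motif registry is illustrative; real substrate specificities are
  broader and overlapping, and overlapping motifs in a user registry will
  produce correlated kinase calls — the benchmark's orthogonality is a
  property of the generator, not of biology.
- The 2^−ΔΔCt method assumes perfect doubling efficiency and an
  unregulated reference gene.
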