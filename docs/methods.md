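# Methods

This note documents the statistical procedures cardioniche implements, the
defaults they ship with, the design choices made where the procedure was
genuinely open, and what the synthetic study conditions do and do not show
about real data.

## Data model and quality control

Count matrices are sparse nonnegative integers over observations × genes,
with the observation kind (`cell`, `nucleus`, `spot`) carried explicitly
because the QC rules differ. Cells/nuclei are retained when they have
strictly more than 200 detected genes and a mitochondrial + ribosomal read
fraction strictly below 20% (cells) or 5% (nuclei); spots are retained with
strictly more than 500 total UMIs and at least 300 detected genes. The
wording behind the spot rule is ambiguous about whether the gene bound is
strict; we read the UMI bound as strict and the gene bound as inclusive,
and both are configurable. Mito/ribo genes default to the `MT-`, `RPS`,
`RPL` symbol prefixes and can be overridden by an explicit list. Doublet
detection is not re-implemented; externally computed scores can be
thresholded (default cutoff 0.3). Normalization is per-row total-count
scaling to the median row sum followed by log1p — the ecosystem default;
the upstream description does not pin down a formula, so all scoring
operates on this log-normalized matrix and the choice is a documented
deviation hazard when comparing against pipelines that score raw counts.

Genomic intervals (peaks, SNPs) use the BED convention throughout: 0-based,
half-open. A flag converts 1-based variant coordinates on input.

## Drug-target database

One row per bioactivity record: drug, clinical phase (0–4), organism,
target gene, target family, pChEMBL, ATC codes. Filtering keeps human
records at `max_phase ≥ 4` (a preclinical mode accepts 1–3) and gates
activity per target family at the pChEMBL equivalent of the family's nM
cutoff: kinase 30 nM → 7.523, GPCR and nuclear receptor 100 nM → 7.0, ion
channel 10 µM → 5.0, other 1 µM → 6.0. The comparison is inclusive (the
cutoffs are printed as "≤") and is applied to the **maximum** pChEMBL per
drug–target pair; records with missing pChEMBL are dropped when the
activity gate is on and kept otherwise. ATC grouping places a drug under
every distinct code prefix at the requested level ("unclassified" when it
has none).

## Gene-set scoring and ranking

The plain score is the arithmetic mean of a set's log-normalized
expression per cell (invariant to gene order and duplicates). The
binned-reference score ranks genes by global mean expression, cuts them
into 25 equal-size bins, draws 50 control genes per set gene uniformly
without replacement from the gene's bin (set genes excluded; with
replacement plus a warning when a bin is exhausted), and subtracts the
pooled-control mean from the set mean. On exchangeable data this score is
centered on zero for a random set, which the tests check across seeds.

Per-state ranking uses a two-sided rank-sum test of in-state vs all other
cells: exact null enumeration when both sides have ≤ 8 tie-free
observations, otherwise the normal approximation with mid-rank tie
correction. Fold changes on scores use log₂((m_in+ε)/(m_out+ε)) with
ε = 1e-9 and means clipped at zero, since binned-reference scores can be
negative. A drug is flagged for a state at log₂FC > 2 and BH-adjusted
p < 0.05. Differential expression is a Welch two-sample *t* per gene
(constant genes get p = 1) with BH correction; its fold change follows the
log-normalized convention log₂((expm1(m_in)+ε)/(expm1(m_out)+ε)). Gene–
score correlation is Pearson *r* with the exact *t*-distribution p;
constant genes get r = NaN and are excluded from the correction. The
pan-neuronal marker preset {PRPH, NEFL, NEFM, NEFH} ships as a named
constant for neuronal-content scoring of spots.

## Spatial enrichment and the product niche

Structure enrichment compares, for each cell state, the share of total
abundance it contributes inside vs outside an annotated structure. The
default pools abundances across spots before forming proportions (robust
to low-abundance spots); a per-spot-mean variant is available. The odds
ratio is odds_in/odds_out; significance comes from a Yates-corrected
chi-square on the rounded 2×2 abundance table, BH-corrected across states.
Whether the original analysis fed proportions or counts to the chi-square
is not stated; both variants exist, counts-like rounded abundances being
the default. Degenerate proportions give OR 0 or ∞ with the p-value still
defined.

Spot adjacency links spots within 1.5 × the minimum pairwise distance in
array coordinates — on a hex-offset lattice this yields each interior
spot's 6 neighbours. The stress-niche caller multiplies two states'
per-spot abundances, takes spots with product > 0.03, and keeps connected
components of size strictly greater than 5.

## NMF niche discovery

The factor scan fits Frobenius-loss NMF (coordinate descent, deterministic
`nndsvda` initialization) for each n_fact in {5,…,14} — 95 factors. The
original pipeline used a Bayesian NMF; coordinate-descent Frobenius NMF is
a documented approximation that keeps the selection procedure intact. For
comparability across runs, each factor's spot loadings are normalized to
unit mean before effect sizes are computed. The structure effect size is
Cohen's *d* with pooled SD (the source never defines "effect size"; *d* is
the conventional choice), capped at ±10⁶ in zero-SD degenerate cases. The
permutation p is the inclusive fraction of label permutations with
d* ≥ d_obs (an add-one smoothed estimate is reported alongside; exhaustive
enumeration is available for tiny inputs). The best-factor search spans
all runs jointly; "multiple" fine-factors is read as ≥ 2, with the
smallest qualifying n_fact on ties.

## GWAS SNP enrichment

Peak counts are binarized at > 0 and aggregated by state; a peak is open
for a state when at least 5% (inclusive) of its barcodes show it. The SNP
proportion counts SNPs inside ≥ 1 open peak once, via per-chromosome
interval trees. The permutation null redraws, uniformly, an open-peak set
of the observed size from the state's unified peak set; p is the inclusive
fraction of draws whose SNP proportion reaches the observed one, and
exhaustive enumeration replaces sampling when the subset count is ≤ 10⁴.
BH correction spans the full trait × state grid by default (the correction
scope was unstated; per-trait is available).

## Ligand–receptor screen

The database format mirrors a CellPhoneDB user module: interactions over
protein ids or complex names, a complex-expansion table, an optional
protein→gene map (validation rejects partners that resolve to neither),
and proxy flags marking biosynthetic-enzyme/transporter stand-ins for
non-gene-encoded ligands (treated as ordinary partner genes). A complex
partner's expression is the minimum over member means (limiting subunit;
a mean rule is available). The LR mean averages the ligand partner's mean
in the sender state and the receptor partner's in the receiver state. The
permutation p shuffles cell-state labels; states with fewer than 10 cells,
single-state inputs, and zero observed LR means all give p = 1. The screen
restricts to ordered pairs of niche states and requires every member gene
expressed in ≥ 10% of its state's cells, plus either permutation p < 0.05
("statistical" mode) or at least one member DEG at adjusted p < 0.05 and
log₂FC > 0.1 ("deg" mode).

## Synthetic study conditions

The generators are seeded end to end and define the package's standing
test conditions:

- **Expression** — 600 cells, 400 genes, three states with disjoint
  10-gene marker programs. Counts are negative-binomial with dispersion
  0.5 (var = µ + 0.5µ²), lognormal per-gene base means; marker genes have
  a low out-of-state baseline (mean 0.3) and are shifted 2⁴-fold in their
  state, the profile of a clear cell-state marker such as a natriuretic
  peptide in stressed cardiomyocytes. A spot mode rescales each row's mean
  profile to a lognormal UMI depth (µ = 8, σ = 0.3 on the log scale,
  median ≈ 3,000 UMIs) to emulate Visium capture depth.
- **Spots** — a 20×20 hex-offset lattice (unit spacing) tiled into four
  row bands: background myocardium, a two-compartment node (central,
  dominated by a pacemaker-like state; peripheral, dominated by a
  glial/macrophage program — the dominant programs are disjoint so the
  compartments are recoverable), and a stress region where two states
  co-occur at high abundance. Abundances are Dirichlet draws around the
  region mixture (concentration 50) scaled by lognormal spot totals around
  7 cells/spot (the occupancy of a Visium spot in myocardium); 8 low-
  abundance filler states bring the state count to 16 so the factor scan's
  upper rank is feasible.
- **Peaks/SNPs** — 120 non-overlapping 501-bp peaks on one chromosome,
  three states of 100 barcodes each opening a random 30% of peaks
  (detection probability 0.3 in open peaks, 0.01 otherwise). The planted
  trait's 200 SNPs fall inside the target state's open peaks at 5× the
  uniform rate; a matched null trait is uniform.
- **Drugs** — one hit drug per state targeting exactly its marker program
  (GPCR family, pChEMBL 7.5, phase 4, human) plus decoys failing each gate
  (potency, organism, phase, missing pChEMBL, family cutoff).
- **LR tables** — one planted interaction (state-1 marker ligand → state-2
  marker two-member receptor complex) plus decoy pairs of background
  genes.

What passing on these conditions shows: the statistics agree with
independent brute-force oracles, the permutation tests are calibrated
under the null, and each selection rule recovers an unambiguous planted
signal at the documented thresholds. What it does not show: robustness to
transcriptome-wide co-expression structure, ambient contamination,
batch effects, LD structure among SNPs, or the scale of a full atlas —
none of which the generators attempt to emulate.

## Numerical choices and problem sizes

Permutation defaults are 1,000 draws with a fixed seed; the calibration
suites in the tests and the acceptance script use 300–400 null simulations
of 200 permutations each, sizes chosen to keep the default run fast while
leaving the binomial check's Monte-Carlo error well below the margin it
allows (type-I rate ≤ 0.05 + 2·SE). NMF uses tolerance 1e-6 and up to
2,000 iterations. Ties in the rank-sum test use mid-ranks with variance
correction; the exact path requires tie-free data. BH adjustment is the
standard step-up via statsmodels. Duplicate gene symbols are suffixed
`.1`, `.2` deterministically on read.

## Known limitations

- The NMF is a point-estimate factorization, not the Bayesian model the
  abundance estimates themselves come from; factor stability across seeds
  is not assessed.
- The chi-square on rounded abundances treats deconvolution estimates as
  counts; with very low totals the rounding can matter.
- The LR permutation shuffles labels globally (the standard framework
  convention) rather than within covariate strata.
- Abundance matrices are consumed, never inferred: deconvolution, peak
  calling, LD expansion and doublet detection are out of scope.
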