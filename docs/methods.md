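# Methods

## Simulation model

### Paired proteomes

Human proteins are random sequences over the 20-letter alphabet with
uniform residue frequencies; lengths are gamma-distributed (shape 16, mean
`mean_length`, floor 30 residues), so K/R occur at ~10% and tryptic peptides
average ~10 residues before missed-cleavage expansion. Base abundances are
log10-normal with sd 0.5 (about three orders of magnitude of dynamic range,
typical of deep proteome measurements).

A fraction `ortholog_fraction` (default 0.8) of human proteins receives a
mouse ortholog: the human sequence with each residue independently
substituted with probability `mutation_rate` (uniformly to one of the 19
other residues). The remaining 20% of each proteome is species-exclusive
with freshly drawn sequences. Ortholog abundance is the human abundance
times a log10-normal factor with sd 0.4 — cross-species expression is
correlated but far from identical, which is what makes common-peptide
contamination protein-specific rather than a uniform scale shift.

`mutation_rate` defaults to 0.012. The shared-peptide fraction of the
digested index is monotone decreasing in the rate (a property test covers
this); a coarse sweep at the default proteome size (500 proteins, mean
length 400) placed 0.012 in the middle of the ~40–50% common-peptide regime
that real human/mouse samples show, and the suite asserts the default lands
in [0.40, 0.50].

### Digestion and the peptide index

Trypsin/P (cleave after every K/R, including before proline) with up to 2
missed cleavages, peptide length 7–45. Cleavage is delegated to
`pyteomics.parser.cleave`; a brute-force substring oracle in the test suite
verifies it independently. The maximum length of 45 is our own bound on
what an instrument observes; it is configurable. Peptide keys are
I/L-collapsed by default because mass spectrometry cannot distinguish the
two residues — species uniqueness computed on raw sequences would overstate
the number of species-unique peptides; the collapse is toggleable for
sensitivity analysis. Every key is classified `human_unique`,
`mouse_unique` or `common` according to the species of its parent proteins;
the three classes partition the index.

### Mixture simulation

One simulated row per (peptide key, parent protein). Expected reporter
intensity in channel *c*:

    E[I] = fraction_c(species) · abundance(protein)
           · group_factor(expression_group_c, protein) · response(peptide)

* `fraction_c` is the channel's human (or mouse) signal fraction from the
  mixture design. "Fraction" means fraction of total protein signal: the
  cell-line experiment mixes by protein mass and the PDX percentages are
  cell counts, but since cells differ in protein content there is no
  loss-free conversion; we treat both as signal fractions and note it here.
* `group_factor` is a per-(expression group, protein) log10-normal factor
  (sd 0.3). Expression groups model biological identity: all cell-line
  mixtures share one group (the same two lysates re-mixed), while each PDX
  model is its own group shared by its original and demoused sample. This
  is what gives distinct PDX models genuinely different proteomes — without
  it the inter-PDX truth sets would be empty and the evaluation vacuous.
* `response` is a per-peptide log-normal ionization efficiency (ln-sd 1.0),
  fixed across channels and shared by both parents of a common peptide.

Technical noise is multiplicative log-normal per cell (mean 1) with
coefficient of variation `noise_cv`, independent across channels — faithful
to within-plex technical replicates, where the same PSMs quantify all
channels and only the reporter-ion measurement differs. The default
`noise_cv = 0.3` matches the per-PSM reporter-intensity variability
reported for TMT MS2 data; after averaging over a protein's ~30 peptides it
yields protein-level replicate ratios of a few percent and calibrated
thresholds near 0.68/1.47, which reproduces the benchmark regime where
mixtures within ~8% mouse stay at the technical DEP baseline.

PSM counts are Poisson with mean `psm_rate` (default 0.2) times the row's
expected total signal — the simplest count model in which PSM number tracks
peptide abundance. Rows drawing zero PSMs are dropped: they model peptides
never identified. Because the count is drawn once per row, observation
status is channel-independent, which keeps the noise-free invariance below
exact.

### Benchmark designs

Two fixed 16-channel layouts. Cell-line titration: human percentages
100/98/95/92/85/75/65/55, two technical replicates each (eight replicate
pairs). PDX layout: five liver models, each with an original tumor (mouse
7.8/15.6/51.3/17.3/90.7%) and a mouse-depleted pair (0.2/0.3/0.8/0.4/4.9%
residual); six samples carry two technical replicates.

## Quantification

`apply_policy` restricts the observed peptides to what each search policy
can see and fixes the species of record (common peptides under a
single-species search are attributed to that species wholesale).

Protein grouping is parsimony-style and fully deterministic: proteins whose
visible peptide set is contained in another's are absorbed into it
(identical sets merge under the lexicographically smaller accession); the
remaining candidates are accepted greedily by number of still-unexplained
peptides, and a candidate left with none is merged into the accepted group
sharing most peptides with it. The master is the member with the largest
visible peptide set — a deterministic proxy for "highest expression in the
group", chosen because it is available before quantification; ties break by
unique-peptide count, then accession. On nested isoform families (variants
whose peptides are a subset of one base protein, every base retaining a
unique peptide) this provably finds the minimal protein cover, and the
suite checks that equivalence exhaustively on instances of ≤10 proteins.
On pathological instances where a well-evidenced protein is redundant to
the union of two partial variants, greedy — like production search engines
— keeps the protein; we consider that the correct behavior, not a defect.

Peptides visible in exactly one group are *unique*; peptides shared across
groups are *razor* (assigned to the group with most visible peptides) or,
under the unique-peptide policy, discarded. Roll-up sums the **observed**
channel intensities of a group's peptides, where a peptide's observed
intensity is the sum over its origins — the instrument cannot split a
reporter peak between a human and a mouse parent, and that summation is the
entire artifact mechanism. Each channel is then scaled so its summed
human-protein abundance equals a constant (10⁶ by default). Normalization
uses the human subset only, also in Full-peptide mode where mouse groups
exist; whether production software normalizes before or after excluding
mouse proteins is not documented, so we fix this reading and note it.

The PSM ratio of a protein is `n_unique / (n_unique + n_common)` over the
PSM counts of its assigned peptides (species-unique vs human–mouse common);
proteins with no PSMs are excluded. Peptides unique to the *other* species
that reach a group through a cross-species merge count toward neither tally.

## DEP calling and calibration

Technical-replicate calibration pools, over all replicate pairs and all
completely quantified human proteins, the abundance ratio computed in two
rounds (each replicate once as denominator). Thresholds are the fdr/2 and
1−fdr/2 quantiles of the pooled distribution, computed on the log scale
with linear interpolation and exponentiated — the pooled log set is
symmetric under negation, so `low == 1/high` holds exactly and thresholds
are bit-reproducible. All-equal replicates (noise-free data) give the
degenerate thresholds (1, 1), which are flagged.

DEP calls use replicate-averaged sample abundances (average first, then
ratio — the order matters and is pinned by a regression test), strict
inequalities against the thresholds with a 1e-12 relative guard band (so
float rounding of a mathematically equal ratio can never create a call;
boundary ties are not DEPs), and only human proteins quantified in every
channel of the design. The sample×sample count matrix is symmetric; its
diagonal holds the DEP count between a sample's two technical replicates.

Power-law fits of DEP count versus mouse percentage are ordinary least
squares of log count on log percentage; zero-count points are dropped with
a warning, and a degenerate abscissa is an error.

## PDX evaluation

Intra-PDX: DEP count between each model's original and demoused sample
(same calibrated thresholds), Pearson-correlated against the original
tumor's mouse percentage (needs ≥3 models and non-constant counts;
otherwise the correlation is omitted with a warning).

Inter-PDX, per model pair and minimal TMT ratio *r*: the truth set is the
proteins whose demoused-vs-demoused expression ratio satisfies
`max(ratio, 1/ratio) ≥ r` (two-sided — a one-sided reading would make
down-regulation invisible); the observed set is computed identically from
the two original tumors. TP = |O∩T|, FP = |O\T|, FN = |T\O|, so
FDR = FP/(FP+TP) is the false fraction of *called* DEPs and TPR = TP/(TP+FN)
the recovered fraction of true ones; both are NaN-flagged when their
denominator is zero. The sweep covers r = 1.2 … 3.0 in steps of 0.2 and
reports medians over all model pairs. No additional replicate-calibrated
gate is applied inside the sweep; the minimal-ratio criterion stands alone.

## Problem sizes and defaults

The reference configuration used throughout the tests and the acceptance
script is 500 human proteins (mean length 400, mutation rate 0.012,
ortholog fraction 0.8), giving a ~59k-peptide index and ~60k simulated
peptide rows per plex; a full cell-line or PDX pipeline runs in a few
seconds on one CPU. The replicate-calibration check simulates 7,283
completely quantified proteins directly at the protein level (log-noise sd
0.08 per channel) since only the calibration machinery is under test there.

## What the generator does not model

No spectra: no m/z, fragment ions, isolation interference or reporter-ion
isotope impurity (so no ratio compression), and no identification noise — a
peptide present in the sample is identified by every policy whose database
contains it. Real searches can miss a common peptide in one search and find
it in the other for scoring reasons; this assignment-only idealization
means the measured artifacts are pure species-assignment effects, which is
the quantity of interest, but absolute DEP counts should not be read as
predictions for any particular instrument. Sequences are i.i.d. random, so
within-species peptide sharing (paralog families) is rarer than in real
proteomes, and search-engine confidence tiers are not simulated. Residual
mouse in demoused samples is a design parameter (the PDX layout uses the
measured values), so its effect on the truth sets can be studied directly.
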