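# xenoquant

Benchmark of species-assignment strategies for xenograft TMT proteomics, on
simulated human/mouse peptide mixtures.

## The problem

Patient-derived xenograft (PDX) tumors are human cancer cells growing inside
mouse stroma, so a proteomics run on a PDX measures a mixture of human and
mouse proteins. Because human and mouse proteomes are close, roughly half of
the tryptic peptides seen by the instrument are *common* — their sequence
(with Leu/Ile indistinguishable by mass) occurs in both species — and cannot
be assigned to a species from the spectrum alone. Database-search pipelines
handle this with one of four policies:

* **Full-peptide** — search the combined human+mouse database; shared
  peptides are kept and allocated to a single protein group (razor rule);
* **Unique-peptide** — combined database, but human–mouse common peptides
  are discarded before quantification;
* **Human-only** / **Mouse-only** — search a single-species database, so
  every common peptide is silently booked to that species.

None of these is safe: common peptides either carry mouse signal into human
proteins (Full-peptide, Human-only) or remove half the quantitative
information unevenly across proteins (Unique-peptide). `xenoquant`
reproduces the benchmark that quantifies these artifacts, entirely on
synthetic data with known ground truth:

1. a generator builds a paired human/mouse proteome (mouse orthologs derived
   by per-residue substitution, tuned so ~45% of indexed peptides are
   common) and simulates 16-plex TMT experiments — an 8-point human/mouse
   titration (100…55% human, two technical replicates each) and a
   five-model PDX layout (original "A" and mouse-depleted "B" tumor per
   model, measured mouse percentages 0.2–90.7%);
2. each policy's view of the peptides is quantified with parsimony protein
   grouping, unique/razor assignment, and per-channel normalization of the
   summed human abundance;
3. differential expression (DEP) thresholds are calibrated from technical
   replicates: per-protein ratios between the two replicates are pooled in
   two rounds (each replicate once as denominator) and the 0.5% tails of
   the pooled distribution set the cutoffs (1% FDR);
4. evaluation: DEP counts versus mouse content, the per-protein **PSM
   ratio** (share of peptide-spectrum matches from human-unique peptides,
   `unique / (unique + common)`), and the inter-PDX error framework —
   truth = DEPs between demoused tumors, observed = DEPs between original
   tumors, `FDR = FP/(FP+TP)`, `TPR = TP/(TP+FN)`, swept over minimal TMT
   ratios 1.2–3.0.

## Worked example

```python
import xenoquant as xq

pair = xq.generate_paired_proteomes(500, 400, 0.012, seed=1)
index = xq.build_peptide_index(pair)
print(f"common peptide fraction: {index.common_fraction:.3f}")

cell_design, pdx_design = xq.make_benchmark_designs()
experiment = xq.simulate_mixture(pair, index, cell_design, seed=2)

matrix = xq.quantify(experiment, index, "full_peptide")
thresholds = xq.calibrate_thresholds(matrix, cell_design, fdr=0.01)
counts = xq.dep_count_matrix(matrix, cell_design, thresholds)
print(f"thresholds: {thresholds.low:.3f} / {thresholds.high:.3f}")
print(counts.loc["100"])
```

prints (seeds as above):

```
common peptide fraction: 0.456
thresholds: 0.682 / 1.467
100      7
98       2
95       9
92       8
85      27
75      45
65      89
55     216
Name: 100, dtype: int64
```

Reading: against the pure-human sample, mixtures within ~8% mouse show DEP
counts at the technical baseline (the diagonal replicate comparison gives
7), but counts grow steeply with mouse content — 216 spurious human DEPs at
45% mouse, none of them real expression differences. Running the same
pipeline with `"human_only"` roughly doubles the counts, and with
`"unique_peptide"` at `noise_cv=0` they are exactly zero: discarding common
peptides removes the artifact entirely (at the price of half the signal).

The same objects drive the PDX analyses (`xq.intra_pdx_deps`,
`xq.sweep_min_ratio`) and everything is scriptable from the shell:

```bash
xenoquant run-all --design cell_line --seed 1 --out-dir run1
```

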