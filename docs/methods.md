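# Methods

This note describes the model behind `dipseq`, the conventions and defaults,
what the built-in generator does and does not capture, and the numerical
choices in the statistics.

## 1. Construct model and coordinates

A screen is defined by a host expression construct and a transposon cassette:

- **`ConstructReference`** — the host ORF (length a multiple of 3) embedded in
  a plasmid sequence, with an optional `numbering_offset` so reported codon
  numbers can match a fusion's published numbering.
- **`TransposonCassette`** — the inserted sequence (e.g. a cpGFP module with
  its linkers), the target-site `duplication_len` (default 5 bp, the canonical
  Mu transposase duplication), and the `inframe_phase` (default 0): the value
  of `p mod 3` at which a forward insertion preserves the reading frame.

The insertion coordinate **p** is the number of the last ORF base pair, in
the direction of transcription, that precedes the insert. An insertion is
**productive** iff the cassette is in the forward orientation and
`p % 3 == inframe_phase`; over the six (three frames x two orientations)
classes exactly one is productive. Productive positions map to protein sites
by `codon = ceil(p / 3) + numbering_offset`, so a host of N codons has
exactly N candidate productive sites.

Because transposition duplicates `duplication_len` target bases on both sides
of the insert, the construct of a variant is
`plasmid[:P] + insert + plasmid[P-dup:P] + plasmid[P:]` (P = plasmid
coordinate of p, insert oriented per the event). The junction caller exploits
this: an upstream (N-side in forward orientation) junction read gives
`p = alignment_offset + flank_length`, a downstream one gives
`p = alignment_offset + duplication_len`, and both resolve to the same p.
The two cassette ends are therefore independent observations of one event and
are carried as separate count columns ("internal technical replicates").

## 2. Junction calling

Per read: (1) detect the cassette by exact 18-mer matching against both
cassette strands (2-bit-packed k-mer codes, `np.isin` prefilter over the
batch, then mismatch-counted verification, <=4 mismatches over the overlap);
(2) split off the host flank(s); (3) align each flank >=20 bp to the plasmid
coding strand using exact 14-mer anchors at stride 7 plus full-flank
verification with <=2 mismatches; (4) convert the junction to p as above.
A flank consistent with more than one plasmid offset is reported `ambiguous`,
never guessed. Reads with no cassette, no alignable flank, or a p outside
the ORF get explicit statuses (`filtered_no_insert`, `filtered_no_lbd`,
`non_orf`). A read containing the full cassette yields both junctions and
must self-agree on p.

## 3. Counting

Counts are keyed by `(kind, pos, orientation, phase)` with one column per
`(sample, end)`. Productive rows can be collapsed to codon keys (summing the
three DNA phases is unnecessary — a productive codon has a single in-frame
p — but collapsing re-keys to protein coordinates and merges N/C-consistent
DNA rows). `filter_productive` restricts to forward in-frame rows *before*
normalization, so size factors can be computed relative to productive
insertions only, and `sum_ends` pools N/C when technical replication is not
wanted.

## 4. Enrichment statistics

The statistics follow the classic count-based differential-abundance recipe
(the first-generation negative-binomial formulation), reimplemented here:

- **Size factors**: median over all-nonzero rows of count / row geometric
  mean. An all-zero-free row may not exist in sparse tables; the estimator
  then asks for a pseudocount rather than silently proceeding.
- **Dispersions**: method of moments per row on normalized counts, using
  pooled within-condition variance `w` and the sampling-noise correction:
  `alpha_raw = (w - mu * mean(1/s)) / mu^2`. Raw estimates are shared
  through a trend `alpha(mu) = a0 + a1/mu`; the final per-row value is
  `max(alpha_raw, trend, 0)` (conservative sharing). The max() keeps rows
  with genuinely outlying variance protected — replacing it with the trend
  alone ("fit-only" sharing) recenters a Poisson null slightly but produces
  up to ~70% false positives on high-dispersion rows in heterogeneous
  mixtures, so maximum sharing is kept; its price is a mildly conservative
  null (raw p < 0.05 around 0.03-0.05 instead of 0.05).
- **Trend fit — numerical choice**: the trend is fitted by *median (L1)
  regression* (`statsmodels` QuantReg; non-negative least squares as a
  fallback) over **all** rows, negative raw estimates included. With two
  columns per condition the raw moment estimates are extremely skewed;
  fitting the mean, or only the positive half, biases the trend upward and
  makes every shared dispersion — and hence the test — conservative by an
  order of magnitude. Median regression tracks the center of the estimates
  and restores type-I-error calibration (see `tests/test_enrichment.py` and
  acceptance criterion 5) without becoming anti-conservative on genuinely
  overdispersed data.
- **Per-site test**: an exact conditional test. Given a row total
  N = k_initial + k_final, each condition's sum is modelled as NB with mean
  `q_hat * S_cond` and variance `q_hat * S_cond + alpha * q_hat^2 *
  sum(s_j^2)` (Poisson in the alpha -> 0 limit); the p-value is the
  normalized probability of all splits of N no more likely than the observed
  one (ties included at 1e-10 log tolerance). With `alpha = 0` and equal
  size-factor sums this reduces exactly to the two-sided exact binomial
  test — validated to 1e-9 over every split of N <= 30.
- **Fold change**: log2 of normalized means with pseudocount 0.5 for display
  only; the pseudocount never enters the test. Sites absent from the final
  condition are reported as `cleared` at -cap (default -6), sites absent
  initially as `appeared` at +cap; profiles may re-cap cleared sites to a
  display value (e.g. -5).
- **Multiplicity**: Benjamini-Hochberg across all tested rows
  (`statsmodels.multipletests`, inputs validated); `significant` compares the
  adjusted (optionally raw) p to the FDR threshold, default 0.1.

## 5. Activity and profiles

Plate-reader activity is `dF/F = (F_ligand - F0) / F0` on growth-normalized
fluorescence (fluorescence / OD600): F0 at the timepoint immediately before
ligand addition, F_ligand the mean of post-addition timepoints 2-6 (>=6
post-addition points required). A control well's dF/F can be subtracted.
`correlate_activity` regresses clone dF/F on a per-site enrichment predictor
(fold change, log2 fold change, or mean normalized count) with capped sites
excluded by default, reporting slope, R^2 and the slope's p-value.
`make_profile` emits exactly one row per host codon with detection flags and
an ordinal enrichment bin (for hotspot-map plotting); undetected or
non-significant sites get bin -1.

## 6. The generator: what it models, and its limits

`dipseq.simulate` produces fully ground-truthed desk-scale screens:

- **Library**: unique (p, orientation) draws; all six insertion classes;
  lognormal abundances rescaled to an exact configurable fold range
  (default 1000, matching the order-of-magnitude representation bias real
  libraries show after cloning).
- **Fluorescence**: unproductive variants sit at background (30 AFU);
  productive variants without an assigned activity at a dim folded default
  (120 AFU); an activity map assigns `(F0, dF/F)` so a variant reads
  `F0 * (1 + dF/F)` with ligand and `F0` without.
- **Sorting**: per-variant gate survival is computed analytically under
  lognormal cell-to-cell noise (CV 0.35) plus a 1% gate leak, then cells are
  sampled multinomially and survivors binomially. This keeps 10^6-10^7-cell
  sorts exact and fast.
- **Reads**: abundance-weighted fragments (Normal(250, 60) lengths), single
  or paired 150 bp reads, uniform substitution errors, FASTQ plus a
  ground-truth table per read.

**Benchmark study conditions** (`workflows.run_selection_benchmark`): 3000
variant draws over a 370-codon host; bulk productive activities
`dF/F ~ Exponential(scale 0.25, clipped at 1.5)` with 10 hotspot sites at
`dF/F ~ Uniform(2.0, 2.5)` and F0 = 100 — activity landscapes in insertion
screens are hotspot-like: most sites tolerate or break the fold, a few
linker/loop sites couple strongly. Sorting: positive (gate 250) with ligand,
negative ([0, 150]) without, positive (gate 300) with ligand, 4x10^6 cells
per round (drift noise well below effect size; free under the analytic sort).
Sequencing: 2x10^6 single-end reads for the naive and final libraries —
chosen so sequencing sampling noise is small against the sorting-limited
ceiling (the spearman ceiling at infinite depth is 0.86-0.95 across seeds);
real screens sequence millions of reads per library. The pipeline then runs
exactly as a user would: call, tally, codon-collapse, productive-only
enrichment, quantile-binned profile.

Known simplifications: no PCR duplicates or jackpotting, no chimeric reads,
no indel sequencing errors (substitutions only), no backbone (non-ORF)
insertions, no growth competition between sorts, and gate survival treats
each cell independently. These are deliberate: each omitted effect would add
nuisance realism without changing what the pipeline is tested for — exact
coordinate bookkeeping and calibrated statistics.

## 7. Problem sizes and runtime

Defaults are desk-scale: the acceptance script and test suite run on one CPU
in well under their budgets (calling streams reads in 20k-read batches at
~25-40 us/read; the benchmark's two 2M-read samples call in ~3 minutes; the
2000-row null table's exact tests take seconds). Exact-test enumeration is
O(N) per row and refuses totals above 5x10^6.
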