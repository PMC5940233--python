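# Methods

This note records the models, conventions and parameter choices behind
the package, and what the synthetic-data tests do and do not establish
about real data.

## Gene inventories and normalization

A genome's inventory is the set of canonical symbols of its annotated
CDS features.  Internal coordinates are 0-based half-open; GenBank's
1-based inclusive coordinates are converted once at the I/O boundary.
`gene` and `source` features are dropped because they duplicate the
annotation they envelope; joined/trans-spliced locations stay one
feature, since only presence matters downstream.

Gene identity comes from the `gene` qualifier, falling back to a
`product`-qualifier synonym lookup — depositor practice across the
~127 public red-algal plastid records is inconsistent enough that a
synonym table is unavoidable.  Canonical form: three-letter lower-case
stem with the remaining letters verbatim (`rbcL`, `pbsA`), numeric
suffixes without leading zeros (`ycf034` → `ycf34`), separator-joined
locus/copy suffixes stripped (`psbA_2` → `psbA`).  Normalization is
idempotent, and synonym targets are required to be fixed points.

GC% is 100·(G+C)/(A+C+G+T), ignoring ambiguity codes (their content in
these records is negligible), rounded to one decimal as conventionally
printed.  A gene missing from a record's annotation counts as absent —
no imputation.  That is the screen's main data caveat: an unannotated
but present gene deflates marine retention or inflates freshwater loss.

## The habitat association screen

Habitats form a closed three-value set (marine, freshwater, brackish),
parsed case-insensitively; anything else is an error so the screen's
denominator is always explicit.  Brackish genomes do not fit a
two-habitat contrast; the default policy excludes them (recorded per
table), with `as_marine` / `as_freshwater` available.  The published
survey's denominators cannot be reconciled exactly (a marine
denominator of 116 against a stated 109 marine + 2 brackish), which is
why the policy is a visible parameter rather than a buried convention,
and why the packaged survey table is an explicitly synthetic stand-in
used only for composition checks and demonstrations.

The concordance rate is the maximum of the two complementary pattern
frequencies, so it is ≥ 0.5 by construction; ties resolve to
marine-retained.  From the published pbsA marginals [[100,16],[4,12]]
it evaluates to 112/132 = 84.8%.

The test statistic is the plain Pearson chi-square (df = 1), p from
the upper tail.  Yates continuity correction — the default of R's
`chisq.test` on 2×2 tables — is exposed as a flag but off by default;
the two variants bracket the plausible original analysis, and both are
reported by the acceptance script (31.52 vs 27.96 on the pbsA table).
Tables with a zero row or column margin have no defined statistic and
yield a flagged result with p = 1 instead of an exception, so a
genome-wide screen never aborts on an invariant gene.  No
multiple-testing adjustment is applied by default (the screen uses a
single p < 0.01 cutoff); Bonferroni and Benjamini–Hochberg are
available behind a flag, in which case significance is called on the
adjusted p-values.

Validation uses two independent oracles: the closed-form Pearson
formula, and the exact conditional permutation distribution of the
statistic (both margins fixed, hypergeometric enumeration).  Within
every fixed-margin family with n ≤ 30 the asymptotic p-value ranks
tables exactly as the permutation p does.  Calibration of the screen
is checked by simulation under the null (star tree, loss probability
0.5 in both habitats, survey composition 109/16/2, 2000 genes): the
exact rejection level of the nominal-0.01 test under these conditions
is 0.0088 — slightly conservative, as expected for discrete tables
with a 16-species margin — and the simulated significant fraction is
required to fall in the 95% binomial band around 0.01.  Power under a
planted effect (loss 0.05 marine vs 0.90 freshwater, 20+16 tips) is
essentially 1 across 200 replicates.

## Parsimony mapping

Minimum change counts use the generalized (Hartigan) Fitch rule so
multifurcations are handled exactly: each internal node keeps the set
of states supported by the largest number of children and contributes
(children − support) changes.  On binary trees this is classic Fitch.
Branch lengths are ignored — the mapping is qualitative — and unrooted
trees are rejected because loss/gain polarity depends on the root.

One optimal labeling is materialized top-down, taking the parent's
state wherever it is optimal (this delays changes toward the tips;
ACCTRAN/DELTRAN-style choices alter labelings, never the count).  For
loss/gain polarization the root is set to "present" (plastid genes are
ancestrally present) whenever that state is optimal at the root;
otherwise the inferred optimum is used, so losses + gains always equal
the minimum change count.  A forced non-optimal root would break that
identity, which is why the assumption acts as a tie-breaker rather
than a constraint.  Correctness is established against brute-force
enumeration of all internal labelings on 500 random trees of ≤ 8 tips,
including multifurcations.

## Protein architecture heuristics

The external predictors used in practice (TMHMM, TargetP/ChloroP, CDD)
are not reimplemented; the package defines transparent stand-ins and
accepts the external calls via TSV sidecar for real-data runs.  The
stand-in parameters, all exposed:

- **TM segments**: Kyte–Doolittle window mean (window 19, termini use
  shrunken windows); runs ≥ 1.6 merged when closer than 3 residues;
  minimum length 15.  The 1.6 threshold and 19-residue window are the
  classic sliding-window convention for membrane spans.
- **Transit peptide**: over the first 40 residues, (S+T fraction) −
  (D+E fraction) + 0.1 if position 2 is alanine; call at ≥ 0.15.
  Chloroplast transit peptides are Ser/Thr-rich, acid-poor, and very
  often start Met-Ala; the bonus magnitude and cutoff are package
  choices, not literature constants.
- **Domain**: ungapped log-odds profile (pseudocount 0.5, uniform
  background) built from a packaged **synthetic** toy alignment of
  eight 120-residue sequences (conserved His anchors; generated with a
  fixed seed — not real heme-oxygenase sequences).  The detection
  cutoff is calibrated at build time as mean + 3 SD of best scores of
  25 shuffles per alignment member (fixed seed 1914).
- **C-terminal window**: a TM overlapping the last 60 residues counts
  as C-terminal.

Classifier rule order matters: transit + no TM → HMOX1; transit *and*
C-terminal TM → pbsA with a conflict note (the nuclear-relocated
plastid-type architecture seen in *Cyanophora paradoxa*); plastid +
C-terminal TM − transit → pbsA; nuclear + C-terminal TM → HMOX2;
otherwise unclassified, always carrying the evidence that fired.  A
protein without a detected domain is unclassified regardless.

Because the planted-protein generator and the feature extractor share
these conventions, 100% classification accuracy on synthetic proteins
shows internal consistency of rules and features — not accuracy on
real proteomes, where the external predictors should be supplied.

## Similarity network

All five published EGN thresholds are applied conjunctively (e-value
≤ 1e-05, identity ≥ 20%, alignment ≥ 20% of the shorter sequence,
≥ 70% of both); the shortest-sequence clause is redundant given the
mutual-coverage clause but kept for fidelity to the stated settings.
Coverage uses the tabular alignment-length column per HSP, without
subtracting gaps.  Self-hits are dropped, reciprocal duplicates keep
the lowest e-value, and the node universe is the full lengths table so
sequences without surviving hits remain visible as singletons.  The
filter is idempotent, and tightening any threshold can only remove
edges (both properties tested).

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the analysis
assumes: habitat composition (defaults 109 marine / 16 freshwater /
2 brackish, matching the survey), habitat-dependent Bernoulli loss at
the tips (the independence regime under which the chi-square test is
valid), and alternatively irreversible branch-wise loss on a Yule tree
(the clustered regime that mimics clade-wide losses; the chi-square
test's independence assumption is *violated* there, which is exactly
why both regimes exist).  Habitat evolves as a symmetric two-state
Markov chain from a marine root (switch probability
(1 − e^(−2qt))/2 over a branch of length t); brackish labels are
assigned by count.  Default per-gene loss probabilities mirror the
survey's observed absence fractions (e.g. pbsA ≈ 0.14 marine, 0.75
freshwater).

Toy GenBank records are structurally valid (ORIGIN block, one CDS per
gene, GC-parameterized spacers) but carry no biological sequence
signal; planted proteins are hydrophilic backbones with poly-Leu TM
stretches, a Ser-rich transit prefix, and the profile consensus as the
domain copy — and the non-transit head deliberately contains no
Ser/Thr so that planted-negative architectures are negative by
construction.  No substitution-model sequence evolution is simulated
anywhere.  Consequently, passing tests demonstrate the correctness of
the statistics, conventions and plumbing, not annotation quality or
predictor accuracy on real records.

All generators are deterministic given the seed (byte-identical
outputs), and every script derives its randomness from a single
`--seed`.

## Problem sizes and numerical choices

Simulation-based checks use 2000 null genes (type-I), 200 replicates
(power and binomial-expectation checks), 500 random trees (parsimony),
and exhaustive enumeration for tables with n ≤ 30 — sizes chosen to
keep the whole suite in the minutes range on one CPU while leaving the
Monte-Carlo error well inside the asserted tolerances.  Floating-point
comparisons in tests use absolute tolerances of 1e-3 on chi-square
statistics and relative 1e-2 on tail p-values.

## Known limitations

- Presence/absence only: pseudogenization, copy number and structural
  rearrangements are invisible to the screen.
- The chi-square screen treats species as independent; phylogenetic
  non-independence is addressed descriptively (parsimony mapping,
  clade summaries), not by a phylogenetically corrected test.
- The published survey's exact denominators are not reconstructible
  from the printed text; quantities derived from the printed 2×2
  marginals differ from the printed concordance by ~0.7 points
  (84.8% here vs 84.1% printed), and the package reports what its
  inputs yield rather than reconciling.
- Architecture heuristics are desk-scale stand-ins; real-data isotype
  calls should come through the external-features sidecar.
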