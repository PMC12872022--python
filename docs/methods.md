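# Methods

This note documents the models, conventions and design choices behind
`plastiscreen`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gene calling

The internal caller reports all maximal start→stop open reading frames on six
frames, one gene per stop codon (the first ATG/GTG/TTG after the previous
stop founds the ORF; nested starts sharing a stop are suppressed).
Alternative starts are translated as M, the bacterial convention. Codons
containing N are treated as non-coding and break any pending ORF.
Coordinates are 1-based inclusive on the forward strand and span start codon
through stop codon, so `end − start + 1` is the gene's nucleotide length.

`min_aa_len` defaults to 30 residues: long enough to bound spurious ORFs in
random sequence (a random 10 kb contig still yields dozens of ≥30 aa ORFs)
while keeping small hydrolase domains. This is a stand-in for a statistical
gene finder — it has no GC-frame scoring, RBS model, or partial genes at
contig edges — and is the caller used by every test and fixture. External
predictions can always be supplied directly in `proteins` mode.

## Profile HMMs

**Architecture.** Plan7-like, single-hit, local: L match states with
per-node insert and delete states, no flanking or multi-hit machinery.
Local entry is uniform over match states ($1/L$ each). Local exit from match
state $k$ has probability $1/(L-k+1)$, which makes every exit point equally
likely along a pure match path and forces exit at node L. Unaligned flanks
are emitted by the null model and cancel in the log-odds score, so the
forward and Viterbi recursions run entirely in log-odds space; probabilities
are floored at 1e-300 before taking logs so degenerate (zero-probability)
profiles remain scoreable. A `global` scoring mode (entry at node 1 on the
first residue, exit at node L on the last, no local-exit discounting) exists
for closed-form checks and glocal-style scoring.

**Estimation.** Alignment columns with gap fraction < 0.5 become match
states — the same heuristic family as standard profile builders, without
sequence weighting, kept unweighted for determinism. Emissions are observed
counts plus `pseudocount_weight × background` (default weight 1.0),
normalized. Transitions are counted from each sequence's state path through
the alignment with the same pseudocount scheme against a uniform prior;
insertions before the first or after the last match column are treated as
unmodelled flanks. The null model is the seed set's residue frequency,
falling back to uniform when the seed set holds fewer than 100 residues
(too few for a stable composition estimate).

**E-values.** The package fits a Gumbel distribution by maximum likelihood
to forward bit scores of `n_random` i.i.d. null-background sequences
(default 200, minimum 100; default length 150).
$E(S) = N(1 - e^{-e^{-\lambda(S-\mu)}})$. Mature HMM search tools instead fit
an exponential tail to forward scores; the Gumbel was chosen as a single
mechanism serving both Viterbi- and forward-style scores, and the package's
own calibration-recovery test (5000 draws from a known Gumbel, both
parameters within 5%) plus the strict filter threshold make the difference
immaterial for filter semantics. This is a documented divergence from the
tool family the screen emulates.

**Bias.** The bias score is a null2-style composition correction:
$B = \max(0, S_{\text{bg}} - S_{\text{comp}})$, two forward passes whose
nulls are the profile background and the add-one-smoothed residue
composition of the Viterbi envelope. A hit whose score survives having its
envelope's own composition as the null is not a low-complexity artefact.

**Filters.** `E < 1e-5`, `S > 20`, and for profile-HMM hits only
`B < 0.1·S`; all inequalities strict. The pipeline evaluates the cheap
score/E-value conditions first and runs Viterbi + bias only for hits that
could still pass.

## Pairwise fallback and clustering

Polymers whose seed sets cannot be aligned into an MSA are searched by
Smith–Waterman local alignment (BLOSUM62, gap open 11 / extend 1) through
Biopython's aligner. Raw scores convert to bits with fixed gapped-BLOSUM62
Karlin–Altschul constants ($\lambda = 0.267$, $K = 0.041$), and
$E = mn\,2^{-S}$ with $m$ the query length and $n$ the total target length.
These constants are configurable; composition-adjusted statistics are out of
scope. The bias term is structurally zero for this tool, matching the filter
rule's scoping.

Clustering is CD-HIT-convention greedy-incremental: longest first (ties by
id), each sequence joins the first representative it matches at
`identity ≥ threshold`, identity = identical aligned residues over the
shorter sequence's length under global alignment. No k-mer prefilter is
used — seed sets are hundreds of sequences, where exact all-vs-representative
alignment is affordable and exactly reproducible.

## Embeddings

Candidate sequences are trimmed of terminal X runs, uppercased and validated
against the 20 standard residues (internal ambiguity codes are rejected with
a position). Per-residue vectors are mean-pooled into one fixed-length
vector per protein.

The default embedder is context-free and deterministic: 25 dimensions, a
20-way one-hot (alphabetical ACDEFGHIKLMNPQRSTVWY) plus five scaled
physicochemical scalars (Kyte–Doolittle hydropathy /5, net charge at pH 7
with His neutral, aromaticity flag, polarity flag, monoisotopic residue mass
/200). Mean pooling of a context-free embedder is permutation invariant:
two sequences of identical composition embed identically. That is a known,
deliberate limitation — it trades contextual expressiveness for a pipeline
that runs with zero downloads and bit-reproducible tests. An adapter
contract wraps transformer protein language models behind the same
interface (space-separated residue formatting, CLS/SEP rows stripped before
pooling, since the pool is defined across residues only); the adapter is
optional and never required by tests.

## Dataset construction

Negatives are mined by screening decoy proteomes with the calibrated
profiles and the production filters: every filter-passing protein becomes an
all-zero-label negative. This mirrors the realistic negative class —
sequences homologous enough to be pulled in by the screen but from organisms
without the activity. Labels are one-hot over the configured polymer list,
multi-label allowed.

The train/test split operates on whole 95%-identity clusters: clusters are
shuffled with the seed and the first `ceil(0.2 × n_clusters)` go to test.
Splitting by cluster count means realized sequence fractions need not be
exactly 80/20; the split object records the realized membership. The split
hygiene property (no cross-split pair at ≥ 0.95 identity) is enforced by
construction and verified exhaustively in tests.

## Classifiers

One independent binary head per polymer (one-vs-rest — labels are
multi-label, so a joint softmax would be wrong).

* **Default mode**: XGBoost, `n_estimators = 100`, grid over depth
  {3, 5, 7} × learning rate {0.05, 0.1, 0.3}, `scale_pos_weight` set to the
  class ratio, single-threaded and seeded for determinism.
* **Sensitive mode**: a single-hidden-layer network implemented directly on
  numpy — ReLU hidden layer, sigmoid output, inverted dropout, binary
  cross-entropy with inverse-frequency class weights, Adam (lr 1e-3),
  minibatch 32, early stopping on validation loss with patience 10 and best
  weights restored; grid over hidden units {64, 128} × dropout {0.2, 0.3}.
  The numpy implementation keeps training bit-reproducible across runs and
  platforms. Loss, optimizer and batch size are package configuration
  choices, not claims about any external tool.

Hyperparameters are selected by F1 on an internal 10% validation split; the
default mode then refits on all rows, while the sensitive mode keeps the
validation rows out because early stopping needs them. Calls use a strictly
greater threshold: 0.5 for benchmarking, 0.7 for high-confidence reporting.

Class weighting pushes the network toward recall while the boosted trees
remain comparatively conservative; the test suite asserts sensitive-mode
recall ≥ default-mode recall on a 9:1 imbalanced fixture with zero
tolerance (equality allowed).

## Evaluation

Standard conventions: zero denominators yield 0 for P/R/F1; MCC is 0 when
any marginal is empty. Bootstrap CIs are percentile (2.5/97.5) over
example-level resamples — not cluster-level, a documented simplification —
with inputs canonically sorted by `(y_true, y_pred)` before resampling so
results are order-invariant, and undefined resamples skipped. Paired
t-tests and Pearson correlation delegate to scipy with explicit
degenerate-input errors. No multiple-testing correction is applied.
Published-table comparisons round half-to-even at 2 decimals; internal
values keep full precision.

The benchmark harness maps KEGG-orthology annotations onto confusion
counts: K21104 is the correct PET-hydrolase assignment; K05973/K03932 are
the correct PHB-depolymerase assignments. A truth-set protein with the
correct KO is a TP, otherwise an FN; a negative-control protein carrying any
plastizyme KO is an FP, otherwise a TN. The score scheme applies the same
mapping with a strict 0.5 threshold.

## Abundance

Mapped, primary, non-supplementary records count one read each (each mate
of a pair counts individually — the simplest samtools idiom; fragment
counting is not used). Totals cover the quantified candidate genes, not the
whole metagenome, so CPM/TPM are relative to the screened candidate set —
stated prominently because it changes their interpretation. N is the mapped
read total; with N = 0 all normalized fields are 0.

## Synthetic data

The generators define the study conditions the tests run under:

* **Families**: consensus of 180 residues (typical of depolymerase catalytic
  domains) drawn from a Dirichlet(0.5) skewed composition; 10–12 members per
  family derived by seeded substitutions and rare indels (rate 0.01/site),
  resampled until realized identity to the consensus lies in the target band
  (default 0.7–0.9, the regime of a curated seed set after 95% deduplication).
  The MSA is known by construction, so no aligner is involved.
* **Metagenomes**: members are back-translated with uniform synonymous
  codons (GC content is not controlled), wrapped with an in-frame guard stop
  immediately upstream, and embedded at recorded coordinates and strands in
  uniform-random background DNA, 2–5 kb contigs; background genes are
  residue-shuffled family members — same composition, no positional signal,
  which is exactly what an HMM screen must reject.
* **Reads**: error-free pairs tiled deterministically across each gene's
  coding sequence to an exact per-gene pair count, with a matching SAM of
  true alignments, so abundance assertions are exact rather than Poisson.

What passing tests on these fixtures shows — and does not show — about real
data: recovery and rejection rates here reflect idealized conditions (no
sequencing error, no fragmented genes, no compositional confounders beyond
shuffling, families with a single clean consensus). Real metagenomes will
yield lower recall at fixed thresholds; the fixtures validate the
*mechanics* (scoring, calibration, filtering, bookkeeping, determinism), not
field sensitivity. Classifier fixtures use random-composition negatives
rather than residue-shuffled ones because the default embedder is
permutation invariant: an exact shuffle of a positive embeds identically to
the positive and is undetectable by construction — a property the test suite
asserts, not a defect it hides.

## Numerical choices and degenerate inputs

* Log-space DP with probabilities floored at 1e-300; forward ≥ Viterbi is
  asserted to 1e-9.
* Viterbi ties break toward the match state and earlier predecessors,
  fixed by the traceback order, so alignments are deterministic.
* Summary rows sort by (sample, polymer, descending bitscore, id ascending);
  scores print at 6 significant digits; identical seeds give byte-identical
  reports.
* Calibration refuses degenerate (zero-variance) score sets; E-value
  computation uses `expm1` to avoid cancellation at large scores.
* All stochastic steps take explicit integer seeds; derived seeds stay below
  2^31.

## Known limitations

* Single-envelope scoring: one domain per protein; multi-domain proteins get
  the best envelope only.
* No sequence weighting or Dirichlet-mixture priors in profile estimation;
  heavily redundant seed sets will bias emissions toward the redundant
  members (mitigated upstream by 95% clustering).
* The Gumbel E-value model diverges from exponential-tail forward
  statistics (documented above).
* The default embedder cannot separate sequences by residue order; polymers
  whose positives and negatives differ only positionally need the language
  model adapter.
* The internal gene caller is deliberately minimal (see above).
* `--cores` and `--gpu` are accepted as interface but scoring currently runs
  single-threaded; result ordering is independent of either flag.
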