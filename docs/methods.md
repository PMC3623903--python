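# Methods

## Labeling model

Domain annotations are CATH-style: per chain, an ordered list of domains,
each a list of disjoint residue segments in 1-based inclusive coordinates
(discontinuous domains allowed). Two-state labels mark every residue
outside all segments as boundary, plus the first and last residue of every
segment — so two contacted domains always produce two consecutive boundary
residues, and a chain that begins with a domain still has a boundary
residue at position 1. The termini-are-boundary rule and the hinge windows
are applied to **every segment** of a discontinuous domain, not only the
whole-domain extremes: a boundary is wherever the chain leaves or enters a
domain region, and interior segment junctions are such places. (The
alternative — treating only the outermost termini — would leave
inter-segment excursions unlabeled.)

Hinge windows: for a segment N-terminus at position t the window is
t−R … t+R−1; for a C-terminus, t−R+1 … t+R. Each untruncated window covers
exactly R residues on the domain side and R on the boundary side; windows
are truncated at chain ends, overlapping windows take their union, and
hinge overrides both other codes. R defaults to 10, the size at which the
weighted score is reported to balance sensitivity and specificity.

## Alignment search and e-values

The profile stage needs ranked local-alignment hits. The built-in engine
is Biopython's `PairwiseAligner` in local mode with BLOSUM62 and
BLAST-convention affine gaps (open 11, extend 1, i.e. a gap of length k
costs 11 + k). Raw scores are converted to bit scores and e-values with
the standard gapped Karlin–Altschul constants for this scoring system
(λ = 0.267, K = 0.041), using query length × total database residues as
the search space. Hits with e ≤ 0.1 are ranked ascending by e-value (ties:
bit score descending, then subject id — deterministic), truncated to the
top 10; one best alignment is kept per subject. An iterated profile search
is deliberately out of scope; externally computed hits can be imported
from a documented tabular format and flow through the identical
filter/rank contract. Scoring is done without traceback for every subject
and alignments are only materialized for the survivors, which keeps a
150-query × 300-subject search under a minute.

## DHB profile

Counting follows the normalized-frequency definition exactly; the
denominator is position-wise (only hits aligning position p contribute),
which keeps every covered row a probability vector regardless of hit
coverage. Uncovered positions are the all-zero vector rather than uniform
1/3: zero is a distinct, learnable "no homology evidence" category after
discretization, whereas uniform would alias genuine three-way ambiguity.

## Feature encoding

Classic CRF toolkits treat observations as opaque strings, so the three
real-valued profile columns are discretized: round-half-up onto a 0.1 grid
(11 categories plus the out-of-range sentinels), configurable. The unigram
template reads all four columns at offsets −4 … +4 (36 features per
position); positions beyond the chain emit `_BOS_`/`_EOS_` sentinels.
There are no observation-dependent transition features — transitions are
plain label-pair parameters, matching the template's unigram-only design.
Missing shape strings are replaced by '-' so profile-only models are
well-defined.

## CRF

Implemented from scratch (it is the computational core): weights per
(feature, label) plus a 3×3 transition matrix; scaled (Rabiner) forward–
backward for the partition function and marginals; Viterbi with ties
broken toward the lower label code; training by L-BFGS on the L2-penalized
conditional log-likelihood (σ = 1.0 by default, 200 iterations, gradient
tolerance 1e-5). The objective is concave, so the zero start makes
training deterministic; the config seed exists only for data shuffling by
callers. Training batches all sequences into one padded tensor so the
forward–backward recursion is vectorized across chains; the
single-sequence recursion is kept as an independent code path and the two
are cross-checked in the tests, alongside exhaustive-enumeration oracles
at small lengths and finite-difference gradient checks.

## Decoding

"Predicted hinge region" is operationalized as a maximal run of argmax
states (Viterbi-run segmentation gives indistinguishable results on the
synthetic fixtures and is available via `viterbi_path`). Default mode
applies only the hinge rule (t_h = 0.4), matching the reported large-scale
operating point; the domain rule (t_d = 0.75) and the combined mode are
provided. In domain-only mode, residues of argmax-hinge regions count as
boundary, consistent with the ROC score. That score, 1 − P(domain), is a
package convention (the source method does not specify its ROC score);
it treats hinge and boundary posterior mass alike as boundary evidence.

## Evaluation

Residue-level, boundary positive. Sw = Sn + Sp − 1 (the CASP-style
weighted score; consistent with the published R = 10 row to rounding).
Metrics with zero denominators are reported as `None`/"undef", never
silently 0. AUC is the Mann–Whitney rank statistic with half-credit ties
(scikit-learn's implementation serves as a cross-check in the tests, not
as the implementation). Bootstrap standard errors resample
⌈0.8·n⌉ target chains **without replacement** 1000 times and report the
sample standard deviation; note that without-replacement subsampling
carries a finite-population factor √(1−0.8) ≈ 0.45 relative to the naive
√(p(1−p)/(0.8·m·k)) binomial approximation — the tests assert against the
corrected form. Undefined metrics on a resample trigger a redraw (capped).

## Synthetic data generator

The generator plants homologous domain families so that every pipeline
stage — search, profile, CRF, decoding, metrics — is exercised with known
ground truth. Chains alternate mutated prototype copies (domains) with
random linkers. Divergence from a prototype combines:

* point substitutions at `mutation_rate` (default 0.05; capped at 0.5);
* single-residue indels at `indel_frac × mutation_rate` (default fraction
  1.0). Indels are what make homology detection fail at high mutation
  rates: substitution-only divergence keeps the expected BLOSUM62 column
  score positive at any allowed rate (≈ +1.3 per column even at 34%
  identity), so ungapped homologs would remain detectable no matter how
  mutated. At the default fraction the mean ungapped run near the mutation
  cap (~2–3 columns) falls far below the affine-gap chaining break-even,
  and detection collapses (≈0.3 hits/query, <10% coverage), while at low
  mutation alignments remain essentially full-length (10/10 hits, ~98%
  coverage);
* trimming of 0…`boundary_jitter` residues (default 8) from each end of
  every domain copy, emulating the boundary-position disagreement among
  real homologs of a family. This is what makes hinge posteriors *graded*
  on the domain side of a terminus instead of step-shaped, so that the
  decision-threshold sweep reproduces the characteristic interior optimum
  of the weighted score.

Default sizes: 3 families, domain length 120–200, linkers 10–20, 1–3
domains per chain with weights (0.3, 0.4, 0.3), no terminal tails, 300
reference chains, 150 queries. These were chosen to land the two-state
boundary:domain residue imbalance in the ~1:15 regime of real
domain-annotated chains (measured ≈1:14 at the defaults) while keeping
every linker residue inside a hinge window (linkers ≤ 2R), which mirrors
the fact that real interdomain linkers are short relative to the hinge
definition. Shape strings emit helix/strand-like symbols {A,T,G,K} inside
domain segments and loop-like symbols {R,S,U,V} elsewhere (an arbitrary
but fixed split of the 8-letter alphabet), flipped to a uniformly random
symbol with probability `shape_noise` (default 0.1).

What the generator does **not** emulate: realistic amino-acid composition
or substitution biases, profile-HMM-like position-specific conservation,
long indels, repeats/low-complexity regions, discontinuous domains, and
chains whose termini are *not* boundaries. Passing tests therefore show
that the pipeline recovers planted signal under controlled homology and
noise — not that it matches any particular accuracy on real CATH/PDB
chains.

## Numerical choices and degenerate inputs

Forward–backward uses per-position max-shift plus Rabiner scaling; the two
recursions (batched training path, single-sequence inference path) agree
to 1e-9 and both match exhaustive enumeration in the tests. Argmax ties
anywhere (regions, Viterbi) resolve toward the lower label code, making
all-zero-weight models decode to all-domain. Empty hit lists give all-zero
profiles; empty query files are a warning, not an error; e-values are
floored at 1e-300. Binning adds a 1e-9 epsilon before the floor so that
values like 0.55 round half-up despite floating-point representation.

## Known limitations

* The e-value model ignores BLAST's length adjustment and composition
  statistics; rankings are stable but absolute e-values are approximate.
* One alignment per subject: a subject containing two copies of a query's
  domain contributes evidence for only one of them (the shape-string
  column compensates in practice).
* The CRF is trained full-batch; dataset sizes in the hundreds of chains
  are comfortable, tens of thousands would need a stochastic trainer.
* Event-level (±k residue tolerance) boundary matching is not implemented;
  all reported numbers are residue-level.
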