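# Methods

## Problem and model

`domlink` treats domain/linker assignment as residue-level binary
classification. For a chain of length L, every position that admits a full
window of width w (odd, default 17) becomes one instance; the instance
vector is the concatenation, over the w window positions, of F per-residue
feature channels (residue-major, channel-minor ordering — recorded in the
model manifest so an encoder can never be silently paired with a model that
expects a different layout). The central residue's label (D = domain =
positive, L = linker = negative) is the target. The (w−1)/2 residues at each
terminus never sit at a window centre; predictions report them as U
(unpredicted) so output annotations always have length L.

Window widths of 13–29 are supported; 17 is the default because predictive
performance of this feature set peaks there, and the `roc_auc` metric is
provided precisely for such window-size selection on a validation split.

## Feature channels

Four vendored AAindex scales (flexibility B-value VINM940101, polarity
GRAR740102, modified Kyte–Doolittle hydrophobicity JURD980101, linker
propensity BAEK050101) plus an optional disorder track. All scale channels
are min–max normalized onto [0, 1] at encoding time so that channels are
commensurate for scale-sensitive learners (SVM, MLP); disorder values are
already probabilities in [0, 1]. Ambiguity codes (X, B, Z, U) are imputed
with the scale mean. An AAindex flat-file reader lets users substitute any
catalogue entry.

The disorder channel is an *input*, not an internal predictor: any external
disorder tool's per-residue output (binary or probabilistic) is accepted via
a two-column TSV. When no tracks are supplied the channel is dropped and F
shrinks accordingly; this is recorded in the manifest. If a window
configuration explicitly enables the channel and a track is missing, that is
a hard error rather than a silent drop.

The corpus-derived linker index is S_i = −ln(f_i^linker / f_i^domain) with
Laplace pseudocount 1 per residue type per class (default), which keeps S_i
finite when a residue type is absent from one class. Sign contract: S_i < 0
iff the residue is more frequent in linkers. The derivation is invariant
under corpus duplication and exactly antisymmetric under a D/L label swap.

## Training and consensus

Cross-validation is at the protein level: a seeded permutation deals whole
proteins into k folds (sizes within one protein of each other), so the
overlapping windows of one protein can never appear on both sides of a
split. With k = 3 each model trains on ~2/3 of the windows. Classifier
families are delegated to scikit-learn; hyperparameters default to the
library's documented defaults except where the method fixes them (SVM kernel
= RBF; MLP restricted to one hidden layer, unit count configurable via
`hidden_units`, default 100; MLP `max_iter` raised to 300). All effective
hyperparameters, the seed, window geometry, channel list, scale values and a
fold-assignment digest are serialized in `manifest.json` next to the
per-fold joblib blobs; loading verifies the manifest and prediction refuses
incompatible encoder settings.

No class rebalancing is applied by default — the natural domain/linker
distribution is heavily skewed toward domains and the classifiers see it as
is; a seeded undersampling switch exists for experimentation.

The n-star consensus over the N = k fold models labels a residue positive
iff at least n models vote positive (hard votes, no probability
calibration). Abstentions (U positions) are excluded from the count, and a
position where all models abstain is reported U; because fold models share
one window width, positions abstain all-or-none in practice. Nesting
guarantees follow directly: positives(n+1) ⊆ positives(n), 1-star = union,
N-star = intersection, and recall / false-positive counts are non-increasing
in n. Consensus is within one classifier family across its fold models;
mixing families is possible through the same `n_star` primitive but is not
the packaged scheme.

## Evaluation

Confusion counts exclude positions where either track is U (the exclusion
count is reported). Accuracy, recall, precision, F = 2RP/(R+P); any ratio
with a zero denominator is flagged `undefined` (None) instead of being
coerced — with skewed data FP or FN genuinely vanish and a silent 0/1 would
look like a measurement. Dataset aggregation reports both pooled (sum
counts, then score) and macro (average per-protein scores, skipping
undefined entries with a count) because the two conventions disagree
whenever protein lengths or skews vary; both are labelled in the output.
ROC-AUC is the rank statistic (Mann–Whitney with averaged ties), equal to
the probability a random positive outscores a random negative.

The ±k boundary-relaxation mode re-labels truth so that every residue within
k positions of any linker residue is positive (k = 0 reduces to the linker
complement). Expansion applies to chain-terminal linkers too, since
terminal segments outside domains are annotated L; predictors that exclude
termini will differ there. Coordinates are 1-based inclusive everywhere;
adjacent or overlapping domain segments merge silently at construction.

## Synthetic data

The generator emulates exactly the two signals the features assume, and
nothing else. Architectures: 1–3 domains of 50–150 residues, linkers of
5–20 residues, terminal linkers with probability 0.8 per end. Domain
residues are drawn from a base composition (uniform by default,
configurable); linker residues from the base tilted by exp(−β·S°_i),
renormalized, where S° is the vendored BAEK050101 propensity vector — so the
planted compositional signal is aligned with a channel the encoder actually
uses, and β = 0 removes it entirely. Disorder tracks are per-residue
Bernoulli draws: p = 0.9 in linkers, 0.1 in domains by default (emulating a
disorder predictor's enrichment), equal probabilities removing that signal.
Defaults (150 proteins, β = 3, 0.9/0.1) are the package's study conditions
for the end-to-end experiment.

What the generator does *not* emulate: homology and shared evolutionary
history between proteins, secondary structure, position-dependent
composition within a domain, correlated disorder runs, or annotation noise.
Passing the end-to-end tests therefore shows that the pipeline recovers
planted composition/disorder signal without leakage — not that it attains
any particular accuracy on real CATH/CASP-style data, which is deliberately
out of scope here because it requires external downloads.

## Numerical and experimental choices

- Determinism: every stochastic step (generator, fold split, estimator
  internals, undersampling) is driven by explicit seeds; the full
  simulate → train → predict → evaluate chain is byte-reproducible.
- The end-to-end experiment uses 150 training and 50 independently generated
  test proteins; "held-out" means a disjoint generated test set, mirroring a
  two-stage train-database / test-targets design, because consensus
  combines all fold models and so no CV fold is unseen by the consensus.
- The linker-index recovery experiment uses 10^5 residues per class with
  planted log-ratios of spread σ = 0.3 (the magnitude of real
  linker/domain composition differences); at that size the binomial
  standard error of the recovered log-ratio is ≈0.02 per residue, so the
  ±0.05 recovery check is meaningful rather than noise-dominated.
- The β-monotonicity experiment (held-out F non-decreasing in β) holds the
  disorder emissions flat and disables the disorder channel so composition
  is the only signal, and uses a balanced architecture (domains 30–60,
  linkers 15–30): under the default skew the domain-class F saturates near
  the majority rate and cannot respond to β. Problem sizes in the test
  suite (tens of proteins, tens of RF trees) are chosen to keep the suite
  quick while leaving the effects well clear of replicate noise.
- The null-control comparison measures accuracy against the majority rate of
  the *evaluated* (non-terminal) positions, since terminal residues are
  linker-enriched and excluded from scoring.

## Limitations

Vendored scale values are transcribed constants; the AAindex reader is the
supported path for users who need authoritative copies. Real-data
performance depends on the external disorder predictor's quality and on
annotation conventions of the source database; the boundary-relaxation mode
exists precisely because published predictors disagree on those conventions.
SVM training is O(n²) in windows and becomes slow beyond ~10^5 windows; RF
is the pragmatic default.
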