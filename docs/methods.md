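# Methods

## Problem setting

Given a probabilistic molecular fingerprint `x^F ∈ [0,1]^n` (each entry the
estimated probability that the molecule has a structural feature) and a
molecular formula `x^M` (integer atom counts over the ten supported
elements C, F, I, Cl, N, O, P, Br, S, H, in that fixed order), the package
generates a ranked list of candidate structures as SMILES strings. The
task is framed as translation: an encoder maps the query pair to a latent
code, and a recurrent decoder writes a SMILES token sequence conditioned
on that code and on a running formula budget.

## Molecule handling

Input SMILES are parsed with RDKit, stereochemistry is removed on the
molecular graph (dialect-safe, unlike textual stripping), and the aromatic
canonical form is kept. Each structure is identified by the first 14
characters of its InChIKey — a hash of atom connectivity that ignores
stereochemistry and charge — used for candidate dereplication and for
structure-disjoint fold splitting (all records with one key land in one
fold). Training corpora are filtered by six rules: parseability, SMILES
length ≤ 127, connectivity (no dot), molecular weight ≤ 1000 Da, no formal
charge, at most seven rings as written in the SMILES (ring-closure digit
pairs, not SSSR), and elements restricted to the ten above. Each rejection
carries exactly one machine-readable reason, checked in that order.

Structural fingerprints are pluggable; the default is an RDKit Morgan
(circular, radius 2) bit vector of configurable length (512 for fixture
work, 128 in the fast test/acceptance conditions). Any deterministic,
reasonably informative binary fingerprint satisfies the generative method;
nothing downstream depends on particular bit semantics.

## Tokenization

SMILES are split into single-character tokens, with `Br`/`Cl` aliased to
`R`/`L` so every token is one scan unit, `%nn` ring labels kept whole, and
square-bracket groups (e.g. `[nH]`) kept as single tokens. Sequences are
framed `$ … *` and padded with `&` to a fixed length `l` (128 at full
scale; 40 in the desk presets, since the synthetic molecules are small).
The vocabulary keeps tokens with corpus frequency above a threshold
(default > 100 at full scale; 0 for the small fixture corpora), ordered by
descending frequency with lexical tie-breaks. Training molecules
containing out-of-vocabulary tokens are dropped (removing single tokens
would corrupt the SMILES); at inference the vocabulary is frozen.

## Fingerprint noise simulation

Predicted fingerprints are noisy; training on clean structural
fingerprints would misrepresent inference conditions. Simulated
fingerprints are produced per bit by resampling: for bit i with true value
b, draw a predicted value from the pool rows whose true bit i equals b,
add jitter `(uniform(0,1) − 0.5) × noisefactor`, and clip to the min/max
predicted value observed for that bit across the pool (the conditioning
batch, with the evaluation fold excluded). Discrete rounding (threshold
0.5, ties up) is the default for both training and prediction. Bits with
no pool row of the required truth value fall back to the clean value (and
are logged). The per-bit-independent scheme ignores bit correlations by
design. `noisefactor` defaults to 0.2; this value is a package convention,
chosen as a moderate jitter relative to the pool's calibration spread, and
has not been validated against any external reference.

Per-bit sensitivity `a_i = TP/(TP+FN)` and specificity `b_i = TN/(TN+FP)`
are estimated from the same pool at threshold 0.5, with an uninformative
prior of 0.5 substituted where a denominator is empty.

## Model

* **Encoder** (parameters θ): batch normalization (ε = 0.001, momentum
  0.99) over the concatenated `(x^F, x^M)`, two rectified-linear dense
  stages (512 → 256 at paper scale; 256 → 64 in the desk preset) giving
  the latent code `z`, and one linear dense stage producing the initial
  (h, c) states of every decoder layer. In naive mode the fingerprint
  input is replaced by zeros, so generation is conditioned on the formula
  alone — the baseline for measuring the value of structural information.
* **Decoder** (θ): at step i the input is `concat(y_i, v_i, z)`, batch
  normalized, fed to a stacked LSTM (3 × 256 at paper scale; 2 × 128 desk)
  with tanh activations and sigmoid gates, then a dense + softmax over the
  t tokens predicting `y_{i+1}`.
* **Counter**: `v_i = v_{i−1} − M · concat(y_i, ŷ_i^H)` with
  `v_0 = concat(x^M, 0)`. The constant matrix M maps each atom token to
  its element row, the hydrogen channel to the hydrogen row, and `(`/`)`
  to ∓1 on the bracket-balance row, so `(` raises the open-bracket count
  and a correctly terminated sequence reaches exactly the zero vector.
  The prose convention "( , ) map to 1, −1" conflicts with this under the
  subtraction update; the implemented signs are the only choice consistent
  with "open minus closing brackets" and zero-at-termination.
* **Hydrogen-count estimator** (parameters φ): a 2 × 32 LSTM + linear head
  reading the token sequence and emitting one "hydrogen equivalent" per
  token. Only the total is supervised: `L_φ = (Σ_i ŷ_i^H − H_total)²`,
  summed over real tokens (start, stop and padding excluded). Outputs may
  be negative. No gradient crosses between φ and θ: the decoder treats
  `ŷ^H` (through the counter) as a constant, and the two Adam optimizers
  run concomitantly but separately. During teacher forcing the counter
  consumes the estimator's predictions by default (graph-derived true
  labels are available behind `counter_from_labels` for diagnostics).

The latent space is deliberately unregularized — no variational sampling —
since the translation objective itself constrains the code and precise
decoding matters more than sample diversity here.

All layers, backpropagation (including through time), batch-normalization
statistics handling and the Adam optimizer (lr 0.001, β₁ 0.9, β₂ 0.999,
ε 1e−7) are implemented directly in NumPy; the gradients are verified
against central finite differences in the test suite. Training is
teacher-forced cross-entropy with sim-FPs drawn fresh each batch.

## Decoding and scoring

Beam search keeps the k best prefixes per step by cumulative token
log-probability (the RNN score). Finished sequences compete in the same
pool with frozen scores; ties break by (score, token index, beam index)
for bitwise reproducibility. Start and pad tokens are never proposed as
continuations. Sequences hitting the length cap unfinished are returned
flagged and fail validation. Two off-by-default options exist: a
feasibility mask that forbids tokens overdrawing any heavy-element budget,
and retiring finished sequences to a separate pool (freeing beam slots).
Defaults trust the learned termination, and the shared-pool bookkeeping is
validated against brute-force enumeration on tiny decoders rather than
assumed. Stochastic decoding samples k sequences independently
(seeded) for ablation work.

Candidates are validated (parsed), canonicalized, dereplicated by
connectivity key keeping the best-scoring spelling, optionally gated on
formula agreement, and re-ranked by the modified Platt score

    Σ_i  0.75·ln x_i + 0.25·ln(1−a_i)   if x_i ≥ 0.5, y_i = 1
         0.75·ln(1−x_i)                 if x_i ≥ 0.5, y_i = 0
         0.75·ln x_i                    if x_i < 0.5, y_i = 1
         0.75·ln(1−x_i) + 0.25·ln(1−b_i) if x_i < 0.5, y_i = 0

with natural logarithms, x clamped to [ε, 1−ε] (ε = 1e−3) and (1−a),
(1−b) clamped from below by ε so a perfect statistic contributes exactly
zero. The boundary x = 0.5 belongs to the upper branches. The log base and
smoothing constant are package conventions (the original defines neither),
so absolute score values are not comparable to other implementations,
rankings are.

## Evaluation

Per instance: % of raw sequences parsing (valid SMILES), % additionally
matching the true formula, retrieval (truth present among dereplicated
candidates, by connectivity key), rank of truth, modified Platt score of
the top candidate, and the Tanimoto similarity of the best *incorrect*
candidate to the truth (truth-matching candidates removed first; "best" is
by the active ranking, which is not necessarily the highest-Tanimoto
candidate). Dataset reports aggregate retrieval, the top-n curve and
25/50/75% quantiles, under modified-Platt or RNN ranking over the same
candidate pool. Training-set baselines (best / random corpus molecule by
modified Platt match) are provided as comparator modes.

Cross-validation is structure-disjoint: for each fold, the model is
trained without the fold's structures and with the fold excluded from the
simulation pool; any connectivity key shared between train and test
aborts the run.

## Synthetic study conditions

The fixture generator grows molecules by seeded valence-respecting graph
growth: half the attempts start from an aromatic template (benzene,
pyrrole, furan, thiophene, pyridine), atoms from the palette
{C, N, O, S, F, Cl, Br} (carbon-weighted 6:1) attach with single bonds
(15% double where valences allow), heteroatoms accept only carbon
neighbors, and occasional extra ring closures are attempted. A few fixed
starters guarantee that every tokenizer path (aromatic ring, branch,
bracket atom, two-letter element) is exercised. The prediction pool gives
each molecule 4 replicate predictions; each bit lands on the wrong side of
0.5 with probability 0.1 (flip probability), with values drawn uniformly
in [0.55, 0.95] / [0.05, 0.45], so the programmed per-bit sensitivity and
specificity are 0.9. These molecules are chemically plausible but tiny
(≤ 9 heavy atoms) and not representative of natural-product space; passing
tests demonstrates the correctness of the machinery, not chemical accuracy
on real metabolomes.

Default desk-scale sizes: 500-molecule corpus, 128-bit fingerprints,
latent 64, decoder 2 × 128, sequence length 40, beam width 32, 100 epochs
of batch-50 Adam (teacher-forced token accuracy plateaus near 0.98
there). These sizes keep a full train-and-evaluate cycle to a few minutes
on one CPU while leaving the model enough capacity to recover the
training structures from their own fingerprints.

## Known limitations

* Desk-scale training cannot reproduce full-scale benchmark numbers; the
  self-recovery (closed-world) setting measures the machinery, not
  generalization to unseen structures.
* A small-corpus model assigns nontrivial probability mass to
  ungrammatical continuations, so deep beam positions contain invalid
  SMILES at rates a 10⁶-molecule model would not show; sharpening the
  model by training longer makes this worse, not better, because a fully
  memorized sequence leaves the remaining beam slots to off-manifold
  alternatives.
* On the closed-world fixture the formula-only (naive) generator can
  memorize its corpus too, so both models can reach ceiling retrieval
  there; the advantage of fingerprint conditioning is a
  structure-disjoint phenomenon and should be measured with the
  cross-validation harness on corpora rich in isomers.
* The per-bit-independent noise model ignores fingerprint bit
  correlations.
* Modified Platt values depend on the documented smoothing/log-base
  conventions and are not numerically comparable to other codebases.
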