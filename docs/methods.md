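# Methods

This note documents the model, the synthetic data it is validated on, the
numerical choices, and the limits of what the tests show.

## Problem and model

A multifunctional therapeutic peptide is a sequence of 5–50 residues over
the 20-letter amino-acid alphabet annotated with a subset of M activity
classes (M = 21 in the standard benchmark vocabulary: AAP, AHIVP, SBP,
AFP, ABP, AHP, AVP, ACP, AIP, APP, AEP, BIP, BBP, ACVP, AMRSAP, CPP,
DPPIP, ADP, ATP, THP, QSP).  The classifier predicts the full label subset
from the sequence alone by fusing three granularities:

**Atomic.** The peptide is rendered as the SMILES of its condensed linear
polymer.  Each residue contributes a backbone unit
`N[C@@H](side)C(=O)` (glycine `NCC(=O)`, proline `N1CCC[C@H]1C(=O)`)
with L-configuration; concatenating units and appending the terminal
hydroxyl gives a molecule identical (canonical SMILES, including
stereocenters) to a cheminformatics toolkit's sequence→molecule
conversion, which the test suite uses as an oracle.  SMILES are tokenized
(bracket atoms and two-letter elements are single tokens), embedded and
encoded by a transformer encoder; the mean-pooled hidden state feeds two
fully connected layers with an intermediate dropout.  The encoder is a
contract (`encode(batch) → (batch, d_atom)`, deterministic in eval); the
default is a small randomly initialized transformer, and a pretrained
text/chemistry encoder can be plugged in without changing shapes.
Mean pooling over non-pad positions was chosen because the encoder
already injects order information.

**Sequence.** Residues are encoded by alphabetical rank (A=1 … Y=20),
right-padded with 0 to n = 50, truncated N-terminally beyond 50.  The
embedded sequence (d = 192 by default) plus fixed sinusoidal positional
encodings passes through one multi-head self-attention block (8 heads by
default; post-norm Add&Norm) and a TextCNN with filter widths 2–5 (the
minimum peptide length is 5) and global max pooling.  Secondary structure
is predicted with the Chou–Fasman heuristic (below), embedded with its own
table (4 classes + pad) and passed through an identical TextCNN *without*
attention — the heuristic labels are noisy, and the simpler pathway
extracts them without over-interpretation.  Both pooled vectors are
concatenated and integrated by a feed-forward block.

**Relational.** All sequences are split into overlapping k-mers (k = 5);
distinct k-mers are hypergraph nodes, each sequence a hyperedge over its
k-mers.  Incidence weights are tf·idf — the within-sequence count times
ln(|E|/df) — realizing "frequency and diversity" weighting.  The HyperGAT
alternates a hyperedge update and a node update per layer (2 layers), each
an attention-weighted aggregation:

    score(v, e) = LeakyReLU(⟨W'_v h_v, W'_e h_e⟩) · w_ev      (edge side)
    β = softmax over v ∈ e;   h'_e = ELU(Σ β_v W'_v h_v)
    score(e, v) = LeakyReLU(⟨W_v h_v, W_e h_e⟩)               (node side)
    α = softmax over e ∋ v;   h'_v = ELU(Σ α_e W_e h_e)

The attention arguments are written as an elementwise product in the
compact notation; a scalar score is required for the softmax, so the
product is summed — an inner product after the linear transforms, as in
standard attention networks.  The edge update runs first in every layer
(node updates consume edge features, which are otherwise undefined);
initial edge features are the plain mean of member node embeddings.  The
per-sequence feature is the sequence's edge feature after a final edge
update (whose attention reference is the same mean bootstrap, so training
and inference readouts match), linearly projected.

**Fusion.** Enabled branch features are concatenated and passed through
fully connected layers (ReLU, dropout) and a per-class sigmoid.  A label
is assigned when its probability is ≥ τ = 0.5 (ties positive).
Concatenation + a learned linear layer strictly generalizes a learned
weighted sum of branch features, so the more general reading is
implemented.  Any subset of branches can be enabled; the seven
combinations mirror the usual ablation naming (1 = atomic, 2 = sequence,
3 = hypergraph).

**Training.** Class-weighted binary cross-entropy, weight
`N/(M·count_c)` per class on the training split (probabilities clamped at
1e-7 before the logarithm; an empty predicted set contributes 0 to the
precision metric, penalizing abstention).  Optimizer: AdamW with linear
warmup over the first 10% of steps and decoupled weight decay 0.01.
Documented defaults keep the published settings where they exist
(n = 50, d = 192, filters 2–5, k = 5, τ = 0.5, batch 128, learning rate
5e-6, 30 epochs); the 5e-6 rate is a fine-tuning scale appropriate for a
pretrained atomic encoder.  The `tiny_classifier` configuration used by
the tests and the benchmark script keeps the architecture at reduced
widths (embedding 32, 4 heads, 16 filters/width, d_fuse 32, HyperGAT
hidden 32, atomic encoder d = 16 with SMILES truncated to 64 tokens) and
uses learning rate 2e-3, the usual Adam scale for small random-initialized
networks.

All neural blocks run on a small in-package reverse-mode autodiff engine
over float64 numpy arrays (`amhf._tensor`); gradients of every layer type
are verified against central finite differences in development and the
attention/hypergraph operators against loop-naive oracles in the test
suite.

## Transduction and inference

Training is transductive over the training-set hypergraph: each minibatch
trains on the sub-hypergraph induced by its sequences (shared k-mer nodes
couple the batch, which is where relational learning happens); a
whole-graph pass per step does not fit a single-CPU budget and the
minibatch-induced subgraph is the standard approximation.  At inference
the k-mer vocabulary and df/idf are frozen; unseen k-mers collapse onto a
reserved UNK node with idf 0 (an unknown k-mer carries no diversity
information).  After training, one forward pass over the full training
graph caches the propagated feature of every vocabulary k-mer; a new
sequence is read out by a single attention-weighted edge update over its
members' cached features.  This keeps each prediction independent of
batch composition (verified to 1e-6) while retaining the relational
information learned on the training graph.  Sequences shorter than k
cannot form a hyperedge and are reported as per-record errors at
prediction time.

## Chou–Fasman assignment

The standard published propensity table (P_helix, P_sheet, P_turn and the
four positional turn frequencies per residue) ships as
`src/amhf/data/chou_fasman.tsv`.  Rules: helix nucleates in any 6-window
with ≥ 4 residues of P_helix > 100 and extends while the 4-residue mean at
the moving end stays ≥ 100; sheet nucleates in any 5-window with ≥ 3
residues of P_sheet > 100 and extends the same way; a turn is assigned to
the tetrapeptide at i when f(i)f(i+1)f(i+2)f(i+3) > 7.5·10⁻⁵ and the mean
P_turn over the window exceeds 100 and both other mean propensities.
Helix/sheet overlaps are resolved per maximal overlap region by the higher
mean propensity (ties to helix); turns are assigned last and override;
everything else is coil.  Sequences shorter than a nucleation window get
no nucleation of that type.  Poly-Ala is all helix (P_helix(A) = 142) and
poly-Val all sheet (P_sheet(V) = 170); a second, independently written
loop evaluator agrees on random sequences.

## Synthetic data

The generator emulates the structure of the real benchmark: sequence
lengths uniform on [5, 50]; a Poisson label count around a mean of 1.3
labels/peptide (minimum 1); class inclusion proportional to tiered
imbalance weights shaped like the benchmark's class-size distribution
(13/21 of classes small, 4/21 medium, 4/21 large, representative sizes
300/750/1500); background residues uniform over the alphabet
(configurable).  Each class owns a random 5-mer motif (pairwise edit
distance ≥ 2 — length 5 so a single hypergraph node can carry the class
signal); one motif per positive label is implanted at non-overlapping
random positions, each motif position substituted with probability
`noise_rate` (default 0.05).  With noise 0 and disjoint motifs a trivial
motif matcher attains perfect subset accuracy, an upper-bound oracle for
the learned model.

What the generator does **not** emulate: real amino-acid composition and
physicochemical property distributions, homology structure between
sequences, label correlations beyond shared motifs, and motifs longer or
fuzzier than a noisy 5-mer.  Passing the learning test therefore shows
the pipeline can extract localized sequence determinants under label
imbalance and noise — not that it reaches any particular accuracy on real
peptide benchmarks, which additionally require the full dataset and a
pretrained atomic encoder.

## Benchmark study sizes

The learning check and `scripts/acceptance.py` use 2000 peptides over 8
classes (noise 0.05), an 80/20 split, the tiny configuration above, 30
epochs, and three seeds for the full model and the sequence-only (_2) and
sequence+hypergraph (_23) ablations, plus one permuted-label baseline
(labels shuffled across training records, same training protocol).  These
sizes keep a complete study within tens of minutes on one CPU while
leaving a wide margin between the trained model (held-out exact-match
fraction typically ≈ 0.85–0.92) and the baseline (≈ 0.05).  The atomic
branch contributes little on this data — its truncated SMILES window
covers only the first few residues — consistent with the published
finding that the atomic view alone is by far the weakest of the three.

## Known limitations

* Chou–Fasman is a 1970s heuristic retained for its role as a cheap,
  deterministic structure prior; it is not a modern structure predictor.
* The UNK-node treatment of unseen k-mers is coarse; motif variants one
  substitution away from training k-mers receive no relational credit.
* The float64 numpy engine is adequate for the tiny configuration but not
  for benchmark-scale models (9841 sequences, d = 192, pretrained
  encoder); those require a GPU framework behind the same interfaces.
* The 80/20 split is unstratified; with 21 classes and heavy imbalance a
  rare class can be underrepresented in a small test split.
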