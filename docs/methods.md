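# Methods

## Model

The generative model is an autoregressive next-token language model over
molecule strings: an embedding layer, `n_layers` stacked LSTM layers of
`hidden_units` each, dropout applied to the last recurrent layer's output,
and a linear map to vocabulary logits. Training minimizes the mean next-token
negative log-likelihood under teacher forcing; each molecule is framed as
`BOS t₁ … tₙ EOS`, mini-batches are padded with PAD and the loss is masked on
PAD positions. Generation is ancestral sampling at temperature 1 from BOS
until EOS or a length cap (`max_sample_len`, default 120 tokens for
small/medium regimes and 1,000 for the large-molecule regime, roughly twice
the longest training sequence in each).

The implementation is pure NumPy: float32 batched matrix products, full
back-propagation through time, and Adam (β₁ = 0.9, β₂ = 0.999) with global
gradient-norm clipping at 5 and a cosine decay of the learning rate to 10%
of its base value over the run. The backward pass is checked against central
finite differences in float64 in the test suite. At the corpus scales the
package targets (10²–10⁴ molecules, vocabularies of a few dozen tokens) an
epoch takes roughly a second per thousand molecules on one CPU core.

Reference configurations are registered by task and string family
(`logp/sm` = 2×400 units, output dropout 0.2, rate 1e-4; `logp/sf` = 2×600,
0.4, 2e-4; `multi/sm` = 3×512, 0.5, 1e-4; `multi/sf` = 2×500, 0.2, 3e-4;
`large/sm` = 2×512, 0.25, 1e-3; `large/sf` = 2×800, 0.4, 1e-4). These are
full-scale settings; tests and the acceptance script use 1×100–128-unit
models sized to their synthetic corpora. Hyper-parameter random search draws
uniformly and independently from discrete grids of 3–5 values per searched
quantity, bounded by learning rate ∈ [1e-4, 1e-3], hidden units ∈
[100, 1000], layers ∈ [1, 5] and dropout ∈ [0, 0.5]; the number of epochs is
not searched. Model selection keeps the top 10% (ceiling) of candidates by
validity + uniqueness + novelty, then picks the survivor that is lowest on
the most of the six per-property Wasserstein metrics, ties broken by the
task's primary property (penalized LogP for the screened task, molecular
weight otherwise).

Optimizer choice, batch size (default 64), gradient clipping and the decay
schedule are implementation defaults — the training contract fixes only the
architecture shape, the dropout placement (output of the last recurrent
layer) and the learning-rate scale.

## String representations

Two encodings are supported. SMILES are tokenized greedily keeping
chemically atomic units whole: bracket atoms `[...]`, two-digit ring
closures `%dd` and `Cl`/`Br` are single tokens; all other characters are
their own token. The alternative is a robust bracket-token representation in
the SELFIES family, implemented in-package as a valence-constrained codec:
atom tokens carry an optional bond-order prefix (`[C]`, `[=O]`, `[#C]`),
branches are delimited by `[Branch]`/`[EndBranch]`, and `[RingN]` bonds the
current atom to the atom placed N positions earlier. The decoder caps every
requested bond order at the remaining valence of its endpoints, skips
unrealizable ring closures, stops when no capacity remains, and derives the
implicit root carbon for token strings containing no atom token — so *every*
string over the alphabet decodes to a valid molecule, including the empty
string (methane) and every prefix of a valid string. This totality is what
yields exactly 100% sample validity from models trained on the
representation, at any training stage.

The codec's domain is neutral organic chemistry (C, N, O, S, P, halogens) at
standard valence, written through the Kekulé structure; charges, isotopes,
radicals, hypervalent states and stereochemistry are not representable, and
the encoder rejects them. It is not byte-compatible with the reference
SELFIES library (branch/ring token conventions differ); it provides the same
guarantee.

Molecule identity everywhere (deduplication, novelty, overlap removal) is
string equality of RDKit canonical SMILES. Stereochemistry is preserved by
the SMILES path when present but never added; the robust codec flattens it.

## Properties

The property battery uses RDKit's standard descriptor implementations:
Wildman–Crippen LogP, Ertl–Schuffenhauer synthetic accessibility (1–10),
Bickerton QED (0–1), exact molecular weight, Bertz complexity, and the Ertl
natural-product likeness score (loaded from the toolkit's contributed
models). Penalized LogP is the raw composite `LogP − SA − #(SSSR rings with
more than 6 atoms)` — the non-normalized form whose scale matches a screen
threshold of 4.0 and a high tail at 6.0; a z-scored variant exists in the
literature but would put the screen threshold on a different scale. The
longest carbon chain is the longest simple path in the carbon–carbon bond
subgraph, found by exhaustive depth-first search (exact, and affordable at
≤ a few hundred atoms).

## Task datasets and the synthetic generator

Three training distributions are built by `taskdata`: penalized LogP
strictly above 4.0; strictly more than 100 heavy atoms; and a four-window
molecular-weight mixture. The window boundaries are MW ≤ 185, 185 ≤ MW ≤ 425,
460 ≤ MW ≤ 600 and MW > 600 g/mol (all printed boundaries inclusive; only
the polymer window is strict), which leaves (425, 460) uncovered — molecules
there are validation errors, not silently binned. Component fractions are
1/6, 1/3, 1/6, 1/3: the drug-like and polymer windows each contribute one
third, and the two remaining windows are read as jointly one third (1/6
each) since the four fractions must sum to one; the split is a keyword
argument for users who prefer a different reading. Quotas use
largest-remainder rounding (each component within one molecule of its exact
share) and pools are subsampled uniformly without replacement, seeded.

The synthetic generator emulates, at desk scale, the source databases of the
full-scale tasks:

* `druglike` — ring cores decorated with substituent+linker groups via
  rejection of chemically impossible attachments, MW 150–450 (screening-
  library character);
* `window(lo, hi)` — mixed-monomer oligomer chains grown toward a
  centre-weighted target mass inside the window (oligomeric character of the
  photovoltaic/polymer collections, with a unimodal within-window weight
  distribution);
* `highlogp` — C16–C35 chains with sparse methyl decoration and no rings,
  the motif of the high-penalized-LogP tail (the majority score above 4.0);
* `peptide` — linear peptides of uniformly random standard residues
  (default 19), built from a per-residue SMILES grammar without
  stereocentres;
* `alkane(k1, k2)` — the linear alkane ladder, cycled to the requested size.

All pools are deterministic per seed and restricted to the robust codec's
supported chemistry so one pool can train both string families. What the
generator does **not** emulate: real databases' scaffold diversity,
stereochemistry, charged species, tautomer ambiguity, and heavy-tailed
property correlations. Passing tests therefore demonstrate that the pipeline
and the model mechanics are correct and that the protocol's quantities
behave as designed — not that a 128-unit model would match ZINC-scale
chemistry; the full-scale runs are supported as workflows, not re-run in CI.

## Evaluation protocol

A batch (10,000 samples at full scale; 1,000–2,000 in tests) is scored
twice. Standard metrics on the raw batch: validity = valid/generated,
uniqueness = unique/valid, novelty = (unique ∉ train)/unique, with 0/0
defined as 0 and flagged. Distribution metrics after removing duplicates and
training molecules: the first Wasserstein distance between generated and
training values of each property — computed with
`scipy.stats.wasserstein_distance`, equal to the integral of the absolute
CDF difference, and cross-checked in tests against the sorted-samples
oracle. When several models are compared their survivor sets are truncated
to the common minimum count by seeded subsampling. The TRAIN oracle is the
mean over 10 random disjoint half/half splits of the training set of the
between-half Wasserstein distance; distances are read relative to it because
even a perfect generator scores no better than sampling noise.

KDE overlays fit a Gaussian kernel to the training values, selecting the
bandwidth by 5-fold cross-validated log-likelihood over 20 log-spaced values
in [0.01, 10] × the training standard deviation, and reuse that bandwidth
for every model's curve (fair visual comparison). Mode-count checks
(the four-window composition; bimodality of recovered MW) use a fixed 15
g/mol bandwidth with prominence-based peak detection (10% of the maximum
density), because a cross-validated bandwidth legitimately resolves the
14-Da comb of homologous series into many peaks while the scientific
question is the number of separated weight regimes.

The distribution-recovery benchmark in the acceptance suite trains a 1-layer
128-unit model for 20 epochs (batch 16) on a 2,000-molecule pool with
bimodal MW — two alkane bands, C7–C14 and C25–C32 — and requires the
seed-averaged ratio `W₁(MW_gen, MW_train) / oracle ≤ 3` over three seeds,
with a bimodal sample KDE in every run. The alkane-band pool makes molecular
weight a pure chain-length statistic, so the benchmark isolates the model's
ability to reproduce a bimodal length distribution from its ability to learn
branching grammar (which the validity and novelty checks cover elsewhere).

## Structural profiles

Fragment decomposition cuts every acyclic single bond (single-order bonds on
no ring) and counts connected components, classified as single-atom (one
heavy atom), single-ring (exactly one SSSR ring) or fused-ring (≥2 rings
sharing an atom). This is a stated convention — the simplest cut rule that
produces those categories — implemented on the intact molecular graph (union-
find over uncut bonds) to avoid re-sanitizing aromatic systems, and verified
against a bridge-deletion oracle in tests. Amino-acid content is counted on
the intact molecule with 20 substructure patterns (backbone N–Cα–C(=O) plus
side chain, with explicit H-count constraints keeping residues mutually
exclusive; proline uses its ring-closed backbone); matches of one pattern
are deduplicated per α-carbon. Both the match-based residue count and the
cut-based fragment counts are reported, since "amino-acid fragment" admits
either reading. Nearest-neighbour search uses Morgan fingerprints (radius 2,
2048 bits) and Tanimoto similarity, ties broken by canonical SMILES for
determinism.

## Numerical and degenerate-input conventions

Empty SMILES strings are invalid records with a reason, never exceptions;
empty robust strings decode to methane (decoder totality, above). Screens on
empty pools return empty sets; an empty post-overlap survivor set is an
error with counts logged. Wasserstein distances of empty samples and oracle
splits of fewer than 4 molecules are errors. KDE tuning requires ≥ 10 points
and a degenerate zero-variance sample falls back to unit bandwidth scale.
Vocabulary token order is sorted (specials fixed at PAD=0, BOS=1, EOS=2) so
checkpoints are reproducible; all randomness flows from explicit integer
seeds (NumPy `default_rng`), and sampling with a fixed seed is reproducible
on one device.

## Known limitations

* The robust codec covers neutral standard-valence organic chemistry only;
  molecules outside it can be modelled via SMILES but not via the robust
  representation.
* Training is CPU-bound NumPy: ample for the package's corpus scales, about
  two orders of magnitude slower than a GPU framework at full database
  scale.
* Penalized LogP is the raw composite; results are not comparable to
  z-score-normalized variants without rescaling.
* The fragment cut rule and the residue pattern library are conventions;
  other decompositions (retrosynthetic schemes, cyclic-peptide-aware residue
  parsing) are out of scope.
* Randomized-SMILES data augmentation is not implemented.
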