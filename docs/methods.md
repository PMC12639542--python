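# Methods

This note records the models implemented in `matkg`, their assumptions,
the parameter choices that matter, what the synthetic corpus does and
does not emulate, and the numerical and design decisions made where the
problem left them open.

## Annotation model and tag codec

A paragraph is a token sequence with 0-based, half-open character and
token offsets, a partition into sentences (sentence boundaries are part
of the annotation; no sentence splitter is included), and one tag per
token. Tags are `O` or `<position><category>` with position ∈ {B, I, E}
and category ∈ {E, C, D, M, R, V}. A span is `B` alone or `B I* E`; a
lone `B` is a complete singleton mention. The decoder closes an open
span at `E` of the same category or at the first tag that does not
continue it. Two decoding modes exist: *strict* (orphan `I`/`E` raises,
the default for gold data) and *lenient* (an orphan tag starts a new
span, for model output, which cannot be guaranteed well-formed).
Encode∘decode and decode∘encode are identities on valid inputs and are
property-tested against an independently written left-to-right scanner.

The train/validation split is paragraph-level at a 10:1 ratio, so every
derived relation record inherits its paragraph's side and the validation
set cannot leak into training. Validation size is nearest-integer
`n/11` with a floor of 1 (486 paragraphs → 44), configurable.

## Sentence-level relation extraction

Candidates are all same-sentence mention pairs whose unordered category
pair is not excluded. The exclusion set is {MV, RD, CV} (semantically
unconnected) plus EE, because material–material relations are resolved
at paragraph scope. ER, EM and RV carry almost no negative examples in
practice; they are classified by default (the error statistics over
relation types show nonzero ER errors, implying they were classified),
with an "always link" preset available. M–M pairs link experimental
steps and may cross sentences; their gold chain comes from metadata, not
token order, because procedures can be narrated out of sequence.

The feature vector for a pair is `concat(pool(a), summary, pool(b))`
(length 3d), where `pool` is the arithmetic mean of the token vectors
under the mention mask and `summary` is the sequence-level vector. No
entity-marker tokens are inserted; mask-average pooling is the whole
mechanism. One shared binary head serves every classified pair type
(candidate sets are pooled for training, with negatives subsampled to
3:1 against positives by default); a pair-type one-hot can be appended
as a config option, off by default. The head is two fully connected
layers (hidden width 64, ReLU, dropout 0.1) with softmax cross-entropy,
trained with AdamW (lr 1e-3, 40 epochs, batch 64). Ties at p = 0.5
predict "unlinked" — conservative linking. All randomness (init,
shuffling, dropout) flows from one seed; two runs with the same seed are
bit-identical.

## Paragraph-level relation extraction (mention-graph GCN)

For a material pair (A, B) in a paragraph, the mention graph has one
node per mention of either material, ordered by position, and an edge
for every *alternating appearance*: each adjacent pair of opposite-
material mentions in the merged document order. When all A-mentions
precede all B-mentions this degenerates to a single edge between the
last A and the first B. An edge is embedded from the tokens strictly
between its two mentions (edges have variable spans), falling back to
the union of the mention spans when the mentions are adjacent. The two
per-material mention sets and the alternating edge set realize the three
conceptual graphs (A-graph, B-graph, connection graph) as one node set
with one adjacency — the convolution needs a single adjacency, and no
intra-material edges are posited (a config flag is reserved for them).

Node features start as mask-averaged token embeddings and are updated by
L = 2 convolutions `H' = ReLU(D̂^{-1/2} Â D̂^{-1/2} H W)` with
self-loops (Â = A + I) and one node weight matrix shared by A-nodes and
B-nodes per layer; edges update as `ReLU(W·e + b)`. After every stage,
including stage 0, the A-node mean, edge mean and B-node mean are
concatenated, giving a 3d(L+1) feature vector classified by a linear
softmax layer over four labels: A-includes-B, B-includes-A, unrelated,
identical. Layer count, widths and the activation are not dictated by
the problem; L = 2, square d×d weights and ReLU are the package's
defaults, all configurable. Training is AdamW (lr 2e-3, 60 epochs,
batch 16) with explicit backpropagation through the convolution stack;
the layer is verified against a dense-matrix oracle, and permutation
equivariance, the shared-weight property and the A/B mirror symmetry of
the feature layout are tested. Note that symmetric normalization bounds
the *spectral radius* of the propagation matrix by 1; individual row
sums can exceed 1 when neighbor degrees differ.

Candidate pairs at inference are all unordered pairs of distinct
material names in the paragraph, grouping E-mentions by surface form
after trimming, whitespace collapsing and case folding.

## Rule-based structuring

Positive relations compile into a per-material directed graph by rules
applied strictly in order: (1) MM relations form the step list and MC
attaches reagents to steps; (2) MD values attach to listed steps;
(3) C entities not claimed by a step attach to the material via EC;
(4) the chain anchors to the material at the EM-linked step that is
last in chain order (C branches stay with their steps when EC, MC and
EM coexist — one C node, however many incoming edges); (5) E→R→V
branches form when ER, EV and RV co-occur, otherwise pairs connect
directly. CD values attach beneath C nodes. The step chain must be a
simple path: cycles and branching raise, naming the offending node.
Chains are oriented from the endpoint earliest in the document; with
out-of-order narration the orientation is ambiguous and document order
is the tie-break.

Node identity is deliberately split: steps are *events*, identified by
mention span; every other category is a *symbol*, identified by
(category, normalized surface), so the same reagent in two branches is
one node and merge-time conflict detection can compare branches. The
cost of surface identity is cross-material leakage when two materials in
one paragraph share a reagent or property surface; CD and RV attachments
are therefore sentence-scoped to the relation that introduced their
parent C/R node. An RV pair whose property node was never ER-linked to
the material in the same sentence is not attributable and is dropped for
that material.

Merging: IDENTICAL pairs are unioned transitively (union–find), keeping
the longest root surface as canonical (ties break lexicographically);
general materials assign their root branches to each specific material
unless the specific graph already holds the same anchor edge with
different contents beneath it — then the whole branch is discarded, and
the specific graph is never overwritten. Contradictory inclusion labels
fail loudly rather than being resolved heuristically. A final IDENTICAL
pass is run for fidelity to the stated order; after transitive closure
it is a no-op. Flattening emits the root plus one record per edge in
topological order of the target (ties by edge type, then node id) and is
lossless; cross-paragraph linking connects equal normalized root names
in document order — a deliberately naive rule, which will also link
generic alias roots ("the sol") if an alias survives as a canonical
name.

## Encoders

The default encoder hashes each token string (BLAKE2b keyed by the seed)
into the seed of a NumPy generator that draws the token's vector from
N(0, 1/d); the summary vector is the token mean. It is deterministic
across processes and platforms, collision-free in practice (tested at
10,000 vocabulary items), and reduces both learned models to functions
of lexical identity — which is exactly what the synthetic corpus makes
sufficient. d defaults to 768 to match the documented embedding width of
the pretrained-transformer adapter; tests and the acceptance script use
d = 64 (sentence RE, GCN) and d = 16 (unit tests) since the synthetic
vocabulary is small. The transformer adapter (frozen weights,
first-position output as summary, mean pooling over subwords) is
optional and import-guarded; fine-tuning is out of scope, and results
with contextual embeddings on real text are expected to differ from the
hash-encoder results reported here.

## Synthetic corpus

Each paragraph is a template-realized synthesis narrative over a
mesoporous-bioactive-glass vocabulary (TEP, TEOS, P123, citric acid,
calcination temperatures, SSA, pore size …): a preparation sentence
(EC + CD), a step chain drawn as a contiguous window (3–5 steps) of the
canonical dissolve → stir → age → dry → calcine sequence (EM, MC, MD,
MM), and characterization sentences (ER, RV, EV). Paragraph composition
follows weighted patterns: a product alone, with a coreferent alias
("the gel"), with a general family term ("bioactive glasses"), and/or
with an unrelated second material — which yields all four paragraph-
level labels (default weights produce roughly 1.4 labeled pairs per
paragraph, all four classes well represented). `alternation_density`
controls how often non-product sentences interleave with product
sentences, tuning mention-graph edge counts; `distractor_rate` injects
never-related reagent/value tokens as negative candidates;
`corrupt_labels` flips labels independently at a given rate and records
the flip mask. The default corpus size is 486 paragraphs, matching the
scale of the annotated corpus the task derives from.

Relatedness is a global property of the vocabulary: each step verb owns
its reagent and value pools, each reagent its amounts, each property its
values, and distractors are related to nothing. Consequently (a) the
same surface pair never appears with contradictory labels, so both
learned tasks are solvable from lexical features — near-ceiling
validation scores on zero-noise synthetic data are a correctness check
of the feature plumbing and training loops, **not** evidence about real
literature, where relatedness is contextual; and (b) the generator can
build each material's gold graph directly from its recipe metadata,
independently of the rule engine, making "structuring the gold
annotations reproduces the gold graphs exactly" a meaningful end-to-end
identity. Features of real data the generator does not emulate:
contextual (non-lexical) relation cues, annotation-boundary noise,
nested or discontinuous entities, more than one step chain per
paragraph, and coreference beyond one alias per product.

## Degenerate inputs and numerical choices

Empty masks, empty token lists, single-class training sets, missing
paragraph-level label classes, unknown labels, overlapping mentions,
malformed tags, contradictory merge labels and cyclic graphs all raise
with specific messages. Metric ratios with zero denominators are
reported as 0.0 and flagged rather than raised; accuracy is
(TP+TN)/total; multi-class precision/recall/F1 default to macro
averaging (micro available) and MCC uses its multi-class
generalization. Probability vectors are validated to sum to 1 within
1e-6; the GCN oracle tolerance is 1e-8; metric oracle agreement is
tested at 1e-12. Problem sizes in the acceptance script (200-paragraph
identity corpus, 300-paragraph sentence-RE corpus, ~400 material pairs,
1,000-case oracle sweeps) keep a full run under a minute on one CPU
while leaving the statistics stable across seeds.

## Known limitations

Chain direction is unrecoverable from relations alone under out-of-order
narration; branch assignment copies only descendants of the anchor, so a
partial chain suffix could be assigned when a general material carries a
chain (the generator never produces one); cross-paragraph linking is
exact-name matching only; and predicted (rather than gold) relations can
violate the simple-path chain assumption — the pipeline records such
paragraphs in its manifest and continues rather than aborting the run.
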