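# Methods

This note documents the models and procedures implemented in `rnascreen`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Binding-site graphs

A binding site is a directed, labelled graph over nucleotides.  The
relation vocabulary has 20 labels: the two backbone orientations
(`B53` 5'→3' and `B35`), six symmetric Leontis–Westhof families
(`cWW, tWW, cHH, tHH, cSS, tSS`) and the six asymmetric families
(`cWH, tWH, cWS, tWS, cHS, tHS`) together with their direction-swapped
variants (`cHW`, …).  Every physical interaction is stored as two directed
edges with mutually reversed labels; validation enforces this reciprocity,
the closed vocabulary, a simple backbone path per chain, and a uniform
language-model feature length.  Node features are the one-hot nucleotide
type (5 classes, `other` included), optionally concatenated with a
fixed-length per-nucleotide feature vector (640-dim when supplied by an
external RNA language model; the synthetic generator uses shorter
vectors).  When language-model features are absent the input dimension
shrinks — nothing is zero-padded — and the dimension is recorded in model
checkpoints so weights and graphs cannot drift apart.

Extraction from a 3D structure keeps exactly the RNA residues with an
atom within 10 Å of any ligand atom.  Sites with fewer than 5 RNA
residues are rejected (`too few residues`), as are sites where protein
residues exceed 40% of all RNA + protein residues in the 10 Å zone
(`protein-dominated`); ions and waters never count toward the zone.  The
denominator choice (RNA + protein, excluding solvent) is deliberate:
"total residues in the zone" is read as the residues that could plausibly
form the pocket.  Candidate ligands pass a configurable exclusion list of
ions/artefacts plus heavy-atom size bounds (8–200 by default); the exact
curation rules of public RNA–ligand resources are not published as a
closed list, so the filter is parameterized rather than hard-coded.
Structure parsing is a narrow adapter contract (residues, kinds,
coordinates, optional base-pair annotations); gemmi backs the optional
mmCIF reader.  Base-pair geometry is never computed from coordinates —
Leontis–Westhof labels come from input annotations or the generator.

Context expansion adds all nodes within 4 BFS hops of the pocket core,
flagged `is_core=False`.  The BFS treats edges as undirected: whether
context should follow edge directions is not specified anywhere
authoritative, and an undirected neighbourhood is the more conservative
(larger) context; the depth is configurable.

## The scoring network

The rGCN layer follows the standard relational update with per-relation
mean normalization `1/c_ir` and one weight matrix per relation plus a
self-loop matrix; no basis decomposition is used because the relation
vocabulary is small (20).  Pooling is the mean over node embeddings (the
usual default where no pooling is named); sum pooling would leak graph
size into every downstream score.  The ligand encoder is the r = 1
special case over the bond graph, with atom features = one-hot element
(10 classes), aromaticity flag and formal charge.  The decoder is a
two-layer MLP on the concatenated embeddings.  Architecture defaults are
3 layers of width 64 with ReLU; the tests and the acceptance script use
2×32 networks, which are fully sufficient for the planted benchmark and
keep a desk-scale run in seconds.

The network is implemented directly in numpy with hand-written
reverse-mode gradients (`rnascreen.nn`), checked against central finite
differences to ~1e-10 relative error in the test suite.  Batched
training embeds each distinct graph once per step and accumulates
embedding gradients over all pairs that use it, which makes a full-batch
epoch over 20 pockets × 200 ligands take well under a second.
Optimization is Adam (lr 5e-3 in examples); all randomness flows through
seeded `numpy` generators, so every training run is bit-reproducible.

## Pretraining

The pocket encoder can be pretrained so that embedding dot products
approximate a structural similarity kernel.  Subgraphs are 2-hop
neighbourhoods of corpus RNAs (one per residue).  The kernel decomposes
each subgraph into radius-1 rooted graphlets, computes an exact
label-aware graph edit distance between every graphlet pair (node/edge
substitution cost 1 on label mismatch, indel cost 1 — configurable),
pads the rectangular cost matrix with full-deletion costs and solves the
assignment with the Hungarian algorithm.  The matching cost is mapped to
`k = 1 − cost / max_cost`, where `max_cost` deletes and reinserts every
graphlet, giving a symmetric similarity in [0, 1] with `k(G, G) = 1`.
Edit distances are computed by networkx's exact A* search with rooted
matching and memoised on Weisfeiler–Lehman signatures (graphlets are
small, so exactness is cheap; the memoisation key includes node and edge
labels and the root's type and degree).  The loss is
`(⟨φ₁, φ₂⟩ − k)²`; pair sampling draws half of the pairs within the same
RNA so the high-similarity regime is covered.  A 3-layer encoder is
needed to reach the kernel's effective radius (2-hop neighbourhoods of
radius-1 graphlets); with one shared 600-pair batch, held-out Spearman
between dot products and kernel values reaches ≈ 0.8–0.86 across seeds
on the synthetic corpus.

## Supervised training

**Compat** optimizes, per epoch and per binding-site group, the BCE of one
sampled active (label 1) and one sampled inactive (label 0) — balancing a
heavily skewed pair distribution — plus the margin loss
`L_m = max(M(G̃,F) − M(G,F) + α, 0)` with a wrong pocket `G̃` resampled
uniformly from the other groups each epoch.  α = 0.2 and margin weight
λ = 1 by default (the source material bounds α in [0, 1] without fixing
it).  Scores are logits; the logistic map is applied only at inference.

**Aff** regresses per-pocket quantile-normalized docking energies with an
L2 loss.  The quantile transform is rank-based: average ranks map each
pocket's empirical distribution onto [0, 1], the values are quantized
onto 50 equispaced quantile levels, and the scale is flipped so 1 = best
(lowest energy).  Rank-based rather than value-interpolated
normalization makes the transform exactly invariant to affine rescaling
of raw energies, gives tied scores identical targets, and matches a
pair-counting CDF oracle to 1e-9.  Passing an unnormalized target is an
error, not a warning.

Both heads hold out a seeded 10% of training groups for checkpoint
selection (best validation AuROC for Compat, best validation L2 for Aff);
test groups are never touched during training.  Non-finite losses abort
with a diagnostic.  `PocketLigandScorer` wraps this in a scikit-learn
estimator (get_params/set_params/clone-compatible, fitted attributes with
trailing underscores).

## Screening and evaluation

Ranks are 1-based, ties broken by ligand id for determinism.  AuROC uses
the Mann–Whitney convention (ties count ½; scikit-learn implementation,
pair-counting oracle in tests).  EF@X% takes the top ⌊N·X/100⌋ compounds.
The **Mixed** ensemble keys every compound by the best (smallest) of its
two rank positions; key ties break by the mean of the two ranks, then by
id — deterministic and symmetric in the two heads.  The **hybrid**
protocol docks compounds in presort order until the time budget is spent
(cost model defaults: 5.8 ms/compound surrogate, 65 s/compound docking —
hardware-dependent figures used only for simulated budget accounting),
re-scores docked compounds by true energy and places them above the
undocked remainder, which keeps the presort order.

**Efficiency** traces AuROC against cumulative cost while compounds are
processed in an initial order: at any time the processed compounds are
ranked by score and the unprocessed ones follow in their initial order.
The curve is integrated by the trapezoid rule over time normalized by the
total span; both the absolute area and the area between a method and a
reference curve are implemented, the relative form being the default
report.  The expectation over initial orders is a mean ± s.e. over 10
seeded shuffles.

The **swap control** reassigns each pocket's active set to another pocket
by a seeded derangement — strictly no fixed points, so every pocket is
actually swapped — and reports the true-minus-swapped mean AuROC gap.
Diversity metrics are the mean nearest-neighbour Tanimoto distance within
a selected set and a Hopkins statistic in fingerprint space whose probe
points are drawn bit-wise from the empirical bit frequencies of the
background set (min(n, 50) probes), so that a uniform random set scores
≈ 0.5.

## Perturbation robustness

For a pocket `p` inside a whole RNA, `p_h` is its h-hop BFS expansion.
*Noised* pockets sample `round(f·|p|)` nodes uniformly from `p_h`
(nearest-integer rounding, minimum one node); *shifted* pockets grow a
connected BFS region of the same size from a seeded boundary node of
`p_h` (boundary = `p_h` nodes with a neighbour outside `p_h`; BFS growth
is used — the original growth rule is not stated in the main text of the
source material, and BFS gives connected, reproducible regions).  The
grid spans f ∈ [0.5, 1.3] with 10 replicates per cell; perturbed pockets
are re-expanded with the standard depth-4 context before scoring.  At
h = 0, f = 1 the perturbation is the identity and the benchmark cell
reproduces the unperturbed baseline exactly.

## Splitting

Pocket similarity is a pluggable contract (an external structural
alignment score in production; a Weisfeiler–Lehman signature-overlap
Jaccard for synthetic data).  Clustering is **single-linkage**
agglomerative on distance 1 − similarity, cut at 1 − 0.75: single linkage
is the only linkage whose clusters guarantee that no cross-cluster pair
reaches the similarity cutoff, which is precisely the no-leakage property
the split must certify, and the certificate (max cross-split similarity)
is recomputed and reported on every split.  Groups are assigned to
train/test wholesale; one seeded representative per group is used for
training and the group's pooled native ligands become group actives.

## The synthetic benchmark

The generator emulates the statistical shape of the real pipeline inputs,
not their physics.  RNAs are hairpin-like: a backbone path (1–2 chains),
a cWW stem, sparse background non-canonical pairs (density 0.08/node).
Each RNA plants a pocket window with one of two archetypes — non-canonical
-poor and A/U-rich, or non-canonical-rich and G/C-rich — the window's
non-canonical partners staying inside the window so the signal
concentrates in the core.  The planted docking oracle is bilinear:
`score = −(w_p·desc(G)) · (w_l·desc(F)) + ε` with ε keyed per
(seed, pocket, ligand) via SHA-256 so tables regenerate stably.  Pocket
descriptors (edge-label fractions, GC content, degree, size) are computed
on the same context-expanded graph the network sees, and the weights are
centred so the pocket factor is bimodal with opposite signs across
archetypes.  Consequences, by construction: (i) the oracle is learnable
by a mean-pooled rGCN — descriptors lie inside its receptive field;
(ii) the two archetypes prefer opposite ends of the ligand spectrum, so
the benchmark has genuine target specificity and the swap control
destroys performance; (iii) mislocalized pockets dilute the archetype
signal, so robustness curves degrade with the expansion radius.  The
test split is re-drawn (deterministically in the seed) until both
archetypes appear among test representatives, otherwise the specificity
control would be vacuous.  Ligands come from a template grammar (ring
cores × substituents) tuned so roughly 80% pass the drug-likeness filter;
actives are the best 5% of the noiseless oracle per pocket; the noisy
docking table adds ε at 0.2 × the noiseless score s.d.  Near-duplicate
pockets (a copy with one mutated nucleotide) plant similarity clusters
that the split machinery must keep together.

What passing tests on this benchmark show: the implementation is
internally correct (layer equation, metrics, transforms match independent
oracles), the training loops recover planted signal, and the pipeline's
qualitative claims (ensembling synergy, budget monotonicity, specificity,
robustness degradation) hold under the planted model.  What they do not
show: performance on real RNA structures, real docking energies or real
chemical libraries — the generator has only two pocket archetypes, a
rank-1 bilinear affinity model, and no 3D geometry.

## Problem sizes and numerical choices

Tests and the acceptance script use 20-pocket × 200-compound benchmarks,
2-layer width-32 networks, 150 (Aff) / 250 (Compat) full-batch epochs and
three seeds — sizes chosen so a complete run takes minutes on one CPU
while leaving comfortable margins on every planted-signal threshold.
Ties anywhere (ranking, quantiles, MaxMin, Mixed keys) break
deterministically, by id or by average rank.  Degenerate inputs raise:
empty graphs, single-class labels, single docking scores, pools that
cannot satisfy decoy constraints (an explicit `allow_relax` opt-in
returns the achievable set instead).

## Known limitations

The numpy network trains small models quickly but is not meant for
GPU-scale corpora; there is no basis/block-diagonal weight sharing, no
uncertainty estimation, and no 3D pose information anywhere.  The ligand
encoder starts from random weights — VAE-style pretraining of the ligand
branch is out of scope, though externally supplied encoder weights can be
injected.  Binding-site similarity for real data must come from an
external structural aligner; the WL-overlap stand-in is only meaningful
for synthetic graphs.  Ligand admissibility during extraction is
approximated by an exclusion list plus size bounds rather than a full
curation pipeline.
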