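# Methods

## Model and assumptions

The predictor treats association inference as scoring ordered pairs in two
weighted similarity graphs. Its central assumption is that the weighted
local topology around a candidate — not just direct neighbours — carries
signal: if miRNA `j` participates in many small connected patterns
(graphlets, up to 4 nodes) together with the miRNAs already known for
disease `i`, the pair `(i, j)` is likely. Because the two sides are scored
independently and averaged, the model degrades gracefully for a new
disease (no known miRNAs) or a new miRNA (no known diseases), but it is by
construction unable to score a pair in which *both* entities are new.

Edges exist wherever similarity is positive and carry the similarity as
weight; no sparsification threshold is applied. The isomer count is an
*induced* weighted pattern count: absent template edges contribute factors
`1 − a_st`, so the two branches of the factor definition are exhaustive
and, with binary weights, counts equal induced-subgraph occurrence counts.
Templates symmetric in their two auxiliary slots are divided by a stored
symmetry factor of 2 so that ordered enumeration does not double-count
unordered configurations and binary counts stay integral. Self-pairs are
undefined and stored as zero.

The catalog (9 graphlets / 15 orbits / 28 ordered orbit-pair templates) is
generated by exhaustive enumeration of connected graphs on 2–4 labelled
nodes reduced by isomorphism, with orbits from the automorphism groups and
isomers as orbits of the group action on ordered node pairs. The ordering
is a deterministic canonical one (node count, edge count, minimal edge
code); published figures of the same catalog may label individual isomers
in a different order, which is immaterial because the per-isomer weights
are fitted, not prescribed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta` | 0.5 | semantic decay per DAG layer (dimensionless, in (0,1)); 0.5 is the convention of the DAG-semantic-similarity lineage |
| `gamma_d_prime`, `gamma_m_prime` | 1.0 | original GIP bandwidths; the effective bandwidth divides by the mean squared profile norm, so 1.0 leaves the kernel on its natural scale |
| `ridge_lambda` | 1e-6 | Tikhonov regulariser of the weight regression; the plain normal equations are frequently singular on small graphs, and 1e-6 perturbs a well-posed solution negligibly while `0` reproduces the textbook formula exactly when it exists |
| `cv_folds`, `cv_repeats` | 5, 100 | k-fold CV defaults; tests and the acceptance script use fewer repeats at their smaller problem sizes |

The "has semantic similarity" membership used by the integrated disease
similarity means: both diseases own a DAG in the corpus. Analogously, two
miRNAs "have functional similarity" when both appear in the supplied
functional matrix. These are the only membership signals available from
the inputs. In the information-content semantic model the corpus size `N`
is the number of diseases that own a DAG; the logarithm is natural, which
is immaterial because the base cancels between numerator and denominator
(asserted by a test).

Regression targets are the binary association labels, with one global
weight vector per graph fitted over all stacked pairs; per-disease fitting
would estimate 28 parameters from a handful of positives. All unknown
pairs act as 0-labelled training points — the closed form handles the full
design cheaply and no negative-sampling scheme is introduced. In
cross-validation the weights (and GIP kernels, and the P/Q partner sets)
are recomputed with the held-out associations zeroed, so held-out cells
never leak into training; DAG semantic similarity is independent of the
association matrix and is cached across folds. An explicit
`recompute=False` / `--fast-approx` mode reuses one full-data model and is
labelled an approximation of that protocol.

## Numerical choices

The vectorised census evaluates each 2-auxiliary template as a full tensor
contraction (`O(n⁴)` work, `O(n³)` memory via the optimised einsum path)
followed by exact inclusion–exclusion subtraction of tuples that reuse the
source, target, or repeat an auxiliary node; tiny negative residues from
cancellation are clipped at zero. The enumeration oracle is guarded to 15
nodes. Count normalisation maps all-zero rows to all-zero (an isolated
source contributes nothing rather than NaN). The ridge system is solved
directly; at `lambda = 0` a condition-number guard (1e12) fails loudly and
instructs raising the regulariser. AUC uses midrank tie handling, so an
uninformative constant predictor scores exactly 0.5; candidate ranking
breaks score ties lexicographically by miRNA id for run-to-run stability.

## Synthetic benchmark and what it shows

The planted world assigns diseases and miRNAs to blocks (default two),
draws similarities from Beta(5,1) within blocks and Beta(1,5) between
them, places associations on block-aligned pairs with probability
`assoc_density` (default 0.9), and hides 20% of them as recoverable
ground truth. A `noise` parameter interpolates to a null world of i.i.d.
uniform similarities and uniformly random associations. Each disease also
gets a two-level DAG through a per-block branch node under a shared root,
so the semantic pathway sees the same block structure.

The default aligned density is deliberately high, for an identifiability
reason: given the visible data, a hidden positive and a within-block
negative are exchangeable, so with aligned density `p` the best achievable
held-out AUC of *any* method is `(1 + 0.5(1−p)) / (1 + (1−p))` — about
0.79 at `p = 0.3` but 0.955 at `p = 0.9`. A "noise-free" world should be
limited by the method, not by the generator, hence the dense default; the
pipeline reaches ≈0.95 there and ≈0.5 on the null world.

The generator emulates block-structured similarity and block-aligned
associations only. It does not reproduce the heavy-tailed degree
distribution of curated association databases, realistic MeSH topology, or
correlated annotation noise — so passing the planted-recovery checks shows
the machinery extracts the structure it models, not that real-data AUCs of
any particular magnitude will be achieved. Published full-scale results
require the curated association, similarity and vocabulary files; the
`score`/`evaluate` commands accept those files directly.

## Known limitations

* Graphlets beyond 4 nodes are out of scope; longer-range indirect
  similarity is invisible to the census.
* Pairs where both entities are new receive only the uninformative zero
  score from both sides.
* The census is dense `O(n⁴)` per 2-auxiliary template; at curated-database
  scale (hundreds of nodes per graph) a single census is still feasible
  but per-held-out retraining in global LOOCV becomes expensive — the
  `--fast-approx` evaluation mode exists for that regime.
* Scores are regression outputs on the label scale, not calibrated
  probabilities; only their ranking is meaningful.
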