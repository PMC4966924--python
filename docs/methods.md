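# Methods

This note documents the models and procedures protasr implements, the
choices made where reasonable alternatives exist, and what the bundled
simulator does and does not capture.

## Substitution models and rate heterogeneity

Protein evolution is modeled as a reversible continuous-time Markov
chain on the 20 amino acids. A model couples a symmetric
exchangeability matrix `S` (JTT, LG or WAG, embedded as published
constants) with equilibrium frequencies `π` — the matrix's published
frequencies by default, or frequencies counted from the alignment with
a +0.25 pseudocount per amino acid (`+F`); the pseudocount prevents
zero-frequency singularities on small or biased alignments. The rate
matrix is `Q_ij = S_ij π_j` off the diagonal, diagonal set so rows sum
to zero, normalized so `-Σ_i π_i Q_ii = 1`; branch lengths are then
expected substitutions per site.

Among-site rate variation uses the discrete gamma approximation:
`ncat` (default 4) equal-probability categories of Gamma(α, α). The
category rate is the mean of the distribution within each quantile
band — computed in closed form from the regularized incomplete gamma
function — and the rates are rescaled so their mean is exactly 1.
Means rather than medians are used because mean-rate discretization
preserves the expected overall rate, which keeps the empirical-Bayes
category weights in ancestral reconstruction coherent. The RAxML-style
CAT approximation is deliberately excluded: it is a large-tree speed
device, and at the tree sizes this package targets the discrete gamma
model covers the rate-heterogeneity axis exactly.

Transition matrices `P(t) = exp(Qt)` come from the symmetric
eigendecomposition of `diag(√π) Q diag(1/√π)`, which is exact for
reversible models and numerically stable; entries are clipped at zero
and rows renormalized, both at the 1e-15 level. Model spec strings
("LG", "JTT+G", "WAG+G4", "LG+G{alpha=0.7}", suffix "+F") select all
of this from configuration.

## Likelihood, fitting, model selection

Site likelihoods use Felsenstein pruning over the (rooted or unrooted)
tree with per-pattern scaling, alignment columns compressed to unique
patterns first. Gaps and 'X' are missing data: their leaf partials are
all ones, so an all-gap column has probability 1 and contributes zero
log-likelihood. Under +G, a column's likelihood is the equal-weight
average of its conditional likelihoods across rate categories.

`TreeLikelihood.fit()` maximizes by coordinate ascent: each sweep
optimizes every branch length by bounded 1-D search (bounds
[1e-8, 20]) using an inside/outside decomposition so the 1-D objective
costs one 20×20 contraction per pattern, then the gamma shape α
(bounds [0.02, 100]). A proposed update is kept only if it improves
the log-likelihood, so lnL is non-decreasing by construction;
convergence is declared when a full sweep gains less than 1e-6 lnL
units (cap 50 sweeps, flagged and warned when hit).

Model selection fits each candidate and ranks by AIC = 2k − 2 lnL,
with k counting branch lengths plus one for α plus 19 when
frequencies are estimated from data. Branch lengths are counted for
every model — constant across models on the same alignment, so the
ranking is driven by α and frequency parameters. Ties break toward
fewer parameters, then model-name order.

Tree search is exhaustive over all (2n−5)!! unrooted topologies, by
stepwise addition, capped at 9 taxa (larger problems must supply a
topology). A constraint tree filters candidates to those displaying
every constraint bipartition restricted to shared taxa. For +G models
the shape is estimated on the first topology, held fixed while the
remaining topologies are scored (branch lengths still optimized per
topology), and the winner refitted with α free; α varies little across
topologies of the same alignment, so this ranks topologies as the full
refit would at a fraction of the cost. Exact lnL ties break on a
canonical topology string, making the search deterministic.

## Branch support

Each internal branch is scored by the approximate likelihood ratio
test: aLRT = 2(lnL_ML − lnL_bestNNI), where the two
nearest-neighbor-interchange rearrangements of the branch are refitted
and the better one is the alternative hypothesis. By default all
branch lengths of the NNI alternatives are re-optimized — affordable
at desk scale — rather than only the focal branch; the published fast
approximation (focal branch only) is available via `exact=False` and
gives slightly larger statistics. The statistic is clipped at zero
(an alternative can exceed a constrained "ML" tree) and reported also
as aLR = exp(aLRT/2), read as "the split is aLR times more likely than
the best hypothesis lacking it"; clipping keeps aLR ≥ 1 coherent with
that reading.

## Ancestral reconstruction

Reconstruction is empirical-Bayes and marginal: with parameters fixed
at their ML estimates, the posterior over states at one internal node
and column is proportional to the product of the inside (below-node)
and outside (above-node) partial likelihoods. Under +G the posterior
mixes rate categories with per-column weights proportional to each
category's likelihood. Joint reconstruction (a single most probable
assignment to all nodes simultaneously) is out of scope. Ancestral
nodes are defined on the outgroup-rooted tree: reconstruction on an
unrooted tree is refused rather than silently rooted.

The ML sequence takes the argmax residue per column; exact ties break
to the alphabetically first amino acid and are flagged. Bayesian
sampled sequences draw each column independently from its posterior —
deliberately matching the marginal data structure, with no attempt to
model across-site correlation. Indels are placed by Fitch parsimony on
the binary present/absent character: intersection-else-union up-pass,
then a down-pass that keeps the parent's state when admissible, with
an ambiguous root resolved to "present". This yields a deterministic
minimum-change labeling (minimality is verified against enumeration in
the tests); "present" at the root is the conservative choice for a
deletion-only view of the gap pattern. Columns absent at a node render
as '-' and carry no residue claim.

Node numbering follows the classic reconstruction convention — leaves
1..n in input order, internal nodes n+1..2n−1 in post-order — so
labels like "Node7" match what users of CODEML-based pipelines expect.

## Alignment comparison and masking

Alternative alignments of the same sequences are compared through a
residue map: for every taxon and every residue, the column it occupies
in each alignment. From the map, the site-identity distribution of a
reference column reports where its residues land in each other
alignment (rows gapped at the reference column are excluded from the
denominator, so the distribution always sums to 1). The per-column
consistency score — the mean over other alignments of the largest
single-column fraction — is a scalar summary defined by this package
(the underlying comparison is usually presented visually) and is
labeled as such in outputs. Column-quality masking consumes an
external per-column score file (one float per line, as probabilistic
maskers emit) or a uniform default; the threshold is a required
configuration value with no silent default, because no universal
cutoff exists.

## The simulator

`simulate_evolution` draws a root sequence from π, evolves it down a
rooted tree (random Yule tree or user-supplied; an unrooted input is
rooted arbitrarily, which a reversible model makes harmless), drawing
each site from the branch's transition matrix, with a continuous
per-site gamma rate when the model has +G. Indels are a deletion-only
process: each branch deletes each surviving column independently with
a configurable probability, and deletions propagate to all
descendants. True sequences at every internal node are recorded.

What this emulates: site-independent substitution under the fitted
model family, rate heterogeneity, and nested gap patterns that give
Fitch placement realistic work. What it does not: insertions (the
alignment coordinate system is the root's, so there is no alignment
uncertainty in simulated data), across-site process heterogeneity,
selection, or alignment error. Tests that pass on simulated data
therefore certify the inference machinery, not robustness to aligner
mistakes — that axis is exercised separately by perturbing gap
placements (`perturb_gaps`), which mimics aligner disagreement while
preserving the underlying sequences.

Default study conditions used by the verification suite, chosen once
as representative desk-scale problems: topology recovery on the
5-taxon tree with all branches 0.2 and 1000 sites; rate-model
selection under LG+G(α = 0.5) with 500 sites; root-sequence recovery
on the 6-taxon unrooted tree with all nine branches 0.1, rooted
through the {A,B} outgroup (the root bisects one branch into
0.05 + 0.05), 500 sites, 1% per-branch deletion rate. The rooting
mirrors how the pipeline actually obtains ancestors — reconstruction
always happens on an outgroup-rooted ML tree.

## Robustness grid and trajectories

Ancestral nodes are identified by descendant leaf sets after outgroup
rooting (rooted-clade semantics; when grids differ in taxa, both sides
are restricted to shared taxa first). The robustness report cross-maps
every internal node of every (alignment × model) cell onto all cells;
a node "exists" in a cell when its leaf set forms a clade there, and
the existence fraction summarizes how contingent the ancestor is on
method and model choice. Outgroup rooting places the root at the
midpoint of the separating edge — the likelihood of a reversible model
is invariant to the split, so the midpoint is purely a convention.

Trajectory diffs compare two ancestors column by column, classing each
difference as "confident" (both ML-residue posteriors ≥ a threshold,
default 0.8, a conventional reconstruction-ambiguity cutoff),
"indel" (presence states differ) or "ambiguous"; path queries
concatenate per-branch diffs through the MRCA. Leaves participate via
point-mass posteriors, so root-to-extant paths work uniformly.

## Pipeline

The job runner executes seven stages in order (input validation,
alignment comparison, model fitting, tree inference, branch support,
ancestral reconstruction, robustness/trajectories), writes only
plain-text products (FASTA, Newick, TSV, JSON), and persists per-stage
state. A stage whose products exist is loaded rather than recomputed,
so deleting downstream products and rerunning resumes there. All
randomness (Bayesian sampling) derives from the configured seed, and
two runs with identical config and seed produce byte-identical
products.

## Numerical choices and limitations

* Partial likelihoods are rescaled per pattern at every internal node;
  log-scale factors are carried separately, so deep trees cannot
  underflow.
* Branch-length bounds [1e-8, 20] and α bounds [0.02, 100] are wide
  enough that hitting them signals a degenerate dataset (e.g. a
  zero-variation alignment drives all lengths to the lower bound).
* Coordinate ascent can, in principle, stall at a non-stationary point
  of the joint surface; the convergence flag and sweep history are
  exposed on the results object.
* Exhaustive search scales as (2n−5)!!; nine taxa (135135 topologies)
  is the hard cap and already slow — the intended regime is 4–7 taxa,
  or fixed/constrained topologies beyond that.
* Branch support is defined for internal edges of the unrooted
  topology; a 3-leaf tree has none.
* The aLR is capped at infinity beyond exp(700) to avoid overflow;
  statistics that large mean "effectively certain" anyway.
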