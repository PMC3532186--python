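# Methods

## Model and assumptions

The scoring model treats an interactome as an undirected simple graph
and assumes its edges are organised into modules: groups of
interactions whose participating proteins interact preferentially with
one another.  Confidence assessment is then a question of agreement
with that modular structure.  Interactions are clustered (not
proteins), by applying Markov clustering to the line graph, so that a
protein can belong to several modules — pathways and machineries
overlap in their components, and a disjoint protein partition would
force an artificial choice.

For an interaction assigned to cluster *c*, each endpoint protein *p*
receives a fidelity

F(p, c) = P(X ≤ L_pc),  X ~ Hypergeometric(L, L_p, L_c),

the probability that a random set of L_c of the network's L links
contains at most the observed number L_pc of p's links.  This is an
enrichment statistic: it approaches 1 when the cluster holds more of
p's links than expected for its size, and decreases when p's links are
scattered elsewhere.  Three properties follow from the distribution
and are enforced by tests: F is non-decreasing in L_pc; at fixed L_pc
a smaller cluster gives a larger F; and when all of a protein's links
lie in the cluster, F grows with the protein's degree (a high-degree
protein fully contained in one module is stronger evidence than a
degree-1 protein trivially contained in it).  The confidence of the
interaction is the product of the two endpoint fidelities — both
partners must be specific to the shared module.

The method has no tunable threshold: the only free parameter,
clustering granularity, is selected by the rewiring procedure below.
Its known failure mode is weakly modular input (sparse maps with
clustering coefficients well under 0.1), where the topological signal
it exploits is faint.

## Markov clustering

MCL is re-implemented from scratch (it is the computational core of
the pipeline, not a peripheral step).  The transition matrix is built
column-stochastic from the line-graph link weights with a unit
self-loop on every node; iteration alternates expansion (power 2) and
inflation (entrywise power, column renormalisation), pruning entries
below 1e-5 (always retaining each column's maximum) and renormalising
after pruning.  Convergence is declared when the largest entry change
between successive iterations falls below 1e-6; the cap is 200
iterations, after which the current state is interpreted with a
warning rather than failing.  Defaults mirror the documented defaults
of the canonical `mcl` tool.  Exact cluster-boundary agreement with
that tool is not guaranteed (its pruning schedule is adaptive and
undocumented in detail) and nothing downstream depends on it.

Clusters are read off the limit matrix's attractor structure: nodes
with positive return probability are attractors, attractors connected
by nonzero entries form one system, and every other node joins the
system holding the largest entry of its column.  The rare overlap
degeneracy (a column attracted to two systems) resolves
deterministically to the largest entry, ties to the cluster that sorts
first by size then by smallest member, so results are independent of
node order — verified by permutation tests.  Dense numpy arithmetic is
used below 2,000 line-graph nodes and scipy sparse matrices above;
with pruning, sparsity is what makes 10k-interaction networks
tractable.

The hypergeometric CDF behind the fidelity is evaluated through
scipy's hypergeometric distribution, which is accurate to ~1e-15
absolute even at interactome scale (L ≈ 75,000) where direct
factorials overflow; tests compare it against exact rational
arithmetic.

## Granularity selection

A partially rewired instance of the input network provides labelled
false interactions: pairs of edges (a,b), (c,d) are repeatedly swapped
to (a,d), (c,b), rejecting any swap that would create a self-loop or
duplicate edge, reconstitute an original edge, touch an already
rewired edge (labels must stay unambiguous), or change the number of
connected components.  Each accepted swap converts two real links into
two false ones and preserves every protein's degree exactly.  The
rewired-edge target is round(fraction·|E|) rounded to an even count;
the default fraction of 3% balances statistical power (enough
negatives) against structural damage (most of the network intact).
The "component count unchanged" rule generalises connectivity
preservation to disconnected inputs; a side effect is that some
fixtures (for example two disjoint triangles) admit no valid swap at
all, which the rewiring reports as an error.

The inflation scan evaluates a coarse grid {1.1, 1.2, …, 2.0} and then
a fine grid at step 0.025 within ±0.1 of the coarse optimum (clipped
below at 1.025; inflation must exceed 1).  One rewired instance serves
the entire scan so the P-values are comparable on a fixed negative
set.  At each inflation the rewired network is clustered and scored,
and a one-sided Wilcoxon rank-sum test asks whether surviving original
links outscore rewired links; the inflation minimising the P-value
wins, ties breaking to the smallest (coarsest) value.  If a clustering
collapses to a single cluster every score is 1 and the P-value is set
to 1 by convention.  The rank-sum test uses the exact distribution for
tie-free samples up to a combined size of 20 and the normal
approximation with tie and continuity corrections beyond; an
enumeration oracle in the package verifies the exact branch.

The optimum found on the rewired instance is then applied to the
intact network.  On desk-scale synthetic networks (a few hundred
links) the minimising inflation is reproducible given a seed but
carries sampling noise of a few fine-scan steps between independent
rewirings: the P-value curve is flat near its minimum, and with only
4–36 rewired negatives the position of the argmin within that plateau
is not sharply determined.  On networks of thousands of links the
plateau P-values separate by orders of magnitude and the estimate
stabilises; the package logs the full scan so users can inspect the
plateau.

## Evaluation protocol

The ROC benchmark mirrors the rewiring construction: positives are
surviving original edges with at least 3 literature evidences,
negatives the planted rewired edges, and each of the (default 100)
runs draws a fresh instance with seed+run.  The scored, partially
rewired network is ranked by decreasing confidence; ties contribute
fractionally (rank-average), making the per-run AUC the Mann–Whitney
statistic and the curve independent of input order.  Curves are
vertically averaged on a fixed 101-point FPR grid and the mean AUC is
the trapezoidal integral of the mean curve — identical, by linearity,
to the mean of the per-run interpolated AUCs.  A scorer with a
terminal jump at FPR=1 (the anti-oracle) integrates to half a grid
cell (0.005) rather than exactly 0; this is the resolution limit of
vertical averaging, not a ranking error.  With the cluster-based
scorer the inflation is tuned once on the intact network and reused
across runs: the granularity optimum transfers between instances
differing in 3% of links, and a shared inflation keeps runs comparable
while avoiding an 18-fold scan overhead.

The common-neighbour baseline scores an edge (u,v) as −log10 of the
upper-tail hypergeometric P-value of the observed number of shared
neighbours given the two degrees drawn from a gene universe (default
6,000, the yeast convention).  Edges without common neighbours are
structurally unscorable by this statistic and receive 0 — the
limitation the cluster-based method is designed to avoid.

Score binning ranks edges by increasing confidence (ties broken by
edge identifier), splits them into five contiguous bins whose sizes
differ by at most one (remainder to the low bins), and reports the
mean of an external per-edge value per bin.  The package does not
compute annotation semantic similarity itself; any user-supplied
per-edge value (for synthetic benchmarks, the planted within-module
indicator) can be binned.

## Synthetic data

The generator produces planted-partition networks: n_modules × 
module_size proteins, within-module pairs connected with probability
p_in, cross-module pairs with p_out, isolated proteins discarded.
Defaults (6 × 20, p_in 0.3, p_out 0.005) give ~360 links, clustering
coefficient ≈ 0.25 and ~74% of links in triangles — inside the range
spanned by published physical interactomes, and dense enough in
modules for topology-only scoring to have signal.  A configurable
fraction of edges (default 0.2, the middle of the 3–23% multi-
publication fractions observed in real maps; 1.0 in benchmarks that
need every original edge as a potential positive) carries evidence
count 3, the rest 1.

What the generator does *not* emulate: power-law degree
distributions and hubs, heterogeneous module sizes, nested/
hierarchical modularity, and experiment-specific sampling biases
(bait/prey asymmetry, sticky proteins).  Passing tests therefore
demonstrate the machinery is correct and discriminates planted false
links under clean modular conditions; they do not certify performance
on any particular real interactome, where modularity strength is the
governing factor.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on the default
synthetic network (120 proteins, ~360 interactions; line graphs of
~360 nodes handled in the dense MCL path), with 20-run ROC averaging
and 5-seed stochastic checks — sizes chosen so the full validation
suite completes in minutes on one CPU while every qualitative
behaviour of the pipeline (granularity plateau, module recovery,
baseline comparison) is already expressed.  Exact-arithmetic oracles
cover the fidelity up to L = 5,000 and the rank-sum test up to
combined sample size 30.

Other numerical conventions: interaction identifiers are
lexicographically sorted endpoint pairs throughout, cluster indices
order by size then smallest member, all randomness flows from
explicit integer seeds through numpy Generators, and duplicate input
rows merge by maximum weight/evidence so parsing is order-independent.
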