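# Methods

## Model

`gibbslink` treats a patient's pathway network as a thermodynamic system in
which each protein's contribution to stability is scored by a Gibbs-entropy
expression over its local concentration environment. For node i with
normalized concentration surrogate c_i ∈ [0, 1] and network neighbors N(i),

G_i = c_i · ln( c_i / S_i ),  S_i = c_i + Σ_{j ∈ N(i)} c_j,

with the sums restricted to nodes that have expression data. Because the
denominator is the closed-neighborhood sum, the log argument is ≤ 1 and
G_i ≤ 0 for every node; G is a dimensionless score on the natural-log scale,
not a physical free energy (no temperature, no units). Boundary conventions
follow the continuous limit of x ln x: c_i = 0 gives G_i = 0, and a node
whose entire covered closed neighborhood is zero also scores 0. An isolated
covered node has S_i = c_i, ratio 1, hence G_i = 0 — it can never be selected
as anchor unless every score ties at zero.

The per-patient target is an *edge*, not a node: the anchor is the node with
the most negative G (the largest contributor to network stability), and the
partner is the anchor's covered neighbor with the highest c. By
construction the pair is an existing interaction, and blocking it leaves both
proteins' other interactions intact. The underlying assumptions are that
(a) normalized mRNA is an acceptable surrogate for protein concentration,
and (b) the interaction worth blocking is the one joining the
thermodynamically dominant node to its most abundant partner.

### Tie-breaking and degenerate inputs

All ties — equal G among anchor candidates, equal c among partner
candidates — break to the lexicographically smallest node identifier, giving
a total order and bit-reproducible output regardless of graph-representation
order. If the argmin-G node has no covered neighbor (possible only when
scores tie at zero, since any node with a covered neighbor of positive
concentration scores strictly below zero when c_i > 0, and covered-isolated
nodes score exactly zero), selection falls back to the next node in
ascending-(G, id) order; a sample is skipped — and reported in the cohort
table metadata, never silently dropped — only when no scored node has any
covered neighbor.

### Normalization

Expression is min–max rescaled per sample across genes (a within-patient
rescale, never per-gene across the cohort): c_g = (x_g − min)/(max − min)
over the sample's non-missing values, so the endpoints 0 and 1 are always
attained. A constant-valued sample has no scale; every gene is set to 0.5
with a warning rather than failing the cohort run (0.5 is the unique
symmetric choice). Missing values are excluded from min/max and from all
neighborhood sums, and genes without data are ineligible as anchor or
partner — exclusion, not imputation, because a fabricated zero would be
indistinguishable from a measured zero in the eligibility logic even though
both yield the same sums. Raw values are used as-is by default; an optional
log2(x + 1) pre-transform is flag-controlled (it changes spacing, not
ranks, so it affects G but not which genes sit at 0 and 1).

## Network construction

Pathways merge by identifier union (the union-merge semantics of network
tools like Cytoscape): node sets and edge sets are united with exact-string
matching, making the merge idempotent, commutative and associative. KGML
parsing takes every `entry` of type `gene` (all identifiers in its `name`
attribute, organism prefix kept, e.g. `hsa:5925`), expands `group` entries
to their components, and converts each `relation` into edges between every
gene of one entry and every gene of the other — clique expansion *across*
related entries, with no within-entry edges, since a multi-gene entry is a
family/complex whose members are alternative interactors rather than
mutually interacting per se. All relation subtypes (activation, inhibition,
binding, …) flatten to undirected edges because scoring and selection use
adjacency only. Self-loops are dropped (and counted in the log): the
closed-neighborhood denominator already contains c_i once, and a loop would
double-count it. Gene-level identifiers can be relabeled (e.g. Entrez →
HGNC symbol) through a user-supplied two-column table — first mapping wins,
unmapped nodes keep their identifier — rather than any hard-coded mapping,
because symbol assignment is release-dependent. Merged-network node/edge
counts for specific KEGG pathway combinations therefore depend on the KEGG
release and are not asserted anywhere in the test suite.

Cohort aggregation keys on the *ordered* (anchor, partner) pair by default,
because the two roles are asymmetric (energy-selected vs
expression-selected); a flag collapses reversed pairs for an unordered
count.

## Auxiliary network statistics

Degree entropy is the Shannon entropy of the node-degree distribution,
H = −Σ_k p(k) ln p(k), with p(k) the fraction of nodes of degree k taken
over nodes of degree ≥ 1 (degrees range 1..n−1 in a simple graph; isolated
nodes are excluded, and an all-isolated network is an error). Natural log by
default, `base=2` for bits. Regular graphs give H = 0; the 3-leaf star
gives −(¾ ln ¾ + ¼ ln ¼) ≈ 0.5623 nats. An alternative reading of the
network-entropy formula — summing over nodes with p taken from normalized
betweenness — exists in the literature; the degree reading is implemented
here, consistent with degree-entropy usage as a complexity measure.

Betweenness centrality is the standard unnormalized, endpoint-excluded
count: C_B(V) = Σ over unordered pairs {s,t}, s ≠ t ≠ V, of
σ(s,t|V)/σ(s,t); disconnected pairs contribute zero. It is computed via
networkx (Brandes' algorithm) and validated in the tests against an
independent exhaustive shortest-path enumerator on all graphs of ≤ 7 nodes;
a flag applies the 2/((n−1)(n−2)) normalization.

## Synthetic cohorts

The simulator provides controllable ground truth, not realism. Over a fixed
network it plants a known target: every gene sits at a background level of
0.1; the planted anchor and its whole neighborhood are raised to 0.9; the
planted partner to 1.0; then i.i.d. Gaussian noise of standard deviation
`noise_sd` is added and values are truncated at 0. At zero noise the anchor
provably carries the largest closed-neighborhood load on the bundled
fixture networks, so the pipeline recovers the planted pair in 100% of
samples (the test suite verifies this mechanically against the brute-force
oracle); the 0.1 margin between partner and other neighbors is the knob
noise competes against, so recovery decays as noise_sd grows through
{0.1, 0.3, 1.0} (≈10× the margin at the top). All randomness flows from an
explicit integer seed through `numpy.random.default_rng`; identical seeds
give bit-identical matrices.

What the simulator does *not* emulate: real expression marginals (RNA-seq
count skew, microarray intensity distributions), gene–gene correlation
beyond the planted neighborhood, batch effects, or realistic missingness.
Passing the planted-recovery tests shows the selection machinery is correct
and noise-sensitive in the intended direction; it says nothing about how
often real cohorts present a clean dominant target.

## Numerical choices and problem sizes

Scoring is exact double-precision arithmetic (no tolerance parameters in the
method itself); oracle-agreement tests assert equality to 1e−12 or better.
Validation runs use random Erdős–Rényi instances of ≤ 20 nodes for Gibbs
scoring, ≤ 12 for end-to-end selection, ≤ 7 for betweenness enumeration
(exhaustive path enumeration is exponential), 200-sample cohorts for planted
recovery and 20 seeds × 10 samples per noise level for the noise sweep —
sizes at which the brute-force references are themselves trivially
verifiable by hand. The pipeline itself is linear in edges per sample and
routinely handles pathway-scale networks (10²–10³ nodes) and cohort-scale
sample counts.

## Known limitations

- Single-target output per sample: no top-k anchors, no multi-edge
  intervention sets.
- Direction and sign of interactions are discarded; an inhibitory and an
  activating edge are indistinguishable to the score.
- The mRNA-as-concentration surrogate ignores translation efficiency and
  protein stability.
- Anchor selection is a hard argmin: two nearly tied anchors can flip on
  minute expression changes (the cohort table's spread across pairs is the
  practical diagnostic for this instability).
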