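# Methods

## Model and assumptions

The detector assumes protein complexes in a PPI network are organized as a
dense, reliable **core** surrounded by sparser **attachment** proteins, and
that raw interaction data carry a substantial false-positive rate. Three
consequences drive the design:

- An interaction whose endpoints share *no* common neighbor has no
  topological support and is treated as spurious: it is removed before any
  clustering. All reliability weights (JCS, CNS, HOCN) are computed from
  the original neighborhoods in a single pass; removal does not cascade.
  Since each Jaccard term is ≤ 1 and each common neighbor contributes one
  term ≤ 1, the retained HOCN weight always lies in (0, 1].
- Core membership is decided by *structural similarity* of closed
  neighborhoods, not by subgraph density: the members of a genuine core see
  largely the same part of the network as the seed does. Similarity is
  purely topological (the HOCN weights do not enter it) and is evaluated on
  the filtered network, since filtering is the point of stage one.
  Pairwise adjacency among all core members is deliberately *not*
  required — only adjacency to the seed — because clique-style requirements
  are exactly what the structural-similarity approach is meant to relax.
- Attachment classification is *per core and independent*: whether a
  candidate is overlapping for core A never consults core B. "Overlapping"
  is therefore a local signature (outward pull ≥ inward pull, yet inward
  weight ≥ half the core's average weighted degree); being assigned to
  several complexes is the emergent consequence, not a test. A tie between
  inward and outward weight goes to overlapping — the peripheral condition
  is strict — so the two branches are mutually exclusive by construction
  and no epsilon tolerances are used in the comparisons. Inward/outward
  sums are accumulated with `math.fsum`, making the inclusive boundary
  comparisons independent of summation order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ss` | 0.4 | structural-similarity threshold for core membership, in (0, 1]. Detection quality peaks around 0.4; 0.4–0.6 is the sensible band. Raising it strictly shrinks every seed's core (nested member sets), trading recall for precision. |
| `min_size` | 3 | smallest emitted complex; pairs are not meaningful complexes. Size-2 *cores* are kept through the attachment stage (they may grow), and filtered only here. |
| `na_threshold` (t) | 0.2 | neighborhood-affinity cutoff for counting a prediction/reference match in recall, precision and F-measure. |
| `mmr_threshold` | 0.0 | NA cutoff below which a pair carries no edge in the maximum-matching computation. The matching ratio conventionally uses all positive affinities, so the default is 0; it is exposed for sensitivity experiments. |
| significance cutoff | 0.01 | a complex is called functionally significant when its smallest hypergeometric upper-tail p-value over the supplied annotation groups is below this. No multiple-testing correction is applied, matching field convention for this statistic. |

## Numerical choices

- Duplicate cores are collapsed keeping the lexicographically first seed;
  seed iteration is sorted, so the pipeline is bytewise deterministic.
- The maximum matching ratio is solved as a rectangular assignment problem
  (`scipy.optimize.linear_sum_assignment`, maximizing). The matching itself
  may be non-unique; the reported total weight is unique.
- Enrichment p-values use the hypergeometric survival function
  (`scipy.stats.hypergeom.sf`), clamped to [0, 1]; m = 0 returns exactly 1.
- Degenerate inputs: an empty prediction or reference set yields 0 for the
  corresponding ratio with a warning rather than an error; a candidate set
  left empty after removing overlapping proteins produces an empty
  peripheral set without computing a mean.

## The worked-example fixture

`ewca.synthetic.example_network()` is an 11-protein, 15-interaction
illustration network of which 14 edges are uniquely reconstructible from
the printed neighbor sets of its reliability walk-through; the fifteenth
lies among the degree-one fringe and cannot affect any illustrated
quantity, so it is omitted rather than guessed. A test pins all five
illustrated Jaccard values as exact rationals to guard the fixture. The
walk-through's headline weight for the (b, d) edge is exactly 155/1512 ≈
0.10251 (0.103 when rounded to three decimals; 0.102 when truncated).

## The synthetic benchmark

`generate_planted` emulates the structural assumptions above: vertex-disjoint
dense cores (each internal edge with probability `p_core`, splice edges
forcing connectivity), peripheral proteins bound to 2–3 mutually adjacent
members of exactly one core, overlapping proteins bound to roughly 60% of
the members of each of two host cores, background vertices, and uniform
noise edges (probability `p_noise` per non-intra-core pair). The 60%
attachment fraction for overlapping proteins is a modelling choice: an
overlapping protein must stay comparable to half the core's average weighted
degree to be recognized as attached at all, which a 2-edge bridge cannot
achieve against a dense core; proteins genuinely shared between complexes
bind both substantially. Peripheral anchors are chosen mutually adjacent so
their edges retain common-neighbor support and survive the reliability
filter.

Defaults — 5 complexes, core sizes 4–8, `p_core` 0.9, 2 peripheral proteins
per complex, 3 overlapping proteins, 10 background vertices, `p_noise` 0.02
— give a ~50-vertex, ~120-edge network, a size at which every pipeline
stage and all test oracles run in milliseconds. A single seeded
`random.Random` stream drives generation; identical seeds give identical
networks.

What the benchmark does *not* model: the degree distribution of real
interactomes (no hubs beyond the planted structure), false-negative edges
inside cores beyond `p_core`, complexes of heterogeneous internal density,
or proteins shared by more than two complexes. Passing the planted-recovery
tests therefore demonstrates correctness of the algorithmics under the
method's own structural assumptions, not expected accuracy on experimental
networks, where reported F-measures are far below 1.

## Known limitations

- Highly similar but non-identical predicted complexes are all emitted;
  there is deliberately no merge step for partially overlapping predictions,
  which inflates prediction counts on dense regions.
- Externally supplied confidence weights on input edges are preserved for
  round-tripping but ignored by detection; the method trusts its own
  topological reliability score.
- Whether size-2 cores should reach the attachment stage, and whether core
  members should be required pairwise adjacent, are genuinely open design
  points; the implemented choices (keep size-2 cores, require seed adjacency
  only) follow the algorithmic description over the prose conditions.
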