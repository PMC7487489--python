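# Methods

## Model

The package treats a miRNA's influence on a downstream cell-fate gene
as a signal that propagates along regulatory chains and decays with
distance. Three assumptions define the model:

1. **Shortest-path propagation.** Of all routes from miRNA *i* to gene
   *j*, the signal follows a minimum-edge directed path; its strength
   is the miRNA's differential-expression amplitude `log2(FC_i)`
   divided by the path length `L_ij` (linear decay).
2. **Sign multiplication.** Each edge either preserves (+1, activation)
   or flips (−1, inhibition) the direction of the perturbation; the net
   sign `S_ij` is the product along the path. miRNA→target edges are
   always −1: miRNAs are modelled purely as repressors.
3. **Additivity.** Impacts of different miRNAs on a gene, and of one
   miRNA on different genes, add:
   `I_gene−j = Σ_i I_ij`, `I_miR−i = Σ_j I_ij`. Both totals therefore
   sum to the same grand total over all scored pairs — an identity the
   test suite checks to 1e−9 on every fixture.

The approach deliberately avoids the matrix-inverse-plus-bootstrap
machinery of full pathway-perturbation models; the price is that
multi-path reinforcement and feedback dynamics are ignored. A miRNA
whose downstream effects genuinely cancel (equally many activating and
inhibiting chains) has `I_miR ≈ 0` by construction — that is a
statement of the statistic, not an artefact (see *Limitations*).

## Multiple shortest paths

The sign product is well defined only when the shortest path is
unique. Three resolution policies are implemented:

- `majority` (default): the sign held by a strict majority of all
  shortest paths; ties give `S = 0`, the pair is flagged ambiguous and
  contributes nothing to the sums.
- `lexicographic`: the sign of the shortest path that is minimal in
  node-id lexicographic order (deterministic and locale-independent,
  useful when a single representative path is wanted).
- `all_paths_mean`: the sign of the mean of all shortest-path signs.
  Since each path sign is ±1, the mean is positive exactly when the
  majority is — this policy coincides with `majority` and is kept only
  as an accepted alias for interface compatibility.

Majority and mean are computed exactly by dynamic programming over the
shortest-path DAG (nodes with `d_source(v) + d_target(v) = L` ordered
by BFS depth, propagating separate +/− path counts), so graphs with
exponentially many tied paths are handled without enumerating them.
The lexicographic policy is a greedy walk that always steps to the
smallest successor still on a shortest path. Cycles need no special
handling: minimum-length paths are simple by construction.

## Differential expression

Fold change is the ratio of group means of raw abundances with a
pseudocount (default 1.0) added to numerator and denominator, so it is
finite for any nonnegative input; tests operate on
`log2(x + pseudocount)`. Two test statistics are offered:

- `welch` (default): Welch's unequal-variance t-test.
- `moderated`: an empirical-Bayes moderated t. Per-feature pooled
  variances are shrunk toward a scaled inverse-chi-square prior whose
  degrees of freedom and scale are estimated by moment matching on the
  log sample variances (digamma/trigamma moments, with the trigamma
  inverse obtained by Newton iteration); the t statistic then uses the
  posterior variance and augmented degrees of freedom. This buys power
  at small sample sizes; at 20+20 samples it behaves almost like Welch.

P-values are BH-adjusted **within each family** — the miRNA matrix and
the mRNA matrix are adjusted separately, and cell-fate gene results are
obtained by restricting the mRNA table after the genome-wide
adjustment (a `readjust_cellfate` switch re-runs BH within the
restricted set instead). The significance gate is two-sided:
`fdr < alpha` **and** `|log2FC| > log2(fc_threshold)` with defaults
`alpha = 0.05`, `fc_threshold = 1.5`, so both over- and under-expressed
features pass.

Degenerate features are kept total: a feature constant and equal
across all samples gets `p = 1` and an `untestable` flag; a feature
with zero within-group variance but different group means is perfectly
separated and gets `p = 0`. Zero group means with a zero pseudocount
raise an error naming the feature.

## Network construction choices

- Back-tracing is unlimited reverse BFS by default (`max_depth` caps
  it when set). The traced network is the vertex-induced subgraph on
  all vertices reaching a sink; cycles upstream of a sink are kept.
- Duplicate edges with conflicting signs: error in strict mode, first
  occurrence kept with a logged conflict count in lenient mode.
- Unknown interaction vocabulary (e.g. "binding"): error in strict
  mode; in lenient mode mapped to +1 as a sign-preserving pass-through
  (configurable to drop instead), with a logged count — dropping can
  disconnect the graph, which is the worse default for a connectivity-
  driven method.
- Self-loops are dropped with a warning: they can never lie on a
  shortest path to a distinct target.
- Node identifiers are opaque, case-sensitive strings; no symbol
  normalisation is attempted.
- The gene universe is **not** restricted to differentially expressed
  genes: expression gates only which miRNAs enter the network, plus
  the cell-fate DE report.
- miRNAs whose DE gate fails are never scored — they are absent from
  the network by construction. Cell-fate genes missing from the edge
  universe are kept as isolated, annotated nodes (they appear in the
  per-gene report with a `no_upstream` flag).

## Ranking and class averages

miRNAs are ranked by `|I_miR|` descending with lexicographic
tie-breaking: magnitude ranking is the only key under which both
strongly over- and strongly under-expressed miRNAs can co-occupy the
top of the list. Per-class average impacts are reported with **two
denominators** — the number of class genes the miRNA actually reaches
(`avg_I_proliferation`, `avg_I_apoptosis`) and the total number of
class genes in the network (`*_all` columns) — since neither
convention is canonical.

## Synthetic benchmark

`mignet simulate` emulates the study inputs at desk scale. Genes are
arranged in `n_layers` layers feeding strictly forward, the final
layer being the cell-fate sinks (default 45 genes, 3 layers, 12 sinks
split 9 proliferation / 3 apoptosis, mirroring the ≈3.5:1 class
imbalance typical of curated cell-fate lists). Each ordered pair of
adjacent-layer genes receives an edge with probability `edge_density`
(default 0.12); every gene is guaranteed one outgoing and one incoming
edge so the cascade is connected. Edges are inhibitory with probability
`inhibition_fraction` (default 0.1 — curated signaling cascades are
strongly activation-dominated, and this keeps a planted driver's net
impact identifiable; see below). A `cyclic` switch adds back-edges.

Expression is log-normal: per-feature baseline `log2` abundance
~ N(8, 1), per-sample noise N(0, `noise_sd`) with default 0.5 on the
log2 scale (a realistic biological-plus-technical spread for 20+20
samples), and planted drivers have their cancer-group mean multiplied
by `2**log2fc`. Background miRNAs can receive bounded uniform shifts
(`background_log2fc_max`) to emulate weak non-driver dysregulation.
All randomness flows from the single integer seed through one
`numpy.random.default_rng` stream; fixed seeds give byte-identical
outputs.

The driver-recovery benchmark (`recovery_benchmark_spec`) plants one
driver at |log2FC| = 3 targeting 30% of first-layer genes against
background miRNAs with true |log2FC| ≤ 0.5, and asks whether the
driver ranks first by `|I_miR|`. Two design points matter here. First,
low edge density keeps shortest paths unique with high probability,
isolating the scoring arithmetic from tie-resolution effects. Second,
sign coherence is an identifiability condition, not a convenience:
when edge signs are heavily mixed, the driver's per-gene impacts carry
nearly independent ±1 signs and their sum concentrates around zero —
the driver then genuinely has no net impact, and no ranking method
could recover it. The default 10% inhibitory fraction corresponds to
the activation-dominated regime where "global impact" is a meaningful
quantity. Mixed-sign behaviour (parity arithmetic, ambiguous-tie
handling) is exercised separately by the sign-policy tests, which set
inhibition as high as 50%.

What the generator does **not** emulate: empirical count distributions
and library-size effects of sequencing data, realistic miRNA target
multiplicity, correlated gene expression along the cascade (unless
`perturb_mrna` is set, mRNA levels are independent of the planted
drivers), or annotation noise in the edge lists. Passing tests
therefore demonstrate correctness of the arithmetic and the stated
statistical properties under the generator's conditions, not
performance on real tumour data.

## Numerical and formatting choices

- Problem sizes in the test suite: oracle-equivalence checks use 200
  random graphs of ≤ 12 nodes (small enough for exhaustive path
  enumeration); null calibration uses 12 seeds × 1000 features at
  20+20 samples; recovery uses 100 seeded runs of the default-size
  benchmark.
- Conservation is asserted to 1e−9; BH agreement with an independent
  step-up implementation to 1e−12.
- Output tables are TSV with floats at 6 significant digits, rows in
  deterministic (sorted) order; rankings are additionally exported as
  JSON. Identical inputs and configuration give byte-identical files.
- Exit codes: 0 success, 2 configuration error, 3 input/IO error,
  4 internal contract violation.

## Limitations

- The shortest-path, linear-decay assumption is a first-order
  approximation of regulatory signal flow; redundant longer paths and
  feedback loops contribute nothing.
- `I_miR` is a *net* quantity: a miRNA with strong but sign-balanced
  downstream effects scores near zero and ranks low, by design.
- All miRNA→target edges are treated as equally strong repressions;
  binding affinity and context specificity are out of scope.
- The moderated-t prior fit assumes a common variance prior across
  features; with very few features (< 2 testable) it degrades to the
  unshrunk statistic.
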