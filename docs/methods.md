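# Methods

## The growth process

One growth step does three things, in a fixed draw order so runs are
bit-reproducible from a seed: (1) resolve β, (2) draw the community /
new-community choice from the step PMF, (3) draw the new node's partners.

**Step PMF.** The default (`community_choice="size"`) assigns probability
`n_i/(n+β)` to each existing community and `β/(n+β)` to founding a new
one.  This is the unique exactly-normalised rule built from the model's
per-community size factors (a Chinese-restaurant-process flavour), and it
yields both limiting behaviours that define the model: at `β = 0` the
new-community probability is identically zero so the community count stays
at `k`, and as `β → ∞` every step founds a community so the count
approaches `n`.  The literal product of all `c+1` factors is logged per
step as `p_inverse` (it may underflow to zero for large `c`; it is a
diagnostic, not an input to sampling).

An alternative reading — that a community's chance of being chosen grows
with its *age rank*, inversely through the partial products of the size
factors — is implemented as `community_choice="age"`: community `i` is
weighted by the inverse of `Π_{j≤i} n_j/(n+β)` and the NEW option by one
further factor `(n+β)/β`, computed in log space and normalised.  This
variant is a reconstruction of an ambiguous verbal rule; it is not the
default and none of the quantitative checks depend on it.

**Attachment.** A founder connects to `min(m, n)` uniformly chosen
existing nodes — all necessarily in other communities.  A joiner draws
each of its `m` partners independently: internal with probability `p`,
external with `1 − p`, without replacement within the step (the graph is
simple).  When a pool runs out of unused partners the link falls back to
the other pool — internal first when the internal pool is preferred,
and symmetrically external links fall back to internal.  Under
`oldest_biased` an internal link goes to the community's oldest *unused*
member with probability `q` (default 0.9), otherwise uniform; for `m = 1`
(the tree regime, where the bias is used) "oldest unused" is simply the
community's founding member.

Consequences used by the tests: the edge count is exactly
`k(k−1)/2 + m(n−k)`; every non-seed node has degree ≥ m and the last-born
node exactly m, so the minimum degree of the regular preset is 3 and of
the tree presets is 1, for every seed.

## Presets (the study conditions)

| preset | k | m | p | n | β policy | extras | Pr index |
|---|---|---|---|---|---|---|---|
| regular_min/mean/max | 3 | 3 | 0.97 | 50 | min/mean/max(n_i) | — | CN |
| tree_basic | 3 | 1 | 1.0 | 50 | min(n_i) | — | HEI |
| sars_like | 3 | 1 | 1.0 | 59 | min(n_i) | oldest_biased q=0.9 | HEI |
| karate_like | 3 | 2 | 0.9 | 34 | min(n_i) | — | CN |

Dynamic β policies are re-resolved every step on the *pre-step* community
sizes.  The `sars_like` preset emulates a coronavirus haplotype
evolutionary network (59 nodes, 59 links, five groups whose root haplotype
is the group hub); the oldest-member bias encodes the observation that
each group's root collects the evolutionary links.  What the generator
does **not** emulate: real haplotype networks have mutation-distance
semantics on edges, occasional between-group nodes, and a designated
medium-vector node — so tests passing on the preset show the model
reproduces the network's *shape statistics* (N_c, degree extremes, tree
depth, modularity scale), not its biology.

Model-grown networks are always scored on their own birth labels;
Girvan–Newman detection is reserved for unlabelled real networks.  Two
table statistics are intrinsically single-run stochastic quantities, so
published rows are checked as lying inside the preset's 5–95% ensemble
band, never as point targets.

## Measurement stack

**Modularity** is the unweighted Newman–Girvan `Q = Σ_i (e_ii − a_i²)`,
delegated to networkx with `weight=None`.  (The public karate-club object
in networkx carries Zachary's original interaction weights; modularity
here is deliberately unweighted, which is what reproduces the classic GN
optimum `Q ≈ 0.4013` on that graph.)

**Girvan–Newman** removes the highest-edge-betweenness edge, recomputing
betweenness after every removal, and returns the partition of maximum Q
over the whole removal sequence including the initial connected
components.  Tie-breaks are deterministic: among edges within a 1e−9
relative band of the top betweenness, the lexicographically smallest
sorted node pair is removed; among equal-Q cuts the earliest (fewest
communities) wins.

**Tree depth** `L_max` is the maximum over communities of the root's
eccentricity in the community's induced subgraph, root = oldest member;
a non-tree induced subgraph raises an error rather than silently
reporting a number.

**Link prediction.** CN, LHN1 and HDI are the standard common-neighbour
family; degree-zero denominators score 0.  HEI, the hub-enhanced index
for tree-like networks, is implemented as `max(k_x, k_y)` — in a tree a
missing link is overwhelmingly more likely to involve a branch root than
two leaves.  Its exact published form was not available, so the scorer is
swappable: any callable `(adjacency, degrees, u_idx, v_idx) → scores` can
be passed wherever an index name is accepted, and HEI-based
predictability values are treated as order-of-magnitude quantities only.

**AUC** follows the sampling convention: `n_auc_samples` comparisons of a
uniformly drawn held-out edge against a uniformly drawn non-edge of the
full graph, scores computed on the training graph, ties counting one
half.  Default 10 000 samples gives a sampling s.e. ≤ 0.005.

**Predictability protocol.** The split protocol is this package's own
(the quantity's definition fixes none): hold out 10% of links
(`test_fraction`, at least one link), 20 repetitions, fresh non-edge
sampling per repetition.  Per repetition the all-links AUC and every
community's internal-links AUC are computed with the same machinery, then
averaged over repetitions before forming
`S_pr = mean_i (S_in_i − S_all)/S_all`.  The summation runs over the `N`
communities with at least `ceil(1/test_fraction)` internal links —
`S_pr` is a community mean, not a node mean — and skipped communities are
reported.  Scaled-down protocol sizes (fewer repetitions / AUC samples)
are used inside the test suite where only ensemble means matter; scaling
affects variance, not bias.

## Fitting N_c(β)

`N_c = n·β/((k+γ)+β)` is the unique one-free-parameter reading of the
community-count relation with the correct limits (0 at β=0 — growth-born
communities only — and n as β→∞).  γ is fitted by bounded scalar least
squares on `(−k+10⁻⁶, 10⁴]` against sweep means; the default sweep grid
is log-spaced over `[10⁻², 10³]` with 50 replicates per point.  A sweep
whose means are all equal triggers a degeneracy warning (γ is then
unidentifiable).  The fit is judged by beating the best constant fit in
RSS and by recovering a known γ from synthetic hyperbola data (±0.5 at
noise σ=0.5); no closed form for E[N_c] is attempted.

## Numerical and design choices

- One RNG stream per run (`numpy.random.default_rng(seed)`); the
  categorical step draw uses a single uniform variate against the CDF.
- β=10⁶ is large but finite: the per-step probability of *not* founding a
  community is `n/(n+β) > 0`, so over many replicates a rare run ends
  with `N_c = n − 1`.  This is a property of the model, not a numerical
  artefact; "all steps found communities" holds only in the β→∞ limit.
- Node ids are 0-based in birth order; community labels 1-based in birth
  order.  GraphML round trips preserve both (`community`, `birth`).
- Problem sizes in the test suite (50-node networks, 50–60-seed
  ensembles, 10⁵-run Monte Carlo against the exhaustive trajectory
  oracle at n=6) were chosen as the smallest ensembles at which the
  checked means are stable to within their quoted tolerances.
- Node-deletion "acceleration" (pruning nodes that only link externally)
  is not implemented; the phenomenon is itself a natural feature of the
  data the model emulates.

## Known limitations

- The `age` community-choice variant is a documented reconstruction of an
  ambiguous rule; no quantitative claim is made for it.
- HEI is a stand-in definition (above); predictability values for
  tree-like networks depend on it and should be compared across runs of
  this package only.
- Real-network predictability (e.g. the karate club) depends on the
  detected partition and the split protocol; values are
  order-of-magnitude comparable, not exact.
- The BA baseline is a plain preferential-attachment generator for
  comparison runs only.
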