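# Methods

`popnet` builds a multilayer *social opportunity network* from
register-style person-year panels and characterizes its structure. An
opportunity network records formal ties that offer occasions for
interaction — kinship, co-residence, shared school cohort, shared
property, shared workplace — not observed interactions. Because real
administrative microdata of this kind are access-restricted, the package
ships a synthetic register generator that reproduces the structural
features the construction depends on; every downstream step is identical
whether the panel is synthetic or real.

## Network model

The population in the analysis year (default 2017) forms the vertex set
V. Ties live in six layers L = {C, E, H, S, N, W}: close family,
extended family, household, school, neighbors, work. The network is
undirected and single-aspect, with intra-layer edges only — no coupling
edges between a vertex's replicas in different layers. We write
A[u, v, l] ∈ {0, 1} for adjacency of u and v in layer l
(A[u, v, l] = A[v, u, l], A[u, u, l] = 0).

Three degree notions coexist:

- per-layer degree k<sub>u,l</sub> = Σ<sub>v</sub> A[u, v, l];
- total degree k<sub>u</sub> = Σ<sub>l</sub> k<sub>u,l</sub> — a dyad
  present in two layers counts twice;
- unique neighbors k′<sub>u</sub> = |{v : Σ<sub>l</sub> A[u, v, l] > 0}|,
  the degree in the *flattened* (monoplex) aggregation.

## Layer construction

**Close family (C).** The register exposes family membership, not named
kin relations, so relations are inferred from age gaps among persons who
shared a family identifier in *any* panel year (aggregating the full
2000–2017 window — a single year would leave most adults unlinked,
because children leave the parental household young). Per family, with
members sorted oldest first: the two oldest members with age gap below
`parent_gap_min` (default 15 y, the register's age floor — it prevents
parent/partner confusion) are partners; a pair sharing at least one
within-family parent are siblings regardless of their own gap; otherwise
a gap ≥ `parent_gap_min` is a parent/child tie and a gap <
`sibling_gap_max` (default 15 y) a sibling tie. Edges are then restricted
to persons present in the analysis year. Persons who never carry a
family identifier (immigrants arriving without family) get no C edges.
Three-generation co-residence is the known failure mode: a grandparent
co-resident with a grandchild is classified parent/child, since age gaps
cannot distinguish the two.

**Extended family (E).** Pure composition over C: grandparent =
parent∘parent; uncle/aunt = sibling-of-parent and
partner-of-sibling-of-parent (aunt/uncle by marriage); cousin =
child-of-sibling-of-parent. No deeper kinship is composed, and an E edge
is dropped if the dyad already exists in C. Because composition needs
two generations of co-residence inside the panel window, E is sparse by
construction — this scarcity is a property of the data situation, not a
bug, and it is what makes the neighbor layer decisive for global
connectivity (below).

**Household (H).** Clique among persons sharing a household identifier
in the analysis year. The register links households only through family
relatives, so non-relative co-habitation (roommates, dormitories) is
absent by construction and H is nearly nested in C.

**School (S).** Groups share (education level, municipality, graduation
year); groups above 1,000 members (university scale) are re-split by
field of study; groups still above 10,000 emit no edges (too little
information to infer plausible opportunity ties). Graduation year is the
latest passed course, so current students of one programme share it.

**Neighbors (N).** Groups share a property identifier. Rural properties
hold a handful of residents and become cliques; urban apartment blocks
hold hundreds and are sampled.

**Work (W).** Groups share the analysis-year main employer; companies
with at least 200 employees are subdivided into workplaces.

**Affiliation edge sampling.** Groups up to `full_connect_max` members
(default 30 — school-class scale) become cliques. Larger groups get
sampled edges: each member draws a Poisson target degree around
`expected_degree(group size)`, and edges are realized by stub matching
with rejection of self-loops and duplicate dyads (up to 12 re-shuffle
rounds; leftover stubs are discarded). Stub matching rather than
per-dyad Bernoulli sampling honors individual degree targets. The
expected degree is a power law a·s^b up to a break s₀ and linear above
it, joined with continuous value and slope; defaults a = 1, b = 0.55,
s₀ = 200 put the mean degree of few-hundred-member groups near 20 (the
modal school/work degree such constructions report) and ten-thousand-
member workplaces near 500, while keeping large groups sparse enough
(density ≲ 0.06) for stub matching to hit its target within a few
percent. All constants are configurable; they parameterize a fit whose
original data are not public, so they are calibrated qualitatively, not
estimates of it.

## Measures

**Flattening.** The monoplex graph E′ with an edge wherever any layer
has one; k′ is its degree.

**Layer comparison.** Degree correlation: Pearson r of (k<sub>u,l₁</sub>,
k<sub>u,l₂</sub>) over *all* vertices, zeros included (no exclusion rule
needs extra parameters); zero-variance layers yield missing entries.
Edge overlap: entry (l₁, l₂) = |E<sub>l₁</sub> ∩ E<sub>l₂</sub>| /
|E<sub>l₁</sub>| over unordered dyads — row-normalized, so a layer
nested in another shows 1.0 in its own row.

**Tail slope.** Negated OLS slope of log₁₀ CCDF vs log₁₀ degree, fitted
over the top decile of observations (CCDF ≤ 0.1) excluding the
ultra-sparse extreme (CCDF < 10⁻⁴), where single-count order statistics
would dominate the fit. This is the graphical estimator matching a
plotted CCDF, not a maximum-likelihood power-law fit; the window bounds
are parameters. On an exact Pareto CCDF it recovers the exponent to
numerical precision; on Zipf(α) samples it recovers the CCDF exponent
α − 1.

**Components and distances.** Path existence is evaluated on the
flattened union of the chosen layers. Zero-degree persons are part of V
(they are residents) and count as singleton components; the
giant-component share is relative to |V|. Both conventions make the
accumulation report provably monotone: adding a layer can only merge
components and grow the giant component. The report's `vertices` column
gives the non-isolated count per combination, which is what varies
between combinations. The giant component's diameter is exact, by an
eccentricity-bounding search: each BFS from a candidate vertex v yields
ecc(v) and bounds every other vertex's eccentricity within
[max(ecc(v) − d, d), ecc(v) + d]; vertices whose upper bound cannot
exceed the current best are pruned, candidates alternate between
peripheral (max upper bound) and central (min lower bound), and the
search terminates with a certified value and a witness pair. The mean
shortest path is estimated from BFS out of a seeded uniform sample of
giant-component sources (default 1,000; per-source means give a standard
error); whether to sample sources or pairs is an open choice — sources
are used because each BFS prices all pairs from that source.

**Closeness.** closeness(u) = (|V| − 1) / Σ<sub>v</sub> d(u, v), with
distances computed inside the giant component for a seeded uniform
sample of it. The numerator deliberately keeps the full |V| − 1 (the
printed definition) even though unreachable vertices are excluded from
the sum; users comparing across networks should know both conventions
exist.

**Embeddedness and tie range.** Embeddedness of an edge counts common
neighbors with layer multiplicity on both sides:
Σ<sub>l₁,l₂</sub> Σ<sub>w</sub> A[u, w, l₁]·A[v, w, l₂] — computed for
all edges at once as (S²)<sub>uv</sub> with S the layer-multiplicity
matrix. For zero-embeddedness edges whose endpoints both have k′ > 1,
the tie range is the flattened shortest path after deleting the edge in
every layer, found by bidirectional BFS; it is ≥ 3 by definition
(embeddedness zero excludes a length-2 detour). The search is capped at
`max_depth` (default 15) — beyond that an edge reports "unreachable",
which also covers true bridges whose removal disconnects their
endpoints. A *wormhole* is an edge with finite tie range ≥ 6;
unreachable edges are not wormholes (a bridge into an otherwise
disconnected cluster spans no measurable distance). At scale the census
can be restricted to a seeded sample of qualifying edges.

**Triangles and excess closure.** Per vertex, T_unique counts distinct
flattened triangles and T_pure those whose three edges co-exist within
at least one single layer. Both use *distinct vertex-triple* semantics:
a triangle pure in two layers counts once. This guarantees
T_pure ≤ T_unique and keeps excess closure in [0, 1]; the literal
ordered-layer-triple reading (retained behind
`semantics="multiplicity"` for sensitivity checks) can push the
numerator of excess closure negative and is not used. T_pure is
computed by inclusion–exclusion over layer subsets (triangles of the
elementwise intersection graphs), pruning empty intersections. With the
alter-tie-pair count P<sub>u</sub> = C(k<sub>u</sub>, 2) −
Σ<sub>v</sub> C(m<sub>uv</sub>, 2) (m<sub>uv</sub> = layer multiplicity
of the tie), excess closure is

    c_excess(u) = (T_unique − T_pure) / (P_u − T_pure),

defined when P<sub>u</sub> > T_pure, and measures how much of the
non-redundant closure around u comes from combining social contexts
rather than from any single one. Local clustering uses the flattened
graph and k′; vertices with k′ < 2 report 0 with an undefined flag.

**Profiles.** Per (band, age) cells of mean total degree, mean excess
closure (over vertices where defined) and mean sampled closeness (over
the closeness sample, with standard errors), stratified by income,
education or urbanization bands. Ages are unsmoothed single years; cells
under a disclosure floor (default 10) are suppressed — a register-data
hygiene habit, harmless on synthetic data. Band definitions are
configuration, not claims about any statistical agency's banding.

## Synthetic register generator

The generator emulates the structure of a Nordic person-year register
(2000–2017, persons 15+), driven by a single seed; identical
configurations produce byte-identical panels.

What it reproduces, and why it matters downstream:

- **Final-year households** drawn from a household-size pmf (defaults
  put ≈ 40% of households at size one, the Swedish order of magnitude);
  sizes count only persons 15+. Singles produce the zero-degree mass in
  H; at-home children produce parent/child and sibling ties.
- **Move-out dynamics**: each adult householder is, with probability
  `lineage_link_prob` (default 0.7), the child of an older couple
  generated in the same run, with a move-out age drawn on 18–28. The
  person carries the parents' family identifier in panel years before
  moving out — so a cross-generation C tie exists only if the panel
  window overlaps those years. This is precisely the mechanism that
  starves the extended-family layer: E ties need two such overlaps.
- **Immigrants without family** (default 8%): no family or household
  identifier in any year, hence degree zero in C, E and H, connected
  only through S, N, W.
- **Properties** as a four-component mixture (rural 1–2 households,
  town, urban block, large complex of 60–180 households), giving the
  multi-modal neighbor-degree distribution (rural cliques of 2–4 vs
  sampled ≈ 20-degree urban blocks) and the urbanization attribute.
- **Education** with an age-capped level, graduation year tied to birth
  year (masked in rows before graduation), and field of study at
  university levels — making school groups cohort-by-municipality cells
  of realistic size and splittable by field.
- **Employment** for ages 19–67 at rate 0.85 into firms drawn from a
  heavy-tailed size pmf; higher income bands choose larger firms
  preferentially (weight ∝ size^(0.35·(band−3))), which produces the
  income gradient in degree that the stratified profiles detect. Firms
  with ≥ 200 realized employees split into ≈ 150-person workplaces.
- **Income** as quintile bands of an education-plus-age-hump score.

What it does *not* emulate: mortality and migration (everyone present in
the final year), re-partnering, non-relative co-habitation, geographic
distance between properties, heavy-tailed total-degree distributions
(the synthetic total degree is a sum of near-Poisson layer degrees, so
its CCDF falls much faster than a real register's — tail-slope estimates
on synthetic runs are correspondingly steep), and any calibration to
literal national marginals. Consequently, passing tests demonstrate the
correctness and internal consistency of the construction and measures —
not that synthetic structural constants (component counts, closure
levels) equal those of any real population.

## Problem sizes and determinism

Default analysis runs use 20,000 persons; the test suite exercises the
pipeline at 10,000 (byte-identical re-run check), monotone layer
accumulation at 100,000, and the oracle-equivalence battery at n ≤ 50
over 100 seeds; `scripts/acceptance.py` uses 30,000. These sizes keep a
laptop-scale run in minutes while leaving every qualitative behavior
(fragmented family layers, neighbor-driven giant component, small-world
distances) intact. All stochastic stages — generator, per-layer
affiliation sampling, path-length sources, closeness sample, tie-range
census sample — draw from independent streams spawned from one seed, and
all tables are written with fixed float formatting, so a re-run with the
same seed is byte-identical.

## Known limitations

- Age-gap kinship cannot separate grandparents from parents in
  three-generation households, nor partners from same-age siblings in
  two-adult families (the two-oldest rule claims the pair as partners).
- The expected-degree constants are qualitative stand-ins for a fit
  whose source data are not public.
- Tie ranges beyond the depth cap are indistinguishable from
  disconnection ("unreachable"), slightly undercounting extremely long
  wormholes.
- Closeness and mean-path values are sampled estimates; their standard
  errors are reported and should be propagated by downstream users.
- The Pearson layer-degree correlations on heavily zero-inflated layers
  (E especially) are dominated by the zero mass; this matches the
  printed definition but limits interpretability.
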