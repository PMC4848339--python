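# Methods

## The dominance order and its diagram

A procedure table is an N × R matrix **Q** with entry *y*<sub>ir</sub> the
value of variable *r* for procedure *i*. Ranking is always relative to an
*information basis* (IB) — a chosen subset of variables. Before ordering,
every variable is oriented so that **lower = better**:

| orientation | transform | used for |
|---|---|---|
| `low_is_good` | identity | LOD, precision (RSD), solvent, waste, time, sample mass |
| `high_is_good` | `scale_max − value` (fixed anchor 4 for NEMI, 100 for Eco-Scale; column max otherwise) | bounded greenness scores, other-analytes count |
| `target_100` | `\|100 − value\|` | recovery (over-recovery is as imperfect as under-recovery) |

Any strictly order-reversing transform yields the same poset; the anchors
only matter for audit output, which is why each run records a per-variable
orientation audit.

Procedure *s* precedes *t* (s ≤ t, "s is at least as green/good") iff
*y*<sub>r</sub>(s) ≤ *y*<sub>r</sub>(t) for **every** r in the IB. Rows equal
on all IB variables are merged into equivalence classes (the order is built
on class representatives; every report expands members). The Hasse diagram
is the transitive reduction of the strict order — computed with networkx —
and the structural descriptors follow the standard definitions: maximal /
minimal objects have no cover above / below; *isolated* objects are both,
i.e. comparable to nothing; levels are assigned bottom-up by longest-chain
layering (level 1 = minimal = best, so "worse" procedures sit near the top);
height = longest chain; width = largest antichain, computed **exactly** via
Dilworth's duality (minimum chain cover = N − maximum bipartite matching,
Hopcroft–Karp). Exactness is feasible throughout the intended N ≲ 100 range.

A design point worth flagging: a lone equivalence class containing the whole
table, or any pure antichain, makes every object isolated. Level summaries
therefore report the isolated group separately and leave the per-level means
to the non-isolated objects; degenerate inputs end up entirely in the
isolated group rather than producing a fake "level mean".

## Averaged ranks over linear extensions

For a poset on N objects the averaged rank of x is its mean position over
all linear extensions. Exact computation uses two dynamic programs over the
lattice of order ideals (down-sets), with ideals encoded as bitmasks:
f(S) counts extensions of the sub-poset induced by ideal S, h(S) counts
extensions of its complement filter. x occupies position |S|+1 in
f(S)·h(S ∪ {x}) extensions for every ideal S to which x is addable, giving
the rank as an f·h-weighted mean. The ideal lattice has at most 2^N
elements (antichain worst case), so the exact path is limited to
N ≤ 20 by default (`exact_threshold`); the published guidance that exact
average ranks are feasible below ~25 objects is consistent with this, and
20 keeps the worst-case lattice small in memory.

Above the threshold ranks are estimated with the Bubley–Dyer chain: the
state is a linear extension; each step draws a position p uniformly from
1..N−1 and, with probability 1/2 (the lazy coin that makes the chain
provably convergent to the uniform distribution on extensions), swaps the
elements at p and p+1 when they are incomparable. Defaults: burn-in N³
steps, thinning N steps, 10,000 recorded samples — all overridable, and a
seed is **required** (no implicit randomness; identical seed + input +
parameters give identical output). With N = 7 and 10⁵ samples the maximum
rank error against the exact values is typically a few hundredths; because
thinned samples remain autocorrelated at small thinning, occasional
deviations slightly above 0.05 are within expectation.

Ties: equivalence classes enter the ranking as single objects and members
inherit the representative's averaged rank; the permutation identity
Σ ranks = N(N+1)/2 is stated over representatives.

## Greenness scoring

NEMI's four criteria are total functions of a procedure inventory: the PBT
and K/F/P/U fields are green iff no used chemical carries the respective
list flag (list membership is caller-supplied — regulatory lists change, so
none is hard-coded); the corrosivity field reads "pH within 2–12" as the
closed interval; the waste field is a strict inequality (< 50 g). The score
is the number of green fields.

The Eco-Scale is 100 minus the sum of penalty points and is deliberately
not clamped at zero. Penalty points are first-class inputs; the shipped
default penalty table (JSON package data) is adapted from the cited
Eco-Scale reference and clearly labelled as such — it is configuration, not
a result of this package.

Hazard-weighted solvent use multiplies each solvent amount (mL) by 0 / 1 / 2
for no pictogram / warning / danger and sums.

## The assessment pipeline

`HasseRanking.fit` composes completeness filtering → orientation → order
construction → transitive reduction → descriptors → averaged ranks, with
every stage's errors labelled by stage name and full provenance (variable
set, orientation audit, dropped ids) kept on the result. The default
environmental IB is {sample mass, other analytes, solvent volume,
hazard-weighted solvent, solid waste, time}; NEMI and Eco-Scale can be
toggled in (`include_scores=True`) — they are composite assessments of the
same physical quantities, so the default keeps them out and uses them as
external validation scores instead. The metrological IB is {LOD, precision,
recovery}. The orientation of the other-analytes count is genuinely
arguable (a multianalyte run amortises its footprint); the default treats
more analytes as better, and the schema makes it a one-line override.

The bivariate report inner-joins the environmental ("greenness") and
metrological ("performance") averaged ranks and flags the Pareto front
(rows no other row beats on both axes). The front is a made explicit
version of the "lower-left corner" reading of a bivariate rank plot; raw
ranks are always emitted so users can apply their own cutoffs.

The PCA overview standardises columns to zero mean / unit variance and
decomposes by SVD, returning correlation loadings (L·Lᵀ reproduces the
correlation matrix) — constant columns are rejected by name.

## Synthetic data

`generate_correlated_table` is a Gaussian copula: latent normals with a
block-diagonal correlation matrix, mapped through realistic marginals
(lognormal amounts/times/waste, a binomial 0–4 greenness count, a scaled
beta for the 0–100 score, truncated normal recovery on [60, 110]). The
default blocks mirror the variable groupings observed in the survey data:
{NEMI, Eco-Scale, −sample mass} at |ρ| = 0.8 (scores high exactly when
sample demand is low), {solvent, hazard-weighted solvent} at 0.9, and
{time, solid waste, other analytes} at 0.7. Block targets are **Spearman**
correlations — monotone marginal transforms preserve rank correlation but
not Pearson — implemented by the latent adjustment
ρ_latent = 2·sin(π·ρ_S/6). Discretising NEMI to five values attenuates its
observed rank correlations by a few hundredths, which the ±0.1 recovery
checks absorb. Marginal defaults are loosely calibrated to the survey's
units (grams of sample, tens of mL of solvent, hours of analysis);
they are illustrative, not fitted to any published matrix — so passing
tests demonstrate correctness of the machinery on data with the assumed
correlation structure, not agreement with any particular laboratory
dataset.

`plant_poset_table` embeds a known poset as coordinates: each variable is a
linear extension of the poset, the value of an object being its position.
The extensions are a realizer built greedily — start from one topological
order, repeatedly add an extension (reverse-priority topological sort,
forcing one still-agreed incomparable pair to flip) until the intersection
of the pairwise agreements equals the planted order, then pad with random
extensions up to `n_variables`. At zero noise the rebuilt dominance order
is therefore exactly the planted order; Gaussian noise (`noise_sd`, in
units of one rank step) degrades recovery smoothly, which the tests
quantify as cover-edge precision/recall. The greedy realizer may use more
orders than the poset's true order dimension (e.g. 4 instead of 3 for the
standard 3+3 example); if it exceeds `n_variables` the embedding is refused
with an explanation rather than silently distorting the order.

## Numerical and testing choices

Problem sizes in the test and acceptance runs are chosen so every oracle is
brute-force-exact: permutation enumeration up to N = 7, exhaustive
antichain search at N = 9, Warshall closure at N ≤ 8, fifty random posets
for reduction checks, three 7-object posets at 10⁵ samples for the sampler.
The whole suite runs in a few seconds on one CPU.

Known limitations: no rank-probability matrices or cumulative-rank
approximations (averaged ranks only); no crossing minimisation in diagram
layout; the bundled survey table carries only the two greenness scores —
the full environmental/metrological matrix of that survey was published as
supplementary material and is not redistributed here, so its
figure-specific results (exact level memberships and extremal identities)
are exercised on synthetic tables instead.
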