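# Methods

## Descriptors

All descriptors live on finite, simple, undirected graphs. Distance-based
quantities (ε, W, ξᶜ, δ_en and the three ENM indices) require connectivity;
disconnected input always raises an error rather than propagating
infinities. Values are exact integers — no floating point enters the
descriptor modules.

The eccentricity neighborhood degree δ_en(v) = Σ_{u∈N(v)} ε(u) sits between
the purely local degree and the purely global eccentricity: it is the
degree of v reweighted by how peripheral its neighbors are. Immediate
consequences used as test invariants:

- Σ_v δ_en(v) = ξᶜ(G) (each vertex contributes ε(v) once per neighbor);
- d(v)·r(G) ≤ δ_en(v) ≤ d(v)·D(G), hence the sandwich bounds
  r²M1 ≤ ENM1 ≤ D²M1, r²M2 ≤ ENM2 ≤ D²M2, r·M1 ≤ ENM3 ≤ D·M1, with
  equality exactly on complete graphs (D = 1);
- ENM3's edge-sum and vertex-sum forms coincide;
- on self-centered graphs (ε ≡ c): δ_en = c·d, so ENM1 = c²M1 etc.

### Degenerate conventions

K1: ε = 0, δ_en = 0, every index 0. K2: both vertices have ε = 1 and
δ_en = 1. A *universal* vertex is one adjacent to all others (equivalently
ε = 1 when n ≥ 2); K1's vertex is not counted as universal by
`universal_vertices` (its ε is 0), but it does act universally inside a
join — the join code handles that case separately (K1 + C₄ is the 5-wheel
with hub eccentricity 1).

### Computation

Eccentricities come from one BFS per vertex (networkx); the Wiener index is
accumulated per BFS source, so no n×n distance matrix is ever materialized
and memory stays O(n + m). The test suite re-derives every descriptor from
a scipy Floyd–Warshall distance matrix with direct double loops as an
independent oracle.

## Closed forms for families

Each formula is an integer polynomial in the family parameters, checked
against direct computation over a sweep (paths/cycles n = 3..30, stars
r = 1..20, double stars r,s = 1..10, wheels n = 5..20, complete bipartite
r,s = 1..10, bananas r = 2..6, s = 3..8). Conventions that matter:

- the wheel W_n has **n total vertices** (hub + (n−1)-cycle) — forced by
  matching the wheel polynomial 4n²+17n−21 against direct computation
  (hub δ_en = 2(n−1), rim δ_en = 5);
- the s-star inside the banana tree B_{r,s} has **s vertices** (center +
  s−1 leaves, one of which is the connector to the root), giving s−2
  pendants per copy and rs+1 vertices total;
- the double star S_{r,s} is two adjacent centers with r and s pendant
  leaves (r+s+2 vertices); its ENM1 closed form is read as
  9(r²+s²)+16(r+s)+8 (checked: S₁,₁ = P₄ gives 58);
- validity edges: the star formulas assume the center/leaf eccentricity
  split and fail for S₁ = K2; the complete-bipartite formulas
  (4(rs²+sr²), 4r²s², 2(rs²+sr²)) assume no universal vertex and fail for
  min(r,s) = 1; the path ENM2 polynomials hold only for even n ≥ 6 /
  odd n ≥ 5. In all of these cases `family_closed_form` computes directly
  and flags the affected indices in `fallback` instead of guessing — the
  odd-cycle formulas, by contrast, are exact already at n = 3 and are
  applied there.

## Graph products

For the join G+H, disjunction G∨H, composition G[H] and symmetric
difference G⊕H, the package computes product eccentricities, δ_en profiles
and the ENM indices **from factor data only**: factor degrees and vertex
counts, the universal-vertex counts r = |Vω(G)|, s = |Vω(H)|, and edge
partitions by endpoint universality. The direct route (BFS on the
constructed product) exists solely as the independent check; the test
suite runs both on 100+ seeded random factor pairs (n = 2..7, mixing
sparse/dense ER graphs, trees, stars and complete graphs) per operation.

Key structural facts used: in a join a vertex keeps ε = 1 iff it was
universal in its factor, else ε = 2; in a disjunction ε(u,v) = 1 iff both
coordinates are universal, else 2; the symmetric difference is always
self-centered with ε ≡ 2; the composition inherits ε(u,v) = ε_G(u)
whenever ε_G(u) ≥ 2. Every vertex of a product is adjacent to all ε = 1
vertices, so δ_en = 2d − (#ε=1 vertices) + [ε(v)=1], which is what the
per-case formulas implement.

Two cases need care:

- **Join ENM1.** The expanded join expression contains a factor that must
  read (|V(G)| − r) for the worked example ENM1(P₂+P₄) = 266 to come out
  (and for consistency with the derivation); the implementation uses that
  reading. Join ENM2 is evaluated term-by-term over the ten edge classes
  using each endpoint's δ_en linear form; join ENM3 uses the expanded
  expression.
- **Composition with Vω(G) = ∅.** Product eccentricities then exceed 2 and
  no closed ENM expression covers the case: `product_enm_closed` raises
  `NoClosedFormError`. The δ_en profile is still available from factor
  data via δ_en(u,v) = |V(H)|·δ_en_G(u) + ε_G(u)·d_H(v), derived from the
  eccentricity inheritance above and verified against brute force in the
  sweep.

The join accepts disconnected (even edgeless) factors, since only
adjacency-level universality enters the formulas; this is how complete
bipartite graphs arise as joins of edgeless graphs. The other products
require connected factors with at least two vertices each.

## The amine study

The 21 primary amines are shipped as plain-text heavy-atom edge lists
(all trees, ≤ 12 vertices) with experimental boiling points (°C) and the
published five-descriptor table stored **verbatim, typos included**. Six
published cells disagree with direct recomputation from the structures
(one ENM1, one ENM2, four Wiener cells); `discrepancy_report` recomputes
all 105 cells and flags exactly those. Three structure pairs in the set
are isomorphic as graphs (2-aminobutane/2-methylpropylamine,
2-aminopentane/3-methylbutylamine, 3-aminopentane/2-methylbutylamine) and
necessarily share descriptor rows, which is one source of the Wiener
inconsistencies. Atom identity (C vs N) never enters a descriptor and is
not stored.

## Regression model

"Boiling point vs descriptor" is modeled as the power law
BP = e^a · X^b, fitted as ordinary least squares of ln(BP) on ln(X)
(natural logs; statsmodels OLS). With n = 21 compounds the fit has 19
residual degrees of freedom, and F = R²/(1−R²)·19 holds as an identity.
Defaults follow the study being reproduced: descriptor columns are taken
from the published table (the numbers the published statistics derive
from), and predicted-boiling-point tables use the published rounded
equations (e.g. ln(BP) = 2.14 + 0.441·ln(ENM1), which yields the published
50.94 °C for n-propylamine, where the unrounded fit does not). Both
defaults can be switched — `use_printed_table1=False` regresses on
recomputed descriptors, `equations="fitted"` predicts from unrounded
coefficients — as sensitivity modes that are deliberately not pinned to
published numbers.

The synthetic-recovery test draws ln-scale noise σ = 0.05 around
a = 2.4, b = 0.4 at n = 21 (matching the study's size and roughly its
residual scale) and requires the OLS estimates to land within three
standard errors — a calibration check on the machinery, not on real data.

## Random-graph fixtures

Property suites draw from seeded, bit-reproducible generators: uniform
random labeled trees and connected Erdős–Rényi graphs by rejection
(retry-capped). The pools mix densities so that both empty and non-empty
universal-vertex sets occur, since every product formula branches on them.
These fixtures exercise the *mathematical* claims on arbitrary small
graphs; they do not emulate chemical structure (valence bounds, planarity,
ring statistics), so passing sweeps validates the identities and closed
forms, not chemical representativeness. Problem sizes — factors n ≤ 7,
identity pools n ≤ 12, 100–200 graphs per suite — were chosen so the full
suite completes in a few seconds while still crossing every case branch.

## Known limitations

- No weighted, directed or multigraph support; no SMILES/name parsing —
  molecular graphs enter as edge lists.
- Closed forms exist only for the families and product cases listed;
  everything else is direct computation.
- The composition closed-form gap (Vω(G) = ∅) is inherent to the case
  analysis, not an implementation limit.
- Published-table reproduction is exact only for the cells that are
  internally consistent; the six flagged cells are reported, not
  reconciled.
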