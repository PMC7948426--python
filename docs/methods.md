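# Methods

This note records the models and numerical choices behind each stage, the
assumptions they make, and what the synthetic fixtures do and do not
establish about real data.

## Buried ionizable residue detection

**Model.** A residue can titrate in the physiological range only if its
charged group is sequestered from solvent, so the unit of analysis is the
charged-group *reference point*: CG for Asp, CD for Glu, NZ for Lys, CZ for
Arg, and the midpoint of ND1/NE2 for His. When the named atom is missing the
side-chain centroid is used, then Cβ; residues reduced to backbone atoms are
rejected rather than guessed. The choice of the charged-group atom (rather
than, say, the Cβ or residue centroid) matters because it is the titratable
moiety's burial that shifts the pKₐ.

**Network.** Reference points are triangulated with a 3-D Delaunay
tetrahedralization (scipy/Qhull); the edge set of the tetrahedra is the raw
network. Fewer than five points, or degenerate (coplanar/collinear)
configurations where a tetrahedralization is undefined, fall back to the
complete graph — trimming is still meaningful there. Coincident points are
jittered by 1e-4 Å with a fixed seed so the triangulation is reproducible.

**Minimization** removes, repeatedly, the longest remaining edge whose two
endpoints stay connected through a path of strictly shorter edges, until no
edge qualifies. "Strictly shorter" is shorter by more than 1e-9 Å, so
numerically tied lengths (an equilateral triangle) never justify removal;
candidate ties break lexicographically by node key. This keeps local
contacts and discards long shortcuts that duplicate a chain of short ones.
**Trimming** then removes edges longer than 10 Å; an edge of exactly 10 Å
does not exceed the cutoff and is kept.

**Surface.** The Cα atoms are tetrahedralized and tetrahedra with any edge
longer than `alpha_edge` (default 9 Å, configurable) are discarded; the
boundary facets of the surviving solid form the mesh. An alpha shape rather
than a convex hull so that grooves and pockets are wrapped, not bridged. If
the chosen alpha opens or fragments the solid, `alpha_edge` is raised in
0.5 Å steps until the largest boundary component is closed (every edge
shared by exactly two facets). Facet normals are oriented away from the
owning tetrahedron, which makes them outward for a boundary of a solid.

**Depth** is the canonical signed distance to the closed mesh: the
magnitude is the distance to the closest point on any facet (ties broken by
facet index); the sign comes from the outward normals of the closest facet
*and its edge-adjacent neighbors*, which vote on which side the query point
lies — a single facet's normal is ambiguous when the closest point falls on
a shared edge or vertex. Points on the surface have depth exactly 0;
negative is inside. An alternative reading — averaging signed
point-to-plane distances over the closest facet and its neighbors — was
rejected because it does not vanish on the surface itself (a cube corner is
5 Å off the plane of an opposite-edge neighbor facet), which breaks the
basic invariant that surface atoms have zero depth.

**Classification**: core at depth ≤ −3.0 Å, exposed above +1.05 Å, margin
between (inclusive of +1.05). The buried subnetwork keeps every core node
plus any margin/exposed node sharing a trimmed-network edge with a core
node, with the induced edges.

Assumptions worth noting: the surface sees only Cα atoms, so side-chain
packing density does not influence burial; depth is purely geometric — no
electrostatics, hydrogen placement or conformational sampling — and the
alpha parameter trades pocket resolution against surface closure.

## Consensus network analysis

Pooled points from superposed structures are connected at a distance cutoff
(1.5 Å for residue nodes, 2.0 Å for Na⁺) and connected components with at
least 5 members are clusters, sorted by decreasing size then centroid.
Connectivity is computed from the Delaunay graph trimmed at the cutoff and
cross-checked against the brute-force all-pairs cutoff graph; if the two
partitions ever disagree (the Delaunay graph can omit a short edge between
points it does not connect), the brute-force graph wins. Clustering runs in
two rounds: round one with minimum size 1 locates every co-located group;
within each cluster, every gene keeps only its member nearest the cluster
centroid (ties by structure id); round two re-clusters the survivors at the
true minimum size. The point of the second round is that a gene represented
by many near-identical structures must not reach the cluster-size threshold
by itself.

Extracellular His counting takes the membrane midplane through three anchor
Cα atoms of a reference structure (residues 52, 163 and 214 of the bovine
rhodopsin frame for real data; the z = 0 plane for synthetic frames), with
the normal oriented by an explicit extracellular probe point — three points
alone do not define a side. A His is extracellular when its Cα is strictly
above the plane; a Cα within 1e-9 Å of the plane is not counted. His
residues lacking a Cα are skipped with a warning and tallied.

## Signaling readouts

*Fluorescence normalization*: reporter fluorescence grows with culture
density, so each strain's readout is the OLS line of fluorescence vs A₆₀₀
evaluated at A₆₀₀ = 1.0; the slope standard error is carried. Replicates
are extrapolated separately and summarized afterwards.

*Variant calls*: log₂FC = log₂(F_variant / F_WT); |log₂FC| ≤ threshold is
"no change" (band inclusive), above is "increase", below "decrease". Zero
fluorescence maps to a −∞ sentinel and the call "nonfunctional"; a strain
counts as functional only when its fluorescence exceeds the matched
no-receptor control mean by more than 2 SD. Summing a variant's fold
changes across strains skips sentinels and counts them. Default threshold
0.5 (screening at pH 5.0); at pH 7.0 the thresholds are per-receptor (2.0
for GPR4/GPR68, 0.5 for GPR65) because baseline signaling differs.

*netBRET* = acceptor/donor − donor-only ratio. The sign convention makes
coupling above baseline positive; a flag flips it for the literal
baseline-minus-ratio convention.

*Titration fits*: the four-parameter logistic is parameterized directly in
pH, `R = bottom + (top − bottom)/(1 + 10^(s(pH − pH₅₀)))`, so pH₅₀ is the
midpoint in pH units (the proton analogue of −log EC₅₀) and s > 0 describes
acid-activated receptors (response falls as pH rises). Fits require ≥ 5
points spanning ≥ 1 pH unit and non-zero response variance. Initialization
is a fixed 3×3 multistart grid — pH₅₀ at the 20th/50th/80th percentile of
the pH values, slope in {0.5, 1, 2}, bottom/top at the data extremes — and
the start with the lowest residual sum of squares wins; the Hill slope is
bounded to (1e-3, 50). Parameter standard errors come from the fit
covariance (lmfit); a fitted pH₅₀ more than 1 pH unit outside the data
range is flagged extrapolated. ΔpH₅₀ subtracts the WT fit, with the
standard errors combined in quadrature; both fits must have converged.

## Synthetic fixtures

`make_bundle` emulates a seven-transmembrane fold as seven helical Cα
curves (radius 2.3 Å, rise 1.5 Å/residue, 100°/residue) on a ring of radius
8 Å, plus a narrow axial spiral filling the central pore so the bundle
interior is solid and deep burial exists. Seeded 0.15 Å jitter on every Cα
makes distinct seeds produce distinct bundles. Ionizable residues are
planted by renaming a scaffold residue and placing its charged-group atom
iteratively: place, measure with the pipeline's own surface and depth,
move radially by the error, at most 20 steps, accepted at |error| ≤ 0.2 Å
and rejected as infeasible beyond 1 Å. The ground-truth table records the
*measured* converged depth, not the requested one, so recovery tests are
honest. Class targets sit ≥ 1.5 Å from both class boundaries (core −5.0,
margin −0.75, exposed +3.0 Å). `make_triad_bundle` additionally re-places
the Glu reference point on the 16 Å sphere around the DyaD midpoint,
scanning elevation angles for the direction whose depth stays at the core
target — so the triad geometry (a close Asp pair plus a Glu 16 Å away)
matches the receptors' motif by construction.

`make_ensemble` plants consensus sites jittered by Gaussian noise (default
SD 0.3 Å, the scale of superposition error between well-aligned
structures), Poisson-distributed decoys kept at least 7.5 Å (5× the
clustering cutoff) from any planted site, and optional Na⁺ HETATMs around a
pocket-like position. `simulate_titration` adds Gaussian noise (default 5%
of the dynamic range, replicating typical BRET titration scatter) to exact
4PL curves on a 10-point pH 5–8 grid; `simulate_dvp` uses lognormal
measurement noise around known fold changes. Every generator is a pure
function of its spec and seed.

What the fixtures do *not* model: real side-chain geometry and rotamer
packing, membrane lipids, structure-quality artifacts (missing loops,
alternate conformations beyond altloc records), inter-structure
superposition bias, or instrument-specific plate effects. Passing the
recovery tests therefore shows the algorithms implement their definitions
correctly on controllable inputs with known truth — not that the burial
thresholds or cluster cutoffs are optimal for any particular receptor
family.

## Problem sizes and determinism

Defaults keep every computation interactive: bundles of ~240 atoms
(~250-facet surfaces), ensembles of 8 structures, 20-replicate recovery
experiments, and 200 simulated titrations (~10 s total for the full
recomputation script). All tie-breaks are deterministic (lexicographic node
keys, facet indices, structure ids), every random draw flows from an
explicit seed, and pipeline reruns produce byte-identical reports — the run
manifest embeds a hash of the configuration to make this checkable.

## Known limitations

- The network-minimization rule is a declared reconstruction of "minimize
  the triangulation": the shortest-alternative-path criterion is
  deterministic and tested against a brute-force restatement, but other
  minimal-network definitions exist.
- The alpha-shape closure loop guarantees a closed largest component, not a
  unique surface; strongly non-uniform Cα densities can close internal
  cavities at a larger alpha than ideal.
- Exactly cospherical point sets (all points on one sphere) are degenerate
  for the Delaunay step; the surface builder expects volume-filling
  scaffolds, as real Cα sets are.
- 4PL fits assume a single titration event; biphasic curves will fit the
  dominant transition and inflate residuals rather than fail loudly.
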