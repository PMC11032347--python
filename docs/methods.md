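# Methods

## Scope

`ppi_pocketome` is a pocket-centric toolkit for protein–protein
interaction (PPI) structures. It covers five stages: (1) curation of
heterodimer (HD) and protein–ligand (PL) entries by experimental-quality
and ligand rules, (2) grid-based detection and pharmacophoric typing of
binding pockets, (3) classification of liganded pockets relative to the
PPI interface, (4) a 109-component descriptor vector per pocket with a
filtering/rescaling/standardization pipeline, and (5) a Gaussian-kernel
Pocket Similarity Index (PSI) visualised as a minimum-spanning-tree
pocketome. Side-chain repair and protonation are out of scope (the
pipeline accepts structures as given; distances use heavy atoms so the
result does not depend on protonation).

## Curation model

An entry passes the quality filter when its method and statistics meet:

| method  | resolution | statistic |
|---------|-----------|-----------|
| X-ray   | ≤ 3.5 Å   | R-free − R-factor ≤ 0.07 |
| cryo-EM | ≤ 3.0 Å   | FSC criterion value ≤ 0.143 |
| NMR     | no test   | no test |

Anything else is rejected; a missing statistic is a rejection
(`missing_metadata`), never an exception. HD candidates are exactly two
protein chains with distinct UniProt accessions and more than three
residues each (implemented strictly as ≥ 4). PL candidates are
single-chain entries whose protein occurs in at least one curated HD.
Ligands need ≥ 5 heavy atoms, all from {C, N, O, S, P, B, F, Cl, Br, I};
deuterium counts as hydrogen. Ubiquitous additives are modelled by
excluding het codes with a PDB-wide occurrence count strictly below 10,
minus a user-curated whitelist that stands in for manual inspection.
Entries with alternate-location atoms in the 6 Å interface patch are
rejected; altlocs elsewhere are tolerated. All filters are pure
per-entry predicates, hence order-independent.

## Pocket detection

Detection is a VolSite-style grid procedure parameterized by:

| parameter | default | meaning |
|-----------|---------|---------|
| `step`    | 1 Å     | lattice spacing (pocket "cube" edge) |
| `boxS`    | 20 Å    | edge of the box centred on the reference centroid |
| `b`       | 65      | minimal buriedness to retain a point |
| `n`       | 12      | minimal retained 26-neighbours (erosion rule) |
| `nPTS`    | 20      | minimal points per cavity |
| `n_rays`  | 120     | size of the spherical ray set |
| `ray_range` | 8 Å   | maximal ray length; also the bulk-solvent cutoff |
| `clash_distance` | 2.5 Å | minimal point-to-atom distance |

The reference is the ligand (PL mode) or the partner chain (HD mode; the
partner contributes no occupancy, only the box centre). Candidate points
within `clash_distance` of a target heavy atom, or farther than
`ray_range` from all of them, are removed. *Buriedness* of a point is
the number of rays, from a fixed 120-direction spherical Fibonacci set,
that intersect a target heavy-atom van der Waals sphere within
`ray_range`; `n_rays = 120` makes the burial scale coincide with the
conventional 40 (exposed) to 120 (fully buried) reporting scale. Van der
Waals radii come from a fixed element table (unknown elements 1.7 Å).
Points below `b` are discarded; the survivors are eroded *iteratively*
(to a fixed point) until each keeps ≥ `n` retained 26-neighbours —
iterative erosion is the stricter, stable reading of the neighbour rule.
26-connected components of ≥ `nPTS` points become cavities, ranked by
size as CAVITY_N1, N2, …; ties break on centroid (x, y, z) for
reproducible identifiers. All comparisons are inclusive (≤ / ≥).

Each cavity point inherits a pharmacophoric probe from its nearest
target heavy atom within 4 Å, via a residue/atom-name table: CA
hydrophobic (aliphatic carbon, S), CZ aromatic ring atoms, O backbone
and amide acceptors, OD1 carboxylate, OG hydroxyl donor/acceptor, N
donors, NZ cationic nitrogens; no atom within 4 Å gives DU. Unlisted
atoms fall back to CA for carbon and DU otherwise, with a logged
warning.

## Interface and pocket classes

The interaction patch is every target heavy atom within 6 Å of a
partner heavy atom. A cavity is *orthosteric* when at least half of its
points lie within 6 Å of the partner; the 50% fraction is this
toolkit's quantitative reading of "resides at the interface" (the
qualitative criterion fixes no fraction) and is configurable. Liganded
pockets are classified after superposing the PL chain onto the matching
HD chain (least-squares on shared Cα atoms): competitive orthosteric
(PLOC) when the minimal ligand-to-epitope heavy-atom distance is ≤ 1 Å,
non-competitive orthosteric (PLONC) when it is greater, allosteric
(PLA) when the pocket is not orthosteric — no proximity requirement is
imposed on PLA sites. The ligand must occupy the cavity (≥ 1 heavy atom
within 2 Å of a cavity point); otherwise classification refuses rather
than guessing.

## Descriptors

Per cavity: volume (= point count × `step`³), 8 probe totals, and an
8 × 10 probe-by-burial histogram with bins `40` (≤ 40), `x.y`
(x < b ≤ y in steps of 10) and `120` (every ray blocked) — 89 values;
10 aggregate `T` bins sum the histogram over probe types; 10 geometric
descriptors treat the negative image as a unit-mass point cloud:
eigenvalues PMI1 ≤ PMI2 ≤ PMI3 of the inertia tensor about the
centroid, NPR1 = PMI1/PMI3, NPR2 = PMI2/PMI3, radius of gyration,
asphericity and spherocity index from the gyration-tensor eigenvalues,
eccentricity √(PMI3² − PMI1²)/PMI3, and inertial shape factor
PMI2/(PMI1·PMI3). These match the RDKit 3D descriptor definitions at
unit atomic mass, and the test suite cross-checks against RDKit.
Collinear clouds are a degenerate case: eccentricity reaches its rod
limit 1, spherocity 0, and the inertial shape factor (which diverges)
is reported as 0 with a warning.

Conservation laws hold exactly: probe totals, histogram sums and `T`
sums all equal the point count, which equals volume/`step`³.

### Processing pipeline

1. Columns zero in **more than** 95% of pockets are dropped (strict).
2. Non-negative columns with mean < 15% of the maximum **and** median
   < 65% of the mean move to log(1+x); `log1p` handles the zeros that
   motivate the rescale. Columns containing negatives are never
   candidates — the rule targets count-like distributions.
3. Every kept column is scaled to zero mean, unit **population**
   variance (the ddof difference is immaterial at any realistic sample
   size); constant columns are dropped with a warning.

The fitted state (kept columns, log flags, means, SDs) serializes to
JSON and projects new pockets without refitting.

## PSI and the pocketome tree

For standardized descriptor rows, d_ij is the Euclidean distance and

    PSI_ij = exp(−d_ij² / 2σ²)

with σ the population standard deviation of the N(N−1)/2 unordered
off-diagonal distances — including the zero diagonal would deflate σ
and is deliberately excluded; for N = 2, σ is the single distance, so
PSI₁₂ = e^(−1/2) exactly. PSI is a similarity in (0, 1], not a
calibrated probability. The pocketome is the **exact** minimum spanning
tree of the distance matrix (Kruskal, edges pre-sorted in lexicographic
pocket-ID order so equal weights resolve deterministically). Edge
weight is distance rather than 1 − PSI: the kernel is strictly
monotone, so both orderings give the same tree while distance avoids
coupling the tree to σ. An approximate locality-sensitive-hashing
layout would scale further but is unnecessary at the matrix sizes this
toolkit targets, and exactness makes the tree testable by enumeration.
Node *exposure* is a toolkit definition — the fraction of cavity points
with buriedness ≤ 60 — since no standard formula exists. Branch
homogeneity is the fraction of edges whose endpoints share a label,
with NA-labelled endpoints excluded from the denominator.

## Synthetic fixtures

Real curated structures cannot ship with the package, so the generators
build controllable stand-ins:

* **Toy heterodimer** — chain A is a double-layer spherical shell
  (radius `pocket_radius`, default 6 Å; layers `wall_thickness` apart)
  with a 60° aperture cone forming a concave pocket at the origin, plus
  a second outward-facing bowl on the far side for allosteric
  placements; chain B is a convex plug in the pocket mouth. Atoms are
  carbons in ALA residues on Fibonacci-sphere lattices with 0.05 Å
  seeded jitter; generators are pure functions of their spec. At the
  default detection parameters the pocket must be ≳ 6 Å in radius to
  survive clash pruning and erosion.
* **Toy liganded monomer** — chain A plus a rigid six-carbon ring slid
  down the pocket axis until its closest approach to the partner
  epitope equals `ligand_offset` (root-found to ±0.05 Å), or placed in
  the far-face bowl for allosteric cases.
* **Descriptor sample** — Gaussian clusters whose centres sit pairwise
  `cluster_separation` apart (in z-units, i.e. already on the
  standardized scale), isotropic noise `noise_sd`, and exact planted
  per-column zero fractions. Cluster-recovery checks run on this matrix
  as generated; re-standardizing it would shrink the planted separation
  because the between-cluster offset inflates the column variance.

What passing fixture tests show — and what they do not: the geometry,
counting, kernel and tree machinery are exact on inputs with known
ground truth; they do not show that detection parameters are optimal
for real PPI interfaces, that the probe table captures real chemistry
beyond the standard residues, or that descriptor distributions of real
pockets resemble the synthetic ones. Conclusions about real structures
require real structures.

## Problem sizes

The test suite verifies the MST against exhaustive enumeration on
100 seeded 7-node instances (16,807 spanning trees each), buriedness
against a ray-by-ray oracle on 50 points over a ~1,300-atom fixture,
shape descriptors against brute-force formulas on 20 random clouds, and
classification on 20 seeds × 3 pocket classes with full detection.
`scripts/acceptance.py` uses 5 heterodimer replicates, 5 classification
seeds (15 liganded detections) and 10 planted-cluster samples of 60
pockets; these sizes keep a complete run in well under a minute while
every quantity is still computed from scratch.

## Known limitations

* Exact numerical parity with the proprietary VolSite binary is not a
  goal; parameters, not implementation details, are matched.
* Conformational changes induced by ligands at the PPI surface are not
  detected; classification is purely geometric on the given
  coordinates.
* Chains with multiple UniProt segments (chimeras) are rejected as
  unmapped rather than split.
* The retained-descriptor count after the zero filter is a property of
  the pocket sample, not a constant of the method.
* The aggregate `T` block reconstructs the burial histogram summed over
  probes from the published column vocabulary; other aggregations of
  the probe/burial table are conceivable.
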