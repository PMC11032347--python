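# ppi-pocketome

A pocket-centric toolkit for protein–protein interaction (PPI)
structures: curate heterodimer and protein–ligand entries, detect and
type binding pockets on a cubic grid, classify liganded pockets
relative to the PPI interface, describe every pocket with a
109-component feature vector, and compare pockets through a
Gaussian-kernel similarity index visualised as a minimum-spanning-tree
"pocketome".

It is aimed at structural bioinformaticians and drug-discovery groups
who work on PPI modulation: the same pocket machinery runs on
heterodimers (where is the orthosteric site, and how buried is it?) and
on liganded monomers of the same protein (does this ligand compete with
the native partner?), and the similarity index supports hypotheses of
the form "this unliganded interface pocket resembles that successfully
drugged one".

## The model

**Detection.** A 1 Å cubic lattice is laid over a 20 Å box centred on a
reference — the ligand for protein–ligand entries, the partner chain
for heterodimers. Points clashing with the protein (≤ 2.5 Å) or in bulk
solvent (> 8 Å from every atom) are removed. Each point's *buriedness*
is the number of rays, out of a fixed 120-direction spherical set, that
hit a protein heavy atom within 8 Å; points with buriedness ≥ 65 are
kept, eroded until each retains ≥ 12 of its 26-neighbours, and
clustered into cavities of ≥ 20 points. Each cavity point inherits a
pharmacophoric probe (hydrophobic CA, aromatic CZ, acceptor O, anionic
OD1, donor/acceptor OG, donor N, cationic NZ, dummy DU) from its
nearest protein atom.

**Classification.** A pocket is *orthosteric* when at least half its
points lie within 6 Å of the partner chain. A liganded pocket is
competitive (PLOC) when the ligand comes within 1 Å of the partner
epitope after superposing the monomer onto the heterodimer,
non-competitive (PLONC) when farther, allosteric (PLA) when the pocket
is not orthosteric at all.

**Similarity.** Each pocket's descriptor vector (volume, probe counts,
probe-by-burial histogram, aggregate burial bins, and ten shape
descriptors of the negative image) is filtered, log-rescaled where
strongly skewed, and standardized. For pockets *i*, *j* at Euclidean
distance d_ij in this space,

    PSI_ij = exp(−d_ij² / 2σ²),

where σ is the standard deviation of all pairwise distances. The
pocketome is the exact minimum spanning tree of the distance matrix,
annotated (class, volume, exposure, Pfam/CATH) and exportable as
GraphML or a self-contained interactive HTML page.

## Worked example

```python
import ppi_pocketome as pk

# a synthetic heterodimer with a concave interface pocket at the origin
spec = pk.ToyComplexSpec(seed=1)
hd = pk.make_toy_heterodimer(spec)
cavities = pk.detect_pockets(hd.chain("A"), hd.chain("B").heavy_atoms())
pocket = cavities[0]
print(f"{pocket.cavity_id}: {len(pocket)} points, volume {pocket.volume:.0f} A^3")
print(f"orthosteric: {pk.is_orthosteric(pocket, hd.chain('B'))}")
vec = pk.describe_cavity(pocket)
print(f"descriptors: {len(vec)} (CA={vec['CA']:.0f}, DU={vec['DU']:.0f}, "
      f"NPR1={vec['NPR1']:.3f}, Rgyr={vec['Rgyr']:.2f})")

# a planted two-cluster descriptor sample through PSI and the tree
sample, labels = pk.make_descriptor_sample(
    pk.DescriptorSampleSpec(seed=0, cluster_separation=6.0))
dist = pk.pairwise_distances(sample)
tree = pk.minimum_spanning_tree(dist)
pk.annotate_tree(tree, {pid: {"subset": f"c{lab}"}
                        for pid, lab in zip(sample.index, labels)})
print(f"sigma = {dist.sigma:.3f}, PSI(sigma) = {pk.psi(dist.sigma, dist.sigma):.5f}")
print(f"MST: {len(tree)} nodes, total weight {tree.total_weight:.2f}, "
      f"branch homogeneity {pk.branch_homogeneity(tree, 'subset'):.3f}")
```

prints

```
CAVITY_N1: 147 points, volume 147 A^3
orthosteric: True
descriptors: 109 (CA=105, DU=42, NPR1=1.000, Rgyr=2.54)
sigma = 1.580, PSI(sigma) = 0.60653
MST: 60 nodes, total weight 268.04, branch homogeneity 0.966
```

The 147-point cavity sits exactly in the constructed pocket (volume =
points × 1 Å³; all points are hydrophobic or dummy probes because the
toy protein is all carbon), the pocket is verified orthosteric under
the partner plug, PSI at one σ equals e^(−1/2) as the kernel dictates,
and 96.6% of tree edges connect pockets from the same planted cluster.

A `pocketome` command-line interface wraps the same stages
(`curate`, `detect`, `classify`, `describe`, `psi`, `tree`); run
`pocketome --help` for usage.

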