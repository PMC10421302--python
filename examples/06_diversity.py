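"""Diversity analysis: 0/1 matrix -> Jaccard distances -> NJ tree and PCoA.

Simulates two diverged subpopulations and shows that both the tree and the
first principal coordinate separate them.
"""

from mgbssr import distance, nj_tree, pcoa, to_binary_matrix, tree_to_newick
from mgbssr.popgen import GenotypeTable
from mgbssr.synthetic import generate_genotypes

markers = ["M1", "M2", "M3", "M4"]
pop_a = {m: {100 + 10 * i: 0.95, 120 + 10 * i: 0.05} for i, m in enumerate(markers)}
pop_b = {m: {100 + 10 * i: 0.05, 120 + 10 * i: 0.95} for i, m in enumerate(markers)}
ta, _ = generate_genotypes(pop_a, n_samples=5, seed=31)
tb, _ = generate_genotypes(pop_b, n_samples=5, seed=32)

table = GenotypeTable(
    samples=[f"A{i}" for i in range(1, 6)] + [f"B{i}" for i in range(1, 6)],
    markers=markers,
    cells={
        **{(f"A{i+1}", m): ta.cell(s, m) for i, s in enumerate(ta.samples) for m in ta.markers},
        **{(f"B{i+1}", m): tb.cell(s, m) for i, s in enumerate(tb.samples) for m in tb.markers},
    },
)

bm = to_binary_matrix(table)
dm = distance(bm, "jaccard")
print("newick:", tree_to_newick(nj_tree(dm)))

res = pcoa(dm, k=2)
print("\nfirst two principal coordinates:")
print(res.coordinates.round(3))
pos = res.eigenvalues[res.eigenvalues > 0]
print(f"\naxis 1 explains {100 * pos[0] / pos.sum():.1f}% of positive inertia")

# Samples drawn from the same subpopulation share alleles, so their Jaccard
# distances are small: the A and B groups form separate clusters in the
# tree, and PCo1 splits them with most of the positive inertia.
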