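"""Neighbor-joining tree with bootstrap supports and clade extraction.

Two synthetic transposase families are mixed, a tree is inferred from
p-distances with 100 bootstrap replicates, rooted on the first family,
and supported clades (>= 70%) are extracted.
"""

from tcmariner.phylo import bootstrap_supports, extract_supported_clades, root_with_outgroup
from tcmariner.seqio import write_newick
from tcmariner.synthetic_data import FamilySpec, sim_family

fam_a, _ = sim_family(FamilySpec(name="famA", n=4, divergence=0.05), seed=1)
fam_b, _ = sim_family(FamilySpec(name="famB", n=4, divergence=0.05), seed=2)
records = fam_a + fam_b

tree = bootstrap_supports(
    [r.residues for r in records], [r.id for r in records], n_reps=100, seed=5
)
rooted = root_with_outgroup(tree, {r.id for r in fam_a})
groups, isolated = extract_supported_clades(rooted, min_support=70)

print(write_newick(rooted))
for g in groups:
    print(f"{g.label}: support {g.support:.0f}%, members {list(g.members)}")
print(f"isolated leaves: {isolated}")

# With two well-separated families the focal bipartition reaches ~100%
# bootstrap support and each family comes back as one supported clade.
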