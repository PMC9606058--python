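"""Collapse a phylogeny into a haplotype genealogy graph by Fitch parsimony.

Fourteen barcode sequences — eleven sharing one haplotype and three each
carrying a single private substitution — are reconstructed ancestrally on
their tree; zero-change branches are contracted and identical haplotypes
merged, leaving one central node and three single-substitution edges.
"""

from museomito import SequenceAlignment
from museomito.hapgraph import export_graph, haplotype_graph
from museomito.io import parse_newick

base = "ACGTACGTACGTACGTACGT"
rows = [(f"m{i}", base) for i in range(1, 12)]
rows += [
    ("v1", base[:3] + "A" + base[4:]),
    ("v2", base[:9] + "G" + base[10:]),
    ("v3", base[:14] + "A" + base[15:]),
]
aln = SequenceAlignment(rows)
tree = parse_newick(
    "(((((m1,m2),(m3,m4)),((m5,m6),(m7,m8))),((m9,m10),m11)),(v1,(v2,v3)));"
)

g, score = haplotype_graph(tree, aln)
print(f"haplotypes      : {len(g.nodes)}")
for n in g.nodes:
    print(f"  {n.hap_id}: multiplicity {n.multiplicity}")
print(f"edges           : {[(u, v, w) for u, v, w in g.edges]}")
print(f"parsimony score : {score} (= sum of edge weights)")
export_graph(g, "haplotypes.dot", "dot")
print("wrote haplotypes.dot (node size proportional to multiplicity)")
# The 11/1/1/1 star with unit edges is the structure expected when three
# singleton haplotypes each sit one substitution from a shared majority type.
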