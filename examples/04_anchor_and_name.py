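"""Anchor an inferred hierarchy to the haplogroup-Q backbone and name it.

The pairwise sorter knows nothing about established haplogroups.
Anchoring merges its output with a curated reference table (branch,
parent, defining SNPs): branches sharing a SNP name adopt the reference
name, novel branches are inserted where the pairwise constraints place
them, and each novel branch receives a lineage-based name — the
parent's lineage label extended by an alternating letter/digit ordinal
plus its first defining SNP (Y Chromosome Consortium style).
"""

from ylineage.pairtree import Branch, PhyloTree
from ylineage.refanchor import anchor_tree, name_branches, q_backbone_reference

# a toy inferred hierarchy: two database markers recovered (M3, M848)
# plus three clusters never seen in any database
inferred = PhyloTree({
    "B1": Branch(id="B1", snps=("M3",), parent=None,
                 carriers=frozenset("abcdef")),
    "B2": Branch(id="B2", snps=("ZK10", "ZK11"), parent="B1",
                 carriers=frozenset("abcd")),
    "B3": Branch(id="B3", snps=("M848",), parent="B2",
                 carriers=frozenset("abc")),
    "B4": Branch(id="B4", snps=("ZK7",), parent="B3",
                 carriers=frozenset("ab")),
    "B5": Branch(id="B5", snps=("ZK20",), parent="B1",
                 carriers=frozenset("ef")),
})

ref = q_backbone_reference()
merged = name_branches(anchor_tree(inferred, ref))

print("merged tree (indentation = nesting):")
def show(bid, indent=0):
    b = merged.branches[bid]
    print(f"  {'  ' * indent}{b.display_name:22s} [{b.provenance}]"
          f"{' carriers=' + str(len(b.carriers)) if b.carriers else ''}")
    for kid in merged.children(bid):
        show(kid, indent + 1)
for root in merged.children(None):
    show(root)

print(f"\nnovel branches: {[merged.branches[b].name for b in merged.novel_branches]}")
print("B2 sits BETWEEN the database branches Q1b1a1a-M3 and Q1b1a1a1-M848 —")
print("the pairwise constraints force the insertion; unobserved backbone")
print("branches (Q-M242 ... Q1b1-L53) are kept as pass-through nodes so novel")
print("names inherit the full database lineage depth.")
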