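"""Map motif presence/absence onto a phylogeny with parsimony.

Mimics the classic ancestor/loss story: a motif present across a clade
except one genus is most parsimoniously explained by ancestral
presence followed by a single loss.
"""

import chiscan as cs

newick = "(((Escherichia,Salmonella),(Yersinia1,Yersinia2)),Vibrio);"
tree = cs.parse_newick(newick)
tip_states = {
    "Escherichia": "present",
    "Salmonella": "present",
    "Yersinia1": "absent",
    "Yersinia2": "absent",
    "Vibrio": "present",
}
anc = cs.fitch_presence_absence(tree, tip_states)
print(f"minimum state changes : {anc.min_changes}")
print(f"root states (all most-parsimonious reconstructions): "
      f"{sorted(anc.root_states)}")

ann = cs.annotate_tree(
    tree,
    {sp: (["GCTGGTGG"] if st == "present" else [])
     for sp, st in tip_states.items()},
)
print(ann.tips.to_string(index=False))
# With the outgroup carrying the motif, a single loss on the Yersinia
# stem explains the pattern: the motif was present in the common
# ancestor and lost once.  When gain and loss scenarios tie, the
# per-node state sets report both instead of picking one.
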