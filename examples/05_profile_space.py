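"""Exploring the space of realizations: splits, distance, enumeration.

Every realization of a profile unzips to a multiple-labelled tree via
split operations that conserve label-summed path counts; the number of
splits plus a MUL-tree edit distance bounds the profile-space distance
between two realizations.  For the tiny profile (3), exhaustive search
shows no realization with at most two reticulations is an orchard,
though a weak orchard exists and none is tree-child.
"""

from ploidynet import (
    build_B,
    count_paths,
    distance_upper_bound,
    enumerate_realizations,
    is_tree_child,
    naive_core,
    normalize,
    realize_profile,
    to_enewick,
    unzip_to_multree,
)
from ploidynet.cherries import orchard_status

p = normalize([5, 1, 1])
n1 = realize_profile(p, core=build_B(p))
n2 = realize_profile(p, core=naive_core(p))
tree, nsplits = unzip_to_multree(n1)
print("unzip of the beaded realization:", to_enewick(tree))
print("splits used:", nsplits, "counts conserved:", count_paths(tree) == count_paths(n1))
bound = distance_upper_bound(n1, n2, tree_distance=lambda a, b: 1)
print("distance bound between the two cores' realizations:", bound)

print("\nexhaustive search for profile (3), at most 2 reticulations:")
for net in enumerate_realizations(normalize([3]), 2):
    print(" ", to_enewick(net),
          orchard_status(net, allow_trim=True).status.value,
          "tree-child:", is_tree_child(net))
print(
    "\nThe bound counts one split per reticulation on each side plus the\n"
    "plugged-in MUL-tree distance (here a stand-in returning 1)."
)
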