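"""Simplify a ploidy profile and realize it as a beaded network.

The profile (7,6,6,5) records the ploidy levels of four taxa.  The
simplification sequence reduces it via the difference of its two largest
components until a simple profile remains; tracing the sequence back
from a core network yields a phylogenetic network N(m) in which the
number of root-to-leaf paths to each taxon equals its ploidy level.
"""

from ploidynet import (
    normalize,
    simplification_sequence,
    realize_profile,
    count_paths,
    to_enewick,
)
from ploidynet.realize import realization_summary

profile = normalize([7, 6, 6, 5])
seq = simplification_sequence(profile)
print("simplification sequence:")
for q, step in zip(seq.profiles, list(seq.steps) + [None]):
    arrow = f"  --{step.case.value}(alpha={step.alpha})-->" if step else "  (terminal)"
    print(f"  {q}{arrow}")

net = realize_profile(profile)
print("\nN(m) as eNewick:", to_enewick(net))
print("root-to-leaf path counts:", count_paths(net))
print("summary:", realization_summary(net))
print(
    "\nThe path counts equal the input ploidy levels; the reticulation"
    "\ncount is the core's plus one per simplification step with alpha != 0."
)
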