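"""Cherry-modification sequences: orchard and weak-orchard certificates.

A network is an orchard when reduce/cut/simp operations can shrink it to
a single vertex; allowing trim as well gives a weak orchard.  The
certificate for N(m) is read directly off the simplification sequence —
no search — and replaying it backwards produces a time labelling.
"""

from ploidynet import (
    label_from_cherry_sequence,
    normalize,
    realize_profile,
    traceback_cherry_sequence,
    verify_labelling,
)
from ploidynet.cherries import replay

for comps in [(7, 6, 6, 5), (6, 3)]:
    p = normalize(list(comps))
    net = realize_profile(p)
    cert = traceback_cherry_sequence(p)
    final = replay(net, cert.sequence)
    stamps = label_from_cherry_sequence(net, cert.sequence)
    rep = verify_labelling(net, stamps)
    print(f"profile {p}: {cert.status.value}")
    print("  sequence:", ", ".join(str(op) for op in cert.sequence))
    print("  replays to single vertex:", len(final.g) == 1)
    print("  induced labelling:", rep.classification.value)
    print()

print(
    "(7,6,6,5) has a practical terminal element, so its certificate is\n"
    "trim-free and the induced labelling is fully HGT-consistent; (6,3)\n"
    "terminates in the arc-rich (3) and needs one trim (weak orchard)."
)
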