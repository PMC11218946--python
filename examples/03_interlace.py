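"""Detect a Hopf-linked pair of hairpin loops (L&L interlace).

Two hairpin loops in one chain are built so their closed cycles have Gauss
linking number +-1 — the misfolded counterpart of kissing loops.  Any
interlace contradicts the RNA folding hierarchy and is always an artifact.
"""

from rnatangle.elements import find_loops
from rnatangle.entangle import detect_all, linking_number
from rnatangle.structure_io import annotate_base_pairs
from rnatangle.synthetic import make_hopf_loops

model, dotbracket, truth = make_hopf_loops()
ss = annotate_base_pairs(model, "dotbracket", dotbracket)
(entanglement,) = detect_all(model, ss)

loops = [lp for chain in model.chains for lp in find_loops(ss, chain)]
lk = linking_number(loops[0].curve, loops[1].curve)

print(f"subclass           : {entanglement.subclass}")
print(f"linking number     : {lk}")
print(f"flagged as artifact: {entanglement.artifact}")

model, dotbracket, _ = make_hopf_loops(linked=False)
ss = annotate_base_pairs(model, "dotbracket", dotbracket)
print(f"unlinked control   : {len(detect_all(model, ss))} detections")
# |lk| = 1 marks a genuine Hopf link between the two loop cycles; separating
# the loops removes the detection entirely.
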