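"""Chemical-shift-perturbation mapping of a binding interface.

Simulates free/bound amide shift tables with perturbations localized to the
mid-loop (ML) surface, computes combined CSPs
ddelta = sqrt(ddelta_H^2 + (0.14 ddelta_N)^2), and classifies interface
residues with the 0.2 ppm rule.
"""

from pntkit import datasets, synth
from pntkit.csp import classify_interface, compute_csp, interface_overlap

base = synth.make_base_shift_table(seed=8)
interface = set(datasets.ML_SURFACE.residues)
free, bound, truth = synth.gen_shift_tables(base, interface, seed=8)

records = compute_csp(free, bound)
flagged = classify_interface(records, threshold=0.2)
overlap = interface_overlap(flagged, datasets.ML_SURFACE)

print(f"{len(records)} amides compared between free and bound states")
print(f"{len(flagged)} residues show a combined CSP > 0.2 ppm: {flagged}")
print(f"fraction of flagged residues on the annotated ML surface: "
      f"{overlap['fraction']:.2f}")
print("A fraction near 1.0 means the perturbations cluster on the "
      "self-association surface, as expected for a binding interface "
      "rather than a conformational change.")
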