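"""Classify deletion/duplication breakpoints into the five classes.

Events are classified by breakpoint *context* (which SD segment copies or
unique sequence host the two breakpoints), so the same rules apply to the
packaged GRCh38-coordinate model and to synthetic loci.
"""

from sdhap import classify_event, event_from_coords, load_grch38_model
from sdhap.breakpoints import localize_breakpoints
from sdhap.simulate import (SimulationConfig, default_haplotypes,
                            simulate_locus, simulate_nahr_event)

model = load_grch38_model()
events = [(195.94e6, 197.64e6, "deletion", 5e3),
          (195.99e6, 197.64e6, "deletion", 5e3),
          (196.01e6, 197.30e6, "deletion", 5e3),
          (196.00e6, 197.60e6, "duplication", 50e3),
          (196.25e6, 197.20e6, "duplication", 5e3)]
print("printed coordinates on the packaged 3q29 model:")
for prox, dist, etype, unc in events:
    call = classify_event(event_from_coords(prox, dist, etype,
                                            uncertainty=unc), model)
    print(f"  {etype:11s} {prox / 1e6:.2f}-{dist / 1e6:.2f} Mbp -> "
          f"Class {call.class_label:2s} ({call.mechanism}, {call.confidence})")

# engineered NAHR events on the synthetic locus classify by the same rules
locus = simulate_locus(SimulationConfig(seed=2))
h1 = default_haplotypes(locus, ["H1"])["H1"]
rearranged, truth = simulate_nahr_event(h1, "SDB.blue2", "SDC.blue",
                                        2_000, "deletion")
ev = localize_breakpoints(rearranged.structure, locus.model)
call = classify_event(ev, locus.model)
print(f"\nsynthetic recurrent deletion: size {ev.size_bp / 1e6:.2f} Mbp, "
      f"Class {call.class_label}, mechanism {call.mechanism}")
# Class I/II split on which 5-kbp cassette copy in the proximal SD block
# hosts the breakpoint; unique-context events become Class III (deletion)
# or V (duplication); NAHR is called only for paralogous contexts.
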