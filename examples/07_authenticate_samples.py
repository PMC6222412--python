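"""Authenticate unknown samples with the duplex virtual assay.

Three samples are tested: a genuine conspecific sample, a non-panel
sequence, and a two-species chimera (an adulterated product). The call
combines the duplex rule (both markers of a species must yield their
expected sizes), a universal-primer amplification control, and a
nearest-reference identity cross-check.
"""

import numpy as np

from scarkit.authenticate import UNIVERSAL_ITS_PRIMERS, authenticate_report
from scarkit.design import design_marker_set
from scarkit.seqs import SeqRecord, revcomp
from scarkit.simulate import PanelSpec, generate_panel, generate_sample

panel, _ = generate_panel(PanelSpec(seed=42, n_species=3, n_per_species=2))
sets = [design_marker_set(panel, sp) for sp in panel.species]

genuine = generate_sample(panel, panel.species[0], n_private_mutations=2, seed=5, sample_id="product_1")
rng = np.random.default_rng(0)
alien = SeqRecord(
    id="product_2",
    bases=UNIVERSAL_ITS_PRIMERS[0] + "".join(rng.choice(list("ACGT"), 400)) + revcomp(UNIVERSAL_ITS_PRIMERS[1]),
)
chimera = SeqRecord(
    id="product_3",
    bases=panel.reference_of(panel.species[0]).ungapped + panel.reference_of(panel.species[1]).ungapped,
)

report = authenticate_report([genuine, alien, chimera], sets, panel)
print(report.to_string())

# product_1 -> its true species (duplex fired, identity ~99.5%);
# product_2 -> unresolved non-panel species (control positive, no marker);
# product_3 -> mixed/adulterated (markers of two species fired).
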