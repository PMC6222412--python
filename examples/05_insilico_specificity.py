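"""Cross-test designed markers against every panel template (virtual gel).

Exact-match in-silico PCR of every marker x template combination. A
species-specific marker set produces a block-diagonal pattern: bands
only in the lanes of each marker's target species.
"""

from scarkit.design import design_marker_set
from scarkit.ispcr import specificity_matrix, virtual_gel
from scarkit.simulate import PanelSpec, generate_panel

panel, _ = generate_panel(PanelSpec(seed=42, n_species=3, n_per_species=2))
markers = [m for sp in panel.species for m in design_marker_set(panel, sp).markers]

matrix = specificity_matrix(markers, panel)
print(virtual_gel(matrix))
print("verdicts:", matrix.verdicts)
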