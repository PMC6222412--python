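"""In-silico PCR: primer binding sites, amplicon prediction, specificity.

Binding is IUPAC-aware: a primer base anneals to a template base when
their IUPAC expansion sets intersect. A forward primer is matched
directly against the template; a reverse primer binds the minus strand,
i.e. its reverse complement is matched against the plus strand, with the
primer's 3' end at the left edge of the footprint. Amplicon length is
the inclusive span from the forward primer's 5' end through the reverse
primer's 5' end (both primer footprints included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scarkit.seqs import GAP, IUPAC_SETS, SeqRecord, SpeciesPanel, revcomp

#: 4-bit encoding of IUPAC codes (A=1, C=2, G=4, T=8); gap/other = 0 never matches
_BITS = {code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases) for code, bases in IUPAC_SETS.items()}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BITS.get(ch, 0) for ch in seq.upper()), dtype=np.uint8, count=len(seq))


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str                 # '+' forward orientation, '-' reverse primer
    start: int                  # leftmost footprint coordinate, 0-based
    mismatches: int
    three_prime_mismatch: bool


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    marker_id: str
    start: int                  # forward primer 5' (0-based)
    end: int                    # half-open: one past the reverse primer 5'
    length: int
    f_mismatches: int
    r_mismatches: int


def _scan(primer_bits: np.ndarray, template_bits: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every template offset (vectorised)."""
    m, n = len(primer_bits), len(template_bits)
    if m > n:
        return np.empty((0,), dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, m)
    return ((windows & primer_bits) == 0).sum(axis=1)


def find_binding_sites(
    primer: str,
    template: SeqRecord | str,
    orientation: str = "+",
    max_mismatch: int = 0,
    forbid_3prime_mismatch: bool = True,
    three_prime_window: int = 3,
) -> list[BindingSite]:
    """Binding sites of a primer on an ungapped template.

    ``orientation='+'``: primer anneals in forward orientation (3' end at
    the right edge of the footprint). ``orientation='-'``: primer anneals
    to the minus strand (3' end at the left edge). Sites with any
    mismatch inside the 3'-terminal window are excluded when
    ``forbid_3prime_mismatch`` is set.
    """
    tid = template.id if isinstance(template, SeqRecord) else "template"
    bases = template.bases if isinstance(template, SeqRecord) else template
    if GAP in bases:
        raise ValueError("template must be ungapped")
    if orientation == "+":
        probe = primer
    elif orientation == "-":
        probe = revcomp(primer)
    else:
        raise ValueError("orientation must be '+' or '-'")
    pbits, tbits = _encode(probe), _encode(bases)
    m = len(pbits)
    mism = _scan(pbits, tbits)
    hits = np.nonzero(mism <= max_mismatch)[0]
    w = min(three_prime_window, m)
    sites: list[BindingSite] = []
    for pos in hits:
        window = tbits[pos : pos + m]
        per_base = (window & pbits) == 0
        tp = bool(per_base[-w:].any()) if orientation == "+" else bool(per_base[:w].any())
        if forbid_3prime_mismatch and tp:
            continue
        sites.append(BindingSite(tid, orientation, int(pos), int(mism[pos]), tp))
    return sites


def predict_amplicons(
    marker,
    template: SeqRecord,
    size_limits: tuple[int, int] = (50, 2000),
    max_mismatch: int = 0,
    forbid_3prime_mismatch: bool = True,
) -> list[AmpliconPrediction]:
    """All products of a primer pair on one template.

    Every (forward site, reverse site) combination with the forward
    footprint upstream of the reverse footprint and an in-range product
    size yields a prediction.
    """
    lo, hi = size_limits
    fsites = find_binding_sites(marker.forward.bases, template, "+", max_mismatch, forbid_3prime_mismatch)
    if not fsites:
        return []
    rsites = find_binding_sites(marker.reverse.bases, template, "-", max_mismatch, forbid_3prime_mismatch)
    out: list[AmpliconPrediction] = []
    rlen = len(marker.reverse.bases)
    flen = len(marker.forward.bases)
    for f in fsites:
        for r in rsites:
            if r.start < f.start + flen:
                continue
            end = r.start + rlen
            length = end - f.start
            if lo <= length <= hi:
                out.append(
                    AmpliconPrediction(
                        template_id=template.id, marker_id=marker.marker_id,
                        start=f.start, end=end, length=length,
                        f_mismatches=f.mismatches, r_mismatches=r.mismatches,
                    )
                )
    return out


@dataclass
class SpecificityMatrix:
    markers: list
    templates: list[SeqRecord]
    cells: dict[tuple[str, str], list[AmpliconPrediction]]
    verdicts: dict[str, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            m.marker_id: [
                ";".join(str(p.length) for p in self.cells[(m.marker_id, t.id)]) or "-"
                for t in self.templates
            ]
            for m in self.markers
        }
        return pd.DataFrame(data, index=[t.id for t in self.templates]).T

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def specificity_matrix(
    markers,
    templates: SpeciesPanel | list[SeqRecord],
    size_limits: tuple[int, int] = (50, 2000),
    max_mismatch: int = 0,
) -> SpecificityMatrix:
    """Evaluate every marker against every template.

    A marker is ``specific`` iff every template of its target species
    yields a product and no other template yields any product in the
    gel-visible size range; with no templates the verdict is ``untested``.
    """
    if isinstance(templates, SpeciesPanel):
        temps = [SeqRecord(id=r.id, bases=r.ungapped, species=r.species) for r in templates.alignment]
    else:
        temps = list(templates)
    cells: dict[tuple[str, str], list[AmpliconPrediction]] = {}
    verdicts: dict[str, str] = {}
    for m in markers:
        for t in temps:
            cells[(m.marker_id, t.id)] = predict_amplicons(m, t, size_limits, max_mismatch)
        if not temps:
            verdicts[m.marker_id] = "untested"
            continue
        on_target = [t for t in temps if t.species == m.target_species]
        off_hits = [t.id for t in temps if t.species != m.target_species and cells[(m.marker_id, t.id)]]
        missed = [t.id for t in on_target if not cells[(m.marker_id, t.id)]]
        if off_hits:
            verdicts[m.marker_id] = "off_target"
        elif missed or not on_target:
            verdicts[m.marker_id] = "missed_target"
        else:
            verdicts[m.marker_id] = "specific"
    return SpecificityMatrix(list(markers), temps, cells, verdicts)


def marker_is_specific(marker, panel: SpeciesPanel, size_limits=(50, 2000)) -> bool:
    """Strict design-validation check: expected-size product from every
    target-species template, zero products elsewhere (exact matching)."""
    for rec in panel.alignment:
        t = SeqRecord(id=rec.id, bases=rec.ungapped, species=rec.species)
        preds = predict_amplicons(marker, t, size_limits, max_mismatch=0)
        if rec.species == marker.target_species:
            if len(preds) != 1 or preds[0].length != marker.expected_amplicon:
                return False
        elif preds:
            return False
    return True


def audit_cross_species(
    markers,
    external: list[SeqRecord],
    max_mismatch: int = 2,
    risky_threshold: int = 2,
) -> pd.DataFrame:
    """Cross-reactivity audit of markers against non-panel sequences.

    For each marker x template: the minimum mismatch count of each primer
    over all placements (both orientations considered appropriately), any
    predicted products at ``max_mismatch``, and a ``risky`` flag when both
    primers sit within ``risky_threshold`` mismatches of the template.
    """
    rows = []
    for m in markers:
        for t in external:
            fbest = _best_mismatches(m.forward.bases, t.bases, "+")
            rbest = _best_mismatches(m.reverse.bases, t.bases, "-")
            preds = predict_amplicons(m, t, max_mismatch=max_mismatch, forbid_3prime_mismatch=True)
            rows.append(
                {
                    "marker_id": m.marker_id,
                    "target_species": m.target_species,
                    "template_id": t.id,
                    "template_species": t.species,
                    "f_min_mismatches": fbest,
                    "r_min_mismatches": rbest,
                    "n_products": len(preds),
                    "product_sizes": ";".join(str(p.length) for p in preds),
                    "risky": fbest < risky_threshold and rbest < risky_threshold,
                }
            )
    return pd.DataFrame(rows)


def _best_mismatches(primer: str, template: str, orientation: str) -> int:
    probe = primer if orientation == "+" else revcomp(primer)
    mism = _scan(_encode(probe), _encode(template))
    return int(mism.min()) if mism.size else len(primer)


def virtual_gel(matrix: SpecificityMatrix, lane_order: list[str] | None = None) -> str:
    """Text rendering of the specificity matrix as a gel: one block per
    marker, one lane per template, product sizes as the 'bands'."""
    lanes = lane_order or [t.id for t in matrix.templates]
    width = max(len(l) for l in lanes) + 2
    lines = []
    for m in matrix.markers:
        lines.append(f"== {m.marker_id} (target: {m.target_species}, "
                     f"expected {m.expected_amplicon} bp, verdict: {matrix.verdicts.get(m.marker_id, '?')}) ==")
        for lane_no, tid in enumerate(lanes, 1):
            preds = matrix.cells.get((m.marker_id, tid), [])
            bands = " ".join(f"[{p.length} bp]" for p in preds) if preds else "."
            lines.append(f"  lane {lane_no:>2} {tid:<{width}} {bands}")
    return "\n".join(lines) + "\n"
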