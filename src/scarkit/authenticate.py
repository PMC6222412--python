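"""Authentication of unknown samples against a reference panel.

Two independent routes, mirroring how a lab would check a commercial
product: (1) nearest-reference classification of a sequenced amplicon by
global alignment identity, and (2) a virtual duplex SCAR assay — both
markers of a species must produce their expected product sizes on the
sample sequence, with a universal barcode primer pair as amplification
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from scarkit.design import MarkerSet, ScarMarker
from scarkit.ispcr import predict_amplicons
from scarkit.seqs import SeqRecord, SequenceError, SpeciesPanel

#: Universal fungal barcode primers (White et al. ITS1/ITS4), used as the
#: amplification control for real ITS panels. Synthetic panels embed
#: binding sites for these in their conserved flanks.
UNIVERSAL_ITS_PRIMERS = ("TCCGTAGGTGAACCTGCGG", "TCCTCCGCTTATTGATATGC")


@dataclass(frozen=True)
class Classification:
    species: str                 # assigned species or "unresolved"
    identity: float
    best_record: str
    tie: bool = False


def _identity(aligner: Align.PairwiseAligner, query: str, ref: str) -> float:
    """Identity over aligned columns, terminal gaps excluded."""
    aln = aligner.align(query, ref)[0]
    a, b = aln[0], aln[1]  # gapped rows
    n = len(a)
    start = 0
    while start < n and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = n
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for i in range(start, end) if a[i] == b[i] and a[i] != "-")
    return matches / (end - start)


def classify_query(
    query: SeqRecord,
    panel: SpeciesPanel,
    min_identity: float = 0.99,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Classification:
    """Assign a query sequence to the panel species with the highest
    global-alignment identity (terminal gaps excluded).

    Returns ``unresolved`` when the best identity is below
    ``min_identity`` or when two species tie for the best identity.
    """
    if len(panel.alignment) == 0:
        raise SequenceError("empty panel")
    q = query.ungapped
    if len(q) < 100:
        raise SequenceError(f"query {query.id!r}: need >=100 nt, got {len(q)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    best: list[tuple[float, str, str]] = []
    for rec in panel.alignment:
        ident = _identity(aligner, q, rec.ungapped)
        best.append((ident, rec.species, rec.id))
    best.sort(key=lambda t: (-t[0], t[2]))
    top_ident, top_species, top_id = best[0]
    tie_species = {sp for ident, sp, _ in best if abs(ident - top_ident) < 1e-12}
    if len(tie_species) > 1:
        return Classification("unresolved", top_ident, top_id, tie=True)
    if top_ident < min_identity:
        return Classification("unresolved", top_ident, top_id)
    return Classification(top_species, top_ident, top_id)


@dataclass
class AssayResult:
    sample_id: str
    marker_products: dict[str, list[int]]      # marker_id -> product sizes
    species_fired: list[str]                   # species whose full duplex fired at expected sizes
    control_its_present: bool | None           # None = control not run
    assigned_species: str = "unresolved"
    identity_percent: float | None = None
    notes: str = ""


def virtual_assay(
    sample: SeqRecord,
    marker_sets: list[MarkerSet],
    control_primers: tuple[str, str] | None = UNIVERSAL_ITS_PRIMERS,
    panel: SpeciesPanel | None = None,
    min_identity: float = 0.99,
) -> AssayResult:
    """Run every marker against a sample sequence and call the species.

    The duplex rule: a species is called only when *both* of its markers
    produce exactly their expected amplicon sizes. Multiple species
    firing -> ``mixed/adulterated``; none firing with a positive control
    -> ``unresolved (non-panel species)``; control failure -> ``invalid
    sample``. If a panel is supplied, nearest-reference classification is
    attached as a cross-check (identity percent of the best reference).
    """
    template = SeqRecord(id=sample.id, bases=sample.ungapped, species=sample.species)
    products: dict[str, list[int]] = {}
    fired: list[str] = []
    for ms in marker_sets:
        ok = bool(ms.markers)
        for m in ms.markers:
            preds = predict_amplicons(m, template, max_mismatch=0)
            products[m.marker_id] = [p.length for p in preds]
            if not any(p.length == m.expected_amplicon for p in preds):
                ok = False
        if ok:
            fired.append(ms.target_species)

    control_present: bool | None = None
    if control_primers is not None:
        fwd, rev = control_primers
        ctrl = ScarMarker(
            marker_id="ITS_control", target_species="*",
            forward=_bare_primer(fwd, "+"), reverse=_bare_primer(rev, "-"),
            expected_amplicon=0,
        )
        control_present = bool(predict_amplicons(ctrl, template, max_mismatch=0))

    result = AssayResult(
        sample_id=sample.id,
        marker_products=products,
        species_fired=fired,
        control_its_present=control_present,
    )
    if control_present is False:
        result.assigned_species = "invalid sample"
        result.notes = "amplification control failed"
    elif len(fired) == 1:
        result.assigned_species = fired[0]
    elif len(fired) > 1:
        result.assigned_species = "mixed/adulterated"
        result.notes = "markers of multiple species fired: " + ", ".join(fired)
    else:
        result.assigned_species = "unresolved"
        result.notes = "no duplex marker fired (non-panel species?)"

    if panel is not None:
        cls = classify_query(template, panel, min_identity)
        result.identity_percent = 100.0 * cls.identity
        if result.assigned_species == "unresolved" and cls.species != "unresolved":
            result.assigned_species = cls.species
            result.notes = "assigned by sequence identity only"
    return result


def _bare_primer(seq: str, strand: str):
    from scarkit.design import PrimerCandidate
    from scarkit.seqs import gc_content

    return PrimerCandidate(
        name=f"ctrl{strand}", bases=seq.upper(), strand=strand, start=0,
        length=len(seq), gc=gc_content(seq), tm=0.0,
        diagnostic_count=0, three_prime_diagnostic=False,
    )


def authenticate_report(
    samples: list[SeqRecord],
    marker_sets: list[MarkerSet],
    panel: SpeciesPanel | None = None,
    control_primers: tuple[str, str] | None = UNIVERSAL_ITS_PRIMERS,
) -> pd.DataFrame:
    """Product-authentication table: one row per sample with the duplex
    call, control status and best-reference identity."""
    rows = []
    for s in samples:
        res = virtual_assay(s, marker_sets, control_primers, panel)
        rows.append(
            {
                "sample": s.id,
                "identification": res.assigned_species,
                "markers_fired": ";".join(res.species_fired) or "-",
                "control_its": res.control_its_present,
                "identity_percent": res.identity_percent,
                "notes": res.notes,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
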