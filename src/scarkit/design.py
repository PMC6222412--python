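"""Species-diagnostic site discovery and SCAR primer-pair design.

A diagnostic site is an alignment column whose state is fixed within the
target species and shared with no other record in the panel — a
substitution site when both sides carry bases, an indel site when a gap
is involved. SCAR primers are windows of the (ungapped) target reference
that cover at least one diagnostic site; a marker (primer pair) is
accepted only if at least one of its primers covers >=2 diagnostic
substitutions and the pair survives in-silico PCR against the whole
panel with zero off-target products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from scarkit.seqs import (
    GAP,
    IUPAC_SETS,
    SeqRecord,
    SequenceError,
    SpeciesPanel,
    gc_content,
    revcomp,
    tm_wallace,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticSite:
    column: int                     # 0-based alignment column
    target_species: str
    target_state: str               # base or '-'
    background_states: frozenset[str]
    kind: str                       # "substitution" | "indel"


@dataclass(frozen=True)
class PrimerCandidate:
    name: str
    bases: str                      # 5'->3'
    strand: str                     # '+' or '-'
    start: int                      # leftmost coordinate on the ungapped target reference
    length: int
    gc: float
    tm: float
    diagnostic_count: int           # all diagnostic sites under the footprint
    three_prime_diagnostic: bool
    diagnostic_substitution_count: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ScarMarker:
    marker_id: str
    target_species: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_amplicon: int


@dataclass
class MarkerSet:
    target_species: str
    markers: list[ScarMarker]
    status: str = "ok"              # "ok" | "INFEASIBLE_DUPLEX"


@dataclass(frozen=True)
class DesignConstraints:
    """Primer/amplicon constraint windows.

    Defaults reflect typical SCAR assays on ITS barcodes: 18-23 nt
    primers, 40-80% GC, Wallace Tm 52-74 degC, homopolymer runs <=5, and
    amplicons of 80-400 bp resolvable on an agarose gel.
    """

    length_min: int = 18
    length_max: int = 23
    gc_min: float = 0.40
    gc_max: float = 0.80
    tm_min: float = 52.0
    tm_max: float = 74.0
    max_homopolymer: int = 5
    amplicon_min: int = 80
    amplicon_max: int = 400
    resolvable_delta: int = 20
    min_intraspecific_fixation: float = 1.0


def find_diagnostic_sites(
    panel: SpeciesPanel,
    target_species: str,
    min_intraspecific_fixation: float = 1.0,
) -> list[DiagnosticSite]:
    """Alignment columns diagnostic for ``target_species``.

    A column qualifies when a single state is carried by at least
    ``min_intraspecific_fixation`` of the target records and that state
    is incompatible (no IUPAC overlap, gap treated as its own state)
    with every non-target record at the column. Sorted ascending.
    """
    if target_species not in panel.species:
        raise SequenceError(f"species {target_species!r} not in panel")
    targets = panel.records_of(target_species)
    background = [r for r in panel.alignment if r.species != target_species]
    sites: list[DiagnosticSite] = []
    for col in range(panel.alignment.aligned_length):
        states = [r.bases[col] for r in targets]
        counts: dict[str, int] = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
        state, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if count / len(states) < min_intraspecific_fixation:
            continue
        bg = frozenset(r.bases[col] for r in background)
        if not _state_disjoint(state, bg):
            continue
        kind = "indel" if state == GAP or GAP in bg else "substitution"
        sites.append(DiagnosticSite(col, target_species, state, bg, kind))
    return sites


def _state_disjoint(state: str, background: frozenset[str]) -> bool:
    """True iff the target state cannot be confused with any background
    state (IUPAC expansion sets disjoint; gap only matches gap)."""
    for b in background:
        if state == GAP or b == GAP:
            if state == b:
                return False
            continue
        if not IUPAC_SETS[state].isdisjoint(IUPAC_SETS[b]):
            return False
    return True


def _column_map(reference: SeqRecord) -> tuple[list[int], list[int]]:
    """Map between ungapped reference coordinates and alignment columns.

    Returns (col_of_pos, pos_right_of_col): the alignment column of each
    ungapped position, and for bookkeeping the list of ungapped positions.
    """
    col_of_pos = [i for i, ch in enumerate(reference.bases) if ch != GAP]
    return col_of_pos, list(range(len(col_of_pos)))


def _homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_primers(
    panel: SpeciesPanel,
    target_species: str,
    constraints: DesignConstraints = DesignConstraints(),
    sites: list[DiagnosticSite] | None = None,
) -> list[PrimerCandidate]:
    """All primer windows on the target reference (both strands) that
    cover >=1 diagnostic site and satisfy the constraint windows.

    Windows are taken on the ungapped reference; the diagnostic count of
    a window includes indel columns spanned by its footprint. Windows
    containing ambiguity codes are rejected (primers must be synthesis-
    ready), as are windows overlapping intraspecifically polymorphic
    columns (a primer must anneal to every conspecific template).
    """
    if sites is None:
        sites = find_diagnostic_sites(panel, target_species, constraints.min_intraspecific_fixation)
    if not sites:
        logger.warning("no diagnostic sites for %s; no primers possible", target_species)
        return []
    ref = panel.reference_of(target_species)
    col_of_pos, _ = _column_map(ref)
    ungapped = ref.ungapped
    site_cols = sorted(s.column for s in sites)
    sub_cols = sorted(s.column for s in sites if s.kind == "substitution")
    conspecifics = panel.records_of(target_species)
    poly_cols = sorted(
        col
        for col in range(panel.alignment.aligned_length)
        if any(r.bases[col] != ref.bases[col] for r in conspecifics)
    )

    def covered(cols: list[int], col_lo: int, col_hi: int) -> int:
        return sum(1 for c in cols if col_lo <= c <= col_hi)

    out: list[PrimerCandidate] = []
    n = len(ungapped)
    for start in range(n):
        for length in range(constraints.length_min, constraints.length_max + 1):
            end = start + length
            if end > n:
                break
            window = ungapped[start:end]
            if any(b not in "ACGT" for b in window):
                continue
            col_lo, col_hi = col_of_pos[start], col_of_pos[end - 1]
            dc = covered(site_cols, col_lo, col_hi)
            if dc == 0:
                continue
            if covered(poly_cols, col_lo, col_hi):
                continue
            dsc = covered(sub_cols, col_lo, col_hi)
            gc = gc_content(window)
            if not constraints.gc_min <= gc <= constraints.gc_max:
                continue
            tm = tm_wallace(window)
            if not constraints.tm_min <= tm <= constraints.tm_max:
                continue
            if _homopolymer_run(window) > constraints.max_homopolymer:
                continue
            # 3' terminal window: last 3 bases for '+', first 3 for '-'
            plus_3p = covered(site_cols, col_of_pos[max(start, end - 3)], col_hi) > 0
            minus_3p = covered(site_cols, col_lo, col_of_pos[min(end - 1, start + 2)]) > 0
            out.append(
                PrimerCandidate(
                    name=f"{target_species}_F_{start + 1}_{length}",
                    bases=window, strand="+", start=start, length=length,
                    gc=gc, tm=tm, diagnostic_count=dc,
                    three_prime_diagnostic=plus_3p,
                    diagnostic_substitution_count=dsc,
                )
            )
            out.append(
                PrimerCandidate(
                    name=f"{target_species}_R_{start + 1}_{length}",
                    bases=revcomp(window), strand="-", start=start, length=length,
                    gc=gc, tm=tm, diagnostic_count=dc,
                    three_prime_diagnostic=minus_3p,
                    diagnostic_substitution_count=dsc,
                )
            )
    return out


def pair_primers(
    candidates: list[PrimerCandidate],
    target_reference: SeqRecord,
    amplicon_window: tuple[int, int] = (80, 400),
    require_rule: bool = True,
    limit: int | None = None,
    size_exclude: tuple[int, int] | None = None,
) -> list[ScarMarker]:
    """All compatible forward/reverse pairs with in-window amplicons.

    The expected amplicon spans the forward primer's 5' end through the
    reverse primer's 5' end inclusive: (reverse.end - forward.start) on
    the ungapped reference. Pairs are ranked by total diagnostic count,
    then 3'-anchoring, then Tm balance, then leftmost coordinates; with
    ``limit`` only the top pairs are materialised.
    """
    lo, hi = amplicon_window
    fwd = [c for c in candidates if c.strand == "+"]
    rev = [c for c in candidates if c.strand == "-"]
    pairs: list[tuple[tuple, PrimerCandidate, PrimerCandidate, int]] = []
    for f in fwd:
        f_end = f.start + f.length
        for r in rev:
            if r.start < f_end:  # footprints must not overlap
                continue
            size = r.start + r.length - f.start
            if not lo <= size <= hi:
                continue
            if size_exclude is not None and size_exclude[0] < size < size_exclude[1]:
                continue
            if require_rule and f.diagnostic_substitution_count < 2 and r.diagnostic_substitution_count < 2:
                continue
            key = (
                -(f.diagnostic_count + r.diagnostic_count),
                -(int(f.three_prime_diagnostic) + int(r.three_prime_diagnostic)),
                abs(f.tm - r.tm),
                f.start,
                r.start,
            )
            pairs.append((key, f, r, size))
    pairs.sort(key=lambda t: t[0])
    if limit is not None:
        pairs = pairs[:limit]
    species = ""
    if fwd and "_F_" in fwd[0].name:
        species = fwd[0].name.rsplit("_F_", 1)[0]
    return [
        ScarMarker(
            marker_id=f"{f.name}/{r.name}", target_species=species,
            forward=f, reverse=r, expected_amplicon=size,
        )
        for _, f, r, size in pairs
    ]


def design_marker_set(
    panel: SpeciesPanel,
    target_species: str,
    constraints: DesignConstraints = DesignConstraints(),
    max_validations: int = 200,
    prune_per_strand: int = 120,
) -> MarkerSet:
    """Design the duplex marker set: the two top-ranked primer pairs that
    pass in-silico specificity against the whole panel and whose amplicon
    sizes differ by at least ``resolvable_delta`` bp.

    For speed, pairing first considers only the ``prune_per_strand``
    strongest candidates per strand (most diagnostic coverage); the full
    candidate set is retried if that subset cannot complete the duplex.
    Returns status ``INFEASIBLE_DUPLEX`` with a partial result when fewer
    than two validated markers exist.
    """
    from scarkit.ispcr import marker_is_specific  # local import avoids cycle

    sites = find_diagnostic_sites(panel, target_species, constraints.min_intraspecific_fixation)
    candidates = enumerate_primers(panel, target_species, constraints, sites)
    ref = panel.reference_of(target_species)
    window = (constraints.amplicon_min, constraints.amplicon_max)

    def strongest(strand: str) -> list[PrimerCandidate]:
        pool = sorted(
            (c for c in candidates if c.strand == strand),
            key=lambda c: (
                -c.diagnostic_substitution_count,
                -c.diagnostic_count,
                -int(c.three_prime_diagnostic),
                c.start,
            ),
        )
        return pool[:prune_per_strand]

    def first_valid(ranked: list[ScarMarker]) -> ScarMarker | None:
        for marker in ranked[:max_validations]:
            m = replace(marker, target_species=target_species)
            if marker_is_specific(m, panel):
                return m
        return None

    def select(pool: list[PrimerCandidate]) -> list[ScarMarker]:
        chosen: list[ScarMarker] = []
        first = first_valid(pair_primers(pool, ref, window, limit=budget))
        if first is None:
            return chosen
        chosen.append(first)
        # the second marker must be gel-distinguishable from the first,
        # so re-rank with the first marker's size band excluded
        delta = constraints.resolvable_delta
        band = (first.expected_amplicon - delta, first.expected_amplicon + delta)
        second = first_valid(pair_primers(pool, ref, window, limit=budget, size_exclude=band))
        if second is not None:
            chosen.append(second)
        return chosen

    budget = 20 * max_validations
    pruned = strongest("+") + strongest("-")
    chosen = select(pruned)
    if len(chosen) < 2 and len(pruned) < len(candidates):
        chosen = select(candidates)
    status = "ok" if len(chosen) == 2 else "INFEASIBLE_DUPLEX"
    if status != "ok":
        logger.warning("duplex design infeasible for %s (%d validated)", target_species, len(chosen))
    return MarkerSet(target_species=target_species, markers=chosen, status=status)


# ---------------------------------------------------------------- I/O ----

def write_markers_tsv(marker_sets: list[MarkerSet] | list[ScarMarker], path) -> None:
    """Primer-table TSV: one row per primer (name, sequence, expected_size,
    species), forward and reverse rows adjacent."""
    markers: list[ScarMarker] = []
    for ms in marker_sets:
        markers.extend(ms.markers if isinstance(ms, MarkerSet) else [ms])
    with open(path, "w") as fh:
        fh.write("name\tsequence\texpected_size\tspecies\n")
        for m in markers:
            fh.write(f"{m.forward.name}\t{m.forward.bases}\t{m.expected_amplicon}\t{m.target_species}\n")
            fh.write(f"{m.reverse.name}\t{m.reverse.bases}\t{m.expected_amplicon}\t{m.target_species}\n")


def read_markers_tsv(path) -> list[ScarMarker]:
    """Read a primer-pair table (adjacent forward/reverse rows) into markers.

    Only name/sequence/size/species are recoverable from a table; the
    positional and diagnostic annotations are left unset (0/False).
    """
    import csv

    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(row)
    if len(rows) % 2:
        raise SequenceError(f"{path}: expected paired forward/reverse rows")
    markers = []
    for i in range(0, len(rows), 2):
        f, r = rows[i], rows[i + 1]
        size = int(f["expected_size"])
        species = f["species"]
        fwd = PrimerCandidate(
            name=f["name"], bases=f["sequence"].upper(), strand="+", start=0,
            length=len(f["sequence"]), gc=gc_content(f["sequence"]),
            tm=tm_wallace(f["sequence"]), diagnostic_count=0, three_prime_diagnostic=False,
        )
        rev = PrimerCandidate(
            name=r["name"], bases=r["sequence"].upper(), strand="-", start=0,
            length=len(r["sequence"]), gc=gc_content(r["sequence"]),
            tm=tm_wallace(r["sequence"]), diagnostic_count=0, three_prime_diagnostic=False,
        )
        markers.append(
            ScarMarker(
                marker_id=f'{f["name"]}/{r["name"]}', target_species=species,
                forward=fwd, reverse=rev, expected_amplicon=size,
            )
        )
    return markers


def load_reference_markers() -> list[ScarMarker]:
    """The published duplex SCAR primer table for the five Cordyceps-
    related target species, bundled with the package."""
    import importlib.resources

    ref = importlib.resources.files("scarkit.data").joinpath("reference_scar_primers.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_markers_tsv(path)


def write_markers_bed(marker_sets: list[MarkerSet], path) -> None:
    """BED intervals of each marker's amplicon on its target reference."""
    with open(path, "w") as fh:
        for ms in marker_sets:
            for m in ms.markers:
                fh.write(
                    f"{m.target_species}\t{m.forward.start}\t{m.reverse.end}\t{m.marker_id}\t{m.expected_amplicon}\t+\n"
                )
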