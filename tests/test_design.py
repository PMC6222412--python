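"""Diagnostic-site discovery and SCAR primer-pair design."""

import pytest

from scarkit.design import (
    DesignConstraints,
    PrimerCandidate,
    ScarMarker,
    design_marker_set,
    enumerate_primers,
    find_diagnostic_sites,
    load_reference_markers,
    pair_primers,
    read_markers_tsv,
    write_markers_bed,
    write_markers_tsv,
)
from scarkit.ispcr import specificity_matrix
from scarkit.seqs import SequenceError, gc_content, revcomp, tm_wallace


class TestFindDiagnosticSites:
    def test_substitution_and_indel_sites_in_toy_panel(self, toy_panel):
        sites = find_diagnostic_sites(toy_panel, "spA")
        by_col = {s.column: s for s in sites}
        assert set(by_col) == {5, 9}
        assert by_col[5].kind == "substitution"
        assert by_col[5].target_state == "T"
        assert by_col[5].background_states == frozenset("C")
        assert by_col[9].kind == "indel"
        assert by_col[9].target_state == "-"

    def test_single_record_species(self, toy_panel):
        sites = find_diagnostic_sites(toy_panel, "spC")
        assert [s.column for s in sites] == [20]

    def test_absent_species_errors(self, toy_panel):
        with pytest.raises(SequenceError):
            find_diagnostic_sites(toy_panel, "nope")

    def test_columns_sorted_and_states_disjoint(self, synthetic_panel):
        panel, _ = synthetic_panel
        for sp in panel.species:
            sites = find_diagnostic_sites(panel, sp)
            cols = [s.column for s in sites]
            assert cols == sorted(cols)
            for s in sites:
                assert s.target_state not in s.background_states

    def test_agrees_with_definition_oracle(self, synthetic_panel):
        """Full-scan oracle: re-check every column from the definition."""
        panel, _ = synthetic_panel
        sp = panel.species[0]
        targets = panel.records_of(sp)
        background = [r for r in panel.alignment if r.species != sp]
        expected = []
        for col in range(panel.alignment.aligned_length):
            tstates = {r.bases[col] for r in targets}
            if len(tstates) != 1:
                continue
            state = next(iter(tstates))
            if all(r.bases[col] != state for r in background):
                expected.append(col)
        got = [s.column for s in find_diagnostic_sites(panel, sp)]
        assert got == expected


class TestEnumeratePrimers:
    def test_candidates_cover_the_diagnostic_cluster(self, toy_panel):
        constraints = DesignConstraints(length_min=8, length_max=10, gc_min=0, gc_max=1, tm_min=0, tm_max=99)
        cands = enumerate_primers(toy_panel, "spA", constraints)
        assert cands
        sites = find_diagnostic_sites(toy_panel, "spA")
        cols = {s.column for s in sites}
        ref = toy_panel.reference_of("spA")
        col_of_pos = [i for i, ch in enumerate(ref.bases) if ch != "-"]
        for c in cands:
            lo, hi = col_of_pos[c.start], col_of_pos[c.end - 1]
            assert any(lo <= col <= hi for col in cols)
            assert c.diagnostic_count >= 1

    def test_count_matches_sliding_window_oracle(self, small_panel):
        panel, _ = small_panel
        sp = panel.species[0]
        constraints = DesignConstraints()
        cands = enumerate_primers(panel, sp, constraints)
        # independent brute force over every (start, length, strand)
        sites = find_diagnostic_sites(panel, sp)
        cols = sorted(s.column for s in sites)
        ref = panel.reference_of(sp)
        conspecifics = panel.records_of(sp)
        col_of_pos = [i for i, ch in enumerate(ref.bases) if ch != "-"]
        ungapped = ref.ungapped
        count = 0
        for start in range(len(ungapped)):
            for length in range(constraints.length_min, constraints.length_max + 1):
                end = start + length
                if end > len(ungapped):
                    continue
                w = ungapped[start:end]
                if any(b not in "ACGT" for b in w):
                    continue
                lo, hi = col_of_pos[start], col_of_pos[end - 1]
                if not any(lo <= c <= hi for c in cols):
                    continue
                if any(
                    any(r.bases[col] != ref.bases[col] for r in conspecifics)
                    for col in range(lo, hi + 1)
                ):
                    continue
                if not constraints.gc_min <= gc_content(w) <= constraints.gc_max:
                    continue
                if not constraints.tm_min <= tm_wallace(w) <= constraints.tm_max:
                    continue
                runs = max(len(list(_grp)) for _, _grp in __import__("itertools").groupby(w))
                if runs > constraints.max_homopolymer:
                    continue
                count += 2  # one candidate per strand
        assert len(cands) == count

    def test_no_sites_returns_empty(self, toy_panel, caplog):
        constraints = DesignConstraints(length_min=30, length_max=30)
        out = enumerate_primers(toy_panel, "spA", constraints, sites=[])
        assert out == []


def _mk(name, strand, start, length, dc=2, dsc=2, tp=True, tm=60.0):
    bases = "A" * length
    return PrimerCandidate(
        name=name, bases=bases, strand=strand, start=start, length=length,
        gc=0.5, tm=tm, diagnostic_count=dc, three_prime_diagnostic=tp,
        diagnostic_substitution_count=dsc,
    )


class TestPairPrimers:
    def test_amplicon_coordinate_arithmetic(self):
        # forward at 0 (len 20), reverse footprint ending at 101 inclusive
        f = _mk("F", "+", 0, 20)
        r = _mk("R", "-", 82, 20)  # 82 + 20 - 1 = 101
        ref = None
        (m,) = pair_primers([f, r], ref, amplicon_window=(50, 200))
        assert m.expected_amplicon == 102

    def test_two_substitution_rule_enforced(self):
        f = _mk("F", "+", 0, 20, dsc=1)
        r = _mk("R", "-", 100, 20, dsc=1)
        assert pair_primers([f, r], None, (50, 200)) == []
        r2 = _mk("R2", "-", 100, 20, dsc=2)
        assert len(pair_primers([f, r2], None, (50, 200))) == 1

    def test_overlapping_or_reversed_geometry_rejected(self):
        f = _mk("F", "+", 50, 20)
        r = _mk("R", "-", 40, 20)
        assert pair_primers([f, r], None, (10, 500)) == []

    def test_exhaustive_pairing_oracle(self):
        # <=10 candidates: compare against a direct double loop
        cands = [
            _mk(f"F{i}", "+", s, 20, dc=i + 1) for i, s in enumerate([0, 30, 60])
        ] + [
            _mk(f"R{i}", "-", s, 20, dc=i + 1) for i, s in enumerate([120, 180, 260])
        ]
        got = pair_primers(cands, None, (80, 300))
        expected = set()
        for f in cands:
            for r in cands:
                if f.strand != "+" or r.strand != "-":
                    continue
                if r.start < f.start + f.length:
                    continue
                size = r.start + r.length - f.start
                if 80 <= size <= 300:
                    expected.add((f.name, r.name, size))
        assert {(m.forward.name, m.reverse.name, m.expected_amplicon) for m in got} == expected

    def test_ranking_prefers_diagnostic_density(self):
        weak_f = _mk("Fw", "+", 0, 20, dc=2, dsc=2, tp=False)
        strong_f = _mk("Fs", "+", 0, 20, dc=5, dsc=5, tp=True)
        r = _mk("R", "-", 100, 20, dc=2, dsc=2)
        ranked = pair_primers([weak_f, strong_f, r], None, (50, 200))
        assert ranked[0].forward.name == "Fs"


class TestDesignMarkerSet:
    def test_duplex_design_on_synthetic_panel(self, synthetic_panel):
        panel, _ = synthetic_panel
        ms = design_marker_set(panel, panel.species[0])
        assert ms.status == "ok"
        assert len(ms.markers) == 2
        sizes = [m.expected_amplicon for m in ms.markers]
        assert abs(sizes[0] - sizes[1]) >= 20
        for m in ms.markers:
            assert (
                m.forward.diagnostic_substitution_count >= 2
                or m.reverse.diagnostic_substitution_count >= 2
            )

    def test_block_diagonal_specificity(self, small_panel):
        panel, _ = small_panel
        markers = []
        for sp in panel.species:
            ms = design_marker_set(panel, sp)
            assert ms.status == "ok"
            markers += ms.markers
        mat = specificity_matrix(markers, panel)
        assert set(mat.verdicts.values()) == {"specific"}
        for m in markers:
            for t in mat.templates:
                preds = mat.cells[(m.marker_id, t.id)]
                if t.species == m.target_species:
                    assert [p.length for p in preds] == [m.expected_amplicon]
                else:
                    assert preds == []

    def test_design_is_deterministic(self, small_panel):
        panel, _ = small_panel
        a = design_marker_set(panel, panel.species[1])
        b = design_marker_set(panel, panel.species[1])
        assert [m.marker_id for m in a.markers] == [m.marker_id for m in b.markers]

    def test_infeasible_duplex_flagged(self, toy_panel):
        # the toy panel is far too short to host two separated amplicons
        ms = design_marker_set(toy_panel, "spA")
        assert ms.status == "INFEASIBLE_DUPLEX"


class TestMarkerIO:
    def test_tsv_round_trip(self, small_panel, tmp_path):
        panel, _ = small_panel
        sets = [design_marker_set(panel, sp) for sp in panel.species]
        path = tmp_path / "markers.tsv"
        write_markers_tsv(sets, path)
        back = read_markers_tsv(path)
        orig = [m for s in sets for m in s.markers]
        assert [(m.forward.bases, m.reverse.bases, m.expected_amplicon, m.target_species) for m in back] == [
            (m.forward.bases, m.reverse.bases, m.expected_amplicon, m.target_species) for m in orig
        ]

    def test_bed_export(self, small_panel, tmp_path):
        panel, _ = small_panel
        sets = [design_marker_set(panel, panel.species[0])]
        path = tmp_path / "m.bed"
        write_markers_bed(sets, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(sets[0].markers)
        for line in lines:
            chrom, start, end, name, score, strand = line.split("\t")
            assert int(end) - int(start) == int(score)

    def test_bundled_reference_table_loads(self):
        markers = load_reference_markers()
        assert len(markers) == 10
        by_species = {}
        for m in markers:
            by_species.setdefault(m.target_species, []).append(m)
        assert all(len(v) == 2 for v in by_species.values())
        # quirk of the published table: the 102-bp assay's reverse primer
        # is the exact reverse complement of the 339-bp assay's forward
        cm339 = next(m for m in markers if m.expected_amplicon == 339)
        cm102 = next(m for m in markers if m.expected_amplicon == 102)
        assert revcomp(cm339.forward.bases) == cm102.reverse.bases
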