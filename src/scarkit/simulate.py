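"""Synthetic barcode panels, samples and dilution series with ground truth.

The generator emulates the structure of a small multi-species barcode
reference panel: a handful of species, a few sequences each, ~580 bp,
near-zero intraspecific divergence, ~9-21% interspecific divergence,
and species-specific indels. Sequences evolve from one random ancestor
along a star-of-stars genealogy — one branch per species (substitutions
with a 2:1 transition:transversion bias, plus deletions), then one short
branch per individual — so every mutation is recorded and the planted
species-diagnostic columns are known exactly.

Conserved flanks carrying binding sites for the universal barcode
primer pair are attached to both ends, so the amplification-control
check of the virtual assay behaves as it would on real barcode data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from scarkit.seqs import Alignment, SeqRecord, SpeciesPanel, revcomp
from scarkit.authenticate import UNIVERSAL_ITS_PRIMERS

_BASES = np.array(list("ACGT"))
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SimulationError(ValueError):
    pass


@dataclass
class PanelSpec:
    """Parameters of a synthetic reference panel.

    Defaults reproduce the divergence structure typical of an ITS panel
    of closely related fungal species: interspecific distances drawn to
    land in 0.09-0.21 substitutions/site, intraspecific in 0-0.003.
    """

    seed: int
    n_species: int = 6
    n_per_species: int = 3
    length: int = 580
    inter_divergence: tuple[float, float] = (0.09, 0.21)
    intra_divergence: tuple[float, float] = (0.0, 0.003)
    n_indels_per_species: int = 2
    max_indel_length: int = 12
    ts_tv_ratio: float = 2.0
    gc_fraction: float = 0.58

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        for lo, hi in (self.inter_divergence, self.intra_divergence):
            if not (0 <= lo <= hi <= 1):
                raise SimulationError("divergence bounds must satisfy 0 <= lo <= hi <= 1")
        if self.inter_divergence[1] * self.length > self.length:
            raise SimulationError("divergence target incompatible with length")
        if self.n_species < 2 or self.n_per_species < 1:
            raise SimulationError("need >=2 species and >=1 record per species")


@dataclass
class GroundTruth:
    """Everything the generator knows about a panel."""

    spec: dict
    species_branch_lengths: dict[str, float]
    species_mutations: dict[str, list[tuple[int, str, str]]]   # (column, from, to)
    species_deletions: dict[str, list[tuple[int, int]]]        # (column, length)
    individual_mutations: dict[str, list[tuple[int, str, str]]]
    diagnostic_columns: dict[str, list[int]]                   # per species, from species-level states
    flank_lengths: tuple[int, int] = (0, 0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, columns: np.ndarray, ts_tv_ratio: float):
    """Substitute at the given columns; returns list of (col, old, new)."""
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    events = []
    for col in columns:
        old = seq[col]
        if old == "-":
            continue
        if rng.random() < p_ts:
            new = _TRANSITION[old]
        else:
            tv = [b for b in "ACGT" if b != old and b != _TRANSITION[old]]
            new = tv[rng.integers(0, 2)]
        seq[col] = new
        events.append((int(col), str(old), str(new)))
    return events


def generate_panel(spec: PanelSpec) -> tuple[SpeciesPanel, GroundTruth]:
    """Generate a labelled, aligned panel plus full ground truth.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    FASTA output.
    """
    rng = np.random.default_rng(spec.seed)
    core = _random_sequence(rng, spec.length, spec.gc_fraction)
    left = np.array(list(UNIVERSAL_ITS_PRIMERS[0]))
    right = np.array(list(revcomp(UNIVERSAL_ITS_PRIMERS[1])))
    ancestor = np.concatenate([left, core, right])
    lo_core, hi_core = len(left), len(left) + spec.length   # mutable region
    mutable = np.arange(lo_core, hi_core)

    species_names = [f"sp{i + 1:02d}" for i in range(spec.n_species)]
    lo, hi = spec.inter_divergence
    branch = {sp: float(rng.uniform(lo / 2, hi / 2)) for sp in species_names}

    species_seqs: dict[str, np.ndarray] = {}
    truth_mut: dict[str, list] = {}
    truth_del: dict[str, list] = {}
    for sp in species_names:
        seq = ancestor.copy()
        n_sub = int(round(branch[sp] * spec.length))
        cols = rng.choice(mutable, size=min(n_sub, spec.length), replace=False)
        truth_mut[sp] = _mutate(rng, seq, np.sort(cols), spec.ts_tv_ratio)
        dels = []
        for _ in range(spec.n_indels_per_species):
            dlen = int(rng.integers(1, spec.max_indel_length + 1))
            start = int(rng.integers(lo_core, hi_core - dlen))
            seq[start : start + dlen] = "-"
            dels.append((start, dlen))
        truth_del[sp] = dels
        species_seqs[sp] = seq

    # diagnostic columns from the species-level (pre-individual) states
    diag: dict[str, list[int]] = {sp: [] for sp in species_names}
    mat = np.stack([species_seqs[sp] for sp in species_names])
    for col in range(mat.shape[1]):
        states = mat[:, col]
        for i, sp in enumerate(species_names):
            if all(states[j] != states[i] for j in range(len(species_names)) if j != i):
                diag[sp].append(col)

    records: list[SeqRecord] = []
    truth_ind: dict[str, list] = {}
    ilo, ihi = spec.intra_divergence
    for sp in species_names:
        for k in range(spec.n_per_species):
            rid = f"{sp}_{k + 1}"
            seq = species_seqs[sp].copy()
            d_ind = float(rng.uniform(ilo, ihi))
            n_sub = int(round(d_ind * spec.length))
            if n_sub:
                cols = rng.choice(mutable, size=n_sub, replace=False)
                truth_ind[rid] = _mutate(rng, seq, np.sort(cols), spec.ts_tv_ratio)
            else:
                truth_ind[rid] = []
            records.append(SeqRecord(id=rid, bases="".join(seq), species=sp))

    panel = SpeciesPanel(Alignment(records))
    truth = GroundTruth(
        spec=asdict(spec),
        species_branch_lengths=branch,
        species_mutations=truth_mut,
        species_deletions=truth_del,
        individual_mutations=truth_ind,
        diagnostic_columns=diag,
        flank_lengths=(len(left), len(right)),
    )
    return panel, truth


def generate_sample(
    panel: SpeciesPanel,
    species: str,
    n_private_mutations: int = 0,
    seed: int = 0,
    avoid_regions: list[tuple[int, int]] | None = None,
    sample_id: str | None = None,
) -> SeqRecord:
    """An ungapped query sequence derived from one panel member of
    ``species`` with private substitutions added.

    ``avoid_regions`` are (start, end) intervals on the ungapped sequence
    (e.g. primer footprints) that private mutations must not touch. The
    conserved flanks carrying the universal-primer sites are always kept
    intact (they emulate the invariant rRNA ends of a real barcode).
    """
    rng = np.random.default_rng(seed)
    source = panel.reference_of(species)
    seq = np.array(list(source.ungapped))
    allowed = np.ones(len(seq), dtype=bool)
    bases = "".join(seq)
    if bases.startswith(UNIVERSAL_ITS_PRIMERS[0]):
        allowed[: len(UNIVERSAL_ITS_PRIMERS[0])] = False
    if bases.endswith(revcomp(UNIVERSAL_ITS_PRIMERS[1])):
        allowed[len(bases) - len(UNIVERSAL_ITS_PRIMERS[1]) :] = False
    for start, end in avoid_regions or []:
        allowed[start:end] = False
    idx = np.nonzero(allowed)[0]
    if n_private_mutations > len(idx):
        raise SimulationError("not enough mutable positions outside avoided regions")
    if n_private_mutations:
        cols = rng.choice(idx, size=n_private_mutations, replace=False)
        _mutate(rng, seq, np.sort(cols), 2.0)
    return SeqRecord(
        id=sample_id or f"{species}_sample_s{seed}",
        bases="".join(seq),
        species="unknown",
    )


def generate_dilution_series(
    true_slope: float,
    intercept: float,
    quantities: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
):
    """A dilution series with Ct = intercept + slope*log10(q) + N(0, sd)."""
    from scarkit.qpcr import DilutionSeries

    rng = np.random.default_rng(seed)
    pts = []
    for q in quantities:
        ct = intercept + true_slope * np.log10(q)
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        pts.append((float(q), float(ct)))
    return DilutionSeries(label=label, points=pts)
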