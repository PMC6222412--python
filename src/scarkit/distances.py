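"""Pairwise evolutionary distances and divergence summaries.

Implements the p-distance and Kimura two-parameter (K2P) distance with
pairwise deletion: for each sequence pair only the columns where both
sequences carry an unambiguous base (A/C/G/T) are compared; gaps,
ambiguity codes and N are excluded per pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scarkit.seqs import Alignment, SeqRecord, SequenceError, SpeciesPanel, gc_content

# integer codes for the vectorised distance kernel; >=4 means "not comparable"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceError(ValueError):
    """Raised when a distance is undefined for a sequence pair."""


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Integer-encode an alignment: A,C,G,T -> 0..3, anything else -> 4."""
    n, length = len(alignment), alignment.aligned_length
    mat = np.full((n, length), 4, dtype=np.int8)
    for i, rec in enumerate(alignment):
        for j, ch in enumerate(rec.bases):
            mat[i, j] = _CODE.get(ch, 4)
    return mat


@dataclass(frozen=True)
class PairDistance:
    d: float
    P: float  # transition proportion
    Q: float  # transversion proportion
    L: int    # jointly comparable sites


def _pair_from_codes(a: np.ndarray, b: np.ndarray, model: str) -> PairDistance:
    usable = (a < 4) & (b < 4)
    L = int(usable.sum())
    if L == 0:
        raise DistanceError("no comparable sites")
    aa, bb = a[usable], b[usable]
    diff = aa != bb
    # transitions: A<->G (0,2) and C<->T (1,3); everything else differing is a transversion
    ts = diff & (((aa == 0) & (bb == 2)) | ((aa == 2) & (bb == 0)) | ((aa == 1) & (bb == 3)) | ((aa == 3) & (bb == 1)))
    P = float(ts.sum()) / L
    Q = float(diff.sum() - ts.sum()) / L
    if model == "p":
        return PairDistance(P + Q, P, Q, L)
    if model == "k2p":
        arg = (1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q) if Q < 0.5 else 0.0
        if arg <= 0.0:
            raise DistanceError("distance undefined (saturation)")
        return PairDistance(-0.5 * math.log(arg), P, Q, L)
    raise ValueError(f"unknown model {model!r}")


def pairwise_distance(a: SeqRecord, b: SeqRecord, model: str = "k2p") -> PairDistance:
    """Distance between two aligned sequences under the p or K2P model.

    K2P: d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P (transitions) and
    Q (transversions) computed over the jointly unambiguous columns.
    """
    if len(a) != len(b):
        raise SequenceError("sequences must be aligned to equal length")
    ca = np.fromiter((_CODE.get(ch, 4) for ch in a.bases), dtype=np.int8, count=len(a))
    cb = np.fromiter((_CODE.get(ch, 4) for ch in b.bases), dtype=np.int8, count=len(b))
    return _pair_from_codes(ca, cb, model)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    L: np.ndarray
    model: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """Square PHYLIP matrix (names truncated/padded to 10 chars)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for name, row in zip(self.labels, self.d):
                fh.write(f"{name[:10]:<10}" + " ".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(alignment: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix with pairwise deletion."""
    codes = encode_alignment(alignment)
    return distance_matrix_from_codes(codes, [r.id for r in alignment], model)


def distance_matrix_from_codes(codes: np.ndarray, labels: list[str], model: str = "k2p") -> DistanceMatrix:
    n = codes.shape[0]
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    L = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            pr = _pair_from_codes(codes[i], codes[j], model)
            d[i, j] = d[j, i] = pr.d
            P[i, j] = P[j, i] = pr.P
            Q[i, j] = Q[j, i] = pr.Q
            L[i, j] = L[j, i] = pr.L
    return DistanceMatrix(list(labels), d, P, Q, L, model)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    # population SD (n denominator), the convention of the usual
    # barcode-variability reports
    return float(arr.mean()), float(arr.std(ddof=0))


def variability_summary(
    panel: SpeciesPanel,
    model: str = "k2p",
    inter_mode: str = "all_pairs",
) -> pd.DataFrame:
    """Per-species intra- and interspecific variability table.

    For each species: mean +/- SD of distances over conspecific pairs
    (NaN when the species has a single record) and over all pairs with
    one member in the species and one outside (``inter_mode="all_pairs"``)
    or the mean over species-pair means (``inter_mode="species_means"``).
    Also reports each species' ungapped length and GC%.
    """
    dm = distance_matrix(panel.alignment, model)
    idx = {label: k for k, label in enumerate(dm.labels)}
    rows = []
    species_list = panel.species
    for sp in species_list:
        members = [idx[r.id] for r in panel.records_of(sp)]
        others = [idx[r.id] for r in panel.alignment if r.species != sp]
        intra = [dm.d[i, j] for a, i in enumerate(members) for j in members[a + 1:]]
        if inter_mode == "all_pairs":
            inter = [dm.d[i, j] for i in members for j in others]
        elif inter_mode == "species_means":
            inter = []
            for other_sp in species_list:
                if other_sp == sp:
                    continue
                other_members = [idx[r.id] for r in panel.records_of(other_sp)]
                inter.append(float(np.mean([dm.d[i, j] for i in members for j in other_members])))
        else:
            raise ValueError(f"unknown inter_mode {inter_mode!r}")
        intra_mean, intra_sd = _mean_sd(intra) if intra else (math.nan, math.nan)
        inter_mean, inter_sd = _mean_sd(inter)
        ref_lengths = [len(r.ungapped) for r in panel.records_of(sp)]
        gc = float(np.mean([gc_content(r.ungapped) for r in panel.records_of(sp)]))
        rows.append(
            {
                "species": sp,
                "n_records": len(members),
                "constant_length": int(round(float(np.mean(ref_lengths)))),
                "aligned_length": panel.alignment.aligned_length,
                "intra_mean": intra_mean,
                "intra_sd": intra_sd,
                "inter_mean": inter_mean,
                "inter_sd": inter_sd,
                "gc_percent": 100.0 * gc,
            }
        )
    return pd.DataFrame(rows).set_index("species")
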