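"""Pairwise p-distance and Kimura 2-parameter (K2P) distance.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T; proportion P) and transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Columns containing a gap or an ambiguous base in either sequence are excluded
before P and Q are computed (pairwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SaturationError, UndefinedDistanceError, ValidationError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class AlignedPair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValidationError(
                f"aligned sequences differ in length: {self.id_a} "
                f"({len(self.seq_a)}) vs {self.id_b} ({len(self.seq_b)})"
            )
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()


@dataclass
class PairwiseDistance:
    id_a: str
    id_b: str
    n: int
    P: float
    Q: float
    p_dist: float
    k2p: float


def site_classes(pair: AlignedPair) -> tuple[int, float, float]:
    """(n, P, Q): compared-column count, transition and transversion
    proportions under pairwise deletion of gapped/ambiguous columns."""
    n = ts = tv = 0
    for x, y in zip(pair.seq_a, pair.seq_b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise UndefinedDistanceError(
            f"{pair.id_a} vs {pair.id_b}: no comparable columns"
        )
    return n, ts / n, tv / n


def k2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(P, Q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_distance(pair: AlignedPair) -> PairwiseDistance:
    n, P, Q = site_classes(pair)
    return PairwiseDistance(pair.id_a, pair.id_b, n, P, Q, P + Q, k2p(P, Q))


def distance_matrix(seqs: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-all K2P distances for a set of equal-length aligned sequences.

    Returns ``(matrix, long)``: a symmetric zero-diagonal DataFrame of K2P
    distances (NaN for saturated/undefined pairs, which are flagged in the
    long table rather than raised) and a long-format table with columns
    id_a, id_b, n, P, Q, p_dist, k2p, flag.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValidationError("distance_matrix: need at least two sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError(
            f"aligned sequences must share one length, got {sorted(lengths)}"
        )
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            flag = ""
            try:
                d = pairwise_distance(AlignedPair(a, b, seqs[a], seqs[b]))
                row = {"id_a": a, "id_b": b, "n": d.n, "P": d.P, "Q": d.Q,
                       "p_dist": d.p_dist, "k2p": d.k2p}
                mat.loc[a, b] = mat.loc[b, a] = d.k2p
            except (SaturationError, UndefinedDistanceError) as exc:
                flag = type(exc).__name__
                row = {"id_a": a, "id_b": b, "n": np.nan, "P": np.nan,
                       "Q": np.nan, "p_dist": np.nan, "k2p": np.nan}
                mat.loc[a, b] = mat.loc[b, a] = np.nan
            row["flag"] = flag
            rows.append(row)
    return mat, pd.DataFrame(rows)


def write_phylip(mat: pd.DataFrame, path, decimals: int = 5) -> None:
    """PHYLIP-style square distance matrix (names truncated to 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(mat)}\n")
        for name in mat.index:
            vals = " ".join(
                "NA" if pd.isna(v) else f"{v:.{decimals}f}"
                for v in mat.loc[name]
            )
            fh.write(f"{str(name)[:10]:<10} {vals}\n")
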