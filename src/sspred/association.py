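"""Pairwise nucleotide association within aligned motif sets.

For N aligned motifs of length P, the occurrence of base ``s`` at position
``i`` in motif ``k`` is an indicator variable I(x_ik = s).  The association
between base ``s`` at position ``i`` and base ``t`` at a *different*
position ``j`` is the normalised co-occurrence count

    a_ij(s, t) = n_ij(s, t) / sqrt(n_i(s) * n_j(t)),

which ranges from 0 (the two bases never co-occur) to 1 (complete
association: every motif carrying s at i carries t at j and vice versa).

Within a position (i == j) the bases of a motif are mutually exclusive, so
the association follows the correlation of multinomial indicator variables:

    a_ii(s, t) = 1                                          if s == t
    a_ii(s, t) = -sqrt( n_i(s)*n_i(t) / ((N-n_i(s))*(N-n_i(t))) )  otherwise,

which equals -sqrt(p_s p_t / ((1-p_s)(1-p_t))) with p = count/N and lies in
[-1, 0].

Assembling a_ij(s, t) over all positions and bases gives a 4P x 4P matrix
indexed by *units* u = 4*(position-1) + base_rank (1-based; base order
A, T, G, C), the object rendered as a heat map to choose the modeling
window: strongly associated units cluster around the splice junction in
true sites and are absent in false ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BASES, BASE_TO_INDEX, AlignedMotifSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndicatorCounts:
    """Exact indicator counts underlying the association and SAE models.

    ``single[i, s]`` is the number of motifs carrying base ``s`` at
    position ``i``; ``joint[i, j, s, t]`` the number carrying ``s`` at
    ``i`` *and* ``t`` at ``j``.  Diagonal blocks satisfy
    ``joint[i, i, s, t] == single[i, s] * (s == t)`` because bases at one
    position are mutually exclusive.
    """

    N: int
    single: np.ndarray  # (P, 4) int
    joint: np.ndarray  # (P, P, 4, 4) int

    @property
    def P(self) -> int:
        return self.single.shape[0]


@dataclass(frozen=True)
class AssociationMatrix:
    """4P x 4P association values indexed by (position, base) units."""

    P: int
    values: np.ndarray  # (4P, 4P) float, NaN marks degenerate cells

    def unit_label(self, u: int) -> str:
        """Label for 0-based row/column index ``u``: ``pos<i>:<base>`` (1-based)."""
        return f"pos{u // 4 + 1}:{BASES[u % 4]}"

    @property
    def labels(self) -> list[str]:
        return [self.unit_label(u) for u in range(4 * self.P)]


def unit_index(position: int, base: str) -> int:
    """0-based row/column index of (1-based position, base) in the matrix.

    The 1-based unit number is ``4*(position-1) + rank + 1`` with base order
    A, T, G, C; position 8 therefore spans units 29-32.
    """
    return 4 * (position - 1) + BASE_TO_INDEX[base]


def _encode(motifs: AlignedMotifSet) -> np.ndarray:
    arr = np.frombuffer("".join(motifs.motifs).encode(), dtype=np.uint8)
    arr = arr.reshape(motifs.N, motifs.P)
    lut = np.zeros(256, dtype=np.int64)
    for b, k in BASE_TO_INDEX.items():
        lut[ord(b)] = k
    return lut[arr]


def count_indicators(motifs: AlignedMotifSet) -> IndicatorCounts:
    """Tally single-position and ordered pairwise base counts."""
    if motifs.N < 1:
        raise ValueError("need at least one motif")
    codes = _encode(motifs)
    N, P = codes.shape
    onehot = np.zeros((N, P, 4), dtype=np.int64)
    np.put_along_axis(onehot, codes[:, :, None], 1, axis=2)
    single = onehot.sum(axis=0)
    joint = np.einsum("kis,kjt->ijst", onehot, onehot)
    return IndicatorCounts(N=N, single=single, joint=joint)


def association_offdiag(
    counts: IndicatorCounts, i: int, j: int, s: str, t: str
) -> float:
    """Between-position association a_ij(s, t); positions 0-based, i != j.

    When either marginal count is zero the joint count is necessarily zero
    and the 0/0 form is resolved to 0 (logged as a data-sparsity warning).
    """
    if i == j:
        raise ValueError("i == j: use association_diag for within-position values")
    si, ti = BASE_TO_INDEX[s], BASE_TO_INDEX[t]
    denom = counts.single[i, si] * counts.single[j, ti]
    if denom == 0:
        logger.warning(
            "zero marginal count at (pos %d, %s) or (pos %d, %s); association set to 0",
            i, s, j, t,
        )
        return 0.0
    return float(counts.joint[i, j, si, ti] / math.sqrt(denom))


def association_diag(counts: IndicatorCounts, i: int, s: str, t: str) -> float:
    """Within-position association a_ii(s, t); position 0-based.

    Returns 1 for s == t.  For s != t the value is the multinomial
    indicator correlation; if either base is fixed in all N motifs the
    formula divides by zero and NaN is returned as a flagged missing value.
    """
    if s == t:
        return 1.0
    si, ti = BASE_TO_INDEX[s], BASE_TO_INDEX[t]
    ns, nt = int(counts.single[i, si]), int(counts.single[i, ti])
    N = counts.N
    if ns == N or nt == N:
        return float("nan")
    return -math.sqrt(ns * nt / ((N - ns) * (N - nt)))


def association_matrix(motifs: AlignedMotifSet | IndicatorCounts) -> AssociationMatrix:
    """Assemble the full 4P x 4P association matrix.

    Off-diagonal blocks come from the between-position measure, diagonal
    blocks from the within-position one.  Degenerate within-position cells
    (a base fixed in every motif) are NaN.
    """
    counts = (
        motifs if isinstance(motifs, IndicatorCounts) else count_indicators(motifs)
    )
    if counts.N < 2:
        raise ValueError("association matrix needs N >= 2 motifs")
    N, P = counts.N, counts.P
    single = counts.single.astype(float)

    denom = np.sqrt(single[:, None, :, None] * single[None, :, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        blocks = np.where(denom > 0, counts.joint / np.where(denom > 0, denom, 1.0), 0.0)

    # overwrite diagonal blocks with the multinomial indicator correlation
    for i in range(P):
        ns = single[i]  # (4,)
        with np.errstate(divide="ignore", invalid="ignore"):
            off = -np.sqrt(np.outer(ns, ns) / np.outer(N - ns, N - ns))
        off[~np.isfinite(off)] = np.nan
        np.fill_diagonal(off, 1.0)
        # a zero-count base s != t gives exactly 0 unless the partner is fixed
        blocks[i, i] = off

    values = blocks.transpose(0, 2, 1, 3).reshape(4 * P, 4 * P)
    return AssociationMatrix(P=P, values=values)


def export_matrix(m: AssociationMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with ``pos<i>:<base>`` labels on both axes.

    Full float precision (round-trippable); degenerate cells are blank.
    """
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def load_matrix(path: str | Path) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    side = df.shape[0]
    if side % 4 or df.shape[1] != side:
        raise ValueError(f"{path}: not a 4P x 4P association matrix")
    return AssociationMatrix(P=side // 4, values=df.to_numpy(dtype=float))


def plot_heatmap(m: AssociationMatrix, path: str | Path) -> None:
    """Optional nearest-colour rendering of the matrix (no dendrograms)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(m.values, cmap="viridis", interpolation="nearest")
    ax.set_title(f"Pairwise nucleotide association ({4 * m.P} units)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
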