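"""Dataset preprocessing: redundancy removal, identity profiling, sampling.

Because motif windows are fixed-length and position-aligned, sequence
similarity is plain Hamming identity: score 1 per matching position,
0 per mismatch, reported as a percentage of the window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignedMotifSet


def dedupe(
    tss: AlignedMotifSet, fss: AlignedMotifSet
) -> tuple[AlignedMotifSet, AlignedMotifSet]:
    """Remove duplicates within each class, then TSS motifs from FSS.

    Exact string identity over the modeled core window; the first
    occurrence is kept, order is preserved, and the operation is
    idempotent.  The cross-class step removes from FSS any motif whose
    text occurs in the deduplicated TSS (a window cannot honestly carry
    both labels, and keeping it in FSS would bias evaluation).
    """
    if tss.motifs and fss.motifs and tss.P != fss.P:
        raise ValueError("TSS and FSS motif lengths differ")
    uniq_t = tuple(dict.fromkeys(tss.motifs))
    tset = set(uniq_t)
    uniq_f = tuple(m for m in dict.fromkeys(fss.motifs) if m not in tset)
    return (
        AlignedMotifSet(uniq_t, "TSS", tss.exon_flank, tss.intron_flank),
        AlignedMotifSet(uniq_f, "FSS", fss.exon_flank, fss.intron_flank),
    )


def similarity(a: str, b: str) -> float:
    """Percent identity between two equal-length motifs (100 * matches / P)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


@dataclass(frozen=True)
class SimilarityProfile:
    """All-vs-all identity distribution of a query set against a target set.

    ``levels`` are the achievable identity percentages (multiples of
    100/P); ``pair_counts[l]`` the number of (query, target) comparisons
    at that level; ``mean_partners[l]`` the average number of target
    partners per query sequence at that level; ``per_query_max`` the
    maximal identity each query attains against any target.
    """

    levels: np.ndarray
    pair_counts: np.ndarray
    mean_partners: np.ndarray
    per_query_max: np.ndarray
    n_query: int
    n_target: int


def similarity_profile(
    query: AlignedMotifSet, target: AlignedMotifSet
) -> SimilarityProfile:
    """Compare every query motif with every target motif.

    When query and target are the same set (object identity or identical
    motif tuples) the self-comparison at the same index is excluded.
    """
    if query.N == 0 or target.N == 0:
        raise ValueError("empty motif set")
    if query.P != target.P:
        raise ValueError("motif lengths differ")
    P = query.P
    same = query.motifs == target.motifs
    qa = np.frombuffer("".join(query.motifs).encode(), dtype=np.uint8).reshape(
        query.N, P
    )
    ta = np.frombuffer("".join(target.motifs).encode(), dtype=np.uint8).reshape(
        target.N, P
    )
    matches = (qa[:, None, :] == ta[None, :, :]).sum(axis=2)  # (Nq, Nt)
    ident = 100.0 * matches / P
    mask = np.ones_like(ident, dtype=bool)
    if same:
        np.fill_diagonal(mask, False)
    levels = 100.0 * np.arange(P + 1) / P
    vals = ident[mask]
    pair_counts = np.array([(vals == lv).sum() for lv in levels])
    per_query_max = np.where(
        mask.any(axis=1), np.where(mask, ident, -np.inf).max(axis=1), np.nan
    )
    return SimilarityProfile(
        levels=levels,
        pair_counts=pair_counts,
        mean_partners=pair_counts / query.N,
        per_query_max=per_query_max,
        n_query=query.N,
        n_target=target.N,
    )


def sample_imbalanced(
    tss: AlignedMotifSet,
    fss: AlignedMotifSet,
    ratio: float,
    seed: int | None = None,
) -> tuple[AlignedMotifSet, AlignedMotifSet]:
    """Draw an FSS subsample of size round(ratio * N_tss) without replacement.

    ``ratio`` >= 1 is the FSS:TSS multiple (1 gives a balanced dataset);
    the subsample is uniform over the available FSS and reproducible from
    ``seed``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_take = int(np.rint(ratio * tss.N))
    if n_take > fss.N:
        raise ValueError(
            f"need {n_take} FSS motifs for ratio {ratio} but only {fss.N} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(fss.N, size=n_take, replace=False)
    sub = tuple(fss.motifs[i] for i in sorted(idx))
    return tss, AlignedMotifSet(sub, fss.label, fss.exon_flank, fss.intron_flank)
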