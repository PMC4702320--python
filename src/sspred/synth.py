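"""Synthetic donor-site motif and gene generation.

True-site (TSS) motifs are drawn position-wise from a donor-like profile
and then pairwise couplings are injected: for a coupling (i, j, mapping,
strength), each motif independently has its base at ``j`` overwritten by
``mapping[base at i]`` with probability ``strength``.  This is the
simplest mechanism that produces tunable, analytically checkable pairwise
dependence without committing to a full joint model.  False-site (FSS)
motifs are i.i.d. draws from a single background composition — GT-bearing
windows with no signal.

The default TSS profile is a donor-like consensus loosely shaped after
the canonical (C/A)AG | gt | (A/G)AGT pattern around the excised GT; it is
deliberately generic and not fitted to any real dataset.  What the
generator does NOT emulate: genomic composition heterogeneity, higher-
than-pairwise dependencies, and the empirical base mix of real false
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASES, BASE_TO_INDEX, AlignedMotifSet, MotifWindow


@dataclass(frozen=True)
class Coupling:
    """Overwrite position ``j`` by ``mapping[base at i]`` with prob ``strength``."""

    i: int  # 0-based source position
    j: int  # 0-based target position
    mapping: dict  # base -> base, keys/values in ATGC
    strength: float  # in [0, 1]

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("coupling needs i != j")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        for k, v in self.mapping.items():
            if k not in BASE_TO_INDEX or v not in BASE_TO_INDEX:
                raise ValueError(f"mapping {k!r}->{v!r} outside ACGT")


def _check_dist(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 4 or (p < 0).any() or not np.allclose(p.sum(axis=-1), 1.0):
        raise ValueError(f"{name}: rows must be length-4 distributions summing to 1")
    return p


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic TSS/FSS dataset.

    ``tss_profile`` is (P, 4) in base order A, T, G, C; ``fss_background``
    a single length-4 composition.  Geometry defaults to the 9 bp donor
    window (-3 ~ +6).
    """

    P: int
    tss_profile: np.ndarray
    fss_background: np.ndarray
    couplings: tuple[Coupling, ...] = ()
    n_tss: int = 1000
    n_fss: int = 1000
    seed: int | None = None
    exon_flank: int = 3
    intron_flank: int = 6

    def __post_init__(self) -> None:
        prof = _check_dist(self.tss_profile, "tss_profile")
        if prof.shape != (self.P, 4):
            raise ValueError(f"tss_profile must have shape ({self.P}, 4)")
        bg = _check_dist(self.fss_background, "fss_background")
        object.__setattr__(self, "tss_profile", prof)
        object.__setattr__(self, "fss_background", bg)
        object.__setattr__(self, "couplings", tuple(self.couplings))
        for c in self.couplings:
            if not (0 <= c.i < self.P and 0 <= c.j < self.P):
                raise ValueError("coupling positions outside the window")
        if self.exon_flank + self.intron_flank != self.P:
            raise ValueError("geometry inconsistent with P")


#: Donor-like 9 bp profile (positions -3..-1, +1..+6 around the excised GT),
#: base order A, T, G, C.  Consensus strength ~0.6-0.7 per signal position.
DONOR_PROFILE_9 = np.array(
    [
        [0.35, 0.10, 0.15, 0.40],  # -3: C/A rich
        [0.60, 0.10, 0.15, 0.15],  # -2: A
        [0.10, 0.05, 0.75, 0.10],  # -1: G
        [0.45, 0.05, 0.45, 0.05],  # +1: A/G (R)
        [0.70, 0.10, 0.10, 0.10],  # +2: A
        [0.10, 0.05, 0.75, 0.10],  # +3: G
        [0.15, 0.60, 0.10, 0.15],  # +4: T
        [0.30, 0.25, 0.25, 0.20],  # +5: weak
        [0.25, 0.25, 0.25, 0.25],  # +6: background
    ]
)

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Swap A<->G at the coupled target position; identity elsewhere.
_AG_SWAP = {"A": "G", "G": "A", "T": "T", "C": "C"}


def default_donor_spec(
    n_tss: int = 1000,
    n_fss: int = 1000,
    seed: int | None = None,
    coupling_strength: float = 0.6,
) -> SynthSpec:
    """Donor-like study conditions: 9 bp window, one (+1, +3) coupling.

    The coupling ties the purine choice at +1 to the base at +3, the kind
    of adjacent-signal dependence the association heat map is meant to
    reveal.
    """
    return SynthSpec(
        P=9,
        tss_profile=DONOR_PROFILE_9,
        fss_background=UNIFORM_BACKGROUND,
        couplings=(Coupling(i=3, j=5, mapping=_AG_SWAP, strength=coupling_strength),),
        n_tss=n_tss,
        n_fss=n_fss,
        seed=seed,
    )


def matched_marginal_spec(
    P: int = 9,
    n_tss: int = 1000,
    n_fss: int = 1000,
    seed: int | None = None,
    coupling_strength: float = 0.8,
) -> SynthSpec:
    """Uniform marginals in both classes; only the TSS carries couplings.

    Position-wise frequencies are identical between classes, so any
    independent-position scorer is blind; the pairwise dependency is the
    only signal.  Copy-couplings (identity mapping) preserve the uniform
    marginal at the target position.
    """
    ident = {b: b for b in BASES}
    couplings = (
        Coupling(i=0, j=4, mapping=ident, strength=coupling_strength),
        Coupling(i=2, j=6, mapping=ident, strength=coupling_strength),
        Coupling(i=3, j=7, mapping=ident, strength=coupling_strength),
    )
    return SynthSpec(
        P=P,
        tss_profile=np.tile(UNIFORM_BACKGROUND, (P, 1)),
        fss_background=UNIFORM_BACKGROUND,
        couplings=couplings,
        n_tss=n_tss,
        n_fss=n_fss,
        seed=seed,
        exon_flank=3,
        intron_flank=P - 3,
    )


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int, P: int) -> np.ndarray:
    if probs.ndim == 1:
        probs = np.tile(probs, (P, 1))
    u = rng.random((n, P))
    cum = np.cumsum(probs, axis=1)
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2)


def _decode(codes: np.ndarray) -> tuple[str, ...]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return tuple(
        row.tobytes().decode() for row in lut[codes]
    )


def simulate_motifs(spec: SynthSpec) -> tuple[AlignedMotifSet, AlignedMotifSet]:
    """Draw (TSS, FSS) motif sets under the given study conditions."""
    rng = np.random.default_rng(spec.seed)
    tss_codes = _draw(rng, spec.tss_profile, spec.n_tss, spec.P)
    for c in spec.couplings:
        mapped = np.array([BASE_TO_INDEX[c.mapping[b]] for b in BASES])
        hit = rng.random(spec.n_tss) < c.strength
        tss_codes[hit, c.j] = mapped[tss_codes[hit, c.i]]
    fss_codes = _draw(rng, spec.fss_background, spec.n_fss, spec.P)
    geo = dict(exon_flank=spec.exon_flank, intron_flank=spec.intron_flank)
    return (
        AlignedMotifSet(_decode(tss_codes), "TSS", **geo),
        AlignedMotifSet(_decode(fss_codes), "FSS", **geo),
    )


def simulate_genes(
    n: int,
    length: int,
    planted: list[tuple[int, int, str]],
    exon_flank: int = 3,
    intron_flank: int = 6,
    background: np.ndarray = UNIFORM_BACKGROUND,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Background-composition genes with donor-site motifs spliced in.

    ``planted`` lists (gene_index, start, core_motif): the full motif
    ``core[:exon_flank] + "GT" + core[exon_flank:]`` overwrites the gene
    at 1-based inclusive coordinates [start, start + P + 1].  Returns
    FASTA-ready records and a ground-truth table (gene_id, start, end,
    motif) for end-to-end scan/predict tests.  Overlapping plants in one
    gene raise ``ValueError``.
    """
    P = exon_flank + intron_flank
    rng = np.random.default_rng(seed)
    bg = _check_dist(background, "background")
    codes = _draw(rng, bg, n, length)
    genes = [list(seq) for seq in _decode(codes)]
    rows = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for gi, start, core in planted:
        if len(core) != P:
            raise ValueError(f"core motif {core!r} must have length {P}")
        motif = core[:exon_flank] + "GT" + core[exon_flank:]
        end = start + len(motif) - 1
        if not (1 <= start and end <= length):
            raise ValueError(f"planted motif at {start} does not fit in gene")
        for s0, e0 in occupied.get(gi, []):
            if start <= e0 and end >= s0:
                raise ValueError(
                    f"gene {gi}: planted motifs at {s0} and {start} overlap"
                )
        occupied.setdefault(gi, []).append((start, end))
        genes[gi][start - 1 : end] = motif
        rows.append({"gene_id": f"gene{gi + 1}", "start": start, "end": end,
                     "motif": motif})
    records = [(f"gene{i + 1}", "".join(g)) for i, g in enumerate(genes)]
    truth = pd.DataFrame(rows, columns=["gene_id", "start", "end", "motif"])
    return records, truth
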