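"""Sequence input/output and candidate donor-site scanning.

Donor (5') splice sites carry an almost invariant GT di-nucleotide at the
intron start.  A candidate site is therefore any GT occurrence in a gene;
the *motif window* around it comprises ``exon_flank`` bases 5' of the GT
and ``intron_flank`` bases 3' of it.  The GT itself is perfectly conserved
and carries no discriminative information, so the *modeled core* excludes
it: a window of geometry (3, 6) spans 11 nt on the gene but is modeled as
a 9-mer.

Coordinates are 1-based inclusive over the full motif (GT included),
matching the convention of genome-browser style output tables.  Only the
forward strand is scanned; callers wanting both strands reverse-complement
the gene and rescan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Alphabet order used throughout the package for indexing.
BASES = "ATGC"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
_VALID = frozenset(BASES)


@dataclass(frozen=True)
class MotifWindow:
    """A candidate donor-site window anchored on a GT di-nucleotide.

    ``start``/``end`` are 1-based inclusive coordinates of the full motif
    (GT included) on the gene.  ``core`` is the motif with the two GT bases
    excised — the positions the probability models actually score.
    """

    gene_id: str
    start: int
    end: int
    exon_flank: int
    intron_flank: int
    motif: str

    def __post_init__(self) -> None:
        e = self.exon_flank
        if self.motif[e : e + 2] != "GT":
            raise ValueError(
                f"motif {self.motif!r} lacks GT at offset {e} (exon_flank)"
            )
        if self.end - self.start + 1 != len(self.motif):
            raise ValueError("start/end span does not match motif length")

    @property
    def core(self) -> str:
        """Modeled positions: the motif with the conserved GT removed."""
        e = self.exon_flank
        return self.motif[:e] + self.motif[e + 2 :]


@dataclass(frozen=True)
class AlignedMotifSet:
    """N position-wise aligned, equal-length ACGT motifs with a class label.

    The motifs are modeled cores (GT excluded); ``P`` is the modeled window
    size, equal to ``exon_flank + intron_flank`` when geometry is given.
    ``label`` is ``"TSS"`` (true splice site), ``"FSS"`` (false splice site)
    or ``None``.
    """

    motifs: tuple[str, ...]
    label: str | None = None
    exon_flank: int | None = None
    intron_flank: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        if self.label not in (None, "TSS", "FSS"):
            raise ValueError(f"label must be TSS, FSS or None, got {self.label!r}")
        if self.motifs:
            P = len(self.motifs[0])
            for m in self.motifs:
                if len(m) != P:
                    raise ValueError(
                        f"motif {m!r} has length {len(m)}, expected {P}"
                    )
                bad = set(m) - _VALID
                if bad:
                    raise ValueError(f"motif {m!r} contains non-ACGT {bad}")
            if (
                self.exon_flank is not None
                and self.intron_flank is not None
                and self.exon_flank + self.intron_flank != P
            ):
                raise ValueError(
                    f"geometry ({self.exon_flank},{self.intron_flank}) "
                    f"incompatible with motif length {P}"
                )

    @property
    def N(self) -> int:
        return len(self.motifs)

    @property
    def P(self) -> int:
        if not self.motifs:
            raise ValueError("empty motif set has no defined length")
        return len(self.motifs[0])

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, uppercase_sequence), ...]``.

    Record order is preserved.  A file whose first non-blank line is not a
    FASTA header raises ``ValueError`` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno} is not a FASTA header: {line!r}"
                    )
                break
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def scan_donor_candidates(
    gene: str,
    exon_flank: int,
    intron_flank: int,
    gene_id: str = "seq",
) -> list[MotifWindow]:
    """Scan a gene for GT di-nucleotides with full flanks on both sides.

    One window is emitted per GT occurrence whose ``exon_flank`` upstream
    and ``intron_flank`` downstream bases fit entirely inside the gene.
    Windows containing non-ACGT characters (e.g. N) are skipped; the number
    skipped is reported through the module logger.  A gene too short to
    hold any window yields an empty list.
    """
    if exon_flank < 1 or intron_flank < 1:
        raise ValueError("exon_flank and intron_flank must be >= 1")
    gene = gene.upper()
    out: list[MotifWindow] = []
    skipped = 0
    # GT at 0-based offset o needs o >= exon_flank and o+2+intron_flank <= len
    for o in range(exon_flank, len(gene) - intron_flank - 1):
        if gene[o : o + 2] != "GT":
            continue
        motif = gene[o - exon_flank : o + 2 + intron_flank]
        if set(motif) - _VALID:
            skipped += 1
            continue
        start = o - exon_flank + 1
        out.append(
            MotifWindow(
                gene_id=gene_id,
                start=start,
                end=start + len(motif) - 1,
                exon_flank=exon_flank,
                intron_flank=intron_flank,
                motif=motif,
            )
        )
    if skipped:
        logger.info(
            "%s: skipped %d candidate window(s) containing non-ACGT characters",
            gene_id,
            skipped,
        )
    return out


def load_motif_set(
    path: str | Path,
    expected_P: int | None = None,
    label: str | None = None,
    strict: bool = True,
    exon_flank: int | None = None,
    intron_flank: int | None = None,
) -> AlignedMotifSet:
    """Load aligned motifs from plain text (one motif per line) or FASTA.

    All motifs must share one length, equal to ``expected_P`` when given.
    Non-ACGT characters raise in strict mode (the default); in lenient mode
    the offending motifs are skipped with a logged count.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        raw = [(rid, seq) for rid, seq in read_fasta(path)]
    else:
        raw = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if s:
                    raw.append((f"line {lineno}", s.upper()))

    motifs: list[str] = []
    skipped = 0
    for name, seq in raw:
        if expected_P is not None and len(seq) != expected_P:
            raise ValueError(
                f"{path}: record {name}: length {len(seq)} != expected {expected_P}"
            )
        if motifs and len(seq) != len(motifs[0]):
            raise ValueError(
                f"{path}: record {name}: length {len(seq)} != {len(motifs[0])}"
            )
        if set(seq) - _VALID:
            if strict:
                raise ValueError(f"{path}: record {name}: non-ACGT character")
            skipped += 1
            continue
        motifs.append(seq)
    if skipped:
        logger.info("%s: skipped %d motif(s) with non-ACGT characters", path, skipped)
    return AlignedMotifSet(
        motifs=tuple(motifs),
        label=label,
        exon_flank=exon_flank,
        intron_flank=intron_flank,
    )


def save_motif_set(motifs: AlignedMotifSet, path: str | Path) -> None:
    """Write one motif per line."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(m + "\n")
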