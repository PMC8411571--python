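"""Degenerate IUPAC consensus matching and strand-aware motif scanning.

The screen's two consensi are the AP-1 binding motif, TGANTCA, and the
canonical palindromic ecdysone-response element (EcRE) of the
RGGTCANTGACCY type. Both are their own reverse complement at the level of
IUPAC codes, so each genomic span carrying a match is reported exactly once
(double counting would inflate the "at least four AP-1 motifs" filter).

Matching semantics:

* a genome base matches a motif position iff it is A/C/G/T and lies in the
  position's allowed set;
* a genome N matches **no** motif position, including motif N — a site that
  cannot be confirmed from sequence is never counted;
* overlapping occurrences are all reported; no exclusion rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .io_formats import GenomicInterval, GenomeSequence

#: IUPAC code -> set of concrete bases it allows
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: code-level complementation (complement(R)=Y, complement(N)=N, ...)
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    seq = seq.upper()
    bad = set(seq) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    """A named degenerate consensus with per-position allowed-base sets."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        object.__setattr__(self, "consensus", consensus)
        if not consensus:
            raise ValueError("empty consensus")
        bad = set(consensus) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: invalid IUPAC codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)

    @cached_property
    def compiled(self) -> tuple[frozenset[str], ...]:
        """Per-position sets of allowed concrete bases."""
        return tuple(frozenset(IUPAC_CODES[c]) for c in self.consensus)

    def is_palindromic(self) -> bool:
        """True iff the consensus equals its code-level reverse complement."""
        return reverse_complement(self.consensus) == self.consensus

    def reverse_complemented(self) -> "IupacMotif":
        return IupacMotif(self.name, reverse_complement(self.consensus))


#: the AP-1 binding motif consensus
AP1_MOTIF = IupacMotif("AP-1", "TGANTCA")

#: default EcRE consensus (canonical hsp27-derived palindrome); the exact
#: string is a configurable assumption — see the methods note
ECRE_MOTIF = IupacMotif("EcRE", "RGGTCANTGACCY")

DEFAULT_MOTIFS: dict[str, IupacMotif] = {m.name: m for m in (AP1_MOTIF, ECRE_MOTIF)}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, reported as a plus-strand genomic span."""

    motif_name: str
    interval: GenomicInterval
    strand: str
    matched_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"hit strand must be + or -, got {self.strand!r}")
        if self.interval.length() != len(self.matched_seq):
            raise ValueError("matched_seq length differs from interval length")


def match_at(motif: IupacMotif, seq: str, offset: int) -> bool:
    """True iff *motif* matches *seq* at *offset* on the plus strand."""
    if offset < 0 or offset + len(motif) > len(seq):
        raise ValueError(
            f"offset {offset} leaves motif of length {len(motif)} outside "
            f"sequence of length {len(seq)}"
        )
    for allowed, base in zip(motif.compiled, seq[offset : offset + len(motif)]):
        if base not in allowed or base not in "ACGT":
            return False
    return True


def _match_offsets(motif: IupacMotif, arr: np.ndarray) -> np.ndarray:
    """Vectorized plus-strand match test at every offset of a uint8 sequence.

    Lookup tables are built from concrete bases only, so a genome N (or any
    other byte) fails every position automatically.
    """
    n_off = arr.size - len(motif) + 1
    if n_off <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n_off, dtype=bool)
    for j, allowed in enumerate(motif.compiled):
        table = np.zeros(256, dtype=bool)
        for base in allowed:
            table[ord(base)] = True
        ok &= table[arr[j : j + n_off]]
    return ok


def scan_sequence(
    motif: IupacMotif,
    seq: str,
    chrom: str = "seq",
    origin: int = 0,
) -> list[MotifHit]:
    """Find every occurrence of *motif* in *seq*, both strands.

    Matches are reported as plus-strand spans sorted by start. For a
    palindromic motif each genomic span appears exactly once (strand ``+``);
    for a non-palindromic motif, plus- and minus-strand matches at the same
    span are distinct hits. A motif longer than the sequence yields an empty
    list. ``chrom``/``origin`` place the hits in genome coordinates.
    """
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[tuple[int, str]] = [
        (int(i), "+") for i in np.nonzero(_match_offsets(motif, arr))[0]
    ]
    if not motif.is_palindromic():
        rc = motif.reverse_complemented()
        hits += [(int(i), "-") for i in np.nonzero(_match_offsets(rc, arr))[0]]
    hits.sort(key=lambda h: (h[0], h[1]))
    length = len(motif)
    return [
        MotifHit(
            motif_name=motif.name,
            interval=GenomicInterval(chrom, origin + i, origin + i + length),
            strand=strand,
            matched_seq=seq[i : i + length],
        )
        for i, strand in hits
    ]


def count_in_region(
    motif: IupacMotif, genome: GenomeSequence, interval: GenomicInterval
) -> int:
    """Number of motif occurrences fully contained in *interval*.

    Occurrences straddling the region boundary are not counted: the region
    is the unit of the screen.
    """
    seq = genome.fetch(interval)  # raises on out-of-bounds
    if len(seq) < len(motif):
        return 0
    return len(scan_sequence(motif, seq, chrom=interval.chrom, origin=interval.start))
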