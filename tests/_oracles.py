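"""Independent brute-force oracles used to cross-check the production code.

These deliberately avoid the package's vectorized code paths: matching is
naive per-character set membership at every offset, on both strands.
"""

from ecrap1.io_formats import GenomicInterval
from ecrap1.motif_core import IUPAC_CODES, IupacMotif, reverse_complement


def naive_match(consensus: str, sub: str) -> bool:
    if len(consensus) != len(sub):
        return False
    for code, base in zip(consensus, sub):
        if base not in "ACGT" or base not in IUPAC_CODES[code]:
            return False
    return True


def brute_scan(motif: IupacMotif, seq: str) -> list[tuple[int, str]]:
    """All (offset, strand) matches, palindromes deduplicated by span."""
    seq = seq.upper()
    rc = reverse_complement(motif.consensus)
    palindromic = rc == motif.consensus
    hits = []
    for off in range(len(seq) - len(motif.consensus) + 1):
        sub = seq[off : off + len(motif.consensus)]
        if naive_match(motif.consensus, sub):
            hits.append((off, "+"))
        if not palindromic and naive_match(rc, sub):
            hits.append((off, "-"))
    hits.sort()
    return hits


def brute_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Shared-base check by explicit coordinate enumeration semantics."""
    if a.chrom != b.chrom:
        return False
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end))) > 0
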