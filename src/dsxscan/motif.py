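"""Mismatch-tolerant consensus motif scanning.

The Doublesex (Dsx) DNA-binding domain is shared by both sex-specific
splice forms, so a single consensus word describes its binding site. The
scanner enumerates the full Hamming-distance neighborhood of the consensus
into a hash set and then checks every fixed-length window of the genome
against it, which makes the scan cost independent of the mismatch budget
once the neighborhood is built.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

#: Dsx consensus binding site (a 13-bp pseudo-palindrome).
DSX_CONSENSUS = "GCAACAATGTTGC"

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GenomeLike = Union[str, PathLike, Mapping[str, str]]


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strings.

    Case-insensitive; raises ``ValueError`` on unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError(
            f"hamming distance requires equal lengths ({len(a)} != {len(b)})"
        )
    a = a.upper()
    b = b.upper()
    return sum(x != y for x, y in zip(a, b))


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N->N)."""
    s = s.upper()
    if not _DNA_N.issuperset(s):
        bad = sorted(set(s) - _DNA_N)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """Consensus word plus the mismatch tolerance driving the scan.

    Parameters
    ----------
    consensus
        Uppercase ACGT word; defaults to the Dsx consensus.
    max_mismatches
        Hamming-distance budget; a window matches when its distance to the
        consensus is at most this value. Must be < len(consensus).
    scan_both_strands
        When set, each window is additionally compared on the reverse
        strand. Off by default: the described search hashes raw genome
        words only, and the pseudo-palindromic consensus makes exact
        reverse-strand occurrences visible anyway at one mismatch.
    """

    consensus: str = DSX_CONSENSUS
    max_mismatches: int = 1
    scan_both_strands: bool = False

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        if self.consensus != self.consensus.upper() or not _DNA.issuperset(
            self.consensus
        ):
            raise ValueError("consensus must be uppercase ACGT-only")
        if not 0 <= self.max_mismatches < len(self.consensus):
            raise ValueError(
                "max_mismatches must satisfy 0 <= d < len(consensus); got "
                f"d={self.max_mismatches}, len={len(self.consensus)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    """One genomic match: half-open 0-based interval plus the matched word.

    ``word`` is the motif-strand word: the genome substring for ``+`` hits
    and its reverse complement for ``-`` hits.
    """

    scaffold: str
    start: int
    end: int
    strand: str
    word: str
    mismatches: int


def generate_neighborhood(motif: MotifSpec) -> frozenset[str]:
    """All ACGT words within ``max_mismatches`` of the consensus.

    Size follows the closed form sum_{i<=d} C(k,i) * 3^i for a k-mer; at
    d=1 and k=13 this is the consensus plus 39 single-base alternatives.
    """
    consensus = motif.consensus
    k = len(consensus)
    words = {consensus}
    for d in range(1, motif.max_mismatches + 1):
        for positions in itertools.combinations(range(k), d):
            alternatives = [
                [b for b in "ACGT" if b != consensus[p]] for p in positions
            ]
            for combo in itertools.product(*alternatives):
                w = list(consensus)
                for p, b in zip(positions, combo):
                    w[p] = b
                words.add("".join(w))
    return frozenset(words)


def neighborhood_size(k: int, d: int) -> int:
    """Closed-form neighborhood size for a k-mer at distance <= d."""
    from math import comb

    return sum(comb(k, i) * 3**i for i in range(d + 1))


def iter_scaffolds(genome: GenomeLike) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs from a FASTA path or an in-memory dict."""
    if isinstance(genome, Mapping):
        yield from genome.items()
        return
    import pyfaidx

    path = Path(genome)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    fasta = pyfaidx.Fasta(str(path), rebuild=True)
    try:
        for name in fasta.keys():
            yield name, str(fasta[name])
    finally:
        fasta.close()


def scan_genome(genome: GenomeLike, motif: MotifSpec) -> list[MotifHit]:
    """Report every window within the mismatch budget of the consensus.

    Sequence is uppercased before matching (soft-masking is ignored);
    windows containing non-ACGT characters never match; overlapping hits
    are all kept. Output is sorted by (scaffold, start, strand). With
    ``scan_both_strands`` a window may match on both strands and then
    yields two hits.
    """
    hood = generate_neighborhood(motif)
    consensus = motif.consensus
    k = len(consensus)
    hits: list[MotifHit] = []
    for name, seq in iter_scaffolds(genome):
        s = str(seq).upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if w in hood:
                hits.append(
                    MotifHit(name, i, i + k, "+", w, hamming(w, consensus))
                )
            if motif.scan_both_strands and _DNA.issuperset(w):
                rc = reverse_complement(w)
                if rc in hood:
                    hits.append(
                        MotifHit(name, i, i + k, "-", rc, hamming(rc, consensus))
                    )
    hits.sort(key=lambda h: (h.scaffold, h.start, h.strand))
    return hits


def write_hits_bed(hits: Iterable[MotifHit], path: Union[str, PathLike]) -> None:
    """Write hits as 6-column BED: chrom, start, end, word, mismatches, strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.scaffold}\t{h.start}\t{h.end}\t{h.word}\t{h.mismatches}\t{h.strand}\n"
            )


def read_hits_bed(path: Union[str, PathLike]) -> list[MotifHit]:
    """Read a BED file written by :func:`write_hits_bed`."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            scaf, start, end, word, score, strand = fields
            hits.append(
                MotifHit(scaf, int(start), int(end), strand, word, int(score))
            )
    return hits
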