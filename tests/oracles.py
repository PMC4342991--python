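"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the scanner oracle
recomputes a Hamming distance for every window directly, the neighborhood
oracle filters the full k-mer space, the proximity oracle enumerates all
(hit, gene) pairs, and the t-test oracle applies the textbook pooled
formula with the t survival function.
"""

import itertools
import math

import numpy as np
from scipy import special

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(s):
    return "".join(_COMP[b] for b in reversed(s.upper()))


def hamming_oracle(a, b):
    return sum(1 for x, y in zip(a.upper(), b.upper()) if x != y)


def neighborhood_oracle(consensus, d):
    """All k-mers within distance d, by filtering the full 4^k space (k small)."""
    k = len(consensus)
    return {
        "".join(w)
        for w in itertools.product("ACGT", repeat=k)
        if hamming_oracle("".join(w), consensus) <= d
    }


def window_scan_oracle(seq, consensus, max_mismatches, both_strands=False):
    """(start, strand, word, mismatches) for every matching window."""
    seq = seq.upper()
    k = len(consensus)
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        d = hamming_oracle(w, consensus)
        if d <= max_mismatches:
            out.append((i, "+", w, d))
        if both_strands:
            rc = revcomp_oracle(w)
            drc = hamming_oracle(rc, consensus)
            if drc <= max_mismatches:
                out.append((i, "-", rc, drc))
    return out


def window_distances_numpy(seq, consensus):
    """Per-window Hamming distances to the consensus, vectorized.

    Assumes an ACGT-only sequence. Independent of the hash-set scanner:
    every window is compared base by base.
    """
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    motif = np.frombuffer(consensus.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, len(motif))
    return (windows != motif).sum(axis=1)


def proximity_oracle(hits, genes, window_bp):
    """All-pairs interval-gap associations: (gene_id, hit_start, relation, distance)."""
    out = []
    for g in genes:
        for h in hits:
            if h.scaffold != g.scaffold:
                continue
            if h.start < g.end and g.start < h.end:
                out.append((g.gene_id, h.start, "intragenic", 0))
                continue
            if h.end <= g.start:
                gap = g.start - h.end
                side_left = True
            else:
                gap = h.start - g.end
                side_left = False
            if gap > window_bp:
                continue
            if (g.strand == "+") == side_left:
                rel = "upstream"
            else:
                rel = "downstream"
            out.append((g.gene_id, h.start, rel, gap))
    return sorted(out)


def pooled_t_oracle(x, y):
    """Textbook two-sided pooled-variance t-test: (t, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


def hypergeom_tail_oracle(overlap, universe, category, selected):
    """P(X >= overlap) by direct pmf summation with binomial coefficients."""
    total = math.comb(universe, selected)
    num = sum(
        math.comb(category, k) * math.comb(universe - category, selected - k)
        for k in range(overlap, min(category, selected) + 1)
        if selected - k <= universe - category
    )
    return num / total
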