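"""Exhaustive split-alignment oracle, independent of the caller's seed-and-extend.

Scores every (reference, diagonal, split point) triple by dense numpy
comparison under the same scoring contract as the caller (match +1,
mismatch -1, gapless segments) and returns the maximum score together with
the set of optimal junction coordinate pairs. References are rebuilt here
from the gene models with plain loops, so the oracle shares no alignment
machinery with the implementation under test.
"""

import numpy as np

from ftasseq.seqs import revcomp


def oracle_references(genome, models):
    """(seq, gcoords, chrom, strand) for transcripts, intron tails, inverted introns."""
    refs = []
    for gene in models:
        exon_seqs = [gene.exon_seq(i, genome) for i in range(1, gene.n_exons + 1)]
        tseq = "".join(exon_seqs)
        coords = []
        for s, e in gene.exons:
            rng = range(s + 1, e + 1) if gene.strand == "+" else range(e, s, -1)
            coords.extend(rng)
        refs.append((tseq, np.array(coords), gene.chrom, gene.strand))
        for i in range(1, gene.n_exons):
            iseq = gene.intron_seq(i, genome)
            s, e = gene.intron(i)
            irng = list(range(s + 1, e + 1) if gene.strand == "+" else range(e, s, -1))
            t0 = sum(len(x) for x in exon_seqs[:i])
            refs.append((iseq + tseq[t0:], np.array(irng + coords[t0:]),
                         gene.chrom, gene.strand))
            inv_strand = "-" if gene.strand == "+" else "+"
            refs.append((revcomp(iseq), np.array(irng[::-1]), gene.chrom, inv_strand))
    return refs


def oracle_best_split(insert, anchor_tail, anchor_gcoords, refs, min_seg=10):
    """(max score, set of (bp5, bp3, strand3)) over every split and diagonal."""
    L = len(insert)
    m = np.frombuffer(insert.encode(), dtype=np.uint8)
    n5 = min(L, len(anchor_tail))
    a = np.frombuffer(anchor_tail.encode(), dtype=np.uint8)[:n5]
    pre = np.concatenate([[0], np.cumsum(m[:n5] != a)])
    score5 = np.arange(n5 + 1) - 2 * pre
    ii = np.arange(min_seg, min(L - min_seg, n5) + 1)
    if ii.size == 0:
        return None, set()
    best_score = None
    best = set()
    for seq, gcoords, chrom, strand in refs:
        # left-pad with a sentinel so negative diagonals (anchor prefix hanging
        # off the reference) are scanned too; the pad never matches any base
        r = np.concatenate([np.zeros(L, dtype=np.uint8),
                            np.frombuffer(seq.encode(), dtype=np.uint8)])
        win = np.lib.stride_tricks.sliding_window_view(r, L)
        eq = win == m  # (n_diag, L); row d = true diagonal d - L
        sfx = np.cumsum(eq[:, ::-1], axis=1)[:, ::-1]  # suffix matches from column j
        tot = score5[ii][None, :] + 2 * sfx[:, ii] - (L - ii)[None, :]
        mx = int(tot.max())
        if best_score is None or mx >= best_score:
            junctions = set()
            for d, j in np.argwhere(tot == mx):
                off = d - L + ii[j]  # reference offset of the first partner base
                if 0 <= off < len(gcoords):
                    junctions.add((int(anchor_gcoords[ii[j] - 1]),
                                   int(gcoords[off]), strand))
            if not junctions:
                continue
            if best_score is None or mx > best_score:
                best_score, best = mx, junctions
            else:
                best |= junctions
    return best_score, best
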