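"""Adapter and quality trimming of paired FTAS-seq reads.

Reproduces the semantics of the read-processing parameters used by the assay:
right-side adapter trimming by seeded k-mer match (k=23 down to 11 at the
read end, one mismatch allowed), right-side quality trimming below Q15,
pair-even trimming when one mate is adapter-trimmed, and discarding of pairs
with a mate shorter than 50 nt or with more than one ambiguous base. The
contract mirrors the stated parameters rather than any particular tool's
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome_model import OTDDN_ADAPTER
from .library_sim import P5_TAIL, R1_PAD, write_fastq
from .seqs import revcomp


def default_adapters() -> tuple[str, ...]:
    """Adapter references: the OTDDN side read by R1, the P5 side read by R2."""
    return (OTDDN_ADAPTER + R1_PAD, revcomp(P5_TAIL))


@dataclass(frozen=True)
class TrimConfig:
    min_length: int = 50
    qtrim_threshold: int = 15
    max_n: int = 1
    adapter_kmer: int = 23
    adapter_min_kmer: int = 11
    adapter_hdist: int = 1
    adapters: tuple[str, ...] = field(default_factory=default_adapters)

    def __post_init__(self):
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.qtrim_threshold < 0 or self.adapter_hdist < 0:
            raise ValueError("thresholds must be non-negative")


def _adapter_trim_pos(seq: str, adapter: str, cfg: TrimConfig) -> Optional[int]:
    """Leftmost position where the adapter starts in ``seq``, or None.

    A full ``adapter_kmer``-length prefix of the adapter may start anywhere;
    shorter prefixes (down to ``adapter_min_kmer``) are only matched flush
    with the read end. One mismatch is allowed (hdist).
    """
    k = min(cfg.adapter_kmer, len(adapter))
    L = len(seq)
    best = None
    if L >= k:
        probe = adapter[:k]
        # exact fast path
        hit = seq.find(probe)
        if hit >= 0:
            best = hit
        elif cfg.adapter_hdist > 0:
            s = np.frombuffer(seq.encode(), dtype=np.uint8)
            a = np.frombuffer(probe.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(s, k)
            mism = (win != a).sum(axis=1)
            idx = np.nonzero(mism <= cfg.adapter_hdist)[0]
            if idx.size:
                best = int(idx[0])
    # short prefixes flush with the read end
    for m in range(min(k - 1, L), cfg.adapter_min_kmer - 1, -1):
        pos = L - m
        if best is not None and best <= pos:
            break
        tail, pre = seq[pos:], adapter[:m]
        mism = sum(1 for x, y in zip(tail, pre) if x != y)
        if mism <= cfg.adapter_hdist:
            best = pos if best is None else min(best, pos)
            break
    return best


def _qtrim_right(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < threshold:
        end -= 1
    return seq[:end], qual[:end]


def trim_pair(r1: str, q1: str, r2: str, q2: str, cfg: TrimConfig
              ) -> tuple[Optional[tuple[str, str, str, str]], str]:
    """Trim one read pair; returns (trimmed pair or None, reason).

    Reason is "ok" for kept pairs, otherwise why the pair was discarded.
    """
    if len(r1) != len(q1) or len(r2) != len(q2):
        raise ValueError("sequence/quality length mismatch")

    trimmed_flag = False
    reads = []
    for seq, qual in ((r1, q1), (r2, q2)):
        cut = None
        for adapter in cfg.adapters:
            pos = _adapter_trim_pos(seq, adapter, cfg)
            if pos is not None:
                cut = pos if cut is None else min(cut, pos)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
            trimmed_flag = True
        seq, qual = _qtrim_right(seq, qual, cfg.qtrim_threshold)
        reads.append((seq, qual))

    if trimmed_flag:
        # pair-even trimming: an adapter hit fixes the insert length for both mates
        n = min(len(reads[0][0]), len(reads[1][0]))
        reads = [(s[:n], q[:n]) for s, q in reads]

    (t1, tq1), (t2, tq2) = reads
    if len(t1) < cfg.min_length or len(t2) < cfg.min_length:
        return None, "too_short"
    if t1.count("N") > cfg.max_n or t2.count("N") > cfg.max_n:
        return None, "too_many_n"
    return (t1, tq1, t2, tq2), "ok"


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    discarded: dict = field(default_factory=dict)


def iter_fastq_pairs(r1_path, r2_path) -> Iterable[tuple[str, str, str, str, str]]:
    """Yield (pair_id, r1, q1, r2, q2); raises on malformed or unpaired input."""
    import gzip

    def opener(p):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    with opener(r1_path) as f1, opener(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        i = 0
        while True:
            try:
                a = next(it1, None)
                b = next(it2, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
            if a is None and b is None:
                return
            if a is None or b is None:
                raise ValueError(f"unpaired FASTQ record at index {i}")
            t1, s1, q1 = a
            t2, s2, q2 = b
            if t1.split()[0] != t2.split()[0]:
                raise ValueError(f"read name mismatch at index {i}: {t1} vs {t2}")
            yield t1.split()[0], s1, q1, s2, q2
            i += 1


def trim_fastq_pair(r1_path, r2_path, out_r1, out_r2, cfg: TrimConfig,
                    discard_log: Optional[Path] = None) -> TrimStats:
    """Trim a FASTQ pair to disk; identical inputs are memoised."""
    stats = TrimStats()
    cache: dict[tuple, tuple] = {}
    out1, out2, log_rows = [], [], []
    for pid, s1, q1, s2, q2 in iter_fastq_pairs(r1_path, r2_path):
        stats.total += 1
        key = (s1, q1, s2, q2)
        res = cache.get(key)
        if res is None:
            res = trim_pair(s1, q1, s2, q2, cfg)
            cache[key] = res
        pair, reason = res
        if pair is None:
            stats.discarded[reason] = stats.discarded.get(reason, 0) + 1
            log_rows.append((pid, reason))
            continue
        stats.kept += 1
        t1, tq1, t2, tq2 = pair
        out1.append((pid, t1, tq1))
        out2.append((pid, t2, tq2))
    write_fastq(out_r1, out1)
    write_fastq(out_r2, out2)
    if discard_log is not None:
        pd.DataFrame(log_rows, columns=["pair_id", "reason"]).to_csv(
            discard_log, sep="\t", index=False)
    return stats
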