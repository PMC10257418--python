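"""Simulation of terminator-assisted semi-targeted library preparation.

The model follows the wet-lab workflow stage by stage: RNA degradation and
reverse transcription into first-strand cDNA spans; linear second-strand
synthesis from a single target-specific primer with chain termination by
adapter-tethered dideoxynucleotides (OTDDNs); nested indexing PCR with
re-anchoring at an inner primer plus size selection; and paired-end
sequencing with substitution errors.

Incorporation competition between a dNTP and its OTDDN analogue is
concentration-proportional with equal efficiency, so the per-incorporation
termination probability in each pyrimidine channel is
``terminator / (terminator + dNTP)``. Only terminator-terminated molecules
carry the tethered adapter and therefore survive indexing PCR; run-off
products have no reverse priming site.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import NESTED_PRIMER, OTDDN_ADAPTER, OUTER_PRIMER
from .seqs import revcomp

# Illumina-style flanks: the i5 adapter tail upstream of the nested primer
# (read by R2 after read-through) and the post-OTDDN i7 side read by R1.
P5_TAIL = "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
R1_PAD = "AACTCCAGTCACACGTACGTATCTCGTATGCCGTCTTCTGCTTG"

_MIN_OVERHANG = 10  # smallest usable insert overhang beyond the nested primer


@dataclass(frozen=True)
class NucleotideMix:
    """Reaction-mix concentrations (µM) of dNTPs and OTDDN terminators."""

    conc_datp: float = 1.0
    conc_dgtp: float = 1.0
    conc_dctp: float = 0.9
    conc_dttp: float = 0.9
    conc_ddc_on: float = 0.1
    conc_ddu_on: float = 0.1

    def __post_init__(self):
        vals = (self.conc_datp, self.conc_dgtp, self.conc_dctp, self.conc_dttp,
                self.conc_ddc_on, self.conc_ddu_on)
        if any(v < 0 for v in vals):
            raise ValueError("concentrations must be non-negative")
        if self.conc_dctp + self.conc_ddc_on <= 0 or self.conc_dttp + self.conc_ddu_on <= 0:
            raise ValueError("each pyrimidine channel needs a positive total concentration")

    @property
    def p_term_c(self) -> float:
        return self.conc_ddc_on / (self.conc_ddc_on + self.conc_dctp)

    @property
    def p_term_t(self) -> float:
        return self.conc_ddu_on / (self.conc_ddu_on + self.conc_dttp)


@dataclass
class LibraryConfig:
    """Everything that defines one library prep + sequencing run."""

    outer_primer: str = OUTER_PRIMER
    nested_primer: str = NESTED_PRIMER
    otddn_adapter: str = OTDDN_ADAPTER
    p5_tail: str = P5_TAIL
    r1_pad: str = R1_PAD
    mix: NucleotideMix = field(default_factory=NucleotideMix)
    extension_cycles: int = 15
    pcr_cycles: int = 20
    pcr_efficiency: float = 0.9
    size_window: tuple[int, int] = (50, 700)
    read_length: int = 150
    substitution_error_rate: float = 0.001
    degradation_rate: float = 0.0
    random_priming_fraction: float = 0.5
    n_molecules: int = 100_000
    depth: int = 100_000
    replicates: int = 2
    base_quality: int = 34
    error_quality: int = 12
    seed: int = 1

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.pcr_efficiency <= 1.0:
            raise ValueError("pcr_efficiency must be in [0, 1]")
        if self.size_window[0] < len(self.nested_primer) + _MIN_OVERHANG:
            raise ValueError("size_window minimum leaves no usable overhang past the nested primer")


@dataclass(frozen=True)
class TranscriptSpec:
    """A pool member: spliced mRNA sequence with a relative abundance."""

    name: str
    sequence: str
    abundance: float
    isoform: Optional[str] = None  # fusion isoform name; None for wild-type/housekeeping


@dataclass(frozen=True)
class SampleConfig:
    name: str
    transcripts: tuple[TranscriptSpec, ...]


@dataclass(frozen=True)
class CdnaSpan:
    """First-strand cDNA covering transcript interval [start, end)."""

    source: int
    start: int
    end: int


@dataclass
class MoleculeRecord:
    """A terminated second-strand product, tracked through the pipeline."""

    source: int
    mol_id: int
    span_start: int
    span_end: int
    ext_start: int      # transcript offset where the outer primer begins
    term_pos: int       # transcript offset (inclusive) of the terminal base
    by_terminator: bool
    insert_start: int = -1  # nested-primer 5' offset, set at re-anchoring
    duplicate_count: int = 1

    @property
    def termination_offset(self) -> int:
        """nt from the nested-primer 5' end to the terminal base."""
        return self.term_pos - self.insert_start

    @property
    def insert_length(self) -> int:
        return self.term_pos - self.insert_start + 1


@dataclass
class ReadPair:
    r1: str
    q1: str
    r2: str
    q2: str
    pair_id: str
    molecule: MoleculeRecord
    dup_index: int


# ---------------------------------------------------------------------------
# stage 1: degradation + reverse transcription


def degrade_and_reverse_transcribe(
    pool: Sequence[TranscriptSpec],
    degradation_rate: float,
    n_molecules: int,
    rng: np.random.Generator | int,
    random_priming_fraction: float = 0.5,
) -> tuple[list[CdnaSpan], np.ndarray]:
    """Sample RNA molecules, fragment them, and reverse transcribe.

    Molecules are drawn multinomially by abundance; each is fragmented by
    independent per-bond breaks at ``degradation_rate``; each fragment is
    reverse transcribed either from a uniform internal priming site (random
    priming) or from its 3' end (oligo-dT-like), yielding cDNA spans in
    transcript coordinates. Returns the spans plus the per-source sampled
    molecule counts (the ground truth for abundance recovery).
    """
    if not pool:
        raise ValueError("empty transcript pool")
    if any(t.abundance <= 0 for t in pool):
        raise ValueError("abundances must be positive")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    probs = np.array([t.abundance for t in pool], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_molecules, probs)

    spans: list[CdnaSpan] = []
    for src, (spec, c) in enumerate(zip(pool, counts)):
        if c == 0:
            continue
        L = len(spec.sequence)
        if degradation_rate <= 0:
            frags = [[(0, L)]] * c
        else:
            frags = []
            for _ in range(c):
                nb = rng.binomial(L - 1, degradation_rate)
                if nb == 0:
                    frags.append([(0, L)])
                else:
                    cuts = np.sort(rng.choice(np.arange(1, L), size=nb, replace=False))
                    bounds = np.concatenate([[0], cuts, [L]])
                    frags.append(list(zip(bounds[:-1], bounds[1:])))
        for pieces in frags:
            for fs, fe in pieces:
                if rng.random() < random_priming_fraction:
                    r = int(rng.integers(fs, fe))
                    spans.append(CdnaSpan(src, fs, r + 1))
                else:
                    spans.append(CdnaSpan(src, fs, fe))
    return spans, counts


# ---------------------------------------------------------------------------
# stage 2: terminator-assisted second-strand synthesis


class _TerminationSampler:
    """Inverse-CDF sampler for the termination position along a template.

    For the sense sequence downstream of the primer, position ``j`` carries a
    termination hazard of ``p_term_c`` (C), ``p_term_t`` (T) or 0 (A/G). The
    walk terminates at the first success; the sampler draws directly from the
    resulting discrete distribution.
    """

    def __init__(self, downstream: str, mix: NucleotideMix):
        arr = np.frombuffer(downstream.encode(), dtype=np.uint8)
        q = np.zeros(len(arr))
        q[arr == ord("C")] = mix.p_term_c
        q[arr == ord("T")] = mix.p_term_t
        surv = np.cumprod(1.0 - q)
        self.cdf = 1.0 - surv  # P(terminated at or before j)
        self.is_pyr = (arr == ord("C")) | (arr == ord("T"))
        self.pyr_cum = np.cumsum(self.is_pyr)

    def sample(self, rng: np.random.Generator, n: int, limit: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` termination offsets; offsets >= limit become run-off.

        Returns (offsets, by_terminator): the offset of the terminal base
        relative to the first extended position, clipped to ``limit - 1`` for
        run-off products.
        """
        lim = len(self.cdf) if limit is None else min(limit, len(self.cdf))
        u = rng.random(n)
        j = np.searchsorted(self.cdf, u, side="right")
        by_term = j < lim
        j = np.where(by_term, j, lim - 1)
        return j.astype(np.int64), by_term

    def pyrimidines_through(self, offsets: np.ndarray) -> np.ndarray:
        """Pyrimidine incorporations in positions [0..offset] inclusive."""
        return self.pyr_cum[offsets]


def extend_with_terminators(
    template: str,
    primer: str,
    mix: NucleotideMix,
    cycles: int,
    rng: np.random.Generator | int,
) -> list[MoleculeRecord]:
    """Linear amplification: one randomly terminated nascent strand per cycle.

    The primer must match the template exactly; a template without the primer
    site yields no products (this is the enrichment mechanism, not an error).
    Extension walks 3'-ward, terminating at each incorporated C or T with the
    mix-derived channel probability, or at the template end.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p0 = template.find(primer)
    if p0 < 0:
        return []
    ext_end = p0 + len(primer)
    sampler = _TerminationSampler(template[ext_end:], mix)
    if len(template) == ext_end:
        return []
    offs, by_term = sampler.sample(rng, cycles)
    return [
        MoleculeRecord(source=-1, mol_id=i, span_start=0, span_end=len(template),
                       ext_start=p0, term_pos=ext_end + int(o), by_terminator=bool(b))
        for i, (o, b) in enumerate(zip(offs, by_term))
    ]


def termination_statistics(template: str, primer: str, records: Iterable[MoleculeRecord],
                           mix: NucleotideMix) -> tuple[int, int]:
    """(total pyrimidine incorporations, terminator-terminated count)."""
    p0 = template.find(primer)
    sampler = _TerminationSampler(template[p0 + len(primer):], mix)
    offs = np.array([r.term_pos - (p0 + len(primer)) for r in records])
    n_pyr = int(sampler.pyrimidines_through(offs).sum())
    n_term = sum(1 for r in records if r.by_terminator)
    return n_pyr, n_term


# ---------------------------------------------------------------------------
# stage 3: nested PCR + size selection


def nested_pcr_and_size_select(
    molecules: Sequence[MoleculeRecord],
    cfg: LibraryConfig,
    rng: np.random.Generator | int,
    pool: Sequence[TranscriptSpec],
) -> list[MoleculeRecord]:
    """Re-anchor at the nested primer, amplify, and size-select.

    Molecules lacking the nested primer site downstream of their 5' end are
    dropped (nested specificity), as are run-off molecules without the
    OTDDN-tethered adapter (no reverse priming site). Survivors are
    re-anchored so the insert begins at the nested primer's 5' position;
    their copy number is drawn from a per-cycle Galton-Watson branching
    process; inserts outside the size window are removed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    npos = {i: spec.sequence.find(cfg.nested_primer) for i, spec in enumerate(pool)}
    nlen = len(cfg.nested_primer)

    anchored: list[MoleculeRecord] = []
    for m in molecules:
        np_ = npos.get(m.source, -1)
        if np_ < 0 or not m.by_terminator:
            continue
        if m.ext_start > np_ or m.term_pos < np_ + nlen - 1:
            continue
        anchored.append(replace(m, insert_start=np_))

    if anchored:
        x = np.ones(len(anchored), dtype=np.int64)
        for _ in range(cfg.pcr_cycles):
            x = x + rng.binomial(x, cfg.pcr_efficiency)
        for m, c in zip(anchored, x):
            m.duplicate_count = int(c)

    lo, hi = cfg.size_window
    return [m for m in anchored if lo <= m.insert_length <= hi]


# ---------------------------------------------------------------------------
# stage 4: sequencing


def _qual_string(length: int, pad_from: int, base_q: int, pad_q: int = 2) -> str:
    real = min(length, pad_from)
    return chr(base_q + 33) * real + chr(pad_q + 33) * (length - real)


def _apply_errors(seq: str, qual: str, positions: np.ndarray, rng: np.random.Generator,
                  err_q: int) -> tuple[str, str]:
    s, q = list(seq), list(qual)
    for p in positions:
        old = s[p]
        choices = [b for b in "ACGT" if b != old]
        s[p] = choices[int(rng.integers(0, 3))]
        q[p] = chr(err_q + 33)
    return "".join(s), "".join(q)


def sequence_pairs(
    molecules: Sequence[MoleculeRecord],
    cfg: LibraryConfig,
    rng: np.random.Generator | int,
    pool: Sequence[TranscriptSpec],
    depth: Optional[int] = None,
    pair_prefix: str = "FTAS",
) -> list[ReadPair]:
    """Emit paired-end reads for every amplified molecule.

    R1 reads the insert from the nested primer 5' end into the OTDDN adapter
    (then the downstream library flank) when the insert is short; R2 reads
    back from the terminated base toward the primer, running into the reverse
    complement of the P5-side flank. Bases beyond the physical library
    molecule are filled with low-quality G calls. With ``depth`` set, the
    sequencer samples that many pairs proportional to amplified copy number
    and ``duplicate_count`` is updated to the sampled count; otherwise every
    copy is emitted.
    """
    if cfg.read_length <= 0:
        raise ValueError("read_length must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    L = cfg.read_length

    mols = list(molecules)
    if depth is not None:
        weights = np.array([m.duplicate_count for m in mols], dtype=float)
        if len(mols) == 0 or weights.sum() == 0 or depth == 0:
            return []
        sampled = rng.multinomial(depth, weights / weights.sum())
        kept = []
        for m, c in zip(mols, sampled):
            if c > 0:
                m.duplicate_count = int(c)
                kept.append(m)
            else:
                m.duplicate_count = 0
        mols = kept

    pairs: list[ReadPair] = []
    total = sum(m.duplicate_count for m in mols)
    nerr1 = rng.binomial(L, cfg.substitution_error_rate, size=total) if total else np.array([], int)
    nerr2 = rng.binomial(L, cfg.substitution_error_rate, size=total) if total else np.array([], int)

    k = 0
    for m in mols:
        seq = pool[m.source].sequence
        insert = seq[m.insert_start: m.term_pos + 1]
        r1_core = insert + cfg.otddn_adapter + cfg.r1_pad
        r2_core = revcomp(insert) + revcomp(cfg.p5_tail)
        r1_t = (r1_core + "G" * L)[:L]
        r2_t = (r2_core + "G" * L)[:L]
        q1_t = _qual_string(L, len(r1_core), cfg.base_quality)
        q2_t = _qual_string(L, len(r2_core), cfg.base_quality)
        for dup in range(m.duplicate_count):
            r1, q1, r2, q2 = r1_t, q1_t, r2_t, q2_t
            if nerr1[k]:
                pos = rng.choice(L, size=nerr1[k], replace=False)
                r1, q1 = _apply_errors(r1, q1, pos, rng, cfg.error_quality)
            if nerr2[k]:
                pos = rng.choice(L, size=nerr2[k], replace=False)
                r2, q2 = _apply_errors(r2, q2, pos, rng, cfg.error_quality)
            pid = f"{pair_prefix}:{m.mol_id}:{dup}"
            pairs.append(ReadPair(r1, q1, r2, q2, pid, m, dup))
            k += 1
    return pairs


# ---------------------------------------------------------------------------
# FASTQ / truth output and the end-to-end driver


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (name, seq, qual) records as 4-line FASTQ (gzip if *.gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


@dataclass
class SimulationResult:
    sample: str
    r1_paths: list[Path]
    r2_paths: list[Path]
    truth_pairs: Path
    truth_molecules: Path


def simulate_replicate(sample: SampleConfig, cfg: LibraryConfig, replicate: int
                       ) -> tuple[list[ReadPair], np.ndarray]:
    """Run the full chain for one technical replicate; returns pairs + sampled counts."""
    rt_rng = np.random.default_rng([cfg.seed, replicate, 0])
    ext_rng = np.random.default_rng([cfg.seed, replicate, 1])
    pcr_rng = np.random.default_rng([cfg.seed, replicate, 2])
    seq_rng = np.random.default_rng([cfg.seed, replicate, 3])

    spans, counts = degrade_and_reverse_transcribe(
        sample.transcripts, cfg.degradation_rate, cfg.n_molecules, rt_rng,
        cfg.random_priming_fraction)

    # group spans by source; extend every amplifiable template
    by_src: dict[int, list[CdnaSpan]] = {}
    for s in spans:
        by_src.setdefault(s.source, []).append(s)

    molecules: list[MoleculeRecord] = []
    mol_id = 0
    for src in sorted(by_src):
        seq = sample.transcripts[src].sequence
        p0 = seq.find(cfg.outer_primer)
        if p0 < 0:
            continue
        ext_end = p0 + len(cfg.outer_primer)
        sampler = _TerminationSampler(seq[ext_end:], cfg.mix)
        for sp in by_src[src]:
            if sp.start > p0 or sp.end < ext_end + 1:
                continue  # cDNA does not cover the primer site
            limit = sp.end - ext_end
            offs, by_term = sampler.sample(ext_rng, cfg.extension_cycles, limit=limit)
            for o, b in zip(offs, by_term):
                molecules.append(MoleculeRecord(
                    source=src, mol_id=mol_id, span_start=sp.start, span_end=sp.end,
                    ext_start=p0, term_pos=ext_end + int(o), by_terminator=bool(b)))
                mol_id += 1

    survivors = nested_pcr_and_size_select(molecules, cfg, pcr_rng, sample.transcripts)
    pairs = sequence_pairs(survivors, cfg, seq_rng, sample.transcripts,
                           depth=cfg.depth, pair_prefix=f"FTAS:rep{replicate + 1}")
    return pairs, counts


def simulate_library(sample: SampleConfig, cfg: LibraryConfig, out_dir) -> SimulationResult:
    """Simulate ``cfg.replicates`` independent technical replicates to disk.

    Writes per-replicate R1/R2 FASTQ plus two truth sidecars: a per-pair
    table (provenance of every read pair) and a per-source molecule table
    (how many cDNA molecules of each transcript were sampled — the ground
    truth for abundance-ratio recovery).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1_paths, r2_paths = [], []
    pair_rows, mol_rows = [], []
    for rep in range(cfg.replicates):
        pairs, counts = simulate_replicate(sample, cfg, rep)
        r1 = out_dir / f"{sample.name}_rep{rep + 1}_R1.fastq"
        r2 = out_dir / f"{sample.name}_rep{rep + 1}_R2.fastq"
        write_fastq(r1, ((p.pair_id, p.r1, p.q1) for p in pairs))
        write_fastq(r2, ((p.pair_id, p.r2, p.q2) for p in pairs))
        r1_paths.append(r1)
        r2_paths.append(r2)
        for p in pairs:
            spec = sample.transcripts[p.molecule.source]
            pair_rows.append((p.pair_id, rep + 1, spec.name, spec.isoform or "WT",
                              p.molecule.termination_offset, p.molecule.insert_length,
                              p.dup_index, p.molecule.mol_id))
        for spec, c in zip(sample.transcripts, counts):
            mol_rows.append((rep + 1, spec.name, spec.isoform or "WT", int(c)))

    truth_pairs = out_dir / f"{sample.name}_truth_pairs.tsv"
    truth_mols = out_dir / f"{sample.name}_truth_molecules.tsv"
    pd.DataFrame(pair_rows, columns=[
        "pair_id", "replicate", "source_transcript", "isoform",
        "termination_offset", "insert_length", "duplicate_index", "molecule_id",
    ]).to_csv(truth_pairs, sep="\t", index=False)
    pd.DataFrame(mol_rows, columns=[
        "replicate", "source_transcript", "isoform", "molecules_sampled",
    ]).to_csv(truth_mols, sep="\t", index=False)
    return SimulationResult(sample.name, r1_paths, r2_paths, truth_pairs, truth_mols)
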