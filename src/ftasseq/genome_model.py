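"""Gene models, toy reference generation, fusion transcripts, naming and frames.

This module owns every annotation-level concept the rest of the package builds
on: exon/intron numbering in transcript orientation, breakpoint descriptions,
construction of chimeric transcript sequences, the isoform naming grammar
(arabic numerals for exons, Roman numerals for retained introns), and the
three-way reading-frame classification of a fusion junction.

Coordinates are 1-based inclusive in GTF files and in reported breakpoints
(the GTF convention) and 0-based half-open everywhere internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pyfaidx

from .seqs import random_dna, revcomp, roman, write_fasta

# Primer and adapter sequences of the TMPRSS2-anchored assay. The outer primer
# starts second-strand synthesis; the nested primer sits closer to any fusion
# junction and re-anchors the library during indexing PCR; the terminator-
# tethered oligonucleotide becomes the adapter read in short inserts.
OUTER_PRIMER = "TAGGCGCGAGCTAAGCAGGAG"
NESTED_PRIMER = "GGAGGCGGAGGGCGAGGG"
OTDDN_ADAPTER = "AGATCGGAAGAGCACACGTCTG"

#: One-to-several-letter gene abbreviations used by the isoform name grammar.
DEFAULT_GENE_CODES: dict[str, str] = {
    "TMPRSS2L": "T", "ERGL": "E", "PPP3CAL": "P", "AMACRL": "A",
    "SIM2L": "S", "TTC18L": "TTC", "FGFR2L": "F", "GAPDHL": "G",
    "LINC114L": "L",
    # real-genome symbols map to the same codes
    "TMPRSS2": "T", "ERG": "E", "PPP3CA": "P", "AMACR": "A",
    "SIM2": "S", "TTC18": "TTC", "FGFR2": "F", "GAPDH": "G",
    "LINC00114": "L",
}


class FrameClass(str, Enum):
    """Effect of a fusion junction on the 3' partner's reading frame."""

    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    UNCLEAR = "unclear"


FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

EXON_BOUNDARY = "exon_boundary"
EXONIC_INTERNAL = "exonic_internal"
INTRONIC = "intronic"
INVERTED_INTRONIC = "inverted_intronic"
NONCODING = "noncoding"

_FEATURES = {EXON_BOUNDARY, EXONIC_INTERNAL, INTRONIC, INVERTED_INTRONIC, NONCODING}


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a gene: ordered exons and optional CDS.

    ``exons`` are 0-based half-open genomic intervals in *transcript*
    orientation: ``exons[0]`` is exon 1 (the 5'-most exon), which for a
    minus-strand gene is the genomically rightmost interval. ``cds`` follows
    the same convention and is empty for noncoding transcripts.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"exons of {self.gene_id} not in transcript orientation")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon in {self.gene_id}")
        for (cs, ce) in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS interval {cs}-{ce} of {self.gene_id} outside exons")

    # -- structure -----------------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, i: int) -> tuple[int, int]:
        """Genomic interval of 1-based exon ``i`` (transcript orientation)."""
        return self.exons[i - 1]

    def intron(self, i: int) -> tuple[int, int]:
        """Genomic interval of intron ``i`` (between exons i and i+1)."""
        a, b = self.exons[i - 1], self.exons[i]
        return (a[1], b[0]) if self.strand == "+" else (b[1], a[0])

    def exon_len(self, i: int) -> int:
        s, e = self.exon(i)
        return e - s

    def t_exon_start(self, i: int) -> int:
        """Transcript offset of the first base of exon ``i``."""
        return sum(self.exon_len(j) for j in range(1, i))

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    # -- sequence ------------------------------------------------------------

    def exon_seq(self, i: int, genome: Mapping[str, str]) -> str:
        s, e = self.exon(i)
        seq = genome[self.chrom][s:e]
        return seq if self.strand == "+" else revcomp(seq)

    def intron_seq(self, i: int, genome: Mapping[str, str]) -> str:
        s, e = self.intron(i)
        seq = genome[self.chrom][s:e]
        return seq if self.strand == "+" else revcomp(seq)

    def transcript_seq(self, genome: Mapping[str, str]) -> str:
        return "".join(self.exon_seq(i, genome) for i in range(1, self.n_exons + 1))

    # -- coordinate mapping ---------------------------------------------------

    def tcoords(self) -> np.ndarray:
        """1-based genomic coordinate of every transcript base."""
        parts = []
        for s, e in self.exons:
            if self.strand == "+":
                parts.append(np.arange(s + 1, e + 1))
            else:
                parts.append(np.arange(e, s, -1))
        return np.concatenate(parts)

    def tpos_of_genomic(self, pos: int) -> Optional[int]:
        """Transcript offset (0-based) of 1-based genomic ``pos``; None if intronic."""
        off = 0
        for s, e in self.exons:
            if s < pos <= e:
                return off + (pos - s - 1 if self.strand == "+" else e - pos)
            off += e - s
        return None

    def genomic_of_tpos(self, t: int) -> int:
        off = 0
        for s, e in self.exons:
            n = e - s
            if t < off + n:
                i = t - off
                return s + 1 + i if self.strand == "+" else e - i
            off += n
        raise IndexError(f"transcript offset {t} beyond {self.transcript_id}")

    def intron_offset_of_genomic(self, pos: int) -> Optional[tuple[int, int]]:
        """(intron index, gene-sense offset) of genomic ``pos``; None if exonic."""
        for i in range(1, self.n_exons):
            s, e = self.intron(i)
            if s < pos <= e:
                return i, (pos - s - 1 if self.strand == "+" else e - pos)
        return None

    # -- CDS / phase ----------------------------------------------------------

    def cds_t_span(self) -> Optional[tuple[int, int]]:
        """CDS as a half-open transcript-coordinate interval, or None."""
        if not self.cds:
            return None
        firsts = []
        lasts = []
        for cs, ce in self.cds:
            if self.strand == "+":
                firsts.append(self.tpos_of_genomic(cs + 1))
                lasts.append(self.tpos_of_genomic(ce))
            else:
                firsts.append(self.tpos_of_genomic(ce))
                lasts.append(self.tpos_of_genomic(cs + 1))
        return min(firsts), max(lasts) + 1

    def cds_bases_through(self, t: int) -> int:
        """Number of CDS bases in transcript[0..t] inclusive."""
        span = self.cds_t_span()
        if span is None:
            return 0
        ts, te = span
        return max(0, min(t + 1, te) - ts)


@dataclass(frozen=True)
class Breakpoint:
    """One side of a fusion junction.

    ``position`` is 1-based genomic: the last retained base for the 5' side,
    the first retained base for the 3' side. ``index`` is the exon number for
    exonic features and the intron number for (inverted-)intronic ones.
    ``strand`` is the strand of the retained sequence; it opposes the gene's
    annotated strand only for inverted intronic segments.
    """

    chrom: str
    position: int
    side: str
    feature: str
    index: int
    strand: str
    sub_label: Optional[str] = None

    def __post_init__(self):
        if self.side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"bad side {self.side!r}")
        if self.feature not in _FEATURES:
            raise ValueError(f"bad feature {self.feature!r}")
        if self.feature == INVERTED_INTRONIC and self.side != THREE_PRIME:
            raise ValueError("inverted_intronic breakpoints are only legal on the 3' side")


@dataclass(frozen=True)
class FusionDefinition:
    """A 5' segment and a 3' segment that concatenate into a chimeric mRNA."""

    five_gene: GeneModel
    five_bp: Breakpoint
    three_gene: GeneModel
    three_bp: Breakpoint

    def __post_init__(self):
        if self.five_bp.side != FIVE_PRIME or self.three_bp.side != THREE_PRIME:
            raise ValueError("breakpoint sides do not match fusion segment roles")
        for gene, bp, edge in ((self.five_gene, self.five_bp, "end"), (self.three_gene, self.three_bp, "start")):
            if bp.feature == EXON_BOUNDARY:
                s, e = gene.exon(bp.index)
                expect = (e if gene.strand == "+" else s + 1) if edge == "end" else (s + 1 if gene.strand == "+" else e)
                if bp.position != expect:
                    raise ValueError(
                        f"{gene.symbol} exon {bp.index} {edge} is {expect}, breakpoint at {bp.position}"
                    )

    @property
    def name(self) -> str:
        return name_isoform(self)


# ---------------------------------------------------------------------------
# breakpoint builders


def bp_exon_end(gene: GeneModel, exon_i: int) -> Breakpoint:
    """5' breakpoint at the last base of exon ``exon_i``."""
    s, e = gene.exon(exon_i)
    pos = e if gene.strand == "+" else s + 1
    return Breakpoint(gene.chrom, pos, FIVE_PRIME, EXON_BOUNDARY, exon_i, gene.strand)


def bp_exon_start(gene: GeneModel, exon_i: int) -> Breakpoint:
    """3' breakpoint at the first base of exon ``exon_i``."""
    s, e = gene.exon(exon_i)
    pos = s + 1 if gene.strand == "+" else e
    feature = EXON_BOUNDARY if gene.cds else NONCODING
    return Breakpoint(gene.chrom, pos, THREE_PRIME, feature, exon_i, gene.strand)


def _intron_genomic_pos(gene: GeneModel, intron_i: int, offset: int) -> int:
    s, e = gene.intron(intron_i)
    if offset < 0 or offset >= e - s:
        raise ValueError(f"offset {offset} outside intron {intron_i} of {gene.symbol}")
    return s + 1 + offset if gene.strand == "+" else e - offset


def bp_intronic(gene: GeneModel, intron_i: int, offset: int, side: str = THREE_PRIME,
                sub_label: Optional[str] = None) -> Breakpoint:
    """Breakpoint inside intron ``intron_i`` at gene-sense ``offset`` (0-based)."""
    pos = _intron_genomic_pos(gene, intron_i, offset)
    return Breakpoint(gene.chrom, pos, side, INTRONIC, intron_i, gene.strand, sub_label)


def bp_inverted_intronic(gene: GeneModel, intron_i: int, offset: int) -> Breakpoint:
    """3' breakpoint retaining revcomp(intron[:offset+1]) of intron ``intron_i``."""
    pos = _intron_genomic_pos(gene, intron_i, offset)
    opposite = "-" if gene.strand == "+" else "+"
    return Breakpoint(gene.chrom, pos, THREE_PRIME, INVERTED_INTRONIC, intron_i, opposite)


# ---------------------------------------------------------------------------
# fusion transcript construction


def build_fusion_transcript(defn: FusionDefinition, genome: Mapping[str, str]) -> str:
    """Spliced mRNA-sense sequence of the chimeric transcript.

    The 5' segment runs from the transcript start of the 5' gene through the
    breakpoint; the 3' segment runs from the breakpoint to the transcript end.
    Retained intron segments are included in gene-sense orientation, except
    inverted-intronic segments which are reverse-complemented and terminate
    the transcript (the inversion breaks colinearity beyond the junction).
    No bases are gained or lost at the junction.
    """
    g5, bp5 = defn.five_gene, defn.five_bp
    g3, bp3 = defn.three_gene, defn.three_bp
    t5 = g5.transcript_seq(genome)

    if bp5.feature in (EXON_BOUNDARY, EXONIC_INTERNAL, NONCODING):
        t = g5.tpos_of_genomic(bp5.position)
        if t is None:
            raise ValueError(f"5' breakpoint {bp5.position} not exonic in {g5.symbol}")
        prefix = t5[: t + 1]
    elif bp5.feature == INTRONIC:
        hit = g5.intron_offset_of_genomic(bp5.position)
        if hit is None:
            raise ValueError(f"5' breakpoint {bp5.position} not intronic in {g5.symbol}")
        i, off = hit
        prefix = t5[: g5.t_exon_start(i + 1)] + g5.intron_seq(i, genome)[: off + 1]
    else:
        raise ValueError("inverted_intronic is not legal on the 5' side")

    t3seq = g3.transcript_seq(genome)
    if bp3.feature in (EXON_BOUNDARY, EXONIC_INTERNAL, NONCODING):
        t = g3.tpos_of_genomic(bp3.position)
        if t is None:
            raise ValueError(f"3' breakpoint {bp3.position} not exonic in {g3.symbol}")
        suffix = t3seq[t:]
    elif bp3.feature == INTRONIC:
        hit = g3.intron_offset_of_genomic(bp3.position)
        if hit is None:
            raise ValueError(f"3' breakpoint {bp3.position} not intronic in {g3.symbol}")
        i, off = hit
        suffix = g3.intron_seq(i, genome)[off:] + t3seq[g3.t_exon_start(i + 1):]
    else:  # inverted intronic: retained = revcomp of the intron up to the breakpoint
        hit = g3.intron_offset_of_genomic(bp3.position)
        if hit is None:
            raise ValueError(f"3' breakpoint {bp3.position} not intronic in {g3.symbol}")
        i, off = hit
        suffix = revcomp(g3.intron_seq(i, genome)[: off + 1])

    return prefix + suffix


# ---------------------------------------------------------------------------
# isoform naming


def _unit(bp: Breakpoint) -> str:
    if bp.feature == INTRONIC:
        return roman(bp.index) + (bp.sub_label or "a")
    if bp.feature == INVERTED_INTRONIC:
        return roman(bp.index)
    return str(bp.index)


def name_isoform(defn: FusionDefinition, codes: Optional[Mapping[str, str]] = None) -> str:
    """Isoform name ``<5'code><unit>-<3'code><unit>``.

    Units are arabic exon numbers at exon boundaries and Roman numerals of the
    preceding intron for intronic breakpoints; forward-orientation intronic
    breakpoints carry a lowercase disambiguating letter (``a`` by default,
    assigned by ascending distance from the preceding exon when several
    breakpoints share an intron), while inverted-intronic ones do not — the
    inversion is recorded in the call record instead.
    """
    codes = DEFAULT_GENE_CODES if codes is None else codes
    missing = [g.symbol for g in (defn.five_gene, defn.three_gene) if g.symbol not in codes]
    if missing:
        raise ValueError(f"no name code configured for gene(s): {', '.join(missing)}")
    return (
        f"{codes[defn.five_gene.symbol]}{_unit(defn.five_bp)}"
        f"-{codes[defn.three_gene.symbol]}{_unit(defn.three_bp)}"
    )


def assign_intron_sub_labels(defns: Sequence[FusionDefinition]) -> list[FusionDefinition]:
    """Letter intronic 3' breakpoints a,b,... by distance from the preceding exon.

    Applied over a call set so that multiple intronic junctions inside the same
    intron of the same gene get distinct letters.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for k, d in enumerate(defns):
        if d.three_bp.feature == INTRONIC:
            groups.setdefault((d.three_gene.gene_id, d.three_bp.index), []).append(k)
    out = list(defns)
    for (_, intron_i), idxs in groups.items():
        def dist(k: int) -> int:
            d = out[k]
            hit = d.three_gene.intron_offset_of_genomic(d.three_bp.position)
            return hit[1] if hit else 0
        for letter_i, k in enumerate(sorted(idxs, key=dist)):
            bp = out[k].three_bp
            out[k] = dataclasses.replace(
                out[k], three_bp=dataclasses.replace(bp, sub_label=chr(ord("a") + letter_i))
            )
    return out


# ---------------------------------------------------------------------------
# reading frame


def classify_reading_frame(defn: FusionDefinition,
                           models: Optional[Iterable[GeneModel]] = None) -> FrameClass:
    """Classify a fusion as in-frame, out-of-frame or unclear.

    In-frame requires both breakpoints to sit within (or at the boundary of)
    annotated CDS with matching codon phase across the junction; mismatching
    phases on two coding sides are out-of-frame. Everything else — a 5'
    segment contributing no CDS (UTR-only), intronic/inverted/noncoding 3'
    breakpoints, a noncoding 3' partner, or 3' transcripts that disagree on
    phase — is unclear.
    """
    g5, bp5 = defn.five_gene, defn.five_bp
    if bp5.feature not in (EXON_BOUNDARY, EXONIC_INTERNAL) or not g5.cds:
        return FrameClass.UNCLEAR
    t5 = g5.tpos_of_genomic(bp5.position)
    if t5 is None:
        return FrameClass.UNCLEAR
    span5 = g5.cds_t_span()
    cum5 = g5.cds_bases_through(t5)
    if cum5 <= 0 or t5 + 1 > span5[1]:  # UTR-only prefix, or full CDS incl. stop retained
        return FrameClass.UNCLEAR
    phase5 = cum5 % 3

    if defn.three_bp.feature not in (EXON_BOUNDARY, EXONIC_INTERNAL):
        return FrameClass.UNCLEAR

    candidates = [m for m in (models or []) if m.gene_id == defn.three_gene.gene_id]
    if not candidates:
        candidates = [defn.three_gene]

    verdicts = set()
    for m in candidates:
        if not m.cds:
            return FrameClass.UNCLEAR
        t3 = m.tpos_of_genomic(defn.three_bp.position)
        if t3 is None:
            return FrameClass.UNCLEAR
        ts, te = m.cds_t_span()
        if t3 < ts or t3 >= te:
            return FrameClass.UNCLEAR
        verdicts.add((t3 - ts) % 3 == phase5)
    if len(verdicts) > 1:
        return FrameClass.UNCLEAR
    return FrameClass.IN_FRAME if verdicts.pop() else FrameClass.OUT_OF_FRAME


# ---------------------------------------------------------------------------
# annotation / genome I/O


def load_genome(fasta_path) -> dict[str, str]:
    """Load a FASTA into an in-memory chrom -> sequence dict (uppercased)."""
    fa = pyfaidx.Fasta(str(fasta_path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_annotation(annotation_file, genome) -> list[GeneModel]:
    """Parse a GTF into GeneModels, one per transcript.

    Exon numbering follows transcript orientation (exon 1 is 5'-most; for
    reverse-strand genes that is the genomically rightmost exon). Every
    referenced chromosome must exist in the genome FASTA and every exon must
    lie within its sequence.
    """
    db = gffutils.create_db(
        str(annotation_file), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    fa = pyfaidx.Fasta(str(genome))
    lengths = {name: len(fa[name]) for name in fa.keys()}
    models = []
    for tr in db.features_of_type("transcript"):
        if tr.seqid not in lengths:
            raise ValueError(f"chromosome {tr.seqid!r} of {tr.id} missing from genome FASTA")
        exons = sorted(db.children(tr, featuretype="exon"), key=lambda f: f.start)
        cds = sorted(db.children(tr, featuretype="CDS"), key=lambda f: f.start)
        for f in exons + cds:
            if f.end > lengths[tr.seqid] or f.start < 1:
                raise ValueError(f"feature outside sequence bounds: {f.featuretype} "
                                 f"{f.seqid}:{f.start}-{f.end} of {tr.id}")
        if tr.strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        attrs = dict(tr.attributes)
        gene_id = attrs["gene_id"][0]
        symbol = attrs.get("gene_name", [gene_id])[0]
        models.append(GeneModel(
            gene_id=gene_id,
            symbol=symbol,
            chrom=tr.seqid,
            strand=tr.strand,
            exons=tuple((f.start - 1, f.end) for f in exons),
            cds=tuple((f.start - 1, f.end) for f in cds),
            transcript_id=tr.id,
        ))
    return models


def canonical_models(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """One designated transcript per gene (lowest transcript_id)."""
    by_gene: dict[str, GeneModel] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        by_gene.setdefault(m.gene_id, m)
    return by_gene


def by_symbol(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Canonical transcript per gene, keyed by symbol."""
    return {m.symbol: m for m in canonical_models(models).values()}


# ---------------------------------------------------------------------------
# toy reference


@dataclass(frozen=True)
class _ToyGene:
    symbol: str
    chrom: str
    strand: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    # (cds start exon, offset in exon, cds end exon, offset hint); hint is
    # trimmed so total CDS length is a multiple of 3. None = noncoding.
    cds: Optional[tuple[int, int, int, int]]


# Structure of the bundled toy genome. TMPRSS2L exon 1 is pure 5'UTR carrying
# the outer and nested primer sites; exon/CDS lengths are chosen so that the
# documented in-frame junctions (e.g. TMPRSS2 exon 3 -> PPP3CA exon 2) match
# codon phase while 5'UTR-only junctions stay frame-unclear.
_TOY_GENES: tuple[_ToyGene, ...] = (
    _ToyGene("TMPRSS2L", "chrA", "+", (82, 24, 36, 45, 57, 48, 90), (80, 70, 90, 75, 85, 65), (2, 6, 7, 24)),
    _ToyGene("ERGL", "chrA", "+", (55, 63, 72, 84, 66, 75, 60, 120), (70, 90, 110, 85, 75, 95, 80), (2, 10, 8, 61)),
    _ToyGene("GAPDHL", "chrB", "+", (120, 150, 130), (90, 95), (1, 30, 3, 60)),
    _ToyGene("PPP3CAL", "chrB", "+", (65, 88, 70, 95), (100, 80, 90), (1, 20, 4, 46)),
    _ToyGene("AMACRL", "chrB", "+", (58, 92, 77, 85), (85, 95, 75), (1, 25, 4, 47)),
    _ToyGene("SIM2L", "chrB", "+", (60, 75, 82, 70, 66, 88, 72, 95), (90, 85, 100, 80, 95, 140, 75), (2, 12, 8, 40)),
    _ToyGene("TTC18L", "chrB", "-", (50, 70, 64, 80), (90, 85, 100), (1, 14, 4, 30)),
    _ToyGene("FGFR2L", "chrB", "+", (68, 85, 90), (95, 88), (2, 5, 3, 40)),
    _ToyGene("LINC114L", "chrB", "+", (90, 110), (85,), None),
)

# TMPRSS2L exon 1 layout: lead, outer primer, spacer, nested primer, tail.
_EXON1_LEAD = 10
_EXON1_SPACER = 8
_EXON1_TAIL = 25


def _place_genes(rng: np.random.Generator) -> tuple[dict[str, int], dict[str, list[GeneModel]]]:
    """Assign genomic intervals to toy genes; returns chrom lengths and models."""
    chrom_cursor: dict[str, int] = {}
    per_chrom: dict[str, list[GeneModel]] = {}
    models: list[GeneModel] = []
    for spec in _TOY_GENES:
        cursor = chrom_cursor.get(spec.chrom, 100)
        cursor += int(rng.integers(150, 300))
        # genomic-order piece lengths: exons/introns interleaved
        ex, ins = list(spec.exon_lengths), list(spec.intron_lengths)
        if spec.strand == "-":
            ex, ins = ex[::-1], ins[::-1]
        pieces = []
        for i, L in enumerate(ex):
            pieces.append(("exon", L))
            if i < len(ins):
                pieces.append(("intron", ins[i]))
        gpos = cursor
        exon_iv = []
        for kind, L in pieces:
            if kind == "exon":
                exon_iv.append((gpos, gpos + L))
            gpos += L
        chrom_cursor[spec.chrom] = gpos
        if spec.strand == "-":
            exon_iv = exon_iv[::-1]  # transcript orientation
        cds_iv: tuple[tuple[int, int], ...] = ()
        if spec.cds is not None:
            se, so, ee, eo = spec.cds
            total = (spec.exon_lengths[se - 1] - so) + sum(spec.exon_lengths[se:ee - 1]) + eo
            eo -= total % 3
            iv = []
            for i in range(se, ee + 1):
                s, e = exon_iv[i - 1]
                lo = so if i == se else 0
                hi = eo if i == ee else spec.exon_lengths[i - 1]
                if spec.strand == "+":
                    iv.append((s + lo, s + hi))
                else:
                    iv.append((e - hi, e - lo))
            cds_iv = tuple(iv)
        models.append(GeneModel(
            gene_id=spec.symbol, symbol=spec.symbol, chrom=spec.chrom, strand=spec.strand,
            exons=tuple(exon_iv), cds=cds_iv, transcript_id=f"{spec.symbol}-201",
        ))
    for m in models:
        per_chrom.setdefault(m.chrom, []).append(m)
    lengths = {c: chrom_cursor[c] + 150 for c in chrom_cursor}
    return lengths, per_chrom


def _count_occurrences(genome: Mapping[str, str], motif: str) -> int:
    n = 0
    for pattern in (motif, revcomp(motif)):
        for seq in genome.values():
            start = 0
            while True:
                k = seq.find(pattern, start)
                if k < 0:
                    break
                n += 1
                start = k + 1
    return n


def make_toy_reference(seed: int, out_prefix) -> tuple[Path, Path, Path]:
    """Generate the bundled toy reference: FASTA, GTF and a feature manifest.

    Deterministic for a fixed seed. TMPRSS2L exon 1 carries the outer
    extension primer upstream of the nested primer (the nested primer sits
    closer to any downstream junction); both primer sites are verified to be
    unique genome-wide, re-drawing the random background if a collision ever
    occurs.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    for attempt in range(50):
        rng = np.random.default_rng([seed, attempt])
        lengths, per_chrom = _place_genes(rng)
        genome = {c: list(random_dna(rng, L)) for c, L in sorted(lengths.items())}
        tm = next(m for ms in per_chrom.values() for m in ms if m.symbol == "TMPRSS2L")
        s, _ = tm.exon(1)
        exon1 = (random_dna(rng, _EXON1_LEAD) + OUTER_PRIMER + random_dna(rng, _EXON1_SPACER)
                 + NESTED_PRIMER + random_dna(rng, _EXON1_TAIL))
        genome[tm.chrom][s:s + len(exon1)] = list(exon1)
        genome_s = {c: "".join(v) for c, v in genome.items()}
        if (_count_occurrences(genome_s, OUTER_PRIMER) == 1
                and _count_occurrences(genome_s, NESTED_PRIMER) == 1):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not build a toy genome with unique primer sites")

    fasta_path = out_prefix.with_suffix(".fa")
    gtf_path = out_prefix.with_suffix(".gtf")
    manifest_path = Path(str(out_prefix) + ".manifest.tsv")

    write_fasta(fasta_path, sorted(genome_s.items()))

    with open(gtf_path, "w") as fh:
        for chrom in sorted(per_chrom):
            for m in sorted(per_chrom[chrom], key=lambda m: min(s for s, _ in m.exons)):
                attrs = f'gene_id "{m.gene_id}"; gene_name "{m.symbol}"; transcript_id "{m.transcript_id}";'
                gs = min(s for s, _ in m.exons) + 1
                ge = max(e for _, e in m.exons)
                fh.write(f'{chrom}\ttoy\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\tgene_id "{m.gene_id}"; gene_name "{m.symbol}";\n')
                fh.write(f"{chrom}\ttoy\ttranscript\t{gs}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n")
                for i, (s, e) in enumerate(m.exons, start=1):
                    fh.write(f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs} exon_number \"{i}\";\n")
                cum = 0
                for (s, e) in m.cds:
                    frame = (3 - cum % 3) % 3
                    fh.write(f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{frame}\t{attrs}\n")
                    cum += e - s

    with open(manifest_path, "w") as fh:
        fh.write("kind\tname\tchrom\tstart\tend\tstrand\tnote\n")
        for chrom in sorted(per_chrom):
            for m in per_chrom[chrom]:
                gs = min(s for s, _ in m.exons) + 1
                ge = max(e for _, e in m.exons)
                note = f"{m.n_exons} exons" + ("; coding" if m.cds else "; noncoding")
                fh.write(f"gene\t{m.symbol}\t{chrom}\t{gs}\t{ge}\t{m.strand}\t{note}\n")
        s0, _ = tm.exon(1)
        op = s0 + _EXON1_LEAD
        npr = op + len(OUTER_PRIMER) + _EXON1_SPACER
        fh.write(f"primer\touter_primer\t{tm.chrom}\t{op + 1}\t{op + len(OUTER_PRIMER)}\t+\t{OUTER_PRIMER}\n")
        fh.write(f"primer\tnested_primer\t{tm.chrom}\t{npr + 1}\t{npr + len(NESTED_PRIMER)}\t+\t{NESTED_PRIMER}\n")
        fh.write(f"adapter\totddn_adapter\t.\t.\t.\t.\t{OTDDN_ADAPTER}\n")

    return fasta_path, gtf_path, manifest_path
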