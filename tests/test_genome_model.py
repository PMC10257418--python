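import dataclasses
import filecmp

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftasseq.genome_model import (
    EXONIC_INTERNAL, Breakpoint, FIVE_PRIME, FrameClass, FusionDefinition,
    GeneModel, NESTED_PRIMER, OUTER_PRIMER, THREE_PRIME, bp_exon_end,
    bp_exon_start, bp_intronic, bp_inverted_intronic, build_fusion_transcript,
    classify_reading_frame, load_annotation, load_genome, make_toy_reference,
    name_isoform, assign_intron_sub_labels,
)
from ftasseq.seqs import revcomp


def _write_mini_ref(tmp_path, strand):
    seq = "".join(np.random.default_rng(3).choice(list("ACGT"), 500))
    (tmp_path / "mini.fa").write_text(f">chr1\n{seq}\n")
    attrs = 'gene_id "G"; gene_name "G"; transcript_id "G-1";'
    gtf = (
        f"chr1\tt\tgene\t101\t400\t.\t{strand}\t.\t{attrs}\n"
        f"chr1\tt\ttranscript\t101\t400\t.\t{strand}\t.\t{attrs}\n"
        f"chr1\tt\texon\t101\t200\t.\t{strand}\t.\t{attrs}\n"
        f"chr1\tt\texon\t301\t400\t.\t{strand}\t.\t{attrs}\n"
    )
    (tmp_path / "mini.gtf").write_text(gtf)
    return tmp_path / "mini.gtf", tmp_path / "mini.fa"


@pytest.mark.parametrize("strand,first_exon", [("+", (100, 200)), ("-", (300, 400))])
def test_exon_numbering_follows_transcript_orientation(tmp_path, strand, first_exon):
    gtf, fa = _write_mini_ref(tmp_path, strand)
    (m,) = load_annotation(gtf, fa)
    assert m.exon(1) == first_exon
    assert m.n_exons == 2


def test_load_annotation_missing_chrom_is_hard_error(tmp_path):
    gtf, fa = _write_mini_ref(tmp_path, "+")
    bad = tmp_path / "bad.gtf"
    bad.write_text(gtf.read_text().replace("chr1", "chrMissing"))
    with pytest.raises(ValueError, match="chrMissing"):
        load_annotation(bad, fa)


def test_load_annotation_exon_outside_bounds_names_record(tmp_path):
    gtf, fa = _write_mini_ref(tmp_path, "+")
    bad = tmp_path / "bad.gtf"
    bad.write_text(gtf.read_text().replace("\t400\t", "\t9999\t"))
    with pytest.raises(ValueError, match="outside sequence bounds"):
        load_annotation(bad, fa)


def test_toy_reference_deterministic_and_round_trips(tmp_path, toy_ref, models):
    fa2, gtf2, man2 = make_toy_reference(1, tmp_path / "again")
    assert filecmp.cmp(toy_ref["fasta"], fa2, shallow=False)
    assert filecmp.cmp(toy_ref["gtf"], gtf2, shallow=False)
    assert filecmp.cmp(toy_ref["manifest"], man2, shallow=False)
    assert load_annotation(gtf2, fa2) == models


def test_toy_reference_embeds_primers_uniquely(genome, sym):
    tm = sym["TMPRSS2L"]
    exon1 = tm.exon_seq(1, genome)
    # outer primer upstream of (5' of) the nested primer within exon 1
    assert exon1.find(OUTER_PRIMER) < exon1.find(NESTED_PRIMER)
    assert exon1.find(OUTER_PRIMER) >= 0
    for motif in (OUTER_PRIMER, NESTED_PRIMER):
        hits = sum(seq.count(motif) + seq.count(revcomp(motif))
                   for seq in genome.values())
        assert hits == 1


def test_toy_reference_gene_inventory(models, sym):
    erg = sym["ERGL"]
    assert erg.n_exons >= 5
    assert sym["TTC18L"].strand == "-"
    assert not sym["LINC114L"].cds
    # minus-strand exon 1 is genomically rightmost
    ttc = sym["TTC18L"]
    assert ttc.exon(1)[0] > ttc.exon(ttc.n_exons)[0]


def test_fusion_transcript_exon_boundary_structure(genome, sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    d = FusionDefinition(T, bp_exon_end(T, 1), E, bp_exon_start(E, 4))
    expected = T.exon_seq(1, genome) + "".join(
        E.exon_seq(i, genome) for i in range(4, E.n_exons + 1))
    assert build_fusion_transcript(d, genome) == expected


def test_fusion_transcript_retained_intron_structure(genome, sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    d = FusionDefinition(T, bp_exon_end(T, 1), E, bp_intronic(E, 3, 80))
    expected = (T.exon_seq(1, genome) + E.intron_seq(3, genome)[80:]
                + "".join(E.exon_seq(i, genome) for i in range(4, E.n_exons + 1)))
    assert build_fusion_transcript(d, genome) == expected


def test_fusion_transcript_inverted_intron_structure(genome, sym):
    T, S = sym["TMPRSS2L"], sym["SIM2L"]
    d = FusionDefinition(T, bp_exon_end(T, 5), S, bp_inverted_intronic(S, 6, 59))
    expected = ("".join(T.exon_seq(i, genome) for i in range(1, 6))
                + revcomp(S.intron_seq(6, genome)[:60]))
    assert build_fusion_transcript(d, genome) == expected


def test_identity_junction_reproduces_wildtype(genome, sym):
    E = sym["ERGL"]
    d = FusionDefinition(E, bp_exon_end(E, 3), E, bp_exon_start(E, 4))
    assert build_fusion_transcript(d, genome) == E.transcript_seq(genome)


def test_inverted_intronic_is_illegal_on_five_prime_side():
    with pytest.raises(ValueError, match="3' side"):
        Breakpoint("chrA", 100, FIVE_PRIME, "inverted_intronic", 1, "+")


@settings(max_examples=60, derandomize=True)
@given(data=st.data())
def test_junction_conserves_length(data, genome, sym):
    """len(fusion) = len(5' prefix) + len(3' suffix) for random legal breakpoints."""
    T = sym["TMPRSS2L"]
    partners = [sym[s] for s in ("ERGL", "PPP3CAL", "AMACRL", "SIM2L", "TTC18L")]
    e5 = data.draw(st.integers(1, T.n_exons - 1))
    G3 = data.draw(st.sampled_from(partners))
    kind = data.draw(st.sampled_from(["exon", "intronic", "inverted"]))
    exp5 = T.t_exon_start(e5) + T.exon_len(e5)
    if kind == "exon":
        e3 = data.draw(st.integers(2, G3.n_exons))
        bp3 = bp_exon_start(G3, e3)
        exp3 = G3.transcript_length - G3.t_exon_start(e3)
    else:
        i3 = data.draw(st.integers(1, G3.n_exons - 1))
        s, e = G3.intron(i3)
        off = data.draw(st.integers(0, (e - s) - 1))
        if kind == "intronic":
            bp3 = bp_intronic(G3, i3, off)
            exp3 = (e - s) - off + G3.transcript_length - G3.t_exon_start(i3 + 1)
        else:
            bp3 = bp_inverted_intronic(G3, i3, off)
            exp3 = off + 1
    d = FusionDefinition(T, bp_exon_end(T, e5), G3, bp3)
    assert len(build_fusion_transcript(d, genome)) == exp5 + exp3


def test_naming_requires_code_mapping(sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    d = FusionDefinition(T, bp_exon_end(T, 1), E, bp_exon_start(E, 4))
    with pytest.raises(ValueError, match="ERGL"):
        name_isoform(d, codes={"TMPRSS2L": "T"})


def test_naming_injective_over_breakpoint_pairs(sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    names = set()
    n = 0
    for e5 in range(1, T.n_exons):
        for e3 in range(2, E.n_exons + 1):
            names.add(FusionDefinition(T, bp_exon_end(T, e5), E, bp_exon_start(E, e3)).name)
            n += 1
    assert len(names) == n


def test_intron_sub_labels_ordered_by_distance_from_exon(sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    d_far = FusionDefinition(T, bp_exon_end(T, 1), E, bp_intronic(E, 3, 90))
    d_near = FusionDefinition(T, bp_exon_end(T, 1), E, bp_intronic(E, 3, 20))
    far, near = assign_intron_sub_labels([d_far, d_near])
    assert near.name == "T1-EIIIa"   # closer to exon 3 -> letter a
    assert far.name == "T1-EIIIb"


def test_frame_utr_only_five_prime_is_unclear(models, sym):
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    d = FusionDefinition(T, bp_exon_end(T, 1), E, bp_exon_start(E, 4))
    assert classify_reading_frame(d, models) is FrameClass.UNCLEAR


def test_frame_matching_phases_in_frame(models, sym):
    T, P = sym["TMPRSS2L"], sym["PPP3CAL"]
    d = FusionDefinition(T, bp_exon_end(T, 3), P, bp_exon_start(P, 2))
    assert classify_reading_frame(d, models) is FrameClass.IN_FRAME


def test_frame_noncoding_partner_is_unclear(models, sym):
    T, L = sym["TMPRSS2L"], sym["LINC114L"]
    d = FusionDefinition(T, bp_exon_end(T, 3), L, bp_exon_start(L, 2))
    assert classify_reading_frame(d, models) is FrameClass.UNCLEAR


def test_frame_disagreeing_transcripts_are_unclear(models, sym, genome):
    """A second annotated 3' transcript with shifted CDS makes the phase unclear."""
    T, P = sym["TMPRSS2L"], sym["PPP3CAL"]
    (cs, ce), rest = P.cds[0], P.cds[1:]
    alt = dataclasses.replace(P, cds=((cs + 1, ce),) + rest,
                              transcript_id="PPP3CAL-202")
    d = FusionDefinition(T, bp_exon_end(T, 3), P, bp_exon_start(P, 2))
    assert classify_reading_frame(d, list(models) + [alt]) is FrameClass.UNCLEAR


def test_strand_symmetry_of_transcripts_and_fusions(genome, sym):
    """Reverse-complementing the genome and flipping strands leaves sequences unchanged."""
    flipped_genome = {c: revcomp(s) for c, s in genome.items()}

    def flip(gene):
        L = len(genome[gene.chrom])
        return dataclasses.replace(
            gene,
            strand="-" if gene.strand == "+" else "+",
            exons=tuple((L - e, L - s) for s, e in gene.exons),
            cds=tuple((L - e, L - s) for s, e in gene.cds),
        )

    T, E = sym["TMPRSS2L"], sym["ERGL"]
    fT, fE = flip(T), flip(E)
    assert fT.transcript_seq(flipped_genome) == T.transcript_seq(genome)
    d = FusionDefinition(T, bp_exon_end(T, 2), E, bp_exon_start(E, 4))
    fd = FusionDefinition(fT, bp_exon_end(fT, 2), fE, bp_exon_start(fE, 4))
    assert build_fusion_transcript(fd, flipped_genome) == build_fusion_transcript(d, genome)
    assert fd.name == d.name
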