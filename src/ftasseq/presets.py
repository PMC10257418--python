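"""Bundled cell-line-like sample presets for the toy reference.

The fusion-positive preset mirrors an NCI-H660-like transcript pool: the five
TMPRSS2/ERG isoform junctions of the cell-line panel (T1-E4, T2-E4, T1-E5,
T2-E5 and the intron-retaining T1-EIIIa), each ~1000-fold less abundant than
the housekeeping GAPDH-like transcript, alongside the wild-type anchor
transcript. The fusion-negative preset (LNCaP-like) carries only wild-type
transcripts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .genome_model import (
    FusionDefinition, GeneModel, bp_exon_end, bp_exon_start, bp_intronic,
    build_fusion_transcript, by_symbol, name_isoform,
)
from .library_sim import SampleConfig, TranscriptSpec

#: relative abundances of the fusion-positive pool (fusion : housekeeping = 1 : 1000)
HOUSEKEEPING_ABUNDANCE = 1000.0
WILDTYPE_ANCHOR_ABUNDANCE = 50.0
FUSION_ABUNDANCE = 1.0

# retained tail of ERG-like intron 3 in the T1-EIIIa isoform (nt)
_EIIIA_RETAINED = 30


def nci_h660_fusions(models: Sequence[GeneModel]) -> list[FusionDefinition]:
    """The five fusion junctions of the positive cell-line panel."""
    sym = by_symbol(models)
    T, E = sym["TMPRSS2L"], sym["ERGL"]
    t1, t2 = bp_exon_end(T, 1), bp_exon_end(T, 2)
    intron3_len = abs(E.intron(3)[1] - E.intron(3)[0])
    return [
        FusionDefinition(T, t1, E, bp_exon_start(E, 4)),                     # T1-E4
        FusionDefinition(T, t2, E, bp_exon_start(E, 4)),                     # T2-E4
        FusionDefinition(T, t1, E, bp_exon_start(E, 5)),                     # T1-E5
        FusionDefinition(T, t2, E, bp_exon_start(E, 5)),                     # T2-E5
        FusionDefinition(T, t1, E, bp_intronic(E, 3, intron3_len - _EIIIA_RETAINED)),  # T1-EIIIa
    ]


def _wildtype_specs(models: Sequence[GeneModel], genome: Mapping[str, str]
                    ) -> list[TranscriptSpec]:
    sym = by_symbol(models)
    gapdh, tmprss2 = sym["GAPDHL"], sym["TMPRSS2L"]
    return [
        TranscriptSpec(gapdh.transcript_id, gapdh.transcript_seq(genome),
                       HOUSEKEEPING_ABUNDANCE),
        TranscriptSpec(tmprss2.transcript_id, tmprss2.transcript_seq(genome),
                       WILDTYPE_ANCHOR_ABUNDANCE),
    ]


def nci_h660_sample(models: Sequence[GeneModel], genome: Mapping[str, str]
                    ) -> SampleConfig:
    """Fusion-positive pool: five isoforms at 1/1000 of the housekeeping level."""
    specs = _wildtype_specs(models, genome)
    for defn in nci_h660_fusions(models):
        name = name_isoform(defn)
        specs.append(TranscriptSpec(
            f"fusion:{name}", build_fusion_transcript(defn, genome),
            FUSION_ABUNDANCE, isoform=name))
    return SampleConfig("nci-h660", tuple(specs))


def lncap_sample(models: Sequence[GeneModel], genome: Mapping[str, str]
                 ) -> SampleConfig:
    """Fusion-negative pool: wild-type transcripts only."""
    return SampleConfig("lncap", tuple(_wildtype_specs(models, genome)))


PRESETS = {"nci-h660": nci_h660_sample, "lncap": lncap_sample}
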