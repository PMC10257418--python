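import pytest

from ftasseq.fusion_caller import CallerConfig, FusionCallerEngine, call_fusions
from ftasseq.genome_model import (
    FusionDefinition, bp_exon_end, bp_exon_start, bp_inverted_intronic,
    build_fusion_transcript, by_symbol, load_annotation, load_genome,
    make_toy_reference, name_isoform,
)
from ftasseq.library_sim import LibraryConfig, SampleConfig, TranscriptSpec, simulate_library
from ftasseq.presets import nci_h660_fusions


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    out = tmp_path_factory.mktemp("ref")
    fasta, gtf, manifest = make_toy_reference(1, out / "toyref")
    return {"fasta": fasta, "gtf": gtf, "manifest": manifest}


@pytest.fixture(scope="session")
def models(toy_ref):
    return load_annotation(toy_ref["gtf"], toy_ref["fasta"])


@pytest.fixture(scope="session")
def genome(toy_ref):
    return load_genome(toy_ref["fasta"])


@pytest.fixture(scope="session")
def sym(models):
    return by_symbol(models)


@pytest.fixture(scope="session")
def caller_cfg():
    return CallerConfig(anchor_gene="TMPRSS2L")


@pytest.fixture(scope="session")
def engine(genome, models, caller_cfg):
    return FusionCallerEngine(genome, models, caller_cfg)


def rich_pool(models, genome) -> SampleConfig:
    """A fusion-rich pool for caller tests: abundant isoforms of varied structure."""
    s = by_symbol(models)
    T = s["TMPRSS2L"]
    # junctions kept near the primer so terminator-limited fragments span them
    defns = list(nci_h660_fusions(models)) + [
        FusionDefinition(T, bp_exon_end(T, 2), s["SIM2L"], bp_inverted_intronic(s["SIM2L"], 6, 59)),
        FusionDefinition(T, bp_exon_end(T, 3), s["PPP3CAL"], bp_exon_start(s["PPP3CAL"], 2)),
        FusionDefinition(T, bp_exon_end(T, 2), s["TTC18L"], bp_exon_start(s["TTC18L"], 2)),
    ]
    specs = [
        TranscriptSpec("GAPDHL-201", s["GAPDHL"].transcript_seq(genome), 20.0),
        TranscriptSpec("TMPRSS2L-201", T.transcript_seq(genome), 5.0),
    ]
    for d in defns:
        specs.append(TranscriptSpec(f"fusion:{d.name}", build_fusion_transcript(d, genome),
                                    2.0, isoform=name_isoform(d)))
    return SampleConfig("rich", tuple(specs))


@pytest.fixture(scope="session")
def rich_sim(models, genome, tmp_path_factory):
    """Zero-error simulation of the fusion-rich pool (2 replicates)."""
    out = tmp_path_factory.mktemp("rich_sim")
    cfg = LibraryConfig(depth=10_000, n_molecules=10_000, seed=11,
                        substitution_error_rate=0.0)
    return simulate_library(rich_pool(models, genome), cfg, out), cfg


@pytest.fixture(scope="session")
def rich_calls(rich_sim, genome, models, caller_cfg):
    res, _ = rich_sim
    return call_fusions(list(zip(res.r1_paths, res.r2_paths)), genome, models, caller_cfg)
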