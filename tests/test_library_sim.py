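import filecmp

import numpy as np
import pytest
from scipy import stats

from ftasseq.genome_model import NESTED_PRIMER, OTDDN_ADAPTER, OUTER_PRIMER
from ftasseq.library_sim import (
    CdnaSpan, LibraryConfig, MoleculeRecord, NucleotideMix, SampleConfig,
    TranscriptSpec, degrade_and_reverse_transcribe, extend_with_terminators,
    nested_pcr_and_size_select, sequence_pairs, simulate_library,
    simulate_replicate,
)
from ftasseq.presets import lncap_sample, nci_h660_sample
from ftasseq.seqs import random_dna, revcomp


def _pool(*specs):
    return [TranscriptSpec(*s) for s in specs]


def _target_transcript(rng, length=400):
    """A synthetic target transcript starting with the primer cassette."""
    return (random_dna(rng, 10) + OUTER_PRIMER + random_dna(rng, 8)
            + NESTED_PRIMER + random_dna(rng, length))


class TestReverseTranscription:
    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            degrade_and_reverse_transcribe([], 0.0, 10, 1)

    def test_no_degradation_oligo_dt_spans_full_transcript(self):
        pool = _pool(("t", "ACGT" * 100, 1.0))
        spans, _ = degrade_and_reverse_transcribe(pool, 0.0, 50, 1,
                                                  random_priming_fraction=0.0)
        assert all(s.start == 0 and s.end == 400 for s in spans)
        assert len(spans) == 50

    def test_geometric_fragmentation_mean_length(self):
        """Per-bond breaks at rate p give mean fragment length L/(1+(L-1)p)."""
        L, p, n = 1000, 0.01, 10_000
        pool = _pool(("t", "A" * L, 1.0))
        spans, _ = degrade_and_reverse_transcribe(pool, p, n, 5,
                                                  random_priming_fraction=0.0)
        lengths = np.array([s.end - s.start for s in spans])
        expected = L / (1 + (L - 1) * p)
        assert lengths.mean() == pytest.approx(expected, rel=0.02)
        # and approximately the 1/p law for L >> 1/p
        assert lengths.mean() == pytest.approx(1 / p, rel=0.10)

    def test_thousandfold_abundance_sampling_is_poisson_consistent(self):
        pool = _pool(("fusion", "A" * 100, 1.0), ("hk", "C" * 100, 1000.0))
        _, counts = degrade_and_reverse_transcribe(pool, 0.0, 100_000, 2)
        lam = 100_000 / 1001
        assert abs(counts[0] - lam) <= 3 * np.sqrt(lam)


class TestTerminatorExtension:
    def test_mix_invariants(self):
        mix = NucleotideMix()
        assert mix.p_term_c == pytest.approx(0.1)
        assert mix.p_term_t == pytest.approx(0.1)
        with pytest.raises(ValueError):
            NucleotideMix(conc_dctp=0.0, conc_ddc_on=0.0)

    def test_primer_absent_returns_empty(self):
        assert extend_with_terminators("ACGT" * 50, "TTTTTTTTTTGG", NucleotideMix(), 5, 1) == []

    def test_purine_only_template_runs_to_template_end(self):
        template = "ACGTACGTACGT" + "AG" * 100
        recs = extend_with_terminators(template, "ACGTACGTACGT", NucleotideMix(), 200, 1)
        assert len(recs) == 200
        assert all(not r.by_terminator for r in recs)
        assert all(r.term_pos == len(template) - 1 for r in recs)

    def test_terminal_base_is_pyrimidine_when_terminated(self):
        rng = np.random.default_rng(4)
        template = "ACGTACGTACGT" + random_dna(rng, 500)
        recs = extend_with_terminators(template, "ACGTACGTACGT", NucleotideMix(), 500, 2)
        for r in recs:
            if r.by_terminator:
                assert template[r.term_pos] in "CT"

    def test_alternating_template_matches_geometric_law(self):
        """On a C-every-2nt template, pyrimidine count to termination is geometric."""
        primer = "ACGTACGTACGT"
        template = primer + "CA" * 2000
        recs = extend_with_terminators(template, primer, NucleotideMix(), 5000, 3)
        counts = np.array([(r.term_pos - len(primer)) // 2 + 1
                           for r in recs if r.by_terminator])
        # randomized PIT makes the discrete sample exactly uniform under H0
        geom = stats.geom(0.1)
        u = geom.cdf(counts - 1) + np.random.default_rng(0).random(len(counts)) * geom.pmf(counts)
        d = stats.kstest(u, "uniform")
        assert d.pvalue > 0.01


class TestNestedPcrSizeSelect:
    def _molecule(self, term_offset_from_nested, pool, by_terminator=True):
        seq = pool[0].sequence
        npos = seq.find(NESTED_PRIMER)
        return MoleculeRecord(source=0, mol_id=0, span_start=0, span_end=len(seq),
                              ext_start=seq.find(OUTER_PRIMER),
                              term_pos=npos + term_offset_from_nested,
                              by_terminator=by_terminator)

    def test_short_insert_dropped_by_size_window(self):
        pool = _pool(("t", _target_transcript(np.random.default_rng(0)), 1.0))
        m = self._molecule(len(NESTED_PRIMER) + 4, pool)  # terminated 5 nt past primer
        cfg = LibraryConfig(size_window=(50, 700))
        assert nested_pcr_and_size_select([m], cfg, 1, pool) == []

    def test_molecule_without_nested_site_dropped(self):
        pool = _pool(("t", _target_transcript(np.random.default_rng(0)), 1.0))
        seq = pool[0].sequence
        npos = seq.find(NESTED_PRIMER)
        late = MoleculeRecord(source=0, mol_id=0, span_start=0, span_end=len(seq),
                              ext_start=npos + 30, term_pos=npos + 200,
                              by_terminator=True)
        assert nested_pcr_and_size_select([late], LibraryConfig(), 1, pool) == []

    def test_zero_efficiency_gives_single_copies(self):
        pool = _pool(("t", _target_transcript(np.random.default_rng(0)), 1.0))
        m = self._molecule(120, pool)
        (out,) = nested_pcr_and_size_select([m], LibraryConfig(pcr_efficiency=0.0), 1, pool)
        assert out.duplicate_count == 1

    def test_branching_process_mean_matches_expectation(self):
        pool = _pool(("t", _target_transcript(np.random.default_rng(0)), 1.0))
        mols = [self._molecule(120, pool) for _ in range(1000)]
        for i, m in enumerate(mols):
            m.mol_id = i
        cfg = LibraryConfig(pcr_efficiency=0.9, pcr_cycles=20)
        out = nested_pcr_and_size_select(mols, cfg, 7, pool)
        mean = np.mean([m.duplicate_count for m in out])
        assert mean == pytest.approx(1.9 ** 20, rel=0.05)


class TestSequencing:
    def _prepped(self, insert_len, seed=0):
        pool = _pool(("t", _target_transcript(np.random.default_rng(seed), 600), 1.0))
        seq = pool[0].sequence
        npos = seq.find(NESTED_PRIMER)
        m = MoleculeRecord(source=0, mol_id=0, span_start=0, span_end=len(seq),
                           ext_start=seq.find(OUTER_PRIMER),
                           term_pos=npos + insert_len - 1, by_terminator=True,
                           insert_start=npos)
        return pool, m

    def test_long_insert_r1_is_exact_prefix(self):
        pool, m = self._prepped(200)
        cfg = LibraryConfig(substitution_error_rate=0.0)
        (p,) = sequence_pairs([m], cfg, 1, pool)
        insert = pool[0].sequence[m.insert_start: m.term_pos + 1]
        assert p.r1 == insert[:150]
        assert p.r1.startswith(NESTED_PRIMER)
        # R2 starts at the termination base, reading back
        assert p.r2 == revcomp(insert)[:150]

    def test_short_insert_reads_through_adapter(self):
        pool, m = self._prepped(80)
        cfg = LibraryConfig(substitution_error_rate=0.0)
        (p,) = sequence_pairs([m], cfg, 1, pool)
        assert p.r1[80:102] == OTDDN_ADAPTER

    def test_substitution_error_rate_recovered(self):
        pool, m = self._prepped(200)
        m.duplicate_count = 400  # > 1e5 sequenced bases
        cfg = LibraryConfig(substitution_error_rate=0.01)
        pairs = sequence_pairs([m], cfg, 1, pool)
        insert = pool[0].sequence[m.insert_start: m.term_pos + 1]
        truth1, truth2 = insert[:150], revcomp(insert)[:150]
        mism = sum(sum(a != b for a, b in zip(p.r1, truth1))
                   + sum(a != b for a, b in zip(p.r2, truth2)) for p in pairs)
        n = 400 * 300
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(mism / n - 0.01) < 3 * se

    def test_duplicate_counts_conserved_in_emission(self):
        pool, m = self._prepped(120)
        m.duplicate_count = 7
        pairs = sequence_pairs([m], LibraryConfig(), 1, pool)
        assert len(pairs) == 7
        assert {p.pair_id for p in pairs} == {f"FTAS:0:{i}" for i in range(7)}


class TestSimulateLibrary:
    def test_fusion_positive_truth_covers_every_isoform(self, models, genome, tmp_path):
        import pandas as pd
        cfg = LibraryConfig(depth=5000, n_molecules=100_000, seed=3, replicates=1)
        res = simulate_library(nci_h660_sample(models, genome), cfg, tmp_path)
        mols = pd.read_csv(res.truth_molecules, sep="\t")
        fus = mols[mols.isoform != "WT"]
        assert len(fus) == 5
        assert (fus.molecules_sampled >= 1).all()

    def test_fusion_negative_truth_has_zero_fusion_molecules(self, models, genome, tmp_path):
        import pandas as pd
        cfg = LibraryConfig(depth=1000, n_molecules=5000, seed=3, replicates=1)
        res = simulate_library(lncap_sample(models, genome), cfg, tmp_path)
        pairs = pd.read_csv(res.truth_pairs, sep="\t")
        assert (pairs.isoform == "WT").all()

    def test_same_seed_is_byte_identical(self, models, genome, tmp_path):
        cfg = LibraryConfig(depth=500, n_molecules=2000, seed=9, replicates=2)
        s = lncap_sample(models, genome)
        a = simulate_library(s, cfg, tmp_path / "a")
        b = simulate_library(s, cfg, tmp_path / "b")
        for pa, pb in zip(a.r1_paths + a.r2_paths, b.r1_paths + b.r2_paths):
            assert filecmp.cmp(pa, pb, shallow=False)

    def test_enrichment_transcripts_without_primer_yield_no_reads(self, models, genome):
        sample = lncap_sample(models, genome)  # GAPDHL 1000x vs TMPRSS2L 50x
        cfg = LibraryConfig(depth=2000, n_molecules=20_000, seed=5)
        pairs, _ = simulate_replicate(sample, cfg, 0)
        sources = {p.molecule.source for p in pairs}
        assert sources == {1}  # only the anchor-gene transcript amplifies

    def test_every_r1_begins_with_nested_primer_at_zero_error(self, models, genome):
        sample = nci_h660_sample(models, genome)
        cfg = LibraryConfig(depth=1500, n_molecules=30_000, seed=6,
                            substitution_error_rate=0.0, replicates=1)
        pairs, _ = simulate_replicate(sample, cfg, 0)
        assert pairs and all(p.r1.startswith(NESTED_PRIMER) for p in pairs)
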