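"""Simulator tests: genomes, strain sets, abundances, error model, shredding."""
import math

import numpy as np
import pytest

import microdepth as m
from microdepth._dna import revcomp
from microdepth.synthgen import ErrorProfile, apply_edits

from oracle_utils import brute_mismatch_count


class TestGenerateAncestor:
    def test_gc_fraction_recovered(self):
        g = m.generate_ancestor(10_000, 0.5, seed=1)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert abs(gc - 0.5) < 0.02

    def test_degenerate_gc_zero_gives_at_only(self):
        g = m.generate_ancestor(10_000, 0.0, seed=1)
        assert set(g.sequence) <= {"A", "T"}

    def test_seeded_determinism(self):
        assert (m.generate_ancestor(2_000, 0.4, seed=9).sequence
                == m.generate_ancestor(2_000, 0.4, seed=9).sequence)

    @pytest.mark.parametrize("length,gc", [(100, 0.5), (0, 0.5), (-5, 0.5),
                                           (2_000, -0.1), (2_000, 1.5)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            m.generate_ancestor(length, gc, seed=0)


class TestDeriveStrainSet:
    def test_single_strain_is_ancestor(self, ancestor10k):
        sset = m.derive_strain_set(ancestor10k, 1, (0.0, 0.02), seed=0)
        assert sset.strains[0].sequence == ancestor10k.sequence
        assert sset.pairwise_ani.tolist() == [[1.0]]

    def test_exact_substitution_count_and_ani(self):
        # fixed 1% divergence on 100 kb: exactly 1000 substituted positions
        anc = m.generate_ancestor(100_000, 0.5, seed=3)
        sset = m.derive_strain_set(anc, 2, (0.01, 0.01), seed=4)
        diff = brute_mismatch_count(anc.sequence, sset.strains[1].sequence)
        assert diff == 1000
        assert sset.pairwise_ani[0, 1] == pytest.approx(0.99, abs=1e-12)

    def test_pairwise_ani_matches_bruteforce_hamming(self, ancestor10k):
        sset = m.derive_strain_set(ancestor10k, 8, (0.0, 0.0249), seed=5)
        seqs = [np.frombuffer(g.sequence.encode(), dtype=np.uint8)
                for g in sset.strains]
        for i in range(8):
            for j in range(8):
                ham = int(np.count_nonzero(seqs[i] != seqs[j]))
                expected = 1.0 - ham / ancestor10k.length
                assert sset.pairwise_ani[i, j] == pytest.approx(expected,
                                                               abs=1e-12)

    def test_offdiagonal_ani_within_configured_range(self, ancestor10k):
        # two strains each <= 2.49% from the ancestor differ <= 4.98%
        sset = m.derive_strain_set(ancestor10k, 20, (0.0, 0.0249), seed=6)
        off = sset.pairwise_ani[~np.eye(20, dtype=bool)]
        assert off.min() >= 0.9502
        assert off.max() <= 1.0

    def test_divergence_beyond_recruitment_regime_rejected(self, ancestor10k):
        with pytest.raises(ValueError):
            m.derive_strain_set(ancestor10k, 2, (0.0, 0.06), seed=0)
        with pytest.raises(ValueError):
            m.derive_strain_set(ancestor10k, 0, (0.0, 0.01), seed=0)


class TestAbundances:
    def test_single_strain_normalizes_to_one(self):
        assert m.sample_lognormal_abundances(1, 1.0, seed=7).weights.tolist() \
            == [1.0]

    def test_simplex_membership(self):
        ab = m.sample_lognormal_abundances(5, 1.0, seed=7)
        assert np.all(ab.weights > 0)
        assert ab.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_log_weights_are_normal(self):
        from scipy import stats
        ab = m.sample_lognormal_abundances(1000, 1.0, seed=8)
        assert abs(stats.skew(np.log(ab.weights))) < 0.25

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            m.sample_lognormal_abundances(3, 0.0, seed=0)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, clonal_set,
                                                   single_abundance):
        reads = m.simulate_reads(clonal_set, single_abundance, 300, 150,
                                 m.ERROR_FREE, seed=11)
        genome = clonal_set.ancestor.sequence
        for r in reads:
            probe = revcomp(r.sequence) if r.strand == "-" else r.sequence
            assert probe in genome
            assert r.true_identity == 1.0

    def test_q20_mean_identity_matches_event_model(self, clonal_set,
                                                   single_abundance):
        n, rl = 20_000, 150
        reads = m.simulate_reads(clonal_set, single_abundance, n, rl, m.Q20,
                                 seed=12)
        ident = np.array([r.true_identity for r in reads])
        p = m.Q20
        events_per_base = (p.p_ins + p.p_del + p.p_mm
                           + (p.p_mm_start * p.start_window
                              + p.p_mm_end * p.end_window) / rl)
        expected = 1.0 - events_per_base  # first-order: one column per event
        se = ident.std() / math.sqrt(n)
        assert abs(ident.mean() - expected) < 3 * se + 2e-4

    def test_per_base_mismatch_rate_recovered(self, clonal_set,
                                              single_abundance):
        # mismatch-only profile so read offsets stay aligned to the source
        profile = ErrorProfile(0.0, 0.0, 0.006, 0.0, 0.0)
        n, rl = 30_000, 150
        reads = m.simulate_reads(clonal_set, single_abundance, n, rl, profile,
                                 seed=13)
        n_mm = sum(len(r.edits) for r in reads)
        rate = n_mm / (n * rl)
        se = math.sqrt(0.006 * 0.994 / (n * rl))
        assert abs(rate - 0.006) < 3 * se

    def test_window_mismatches_stay_in_window(self, clonal_set,
                                              single_abundance):
        profile = ErrorProfile(0.0, 0.0, 0.0, 0.05, 0.0, start_window=10)
        reads = m.simulate_reads(clonal_set, single_abundance, 2_000, 150,
                                 profile, seed=14)
        offsets = [off for r in reads for off, kind, _ in r.edits]
        assert offsets  # elevated rate produces events
        assert all(off < 10 for off in offsets)

    def test_abundance_recovery(self, ancestor10k):
        sset = m.derive_strain_set(ancestor10k, 5, (0.0, 0.01), seed=15)
        ab = m.sample_lognormal_abundances(5, 1.0, seed=16)
        n = 100_000
        reads = m.simulate_reads(sset, ab, n, 150, m.ERROR_FREE, seed=17)
        counts = {g.id: 0 for g in sset.strains}
        for r in reads:
            counts[r.source_strain] += 1
        for g, w in zip(sset.strains, ab.weights):
            se = math.sqrt(n * w * (1 - w))
            assert abs(counts[g.id] - n * w) < 3 * se

    def test_edit_composition_reconstructs_every_read(self, mix_set):
        sset, ab = mix_set
        reads = m.simulate_reads(sset, ab, 400, 150, m.Q20, seed=18)
        by_id = {g.id: g.sequence for g in sset.strains}
        assert any(r.edits for r in reads)
        for r in reads:
            window = by_id[r.source_strain][r.start:r.start + 150]
            if r.strand == "-":
                window = revcomp(window)
            assert apply_edits(window, r.edits) == r.sequence

    def test_per_read_mode_bounds_events(self, clonal_set, single_abundance):
        profile = ErrorProfile(0.3, 0.3, 0.3, 0.0, 0.0)
        reads = m.simulate_reads(clonal_set, single_abundance, 500, 100,
                                 profile, seed=19, per_read=True)
        assert any(r.edits for r in reads)
        assert all(len(r.edits) <= 3 for r in reads)

    def test_rejects_bad_inputs(self, clonal_set, single_abundance):
        with pytest.raises(ValueError):
            m.simulate_reads(clonal_set, single_abundance, 0, 150)
        with pytest.raises(ValueError):
            bad = m.AbundanceProfile(np.array([0.5, 0.5]))
            m.simulate_reads(clonal_set, bad, 10, 150)
        with pytest.raises(ValueError):
            m.simulate_reads(clonal_set, single_abundance, 10,
                             clonal_set.ancestor.length + 1)


class TestSimulateMetagenome:
    def test_byte_identical_outputs_under_same_seed(self, tmp_path, mix_set):
        sset, ab = mix_set
        outs = []
        for name in ("a", "b"):
            res = m.simulate_metagenome(sset, ab, 300, 150, m.Q30, seed=31,
                                        out_prefix=tmp_path / name)
            outs.append(res)
        assert outs[0].fastq.read_bytes() == outs[1].fastq.read_bytes()
        assert outs[0].sam.read_bytes() == outs[1].sam.read_bytes()
        assert outs[0].truth.read_bytes() == outs[1].truth.read_bytes()

    def test_truth_sam_is_valid_for_pysam(self, q20_recruits):
        sim, reads = q20_recruits
        assert len(reads) == 600
        assert all(r.ref_start >= 0 for r in reads)


class TestShred:
    def _write_fastq(self, path, records):
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def _read_fastq(self, path):
        lines = path.read_text().splitlines()
        return [(lines[i][1:], lines[i + 1]) for i in range(0, len(lines), 4)]

    def test_fragment_lengths(self, tmp_path):
        src = tmp_path / "long.fastq"
        self._write_fastq(src, [("long1", "ACGT" * 162 + "AC")])  # 650 bp
        out = tmp_path / "frag.fastq"
        n = m.shred_reads(src, out, fragment_length=200)
        frags = self._read_fastq(out)
        assert n == 4
        assert [len(s) for _, s in frags] == [200, 200, 200, 50]

    def test_short_read_passes_unchanged(self, tmp_path):
        src = tmp_path / "short.fastq"
        self._write_fastq(src, [("s1", "ACGTACGT")])
        out = tmp_path / "out.fastq"
        assert m.shred_reads(src, out, fragment_length=200) == 1
        assert self._read_fastq(out)[0][1] == "ACGTACGT"

    def test_total_bases_conserved(self, tmp_path):
        src = tmp_path / "mixed.fastq"
        recs = [("a", "A" * 650), ("b", "C" * 200), ("c", "G" * 73)]
        self._write_fastq(src, recs)
        out = tmp_path / "out.fastq"
        m.shred_reads(src, out, fragment_length=200)
        total = sum(len(s) for _, s in self._read_fastq(out))
        assert total == sum(len(s) for _, s in recs)

    def test_drop_terminal_fragments(self, tmp_path):
        src = tmp_path / "r.fastq"
        self._write_fastq(src, [("a", "A" * 650)])
        out = tmp_path / "out.fastq"
        assert m.shred_reads(src, out, 200, keep_terminal=False) == 3

    def test_malformed_fastq_raises(self, tmp_path):
        src = tmp_path / "bad.fastq"
        src.write_text("@read1\nACGT\nNOPLUS\nIIII\n")
        with pytest.raises(ValueError):
            m.shred_reads(src, tmp_path / "out.fastq")
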