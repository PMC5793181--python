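"""Synthetic-data generator: determinism, construction rules, calibration."""

import numpy as np
import pandas as pd
import pytest

from srnascape import io as sio
from srnascape.preprocess import trim_adapter
from srnascape.simulate import (
    CapacityError,
    SimulationConfig,
    build_reference,
    simulate_counts,
    simulate_paired_expression,
    spearman_to_pearson,
    synthesize_reads,
)


def mini_config(**kwargs):
    defaults = dict(
        seed=3,
        reads_per_sample=2_000,
        chromosome_length=20_000,
        design=(("BL1_1", "BL1"), ("BL1_2", "BL1"), ("LAR_1", "LAR"), ("LAR_2", "LAR")),
        features_per_category={"miRNA": 10, "tRNA": 5},
        spike_table=[],
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_probability_maps_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mini_config(nta_probs={0: 0.5, 1: 0.4})

    def test_mirna_lengths_constrained_to_mature_band(self):
        with pytest.raises(ValueError):
            mini_config(category_length_ranges={"miRNA": (15, 25), "tRNA": (73, 94)})

    def test_trna_lengths_constrained(self):
        with pytest.raises(ValueError):
            mini_config(category_length_ranges={"miRNA": (19, 25), "tRNA": (60, 94)})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            mini_config(features_per_category={"lncRNA": 5})

    def test_unknown_subtype_in_spike_rejected(self):
        cfg = mini_config()
        with pytest.raises(ValueError):
            cfg.replace(spike_table=[("miRNA_0001", "HER2", 2.0)])


class TestBuildReference:
    def test_deterministic_serialization(self, tmp_path):
        cfg = mini_config()
        for run in ("a", "b"):
            genome, features = build_reference(cfg)
            sio.write_fasta(genome, tmp_path / f"{run}.fa")
            sio.write_gff3(features, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_requested_features_only(self):
        cfg = mini_config(features_per_category={"miRNA": 10})
        _genome, features = build_reference(cfg)
        assert len(features) == 10
        assert all(f.category == "miRNA" for f in features)
        assert all(19 <= f.length <= 25 for f in features)

    def test_no_pairwise_overlap_brute_force(self):
        cfg = mini_config(
            features_per_category={"miRNA": 30, "tRNA": 10, "snoRNA": 10}
        )
        _genome, features = build_reference(cfg)
        for i, a in enumerate(features):
            for b in features[i + 1 :]:
                if a.chrom != b.chrom:
                    continue
                assert a.end <= b.start or b.end <= a.start, (a, b)

    def test_trna_features_carry_anticodons(self):
        _genome, features = build_reference(mini_config())
        for f in features:
            assert (f.anticodon is not None) == (f.category == "tRNA")

    def test_capacity_error_when_genome_too_small(self):
        cfg = mini_config(
            chromosome_length=300,
            n_chromosomes=1,
            features_per_category={"tRNA": 10},
        )
        with pytest.raises(CapacityError):
            build_reference(cfg)

    def test_gff_roundtrip(self, tmp_path):
        _genome, features = build_reference(mini_config())
        sio.write_gff3(features, tmp_path / "f.gff3")
        assert sio.read_gff3(tmp_path / "f.gff3") == features


class TestSimulateCounts:
    def test_columns_sum_to_reads_per_sample(self):
        cfg = mini_config()
        _g, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        assert (truth.realized.sum(axis=0) == cfg.reads_per_sample).all()
        assert np.allclose(truth.expected.sum(axis=0), cfg.reads_per_sample)

    def test_no_spike_means_no_subtype_effect(self):
        """Without spikes, group means agree within the Monte-Carlo CI."""
        diffs = []
        for seed in range(50):
            cfg = mini_config(seed=seed)
            _g, features = build_reference(cfg)
            truth = simulate_counts(cfg, features)
            bl1 = truth.realized[["BL1_1", "BL1_2"]].mean(axis=1)
            lar = truth.realized[["LAR_1", "LAR_2"]].mean(axis=1)
            diffs.append((bl1 - lar).mean())
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 4 * se + 1e-9

    def test_spiked_fold_change_recovered(self):
        """A +3 log2 spike yields a realized LAR/non-LAR ratio near 8.

        Many features keep the spiked feature's library share small, so the
        multinomial's compositional coupling does not distort the ratio.
        """
        lar_total = other_total = 0.0
        for seed in range(50):
            cfg = mini_config(
                seed=seed,
                features_per_category={"miRNA": 200},
                baseline_log2_sd=0.5,
                reads_per_sample=20_000,
                spike_table=[("miRNA_0001", "LAR", 3.0)],
            )
            _g, features = build_reference(cfg)
            truth = simulate_counts(cfg, features)
            lar_total += truth.realized.loc[
                "miRNA_0001", ["LAR_1", "LAR_2"]
            ].mean()
            other_total += truth.realized.loc[
                "miRNA_0001", ["BL1_1", "BL1_2"]
            ].mean()
        ratio = lar_total / other_total
        assert 6.0 <= ratio <= 10.7

    def test_unknown_spike_feature_rejected(self):
        cfg = mini_config(spike_table=[("miRNA_9999", "LAR", 2.0)])
        _g, features = build_reference(cfg)
        with pytest.raises(ValueError):
            simulate_counts(cfg, features)


class TestSynthesizeReads:
    def test_zero_noise_reads_are_feature_substrings(self):
        cfg = mini_config(
            error_rate=0.0,
            nta_probs={0: 1.0},
            isomir_offset_probs={0: 1.0},
        )
        genome, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        reads, prov = synthesize_reads(truth, genome, features, cfg)
        seqs = {
            f.feature_id: genome[f.chrom][f.start : f.end] for f in features
        }
        for sample, rr in reads.items():
            for (rid, seq), row in zip(
                rr, prov[prov.sample_id == sample].itertuples()
            ):
                insert = trim_adapter(seq, cfg.adapter_sequence)
                frag = seqs[row.feature_id][row.frag_start : row.frag_end][
                    : cfg.read_length
                ]
                if len(insert) <= len(frag):
                    # spurious early trim can only shorten the templated part
                    assert frag.startswith(insert), rid
                else:
                    # reads truncated before min_overlap adapter bases keep
                    # an untrimmable adapter remnant (< 5 nt)
                    assert insert[: len(frag)] == frag, rid
                    remnant = insert[len(frag) :]
                    assert len(remnant) < 5, rid
                    assert cfg.adapter_sequence.startswith(remnant), rid

    def test_forced_two_base_nta_on_mirna_reads(self):
        cfg = mini_config(
            error_rate=0.0, nta_probs={2: 1.0}, isomir_offset_probs={0: 1.0}
        )
        genome, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        reads, prov = synthesize_reads(truth, genome, features, cfg)
        mirna = prov[prov.category == "miRNA"]
        assert len(mirna) > 0
        assert (mirna.nta_len == 2).all()
        seq_by_id = {rid: s for rr in reads.values() for rid, s in rr}
        feats = {f.feature_id: f for f in features}
        for row in mirna.sample(50, random_state=0).itertuples():
            f = feats[row.feature_id]
            insert_len = row.frag_end - row.frag_start
            read = seq_by_id[row.read_id]
            # two bases between the templated insert and the adapter
            assert read[insert_len + 2 :].startswith(
                cfg.adapter_sequence[: len(read) - insert_len - 2]
            )

    def test_error_rate_matches_binomial(self):
        """Observed substitutions vs genome within 3 SD of Binomial."""
        cfg = mini_config(
            seed=9,
            error_rate=0.01,
            reads_per_sample=5_000,
            design=(("BL1_1", "BL1"),),
            features_per_category={"miRNA": 10},
            nta_probs={0: 1.0},
            isomir_offset_probs={0: 1.0},
        )
        genome, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        reads, prov = synthesize_reads(truth, genome, features, cfg)
        seqs = {f.feature_id: genome[f.chrom][f.start : f.end] for f in features}
        total_bases = 0
        mismatches = 0
        for (rid, seq), row in zip(reads["BL1_1"], prov.itertuples()):
            clean = (seqs[row.feature_id] + cfg.adapter_sequence)[: cfg.read_length]
            assert len(clean) == len(seq)
            total_bases += len(seq)
            mismatches += sum(1 for a, b in zip(clean, seq) if a != b)
        assert total_bases >= 100_000
        expected = total_bases * 0.01
        sd = np.sqrt(total_bases * 0.01 * 0.99)
        assert abs(mismatches - expected) <= 3 * sd

    def test_read_counts_match_provenance_and_truth(self):
        cfg = mini_config()
        genome, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        reads, prov = synthesize_reads(truth, genome, features, cfg)
        for sample, rr in reads.items():
            assert len(rr) == cfg.reads_per_sample
            assert (prov.sample_id == sample).sum() == cfg.reads_per_sample
        assert prov.read_id.is_unique

    def test_deterministic_under_seed(self):
        cfg = mini_config()
        genome, features = build_reference(cfg)
        truth = simulate_counts(cfg, features)
        r1, p1 = synthesize_reads(truth, genome, features, cfg)
        r2, p2 = synthesize_reads(truth, genome, features, cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(p1, p2)


class TestPairedExpression:
    def test_rho_one_preserved_exactly(self):
        from srnascape.correlation import spearman

        srna, mrna, _ = simulate_paired_expression(
            3, 3, 30, [("sRNA_0001", "mRNA_0001", 1.0)], seed=5
        )
        rho, _ = spearman(srna.loc["sRNA_0001"], mrna.loc["mRNA_0001"])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_target_rho_calibration(self):
        from srnascape.correlation import spearman

        rhos = []
        for seed in range(20):
            srna, mrna, _ = simulate_paired_expression(
                2, 2, 1000, [("sRNA_0001", "mRNA_0001", 0.8)], seed=seed
            )
            rhos.append(
                spearman(srna.loc["sRNA_0001"], mrna.loc["mRNA_0001"])[0]
            )
        assert abs(np.mean(rhos) - 0.8) < 0.05

    def test_non_designated_pairs_uncorrelated(self):
        from srnascape.correlation import spearman

        ok = 0
        for seed in range(100):
            srna, mrna, _ = simulate_paired_expression(2, 2, 1000, [], seed=seed)
            rho, _ = spearman(srna.loc["sRNA_0002"], mrna.loc["mRNA_0002"])
            ok += abs(rho) < 0.1
        assert ok >= 95

    def test_invalid_target_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_paired_expression(
                2, 2, 10, [("sRNA_0001", "mRNA_0001", 1.5)], seed=0
            )

    def test_gaussian_map_endpoints(self):
        assert spearman_to_pearson(0.0) == 0.0
        assert spearman_to_pearson(1.0) == pytest.approx(1.0)
        assert spearman_to_pearson(-1.0) == pytest.approx(-1.0)
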