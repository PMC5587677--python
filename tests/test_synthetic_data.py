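"""Generator contracts: determinism, planted structure, truth soundness."""

import numpy as np
import pandas as pd
import pytest

from lncwheat import synthetic_data as sim
from lncwheat.synthetic_data import ConfigError, GeneratorConfig

from oracles import brute_longest_orf


class TestConfigValidation:
    def test_lncrna_range_must_exceed_200(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(lncrna_length_range=(150, 500))

    def test_event_mix_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(as_event_mix={"intron_retention": 0.5, "other": 0.4})

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_coding=-1)

    def test_coding_range_must_fit_orf(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(coding_length_range=(250, 500), coding_orf_min=300)


class TestTranscriptome:
    def test_deterministic_across_runs(self, small_config, small_dataset):
        t1, truth1 = small_dataset
        t2, truth2 = sim.generate_transcriptome(small_config)
        assert [a.sequence for a in t1] == [b.sequence for b in t2]
        pd.testing.assert_frame_equal(truth1.transcripts, truth2.transcripts)

    def test_class_counts_match_config(self, small_config, small_dataset):
        _, truth = small_dataset
        vc = truth.transcripts["true_class"].value_counts()
        assert vc["coding"] == small_config.n_coding
        assert vc["lncRNA"] == small_config.n_lncrna
        assert vc["contaminant"] == small_config.n_contaminant

    def test_zero_lncrna_config(self):
        cfg = GeneratorConfig(seed=1, n_coding=5, n_lncrna=0, n_contaminant=2)
        _, truth = sim.generate_transcriptome(cfg)
        assert (truth.transcripts["true_class"] == "lncRNA").sum() == 0

    def test_every_coding_transcript_has_long_orf(self, small_dataset):
        transcripts, truth = small_dataset
        for t in transcripts:
            if truth.transcripts.loc[t.id, "true_class"] == "coding":
                assert brute_longest_orf(t.sequence) >= 240

    def test_planted_orf_span_is_a_real_orf(self, small_dataset):
        transcripts, truth = small_dataset
        info = truth.transcripts
        for t in transcripts[:20]:
            if info.loc[t.id, "true_class"] != "coding":
                continue
            s, e = int(info.loc[t.id, "orf_start"]), int(info.loc[t.id, "orf_end"])
            orf = t.sequence[s:e]
            assert orf.startswith("ATG") and orf[-3:] in ("TAA", "TAG", "TGA")
            assert (e - s) % 3 == 0

    def test_no_lncrna_contains_coding_scale_orf(self, small_dataset):
        transcripts, truth = small_dataset
        for t in transcripts:
            if truth.transcripts.loc[t.id, "true_class"] == "lncRNA":
                assert brute_longest_orf(t.sequence) < 240

    def test_lncrna_gc_within_three_points_of_target(self, small_config, small_dataset):
        _, truth = small_dataset
        gc = truth.transcripts.query("true_class == 'lncRNA'")["gc"]
        assert (abs(gc - small_config.lncrna_gc_target) <= 0.03).all()

    def test_contaminants_are_high_identity_fixture_copies(self, small_dataset):
        from lncwheat._tables import CONTAMINANT_FIXTURES

        transcripts, truth = small_dataset
        fixtures = dict(CONTAMINANT_FIXTURES)
        for t in transcripts:
            row = truth.transcripts.loc[t.id]
            if row["true_class"] != "contaminant":
                continue
            ref = fixtures[row["source"]]
            assert len(t.sequence) == len(ref)
            ident = sum(a == b for a, b in zip(t.sequence, ref)) / len(ref)
            assert ident >= 0.96


class TestCounts:
    def test_fixed_seed_reproduces_matrix(self, small_config, small_dataset):
        _, truth = small_dataset
        m1 = sim.generate_counts(truth, small_config)
        m2 = sim.generate_counts(truth, small_config)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_planted_condition_mean_ratio_is_exact(self, small_config, small_dataset):
        _, truth = small_dataset
        sim.generate_counts(truth, small_config)
        de = truth.de
        planted = de[de["de_status"] != "none"]
        assert (planted["planted_log2fc"].abs() == small_config.de_log2fc).all()
        ups = (de["de_status"] == "up").sum()
        downs = (de["de_status"] == "down").sum()
        assert abs(ups - downs) <= 1  # symmetric planting

    def test_no_de_when_fraction_zero(self):
        cfg = GeneratorConfig(seed=2, n_coding=200, n_lncrna=0, n_contaminant=0,
                              de_fraction=0.0)
        _, truth = sim.generate_transcriptome(cfg)
        m = sim.generate_counts(truth, cfg)
        assert (truth.de["de_status"] == "none").all()
        # condition mean ratio distribution centred at 1
        ctrl = m.counts[m.samples_of("control")].mean(axis=1)
        drt = m.counts[m.samples_of("drought")].mean(axis=1)
        ratio = (drt + 1) / (ctrl + 1)
        assert 0.9 < ratio.median() < 1.1

    def test_poisson_limit_as_dispersion_vanishes(self):
        cfg = GeneratorConfig(seed=3, n_coding=5000, n_lncrna=0, n_contaminant=0,
                              nb_dispersion=0.0, de_fraction=0.0, n_replicates=2)
        _, truth = sim.generate_transcriptome(cfg)
        m = sim.generate_counts(truth, cfg)
        mu = truth.de["base_mean"].to_numpy()
        x = m.counts.to_numpy()[:, :1].ravel()
        # pooled variance-to-mean of (count - mu): var of Poisson = mean
        z = (x - mu) / np.sqrt(mu)
        assert abs(np.var(z) - 1.0) < 0.1

    def test_lncrna_expression_below_coding(self):
        cfg = GeneratorConfig(seed=4, n_coding=300, n_lncrna=300, n_contaminant=0,
                              de_fraction=0.0)
        _, truth = sim.generate_transcriptome(cfg)
        m = sim.generate_counts(truth, cfg)
        means = m.counts.mean(axis=1)
        cls = truth.transcripts["true_class"]
        assert means[cls == "lncRNA"].mean() < means[cls == "coding"].mean()


@pytest.fixture(scope="module")
def planted():
    cfg = GeneratorConfig(seed=9, n_coding=0, n_lncrna=40, n_contaminant=0,
                          n_precursors=12)
    ts, truth = sim.generate_transcriptome(cfg)
    matures = sim.synthetic_mature_set(cfg, n=12)
    ts, table = sim.plant_mirna_precursors(ts, matures, cfg, truth)
    return ts, table, matures


class TestPrecursors:

    def test_recorded_hamming_distance_is_exact(self, planted):
        ts, table, matures = planted
        by_id = {t.id: t.sequence for t in ts}
        for _, row in table.iterrows():
            window = by_id[row.transcript_id][row.mature_start : row.mature_end]
            mature = matures[row.mature_name].replace("U", "T")
            dist = sum(a != b for a, b in zip(window, mature))
            assert dist == row.mismatches <= 2

    def test_zero_substitution_plants_are_exact_substrings(self, planted):
        ts, table, matures = planted
        by_id = {t.id: t.sequence for t in ts}
        exact = table[table.mismatches == 0]
        assert len(exact) > 0
        for _, row in exact.iterrows():
            assert matures[row.mature_name].replace("U", "T") in by_id[row.transcript_id]

    def test_hairpin_loop_separates_arms(self, planted):
        _, table, _ = planted
        # mature occupies one arm: hairpin length minus two arms >= 6 nt loop
        arm = table.mature_end - table.mature_start
        loop = (table.hairpin_end - table.hairpin_start) - 2 * arm
        assert (loop >= 6).all()

    def test_planted_hairpins_fold_with_mature_mostly_paired(self, planted):
        from lncwheat import mirnet as M

        ts, table, _ = planted
        by_id = {t.id: t.sequence for t in ts}
        fracs = []
        for _, row in table.iterrows():
            hit = M.MatureHit(row.transcript_id, row.mature_name,
                              row.mature_start, row.mature_end, row.mismatches)
            call = M.validate_precursor(by_id[row.transcript_id], hit)
            fracs.append(call.mature_paired_fraction)
        assert np.mean(np.array(fracs) >= 0.6) >= 0.9


class TestToyGenome:
    def test_gff_round_trip_has_zero_drift(self, tmp_path):
        from lncwheat import splice as S

        cfg = GeneratorConfig(seed=5, n_coding=80, n_lncrna=0, n_contaminant=0,
                              n_as_loci=25)
        _, truth = sim.generate_transcriptome(cfg)
        genome, gff = sim.generate_toy_genome(truth, cfg)
        path = tmp_path / "aln.gff3"
        path.write_text(gff)
        models = {m.transcript_id: m for m in S.load_alignments(path)}
        for _, row in truth.models.iterrows():
            assert list(models[row.transcript_id].exons) == [tuple(e) for e in row.exons]

    def test_chromosome_names_cover_both_subgenomes_and_scaffolds(self):
        cfg = GeneratorConfig(seed=6, n_coding=80, n_lncrna=0, n_contaminant=0,
                              n_as_loci=25)
        _, truth = sim.generate_transcriptome(cfg)
        genome, _ = sim.generate_toy_genome(truth, cfg)
        assert any(c.endswith("A") for c in genome)
        assert any(c.endswith("B") for c in genome)
        assert any(c.startswith("scaffold") for c in genome)

    def test_single_event_type_mix(self):
        cfg = GeneratorConfig(seed=7, n_coding=40, n_lncrna=0, n_contaminant=0,
                              n_as_loci=10,
                              as_event_mix={"exon_skipping": 1.0})
        _, truth = sim.generate_transcriptome(cfg)
        sim.generate_toy_genome(truth, cfg)
        assert set(truth.events["event_type"]) == {"exon_skipping"}

    def test_intron_retention_construction_rule(self):
        cfg = GeneratorConfig(seed=8, n_coding=40, n_lncrna=0, n_contaminant=0,
                              n_as_loci=10,
                              as_event_mix={"intron_retention": 1.0})
        _, truth = sim.generate_transcriptome(cfg)
        sim.generate_toy_genome(truth, cfg)
        chains = truth.models.set_index("transcript_id")["exons"]
        for _, ev in truth.events.iterrows():
            c1 = chains[ev.transcript_1]
            c2 = chains[ev.transcript_2]
            spliced, retained = (c1, c2) if len(c1) > len(c2) else (c2, c1)
            intron = (spliced[0][1], spliced[1][0])
            assert retained[0][0] <= intron[0] and intron[1] <= retained[0][1]
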