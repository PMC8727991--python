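"""Ground-truth generator: genome construction, mutation and read sampling."""

import numpy as np
import pandas as pd
import pytest

from mamutspec.simulate import (
    ExperimentConfig,
    GenomeSpec,
    SpectrumConfig,
    build_reference,
    default_spectrum,
    simulate_ma_lines,
    simulate_read_evidence,
)
from mamutspec.study_tables import SUBSTITUTION_CLASSES


def _flat_spectrum(snp_rate=0.0, indel_rate=0.0, **kw):
    rates = {c: snp_rate / 6 for c in SUBSTITUTION_CLASSES}
    return SpectrumConfig(substitution_rates=rates, indel_rate=indel_rate, **kw)


class TestBuildReference:
    def test_explicit_run_planted_verbatim(self):
        spec = GenomeSpec(chromosomes=(("I", 20_000),), place_genes=False,
                          explicit_repeats=(("I", 1000, "A", 11),))
        ref = build_reference(spec, seed=3)
        assert ref.genome.seqs["I"][1000:1011] == "A" * 11
        # flanks break the run so the planted length is exact
        assert ref.genome.seqs["I"][999] != "A"
        assert ref.genome.seqs["I"][1011] != "A"
        assert any(r.start == 1000 and r.length == 11
                   for r in ref.catalog.runs if r.chrom == "I")

    def test_explicit_run_breaking_a_reading_frame_is_rejected(self):
        spec = GenomeSpec(chromosomes=(("I", 60_000),))
        ref = build_reference(spec, seed=3)
        exon_start = ref.layers.genes[0].exons[0][0]
        bad = GenomeSpec(chromosomes=(("I", 60_000),),
                         explicit_repeats=(("I", exon_start, "A", 7),))
        with pytest.raises(ValueError, match="frame"):
            build_reference(bad, seed=3)

    def test_background_gc_concentrates_near_target(self):
        spec = GenomeSpec(chromosomes=(("I", 500_000),), place_genes=False,
                          at_runs_per_mb={}, gc_runs_per_mb={},
                          dinuc_runs_per_mb={}, tri_runs_per_mb=0,
                          tetra_runs_per_mb=0)
        ref = build_reference(spec, seed=9)
        assert 0.34 <= ref.genome.gc_fraction() <= 0.38

    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = GenomeSpec(chromosomes=(("I", 50_000),))
        a = build_reference(spec, seed=7, out_dir=tmp_path / "a")
        b = build_reference(spec, seed=7, out_dir=tmp_path / "b")
        assert a.genome.seqs == b.genome.seqs
        assert (tmp_path / "a/genome.fa").read_bytes() == \
            (tmp_path / "b/genome.fa").read_bytes()
        c = build_reference(spec, seed=8)
        assert c.genome.seqs != a.genome.seqs

    def test_mito_chromosome_is_flagged(self):
        spec = GenomeSpec(chromosomes=(("I", 30_000),), mito_length=13_794)
        ref = build_reference(spec, seed=1)
        assert ref.genome.is_mito("MtDNA")
        assert ref.genome.length("MtDNA") == 13_794
        assert ref.genome.nuclear_names == ["I"]


class TestSimulateMaLines:
    def test_zero_rates_give_empty_truth(self, toy_reference):
        exp = ExperimentConfig(n_lines=3, generations=10, seed=1)
        truth = simulate_ma_lines(toy_reference, _flat_spectrum(), exp)
        assert truth.empty

    def test_poisson_expectation_of_substitution_counts(self):
        """rate 1e-5/site/gen, B=1e5, G=10: mean 10 per line within 3 SE."""
        spec = GenomeSpec(chromosomes=(("I", 100_000),), place_genes=False)
        ref = build_reference(spec, seed=21)
        B = ref.genome.callable_bases()
        sp = _flat_spectrum(snp_rate=1e-5, at_ta_boundary_fraction=0.0)
        exp = ExperimentConfig(n_lines=20, generations=10, seed=21)
        truth = simulate_ma_lines(ref, sp, exp)
        counts = truth.groupby("line").size().reindex(exp.line_ids, fill_value=0)
        expected = 1e-5 * 10 * B
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_deletion_bias_two_to_one(self, toy_reference):
        """2:1 bias over >=2000 indels recovers deletion fraction 2/3."""
        sp = _flat_spectrum(indel_rate=1e-4, deletion_bias=2.0,
                            dinucleotide_fraction=0.0)
        exp = ExperimentConfig(n_lines=4, generations=40, seed=2)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        assert len(truth) >= 2000
        frac = (truth["vtype"] == "deletion").mean()
        assert frac == pytest.approx(2 / 3, abs=0.03)

    def test_mutations_are_unique_per_line_and_position(self, toy_reference):
        sp = default_spectrum().scaled(100)
        exp = ExperimentConfig(n_lines=3, generations=40, seed=5)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        assert not truth.duplicated(["line", "chrom", "pos"]).any()

    def test_truth_matches_reference_alleles(self, toy_reference):
        sp = default_spectrum().scaled(100)
        exp = ExperimentConfig(n_lines=2, generations=40, seed=6)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        for r in truth.sample(50, random_state=0).itertuples():
            seq = toy_reference.genome.seqs[r.chrom]
            assert seq[r.pos - 1 : r.pos - 1 + len(r.ref)] == r.ref
            assert r.ref != r.alt

    def test_excessive_rate_warns(self, toy_reference):
        sp = _flat_spectrum(snp_rate=0.01)
        exp = ExperimentConfig(n_lines=1, generations=20, seed=1)
        with pytest.warns(UserWarning, match="10%"):
            simulate_ma_lines(toy_reference, sp, exp)

    def test_at_ta_events_concentrate_at_run_boundaries(self, toy_reference):
        from mamutspec.spectrum import annotate_records

        sp = default_spectrum().scaled(300)
        exp = ExperimentConfig(n_lines=10, generations=40, seed=9)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        recs = annotate_records(truth, toy_reference.genome,
                                toy_reference.layers, toy_reference.catalog,
                                coding_effects=False)
        atta = recs[recs["subst_class"] == "A/T->T/A"]
        other = recs[recs["subst_class"].isin(["A/T->G/C", "G/C->A/T"])]
        assoc = atta["repeat_status"].isin(["adjacent", "in_repeat"]).mean()
        assert len(atta) > 100
        assert assoc > 0.6  # boundary fraction 0.8 minus resampling losses
        assert assoc > 2 * other["repeat_status"].isin(
            ["adjacent", "in_repeat"]).mean()

    def test_per_line_generations_scale_counts(self):
        spec = GenomeSpec(chromosomes=(("I", 100_000),), place_genes=False)
        ref = build_reference(spec, seed=4)
        sp = _flat_spectrum(snp_rate=2e-5, at_ta_boundary_fraction=0.0)
        exp = ExperimentConfig(n_lines=2, generations=(10, 40), seed=4)
        truth = simulate_ma_lines(ref, sp, exp)
        counts = truth.groupby("line").size()
        assert counts["L02"] > 2 * counts["L01"]


@pytest.fixture(scope="module")
def small_sim(toy_reference):
    sp = default_spectrum().scaled(60)
    exp = ExperimentConfig(n_lines=6, generations=40, n_noise_sites=3000,
                           error_rate=0.01, depth=30, seed=17)
    truth = simulate_ma_lines(toy_reference, sp, exp)
    return truth, exp, simulate_read_evidence(truth, toy_reference, exp)


class TestReadEvidence:
    def test_no_error_limit_gives_full_support(self, toy_reference):
        sp = default_spectrum().scaled(60)
        exp = ExperimentConfig(n_lines=2, generations=40, error_rate=0.0,
                               n_noise_sites=100, seed=3)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        ev = simulate_read_evidence(truth, toy_reference, exp)
        true_calls = ev.calls.merge(ev.truth_keys)
        assert (true_calls["K"] == true_calls["N"]).all()
        assert len(ev.calls) == len(true_calls)  # no noise calls at e = 0

    def test_noise_support_fraction_matches_error_rate(self, small_sim):
        truth, exp, ev = small_sim
        noise_pile = ev.pileup.merge(ev.noise_keys)
        frac = noise_pile["K"].sum() / noise_pile["N"].sum()
        assert frac == pytest.approx(0.01, abs=0.002)

    def test_ancestor_has_no_support_at_true_variants(self, small_sim):
        truth, exp, ev = small_sim
        anc_at_truth = ev.ancestor_calls.merge(
            ev.truth_keys[["chrom", "pos", "alt"]].drop_duplicates())
        assert anc_at_truth.empty

    def test_same_seed_identical_call_table(self, toy_reference, small_sim):
        truth, exp, ev = small_sim
        ev2 = simulate_read_evidence(truth, toy_reference, exp)
        pd.testing.assert_frame_equal(ev.calls, ev2.calls)
        pd.testing.assert_frame_equal(ev.pileup, ev2.pileup)

    def test_pileup_covers_every_line_at_every_candidate(self, small_sim):
        truth, exp, ev = small_sim
        per_site = ev.pileup.groupby(["chrom", "pos", "alt"])["line"].nunique()
        assert (per_site == exp.n_lines).all()


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_class_rates(self, toy_reference):
        """Full pipeline on a scaled simulation: unbiased class rates."""
        from mamutspec.filters import filter_pipeline
        from mamutspec.spectrum import annotate_records, line_mean_rate

        sp = default_spectrum().scaled(100)
        exp = ExperimentConfig(n_lines=10, generations=40, n_noise_sites=3000,
                               seed=23)
        truth = simulate_ma_lines(toy_reference, sp, exp)
        ev = simulate_read_evidence(truth, toy_reference, exp)
        accepted, _, _ = filter_pipeline(ev.calls, ev.pileup, ev.ancestor_calls)
        recs = annotate_records(accepted, toy_reference.genome,
                                toy_reference.layers, toy_reference.catalog,
                                coding_effects=False)
        B = toy_reference.genome.callable_bases()
        G = exp.line_generations["L01"]
        for cls, rate in sp.substitution_rates.items():
            lam = rate * G * B * exp.n_lines  # expected total count
            F = int((recs["subst_class"] == cls).sum())
            assert abs(F - lam) <= 4 * np.sqrt(lam) + 3, cls
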