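"""Classification, rates, ratios, biases and partition comparisons."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from mamutspec.genome import (
    GeneModel,
    GenomicInterval,
    ReferenceGenome,
    layers_from_components,
    mask_from_sequence,
)
from mamutspec import spectrum as sp
from mamutspec.repeats import revcomp
from mamutspec.study_tables import SUBSTITUTION_CLASSES, StudyTables


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref,alt,cls,is_ts", [
        ("A", "G", "A/T->G/C", True),
        ("T", "C", "A/T->G/C", True),
        ("C", "A", "G/C->T/A", False),
        ("T", "A", "A/T->T/A", False),
        ("A", "T", "A/T->T/A", False),
        ("G", "A", "G/C->A/T", True),
        ("C", "G", "G/C->C/G", False),
    ])
    def test_strand_collapse(self, ref, alt, cls, is_ts):
        assert sp.classify_substitution(ref, alt) == (cls, is_ts)

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_substitution("A", "A")
        with pytest.raises(ValueError):
            sp.classify_substitution("N", "A")

    def test_twelve_changes_partition_into_six_classes(self):
        got = {sp.classify_substitution(r, a)[0]
               for r, a in product("ACGT", repeat=2) if r != a}
        assert got == set(SUBSTITUTION_CLASSES)


class TestCollapseContext:
    def test_aat_and_att_share_a_key(self):
        # focal A in 5'-AAT-3' and focal T in 5'-ATT-3' are the same context
        assert sp.collapse_triplet("AAT") == sp.collapse_triplet("ATT")

    def test_exhaustive_collapse_is_bijective_with_brute_force(self):
        keys = {sp.collapse_triplet("".join(t)) for t in product("ACGT", repeat=3)}
        # brute force: orbits of the reverse-complement involution
        orbits = set()
        for t in product("ACGT", repeat=3):
            t = "".join(t)
            orbits.add(frozenset({t, revcomp(t)}))
        assert len(keys) == len(orbits) == 32
        assert all(sp.collapse_triplet(min(o)) == min(o) for o in orbits)

    def test_genome_edges_give_na(self):
        seq = "ACGTACGT"
        g = ReferenceGenome(["c"], {"c": seq}, {"c": mask_from_sequence(seq)})
        assert sp.collapse_context(g, "c", 0) == "NA"
        assert sp.collapse_context(g, "c", 3) == sp.collapse_triplet("GTA")


def _coding_fixture():
    # gene on +: exons [10,19) and [25,34): CDS = GGA GCT AAA TTT GGG CCC
    seq = "T" * 10 + "GGAGCTAAA" + "TTTCCC" + "TTTGGGCCC" + "T" * 20
    g = ReferenceGenome(["c"], {"c": seq}, {"c": mask_from_sequence(seq)})
    gene = GeneModel("g1", "c", "+", exons=((10, 19), (25, 34)))
    layers = layers_from_components(g, [gene], [GenomicInterval("c", 0, len(seq), "core")])
    return g, layers


class TestCodingEffect:
    def test_synonymous_and_nonsynonymous_snps(self):
        g, layers = _coding_fixture()
        # GGA -> GGG (Gly->Gly): third base of first codon, pos 12
        assert sp.classify_coding_effect(g, layers, "c", 12, "A", "G", "snp") \
            == "synonymous"
        # GGA -> GAA (Gly->Glu)
        assert sp.classify_coding_effect(g, layers, "c", 11, "G", "A", "snp") \
            == "nonsynonymous"

    def test_indel_frame_effects(self):
        g, layers = _coding_fixture()
        assert sp.classify_coding_effect(g, layers, "c", 11, "GA", "G",
                                         "deletion") == "frameshift"
        assert sp.classify_coding_effect(g, layers, "c", 11, "GAGC", "G",
                                         "deletion") == "in-frame-indel"

    def test_intron_and_intergenic_are_noncoding(self):
        g, layers = _coding_fixture()
        assert sp.classify_coding_effect(g, layers, "c", 20, "T", "A", "snp") \
            == "noncoding"
        assert sp.classify_coding_effect(g, layers, "c", 40, "T", "A", "snp") \
            == "noncoding"

    def test_minus_strand_gene_uses_reverse_complement_codons(self):
        # gene on -, exon [10,16): genomic TTTCAT -> CDS ATGAAA = Met Lys
        seq = "G" * 10 + "TTTCAT" + "G" * 10
        g = ReferenceGenome(["c"], {"c": seq}, {"c": mask_from_sequence(seq)})
        gene = GeneModel("g1", "c", "-", exons=((10, 16),))
        layers = layers_from_components(
            g, [gene], [GenomicInterval("c", 0, len(seq), "core")])
        # genomic T at 10 is the last CDS base (codon2 pos3); T->C makes
        # AAA -> AAG, both Lys
        assert sp.classify_coding_effect(g, layers, "c", 10, "T", "C", "snp") \
            == "synonymous"
        # genomic T at 15 is codon1 pos1 (ATG -> Met); T->C gives GTG (Val)
        assert sp.classify_coding_effect(g, layers, "c", 15, "T", "C", "snp") \
            == "nonsynonymous"

    def test_broken_frame_is_an_error(self):
        seq = "T" * 30
        g = ReferenceGenome(["c"], {"c": seq}, {"c": mask_from_sequence(seq)})
        gene = GeneModel("g1", "c", "+", exons=((5, 9),))
        layers = layers_from_components(
            g, [gene], [GenomicInterval("c", 0, 30, "core")])
        with pytest.raises(ValueError, match="frame"):
            sp.classify_coding_effect(g, layers, "c", 6, "T", "A", "snp")


class TestSynonymousSiteCounts:
    def test_single_codon_hand_values(self):
        # GGG: third position fully synonymous (1.0 syn site); ATG: none
        for codon, syn_expected in (("GGG", 1.0), ("ATG", 0.0)):
            seq = "A" * 9 + codon + "A" * 9
            g = ReferenceGenome(["c"], {"c": seq},
                                {"c": mask_from_sequence(seq)})
            gene = GeneModel("g1", "c", "+", exons=((9, 12),))
            nonsyn, syn = sp.synonymous_site_counts([gene], g)
            assert syn == pytest.approx(syn_expected)
            assert nonsyn + syn == pytest.approx(3.0)

    def test_total_sites_equal_cds_length(self):
        g, layers = _coding_fixture()
        nonsyn, syn = sp.synonymous_site_counts(layers.genes, g)
        assert nonsyn + syn == pytest.approx(18.0)


def _records(rows):
    base = dict(line="L1", chrom="I", pos=1, ref="A", alt="G", vtype="snp",
                subst_class="A/T->G/C", is_transition=True, context="NA",
                indel_size=0, repeat_status="complex", run_length=0,
                run_class=None, run_unit=0, run_family=None,
                functional="intergenic", domain="core", germline=False,
                coding_effect="noncoding", is_autosome=True)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestRates:
    def test_rate_arithmetic(self):
        assert sp.mutation_rate(2, 40, 1e6) == pytest.approx(5e-8)
        with pytest.raises(ValueError):
            sp.mutation_rate(1, 40, 0)

    def test_combined_rate_from_printed_components(self):
        t1 = StudyTables().table1
        combined = (t1.loc["snp", "knockdown"] + t1.loc["indel", "knockdown"]) * 1e-7
        assert combined == pytest.approx(2.65e-7)

    def test_identical_lines_have_zero_ci(self):
        recs = _records([{"line": f"L{i}", "pos": p}
                         for i in range(4) for p in (10, 20)])
        t = sp.line_mean_rate(recs, {f"L{i}": 40.0 for i in range(4)}, 1000)
        assert t.ci95 == 0.0
        assert t.mean == pytest.approx(2 / (40 * 1000))

    def test_lines_without_mutations_still_count(self):
        recs = _records([{"line": "L0"}])
        t = sp.line_mean_rate(recs, {"L0": 40.0, "L1": 40.0}, 1000)
        assert t.n == 2
        assert t.per_line["L1"] == 0.0


class TestFoldChange:
    def test_printed_fold_changes(self):
        recs = _records([{"line": "L0"}])
        tab = sp.RateTable("indel", pd.Series({"L0": 2.23e-7}), B=1)
        assert sp.fold_change(tab, 6.8e-10)["fold"] == pytest.approx(327.94, abs=0.5)
        tab = sp.RateTable("del", pd.Series({"L0": 1.47e-7}), B=1)
        assert sp.fold_change(tab, 5.1e-10)["fold"] == pytest.approx(288.2, abs=0.5)

    def test_identity_and_undefined(self):
        tab = sp.RateTable("x", pd.Series({"L0": 1e-7}), B=1)
        assert sp.fold_change(tab, 1e-7)["fold"] == pytest.approx(1.0)
        assert not sp.fold_change(tab, 0.0)["defined"]

    def test_welch_test_when_reference_lines_given(self):
        tab = sp.RateTable("x", pd.Series({f"L{i}": 2e-7 + i * 1e-9
                                           for i in range(6)}), B=1)
        ref = pd.Series([1e-8, 1.2e-8, 0.9e-8, 1.1e-8])
        out = sp.fold_change(tab, ref.mean(), ref)
        assert out["p"] < 1e-4 and out["fold"] > 10


class TestTsTv:
    def test_pooled_value_from_observed_class_counts(self):
        t2 = StudyTables().table2["total"]
        assert sp.tstv_from_class_counts(t2) == pytest.approx(1.12, abs=0.005)

    def test_equal_counts_give_unity(self):
        recs = _records([
            {"pos": 1, "subst_class": "A/T->G/C", "is_transition": True},
            {"pos": 2, "subst_class": "A/T->T/A", "is_transition": False},
        ])
        assert sp.tstv_ratio(recs) == 1.0

    def test_per_line_and_pooled_differ_on_unequal_lines(self):
        rows = []
        # line A: 9 transitions, 1 transversion; line B: 1 and 1
        rows += [{"line": "A", "pos": i, "is_transition": True} for i in range(9)]
        rows += [{"line": "A", "pos": 90, "is_transition": False}]
        rows += [{"line": "B", "pos": 91, "is_transition": True},
                 {"line": "B", "pos": 92, "is_transition": False}]
        recs = _records(rows)
        pooled = sp.tstv_ratio(recs)
        per_line = sp.tstv_ratio(recs, per_line=True)
        assert pooled == pytest.approx(10 / 2)
        assert per_line == pytest.approx((9 + 1) / 2)

    def test_no_transversions_is_an_error(self):
        recs = _records([{"is_transition": True}])
        with pytest.raises(ZeroDivisionError):
            sp.tstv_ratio(recs)


class TestAtBias:
    def test_observed_counts_with_genomic_composition(self):
        t2 = StudyTables().table2["total"]
        assert sp.at_bias(t2, 0.354)["normalized"] == pytest.approx(0.64, abs=0.005)

    def test_uniform_composition_reduces_to_raw_fraction(self):
        counts = pd.Series({"G/C->A/T": 30, "A/T->G/C": 70})
        out = sp.at_bias(counts, 0.5)
        assert out["normalized"] == pytest.approx(out["raw"]) == pytest.approx(0.3)

    def test_pure_at_ward_spectrum(self):
        counts = pd.Series({"G/C->A/T": 10, "G/C->T/A": 5})
        assert sp.at_bias(counts, 0.36)["normalized"] == 1.0

    def test_degenerate_composition_rejected(self):
        with pytest.raises(ValueError):
            sp.at_bias(pd.Series({"G/C->A/T": 1}), 0.0)


class TestIndelSummary:
    def test_observed_1bp_counts_give_printed_net_loss(self):
        rows = [{"pos": i, "vtype": "deletion", "indel_size": -1}
                for i in range(6960)]
        rows += [{"pos": 10**6 + i, "vtype": "insertion", "indel_size": 1}
                 for i in range(3513)]
        out = sp.indel_summary(_records(rows))
        assert out["net_bp_change"] == -3447
        assert out["deletion_insertion_ratio"] == pytest.approx(6960 / 3513)

    def test_empty_set_is_all_zero(self):
        out = sp.indel_summary(_records([{}]).iloc[0:0])
        assert out["n_deletions"] == out["n_insertions"] == 0
        assert out["net_bp_change"] == 0


class TestMitoRate:
    def test_observed_heteroplasmies_reproduce_reported_rate(self):
        t = StudyTables()
        gens = {str(r.line): float(r.generations) for r in t.table3.itertuples()}
        for i in range(15):
            gens[f"z{i}"] = t.mean_generations
        rate = sp.mito_rate(t.table3, gens, t.mito_length)
        assert 2.1e-7 <= rate.mean <= 2.25e-7

    def test_single_fixed_variant(self):
        het = pd.DataFrame([{"line": "L1", "frequency": 1.0}])
        rate = sp.mito_rate(het, {"L1": 10.0}, L_mt=10_000)
        assert rate.mean == pytest.approx(1e-5)

    def test_no_variants_gives_zero(self):
        rate = sp.mito_rate(pd.DataFrame(columns=["line", "frequency"]),
                            {"L1": 40.0, "L2": 40.0}, 13794)
        assert rate.mean == 0.0

    def test_linearity_in_frequency(self):
        het = pd.DataFrame([{"line": "L1", "frequency": 0.2},
                            {"line": "L2", "frequency": 0.3}])
        gens = {"L1": 30.0, "L2": 40.0, "L3": 40.0}
        r1 = sp.mito_rate(het, gens).mean
        het2 = het.assign(frequency=het["frequency"] * 2)
        assert sp.mito_rate(het2, gens).mean == pytest.approx(2 * r1)

    def test_invalid_frequency_rejected(self):
        het = pd.DataFrame([{"line": "L1", "frequency": 1.2}])
        with pytest.raises(ValueError):
            sp.mito_rate(het, {"L1": 40.0})


def _poisson_records(rng, n_lines, lam_x, lam_a):
    rows = []
    for i in range(n_lines):
        line = f"L{i:02d}"
        for _ in range(rng.poisson(lam_x)):
            rows.append({"line": line, "chrom": "X", "is_autosome": False,
                         "pos": rng.integers(1, 10**6)})
        for _ in range(rng.poisson(lam_a)):
            rows.append({"line": line, "chrom": "I", "is_autosome": True,
                         "pos": rng.integers(1, 10**6)})
    return _records(rows)


class TestPartitionCompare:
    def test_paired_test_detects_planted_x_deficit(self, rng):
        """15% lower X rate; direction must be detected in most replicates."""
        B_x, B_a = 100_000, 100_000
        hits = 0
        reps = 40
        for _ in range(reps):
            recs = _poisson_records(rng, 20, lam_x=85, lam_a=100)
            out = sp.compare_x_autosomes(recs, {f"L{i:02d}": 40.0
                                                for i in range(20)}, B_x, B_a)
            if out["mean_difference"] < 0 and out["paired_t"]["p"] < 0.05:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_type_one_error_is_calibrated(self, rng):
        rejections = 0
        reps = 120
        for _ in range(reps):
            recs = _poisson_records(rng, 12, lam_x=50, lam_a=50)
            out = sp.compare_x_autosomes(recs, {f"L{i:02d}": 40.0
                                                for i in range(12)},
                                         100_000, 100_000)
            rejections += out["paired_t"]["p"] < 0.05
        # binomial(120, 0.05): 3 sigma above the mean is ~13
        assert rejections <= 13

    def test_single_line_reports_rates_without_tests(self):
        recs = _records([{"line": "L0", "functional": "exon"}])
        out = sp.partition_compare(recs, {"L0": 40.0}, "functional",
                                   {"exon": 1000, "intron": 1000})
        assert "anova" not in out
        assert out["tables"]["exon"].mean > 0

    def test_partition_tables_and_anova_present(self, rng):
        recs = _poisson_records(rng, 8, 40, 40)
        recs["functional"] = np.where(rng.random(len(recs)) < 0.3, "exon",
                                      "intergenic")
        out = sp.partition_compare(recs, {f"L{i:02d}": 40.0 for i in range(8)},
                                   "functional",
                                   {"exon": 50_000, "intergenic": 150_000})
        assert set(out["tables"]) == {"exon", "intergenic"}
        assert "anova" in out and "welch" in out


class TestConservation:
    def test_class_and_repeat_status_sums(self, rng):
        rows = []
        for i in range(300):
            cls = SUBSTITUTION_CLASSES[int(rng.integers(6))]
            status = ["complex", "in_repeat", "adjacent"][int(rng.integers(3))]
            rows.append({"pos": i + 1, "subst_class": cls,
                         "repeat_status": status})
        recs = _records(rows)
        snps = recs[recs["vtype"] == "snp"]
        assert snps["subst_class"].value_counts().sum() == len(snps)
        assert snps["repeat_status"].value_counts().sum() == len(snps)
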