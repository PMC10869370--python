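"""Context classification, catalogue building, refitting, HRD rule."""

import matplotlib.pyplot as plt
import numpy as np
import pytest

from digenicloh import synthetic as syn
from digenicloh.signatures import (
    ID83_CHANNELS,
    SBS96_CHANNELS,
    ExposureVector,
    HRDRuleConfig,
    MutationCatalogue,
    ReferenceMismatchError,
    SignatureMatrix,
    build_catalogue,
    catalogue_profile_plot,
    classify_indel_context,
    classify_sbs_context,
    cosine_similarity,
    hrd_classify,
    refit_exposures,
)
from digenicloh.variants import VariantSite


def _snv(chrom, pos, ref, alt):
    return VariantSite(chrom, pos, ref, alt, depth=100, alt_depth=30)


def sbs96_enumeration_fixture():
    """One SNV per channel: each variant lives on its own tiny contig."""
    reference, variants, expected = {}, [], []
    i = 0
    for channel in SBS96_CHANNELS:
        five, mid, _, alt, three = channel[0], channel[2], channel[3], channel[4], channel[6]
        chrom = f"ctg{i}"
        reference[chrom] = f"{five}{mid}{three}"
        variants.append(_snv(chrom, 2, mid, alt))
        expected.append(channel)
        i += 1
    return reference, variants, expected


class TestSBSContext:
    def test_pyrimidine_reference_direct_label(self):
        ref = {"1": "ACG"}
        assert classify_sbs_context(_snv("1", 2, "C", "T"), ref) == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # C G T with G>A at the middle == reverse strand A[C>T]G
        ref = {"1": "CGT"}
        assert classify_sbs_context(_snv("1", 2, "G", "A"), ref) == "A[C>T]G"

    def test_reference_mismatch_names_position(self):
        ref = {"1": "AAG"}
        with pytest.raises(ReferenceMismatchError, match="1:2"):
            classify_sbs_context(_snv("1", 2, "C", "T"), ref)

    def test_enumeration_hits_every_channel_once(self):
        reference, variants, expected = sbs96_enumeration_fixture()
        got = [classify_sbs_context(v, reference) for v in variants]
        assert got == expected
        catalogue, skipped = build_catalogue(variants, reference, "SBS96")
        assert skipped == []
        assert (catalogue.counts == 1).all()


class TestIndelContext:
    def _del(self, chrom, pos, ref, alt):
        return VariantSite(chrom, pos, ref, alt, depth=100, alt_depth=30)

    def test_1bp_del_in_6T_homopolymer_top_bin(self):
        # deleting one T out of TTTTTT: five additional copies -> bin 5
        ref = {"1": "ACG" + "T" * 6 + "ACG"}
        v = self._del("1", 3, "GT", "G")
        assert classify_indel_context(v, ref) == "1:Del:T:5"

    def test_1bp_del_of_A_complemented_to_T_channel(self):
        ref = {"1": "CCGAACC"}
        v = self._del("1", 3, "GA", "G")
        assert classify_indel_context(v, ref) == "1:Del:T:1"

    def test_1bp_ins_next_to_zero_copies(self):
        ref = {"1": "ATGTA"}
        v = self._del("1", 2, "T", "TC")
        assert classify_indel_context(v, ref) == "1:Ins:C:0"

    def test_1bp_ins_extending_homopolymer(self):
        ref = {"1": "ATTTGA"}
        v = self._del("1", 1, "A", "AT")
        assert classify_indel_context(v, ref) == "1:Ins:T:3"

    def test_long_del_at_repeat_counts_units(self):
        # CA CA CA: deleting one CA leaves two copies
        ref = {"1": "G" + "CACACA" + "GT"}
        v = self._del("1", 1, "GCA", "G")
        assert classify_indel_context(v, ref) == "2:Del:R:2"

    def test_3bp_del_with_2bp_microhomology(self):
        # delete TAG; right flank begins TA (2-bp homology), no full copy
        ref = {"1": "C" + "TAG" + "TACC"}
        v = self._del("1", 1, "CTAG", "C")
        assert classify_indel_context(v, ref) == "3:Del:M:2"

    def test_3bp_del_no_repeat_no_homology(self):
        ref = {"1": "C" + "TAG" + "CCGG"}
        v = self._del("1", 1, "CTAG", "C")
        assert classify_indel_context(v, ref) == "3:Del:R:0"

    def test_repeat_classification_wins_over_microhomology(self):
        # deleted TA has a full adjacent copy: repeat channel, not M
        ref = {"1": "G" + "TATA" + "CGC"}
        v = self._del("1", 1, "GTA", "G")
        assert classify_indel_context(v, ref) == "2:Del:R:1"

    def test_long_insertion_repeat_units(self):
        ref = {"1": "G" + "CACA" + "GG"}
        v = self._del("1", 1, "G", "GCA")
        assert classify_indel_context(v, ref) == "2:Ins:R:2"

    def test_reference_mismatch_raises(self):
        ref = {"1": "GGGG"}
        with pytest.raises(ReferenceMismatchError):
            classify_indel_context(self._del("1", 1, "GT", "G"), ref)

    def test_all_emitted_labels_are_valid_channels(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), size=2000))
        ref = {"1": seq}
        labels = set()
        for pos in range(5, 1900, 7):
            anchor = seq[pos - 1]
            del_len = int(rng.integers(1, 6))
            v_del = self._del(
                "1", pos, anchor + seq[pos:pos + del_len], anchor
            )
            labels.add(classify_indel_context(v_del, ref))
            ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 6))))
            v_ins = self._del("1", pos, anchor, anchor + ins)
            labels.add(classify_indel_context(v_ins, ref))
        assert labels <= set(ID83_CHANNELS)
        assert len(labels) > 20  # broad coverage of the alphabet


class TestBuildCatalogue:
    def test_empty_variant_list_all_zero(self):
        catalogue, skipped = build_catalogue([], {}, "SBS96")
        assert catalogue.total == 0
        assert skipped == []

    def test_indels_skipped_for_sbs_alphabet(self):
        ref = {"1": "ACGTACGT"}
        variants = [
            _snv("1", 2, "C", "T"),
            VariantSite("1", 4, "TA", "T", depth=100, alt_depth=30),
        ]
        catalogue, skipped = build_catalogue(variants, ref, "SBS96")
        assert catalogue.total == 1
        assert len(skipped) == 1 and "not an SNV" in skipped[0]


class TestRefit:
    def test_single_signature_catalogue_identity(self, sbs_matrix_3):
        name = sbs_matrix_3.names[0]
        counts = sbs_matrix_3.matrix[:, 0] * 1000
        exposures = refit_exposures(
            MutationCatalogue("SBS96", counts), sbs_matrix_3
        )
        assert exposures.proportion(name) == pytest.approx(1.0, abs=1e-6)
        assert exposures.residual_norm <= 1e-9

    def test_exact_half_half_blend(self, sbs_matrix_3):
        counts = (
            0.5 * sbs_matrix_3.matrix[:, 0] + 0.5 * sbs_matrix_3.matrix[:, 1]
        ) * 2000
        exposures = refit_exposures(
            MutationCatalogue("SBS96", counts), sbs_matrix_3
        )
        assert exposures.proportions[0] == pytest.approx(0.5, abs=1e-6)
        assert exposures.proportions[1] == pytest.approx(0.5, abs=1e-6)
        assert exposures.residual_norm <= 1e-9

    def test_scale_invariance(self, sbs_matrix_3):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=96).astype(float)
        counts[0] += 1  # nonempty
        e1 = refit_exposures(MutationCatalogue("SBS96", counts), sbs_matrix_3)
        e2 = refit_exposures(
            MutationCatalogue("SBS96", counts * 7), sbs_matrix_3
        )
        np.testing.assert_allclose(e1.proportions, e2.proportions, atol=1e-9)

    def test_simplex_constraints_always_hold(self, sbs_matrix_3):
        rng = np.random.default_rng(4)
        for _ in range(10):
            counts = rng.poisson(5.0, size=96).astype(float)
            counts[int(rng.integers(0, 96))] += 1
            e = refit_exposures(
                MutationCatalogue("SBS96", counts), sbs_matrix_3
            )
            assert (e.proportions >= 0).all()
            assert e.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3])
    def test_objective_matches_simplex_grid_oracle(self, sbs_matrix_3, k):
        """Brute-force 0.01-step grid search cannot beat the solver by more
        than the grid's own resolution."""
        rng = np.random.default_rng(20 + k)
        matrix = sbs_matrix_3.subset(list(sbs_matrix_3.names[:k]))
        e_true = rng.dirichlet(np.ones(k))
        p = matrix.matrix @ e_true
        counts = rng.multinomial(10_000, p / p.sum()).astype(float)
        catalogue = MutationCatalogue("SBS96", counts)
        fitted = refit_exposures(catalogue, matrix)

        c = catalogue.proportions()
        steps = 100
        best_obj, best_e = np.inf, None
        if k == 2:
            grid = [(i / steps, 1 - i / steps) for i in range(steps + 1)]
        else:
            grid = [
                (i / steps, j / steps, (steps - i - j) / steps)
                for i in range(steps + 1)
                for j in range(steps + 1 - i)
            ]
        G = np.array(grid)
        objs = np.linalg.norm(matrix.matrix @ G.T - c[:, None], axis=0)
        best_obj = objs.min()
        best_e = G[int(objs.argmin())]

        assert fitted.residual_norm <= best_obj + 1e-6
        assert np.abs(fitted.proportions - best_e).max() <= 0.02

    def test_multinomial_mixture_recovery_small(self, sbs_matrix_3):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            e_true = rng.dirichlet(np.ones(3))
            true = dict(zip(sbs_matrix_3.names, e_true))
            cat = syn.simulate_catalogue(
                syn.CatalogueSimulationConfig(sbs_matrix_3, {
                    k: float(v) for k, v in true.items()
                }, 10_000, seed=seed)
            )
            fitted = refit_exposures(cat, sbs_matrix_3)
            errs.append(np.abs(fitted.proportions - e_true).mean())
        assert np.mean(errs) < 0.02

    def test_unknown_subset_name_rejected(self, sbs_matrix_3):
        catalogue = MutationCatalogue(
            "SBS96", sbs_matrix_3.matrix[:, 0] * 100
        )
        with pytest.raises(ValueError, match="SBSX"):
            refit_exposures(catalogue, sbs_matrix_3, ["SBSX"])

    def test_empty_catalogue_rejected(self, sbs_matrix_3):
        with pytest.raises(ValueError, match="empty"):
            refit_exposures(
                MutationCatalogue("SBS96", np.zeros(96)), sbs_matrix_3
            )


class TestSignatureMatrixIO:
    def test_tsv_round_trip_with_shuffled_rows(self, tmp_path, sbs_matrix_3):
        path = tmp_path / "sig.tsv"
        sbs_matrix_3.to_tsv(path)
        # shuffle data rows; reader must restore canonical channel order
        lines = path.read_text().splitlines()
        rng = np.random.default_rng(1)
        body = list(lines[1:])
        rng.shuffle(body)
        path.write_text("\n".join([lines[0]] + body) + "\n")
        back = SignatureMatrix.from_tsv(path, "SBS96")
        assert back.names == sbs_matrix_3.names
        np.testing.assert_allclose(back.matrix, sbs_matrix_3.matrix, atol=1e-12)

    def test_column_sum_validated(self):
        bad = np.full((96, 1), 1.0 / 96)
        bad[0] += 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix("SBS96", ("S1",), bad)


class TestHRD:
    def test_reported_tumor_exposures_fire_both_rules(self):
        call = hrd_classify({"SBS3": 0.618}, {"ID6": 0.652})
        assert call.positive
        assert len(call.reasons) == 2

    def test_thresholds_are_strict(self):
        call = hrd_classify({"SBS3": 0.10}, {"ID6": 0.20})
        assert not call.positive
        assert call.status == "HRD_negative"

    def test_id6_alone_suffices(self):
        call = hrd_classify({"SBS3": 0.05}, {"ID6": 0.25})
        assert call.positive
        assert call.reasons and "ID6" in call.reasons[0]

    def test_missing_required_signature_rejected(self):
        with pytest.raises(ValueError, match="SBS3"):
            hrd_classify({"SBS1": 1.0}, {"ID6": 0.0})

    def test_monotone_in_both_exposures(self):
        grid = np.linspace(0, 1, 21)
        prev = False
        for v in grid:
            now = hrd_classify({"SBS3": v}, {"ID6": 0.0}).positive
            assert now >= prev
            prev = now
        prev = False
        for v in grid:
            now = hrd_classify({"SBS3": 0.0}, {"ID6": v}).positive
            assert now >= prev
            prev = now


class TestPlots:
    def test_sbs_profile_bar_count(self):
        catalogue = MutationCatalogue("SBS96", np.ones(96))
        fig = catalogue_profile_plot(catalogue)
        assert len(fig.axes[0].patches) == 96
        plt.close(fig)

    def test_id_profile_bar_count(self):
        catalogue = MutationCatalogue("ID83", np.arange(83, dtype=float))
        fig = catalogue_profile_plot(catalogue)
        assert len(fig.axes[0].patches) == 83
        plt.close(fig)

    def test_sampled_catalogue_vs_source_signature_high_cosine(self, sbs_matrix_3):
        true = {sbs_matrix_3.names[0]: 1.0}
        cat = syn.simulate_catalogue(
            syn.CatalogueSimulationConfig(sbs_matrix_3, true, 10_000, seed=2)
        )
        ref_col = sbs_matrix_3.matrix[:, 0]
        assert cosine_similarity(cat.counts, ref_col) > 0.9
        fig = catalogue_profile_plot(cat, ref_col, "source signature")
        assert len(fig.axes) == 2
        plt.close(fig)


class TestExposureVector:
    def test_display_dict_floors_tiny_exposures(self):
        e = ExposureVector(("A", "B"), np.array([1.0 - 5e-5, 5e-5]), 0.0)
        shown = e.as_display_dict()
        assert shown["B"] == 0.0
        assert e.as_dict()["B"] == pytest.approx(5e-5)

    def test_json_round_trip(self, tmp_path):
        e = ExposureVector(("A", "B"), np.array([0.25, 0.75]), 0.01)
        path = tmp_path / "e.json"
        e.to_json(path)
        back = ExposureVector.from_json(path)
        assert back.names == e.names
        np.testing.assert_allclose(back.proportions, e.proportions)
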