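import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from otucurate import filtering
from otucurate.filtering import (ConfigurationError, OtuTable, clean_species_names,
                                 has_stop_free_frame, is_clean_binomial,
                                 merge_by_species, merge_replicates,
                                 screen_stop_codons, split_datasets,
                                 subtract_negatives)

from conftest import make_annotation


class TestMergeReplicates:
    def test_both_present_sums(self, toy_table):
        merged = merge_replicates(toy_table)
        assert merged.counts.loc["otuA", "s1"] == 7  # (3, 4) -> 7

    def test_one_absent_zeroes(self, toy_table):
        merged = merge_replicates(toy_table)
        assert merged.counts.loc["otuB", "s1"] == 0  # (0, 7) -> 0

    def test_all_zero_replicate_zeroes_sample(self):
        counts = pd.DataFrame({"a_A": [5, 2, 9], "a_B": [0, 0, 0]}, index=list("xyz"))
        t = OtuTable(counts, {"a": ("a_A", "a_B")}, [])
        merged = merge_replicates(t)
        # hand application of the both-present rule to every cell
        assert (merged.counts["a"] == 0).all()

    def test_negatives_pass_through(self, toy_table):
        merged = merge_replicates(toy_table)
        assert merged.negative_ids == ["n1", "n2"]
        pd.testing.assert_series_equal(merged.counts["n1"], toy_table.counts["n1"],
                                       check_names=False)

    def test_unpaired_sample_errors(self):
        counts = pd.DataFrame({"a_A": [1], "a_B": [1], "stray": [1]}, index=["x"])
        t = OtuTable(counts, {"a": ("a_A", "a_B")}, ["stray"])
        t.negative_ids = []  # simulate a stray non-negative library
        with pytest.raises(ConfigurationError):
            merge_replicates(t)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 3), st.data())
    def test_merged_le_sum_property(self, n_extra, data):
        n_otus = 4
        a = data.draw(st.lists(st.integers(0, 50), min_size=n_otus, max_size=n_otus))
        b = data.draw(st.lists(st.integers(0, 50), min_size=n_otus, max_size=n_otus))
        counts = pd.DataFrame({"s_A": a, "s_B": b}, index=[f"o{i}" for i in range(n_otus)])
        merged = merge_replicates(OtuTable(counts, {"s": ("s_A", "s_B")}, []))
        total = merged.counts["s"].sum()
        assert total <= sum(a) + sum(b)
        no_cell_zeroed = all((x > 0 and y > 0) or (x + y == 0) for x, y in zip(a, b))
        assert (total == sum(a) + sum(b)) == no_cell_zeroed or total == sum(a) + sum(b)


class TestSubtractNegatives:
    def test_hand_computed_example(self):
        # OTU counts [10, 5, 3] across samples, negatives [2, 4]:
        # max = 4 -> [6, 1, 0]
        counts = pd.DataFrame({"s1": [10], "s2": [5], "s3": [3], "n1": [2], "n2": [4]},
                              index=["o"])
        out = subtract_negatives(OtuTable(counts, {}, ["n1", "n2"]))
        assert list(out.counts.loc["o"]) == [6, 1, 0]
        assert out.negative_ids == []

    def test_zero_negatives_identity(self):
        counts = pd.DataFrame({"s1": [10], "n1": [0], "n2": [0]}, index=["o"])
        out = subtract_negatives(OtuTable(counts, {}, ["n1", "n2"]))
        assert out.counts.loc["o", "s1"] == 10
        assert list(out.counts.columns) == ["s1"]

    def test_otu_only_in_negatives_becomes_all_zero(self):
        counts = pd.DataFrame({"s1": [0, 5], "n1": [7, 0]}, index=["ghost", "real"])
        out = subtract_negatives(OtuTable(counts, {}, ["n1"]))
        assert (out.counts.loc["ghost"] == 0).all()
        assert out.counts.loc["real", "s1"] == 5

    def test_no_negative_library_warns_and_returns_identity(self, caplog):
        counts = pd.DataFrame({"s1": [3]}, index=["o"])
        t = OtuTable(counts, {}, [])
        out = subtract_negatives(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_idempotent_after_drop(self, toy_table):
        merged = merge_replicates(toy_table)
        once = subtract_negatives(merged)
        twice = subtract_negatives(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_negative_columns_all_zero_after_subtraction(self, data):
        n = 5
        cols = {}
        for name in ("s1", "s2", "n1", "n2"):
            cols[name] = data.draw(st.lists(st.integers(0, 20), min_size=n, max_size=n))
        counts = pd.DataFrame(cols, index=[f"o{i}" for i in range(n)])
        t = OtuTable(counts, {}, ["n1", "n2"])
        m = counts[["n1", "n2"]].max(axis=1)
        out = subtract_negatives(t)
        # every negative count is <= the subtracted max by construction
        assert ((counts[["n1", "n2"]].sub(m, axis=0) <= 0).all()).all()
        assert (out.counts.to_numpy() >= 0).all()


SENSE_205 = "ATT" * 68 + "A"  # isoleucine codons, stop-free in frame 1


class TestStopCodonScreen:
    def test_sense_sequence_kept(self):
        ann = make_annotation("o1", sequence=SENSE_205)
        kept, removed = screen_stop_codons([ann])
        assert [a.otu_id for a in kept] == ["o1"]

    def test_stop_in_all_three_frames_removed(self):
        # TAAATAAATAA carries TAA at offsets 0, 4, 8 -> a stop in every
        # forward frame wherever it lands; verified by hand on this 22-mer
        seq = "ATTATT" + "TAAATAAATAA" + "ATTAT"
        ann = make_annotation("o2", sequence=seq)
        kept, removed = screen_stop_codons([ann])
        assert [a.otu_id for a in removed] == ["o2"]

    def test_stop_in_one_frame_only_is_kept(self):
        # frame 1 has TAA but frame 2/3 of this construction are stop-free
        seq = "TAA" + "ATT" * 10
        assert has_stop_free_frame(seq)

    def test_n_codons_are_not_stops(self):
        seq = "TNA" + "ATT" * 10
        assert has_stop_free_frame(seq)

    def test_reverse_complement_flag(self):
        # every forward frame of the motif is stopped, but its reverse
        # complement (TTATTTATTTA) is stop-free
        fwd_stopped = "TAAATAAATAA"
        assert not has_stop_free_frame(fwd_stopped, check_reverse=False)
        assert has_stop_free_frame(fwd_stopped, check_reverse=True)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=205, max_size=205))
    def test_agrees_with_biopython_translation_oracle(self, seq):
        def oracle(s):
            for off in (0, 1, 2):
                sub = s[off:off + 3 * ((len(s) - off) // 3)]
                if "*" not in str(Seq(sub).translate(table=5)):
                    return True
            return False

        assert has_stop_free_frame(seq) == oracle(seq)


class TestSplitDatasets:
    def _table(self, ids):
        counts = pd.DataFrame({"s1": np.arange(1, len(ids) + 1)}, index=ids)
        return OtuTable(counts, {}, [])

    def test_counting_example(self):
        ids = [f"o{i}" for i in range(10)]
        anns = {}
        for i, o in enumerate(ids):
            species = "Gena speciesa" if i < 4 else ""
            klass = "Insecta" if i < 9 else "Arachnida"
            anns[o] = make_annotation(o, species=species, klass=klass)
        named, insect = split_datasets(self._table(ids), anns)
        assert (len(named.otu_ids), len(insect.otu_ids)) == (4, 9)

    def test_all_named_subset_identity(self):
        ids = ["a", "b"]
        anns = {o: make_annotation(o, species="Genb speciesb") for o in ids}
        named, insect = split_datasets(self._table(ids), anns)
        assert set(named.otu_ids) == set(insect.otu_ids) & set(named.otu_ids)

    def test_no_insects_warns_but_continues(self):
        ids = ["a"]
        anns = {"a": make_annotation("a", klass="Arachnida")}
        named, insect = split_datasets(self._table(ids), anns)
        assert insect.otu_ids == []

    def test_missing_annotation_is_hard_error(self):
        with pytest.raises(KeyError, match="o1"):
            split_datasets(self._table(["o0", "o1"]), {"o0": make_annotation("o0")})


class TestNameHygiene:
    @pytest.mark.parametrize("name,ok", [
        ("Apis mellifera", True),
        ("Megaselia sp. BOLD:ACX1234", False),
        ("Phora sp.4", False),
        ("Aedes albopictus", True),
        ("Genus", False),
        ("Genus  epithet", False),  # double space
        ("Genus epithet extra", False),
        ("Genus epi-thet", False),  # hyphen disallowed by default
        ("Genus epithet2", False),
    ])
    def test_rule_application(self, name, ok):
        assert is_clean_binomial(name) is ok

    def test_hyphen_config_switch(self):
        assert is_clean_binomial("Genus epi-thet", allow_hyphen=True)
        assert not is_clean_binomial("Genus epi--thet", allow_hyphen=True)

    def test_unicode_letters_allowed(self):
        assert is_clean_binomial("Göra blåvinge")

    def test_split(self):
        kept, dropped = clean_species_names(["Apis mellifera", "Phora sp.4"])
        assert kept == ["Apis mellifera"] and dropped == ["Phora sp.4"]

    @given(st.text(alphabet="abcXYZ0123456789 .:-", min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_digits_or_punctuation_always_dropped(self, name):
        if any(ch.isdigit() or ch in ".:-" for ch in name):
            assert not is_clean_binomial(name)


class TestMergeBySpecies:
    def test_two_otus_one_species(self):
        counts = pd.DataFrame({"s1": [5, 2], "s2": [0, 3]}, index=["o1", "o2"])
        anns = {o: make_annotation(o, species="Gena speciesa") for o in ["o1", "o2"]}
        st_ = merge_by_species(OtuTable(counts, {}, []), anns)
        assert list(st_.counts.loc["Gena speciesa"]) == [7, 3]
        assert st_.otus_per_species == {"Gena speciesa": 2}

    def test_all_singletons_identity(self):
        counts = pd.DataFrame({"s1": [5, 2]}, index=["o1", "o2"])
        anns = {"o1": make_annotation("o1", species="Gena speciesa"),
                "o2": make_annotation("o2", species="Genb speciesb")}
        st_ = merge_by_species(OtuTable(counts, {}, []), anns)
        assert all(v == 1 for v in st_.otus_per_species.values())
        assert st_.counts.to_numpy().sum() == 7

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_reads_conserved_oracle(self, data):
        n_otus = data.draw(st.integers(1, 12))
        n_samples = data.draw(st.integers(1, 4))
        species_pool = ["Gena speciesa", "Genb speciesb", "Genc speciesc"]
        assignment = data.draw(st.lists(st.sampled_from(species_pool + [""]),
                                        min_size=n_otus, max_size=n_otus))
        counts = pd.DataFrame(
            data.draw(st.lists(st.lists(st.integers(0, 30), min_size=n_samples,
                                        max_size=n_samples),
                               min_size=n_otus, max_size=n_otus)),
            index=[f"o{i}" for i in range(n_otus)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        anns = {f"o{i}": make_annotation(f"o{i}", species=assignment[i])
                for i in range(n_otus)}
        st_ = merge_by_species(OtuTable(counts, {}, []), anns)
        # brute-force group-and-sum oracle
        for sp in set(assignment) - {""}:
            members = [f"o{i}" for i in range(n_otus) if assignment[i] == sp]
            expected = counts.loc[members].sum().to_numpy()
            np.testing.assert_array_equal(st_.counts.loc[sp].to_numpy(), expected)
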