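import numpy as np
import pandas as pd
import pytest

from isomirpe.caller import AnchorIndex, call_isomir, write_mirgff3
from isomirpe.quantify import (
    MatrixError,
    PairTrace,
    aggregate,
    build_matrix,
    compare_modes,
    flag_sr_false_positives,
    log2fc_rank,
    matrix_from_counts,
    read_rank_file,
    row_key,
    write_rank_file,
)
from isomirpe.variants import build_truth_set


@pytest.fixture
def calls(small_reference):
    anchors = small_reference[3]
    truth = build_truth_set(anchors, n_mirnas=5, seed=8)
    index = AnchorIndex(anchors)
    return [call_isomir(r.sequence, index).call for r in truth]


def _gff(path, call_counts, sample):
    write_mirgff3(call_counts, [sample], path)
    return path


class TestBuildMatrix:
    def test_single_sample(self, calls, tmp_path):
        p = _gff(tmp_path / "a.gff3", [(c, [3]) for c in calls[:3]], "a")
        bundle = build_matrix([p])
        assert bundle.matrix.shape == (3, 1)
        assert (bundle.matrix["a"] == 3).all()

    def test_union_with_zero_fill(self, calls, tmp_path):
        pa = _gff(tmp_path / "a.gff3", [(calls[0], [5])], "a")
        pb = _gff(tmp_path / "b.gff3", [(calls[1], [7])], "b")
        bundle = build_matrix([pa, pb])
        assert bundle.matrix.shape == (2, 2)
        assert bundle.matrix.loc[row_key(calls[0]), "b"] == 0
        assert bundle.matrix.loc[row_key(calls[1]), "a"] == 0

    def test_uid_companion_table(self, calls, tmp_path):
        p = _gff(tmp_path / "a.gff3", [(c, [1]) for c in calls[:4]], "a")
        bundle = build_matrix([p])
        got = dict(zip(bundle.uid_to_sequence.uid, bundle.uid_to_sequence.sequence))
        assert got == {c.uid: c.sequence for c in calls[:4]}

    def test_sequence_claimed_by_two_mirnas_dropped(self, calls, tmp_path):
        import dataclasses

        impostor = dataclasses.replace(calls[0], mirna="syn-miR-other")
        pa = _gff(tmp_path / "a.gff3", [(calls[0], [5]), (calls[1], [2])], "a")
        pb = _gff(tmp_path / "b.gff3", [(impostor, [4])], "b")
        bundle = build_matrix([pa, pb])
        assert row_key(calls[1]) in bundle.matrix.index
        assert row_key(calls[0]) not in bundle.matrix.index
        assert set(bundle.dropped.uid) == {calls[0].uid}


class TestAggregate:
    def _matrix(self):
        return matrix_from_counts(
            {
                "s1": {
                    "miR-X|iso_3p:-2|iso-22-0A": 3,
                    "miR-X|iso_3p:-2|iso-22-0B": 4,
                    "miR-X|NA|iso-22-0C": 10,
                    "miR-Y|iso_snv_seed|iso-22-0D": 2,
                },
                "s2": {
                    "miR-X|iso_3p:-2|iso-22-0A": 1,
                    "miR-Y|iso_snv_seed|iso-22-0D": 6,
                },
            }
        )

    def test_length_cluster_groups_same_variant(self):
        out = aggregate(self._matrix(), "length_cluster")
        assert out.loc["miR-X_iso_3p:-2", "s1"] == 7
        assert out.loc["miR-X_iso_3p:-2", "s2"] == 1

    def test_class_level_uses_class_names(self):
        out = aggregate(self._matrix(), "class")
        assert set(out.index) == {
            "miR-X_iso_3p",
            "miR-X_canonical",
            "miR-Y_iso_snv_seed",
        }

    def test_column_sums_preserved_at_every_level(self):
        m = self._matrix()
        for level in ("class", "length_cluster", "mirna"):
            out = aggregate(m, level)
            assert (out.sum() == m.sum()).all()

    def test_single_row_self_aggregates(self):
        m = matrix_from_counts({"s1": {"miR-X|NA|iso-22-0C": 4}})
        for level in ("class", "length_cluster", "mirna"):
            out = aggregate(m, level)
            assert out.shape == (1, 1) and out.iloc[0, 0] == 4

    def test_unparseable_index_rejected(self):
        m = pd.DataFrame({"s1": [1]}, index=["garbage-row"])
        with pytest.raises(MatrixError, match="unparseable"):
            aggregate(m, "mirna")


class TestCompareModes:
    def _m(self, rows):
        return matrix_from_counts({"s1": {k: 1 for k in rows}})

    def test_identical_matrices_all_in_four_way_cell(self):
        rows = ["miR-X|NA|iso-22-0C", "miR-X|iso_3p:-2|iso-22-0A"]
        comp = compare_modes({m: self._m(rows) for m in ("SR1", "SR2", "PE_0", "PE_8")})
        assert comp.venn_cell("SR1", "SR2", "PE_0", "PE_8") == 2
        assert sum(comp.venn.values()) == 2

    def test_mode_exclusive_sequence_counted_in_own_cell(self):
        shared = "miR-X|NA|iso-22-0C"
        only_sr1 = "miR-X|iso_snv_seed|iso-22-0D"
        comp = compare_modes(
            {
                "SR1": self._m([shared, only_sr1]),
                "PE_0": self._m([shared]),
            }
        )
        assert comp.venn_cell("SR1") == 1
        assert comp.venn_cell("SR1", "PE_0") == 1

    def test_partition_sums_to_union(self, hiseq_experiment):
        comp = hiseq_experiment.comparison
        union = set()
        for df in hiseq_experiment.matrices.values():
            union |= set(df.index[df.sum(axis=1) > 0])
        assert sum(comp.venn.values()) == len(union)

    def test_unknown_mode_rejected(self):
        with pytest.raises(MatrixError, match="unknown mode"):
            compare_modes({"SR9": self._m(["miR-X|NA|iso-22-0C"])})


class TestFlagSrFalsePositives:
    SNV = "miR-X|iso_snv_seed|iso-22-0D"
    CANON = "miR-X|NA|iso-22-0C"

    def _sr(self):
        return matrix_from_counts({"s1": {self.SNV: 2, self.CANON: 5}})

    def _pe(self):
        return matrix_from_counts({"s1": {self.CANON: 7}})

    def test_pe_canonical_contradiction_flagged(self):
        trace = [
            PairTrace("p1", "s1", self.SNV, True, self.CANON),
            PairTrace("p2", "s1", self.SNV, True, self.SNV),
            PairTrace("p3", "s1", self.CANON, True, self.CANON),
        ]
        res = flag_sr_false_positives(self._sr(), self._pe(), trace)
        assert res.flagged_rows == {self.SNV}
        assert res.filtered.loc[self.SNV, "s1"] == 1
        assert res.filtered.loc[self.CANON, "s1"] == 5

    def test_unjoined_pair_is_no_evidence(self):
        trace = [PairTrace("p1", "s1", self.SNV, False, None)]
        res = flag_sr_false_positives(self._sr(), self._pe(), trace)
        assert not res.flagged_rows and res.n_no_evidence == 1

    def test_identical_calls_not_flagged(self):
        trace = [PairTrace("p1", "s1", self.SNV, True, self.SNV)]
        res = flag_sr_false_positives(self._sr(), self._pe(), trace)
        assert not res.flagged_rows

    def test_idempotent(self):
        trace = [
            PairTrace("p1", "s1", self.SNV, True, self.CANON),
            PairTrace("p2", "s1", self.SNV, True, self.CANON),
            PairTrace("p3", "s1", self.SNV, True, self.CANON),
        ]
        once = flag_sr_false_positives(self._sr(), self._pe(), trace)
        twice = flag_sr_false_positives(once.filtered, self._pe(), trace)
        assert twice.filtered.equals(once.filtered)


class TestLog2fcRank:
    def _matrix(self):
        return matrix_from_counts(
            {
                "a1": {"miR-X|NA|iso-22-0C": 100, "miR-Y|NA|iso-22-0E": 50},
                "a2": {"miR-X|NA|iso-22-0C": 80, "miR-Y|NA|iso-22-0E": 40},
                "b1": {"miR-X|NA|iso-22-0C": 100, "miR-Y|NA|iso-22-0E": 50},
                "b2": {"miR-X|NA|iso-22-0C": 80, "miR-Y|NA|iso-22-0E": 40},
            }
        )

    GROUPS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_equal_groups_give_zero_metric(self):
        ranked = log2fc_rank(self._matrix(), self.GROUPS, min_samples=1)
        assert np.allclose(ranked.to_numpy(), 0.0)

    def test_min_samples_filters_sparse_rows(self):
        m = self._matrix()
        m.loc["miR-Z|iso_snv|iso-22-0F"] = [7, 0, 0, 0]
        ranked = log2fc_rank(m, self.GROUPS, min_samples=2)
        assert "miR-Z|iso_snv|iso-22-0F" not in ranked.index

    def test_library_size_doubling_cancels(self):
        m = self._matrix()
        doubled = m.copy()
        doubled[["a1", "a2"]] *= 2
        a = log2fc_rank(m, self.GROUPS, min_samples=1)
        b = log2fc_rank(doubled, self.GROUPS, min_samples=1)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_empty_group_rejected(self):
        with pytest.raises(MatrixError, match="both groups"):
            log2fc_rank(self._matrix(), {"a1": "A", "a2": "A"}, min_samples=1)

    def test_rank_file_round_trip(self, tmp_path):
        m = self._matrix()
        m.loc["miR-Z|iso_snv|iso-22-0F"] = [70, 50, 1, 2]
        ranked = log2fc_rank(m, self.GROUPS, min_samples=1)
        path = tmp_path / "x.rnk"
        write_rank_file(ranked, path)
        back = read_rank_file(path)
        assert list(back.index) == list(ranked.index)
        assert np.allclose(back.to_numpy(), ranked.to_numpy(), atol=1e-4)
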