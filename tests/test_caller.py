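import itertools

import numpy as np
import pytest

from isomirpe.caller import (
    AnchorIndex,
    CallLimits,
    call_isomir,
    class_of_label,
    classify_snv_position,
    decode_license_plate,
    license_plate,
    read_mirgff3,
    write_mirgff3,
)
from isomirpe.reference import SequenceRecord, anchor_mature
from isomirpe.variants import build_truth_set

from oracles import brute_min_edits, enumerate_isoforms


@pytest.fixture
def toy_anchor():
    return anchor_mature(SequenceRecord("m", "CCC"), [SequenceRecord("h", "AACCCGG")])


class TestClassifySnvPosition:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (2, "iso_snv_seed"),
            (7, "iso_snv_seed"),
            (8, "iso_snv_central_offset"),
            (9, "iso_snv_central"),
            (12, "iso_snv_central"),
            (13, "iso_snv_central_supp"),
            (17, "iso_snv_central_supp"),
            (1, "iso_snv"),
            (18, "iso_snv"),
            (22, "iso_snv"),
        ],
    )
    def test_windows(self, pos, expected):
        assert classify_snv_position(pos) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_snv_position(0)
        with pytest.raises(ValueError):
            classify_snv_position(23)


class TestCallIsomir:
    def test_canonical_zero_edits(self, small_reference):
        anchors = small_reference[3]
        res = call_isomir(anchors[0].mature_seq, anchors)
        assert res.status == "assigned"
        assert res.call.variant_label == "NA" and res.call.n_edits == 0

    def test_templated_vs_nontemplated_extension(self, toy_anchor):
        limits = CallLimits(min_len=1, max_len=10)
        templated = call_isomir("CCCG", [toy_anchor], limits)
        assert templated.call.variant_label == "iso_3p:+1"
        added = call_isomir("CCCA", [toy_anchor], limits)
        assert added.call.variant_label == "iso_add3p:1"

    def test_seed_snv_classified(self, small_reference):
        anchors = small_reference[3]
        mature = anchors[0].mature_seq
        alt = "A" if mature[4] != "A" else "G"
        res = call_isomir(mature[:4] + alt + mature[5:], anchors)
        assert res.status == "assigned"
        assert res.call.variant_label == "iso_snv_seed"
        assert res.call.decomposition.snvs == ((5, mature[4], alt),)

    def test_two_snvs_unassigned(self, small_reference):
        anchors = small_reference[3]
        mature = anchors[0].mature_seq
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}
        mutated = (
            mature[:4] + sub[mature[4]] + mature[5:11] + sub[mature[11]] + mature[12:]
        )
        assert call_isomir(mutated, anchors).status == "unassigned"

    def test_length_gate(self, small_reference):
        anchors = small_reference[3]
        assert call_isomir("ACGTACGT", anchors).status == "unassigned"

    def test_ambiguous_when_two_anchors_tie(self):
        a1 = anchor_mature(
            SequenceRecord("m1", "ACGTACGTACGTACGTAC"),
            [SequenceRecord("h1", "TTTACGTACGTACGTACGTACTTT")],
        )
        a2 = anchor_mature(
            SequenceRecord("m2", "ACGTACGTACGTACGTAC"),
            [SequenceRecord("h2", "GGGACGTACGTACGTACGTACGGG")],
        )
        res = call_isomir("ACGTACGTACGTACGTAC", [a1, a2])
        assert res.status == "ambiguous"

    def test_index_and_plain_list_agree(self, small_reference):
        anchors = small_reference[3]
        index = AnchorIndex(anchors)
        truth = build_truth_set(anchors, n_mirnas=10, seed=3)
        for rec in truth:
            a = call_isomir(rec.sequence, anchors)
            b = call_isomir(rec.sequence, index)
            assert a == b

    def test_minimal_edits_match_brute_force(self):
        """The chosen decomposition's edit count equals the exhaustive
        forward-enumeration minimum on toy anchors (mature <= 12 nt)."""
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        anchors = []
        for i in range(3):
            while True:
                hp = "".join(rng.choice(bases, 20))
                mature = hp[4:4 + 10]
                if hp.count(mature) == 1:
                    break
            anchors.append(
                anchor_mature(
                    SequenceRecord(f"m{i}", mature), [SequenceRecord(f"h{i}", hp)]
                )
            )
        limits = CallLimits(max_shift=2, max_add=2, max_snv=1, min_len=1, max_len=20)
        kw = dict(max_shift=2, max_add=2, max_snv=1)
        seqs = set()
        for a in anchors:
            for seq, _ in enumerate_isoforms(a.mature_seq, a.flank5, a.flank3, **kw):
                seqs.add(seq)
        checked = 0
        for seq in sorted(seqs)[::7]:  # systematic subsample for speed
            want_edits, n_anchors = brute_min_edits(seq, anchors, **kw)
            res = call_isomir(seq, anchors, limits)
            if n_anchors > 1:
                assert res.status == "ambiguous"
            else:
                assert res.status == "assigned"
                assert res.call.n_edits == want_edits
            checked += 1
        assert checked > 100


class TestLicensePlate:
    def test_round_trip_random_sequences(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            seq = "".join(rng.choice(bases, int(rng.integers(1, 30))))
            uid = license_plate(seq)
            assert uid.startswith(f"iso-{len(seq)}-")
            assert decode_license_plate(uid) == seq

    def test_injective_over_all_8mers(self):
        uids = {
            license_plate("".join(kmer))
            for kmer in itertools.product("ACGT", repeat=8)
        }
        assert len(uids) == 4**8

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            license_plate("")
        with pytest.raises(ValueError):
            license_plate("ACGN")
        with pytest.raises(ValueError):
            decode_license_plate("iso-x-00")


class TestMirGff3:
    def _calls(self, small_reference):
        anchors = small_reference[3]
        truth = build_truth_set(anchors, n_mirnas=5, seed=8)
        index = AnchorIndex(anchors)
        return [call_isomir(r.sequence, index).call for r in truth]

    def test_round_trip(self, small_reference, tmp_path):
        calls = self._calls(small_reference)
        path = tmp_path / "sample.gff3"
        counts = [[i + 1, (i + 1) * 2] for i in range(len(calls))]
        write_mirgff3(list(zip(calls, counts)), ["s1", "s2"], path)
        entries, samples = read_mirgff3(path)
        assert samples == ["s1", "s2"]
        assert len(entries) == len(calls)
        for call, cnt, entry in zip(calls, counts, entries):
            assert entry.sequence == call.sequence
            assert entry.uid == call.uid
            assert entry.name == call.mirna
            assert entry.variant == call.variant_label
            assert list(entry.expression) == cnt

    def test_canonical_serializes_variant_na(self, small_reference, tmp_path):
        calls = [c for c in self._calls(small_reference) if c.n_edits == 0]
        path = tmp_path / "canon.gff3"
        write_mirgff3([(calls[0], [5])], ["s1"], path)
        line = [
            ln for ln in path.read_text().splitlines() if not ln.startswith("#")
        ][0]
        assert "Variant=NA" in line and "\tref_miRNA\t" in line

    def test_mixed_label_comma_joined(self, toy_anchor):
        from isomirpe.caller import Decomposition, variant_label

        label = variant_label(
            Decomposition(0, -1, "", ((2, "C", "T"),)), mature_len=22
        )
        assert label == "iso_3p:-1,iso_snv_seed"
        assert class_of_label(label) == "mixed"

    def test_malformed_attribute_errors_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text(
            "## mirGFF3. VERSION 1.2\n## COLDATA: s1\n"
            "h1\tx\tisomiR\t1\t22\t.\t+\t.\tRead ACGT no equals\n"
        )
        with pytest.raises(ValueError, match=":3"):
            read_mirgff3(path)
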