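import io

import numpy as np
import pandas as pd
import pytest

from sporetrace.barcode_io import (
    AssignmentResult,
    CountTable,
    ReadPair,
    SampleSheet,
    count_barcodes,
    demultiplex,
    iter_read_pairs,
    match_barcode,
    read_barcode_library,
)
from sporetrace.errors import FormatError, InvalidInputError, ReconciliationError
from sporetrace.synth import (
    BarcodeLibrary,
    default_samplesheet_frame,
    generate_barcodes,
    render_reads,
    revcomp,
    write_fastq_pair,
)

FILL = "ACGTGTCAGTACGTTGCAACGTGTCAGTACGTTGCAACGTGTCAGTACGT"


def pad(seq, n=50):
    return (seq + FILL)[:n]


@pytest.fixture
def pair_for(sheet24, toy_library):
    row = sheet24.frame.iloc[0]

    def make(bc1=None, bc2=None, seq1=None, seq2=None):
        s1 = seq1 if seq1 is not None else pad(row.forward_tag + "TTGCA" + (bc1 or ""))
        s2 = seq2 if seq2 is not None else pad(row.reverse_tag + "GATTC" + (bc2 or ""))
        return ReadPair("r1", s1, s2)

    return make


class TestSampleSheet:
    def test_valid_sheet(self, sheet24):
        assert len(sheet24) == 24
        assert sheet24.forward_len == 5 and sheet24.reverse_len == 7

    def test_duplicate_tag_pair_rejected(self):
        frame = default_samplesheet_frame()
        frame.loc[1, ["forward_tag", "reverse_tag"]] = frame.loc[
            0, ["forward_tag", "reverse_tag"]
        ].values
        with pytest.raises(InvalidInputError, match="duplicate"):
            SampleSheet(frame)

    def test_over_48_samples_rejected(self):
        frames = [
            default_samplesheet_frame(condition=c, incubation=i)
            for c, i in [("planktonic", "2d"), ("planktonic", "5d"), ("pellicle", "2d")]
        ]
        for k, f in enumerate(frames):
            f["reverse_tag"] = f["reverse_tag"].str[:-1] + "ACG"[k]
        big = pd.concat(frames, ignore_index=True)
        with pytest.raises(InvalidInputError, match="48"):
            SampleSheet(big)

    def test_unknown_condition_rejected(self):
        frame = default_samplesheet_frame()
        frame.loc[0, "condition"] = "colony"
        with pytest.raises(InvalidInputError, match="condition"):
            SampleSheet(frame)

    def test_tsv_round_trip(self, sheet24, tmp_path):
        sheet24.to_tsv(tmp_path / "sheet.tsv")
        back = SampleSheet.from_tsv(tmp_path / "sheet.tsv")
        pd.testing.assert_frame_equal(back.frame, sheet24.frame)

    def test_metadata_lookup(self, sheet24):
        sid = sheet24.sample_ids[0]
        meta = sheet24.metadata(sid)
        assert meta["condition"] == "planktonic"
        with pytest.raises(KeyError):
            sheet24.metadata("nope")


class TestDemultiplex:
    def test_exact_match(self, sheet24, pair_for):
        assert demultiplex(pair_for(), sheet24) == sheet24.sample_ids[0]

    def test_single_mismatch_unmatched(self, sheet24):
        row = sheet24.frame.iloc[0]
        tag = ("G" if row.forward_tag[0] != "G" else "T") + row.forward_tag[1:]
        pair = ReadPair("r", pad(tag + "AAAAA"), pad(row.reverse_tag + "AAAAA"))
        assert demultiplex(pair, sheet24) is None

    def test_mismatch_tolerance_knob(self, sheet24):
        row = sheet24.frame.iloc[0]
        tag = ("G" if row.forward_tag[0] != "G" else "T") + row.forward_tag[1:]
        pair = ReadPair("r", pad(tag + "AAAAA"), pad(row.reverse_tag + "AAAAA"))
        assert demultiplex(pair, sheet24, tag_mismatches=1) == row.sample_id

    def test_48_plex_resolution(self):
        # the full cross of 4 forward x 12 reverse tags -> 48 resolvable samples
        from sporetrace.synth import DEFAULT_FORWARD_TAGS, DEFAULT_REVERSE_TAGS

        rows = []
        for mi, ft in enumerate(DEFAULT_FORWARD_TAGS):
            for ri, rt in enumerate(DEFAULT_REVERSE_TAGS):
                rows.append(
                    {
                        "forward_tag": ft,
                        "reverse_tag": rt,
                        "sample_id": f"s{mi}-{ri}",
                        "condition": "planktonic",
                        "incubation": "2d",
                        "mix": "ABCD"[mi],
                        "replicate": ri + 1,
                        "transfer": 9,
                    }
                )
        sheet = SampleSheet(pd.DataFrame(rows))
        resolved = set()
        for row in sheet.frame.itertuples(index=False):
            pair = ReadPair("r", pad(row.forward_tag + "A" * 10), pad(row.reverse_tag + "A" * 10))
            resolved.add(demultiplex(pair, sheet))
        assert len(resolved) == 48


class TestMatchBarcode:
    def test_one_intact_mate_assigns(self, toy_library, pair_for):
        bc = toy_library.barcode_of("A")
        pair = pair_for(bc1=bc, seq2=pad("GGGGGGGGGGGGGGGGGGGG"))
        res = match_barcode(pair, toy_library)
        assert res.category == "assigned" and res.strain_id == "A"

    def test_two_distinct_barcodes_ambiguous(self, toy_library, pair_for):
        pair = pair_for(bc1=toy_library.barcode_of("A"), bc2=toy_library.barcode_of("B"))
        assert match_barcode(pair, toy_library).category == "ambiguous"

    def test_two_barcodes_same_mate_ambiguous(self, toy_library):
        both = toy_library.barcode_of("A") + toy_library.barcode_of("B")
        pair = ReadPair("r", pad(both, 50), pad("G" * 30))
        assert match_barcode(pair, toy_library).category == "ambiguous"

    def test_single_substitution_unassigned(self, toy_library, pair_for):
        bc = toy_library.barcode_of("A")
        broken = ("C" if bc[5] != "C" else "G").join([bc[:5], bc[6:]])
        pair = pair_for(bc1=broken, seq2=pad("G" * 30))
        assert match_barcode(pair, toy_library).category == "unassigned"

    def test_same_barcode_both_mates_counted_once(self, toy_library, pair_for):
        bc = toy_library.barcode_of("B")
        pair = ReadPair("r", pad("TTGCA" + bc), pad("GATTC" + revcomp(bc)))
        res = match_barcode(pair, toy_library)
        assert res.category == "assigned" and res.strain_id == "B"

    def test_revcomp_search_configurable(self, toy_library):
        bc = toy_library.barcode_of("A")
        pair = ReadPair("r", pad("G" * 30), pad("AATC" + revcomp(bc)))
        assert match_barcode(pair, toy_library, search_revcomp=True).strain_id == "A"
        assert match_barcode(pair, toy_library, search_revcomp=False).category == "unassigned"

    def test_result_invariant(self):
        with pytest.raises(InvalidInputError):
            AssignmentResult("ambiguous", strain_id="A")
        with pytest.raises(InvalidInputError):
            AssignmentResult("assigned", strain_id=None)

    def test_oracle_equivalence_random_pairs(self, rng):
        # naive all-barcodes x all-positions scan must agree everywhere
        lib = generate_barcodes(10, 6, 2, seed=3)

        def oracle(pair):
            found = set()
            for seq in (pair.seq1, pair.seq2, revcomp(pair.seq1), revcomp(pair.seq2)):
                for bc in lib.barcodes:
                    for i in range(len(seq) - len(bc) + 1):
                        if seq[i : i + len(bc)] == bc:
                            found.add(bc)
            if len(found) == 1:
                return "assigned", lib.entries[found.pop()]
            return ("ambiguous" if found else "unassigned"), None

        bases = np.array(list("ACGT"))
        for _ in range(500):
            s1 = "".join(rng.choice(bases, size=30))
            s2 = "".join(rng.choice(bases, size=30))
            if rng.random() < 0.5:  # plant a barcode to hit assigned/ambiguous paths
                bc = lib.barcodes[rng.integers(0, 10)]
                pos = rng.integers(0, 24)
                s1 = s1[:pos] + bc + s1[pos + 6 :]
            pair = ReadPair("r", s1, s2)
            cat, sid = oracle(pair)
            res = match_barcode(pair, lib)
            assert (res.category, res.strain_id) == (cat, sid)


class TestCountBarcodes:
    def _make_run(self, sheet24, toy_library, design, tmp_path, depth, error_rate, seed=0):
        rng = np.random.default_rng(seed)
        all_pairs, truths = [], {}
        comp = {"WT": 0.5, "A": 0.3, "B": 0.2}
        for row in sheet24.frame.head(3).itertuples(index=False):
            pairs, truth = render_reads(
                comp, design, toy_library, (row.forward_tag, row.reverse_tag),
                depth=depth, error_rate=error_rate, rng=rng, read_id_prefix=row.sample_id,
            )
            all_pairs.extend(pairs)
            truths[row.sample_id] = truth.set_index("strain_id")["true_count"]
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq_pair(all_pairs, r1, r2)
        return r1, r2, truths

    def test_lossless_channel_exact_counts(self, sheet24, toy_library, design, tmp_path):
        r1, r2, truths = self._make_run(sheet24, toy_library, design, tmp_path, 10_000, 0.0)
        table = count_barcodes((str(r1), str(r2)), toy_library, sheet24)
        for sid, truth in truths.items():
            counts = table.counts.loc[sid]
            assert (counts.reindex(truth.index).astype(int) == truth).all()
        assert table.tag_unmatched == 0
        assert int(table.summary["ambiguous"].sum()) == 0

    def test_empty_input(self, sheet24, toy_library, tmp_path):
        r1, r2 = tmp_path / "e1.fastq", tmp_path / "e2.fastq"
        r1.write_text("")
        r2.write_text("")
        table = count_barcodes((str(r1), str(r2)), toy_library, sheet24)
        assert table.total_pairs == 0
        assert (table.counts.to_numpy() == 0).all()

    def test_conservation(self, sheet24, toy_library, design, tmp_path):
        r1, r2, _ = self._make_run(sheet24, toy_library, design, tmp_path, 2000, 0.02)
        table = count_barcodes((str(r1), str(r2)), toy_library, sheet24)
        assert table.total_pairs == 3 * 2000
        total = (
            int(table.summary["assigned"].sum())
            + int(table.summary["ambiguous"].sum())
            + int(table.summary["unassigned"].sum())
            + table.tag_unmatched
        )
        assert total == 3 * 2000

    def test_assigned_fraction_closed_form(self, sheet24, toy_library, design, tmp_path):
        # assigned iff the barcode survives intact on >= 1 of the two mates
        e, depth = 0.005, 20_000
        r1, r2, _ = self._make_run(sheet24, toy_library, design, tmp_path, depth, e, seed=5)
        table = count_barcodes((str(r1), str(r2)), toy_library, sheet24)
        # condition on tag-matched pairs: errors in the 5+7 tag bases drop a
        # pair before barcode matching, independently of the barcode windows
        q = (1 - e) ** 12
        expected = 1 - (1 - q) ** 2
        n = 3 * depth - table.tag_unmatched
        observed = int(table.summary["assigned"].sum()) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 5 * se + 1e-3

    def test_desynchronized_mates_raise(self, tmp_path, toy_library, sheet24):
        r1 = io.StringIO("@a/1\nACGT\n+\nIIII\n")
        r2 = io.StringIO("@b/2\nACGT\n+\nIIII\n")
        with pytest.raises(FormatError, match="desynchronized"):
            list(iter_read_pairs(r1, r2))

    def test_truncated_mate2_raises(self):
        r1 = io.StringIO("@a/1\nACGT\n+\nIIII\n@b/1\nACGT\n+\nIIII\n")
        r2 = io.StringIO("@a/2\nACGT\n+\nIIII\n")
        with pytest.raises(FormatError, match="ended early"):
            list(iter_read_pairs(r1, r2))

    def test_tag_unmatched_tally(self, sheet24, toy_library):
        bc = toy_library.barcode_of("A")
        pairs = [ReadPair("x", pad("NNNNN" + bc), pad("N" * 20))]
        table = count_barcodes(pairs, toy_library, sheet24)
        assert table.tag_unmatched == 1 and table.total_pairs == 1


class TestBarcodeLibraryIO:
    def test_read_barcode_library(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text("barcode\tstrain_id\nAAAACCCCGGGG\tWT\nTTTTGGGGAAAA\tA\n")
        lib = read_barcode_library(path)
        assert lib.entries["AAAACCCCGGGG"] == "WT"

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("bc\tname\nAAAA\tx\n")
        with pytest.raises(InvalidInputError):
            read_barcode_library(path)


class TestCountTableIO:
    def test_tsv_round_trip(self, tmp_path):
        counts = pd.DataFrame(
            [[5, 3], [2, 0]],
            index=pd.Index(["s1", "s2"], name="sample_id"),
            columns=["WT", "A"],
        )
        summary = pd.DataFrame(
            [[8, 1, 0], [2, 0, 1]],
            index=pd.Index(["s1", "s2"], name="sample_id"),
            columns=["assigned", "ambiguous", "unassigned"],
        )
        table = CountTable(counts, summary, tag_unmatched=4)
        table.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountTable.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, counts)
        assert back.tag_unmatched == 4
        assert back.total_pairs == table.total_pairs
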