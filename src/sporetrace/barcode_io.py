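"""Demultiplexing and strain assignment for tagged barcode amplicon reads.

A read pair is resolved in two steps: (1) the inline 5-nt (mate 1) and 7-nt
(mate 2) prefixes are matched exactly against the sample sheet; (2) both mates
(and by default their reverse complements) are scanned for exact, full-length
occurrences of library barcodes.  Exactly one distinct barcode anywhere in the
pair assigns the strain; two or more distinct barcodes make the pair ambiguous
and it is excluded from counts; none leaves it unassigned.  No quality
filtering is applied at any step.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, InvalidInputError
from .synth.panel import BarcodeLibrary, hamming
from .synth.reads import revcomp

TAG_UNMATCHED = "__tag_unmatched__"

SHEET_COLUMNS = [
    "forward_tag",
    "reverse_tag",
    "sample_id",
    "condition",
    "incubation",
    "mix",
    "replicate",
    "transfer",
]

CONDITIONS = {"planktonic", "pellicle"}
INCUBATIONS = {"2d", "5d"}
MIXES = {"A", "B", "C", "D"}
MAX_SAMPLES_PER_SHEET = 48


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of barcode lookup for one read pair."""

    category: str  # assigned | ambiguous | unassigned
    strain_id: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if (self.category == "assigned") != (self.strain_id is not None):
            raise InvalidInputError("strain_id must be present iff category == 'assigned'")


class SampleSheet:
    """Maps (forward_tag, reverse_tag) pairs to sample identities and metadata."""

    def __init__(self, frame: pd.DataFrame, strict: bool = True):
        missing = [c for c in SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidInputError(f"sample sheet missing columns: {missing}")
        frame = frame.copy()
        frame["replicate"] = frame["replicate"].astype(int)
        frame["transfer"] = frame["transfer"].astype(int)
        pairs = list(zip(frame["forward_tag"], frame["reverse_tag"]))
        if len(set(pairs)) != len(pairs):
            raise InvalidInputError("duplicate (forward_tag, reverse_tag) pairs in sample sheet")
        if frame["sample_id"].duplicated().any():
            raise InvalidInputError("duplicate sample_id in sample sheet")
        if len(frame) > MAX_SAMPLES_PER_SHEET:
            raise InvalidInputError(
                f"at most {MAX_SAMPLES_PER_SHEET} samples per sheet, got {len(frame)}"
            )
        flens = {len(t) for t in frame["forward_tag"]}
        rlens = {len(t) for t in frame["reverse_tag"]}
        if len(flens) != 1 or len(rlens) != 1:
            raise InvalidInputError("tags must be fixed-length within a sheet")
        if strict:
            bad = set(frame["condition"]) - CONDITIONS
            if bad:
                raise InvalidInputError(f"unknown condition values: {sorted(bad)}")
            bad = set(frame["incubation"]) - INCUBATIONS
            if bad:
                raise InvalidInputError(f"unknown incubation values: {sorted(bad)}")
            bad = set(frame["mix"]) - MIXES
            if bad:
                raise InvalidInputError(f"unknown mix values: {sorted(bad)}")
        self.frame = frame
        self.forward_len = flens.pop()
        self.reverse_len = rlens.pop()
        self._lookup = {
            (r.forward_tag, r.reverse_tag): r.sample_id for r in frame.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def metadata(self, sample_id: str) -> pd.Series:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(sample_id)
        return rows.iloc[0]

    @classmethod
    def from_tsv(cls, path, strict: bool = True) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"forward_tag": str, "reverse_tag": str}),
                   strict=strict)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def demultiplex(
    pair: ReadPair, sheet: SampleSheet, tag_mismatches: int = 0
) -> str | None:
    """Resolve a pair to a sample_id by inline tag prefixes; None if unmatched.

    Exact matching by default; with ``tag_mismatches`` > 0 a unique sheet row
    within the Hamming tolerance on both tags is accepted.
    """
    p1 = pair.seq1[: sheet.forward_len]
    p2 = pair.seq2[: sheet.reverse_len]
    if tag_mismatches == 0:
        return sheet._lookup.get((p1, p2))
    if len(p1) < sheet.forward_len or len(p2) < sheet.reverse_len:
        return None
    hits = [
        sid
        for (ft, rt), sid in sheet._lookup.items()
        if hamming(p1, ft) <= tag_mismatches and hamming(p2, rt) <= tag_mismatches
    ]
    return hits[0] if len(hits) == 1 else None


def _scan_barcodes(seq: str, entries: dict[str, str], length: int) -> set[str]:
    found = set()
    for i in range(len(seq) - length + 1):
        window = seq[i : i + length]
        if window in entries:
            found.add(window)
    return found


def match_barcode(
    pair: ReadPair,
    library: BarcodeLibrary,
    search_revcomp: bool = True,
    sample_id: str | None = None,
) -> AssignmentResult:
    """Assign a strain by exact full-length barcode occurrence in either mate.

    One distinct barcode found (anywhere, possibly in both mates) -> assigned;
    two or more distinct barcodes -> ambiguous; none -> unassigned.
    """
    length = library.barcode_length
    found: set[str] = set()
    for seq in (pair.seq1, pair.seq2):
        found |= _scan_barcodes(seq, library.entries, length)
        if search_revcomp:
            found |= _scan_barcodes(revcomp(seq), library.entries, length)
    if len(found) == 1:
        bc = found.pop()
        return AssignmentResult("assigned", library.entries[bc], sample_id)
    if len(found) >= 2:
        return AssignmentResult("ambiguous", None, sample_id)
    return AssignmentResult("unassigned", None, sample_id)


@dataclass
class CountTable:
    """Per-sample, per-strain assigned counts plus exclusion tallies.

    ``summary`` rows: assigned, ambiguous, unassigned per sample.
    ``tag_unmatched`` pairs match no sample and are tallied globally.
    """

    counts: pd.DataFrame  # index sample_id, columns strain_id
    summary: pd.DataFrame  # index sample_id, columns assigned/ambiguous/unassigned
    tag_unmatched: int = 0

    @property
    def total_pairs(self) -> int:
        return int(self.summary.to_numpy().sum() + self.tag_unmatched)

    def check_conservation(self) -> None:
        if int(self.counts.to_numpy().sum()) != int(self.summary["assigned"].sum()):
            raise FormatError("assigned tallies inconsistent with count matrix")

    def to_tsv(self, counts_path, summary_path) -> None:
        self.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
        out = self.summary.rename_axis("sample_id").copy()
        out.loc[TAG_UNMATCHED] = 0
        out.loc[TAG_UNMATCHED, "unassigned"] = self.tag_unmatched
        out.to_csv(summary_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, summary_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        summary = pd.read_csv(summary_path, sep="\t", index_col="sample_id")
        tag_unmatched = 0
        if TAG_UNMATCHED in summary.index:
            tag_unmatched = int(summary.loc[TAG_UNMATCHED, "unassigned"])
            summary = summary.drop(index=TAG_UNMATCHED)
        return cls(counts, summary, tag_unmatched)


def read_barcode_library(path) -> BarcodeLibrary:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"barcode", "strain_id"} <= set(frame.columns):
        raise InvalidInputError("barcode table needs 'barcode' and 'strain_id' columns")
    return BarcodeLibrary(dict(zip(frame["barcode"], frame["strain_id"])))


def _open_read(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _strip_mate(read_id: str) -> str:
    rid = read_id.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def iter_read_pairs(r1, r2) -> Iterator[ReadPair]:
    """Stream synchronized pairs from two FASTQ sources (paths or handles)."""
    h1 = _open_read(r1) if isinstance(r1, (str, Path)) else r1
    h2 = _open_read(r2) if isinstance(r2, (str, Path)) else r2
    try:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for rec1 in it1:
            rec2 = next(it2, None)
            if rec2 is None:
                raise FormatError(f"mate 2 stream ended early at record {rec1[0]!r}")
            id1, id2 = _strip_mate(rec1[0]), _strip_mate(rec2[0])
            if id1 != id2:
                raise FormatError(f"desynchronized mates: {id1!r} vs {id2!r}")
            yield ReadPair(id1, rec1[1].upper(), rec2[1].upper(), rec1[2], rec2[2])
        extra = next(it2, None)
        if extra is not None:
            raise FormatError(f"mate 1 stream ended early at record {extra[0]!r}")
    finally:
        if isinstance(r1, (str, Path)):
            h1.close()
        if isinstance(r2, (str, Path)):
            h2.close()


def count_barcodes(
    reads: Iterable[ReadPair] | tuple,
    library: BarcodeLibrary,
    sheet: SampleSheet,
    search_revcomp: bool = True,
    tag_mismatches: int = 0,
) -> CountTable:
    """Single pass over synchronized pairs: demultiplex, match, tally.

    ``reads`` may be an iterable of ReadPair or an (r1_path, r2_path) tuple.
    """
    if isinstance(reads, tuple) and len(reads) == 2:
        reads = iter_read_pairs(*reads)

    samples = sheet.sample_ids
    strains = sorted(set(library.strain_ids))
    s_index = {s: i for i, s in enumerate(samples)}
    g_index = {g: i for i, g in enumerate(strains)}
    counts = np.zeros((len(samples), len(strains)), dtype=np.int64)
    summary = np.zeros((len(samples), 3), dtype=np.int64)  # assigned/ambiguous/unassigned
    tag_unmatched = 0

    for pair in reads:
        sample_id = demultiplex(pair, sheet, tag_mismatches)
        if sample_id is None:
            tag_unmatched += 1
            continue
        res = match_barcode(pair, library, search_revcomp, sample_id)
        si = s_index[sample_id]
        if res.category == "assigned":
            counts[si, g_index[res.strain_id]] += 1
            summary[si, 0] += 1
        elif res.category == "ambiguous":
            summary[si, 1] += 1
        else:
            summary[si, 2] += 1

    table = CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(samples, name="sample_id"), columns=strains),
        summary=pd.DataFrame(
            summary,
            index=pd.Index(samples, name="sample_id"),
            columns=["assigned", "ambiguous", "unassigned"],
        ),
        tag_unmatched=tag_unmatched,
    )
    table.check_conservation()
    return table
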