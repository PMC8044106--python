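"""Render tagged, error-bearing paired-end amplicon reads from a known composition.

Amplicon layout (top strand):

    [forward 5-nt tag][left flank][12-nt barcode][right flank][revcomp(reverse 7-nt tag)]

R1 is the first ``read_length`` bases of the top strand; R2 is the first
``read_length`` bases of the bottom strand, so it begins with the reverse tag.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidInputError
from .panel import ALPHABET, BarcodeLibrary

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD_TAG_LENGTH = 5
REVERSE_TAG_LENGTH = 7


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconDesign:
    """Fixed sequence context around the barcode and the read geometry."""

    left_flank: str = "GACCTGAACGGTCAT"
    right_flank: str = "TTCGGAGCCTAAGTCACGA"
    read_length: int = 50
    forward_tag: str | None = None
    reverse_tag: str | None = None

    def __post_init__(self) -> None:
        if self.forward_tag is not None and len(self.forward_tag) != FORWARD_TAG_LENGTH:
            raise InvalidInputError("forward_tag must be exactly 5 nt")
        if self.reverse_tag is not None and len(self.reverse_tag) != REVERSE_TAG_LENGTH:
            raise InvalidInputError("reverse_tag must be exactly 7 nt")

    def validate_geometry(self, barcode_length: int) -> None:
        """The barcode must be fully contained in at least one read."""
        in_r1 = FORWARD_TAG_LENGTH + len(self.left_flank) + barcode_length <= self.read_length
        in_r2 = REVERSE_TAG_LENGTH + len(self.right_flank) + barcode_length <= self.read_length
        if not (in_r1 or in_r2):
            raise InvalidInputError(
                f"read_length={self.read_length} too short to cover a "
                f"{barcode_length}-nt barcode in either mate"
            )

    def amplicon(self, barcode: str, forward_tag: str, reverse_tag: str) -> str:
        return forward_tag + self.left_flank + barcode + self.right_flank + revcomp(reverse_tag)


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """IID per-base substitutions; an erroneous base becomes one of the 3 others."""
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in ALPHABET if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def render_reads(
    composition: dict[str, float] | pd.Series,
    design: AmpliconDesign,
    library: BarcodeLibrary,
    sample_tag_pair: tuple[str, str],
    depth: int,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    read_id_prefix: str = "read",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw ``depth`` read pairs multinomially from ``composition``.

    Returns the read pairs plus a ground-truth table with the drawn per-strain
    counts and frequencies (the sidecar for round-trip validation).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fwd_tag, rev_tag = sample_tag_pair
    if len(fwd_tag) != FORWARD_TAG_LENGTH or len(rev_tag) != REVERSE_TAG_LENGTH:
        raise InvalidInputError("sample tags must be 5 nt (forward) and 7 nt (reverse)")
    if depth < 0:
        raise InvalidInputError("depth must be >= 0")
    design.validate_geometry(library.barcode_length)

    comp = pd.Series(composition, dtype=float)
    if depth > 0 and abs(comp.sum() - 1.0) > 1e-6:
        raise InvalidInputError(f"composition frequencies sum to {comp.sum()}, not 1")
    bc_of = {sid: bc for bc, sid in library.entries.items()}
    missing = [s for s in comp.index if s not in bc_of]
    if missing:
        raise InvalidInputError(f"strains absent from barcode library: {missing}")

    strains = list(comp.index)
    if depth > 0:
        counts = rng.multinomial(depth, comp.to_numpy() / comp.sum())
    else:
        counts = np.zeros(len(strains), dtype=int)

    # expand to a per-read strain index and shuffle to avoid block structure
    order = np.repeat(np.arange(len(strains)), counts)
    rng.shuffle(order)

    qual = "I" * design.read_length
    pairs: list[ReadPair] = []
    for i, si in enumerate(order):
        amplicon = design.amplicon(bc_of[strains[si]], fwd_tag, rev_tag)
        r1 = amplicon[: design.read_length]
        r2 = revcomp(amplicon)[: design.read_length]
        pairs.append(
            ReadPair(
                read_id=f"{read_id_prefix}:{i}",
                seq1=_apply_errors(r1, error_rate, rng),
                seq2=_apply_errors(r2, error_rate, rng),
                qual1=qual[: len(r1)],
                qual2=qual[: len(r2)],
            )
        )

    truth = pd.DataFrame(
        {
            "strain_id": strains,
            "true_count": counts,
            "true_frequency": counts / depth if depth > 0 else 0.0,
        }
    )
    return pairs, truth


def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq_pair(pairs: list[ReadPair], r1_path, r2_path) -> None:
    """Write standard 4-line FASTQ files (gzip if the path ends in .gz)."""
    with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def validate_amplicon_compatibility(
    library: BarcodeLibrary,
    design: AmpliconDesign,
    tag_pairs: list[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Find (amplicon barcode, intruding barcode) pairs where a *different*
    library barcode occurs inside an amplicon (either strand).

    An empty result means exact substring matching can never be confused by the
    fixed context; used by the run generator to reject unlucky libraries.
    """
    clashes: list[tuple[str, str]] = []
    barcodes = library.barcodes
    for ft, rt in tag_pairs:
        for b1 in barcodes:
            amp = design.amplicon(b1, ft, rt)
            amp_rc = revcomp(amp)
            for b2 in barcodes:
                if b2 == b1:
                    continue
                if b2 in amp or b2 in amp_rc:
                    clashes.append((b1, b2))
        if clashes:
            break
    return clashes
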