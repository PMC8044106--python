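"""Strain panel construction and barcode library generation.

The competition panel consists of a wild-type strain plus every single and
unordered-pair deletion genotype over a universe of regulatory loci (12 loci
gives 1 + 12 + 66 = 79 strains).  Each strain carries a unique 12-nt barcode
used for abundance read-out from pooled amplicon sequencing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import BarcodeGenerationError, InvalidInputError

ALPHABET = "ACGT"

#: Default 12-locus universe of the wild-type strain.
DEFAULT_LOCI = (
    "rapA", "rapB", "rapC", "rapD", "rapE", "rapF",
    "rapG", "rapH", "rapI", "rapJ", "rapK", "rapP",
)

BARCODE_LENGTH = 12


def locus_label(locus: str) -> str:
    """Short label for a locus: ``rapA`` -> ``A``; anything else is kept as-is."""
    if locus.lower().startswith("rap") and len(locus) > 3:
        return locus[3:]
    return locus


@dataclass(frozen=True)
class StrainGenotype:
    """One competing lineage: identity, deleted loci, and its barcode tag."""

    strain_id: str
    deleted_loci: frozenset[str]
    barcode: str | None = None

    def __post_init__(self) -> None:
        if len(self.deleted_loci) > 2:
            raise InvalidInputError(
                f"at most 2 deleted loci supported, got {len(self.deleted_loci)}"
            )
        if self.barcode is not None:
            if len(self.barcode) != BARCODE_LENGTH:
                raise InvalidInputError(
                    f"barcode must be {BARCODE_LENGTH} nt, got {len(self.barcode)!r}"
                )
            if set(self.barcode) - set(ALPHABET):
                raise InvalidInputError(f"barcode has non-ACGT characters: {self.barcode}")

    @property
    def n_deletions(self) -> int:
        return len(self.deleted_loci)


def build_strain_panel(loci: list[str] | tuple[str, ...] = DEFAULT_LOCI) -> list[StrainGenotype]:
    """Enumerate the full panel: WT, all singles, all unordered pairs.

    Ordering is deterministic: WT first, then singles sorted by label, then
    pairs in lexicographic label order.

    Raises
    ------
    InvalidInputError
        If locus names are duplicated or empty.
    """
    loci = list(loci)
    if not loci:
        raise InvalidInputError("need at least one locus name")
    if len(set(loci)) != len(loci):
        dupes = sorted({x for x in loci if loci.count(x) > 1})
        raise InvalidInputError(f"duplicate locus names: {dupes}")

    by_label = sorted(loci, key=locus_label)
    panel = [StrainGenotype("WT", frozenset())]
    for locus in by_label:
        panel.append(StrainGenotype(locus_label(locus), frozenset({locus})))
    for a, b in itertools.combinations(by_label, 2):
        la, lb = sorted((locus_label(a), locus_label(b)))
        panel.append(StrainGenotype(la + lb, frozenset({a, b})))
    return panel


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InvalidInputError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeLibrary:
    """Injective mapping barcode -> strain_id, all barcodes the same length."""

    entries: dict[str, str]
    min_pairwise_hamming: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.entries:
            raise InvalidInputError("barcode library is empty")
        lengths = {len(b) for b in self.entries}
        if len(lengths) != 1:
            raise InvalidInputError(f"heterogeneous barcode lengths: {sorted(lengths)}")
        if len(set(self.entries.values())) != len(self.entries):
            raise InvalidInputError("barcode -> strain mapping is not injective")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries)))

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.entries.values())

    def barcode_of(self, strain_id: str) -> str:
        for bc, sid in self.entries.items():
            if sid == strain_id:
                return bc
        raise KeyError(strain_id)

    @classmethod
    def from_panel(cls, panel: list[StrainGenotype]) -> "BarcodeLibrary":
        entries: dict[str, str] = {}
        for g in panel:
            if g.barcode is None:
                raise InvalidInputError(f"strain {g.strain_id} has no barcode assigned")
            entries[g.barcode] = g.strain_id
        lib = cls(entries)
        lib.min_pairwise_hamming = min_pairwise_distance(lib.barcodes)
        return lib


def min_pairwise_distance(barcodes: list[str]) -> int:
    if len(barcodes) < 2:
        return len(barcodes[0]) if barcodes else 0
    return min(hamming(a, b) for a, b in itertools.combinations(barcodes, 2))


def generate_barcodes(
    n: int,
    length: int = BARCODE_LENGTH,
    min_hamming: int = 3,
    seed: int | None = None,
    strain_ids: list[str] | None = None,
    max_attempts: int = 200_000,
) -> BarcodeLibrary:
    """Rejection-sample ``n`` barcodes with pairwise Hamming distance >= ``min_hamming``.

    Reproducible under a fixed ``seed``.  When ``strain_ids`` is omitted,
    placeholder identifiers ``S000``.. are used.

    Raises
    ------
    BarcodeGenerationError
        If the (n, length, min_hamming) combination cannot be satisfied within
        ``max_attempts`` candidate draws.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if min_hamming < 1:
        raise InvalidInputError("min_hamming must be >= 1")
    if n > 4 ** length:
        raise BarcodeGenerationError(
            f"cannot draw {n} distinct barcodes of length {length} (only {4 ** length} exist)"
        )
    if min_hamming > length and n > 1:
        raise BarcodeGenerationError(
            f"min_hamming={min_hamming} exceeds barcode length {length}"
        )
    if strain_ids is not None and len(strain_ids) != n:
        raise InvalidInputError("strain_ids length must equal n")

    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        if attempts >= max_attempts:
            raise BarcodeGenerationError(
                f"could not place {n} barcodes (length={length}, "
                f"min_hamming={min_hamming}) within {max_attempts} attempts"
            )
        attempts += 1
        candidate = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(candidate, prev) >= min_hamming for prev in accepted):
            accepted.append(candidate)

    ids = strain_ids if strain_ids is not None else [f"S{i:03d}" for i in range(n)]
    lib = BarcodeLibrary(dict(zip(accepted, ids)))
    lib.min_pairwise_hamming = min_pairwise_distance(accepted)
    return lib


def assign_barcodes(
    panel: list[StrainGenotype],
    min_hamming: int = 3,
    seed: int | None = None,
) -> tuple[list[StrainGenotype], BarcodeLibrary]:
    """Generate barcodes for a panel and return the tagged panel plus its library."""
    lib = generate_barcodes(
        len(panel),
        min_hamming=min_hamming,
        seed=seed,
        strain_ids=[g.strain_id for g in panel],
    )
    bc_of = {sid: bc for bc, sid in lib.entries.items()}
    tagged = [replace(g, barcode=bc_of[g.strain_id]) for g in panel]
    return tagged, lib
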