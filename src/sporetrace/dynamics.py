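"""Population-dynamics summaries: frequency trajectories, persistence, winners.

Frequencies use assigned reads only as the denominator; ambiguous and
unassigned pairs are excluded upstream.  Persistence counts replicate
populations in which a strain exceeds its putative input frequency (1/79 for
the full panel, i.e. ~1.27%); winners are strains above a 25% share.
"""

from __future__ import annotations

import logging

import pandas as pd

from .barcode_io import CountTable, SampleSheet
from .errors import InvalidInputError, ReconciliationError

logger = logging.getLogger(__name__)

#: Equal-ratio input frequency of the 79-strain panel.
DEFAULT_INPUT_FREQUENCY = 1.0 / 79.0
DEFAULT_WINNER_THRESHOLD = 0.25

METADATA_COLUMNS = ["condition", "incubation", "mix", "replicate", "transfer"]


def to_frequencies(counts: CountTable, sheet: SampleSheet) -> pd.DataFrame:
    """Long-format frequency table with sheet metadata joined per sample.

    Samples whose assigned total is zero are dropped with a logged warning.
    Samples absent from the sheet raise ReconciliationError.
    """
    known = set(sheet.sample_ids)
    missing = [s for s in counts.counts.index if s not in known]
    if missing:
        raise ReconciliationError(f"samples missing from sample sheet: {missing}")

    rows = []
    for sample_id, row in counts.counts.iterrows():
        total = int(row.sum())
        if total == 0:
            logger.warning("sample %s has no assigned reads; dropped", sample_id)
            continue
        meta = sheet.metadata(sample_id)
        for strain_id, c in row.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    **{k: meta[k] for k in METADATA_COLUMNS},
                    "strain_id": strain_id,
                    "frequency": c / total,
                    "assigned_total": total,
                }
            )
    freqs = pd.DataFrame(rows)
    if not freqs.empty:
        sums = freqs.groupby("sample_id")["frequency"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if not bad.empty:
            raise InvalidInputError(f"frequencies do not sum to 1 for: {list(bad.index)}")
    return freqs


def _at_transfer(freqs: pd.DataFrame, transfer: int) -> pd.DataFrame:
    sub = freqs[freqs["transfer"] == transfer]
    if sub.empty:
        raise InvalidInputError(f"no samples at transfer {transfer}")
    return sub


def persistence(
    freqs: pd.DataFrame,
    transfer: int,
    threshold: float = DEFAULT_INPUT_FREQUENCY,
) -> pd.DataFrame:
    """Per (condition, incubation, strain): number of replicate populations with
    frequency strictly above ``threshold`` at the given transfer."""
    sub = _at_transfer(freqs, transfer)
    grouped = sub.groupby(["condition", "incubation", "strain_id"], sort=True)
    out = grouped.agg(
        n_above=("frequency", lambda f: int((f > threshold).sum())),
        n_replicates=("sample_id", "nunique"),
    ).reset_index()
    out["threshold"] = threshold
    return out


def winners(
    freqs: pd.DataFrame,
    transfer: int,
    threshold: float = DEFAULT_WINNER_THRESHOLD,
) -> pd.DataFrame:
    """Strains strictly above ``threshold`` in each replicate population.

    At most floor(1/threshold) strains can win in one sample.
    """
    sub = _at_transfer(freqs, transfer)
    hits = sub[sub["frequency"] > threshold]
    cols = ["sample_id", *METADATA_COLUMNS, "strain_id", "frequency"]
    return hits[cols].sort_values(["sample_id", "frequency"], ascending=[True, False]).reset_index(
        drop=True
    )


def winner_replicates(winner_table: pd.DataFrame, freqs: pd.DataFrame, transfer: int) -> pd.DataFrame:
    """Per (condition, incubation): replicate populations containing >=1 winner."""
    sub = _at_transfer(freqs, transfer)
    pops = sub.groupby(["condition", "incubation"])["sample_id"].nunique().rename("n_populations")
    if winner_table.empty:
        out = pops.reset_index()
        out["n_with_winner"] = 0
        return out
    wins = (
        winner_table.groupby(["condition", "incubation"])["sample_id"]
        .nunique()
        .rename("n_with_winner")
    )
    return pd.concat([pops, wins], axis=1).fillna(0).astype({"n_with_winner": int}).reset_index()


def strain_order(freqs: pd.DataFrame) -> list[str]:
    """Heat-map ordering: WT first, singles by label, pairs lexicographic."""
    ids = sorted(set(freqs["strain_id"]))
    return sorted(ids, key=lambda s: (s != "WT", len(s), s))
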