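"""End-to-end synthetic run generator: panel -> simulation -> tagged FASTQ files.

One generated run mirrors a single 48-plex sequencing run: up to 4 forward
tags x 12 reverse tags; the default layout is one condition regime with
4 mixes x 6 replicates = 24 populations.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pandas as pd

from ..errors import BarcodeGenerationError
from .panel import StrainGenotype, assign_barcodes, build_strain_panel, DEFAULT_LOCI
from .reads import (
    AmpliconDesign,
    render_reads,
    validate_amplicon_compatibility,
    write_fastq_pair,
)
from .simulate import SimulationParams, Trajectory, simulate_experiment, stream_rng

#: Deterministic default tag sets (4 forward 5-mers, 12 reverse 7-mers).
DEFAULT_FORWARD_TAGS = ("ACGTA", "CGTAC", "GTACG", "TACGT")
DEFAULT_REVERSE_TAGS = (
    "AACCGGT", "CCGGTTA", "GGTTAAC", "TTAACCG",
    "ACACGTG", "CACGTGT", "GACTGAC", "TGACTGA",
    "AGGCCTT", "CTTAGGC", "GCCTTAG", "TAGGCCT",
)

MIXES = ("A", "B", "C", "D")
REPLICATES_PER_MIX = 6


def default_samplesheet_frame(
    condition: str = "planktonic",
    incubation: str = "2d",
    transfer: int = 9,
    mixes=MIXES,
    replicates_per_mix: int = REPLICATES_PER_MIX,
    forward_tags=DEFAULT_FORWARD_TAGS,
    reverse_tags=DEFAULT_REVERSE_TAGS,
) -> pd.DataFrame:
    """24-sample sheet for one condition regime: mix -> forward tag, replicate -> reverse tag."""
    rows = []
    for mi, mix in enumerate(mixes):
        for rep in range(1, replicates_per_mix + 1):
            rows.append(
                {
                    "forward_tag": forward_tags[mi],
                    "reverse_tag": reverse_tags[rep - 1],
                    "sample_id": f"{condition[:3]}-{incubation}-{mix}-r{rep}-t{transfer}",
                    "condition": condition,
                    "incubation": incubation,
                    "mix": mix,
                    "replicate": rep,
                    "transfer": transfer,
                }
            )
    return pd.DataFrame(rows)


def build_clean_library(
    panel: list[StrainGenotype],
    design: AmpliconDesign,
    tag_pairs: list[tuple[str, str]],
    seed: int,
    min_hamming: int = 3,
    max_regenerations: int = 20,
):
    """Barcode the panel, regenerating until no barcode collides with any
    amplicon context (guarantees exact substring matching is unambiguous)."""
    for attempt in range(max_regenerations):
        tagged, lib = assign_barcodes(panel, min_hamming=min_hamming, seed=seed + attempt)
        if not validate_amplicon_compatibility(lib, design, tag_pairs):
            return tagged, lib
    raise BarcodeGenerationError(
        f"no context-clean barcode library found in {max_regenerations} regenerations"
    )


def generate_run(
    outdir,
    params: SimulationParams | None = None,
    loci=DEFAULT_LOCI,
    condition: str = "planktonic",
    incubation: str = "2d",
    transfer: int | None = None,
    design: AmpliconDesign | None = None,
    mixes=MIXES,
    replicates_per_mix: int = REPLICATES_PER_MIX,
) -> dict:
    """Simulate every population of one condition regime and write the run to disk.

    Writes ``r1.fastq`` / ``r2.fastq``, ``samplesheet.tsv``, ``barcodes.tsv``,
    ``truth.tsv`` (per-sample drawn ground truth), and ``params.yaml``.
    Returns the in-memory artifacts for direct use.
    """
    params = params or SimulationParams()
    design = design or AmpliconDesign()
    transfer = params.n_cycles if transfer is None else transfer
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sheet = default_samplesheet_frame(
        condition, incubation, transfer, mixes, replicates_per_mix
    )
    tag_pairs = list(zip(sheet["forward_tag"], sheet["reverse_tag"]))
    panel = build_strain_panel(loci)
    tagged, lib = build_clean_library(panel, design, tag_pairs, seed=params.seed)

    all_pairs = []
    truth_frames = []
    trajectories: dict[str, Trajectory] = {}
    for row in sheet.itertuples(index=False):
        sim_rng = stream_rng(params.seed, "sim", row.mix, row.replicate)
        traj = simulate_experiment(tagged, params, rng=sim_rng)
        trajectories[row.sample_id] = traj
        comp = traj.frequencies.loc[min(transfer, params.n_cycles)]
        read_rng = stream_rng(params.seed, "reads", row.mix, row.replicate, transfer)
        pairs, truth = render_reads(
            comp,
            design,
            lib,
            (row.forward_tag, row.reverse_tag),
            depth=params.depth,
            error_rate=params.error_rate,
            rng=read_rng,
            read_id_prefix=row.sample_id,
        )
        all_pairs.extend(pairs)
        truth.insert(0, "sample_id", row.sample_id)
        truth_frames.append(truth)

    write_fastq_pair(all_pairs, outdir / "r1.fastq", outdir / "r2.fastq")
    sheet.to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"barcode": lib.barcodes, "strain_id": lib.strain_ids}
    ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    truth_all = pd.concat(truth_frames, ignore_index=True)
    truth_all.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    params.to_yaml(outdir / "params.yaml")

    return {
        "panel": tagged,
        "library": lib,
        "sheet": sheet,
        "design": design,
        "truth": truth_all,
        "trajectories": trajectories,
        "outdir": outdir,
    }


def panel_table(panel: list[StrainGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [g.strain_id for g in panel],
            "deleted_loci": [",".join(sorted(g.deleted_loci)) for g in panel],
            "barcode": [g.barcode or "" for g in panel],
        }
    )


def all_tag_pairs(forward_tags=DEFAULT_FORWARD_TAGS, reverse_tags=DEFAULT_REVERSE_TAGS):
    return list(itertools.product(forward_tags, reverse_tags))
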