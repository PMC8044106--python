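"""Relative fitness and sporulation fitness from pairwise-competition CFU counts.

Relative fitness for strain A against B over a 48-h competition:

    W_A = [ln(CFU_A_48h) / ln(CFU_A_start)] / [ln(CFU_B_48h) / ln(CFU_B_start)]

implemented exactly as printed (a ratio of log-count ratios, not of Malthusian
growth rates; an explicitly labeled Malthusian alternative is provided for
comparison but never used by default).  Sporulation fitness:

    SF_A = [spores_A_48h / (cells+spores)_A_start] / [spores_B_48h / (cells+spores)_B_start]

Group inference log10-transforms the ratios, gates on Shapiro-Wilk normality,
and applies a one-sample two-sided t-test against 0, with significance stars
at P < 0.05 / 0.005 / 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientReplicatesError, InvalidInputError, UndefinedFitnessError

STAR_THRESHOLDS = ((0.001, "***"), (0.005, "**"), (0.05, "*"))
SHAPIRO_ALPHA = 0.05


@dataclass
class CompetitionRecord:
    """CFU plate counts for one replicate of a pairwise competition."""

    strain_A: str
    strain_B: str
    cfu_A_start: float
    cfu_B_start: float
    cfu_A_48h: float
    cfu_B_48h: float
    spores_A_48h: float | None = None
    spores_B_48h: float | None = None
    replicate: int = 1

    def swapped(self) -> "CompetitionRecord":
        return replace(
            self,
            strain_A=self.strain_B,
            strain_B=self.strain_A,
            cfu_A_start=self.cfu_B_start,
            cfu_B_start=self.cfu_A_start,
            cfu_A_48h=self.cfu_B_48h,
            cfu_B_48h=self.cfu_A_48h,
            spores_A_48h=self.spores_B_48h,
            spores_B_48h=self.spores_A_48h,
        )


@dataclass
class PlatePair:
    """Permissive (LB) and selective (LB+chl) plate counts for one suspension."""

    cfu_lb: float
    cfu_lb_chl: float


def split_plate_counts(pp: PlatePair) -> tuple[float, float, bool]:
    """(evolved, ancestor, noise_flag): evolved grows on both plate types, so
    ancestor = permissive minus selective, truncated at 0 when plating noise
    makes the difference negative."""
    if pp.cfu_lb < 0 or pp.cfu_lb_chl < 0:
        raise InvalidInputError("plate counts must be >= 0")
    evolved = pp.cfu_lb_chl
    diff = pp.cfu_lb - pp.cfu_lb_chl
    noise = diff < 0
    return evolved, max(diff, 0.0), noise


def _require_positive_log(value: float, name: str) -> None:
    if value <= 1:
        raise UndefinedFitnessError(f"{name}={value} must be > 1 for a positive log")


def relative_fitness(rec: CompetitionRecord) -> float:
    """W_A as a ratio of ln(final)/ln(start) between the two strains."""
    for name in ("cfu_A_start", "cfu_B_start", "cfu_A_48h", "cfu_B_48h"):
        _require_positive_log(getattr(rec, name), name)
    num = math.log(rec.cfu_A_48h) / math.log(rec.cfu_A_start)
    den = math.log(rec.cfu_B_48h) / math.log(rec.cfu_B_start)
    return num / den


def malthusian_fitness(rec: CompetitionRecord) -> float:
    """Alternative estimator ln(final/start)_A / ln(final/start)_B.

    Provided for comparison only; all reported values use relative_fitness.
    """
    for name in ("cfu_A_start", "cfu_B_start", "cfu_A_48h", "cfu_B_48h"):
        if getattr(rec, name) <= 0:
            raise UndefinedFitnessError(f"{name} must be > 0")
    return math.log(rec.cfu_A_48h / rec.cfu_A_start) / math.log(rec.cfu_B_48h / rec.cfu_B_start)


def sporulation_fitness(rec: CompetitionRecord) -> float:
    """SF_A: spore yield per inoculated CFU, relative between the strains."""
    if rec.spores_A_48h is None or rec.spores_B_48h is None:
        raise UndefinedFitnessError("spore counts missing")
    if rec.cfu_A_start <= 0:
        raise UndefinedFitnessError(f"cfu_A_start={rec.cfu_A_start} must be > 0")
    if rec.cfu_B_start <= 0:
        raise UndefinedFitnessError(f"cfu_B_start={rec.cfu_B_start} must be > 0")
    if rec.spores_B_48h <= 0:
        raise UndefinedFitnessError(f"spores_B_48h={rec.spores_B_48h} must be > 0")
    return (rec.spores_A_48h / rec.cfu_A_start) / (rec.spores_B_48h / rec.cfu_B_start)


def dilution_corrected_cfu(colonies: float, dilution_factor: float, volume_ml: float) -> float:
    """Helper: CFU/ml from a plate count at a given dilution and plated volume."""
    if volume_ml <= 0 or dilution_factor <= 0:
        raise InvalidInputError("dilution_factor and volume_ml must be > 0")
    return colonies * dilution_factor / volume_ml


def _stars(p: float) -> str:
    for cutoff, mark in STAR_THRESHOLDS:
        if p < cutoff:
            return mark
    return "ns"


@dataclass
class FitnessResult:
    """Group-level inference over replicate fitness ratios."""

    n: int
    mean_log10: float
    geometric_mean: float
    arithmetic_mean: float
    t_statistic: float
    p_value: float
    stars: str
    shapiro_p: float
    normality_ok: bool
    degenerate: bool = False


def fitness_inference(values: list[float] | np.ndarray) -> FitnessResult:
    """log10-transform, Shapiro-Wilk gate, one-sample t-test vs 0.

    A normality failure is reported as a caveat (``normality_ok=False``); the
    t-test is still run.  Zero variance (all values identical) yields a
    degenerate result without stars.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientReplicatesError(f"need >= 3 replicates, got {values.size}")
    if (values <= 0).any():
        raise InvalidInputError("fitness ratios must be > 0 to log-transform")
    logs = np.log10(values)
    mean_log = float(logs.mean())
    geo = float(10 ** mean_log)
    arith = float(values.mean())
    if np.allclose(logs, logs[0]):
        return FitnessResult(
            n=values.size,
            mean_log10=mean_log,
            geometric_mean=geo,
            arithmetic_mean=arith,
            t_statistic=float("nan"),
            p_value=float("nan"),
            stars="ns",
            shapiro_p=float("nan"),
            normality_ok=False,
            degenerate=True,
        )
    sw_stat, sw_p = sps.shapiro(logs)
    t_stat, p = sps.ttest_1samp(logs, popmean=0.0)
    return FitnessResult(
        n=values.size,
        mean_log10=mean_log,
        geometric_mean=geo,
        arithmetic_mean=arith,
        t_statistic=float(t_stat),
        p_value=float(p),
        stars=_stars(float(p)),
        shapiro_p=float(sw_p),
        normality_ok=bool(sw_p >= SHAPIRO_ALPHA),
    )


# -- table-level interface -----------------------------------------------------

RECORD_COLUMNS = [
    "strain_A", "strain_B", "cfu_A_start", "cfu_B_start",
    "cfu_A_48h", "cfu_B_48h", "spores_A_48h", "spores_B_48h", "replicate",
]


def read_competition_table(path) -> list[CompetitionRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RECORD_COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"competition table missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            CompetitionRecord(
                strain_A=row.strain_A,
                strain_B=row.strain_B,
                cfu_A_start=row.cfu_A_start,
                cfu_B_start=row.cfu_B_start,
                cfu_A_48h=row.cfu_A_48h,
                cfu_B_48h=row.cfu_B_48h,
                spores_A_48h=getattr(row, "spores_A_48h", None),
                spores_B_48h=getattr(row, "spores_B_48h", None),
                replicate=int(getattr(row, "replicate", 1)),
            )
        )
    return records


def competition_summary(records: list[CompetitionRecord]) -> pd.DataFrame:
    """Per strain pair: replicate W and SF values with group inference."""
    frame = pd.DataFrame(
        {
            "strain_A": [r.strain_A for r in records],
            "strain_B": [r.strain_B for r in records],
            "W": [relative_fitness(r) for r in records],
            "SF": [
                sporulation_fitness(r)
                if r.spores_A_48h is not None and r.spores_B_48h is not None
                else np.nan
                for r in records
            ],
        }
    )
    rows = []
    for (a, b), grp in frame.groupby(["strain_A", "strain_B"], sort=False):
        row = {"strain_A": a, "strain_B": b, "n": len(grp)}
        for metric in ("W", "SF"):
            vals = grp[metric].dropna().to_numpy()
            if vals.size >= 3:
                res = fitness_inference(vals)
                row.update(
                    {
                        f"{metric}_geometric_mean": res.geometric_mean,
                        f"{metric}_arithmetic_mean": res.arithmetic_mean,
                        f"{metric}_t": res.t_statistic,
                        f"{metric}_p": res.p_value,
                        f"{metric}_stars": res.stars,
                        f"{metric}_shapiro_p": res.shapiro_p,
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)
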