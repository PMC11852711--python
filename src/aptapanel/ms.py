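"""MS pull-down intensity normalisation and most-probable-target calls.

Pull-downs run in triplicate per aptamer; under native conditions most
pull-downs recover several proteins, so each protein's signal is first
expressed as a percent of its run's total, percents are averaged over the
triplicate, and the mean percent is log2-transformed. The protein with
the highest mean percent is the aptamer's most probable target; a
runner-up within a configurable log2 margin (default 1.0, i.e. within
two-fold) is reported as a comparable secondary target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LONG_COLUMNS = ["protein_id", "aptamer_id", "replicate", "intensity"]


@dataclass
class MSIntensityTable:
    """Protein intensities per (aptamer, replicate) run.

    ``intensities`` is a wide DataFrame: rows proteins, columns a
    MultiIndex (aptamer_id, replicate); all values >= 0, every run total
    > 0.
    """

    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.intensities.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("negative intensity")
        totals = self.intensities.sum(axis=0)
        zero = totals[totals <= 0]
        if len(zero):
            raise ValueError(f"zero-total run(s): {list(zero.index)[:5]}")

    @property
    def aptamer_ids(self) -> list[str]:
        return sorted({a for a, _ in self.intensities.columns})

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "MSIntensityTable":
        missing = set(LONG_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"MS table missing columns {sorted(missing)}")
        wide = table.pivot_table(
            index="protein_id",
            columns=["aptamer_id", "replicate"],
            values="intensity",
            aggfunc="sum",
            fill_value=0.0,
        )
        return cls(intensities=wide)


def read_ms_table(path: str | Path) -> MSIntensityTable:
    """Read a long-format MS TSV (protein_id, aptamer_id, replicate, intensity)."""
    return MSIntensityTable.from_long(pd.read_csv(path, sep="\t"))


def write_ms_table(table: pd.DataFrame, path: str | Path) -> None:
    table[LONG_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class MSTargetProfile:
    """Per-aptamer mean percent-of-total profiles and the log2 transform."""

    mean_percent: pd.DataFrame  # aptamers x proteins
    log2_percent: pd.DataFrame
    floor_percent: float


def normalize_and_aggregate(
    table: MSIntensityTable, floor_percent: float = 0.01
) -> MSTargetProfile:
    """Percent-of-total per run, mean over the triplicate, then log2.

    The aggregation order matters and is fixed: percent per run first,
    then the mean over replicates, then log2 of max(mean percent,
    ``floor_percent``) — the floor keeps proteins absent from every run
    finite on the log scale.
    """
    totals = table.intensities.sum(axis=0)
    percent = table.intensities.div(totals, axis=1) * 100.0
    mean_percent = percent.T.groupby(level="aptamer_id").mean()  # aptamers x proteins
    log2_percent = np.log2(mean_percent.clip(lower=floor_percent))
    return MSTargetProfile(
        mean_percent=mean_percent,
        log2_percent=log2_percent,
        floor_percent=floor_percent,
    )


def assign_targets(
    profile: MSTargetProfile,
    comparability_log2_margin: float = 1.0,
    discriminative_ability: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Most-probable-target table, one row per aptamer.

    The primary target is the protein with the highest mean percent (ties
    break lexicographically by protein id); the runner-up is reported as
    a comparable secondary target iff its log2 mean percent is within
    ``comparability_log2_margin`` of the primary's, rendering a dual
    label like ``FN/C4BP``. ``discriminative_ability`` optionally labels
    each aptamer with the contrast that selected it.
    """
    rows = []
    for aid in profile.mean_percent.index:
        means = profile.mean_percent.loc[aid]
        order = sorted(means.index, key=lambda p: (-means[p], p))
        primary = order[0]
        secondary = None
        if len(order) > 1:
            gap = (
                profile.log2_percent.loc[aid, primary]
                - profile.log2_percent.loc[aid, order[1]]
            )
            if gap <= comparability_log2_margin:
                secondary = order[1]
        label = primary if secondary is None else f"{primary}/{secondary}"
        rows.append(
            {
                "aptamer_id": aid,
                "discriminative_ability": (
                    (discriminative_ability or {}).get(aid, "NA")
                ),
                "primary_target": primary,
                "secondary_target": secondary if secondary else "NA",
                "probable_target": label,
                "primary_mean_percent": float(means[primary]),
            }
        )
    return pd.DataFrame(rows)
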