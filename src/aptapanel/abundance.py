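"""Abundance ranking, zero-vs-rank missingness profile, top-K cutoff, QC.

Only the most abundant aptamers carry enough signal for differential
testing: rare sequences are zero in many samples, which both breaks
normalisation and drowns the signal in noise. Ranking by total count and
cutting at a configured K (default 500) keeps the analysis set explicit
and reproducible; the knee finder on the zero curve is a diagnostic to
inform the choice of K, never an automatism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .samples import SampleMetadata, metadata_frame


@dataclass
class AbundanceRanking:
    """Per-aptamer totals, ranks (1 = most abundant) and zero counts."""

    table: pd.DataFrame  # index aptamer_id; columns total_count, rank, n_zero_samples

    def ordered_ids(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def rank_aptamers(matrix: CountMatrix) -> AbundanceRanking:
    """Rank aptamers by descending total count over all samples.

    Ties break lexicographically by aptamer_id so ranks are deterministic.
    """
    if matrix.counts.shape[1] == 0:
        raise ValueError("count matrix has no aptamers")
    totals = matrix.counts.sum(axis=0)
    n_zero = (matrix.counts == 0).sum(axis=0)
    order = sorted(totals.index, key=lambda a: (-totals[a], a))
    table = pd.DataFrame(
        {
            "total_count": totals,
            "rank": pd.Series({a: r + 1 for r, a in enumerate(order)}),
            "n_zero_samples": n_zero,
        }
    )
    table.index.name = "aptamer_id"
    return AbundanceRanking(table=table)


def zero_profile(
    matrix: CountMatrix, ranking: AbundanceRanking, window: int = 25
) -> tuple[pd.DataFrame, int]:
    """Zero-count-vs-rank series plus a suggested abundance cutoff.

    The suggestion is the rank maximising the forward difference of the
    moving-average-smoothed zero curve (centered window ``window``): where
    the number of zeros jumps most steeply. A flat curve (no positive
    jump) suggests keeping everything. The suggestion is advisory; the
    pipeline always filters at the configured K.
    """
    table = ranking.table.sort_values("rank")
    profile = pd.DataFrame(
        {"rank": table["rank"].to_numpy(), "n_zero_samples": table["n_zero_samples"].to_numpy()}
    )
    smoothed = (
        profile["n_zero_samples"]
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    n = len(smoothed)
    if n < 2:
        return profile, n
    diff = smoothed[1:] - smoothed[:-1]
    if diff.max() <= 0:
        return profile, n
    suggested = int(profile["rank"].iloc[int(np.argmax(diff))])
    return profile, suggested


def select_top_k(matrix: CountMatrix, ranking: AbundanceRanking, k: int) -> CountMatrix:
    """Restrict the matrix to ranks 1..k, columns in rank order."""
    n = matrix.counts.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    keep = ranking.ordered_ids()[:k]
    seqs = (
        {a: matrix.sequences[a] for a in keep if a in matrix.sequences}
        if matrix.sequences
        else None
    )
    return CountMatrix(counts=matrix.counts[keep].copy(), sequences=seqs)


def qc_sample_summary(
    matrix: CountMatrix,
    metadata: list[SampleMetadata],
    grouping_variables: list[str],
) -> pd.DataFrame:
    """Per-group library-size summaries with Tukey-fence outlier flags.

    For each grouping variable and group: the median and quartiles of
    per-sample total counts, and a flag for samples outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] within their group. Groups with a single
    sample are never flagged. Flags are advisory; nothing is excluded.
    """
    meta = metadata_frame(metadata).set_index("sample_id")
    totals = matrix.library_sizes()
    meta = meta.loc[[s for s in totals.index if s in meta.index]]
    rows = []
    for var in grouping_variables:
        if var not in meta.columns:
            raise ValueError(f"unknown grouping variable {var!r}")
        for level, idx in meta.groupby(var, dropna=False).groups.items():
            values = totals.loc[idx]
            q1, med, q3 = values.quantile([0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            flagged = (
                [] if len(values) < 2
                else sorted(values.index[(values < lo) | (values > hi)])
            )
            rows.append(
                {
                    "grouping_variable": var,
                    "group": level,
                    "n_samples": len(values),
                    "median_total": med,
                    "q1": q1,
                    "q3": q3,
                    "flagged_samples": ",".join(flagged),
                }
            )
    return pd.DataFrame(rows)
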