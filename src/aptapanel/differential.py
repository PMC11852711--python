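"""Normalisation, per-aptamer two-group OLS, BH adjustment, panel selection.

Counts are normalised to log2(CPM + 1): counts-per-million removes the
library-size differences between samples, the pseudocount resolves the
zeros that make a bare log undefined, and the log2 scale makes the
regression coefficient an interpretable log2 fold change, so the
selection rule is |coefficient| >= 0.25 and BH-adjusted p <= 0.05.

With a single binary contrast, per-aptamer OLS on an intercept plus group
indicator is exactly the pooled-variance two-sample t-test: the
coefficient is the difference of group means and the t statistic has
n_A + n_B - 2 degrees of freedom. It is computed in closed form,
vectorised across aptamers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix
from .samples import SampleMetadata, metadata_frame


@dataclass
class PanelSelectionConfig:
    """Thresholds of the selection rule (defaults: top 500 most abundant
    aptamers, |log2 coefficient| >= 0.25, BH-adjusted p <= 0.05)."""

    top_k: int = 500
    coef_threshold: float = 0.25
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.coef_threshold <= 0 or self.pseudocount <= 0:
            raise ValueError("coef_threshold and pseudocount must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class Contrast:
    """A two-group comparison; level_b is the positive / disease-ward level.

    ``kind='categorical'`` compares metadata values equal to the levels;
    ``kind='threshold'`` splits a numeric variable at ``threshold``
    (level_a below, level_b at-or-above). Samples outside both levels
    (or with a missing value) are excluded.
    """

    name: str
    variable: str
    level_a: str
    level_b: str
    kind: str = "categorical"
    threshold: float | None = None

    def masks(self, metadata: list[SampleMetadata]) -> tuple[pd.Series, pd.Series]:
        meta = metadata_frame(metadata).set_index("sample_id")
        if self.variable not in meta.columns:
            raise ValueError(f"contrast {self.name!r}: unknown variable {self.variable!r}")
        col = meta[self.variable]
        if self.kind == "categorical":
            mask_a = col.astype(str) == str(self.level_a)
            mask_b = col.astype(str) == str(self.level_b)
        elif self.kind == "threshold":
            values = pd.to_numeric(col, errors="coerce")
            mask_a = values < self.threshold
            mask_b = values >= self.threshold
        else:
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        return mask_a, mask_b


def normalize_log2cpm(matrix: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / sample_total * 1e6 + pseudocount), per cell.

    A zero count maps to log2(pseudocount) (0 at the default pseudocount);
    scaling all counts in a sample leaves its values unchanged.
    """
    totals = matrix.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    cpm = matrix.counts.div(totals, axis=0) * 1e6
    return np.log2(cpm + pseudocount)


def dichotomize_by_median(
    metadata: list[SampleMetadata], variable: str, name: str | None = None
) -> Contrast:
    """Split a numeric variable at its median over non-missing values.

    Values at or above the median go to level_b (the positive side). The
    metadata passed in defines the cut — pass the training cohort to fix
    a cutoff that then applies unchanged elsewhere.
    """
    meta = metadata_frame(metadata)
    if variable not in meta.columns:
        raise ValueError(f"unknown variable {variable!r}")
    values = pd.to_numeric(meta[variable], errors="coerce").dropna()
    if len(values) < 2:
        raise ValueError(f"variable {variable!r}: fewer than 2 non-missing values")
    cut = float(values.median())
    return Contrast(
        name=name or f"{variable}_median",
        variable=variable,
        level_a=f"lt_{cut:g}",
        level_b=f"ge_{cut:g}",
        kind="threshold",
        threshold=cut,
    )


def fit_two_group_ols(
    abundance: pd.DataFrame,
    metadata: list[SampleMetadata],
    contrast: Contrast,
) -> pd.DataFrame:
    """Per-aptamer OLS of log2 abundance on a group indicator.

    Returns a DataFrame (index aptamer_id) with columns ``coefficient``
    (mean of level_b minus mean of level_a, log2 units), ``se`` and
    ``p_value`` (two-sided t, df = n_A + n_B - 2). A zero-residual-
    variance aptamer gets p = 0 when its coefficient is nonzero, p = 1
    otherwise.
    """
    mask_a, mask_b = contrast.masks(metadata)
    ids_a = [s for s in abundance.index if mask_a.get(s, False)]
    ids_b = [s for s in abundance.index if mask_b.get(s, False)]
    n_a, n_b = len(ids_a), len(ids_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: each group needs >= 2 samples "
            f"(got {n_a} vs {n_b})"
        )
    A = abundance.loc[ids_a].to_numpy(dtype=float)
    B = abundance.loc[ids_b].to_numpy(dtype=float)
    coef = B.mean(axis=0) - A.mean(axis=0)
    df_resid = n_a + n_b - 2
    ss = ((A - A.mean(axis=0)) ** 2).sum(axis=0) + ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = ss / df_resid
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    p = np.ones_like(coef)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, coef / np.where(ok, se, 1.0), 0.0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_resid)
    degenerate = ~ok
    p[degenerate & (coef != 0)] = 0.0
    p[degenerate & (coef == 0)] = 1.0
    return pd.DataFrame(
        {"coefficient": coef, "se": se, "p_value": p},
        index=pd.Index(abundance.columns, name="aptamer_id"),
    )


def adjust_bh(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class Panel:
    """A selected discriminative aptamer set for one contrast."""

    contrast: Contrast
    members: list[str]
    n_up: int
    n_down: int
    table: pd.DataFrame = field(repr=False)  # full per-aptamer result table

    def volcano_table(self) -> pd.DataFrame:
        out = self.table[["coefficient", "p_adjusted", "significant"]].copy()
        with np.errstate(divide="ignore"):
            out["neg_log10_p_adjusted"] = -np.log10(out["p_adjusted"])
        return out


def select_panel(
    results: pd.DataFrame, contrast: Contrast, config: PanelSelectionConfig
) -> Panel:
    """Apply the selection rule and orient each member.

    Members satisfy |coefficient| >= coef_threshold and BH-adjusted
    p <= alpha; direction 'up' means higher in level_b. An empty panel is
    allowed (reported, not an error).
    """
    table = results.copy()
    table["p_adjusted"] = adjust_bh(table["p_value"].to_numpy())
    table["significant"] = (
        (table["coefficient"].abs() >= config.coef_threshold)
        & (table["p_adjusted"] <= config.alpha)
    )
    table["direction"] = np.where(table["coefficient"] > 0, "up", "down")
    members = list(table.index[table["significant"]])
    n_up = int((table.loc[members, "coefficient"] > 0).sum())
    return Panel(
        contrast=contrast,
        members=members,
        n_up=n_up,
        n_down=len(members) - n_up,
        table=table,
    )
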