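"""PC1 panel scoring, DeLong AUC confidence intervals, rank tests,
comparator clinical scores, and cross-cohort evaluation tables.

The panel score of a sample is its projection onto the first principal
component of the panel members' log2-CPM values in the training cohort.
The fitted model (center, unit loading, orientation) is deployable: it is
applied unchanged to any other cohort, so scores are comparable across
cohorts without re-fitting. Discrimination is summarised by the
Mann-Whitney AUC with DeLong variance and a Wald 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import Contrast
from .samples import SampleMetadata, metadata_frame

AUC_LABELS = ("below_acceptable", "acceptable", "excellent", "outstanding")


@dataclass
class PanelModel:
    """A train-once / apply-anywhere PC1 scoring model."""

    members: list[str]
    center: np.ndarray
    loading: np.ndarray  # unit Euclidean norm
    orientation: float  # +1 or -1; positive class scores higher in training
    contrast_name: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.loading = np.asarray(self.loading, dtype=float)
        if len(self.members) != self.center.size or len(self.members) != self.loading.size:
            raise ValueError("center/loading length must equal panel size")
        if not math.isclose(float(np.linalg.norm(self.loading)), 1.0, rel_tol=1e-9):
            raise ValueError("loading must have unit norm")
        if self.orientation not in (1.0, -1.0):
            raise ValueError("orientation must be +1 or -1")


@dataclass
class AUCResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def fit_panel_projection(
    abundance: pd.DataFrame,
    members: list[str],
    labels: pd.Series,
    contrast_name: str = "",
) -> PanelModel:
    """Fit center + PC1 loading on training samples.

    ``labels`` is a 0/1 Series indexed by training sample_id (1 = positive
    class). The loading is the first right singular vector of the centered
    training submatrix; the sign is flipped so the positive class has the
    higher mean score (first nonzero loading component positive when the
    class means tie exactly).
    """
    labels = labels.dropna()
    train_ids = [s for s in abundance.index if s in labels.index]
    if len(train_ids) < 2:
        raise ValueError("need >= 2 training samples")
    missing = [m for m in members if m not in abundance.columns]
    if missing:
        raise ValueError(f"panel members absent from abundance matrix: {missing[:5]}")
    X = abundance.loc[train_ids, members].to_numpy(dtype=float)
    y = labels.loc[train_ids].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training labels")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("training submatrix has no variance (all-constant columns)")
    loading = vt[0]
    scores = Xc @ loading
    delta = scores[y == 1].mean() - scores[y == 0].mean()
    if delta > 0:
        orientation = 1.0
    elif delta < 0:
        orientation = -1.0
    else:
        nz = loading[loading != 0]
        orientation = 1.0 if (nz.size == 0 or nz[0] > 0) else -1.0
    return PanelModel(
        members=list(members),
        center=center,
        loading=loading,
        orientation=orientation,
        contrast_name=contrast_name,
    )


def project_scores(model: PanelModel, abundance: pd.DataFrame) -> pd.Series:
    """Project samples onto the fitted PC1 axis.

    score = <row - center, loading> * orientation. All panel members must
    be columns of the abundance matrix (an aptamer unobserved in a cohort
    should enter upstream as zero counts, which is a valid log2-CPM).
    """
    missing = [m for m in model.members if m not in abundance.columns]
    if missing:
        raise ValueError(f"panel members absent from abundance matrix: {missing[:5]}")
    X = abundance[model.members].to_numpy(dtype=float)
    scores = (X - model.center) @ model.loading * model.orientation
    return pd.Series(scores, index=abundance.index, name="pc1_score")


def auc_delong(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> AUCResult:
    """Mann-Whitney AUC with DeLong variance and Wald 95% CI.

    AUC is the mean over all (positive, negative) pairs of
    1[s_pos > s_neg] + 0.5 * 1[equal]; the variance combines the sample
    variances of the positive and negative placement values. The CI is
    auc +/- 1.96 sqrt(var), clipped to [0, 1]; zero variance (perfect or
    degenerate separation) collapses the CI to a point.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    y = y.astype(float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    # placement values via midranks of the pooled sample
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    r_pos = ranks[:m]
    r_neg = ranks[m:]
    v10 = (r_pos - stats.rankdata(pos)) / n  # per-positive placements
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m  # per-negative placements
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return AUCResult(
        auc=auc,
        variance=var,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        n_pos=m,
        n_neg=n,
    )


def wilcoxon_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two score groups.

    Exact null enumeration when the pooled size is <= 20 and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction. Returns (U statistic of group A, two-sided p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def classify_auc(auc: float) -> str:
    """Qualitative AUC band: <0.70 below_acceptable, [0.70, 0.80)
    acceptable, [0.80, 0.90) excellent, >= 0.90 outstanding (boundaries
    resolve upward)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc < 0.70:
        return "below_acceptable"
    if auc < 0.80:
        return "acceptable"
    if auc < 0.90:
        return "excellent"
    return "outstanding"


def clinical_scores(metadata: list[SampleMetadata]) -> pd.DataFrame:
    """Comparator scores: FIB-4 and the AST/ALT ratio, per sample.

    FIB-4 = (age[y] * AST[U/L]) / (platelets[1e9/L] * sqrt(ALT[U/L])).
    A missing input yields a missing score (never a silent zero); ALT or
    platelets <= 0 raise, naming the sample.
    """
    meta = metadata_frame(metadata).set_index("sample_id")
    for name in ("alt", "platelets"):
        col = pd.to_numeric(meta[name], errors="coerce")
        bad = col[(col <= 0)].dropna()
        if len(bad):
            raise ValueError(f"non-positive {name} for sample {bad.index[0]!r}")
    age = pd.to_numeric(meta["age"], errors="coerce")
    ast = pd.to_numeric(meta["ast"], errors="coerce")
    alt = pd.to_numeric(meta["alt"], errors="coerce")
    plt = pd.to_numeric(meta["platelets"], errors="coerce")
    fib4 = (age * ast) / (plt * np.sqrt(alt))
    ratio = ast / alt
    return pd.DataFrame({"fib4": fib4, "ast_alt_ratio": ratio}, index=meta.index)


def evaluate_comparisons(
    model: PanelModel,
    cohorts: dict[str, tuple[pd.DataFrame, list[SampleMetadata]]],
    comparisons: list[Contrast],
    score_columns: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Evaluation table: one row per cohort x comparison (x score).

    Each row carries the AUC with DeLong 95% CI, the Wilcoxon p between
    the two classes, the qualitative AUC band, and the class sizes. A
    comparison with an empty class in a cohort is preserved as an N/A row
    with the reason — never dropped. ``score_columns`` adds comparator
    scores (e.g. FIB-4, sCD163) evaluated on the same comparisons.
    """
    rows = []
    for cohort_name, (abundance, metadata) in cohorts.items():
        scorers = {"panel_pc1": project_scores(model, abundance)}
        if score_columns:
            scorers.update(score_columns)
        for contrast in comparisons:
            mask_a, mask_b = contrast.masks(metadata)
            for score_name, score in scorers.items():
                ids_a = [s for s in score.index if mask_a.get(s, False)]
                ids_b = [s for s in score.index if mask_b.get(s, False)]
                base = {
                    "cohort": cohort_name,
                    "comparison": contrast.name,
                    "score": score_name,
                    "n_neg": len(ids_a),
                    "n_pos": len(ids_b),
                }
                vals_a = score.loc[ids_a].dropna()
                vals_b = score.loc[ids_b].dropna()
                if len(vals_a) == 0 or len(vals_b) == 0:
                    rows.append(
                        {**base, "auc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "wilcoxon_p": np.nan, "label": "N/A", "note": "empty class"}
                    )
                    continue
                pooled = pd.concat([vals_a, vals_b])
                y = pd.Series(0.0, index=pooled.index)
                y.loc[vals_b.index] = 1.0
                res = auc_delong(pooled.to_numpy(), y.to_numpy())
                _, p = wilcoxon_test(vals_a.to_numpy(), vals_b.to_numpy())
                rows.append(
                    {**base, "auc": res.auc, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "wilcoxon_p": p,
                     "label": classify_auc(res.auc), "note": ""}
                )
    return pd.DataFrame(rows)
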