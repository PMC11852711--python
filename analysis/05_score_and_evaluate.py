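"""Fit PC1 scoring models on the development cohort and evaluate every
cohort and comparison, with FIB-4 and AST/ALT as comparator scores.

The evaluation table has one row per panel x cohort x comparison x score,
with DeLong 95% CIs, Wilcoxon p-values and the qualitative AUC band;
comparisons with an empty class (the test cohort has no F3-4 samples)
appear as N/A rows.
"""

import pandas as pd

from aptapanel import (
    Contrast,
    PanelSelectionConfig,
    clinical_scores,
    evaluate_comparisons,
    fit_panel_projection,
    fit_two_group_ols,
    normalize_log2cpm,
    rank_aptamers,
    select_panel,
    select_top_k,
)
from common import RESULTS, study_cohorts

RESULTS.mkdir(parents=True, exist_ok=True)

library, cohorts = study_cohorts()
dev_meta, dev_matrix = cohorts["development"]

selection = PanelSelectionConfig()
ranking = rank_aptamers(dev_matrix)
top_ids = select_top_k(dev_matrix, ranking, selection.top_k).aptamer_ids

# normalise each cohort on the same aptamer set (train-time ranking)
abundances = {
    name: normalize_log2cpm(matrix, selection.pseudocount)[top_ids]
    for name, (_, matrix) in cohorts.items()
}
dev_ab = abundances["development"]

panel_contrasts = {
    "noSH_vs_MASH": Contrast("noSH_vs_MASH", "group", "MASLD_no_SH", "MASH"),
    "F0_vs_F34": Contrast("F0_vs_F34", "fibrosis_group", "F0", "F3_4"),
}
comparisons = [
    Contrast("healthy_vs_noSH", "group", "healthy", "MASLD_no_SH"),
    panel_contrasts["noSH_vs_MASH"],
    Contrast("F0_vs_F12", "fibrosis_group", "F0", "F1_2"),
    Contrast("F12_vs_F34", "fibrosis_group", "F1_2", "F3_4"),
    panel_contrasts["F0_vs_F34"],
]

all_meta = [s for meta, _ in cohorts.values() for s in meta]
comparators = clinical_scores(all_meta)
cohort_inputs = {name: (abundances[name], meta) for name, (meta, _) in cohorts.items()}

tables = []
for name, contrast in panel_contrasts.items():
    results = fit_two_group_ols(dev_ab, dev_meta, contrast)
    panel = select_panel(results, contrast, selection)
    mask_a, mask_b = contrast.masks(dev_meta)
    labels = pd.Series(
        {s: 1.0 for s in dev_ab.index if mask_b.get(s, False)}
        | {s: 0.0 for s in dev_ab.index if mask_a.get(s, False)}
    )
    model = fit_panel_projection(dev_ab, panel.members, labels, name)
    table = evaluate_comparisons(
        model, cohort_inputs, comparisons,
        score_columns={"fib4": comparators["fib4"],
                       "ast_alt_ratio": comparators["ast_alt_ratio"]},
    )
    table.insert(0, "panel", name)
    tables.append(table)

evaluation = pd.concat(tables, ignore_index=True)
evaluation.to_csv(RESULTS / "evaluation.tsv", sep="\t", index=False)

panel_rows = evaluation[evaluation["score"] == "panel_pc1"].copy()
panel_rows["auc_ci"] = panel_rows.apply(
    lambda r: "N/A" if r["label"] == "N/A"
    else f"{r['auc']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}) [{r['label']}]",
    axis=1,
)
print(panel_rows.pivot_table(index=["panel", "cohort"], columns="comparison",
                             values="auc_ci", aggfunc="first").to_string())
n_na = (evaluation["label"] == "N/A").sum()
print(f"\n{len(evaluation)} evaluation rows written ({n_na} N/A rows preserved)")
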