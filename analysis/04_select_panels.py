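"""Select discriminative aptamer panels on the development cohort.

For each contrast (steatohepatitis: MASLD-without-SH vs MASH; fibrosis:
F0 vs F3-4) the top-500 aptamers are tested by per-aptamer OLS on
log2-CPM, BH-adjusted, and thresholded at |coefficient| >= 0.25 and
adjusted p <= 0.05. Because the cohorts are synthetic, the selected
panels are compared against the planted discriminative sets.
"""

import pandas as pd

from aptapanel import (
    Contrast,
    PanelSelectionConfig,
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

selection = PanelSelectionConfig()  # top 500, coef 0.25, alpha 0.05
ranking = rank_aptamers(dev_matrix)
filtered = select_top_k(dev_matrix, ranking, selection.top_k)
abundance = normalize_log2cpm(filtered, selection.pseudocount)

contrasts = {
    "noSH_vs_MASH": (
        Contrast("noSH_vs_MASH", "group", "MASLD_no_SH", "MASH"),
        "steatohepatitis",
    ),
    "F0_vs_F34": (
        Contrast("F0_vs_F34", "fibrosis_group", "F0", "F3_4"),
        "fibrosis",
    ),
}

rows = []
for name, (contrast, planted) in contrasts.items():
    results = fit_two_group_ols(abundance, dev_meta, contrast)
    panel = select_panel(results, contrast, selection)
    panel.table.to_csv(RESULTS / f"panel_{name}.tsv", sep="\t")
    panel.volcano_table().to_csv(RESULTS / f"volcano_{name}.tsv", sep="\t")
    truth = library.discriminative_aptamers(planted) & set(abundance.columns)
    tp = len(set(panel.members) & truth)
    rows.append({
        "contrast": name,
        "panel_size": len(panel.members),
        "n_up": panel.n_up,
        "n_down": panel.n_down,
        "planted_in_top500": len(truth),
        "sensitivity": round(tp / len(truth), 3) if truth else float("nan"),
        "realized_fdr": round((len(panel.members) - tp) / len(panel.members), 3)
        if panel.members else 0.0,
    })

summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "panel_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))
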