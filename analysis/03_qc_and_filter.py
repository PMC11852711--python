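"""Rank aptamers, inspect the zero-vs-rank profile, filter to the top 500,
and summarise per-group library sizes with outlier flags.
"""

import pandas as pd

from aptapanel import qc_sample_summary, rank_aptamers, select_top_k, zero_profile
from aptapanel.counts import CountMatrix
from common import RESULTS, study_cohorts

RESULTS.mkdir(parents=True, exist_ok=True)

library, cohorts = study_cohorts()
all_meta = [s for cohort, _ in cohorts.values() for s in cohort]
combined = CountMatrix(
    counts=pd.concat([m.counts for _, m in cohorts.values()]),
    sequences=library.sequences,
)

ranking = rank_aptamers(combined)
profile, knee = zero_profile(combined, ranking)
print(f"{combined.counts.shape[1]} aptamers ranked; zero-curve knee suggestion: "
      f"rank {knee} (configured cutoff stays at K=500)")
profile.iloc[::20].to_csv(RESULTS / "zero_profile_thinned.tsv", sep="\t", index=False)

qc = qc_sample_summary(combined, all_meta, ["cohort", "group", "sex"])
qc.to_csv(RESULTS / "qc_summary.tsv", sep="\t", index=False)
flagged = qc[qc["flagged_samples"] != ""]
print(f"QC: {len(qc)} group summaries, "
      f"{len(flagged)} with flagged library-size outliers")
if len(flagged):
    print(flagged[["grouping_variable", "group", "flagged_samples"]].to_string(index=False))

top = select_top_k(combined, ranking, 500)
kept = ranking.table.loc[top.aptamer_ids]
print(f"top-500 filter: totals span {kept['total_count'].min()}"
      f"-{kept['total_count'].max()}; "
      f"max zeros among kept aptamers: {kept['n_zero_samples'].max()} "
      f"of {combined.counts.shape[0]} samples")
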