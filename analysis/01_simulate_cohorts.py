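"""Simulate the study bundle: one aptamer library, three cohorts, counts.

Writes the library/metadata/count tables (bulky, to scratch/) and a small
cohort summary (to results/). Everything downstream regenerates the same
bundle deterministically from the shared seed, so later drivers do not
depend on these files being present.
"""

import pandas as pd

from aptapanel import metadata_frame, write_count_table, write_metadata
from common import RESULTS, SCRATCH, study_cohorts

RESULTS.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)

library, cohorts = study_cohorts()
library.write_table(SCRATCH / "library.tsv")

all_meta, matrices = [], []
for name, (cohort, matrix) in cohorts.items():
    all_meta.extend(cohort)
    matrices.append(matrix.counts)
write_metadata(all_meta, SCRATCH / "metadata.tsv")
combined = pd.concat(matrices)

n_disc_sh = len(library.discriminative_aptamers("steatohepatitis"))
n_disc_fib = len(library.discriminative_aptamers("fibrosis"))
print(f"library: {len(library.table)} aptamers, "
      f"{library.table['family_id'].notna().sum()} in families, "
      f"{n_disc_sh} planted steatohepatitis-discriminative, "
      f"{n_disc_fib} fibrosis-discriminative")

summary = (
    metadata_frame(all_meta)
    .groupby(["cohort", "group", "fibrosis_group"])
    .size()
    .rename("n_samples")
    .reset_index()
)
summary.to_csv(RESULTS / "cohort_composition.tsv", sep="\t", index=False)
print(summary.to_string(index=False))

from aptapanel.counts import CountMatrix  # noqa: E402

write_count_table(CountMatrix(counts=combined), SCRATCH / "counts.tsv")
print(f"counts: {combined.shape[0]} samples x {combined.shape[1]} aptamers "
      f"-> {SCRATCH / 'counts.tsv'}")
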