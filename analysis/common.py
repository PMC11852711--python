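"""Shared study conditions for the numbered analysis drivers.

One aptamer library is shared by all cohorts (the pool is selected once,
then sequenced against every plasma sample). Cohort compositions mirror
a realistic MASLD study layout: a development cohort enriched for
steatohepatitis and fibrosis, a test cohort without advanced fibrosis
(so some evaluations are structurally N/A), and a bariatric cohort
dominated by early disease. Effects are planted for the steatohepatitis
and fibrosis contrasts at |log2 FC| = 1.
"""

from pathlib import Path

from aptapanel import SimulationConfig, generate_cohort, generate_library, simulate_counts

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"

SEED = 20260925

BASE = dict(
    n_aptamers=2000,
    n_families=60,
    fraction_in_families=0.4,
    fraction_discriminative_families=0.25,
    effect_log2fc=1.0,
    contrast_effects={"steatohepatitis": 1.0, "fibrosis": 1.0},
    nb_dispersion=0.3,
    library_size_range=(100_000, 300_000),
)

# per-cohort (group -> samples per fibrosis stage F0..F4); marginals follow
# the cohort layout described in the module docstring
COHORT_STAGES = {
    "development": {
        "MASLD_no_SH": [10, 3, 2, 1, 0],
        "MASH": [16, 8, 16, 15, 6],
    },
    "test": {
        "healthy": [10, 0, 0, 0, 0],
        "MASLD_no_SH": [14, 9, 0, 0, 0],
        "MASH": [8, 14, 2, 0, 0],
    },
    "bariatric": {
        "healthy": [15, 0, 0, 0, 0],
        "MASLD_no_SH": [1, 25, 6, 0, 0],
        "MASH": [0, 7, 1, 2, 2],
    },
}


def study_library():
    return generate_library(SimulationConfig(seed=SEED, cohort_name="library", **BASE))


def study_cohorts():
    """cohort name -> (metadata list, count matrix), all from one library."""
    library = study_library()
    out = {}
    for i, (name, stages) in enumerate(COHORT_STAGES.items()):
        config = SimulationConfig(seed=SEED + 1 + i, cohort_name=name, **BASE)
        cohort = generate_cohort(config, stage_counts=stages)
        out[name] = (cohort, simulate_counts(library, cohort, config))
    return library, out
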