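"""Synthetic aptamer pools, cohorts, counts, reads and MS tables.

The generator stands in for data that cannot be shared: it emulates a
post-selection aptamer pool (heavy-tailed abundances after four enrichment
rounds), sequence families sharing a planted exact motif, negative-binomial
sequencing counts with sample-specific library sizes, disease effects
planted at family level for named contrasts, clinical covariates with
plausible group-dependent distributions, and triplicate pull-down MS
intensity tables with one dominant true target per aptamer.

Every output is a pure function of its configuration and seed: independent
stages draw from independently derived `numpy` Generators so calling one
stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .samples import SampleMetadata

_BASES = np.array(list("ACGT"))

# stage tags used to derive independent random streams from one seed
_STREAM_LIBRARY = 1
_STREAM_COHORT = 2
_STREAM_COUNTS = 3
_STREAM_READS = 4


@dataclass
class SimulationConfig:
    """All generator knobs in one place.

    The defaults describe the reference simulation used throughout the
    test-bench: a 500-aptamer pool, half of it organised into 25 families
    of ~10 members carrying a planted 16-nt motif, 20% of families (about
    10% of aptamers) discriminative at |log2 fold change| 1.0 for the
    steatohepatitis contrast, negative-binomial dispersion 0.3, and two
    balanced groups of 40 samples.
    """

    n_aptamers: int = 500
    n_families: int = 25
    fraction_in_families: float = 0.5
    family_motif_length: int = 16
    variable_region_length: int = 40
    primer_5p: str = "GGGAGACAAGAATAAACGCT"
    primer_3p: str = "TTCGACAGGAGGCTCACAAC"
    group_sizes: dict = field(
        default_factory=lambda: {"healthy": 0, "MASLD_no_SH": 40, "MASH": 40}
    )
    baseline_log2_mean: float = 0.0
    baseline_log2_sd: float = 2.0
    fraction_discriminative_families: float = 0.2
    effect_log2fc: float = 1.0
    #: contrast name -> planted log2 fold change; discriminative families are
    #: assigned round-robin across these contrasts
    contrast_effects: dict = field(default_factory=dict)
    fraction_down: float = 0.4
    nb_dispersion: float = 0.3
    library_size_range: tuple = (50_000, 200_000)
    sequencing_error_rate: float = 0.0
    #: no two aptamers from different families/singletons share any k-mer of
    #: this length, so motif clustering at threshold >= this recovers the
    #: planted partition exactly
    cluster_guard_kmer: int = 12
    cohort_name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aptamers < 1 or self.variable_region_length < 1:
            raise ValueError("n_aptamers and variable_region_length must be >= 1")
        if self.family_motif_length >= self.variable_region_length:
            raise ValueError(
                "family_motif_length must be smaller than variable_region_length"
            )
        for frac in (
            self.fraction_in_families,
            self.fraction_discriminative_families,
            self.fraction_down,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_size_range")
        if not self.contrast_effects:
            self.contrast_effects = {"steatohepatitis": self.effect_log2fc}

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


#: contrast name -> per-sample 0/1 indicator used when planting effects
CONTRAST_INDICATORS = {
    "steatohepatitis": lambda s: 1.0 if s.group == "MASH" else 0.0,
    "fibrosis": lambda s: 1.0 if s.fibrosis_stage >= 3 else 0.0,
}


@dataclass
class AptamerLibrary:
    """A post-selection pool with planted families, baselines and effects.

    ``effects`` has one column per contrast (log2 fold-change planted for
    samples where the contrast indicator is 1); ``family_id`` is ``None``
    for singletons.
    """

    table: pd.DataFrame  # aptamer_id, sequence, family_id, baseline_log2
    motifs: dict[str, tuple[str, int]]  # family_id -> (motif, offset)
    effects: pd.DataFrame  # aptamer_id x contrast name

    @property
    def aptamer_ids(self) -> list[str]:
        return list(self.table["aptamer_id"])

    @property
    def sequences(self) -> dict[str, str]:
        return dict(zip(self.table["aptamer_id"], self.table["sequence"]))

    def family_partition(self) -> dict[str, str]:
        """aptamer_id -> family label (singletons get their own label)."""
        out = {}
        for aid, fam in zip(self.table["aptamer_id"], self.table["family_id"]):
            out[aid] = fam if fam is not None else f"singleton_{aid}"
        return out

    def discriminative_aptamers(self, contrast: str) -> set[str]:
        """Ground-truth member set for a planted contrast."""
        col = self.effects[contrast]
        return set(self.effects.index[col != 0.0])

    def write_table(self, path: str | Path) -> None:
        out = self.table.copy()
        out["family_id"] = out["family_id"].map(lambda v: v if v else "NA")
        out["motif"] = [
            self.motifs[f][0] if f in self.motifs else "NA" for f in self.table["family_id"]
        ]
        for contrast in self.effects.columns:
            out[f"effect_{contrast}"] = self.effects[contrast].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


class _KmerGuard:
    """Registry preventing cross-unit exact k-mer sharing."""

    def __init__(self, k: int):
        self.k = k
        self.owner: dict[str, object] = {}

    def admissible(self, seq: str, unit: object) -> bool:
        return all(self.owner.get(km, unit) == unit for km in _kmers(seq, self.k))

    def register(self, seq: str, unit: object) -> None:
        for km in _kmers(seq, self.k):
            self.owner[km] = unit


def generate_library(config: SimulationConfig) -> AptamerLibrary:
    """Generate the aptamer pool with planted families and effects.

    Families carry an exact motif of ``family_motif_length`` at a fixed
    per-family offset; the k-mer guard resamples any sequence that would
    share an exact ``cluster_guard_kmer``-mer with a different family or
    singleton, so the planted partition is exactly what motif clustering
    at that threshold recovers. Baseline log2 abundances are i.i.d. normal
    (log-normal abundance: a steep rank-abundance curve); effects are
    assigned at family level, alternating contrasts round-robin, with a
    configured fraction of effects pointing down.
    """
    rng = config.rng(_STREAM_LIBRARY)
    L = config.variable_region_length
    mlen = config.family_motif_length
    guard = _KmerGuard(config.cluster_guard_kmer)

    n_in_fam = int(round(config.fraction_in_families * config.n_aptamers))
    n_families = config.n_families if n_in_fam > 0 else 0
    if n_families > n_in_fam:
        n_families = n_in_fam
    fam_ids = [f"fam_{i + 1:03d}" for i in range(n_families)]

    # family motifs first, each admissible against all previous units
    motifs: dict[str, tuple[str, int]] = {}
    for fam in fam_ids:
        for _ in range(1000):
            motif = _random_seq(rng, mlen)
            if guard.admissible(motif, fam):
                guard.register(motif, fam)
                offset = int(rng.integers(0, L - mlen + 1))
                motifs[fam] = (motif, offset)
                break
        else:
            raise RuntimeError("could not place a guarded family motif")

    # family sizes: as even as possible over the in-family pool
    members_per_fam = np.full(n_families, n_in_fam // n_families if n_families else 0)
    if n_families:
        members_per_fam[: n_in_fam % n_families] += 1

    sequences: list[str] = []
    family_of: list[str | None] = []
    seen: set[str] = set()

    def _emit(seq_builder, unit) -> str:
        for _ in range(1000):
            seq = seq_builder()
            if seq in seen:
                continue
            if guard.admissible(seq, unit):
                guard.register(seq, unit)
                seen.add(seq)
                return seq
        raise RuntimeError("could not generate an admissible sequence")

    for fam, n_members in zip(fam_ids, members_per_fam):
        motif, offset = motifs[fam]

        def _build(motif=motif, offset=offset):
            left = _random_seq(rng, offset)
            right = _random_seq(rng, L - offset - mlen)
            return left + motif + right

        for _ in range(int(n_members)):
            sequences.append(_emit(_build, fam))
            family_of.append(fam)

    n_singletons = config.n_aptamers - len(sequences)
    for i in range(n_singletons):
        unit = f"single_{i}"
        sequences.append(_emit(lambda: _random_seq(rng, L), unit))
        family_of.append(None)

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_aptamers
    )
    aptamer_ids = [f"lib_{i + 1:04d}" for i in range(config.n_aptamers)]
    table = pd.DataFrame(
        {
            "aptamer_id": aptamer_ids,
            "sequence": sequences,
            "family_id": family_of,
            "baseline_log2": baseline,
        }
    )

    contrasts = list(config.contrast_effects)
    effects = pd.DataFrame(
        0.0, index=pd.Index(aptamer_ids, name="aptamer_id"), columns=contrasts
    )
    n_disc = int(round(config.fraction_discriminative_families * n_families))
    disc_fams = list(rng.choice(fam_ids, size=n_disc, replace=False)) if n_disc else []
    for j, fam in enumerate(disc_fams):
        contrast = contrasts[j % len(contrasts)]
        magnitude = config.contrast_effects[contrast]
        sign = -1.0 if rng.random() < config.fraction_down else 1.0
        mask = table["family_id"] == fam
        effects.loc[table.loc[mask, "aptamer_id"], contrast] = sign * magnitude
    return AptamerLibrary(table=table, motifs=motifs, effects=effects)


# per-group clinical covariate distributions, loosely matching a MASLD
# population (medians near: age 45 y, BMI 30, LDL 3.2 mmol/L, sCD163
# 1.8-2.3 mg/L, AST 40-50 U/L, ALT 55-70 U/L, platelets 250e9/L)
_CLINICAL = {
    "healthy": dict(age=(52, 10), bmi=(27, 4), ldl=(3.1, 0.7), scd163_mu=0.45,
                    ast_mu=3.3, alt_mu=3.4, mets_p=0.10),
    "MASLD_no_SH": dict(age=(46, 12), bmi=(31, 5), ldl=(3.2, 0.8), scd163_mu=0.60,
                        ast_mu=3.6, alt_mu=3.9, mets_p=0.40),
    "MASH": dict(age=(44, 12), bmi=(32, 5), ldl=(3.3, 0.8), scd163_mu=0.80,
                 ast_mu=3.9, alt_mu=4.2, mets_p=0.60),
}

# fibrosis-stage distribution per steatohepatitis group
_STAGE_P = {
    "healthy": [1.0, 0.0, 0.0, 0.0, 0.0],
    "MASLD_no_SH": [0.45, 0.30, 0.15, 0.07, 0.03],
    "MASH": [0.15, 0.20, 0.30, 0.22, 0.13],
}


def generate_cohort(
    config: SimulationConfig,
    stage_counts: dict[str, list[int]] | None = None,
) -> list[SampleMetadata]:
    """Draw a cohort with group labels, fibrosis stages and covariates.

    ``stage_counts`` optionally fixes the exact number of samples per
    (group, stage) as ``{group: [n_F0, n_F1, n_F2, n_F3, n_F4]}``,
    overriding ``group_sizes``; otherwise stages are drawn from
    group-dependent stage distributions.
    """
    rng = config.rng(_STREAM_COHORT)
    plan: list[tuple[str, int]] = []
    if stage_counts is not None:
        for group, per_stage in stage_counts.items():
            for stage, n in enumerate(per_stage):
                plan.extend([(group, stage)] * int(n))
    else:
        for group, n in config.group_sizes.items():
            stages = rng.choice(5, size=int(n), p=_STAGE_P[group])
            plan.extend((group, int(s)) for s in stages)
    if not plan:
        raise ValueError("empty cohort: all group sizes are zero")

    lo, hi = config.library_size_range
    samples = []
    for i, (group, stage) in enumerate(plan):
        p = _CLINICAL[group]
        age = float(np.clip(rng.normal(*p["age"]), 18, 85))
        samples.append(
            SampleMetadata(
                sample_id=f"{config.cohort_name}_s{i + 1:03d}",
                cohort=config.cohort_name,
                group=group,
                fibrosis_stage=stage,
                sex="M" if rng.random() < 0.6 else "F",
                age=round(age, 1),
                bmi=round(float(np.clip(rng.normal(*p["bmi"]), 17, 60)), 1),
                ldl=round(float(np.clip(rng.normal(*p["ldl"]), 0.5, 8)), 2),
                scd163=round(float(rng.lognormal(p["scd163_mu"], 0.30)), 2),
                ast=round(float(np.clip(rng.lognormal(p["ast_mu"], 0.35), 5, 500)), 1),
                alt=round(float(np.clip(rng.lognormal(p["alt_mu"], 0.40), 5, 500)), 1),
                platelets=round(float(np.clip(rng.normal(250, 60), 50, 600)), 0),
                metabolic_syndrome=bool(rng.random() < p["mets_p"]),
                library_size=int(rng.integers(lo, hi + 1)),
            )
        )
    return samples


def simulate_counts(
    library: AptamerLibrary,
    cohort: list[SampleMetadata],
    config: SimulationConfig,
) -> CountMatrix:
    """Draw negative-binomial pool counts for every sample.

    Sample j's expected count for aptamer i is library_size_j * p_ij with
    p_ij proportional to 2^(baseline_i + sum_c effect_ic * x_cj), x the
    contrast indicator; counts are gamma-Poisson with dispersion phi
    (variance m + phi m^2), reducing to Poisson at phi = 0.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rng = config.rng(_STREAM_COUNTS)
    baseline = library.table["baseline_log2"].to_numpy()
    contrasts = list(library.effects.columns)
    eff = library.effects.to_numpy()  # aptamers x contrasts
    phi = config.nb_dispersion
    rows = []
    for s in cohort:
        x = np.array([CONTRAST_INDICATORS[c](s) for c in contrasts])
        log2_abund = baseline + eff @ x
        p = np.exp2(log2_abund)
        p /= p.sum()
        mean = s.library_size * p
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
        else:
            lam = mean
        rows.append(rng.poisson(lam))
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index([s.sample_id for s in cohort], name="sample_id"),
        columns=library.aptamer_ids,
    )
    return CountMatrix(counts=df, sequences=library.sequences)


def simulate_reads(
    matrix: CountMatrix,
    library: AptamerLibrary,
    config: SimulationConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one FASTQ per sample; read = 5' primer + region + 3' primer.

    At ``sequencing_error_rate`` 0 the read multiplicities equal the count
    matrix exactly; otherwise each base is substituted independently with
    that probability. Quality is a constant Phred+33 'I' string.
    """
    rng = config.rng(_STREAM_READS)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = library.sequences
    paths = {}
    err = config.sequencing_error_rate
    for sid in matrix.sample_ids:
        path = out / f"{sid}.fastq"
        row = matrix.counts.loc[sid]
        try:
            with open(path, "w") as fh:
                r = 0
                for aid in matrix.aptamer_ids:
                    n = int(row[aid])
                    if n == 0:
                        continue
                    full = config.primer_5p + seqs[aid] + config.primer_3p
                    qual = "I" * len(full)
                    for _ in range(n):
                        r += 1
                        read = _mutate(full, err, rng) if err > 0 else full
                        fh.write(f"@{sid}_read{r} aptamer={aid}\n{read}\n+\n{qual}\n")
        except OSError as exc:
            raise OSError(f"failed writing FASTQ {path}: {exc}") from exc
        paths[sid] = path
    return paths


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < rate
    if hits.any():
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_ms_table(
    truth: dict[str, str],
    n_background_proteins: int = 30,
    noise_sd: float = 0.5,
    seed: int = 0,
    dominant_share: tuple[float, float] = (0.4, 0.7),
    total_intensity: float = 1e6,
) -> pd.DataFrame:
    """Simulate triplicate pull-down MS runs with a planted true target.

    Returns a long-format table (protein_id, aptamer_id, replicate,
    intensity). Each aptamer's true target receives a dominant share of
    total intensity (uniform in ``dominant_share``); the remainder is
    Dirichlet-spread over background proteins and any other targets.
    Replicate intensities get multiplicative log-normal noise
    (sigma = ``noise_sd`` on the natural-log scale).
    """
    rng = np.random.default_rng([int(seed), 5])
    targets = sorted(set(truth.values()))
    background = [f"BG_{i + 1:03d}" for i in range(n_background_proteins)]
    proteins = targets + background
    records = []
    for aid in sorted(truth):
        true_target = truth[aid]
        others = [p for p in proteins if p != true_target]
        share = rng.uniform(*dominant_share)
        rest = rng.dirichlet(np.ones(len(others))) * (1.0 - share)
        base = dict(zip(others, rest))
        base[true_target] = share
        for rep in (1, 2, 3):
            noise = (
                np.exp(rng.normal(0.0, noise_sd, len(proteins)))
                if noise_sd > 0
                else np.ones(len(proteins))
            )
            for p, nz in zip(proteins, noise):
                records.append(
                    {
                        "protein_id": p,
                        "aptamer_id": aid,
                        "replicate": rep,
                        "intensity": total_intensity * base[p] * nz,
                    }
                )
    return pd.DataFrame.from_records(records)
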