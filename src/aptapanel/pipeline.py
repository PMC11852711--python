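"""End-to-end orchestration: counts -> QC -> top-K -> panels -> scoring ->
families -> MS targets, driven by one YAML config, with a reproducibility
manifest.

One count matrix and one metadata table cover all cohorts (the metadata
``cohort`` column splits them); exactly one cohort is the training
(development) cohort, on which panels are selected and scoring models
fitted, and every cohort is evaluated with the trained models. Evaluation
rows with an empty class are preserved as N/A rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import qc_sample_summary, rank_aptamers, select_top_k, zero_profile
from .counts import CountMatrix, PrimerConfig, build_count_matrix, parse_pool_reads, read_count_table
from .differential import (
    Contrast,
    PanelSelectionConfig,
    dichotomize_by_median,
    fit_two_group_ols,
    normalize_log2cpm,
    select_panel,
)
from .families import cluster_families, select_representatives
from .ms import assign_targets, normalize_and_aggregate, read_ms_table
from .samples import SampleMetadata, read_metadata
from .scoring import clinical_scores, evaluate_comparisons, fit_panel_projection, project_scores

log = logging.getLogger("aptapanel")


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    counts_path: str | None = None
    fastq_dir: str | None = None
    metadata_path: str = ""
    ms_table_path: str | None = None
    output_dir: str = "results"
    primers: PrimerConfig | None = None
    selection: PanelSelectionConfig = field(default_factory=PanelSelectionConfig)
    contrasts: dict = field(default_factory=dict)  # name -> definition dict
    panel_contrasts: list = field(default_factory=list)
    evaluation_comparisons: list = field(default_factory=list)
    qc_grouping: list = field(default_factory=lambda: ["group", "sex", "cohort"])
    cohort_roles: dict = field(default_factory=dict)  # cohort -> training|evaluation
    family_min_motif_length: int = 12
    ms_margin: float = 1.0
    ms_floor: float = 0.01
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        training = [c for c, role in self.cohort_roles.items() if role == "training"]
        if len(training) != 1:
            raise ValueError(
                f"exactly one training cohort required, got {training or 'none'}"
            )
        self.training_cohort = training[0]
        if self.counts_path is None and self.fastq_dir is None:
            raise ValueError("either counts_path or fastq_dir must be set")
        for name in self.panel_contrasts + [
            c for c in self.evaluation_comparisons
        ]:
            if name not in self.contrasts:
                raise ValueError(f"contrast {name!r} not defined")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        primers = None
        if "primers" in raw:
            primers = PrimerConfig(**raw["primers"])
        selection = PanelSelectionConfig(**raw.get("selection", {}))
        return cls(
            counts_path=raw.get("counts"),
            fastq_dir=raw.get("fastq_dir"),
            metadata_path=raw["metadata"],
            ms_table_path=raw.get("ms_table"),
            output_dir=raw.get("output_dir", "results"),
            primers=primers,
            selection=selection,
            contrasts=raw.get("contrasts", {}),
            panel_contrasts=raw.get("panel_contrasts", []),
            evaluation_comparisons=raw.get("evaluation_comparisons", []),
            qc_grouping=raw.get("qc_grouping", ["group", "sex", "cohort"]),
            cohort_roles=raw.get("cohort_roles", {}),
            family_min_motif_length=raw.get("family_min_motif_length", 12),
            ms_margin=raw.get("ms_margin", 1.0),
            ms_floor=raw.get("ms_floor", 0.01),
            seed=raw.get("seed", 0),
            raw=raw,
        )


def resolve_contrast(
    name: str, definition: dict, training_metadata: list[SampleMetadata]
) -> Contrast:
    """Turn a config contrast definition into a Contrast.

    ``kind: median`` contrasts are dichotomised at the training-cohort
    median so the cut is fixed once and reused everywhere.
    """
    kind = definition.get("kind", "categorical")
    if kind == "median":
        return dichotomize_by_median(training_metadata, definition["variable"], name=name)
    return Contrast(
        name=name,
        variable=definition["variable"],
        level_a=str(definition["level_a"]),
        level_b=str(definition["level_b"]),
        kind=kind,
        threshold=definition.get("threshold"),
    )


def _load_counts(config: PipelineConfig) -> CountMatrix:
    if config.counts_path:
        return read_count_table(config.counts_path)
    fastq_dir = Path(config.fastq_dir)
    if config.primers is None:
        raise ValueError("fastq input requires a primers section")
    per_sample = {}
    for path in sorted(fastq_dir.glob("*.fastq")):
        regions, report = parse_pool_reads(path, config.primers)
        per_sample[path.stem] = regions
        log.info(
            "counted %s: %d reads, %d retained (no_5p=%d no_3p=%d bad_length=%d)",
            path.name, report.total, report.retained,
            report.no_5p, report.no_3p, report.bad_length,
        )
    if not per_sample:
        raise ValueError(f"no FASTQ files found in {fastq_dir}")
    return build_count_matrix(per_sample)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns a dict of the in-memory results (panels, models, tables);
    writes ranking, QC, per-contrast volcano/panel/score tables, the
    cross-cohort evaluation table, families, MS targets and a JSON run
    manifest under ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _load_counts(config)
    metadata = read_metadata(config.metadata_path)
    meta_by_cohort: dict[str, list[SampleMetadata]] = {}
    for s in metadata:
        meta_by_cohort.setdefault(s.cohort, []).append(s)
    for cohort in config.cohort_roles:
        if cohort not in meta_by_cohort:
            raise ValueError(f"cohort {cohort!r} not present in metadata")
    train_meta = meta_by_cohort[config.training_cohort]
    log.info("stage counts: %d samples x %d aptamers", *matrix.counts.shape)

    ranking = rank_aptamers(matrix)
    profile, suggested = zero_profile(matrix, ranking)
    qc = qc_sample_summary(matrix, metadata, config.qc_grouping)
    k = min(config.selection.top_k, matrix.counts.shape[1])
    filtered = select_top_k(matrix, ranking, k)
    log.info("stage filter: top %d of %d aptamers (knee suggestion: %d)",
             k, matrix.counts.shape[1], suggested)

    abundance = normalize_log2cpm(filtered, config.selection.pseudocount)
    train_ids = [s.sample_id for s in train_meta if s.sample_id in abundance.index]
    contrasts = {
        name: resolve_contrast(name, definition, train_meta)
        for name, definition in config.contrasts.items()
    }

    panels, models, score_tables = {}, {}, {}
    for name in config.panel_contrasts:
        contrast = contrasts[name]
        results = fit_two_group_ols(abundance.loc[train_ids], train_meta, contrast)
        panel = select_panel(results, contrast, config.selection)
        panels[name] = panel
        log.info("stage panel %s: %d members (%d up, %d down)",
                 name, len(panel.members), panel.n_up, panel.n_down)
        if panel.members:
            mask_a, mask_b = contrast.masks(train_meta)
            labels = pd.Series(
                {s: 1.0 for s in train_ids if mask_b.get(s, False)}
                | {s: 0.0 for s in train_ids if mask_a.get(s, False)}
            )
            model = fit_panel_projection(
                abundance, panel.members, labels, contrast_name=name
            )
            models[name] = model
            score_tables[name] = project_scores(model, abundance)

    comparators = clinical_scores(metadata)
    cohorts = {
        cohort: (abundance.loc[[s.sample_id for s in members
                                if s.sample_id in abundance.index]], members)
        for cohort, members in meta_by_cohort.items()
        if cohort in config.cohort_roles
    }
    evaluations = []
    comparisons = [contrasts[n] for n in config.evaluation_comparisons]
    for name, model in models.items():
        table = evaluate_comparisons(
            model, cohorts, comparisons,
            score_columns={
                "fib4": comparators["fib4"],
                "ast_alt_ratio": comparators["ast_alt_ratio"],
            },
        )
        table.insert(0, "panel", name)
        evaluations.append(table)
    evaluation = (
        pd.concat(evaluations, ignore_index=True) if evaluations else pd.DataFrame()
    )

    panel_union = sorted({m for p in panels.values() for m in p.members})
    families, representatives, targets = [], {}, pd.DataFrame()
    if panel_union and filtered.sequences:
        seqs = {a: filtered.sequences[a] for a in panel_union}
        families = cluster_families(seqs, config.family_min_motif_length)
        representatives = select_representatives(families, filtered, seqs)
        log.info("stage families: %d families over %d panel aptamers",
                 len(families), len(panel_union))
    if config.ms_table_path:
        ms_table = read_ms_table(config.ms_table_path)
        ms_profile = normalize_and_aggregate(ms_table, config.ms_floor)
        ability = {
            m: name for name, p in panels.items() for m in p.members
        }
        targets = assign_targets(ms_profile, config.ms_margin, ability)
        log.info("stage ms: %d aptamers assigned targets", len(targets))

    # --- write the bundle -------------------------------------------------
    ranking.table.to_csv(out / "ranking.tsv", sep="\t")
    profile.to_csv(out / "zero_profile.tsv", sep="\t", index=False)
    qc.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
    for name, panel in panels.items():
        panel.table.to_csv(out / f"panel_{name}.tsv", sep="\t")
        panel.volcano_table().to_csv(out / f"volcano_{name}.tsv", sep="\t")
    for name, scores in score_tables.items():
        scores.to_frame().to_csv(out / f"scores_{name}.tsv", sep="\t")
    if len(evaluation):
        evaluation.to_csv(out / "evaluation.tsv", sep="\t", index=False)
    if families:
        pd.DataFrame(
            [
                {
                    "family_id": f.family_id,
                    "n_members": len(f.members),
                    "members": ",".join(f.members),
                    "motif": f.motif,
                    "representative": f.representative,
                }
                for f in families
            ]
        ).to_csv(out / "families.tsv", sep="\t", index=False)
    if len(targets):
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "aptapanel_version": __version__,
        "n_samples": int(matrix.counts.shape[0]),
        "n_aptamers_total": int(matrix.counts.shape[1]),
        "n_aptamers_filtered": int(k),
        "zero_knee_suggestion": int(suggested),
        "panel_sizes": {name: len(p.members) for name, p in panels.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "matrix": matrix,
        "filtered": filtered,
        "abundance": abundance,
        "ranking": ranking,
        "qc": qc,
        "contrasts": contrasts,
        "panels": panels,
        "models": models,
        "scores": score_tables,
        "evaluation": evaluation,
        "families": families,
        "representatives": representatives,
        "targets": targets,
        "manifest": manifest,
    }
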