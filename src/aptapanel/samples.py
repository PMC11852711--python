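"""Sample-level clinical metadata: grouping labels, validation and TSV I/O.

Each plasma sample carries a steatohepatitis group (healthy, MASLD without
steatohepatitis, or MASH), a Kleiner fibrosis stage 0-4, and the clinical
covariates used for comparator scores (FIB-4, AST/ALT) and for median
dichotomisation contrasts (LDL, sCD163). The coarse fibrosis group
(F0 / F1_2 / F3_4) is always derived from the stage, never stored
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("healthy", "MASLD_no_SH", "MASH")
FIBROSIS_GROUPS = ("F0", "F1_2", "F3_4")

#: metadata TSV columns, in canonical order
METADATA_COLUMNS = [
    "sample_id",
    "cohort",
    "group",
    "fibrosis_stage",
    "fibrosis_group",
    "sex",
    "age",
    "bmi",
    "ldl",
    "scd163",
    "ast",
    "alt",
    "platelets",
    "metabolic_syndrome",
    "library_size",
]

_NUMERIC_FIELDS = ("age", "bmi", "ldl", "scd163", "ast", "alt", "platelets")


def fibrosis_group(stage: int) -> str:
    """Map a Kleiner fibrosis stage to its coarse group.

    0 -> F0; 1, 2 -> F1_2; 3, 4 -> F3_4.
    """
    stage = int(stage)
    if stage == 0:
        return "F0"
    if stage in (1, 2):
        return "F1_2"
    if stage in (3, 4):
        return "F3_4"
    raise ValueError(f"fibrosis stage must be in 0..4, got {stage}")


@dataclass
class SampleMetadata:
    """Clinical and grouping labels for one sample.

    Missing clinical values are ``None`` (encoded ``NA`` on disk); the
    positivity constraints (AST, ALT, platelets > 0) apply only to
    non-missing values.
    """

    sample_id: str
    cohort: str
    group: str
    fibrosis_stage: int
    sex: str = "NA"
    age: float | None = None
    bmi: float | None = None
    ldl: float | None = None
    scd163: float | None = None
    ast: float | None = None
    alt: float | None = None
    platelets: float | None = None
    metabolic_syndrome: bool | None = None
    library_size: int = 0
    fibrosis_group: str = field(init=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        self.fibrosis_group = fibrosis_group(self.fibrosis_stage)
        for name in ("ast", "alt", "platelets"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be > 0, got {value}"
                )
        if self.library_size < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative library_size")


def metadata_frame(samples: list[SampleMetadata]) -> pd.DataFrame:
    """Tabulate samples as a DataFrame in canonical column order."""
    rows = []
    for s in samples:
        row = {f.name: getattr(s, f.name) for f in fields(s)}
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[METADATA_COLUMNS]


def _parse_cell(name: str, raw: object):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in ("", "NA", "NaN", "nan"):
        return None
    if name in _NUMERIC_FIELDS:
        return float(text)
    if name == "metabolic_syndrome":
        return text.lower() in ("1", "true", "yes")
    if name in ("fibrosis_stage",):
        return int(text)
    if name == "library_size":
        return int(float(text))
    return text


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a metadata TSV, validating labels and deriving fibrosis groups.

    Group labels are whitespace-stripped before validation; ``NA`` cells
    become missing values. Raises ``ValueError`` naming the offending
    sample on an unknown group or out-of-range stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort", "group", "fibrosis_stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        kwargs = {}
        for name in METADATA_COLUMNS:
            if name in ("sample_id", "fibrosis_group"):
                continue
            if name not in df.columns:
                continue
            value = _parse_cell(name, row[name])
            if value is not None:
                kwargs[name] = value
        stage = kwargs.get("fibrosis_stage")
        if stage is None or not 0 <= stage <= 4:
            raise ValueError(f"sample {sid!r}: fibrosis stage out of range 0..4")
        try:
            samples.append(SampleMetadata(sample_id=sid, **kwargs))
        except ValueError:
            raise
    if not samples:
        raise ValueError(f"metadata file {path}: no samples")
    return samples


def write_metadata(samples: list[SampleMetadata], path: str | Path) -> None:
    df = metadata_frame(samples)
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(lambda v: "NA" if v is None else v)
    out.to_csv(path, sep="\t", index=False)
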