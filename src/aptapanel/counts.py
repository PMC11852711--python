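"""Read counting and the samples x aptamers count matrix.

Pool reads are sequenced as constant 5' primer + variable region + constant
3' primer. Counting collapses reads to unique variable-region sequences:
the per-sample multiplicity of a sequence is the abundance signal the rest
of the pipeline works on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class PrimerConfig:
    """Constant-flank layout of a pool read.

    ``max_mismatches`` is a per-flank Hamming budget (default 0: exact
    prefix/suffix match). Reads whose trimmed region length deviates from
    ``expected_length`` by more than ``length_tolerance`` are discarded.
    """

    primer_5p: str
    primer_3p: str
    max_mismatches: int = 0
    expected_length: int | None = None
    length_tolerance: int = 0

    def __post_init__(self) -> None:
        self.primer_5p = _normalize_seq(self.primer_5p)
        self.primer_3p = _normalize_seq(self.primer_3p)
        if not self.primer_5p or not self.primer_3p:
            raise ValueError("primers must be non-empty")
        if self.max_mismatches < 0 or self.length_tolerance < 0:
            raise ValueError("mismatch budget and length tolerance must be >= 0")


@dataclass
class ParseReport:
    """Per-file accounting of retained and discarded reads."""

    total: int = 0
    retained: int = 0
    no_5p: int = 0
    no_3p: int = 0
    bad_length: int = 0


@dataclass
class CountMatrix:
    """Samples x aptamers integer count matrix.

    ``counts`` is a DataFrame indexed by sample_id with aptamer_id columns;
    ``sequences`` optionally maps aptamer_id -> variable-region sequence.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate aptamer_ids")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def aptamer_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sequence_counts(self) -> pd.DataFrame:
        """Counts re-keyed by sequence (requires ``sequences``)."""
        if self.sequences is None:
            raise ValueError("no sequences attached")
        return self.counts.rename(columns=self.sequences)


def _normalize_seq(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def _hamming_le(a: str, b: str, budget: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def parse_pool_reads(
    fastq_path: str | Path, primers: PrimerConfig
) -> tuple[Counter, ParseReport]:
    """Trim pool reads to their variable region and tally unique sequences.

    A read is retained when both constant flanks match within the mismatch
    budget and the enclosed region length is within tolerance of the
    expected length; everything else is counted in the report under its
    discard reason (no_5p, no_3p, bad_length).
    """
    path = Path(fastq_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTQ file not found: {path}")
    report = ParseReport()
    regions: Counter = Counter()
    n5, n3 = len(primers.primer_5p), len(primers.primer_3p)
    with open(path) as handle:
        try:
            records = FastqGeneralIterator(handle)
            for title, seq, _qual in records:
                report.total += 1
                seq = _normalize_seq(seq)
                if not _hamming_le(seq[:n5], primers.primer_5p, primers.max_mismatches):
                    report.no_5p += 1
                    continue
                if len(seq) < n5 + n3 or not _hamming_le(
                    seq[-n3:], primers.primer_3p, primers.max_mismatches
                ):
                    report.no_3p += 1
                    continue
                region = seq[n5 : len(seq) - n3]
                if primers.expected_length is not None and (
                    abs(len(region) - primers.expected_length)
                    > primers.length_tolerance
                ):
                    report.bad_length += 1
                    continue
                regions[region] += 1
                report.retained += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record near record {report.total + 1} "
                f"in {path}: {exc}"
            ) from exc
    return regions, report


def build_count_matrix(per_sample: dict[str, Counter]) -> CountMatrix:
    """Assemble the count matrix from per-sample sequence multisets.

    One column per distinct sequence observed anywhere; a sequence absent
    from a sample counts 0 there. Aptamer IDs are assigned as ``apt_<rank>``
    by descending total count across all samples, ties broken
    lexicographically by sequence, so the labelling is deterministic.
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    df = pd.DataFrame(
        {sid: pd.Series(dict(counter), dtype=np.int64) for sid, counter in per_sample.items()}
    ).T.fillna(0).astype(np.int64)
    df.index.name = "sample_id"
    if df.shape[1] == 0:
        return CountMatrix(counts=df, sequences={})
    totals = df.sum(axis=0)
    order = sorted(df.columns, key=lambda s: (-totals[s], s))
    df = df[order]
    ids = [f"apt_{i + 1}" for i in range(len(order))]
    sequences = dict(zip(ids, order))
    df.columns = ids
    return CountMatrix(counts=df, sequences=sequences)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a count TSV (first column sample_id, header of aptamer_ids).

    Validates integrality of every cell and uniqueness of ids; errors name
    the offending cell coordinates. ``write_count_table`` then
    ``read_count_table`` is the identity on valid matrices.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup_cols = {c for c in header[1:] if header[1:].count(c) > 1}
    if dup_cols:
        raise ValueError(f"{path}: duplicate aptamer_id {sorted(dup_cols)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate aptamer_id {dup!r}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (sid, raw) in enumerate(df[col].items()):
            try:
                as_float = float(raw)
                as_int = int(as_float)
                if as_int != as_float:
                    raise ValueError
                values[i, j] = as_int
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {raw!r} at sample {sid!r}, "
                    f"aptamer {col!r}"
                ) from None
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    counts.index.name = "sample_id"
    return CountMatrix(counts=counts)
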