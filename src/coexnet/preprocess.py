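"""Depth normalization, low-abundance filtering and matrix assembly.

Each marker's table is processed on its own (the sequencing runs differ in
depth, and normalization exists precisely to make them comparable) and the
normalized, filtered tables are then row-stacked together with the soil
variables into one analysis matrix whose rows enter the rank-correlation
stage on an equal footing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CountTable, SampleFrame, ValidationError

__all__ = [
    "AnalysisMatrix",
    "expected_depth",
    "normalize",
    "filter_low_abundance",
    "assemble",
]


@dataclass
class AnalysisMatrix:
    """Rows = OTUs (all markers) then environmental variables; columns = samples.

    ``row_kind[i]`` is ``"otu"`` or ``"env"``.  OTU rows are non-negative
    normalized abundances; env rows are unrestricted reals that enter the
    correlation through ranks only.
    """

    row_ids: list[str]
    row_kind: np.ndarray
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.row_kind = np.asarray(self.row_kind, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.row_ids) != len(set(self.row_ids)):
            dup = next(i for i in self.row_ids if self.row_ids.count(i) > 1)
            raise ValidationError(f"duplicate analysis row id: {dup!r}")
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError("analysis matrix shape mismatch")
        otu = self.row_kind == "otu"
        if np.any(self.values[otu] < 0):
            raise ValidationError("negative value in an OTU row")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def otu_rows(self) -> np.ndarray:
        return np.flatnonzero(self.row_kind == "otu")

    def env_rows(self) -> np.ndarray:
        return np.flatnonzero(self.row_kind == "env")


def expected_depth(table: CountTable, factor: float = 0.5) -> float:
    """Expected sequencing depth of a run: ``factor`` x median per-sample total.

    The default factor of one half matches the pipeline's default depth target.
    """
    sums = table.sample_sums()
    if not np.any(sums > 0):
        raise ValidationError(f"table {table.marker_id!r} is all zero")
    return float(factor * np.median(sums))


def normalize(table: CountTable, depth: float) -> CountTable:
    """Scale every sample column so its read sum equals ``depth``.

    All-zero columns cannot be rescaled; they are left zero and flagged with
    a warning.
    """
    if depth <= 0:
        raise ValidationError(f"depth must be positive, got {depth!r}")
    sums = table.sample_sums()
    zero = sums == 0
    if zero.any():
        names = [s for s, z in zip(table.sample_ids, zero) if z]
        warnings.warn(
            f"marker {table.marker_id!r}: all-zero samples left unscaled: {names}"
        )
    scale = np.divide(depth, sums, out=np.zeros_like(sums, dtype=float), where=~zero)
    return CountTable(
        table.marker_id, list(table.otu_ids), list(table.sample_ids),
        table.counts * scale[np.newaxis, :],
    )


def filter_low_abundance(table: CountTable, fraction: float = 0.10) -> CountTable:
    """Keep OTUs whose total abundance exceeds ``fraction`` x median OTU total.

    Applied after normalization; discards low-abundance OTUs (including
    singletons).  Idempotent on its own output at the same fraction.
    """
    totals = table.otu_totals()
    if totals.size == 0:
        return table
    threshold = fraction * float(np.median(totals))
    keep = totals > threshold
    if not keep.any():
        warnings.warn(f"marker {table.marker_id!r}: no OTU passes the abundance filter")
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    return CountTable(table.marker_id, kept, list(table.sample_ids),
                      table.counts[keep, :])


def assemble(
    tables: list[CountTable],
    frame: SampleFrame,
    env_vars: list[str] | None = None,
) -> AnalysisMatrix:
    """Row-stack normalized, filtered marker tables and append env-variable rows.

    Samples are the intersection of the markers' sample sets and the sample
    frame, kept in the frame's order; samples missing from any marker are
    excluded with a warning.  OTU ids are prefixed ``<marker>:`` only if they
    are not already unique across tables.
    """
    if not tables:
        raise ValidationError("no count tables to assemble")
    shared = [s for s in frame.sample_ids
              if all(s in t.sample_ids for t in tables)]
    dropped = sorted(
        set(frame.sample_ids).union(*(t.sample_ids for t in tables)) - set(shared)
    )
    if dropped:
        warnings.warn(f"samples absent from some input and excluded: {dropped}")
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} samples shared across inputs; "
            "rank correlation needs at least 3"
        )

    all_ids = [o for t in tables for o in t.otu_ids]
    prefix = len(all_ids) != len(set(all_ids))
    row_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for t in tables:
        sub = t.select_samples(shared)
        row_ids.extend(f"{t.marker_id}:{o}" if prefix else o for o in sub.otu_ids)
        blocks.append(sub.counts)
    kinds = ["otu"] * len(row_ids)

    env = frame.env_matrix(env_vars)
    env = env[shared]
    for var in env.index:
        vals = env.loc[var].to_numpy(dtype=float)
        if np.isnan(vals).any():
            warnings.warn(f"soil variable {var!r} has missing values; dropped")
            continue
        row_ids.append(str(var))
        kinds.append("env")
        blocks.append(vals[np.newaxis, :])

    values = np.vstack(blocks) if blocks else np.empty((0, len(shared)))
    return AnalysisMatrix(row_ids, np.array(kinds, dtype=object), values, shared)
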