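"""Cohort expression matrices and per-sample min–max normalization.

The method treats normalized mRNA abundance as a surrogate for protein
concentration: within each sample, expression is rescaled so the most
down-regulated gene sits at 0 and the most up-regulated at 1.  Normalization
is strictly per-sample across genes (a within-patient rescale), never
per-gene across the cohort.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_io import PPINetwork

logger = logging.getLogger(__name__)


class ExpressionFormatError(ValueError):
    """Raised when an expression matrix file violates its contract."""


class CoverageError(ValueError):
    """Raised when a profile shares no genes with the network."""


@dataclass
class ExpressionMatrix:
    """Raw cohort expression: genes in rows, samples in columns.

    Values are non-negative reals; missing cells are NaN.
    """

    values: pd.DataFrame  # index = genes, columns = samples, float64

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self) -> str:
        out = self.values.copy()
        out.index.name = "gene"
        return out.to_csv(sep="\t", na_rep="NA")


@dataclass
class ExpressionProfile:
    """One sample's normalized concentrations c_i in [0, 1].

    Genes missing in the raw sample are absent from ``c`` (they are never
    imputed, and downstream they are ineligible as anchor or partner).
    """

    sample_id: str
    c: dict[str, float] = field(default_factory=dict)


@dataclass
class AlignmentReport:
    """Overlap between a profile's genes and a network's nodes."""

    covered_nodes: set[str]
    coverage: float  # covered / total network nodes
    unmatched_genes: int  # profile genes absent from the network


def read_expression(text: str, delimiter: str | None = None) -> ExpressionMatrix:
    """Parse a TSV/CSV expression matrix (genes x samples).

    First row holds sample identifiers, first column gene identifiers.
    Empty cells and the token ``NA`` are recorded as missing.  The delimiter
    is auto-detected from the header unless given.

    Raises
    ------
    ExpressionFormatError
        On ragged rows (with the row number), duplicate gene identifiers
        (listing them), duplicate sample identifiers, or negative values.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ExpressionFormatError("empty expression file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","

    rows = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delimiter))
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ExpressionFormatError(
                f"ragged row {i}: expected {width} fields, got {len(row)}"
            )

    df = pd.read_csv(
        io.StringIO(text),
        sep=delimiter,
        index_col=0,
        na_values=["NA", ""],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ExpressionFormatError(f"duplicate gene identifiers: {', '.join(dup_genes)}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ExpressionFormatError(f"duplicate sample identifiers: {', '.join(dup_samples)}")

    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ExpressionFormatError(f"non-numeric expression value: {exc}") from exc
    if (values < 0).any().any():
        bad = values.min().min()
        raise ExpressionFormatError(f"negative expression value present (min = {bad})")
    return ExpressionMatrix(values=values)


def normalize_sample(
    matrix: ExpressionMatrix,
    sample_id: str,
    log_transform: bool = False,
) -> ExpressionProfile:
    """Min–max rescale one sample's non-missing values to [0, 1].

    c_g = (x_g − min) / (max − min); the minimum maps to 0 and the maximum
    to 1.  Missing genes stay absent from the profile.  With
    ``log_transform``, a log2(x + 1) transform precedes the rescale (the
    result is identical for rank-based questions but changes the spacing).

    A constant-valued sample (max == min) has no scale; every gene is set to
    0.5 and a degenerate-input warning is logged.

    Raises
    ------
    KeyError
        If the sample is not in the matrix.
    ValueError
        If every value in the sample is missing.
    """
    if sample_id not in matrix.values.columns:
        raise KeyError(f"unknown sample: {sample_id!r}")
    col = matrix.values[sample_id].dropna()
    if col.empty:
        raise ValueError(f"sample {sample_id!r} has no non-missing values")
    x = col.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        logger.warning(
            "normalize_sample(%s): constant sample, all genes set to 0.5", sample_id
        )
        c = np.full_like(x, 0.5)
    else:
        c = (x - lo) / (hi - lo)
    return ExpressionProfile(sample_id=sample_id, c=dict(zip(col.index, c.tolist())))


def align_to_network(profile: ExpressionProfile, network: PPINetwork) -> AlignmentReport:
    """Report the overlap between a profile and a network.

    Raises
    ------
    CoverageError
        If no network node has a value in the profile (scoring impossible).
    """
    nodes = network.nodes
    covered = nodes & profile.c.keys()
    coverage = len(covered) / len(nodes) if nodes else 0.0
    unmatched = len(profile.c.keys() - nodes)
    logger.info(
        "align_to_network(%s): %d/%d nodes covered (%.1f%%), %d profile gene(s) unmatched",
        profile.sample_id, len(covered), len(nodes), 100 * coverage, unmatched,
    )
    if not covered:
        raise CoverageError(
            f"sample {profile.sample_id!r} shares no genes with the network"
        )
    return AlignmentReport(covered_nodes=covered, coverage=coverage, unmatched_genes=unmatched)
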