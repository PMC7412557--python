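"""Core in-memory containers shared by every pipeline stage.

All tabular data lives in pandas objects; the thin dataclass wrappers exist
to attach validation (unique identifiers, finite values, design/matrix
agreement) and a little domain vocabulary on top of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "ParseError",
    "PipelineError",
    "ExpressionMatrix",
    "SampleDesign",
    "GeneAnnotation",
    "MetaboliteTable",
]


class ConfigError(ValueError):
    """Invalid configuration or invalid parameter combination."""


class ParseError(ValueError):
    """A table on disk violated the expected format."""


class PipelineError(RuntimeError):
    """A pipeline stage could not produce a usable result."""


COUNTS = "counts"
LOG2NORM = "log2norm"


def _check_unique(values: pd.Index, what: str) -> None:
    if values.has_duplicates:
        dupes = values[values.duplicated()].unique().tolist()[:5]
        raise ParseError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    ``scale`` is either ``"counts"`` (non-negative raw counts) or
    ``"log2norm"`` (normalized log2 values); every downstream operation
    checks the tag it requires instead of guessing.
    """

    data: pd.DataFrame
    scale: str = COUNTS

    def __post_init__(self) -> None:
        if self.scale not in (COUNTS, LOG2NORM):
            raise ConfigError(f"unknown expression scale {self.scale!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ParseError("expression matrix contains non-finite values")
        if self.scale == COUNTS and (values < 0).any():
            raise ParseError("count matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SampleDesign:
    """Sample -> (treatment, timepoint, replicate) map for a factorial design.

    Exactly one treatment level is the uninfested control; contrasts are
    always infested-vs-control at a shared timepoint.
    """

    table: pd.DataFrame
    control: str = "control"

    def __post_init__(self) -> None:
        required = {"treatment", "timepoint", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"design table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        if self.control not in set(self.table["treatment"]):
            raise ConfigError(
                f"control treatment {self.control!r} absent from design"
            )

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def treatments(self) -> list[str]:
        seen: list[str] = []
        for t in self.table["treatment"]:
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def infested(self) -> list[str]:
        return [t for t in self.treatments if t != self.control]

    @property
    def timepoints(self) -> list[int]:
        return sorted(set(int(t) for t in self.table["timepoint"]))

    def samples_for(self, treatment: str, timepoint: int) -> list[str]:
        mask = (self.table["treatment"] == treatment) & (
            self.table["timepoint"] == timepoint
        )
        return list(self.table.index[mask])

    def cells(self) -> Iterator[tuple[str, int]]:
        """All (treatment, timepoint) cells in design order."""
        for treatment in self.treatments:
            for timepoint in self.timepoints:
                yield treatment, timepoint

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.samples) - set(self.samples)
        if missing:
            raise ParseError(
                f"samples missing from design: {sorted(missing)[:5]}"
            )


@dataclass
class GeneAnnotation:
    """Gene annotation: transcription-factor status and pathway memberships.

    ``table`` is indexed by gene with boolean ``is_tf`` and string
    ``tf_family`` (empty for non-TFs); ``pathways`` maps each pathway id to
    its member gene set.
    """

    table: pd.DataFrame
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"is_tf", "tf_family"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"annotation table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "gene")
        bad = self.table.loc[~self.table["is_tf"], "tf_family"]
        if (bad.astype(str) != "").any():
            raise ParseError("tf_family set on a gene with is_tf false")
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def tf_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"]])

    def family_of(self, gene: str) -> str:
        return str(self.table.at[gene, "tf_family"])

    def pathways_of(self, gene: str) -> set[str]:
        return {p for p, members in self.pathways.items() if gene in members}


@dataclass
class MetaboliteTable:
    """Metabolites x samples abundance table plus metabolite -> pathway map."""

    data: pd.DataFrame
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "metabolite")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ParseError("metabolite table contains non-finite values")
        if (values <= 0).any():
            raise ParseError("metabolite abundances must be positive")
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}

    @property
    def metabolites(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns
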