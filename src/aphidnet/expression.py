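"""Count normalization, expressed-gene filtering, and differential expression.

The differential-expression stage is a deliberately simple, calibrated
stand-in for a full negative-binomial model: median-of-ratios size factors,
a log2 transform, and a per-contrast Welch t-test with Benjamini-Hochberg
adjustment.  It implements the study thresholds (FDR < 0.05 and fold change
> 2 against the control at the same timepoint) behind a stable interface so
the test can be swapped without touching the network machinery.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    ConfigError,
    ExpressionMatrix,
    PipelineError,
    SampleDesign,
)

__all__ = [
    "size_factors",
    "normalize",
    "filter_expressed",
    "call_degs",
    "UP_INFESTED",
    "UP_CONTROL",
]

logger = logging.getLogger(__name__)

UP_INFESTED = "up_in_infested"
UP_CONTROL = "up_in_control"

DEG_COLUMNS = [
    "gene",
    "treatment",
    "timepoint",
    "log2fc",
    "pvalue",
    "fdr",
    "is_deg",
    "direction",
]


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference profile is the per-gene geometric mean over samples,
    restricted to genes with strictly positive counts everywhere; each
    sample's factor is the median ratio of its counts to the reference.
    Falls back to (rescaled) total-count factors when no gene is positive
    in every sample.
    """
    values = counts.data.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        logref = np.log(values[all_positive]).mean(axis=1)
        ratios = values[all_positive] / np.exp(logref)[:, None]
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene with all-positive counts; using total-count size factors"
        )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise PipelineError("a sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(count / size_factor + 1) normalization of a count matrix."""
    if counts.scale != "counts":
        raise ConfigError("normalize expects a raw count matrix")
    factors = size_factors(counts)
    normed = np.log2(counts.data / factors + 1.0)
    return ExpressionMatrix(data=normed, scale="log2norm")


def filter_expressed(norm: ExpressionMatrix, min_mean: float = 1.0) -> pd.Index:
    """Genes whose mean normalized value reaches ``min_mean`` log2 units.

    This set is the network universe and the background of every
    enrichment and occupancy computation downstream.
    """
    if norm.scale != "log2norm":
        raise ConfigError("filter_expressed expects a normalized matrix")
    keep = norm.data.mean(axis=1) >= min_mean
    if not keep.any():
        raise PipelineError("no gene passes the expression filter")
    return norm.genes[keep]


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with degenerate rows handled.

    Rows where both groups are constant get p = 1 when the means agree and
    p = 0 otherwise (an infinitely confident difference under the model).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvalues = np.asarray(result.pvalue, dtype=float)
    degenerate = np.isnan(pvalues)
    if degenerate.any():
        equal = np.isclose(a[degenerate].mean(axis=1), b[degenerate].mean(axis=1))
        pvalues[degenerate] = np.where(equal, 1.0, 0.0)
    return pvalues


def call_degs(
    norm: ExpressionMatrix,
    design: SampleDesign,
    fdr_alpha: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-contrast differential expression against same-timepoint controls.

    For every (infested treatment, timepoint) cell: Welch two-sample t-test
    on normalized values versus control, Benjamini-Hochberg across genes
    within the contrast, and the strict study thresholds
    ``fdr < fdr_alpha`` and ``|fold change| > min_fold``.
    """
    if norm.scale != "log2norm":
        raise ConfigError("call_degs expects a normalized matrix")
    if not 0 < fdr_alpha <= 1:
        raise ConfigError("fdr_alpha must be in (0, 1]")
    if min_fold < 1:
        raise ConfigError("min_fold must be >= 1")
    design.check_matches(norm)

    min_log2_fold = math.log2(min_fold)
    frames: list[pd.DataFrame] = []
    for treatment in design.infested:
        for timepoint in design.timepoints:
            group = [
                s for s in design.samples_for(treatment, timepoint)
                if s in norm.samples
            ]
            control = [
                s for s in design.samples_for(design.control, timepoint)
                if s in norm.samples
            ]
            if len(group) < 2 or len(control) < 2:
                logger.warning(
                    "skipping contrast %s vs %s at %s DAI: fewer than 2 replicates",
                    treatment, design.control, timepoint,
                )
                continue
            a = norm.data[group].to_numpy()
            b = norm.data[control].to_numpy()
            log2fc = a.mean(axis=1) - b.mean(axis=1)
            pvalues = _welch(a, b)
            fdr = multipletests(pvalues, method="fdr_bh")[1]
            is_deg = (fdr < fdr_alpha) & (np.abs(log2fc) > min_log2_fold)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": norm.genes,
                        "treatment": treatment,
                        "timepoint": timepoint,
                        "log2fc": log2fc,
                        "pvalue": pvalues,
                        "fdr": fdr,
                        "is_deg": is_deg,
                        "direction": np.where(log2fc >= 0, UP_INFESTED, UP_CONTROL),
                    }
                )
            )
    if not frames:
        raise PipelineError("no contrast had enough replicates")
    return pd.concat(frames, ignore_index=True)[DEG_COLUMNS]
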