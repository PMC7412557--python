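"""Pathway enrichment, metabolite differential abundance, and occupancy.

Enrichment of a gene set (a module or a TF subnetwork) in a pathway is the
one-sided Fisher's exact (hypergeometric right-tail) test against the
expressed-gene network background; significance is flagged on the raw
p-value at 0.05, with Benjamini-Hochberg adjusted p-values reported
alongside.  Metabolite differential abundance is a per-timepoint one-way
ANOVA across treatments on log abundances, followed by Tukey HSD contrasts
of each aphid treatment against control when the ANOVA is significant.
Pathway occupancy is the percentage of a pathway's expressed genes (or
detected metabolites) that are differential in a given contrast and
direction.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigError, MetaboliteTable, SampleDesign
from .expression import UP_CONTROL, UP_INFESTED

__all__ = [
    "fisher_enrichment",
    "metabolite_da",
    "transcript_occupancy",
    "metabolite_occupancy",
]

ENRICHMENT_COLUMNS = [
    "pathway", "k", "n", "K", "N", "odds_ratio", "p", "p_bh", "significant",
]
DA_COLUMNS = [
    "metabolite", "timepoint", "f_stat", "anova_p", "treatment", "tukey_p",
    "direction", "significant",
]
OCCUPANCY_COLUMNS = [
    "pathway", "treatment", "timepoint", "direction",
    "numerator", "denominator", "percent",
]


def fisher_enrichment(
    unit_genes: Iterable[str],
    background: Iterable[str],
    pathways: Mapping[str, frozenset[str] | set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Right-tail hypergeometric enrichment of a gene set per pathway.

    ``unit_genes`` must be a subset of ``background`` (the expressed network
    genes).  Pathways with no background member are skipped.  The
    significance flag uses the raw p-value at ``alpha``; BH-adjusted
    p-values across the unit's pathways are reported alongside.
    """
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    background_set = set(background)
    unit = set(unit_genes)
    if not unit <= background_set:
        raise ConfigError("unit genes must be a subset of the background")
    n = len(unit)
    n_total = len(background_set)
    rows = []
    for pathway in sorted(pathways):
        members = set(pathways[pathway]) & background_set
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(unit & members)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n))
        table_or = _sample_odds_ratio(k, n, big_k, n_total)
        rows.append(
            {
                "pathway": pathway,
                "k": k,
                "n": n,
                "K": big_k,
                "N": n_total,
                "odds_ratio": table_or,
                "p": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-2])
    if len(frame):
        frame["p_bh"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame["significant"] = frame["p"] <= alpha
    else:
        frame["p_bh"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
    return frame[ENRICHMENT_COLUMNS]


def _sample_odds_ratio(k: int, n: int, big_k: int, n_total: int) -> float:
    """Odds ratio of the 2x2 overlap table, inf when a margin cell is 0."""
    a = k
    b = n - k
    c = big_k - k
    d = n_total - n - big_k + k
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def metabolite_da(
    metab: MetaboliteTable,
    design: SampleDesign,
    alpha: float = 0.05,
    tukey_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint ANOVA + Tukey HSD differential abundance vs control.

    Abundances are log-transformed before testing.  A metabolite is
    significant for an (aphid treatment, timepoint) when the across-treatment
    ANOVA p < ``alpha`` and the Tukey HSD comparison against control has
    p <= ``tukey_alpha``; direction follows the sign of the mean difference.
    Constant metabolite/timepoint cells get p = 1.
    """
    design.check_matches(metab)  # type: ignore[arg-type]
    log_data = np.log(metab.data)
    treatments = [design.control] + design.infested
    rows = []
    for timepoint in design.timepoints:
        groups_samples = {
            t: [s for s in design.samples_for(t, timepoint) if s in metab.samples]
            for t in treatments
        }
        if any(len(s) < 2 for s in groups_samples.values()):
            continue
        for metabolite in metab.metabolites:
            groups = [
                log_data.loc[metabolite, groups_samples[t]].to_numpy()
                for t in treatments
            ]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                f_stat, anova_p = float("nan"), 1.0
            else:
                f_stat, anova_p = stats.f_oneway(*groups)
                if not np.isfinite(anova_p):
                    f_stat, anova_p = float("nan"), 1.0
            tukey_p = {t: float("nan") for t in design.infested}
            if anova_p < alpha:
                result = stats.tukey_hsd(*groups)
                for i, treatment in enumerate(design.infested, start=1):
                    tukey_p[treatment] = float(result.pvalue[0, i])
            for treatment in design.infested:
                diff = groups[treatments.index(treatment)].mean() - groups[0].mean()
                significant = (
                    anova_p < alpha
                    and np.isfinite(tukey_p[treatment])
                    and tukey_p[treatment] <= tukey_alpha
                )
                rows.append(
                    {
                        "metabolite": metabolite,
                        "timepoint": timepoint,
                        "f_stat": float(f_stat),
                        "anova_p": float(anova_p),
                        "treatment": treatment,
                        "tukey_p": tukey_p[treatment],
                        "direction": UP_INFESTED if diff >= 0 else UP_CONTROL,
                        "significant": bool(significant),
                    }
                )
    return pd.DataFrame(rows, columns=DA_COLUMNS)


def transcript_occupancy(
    deg_table: pd.DataFrame,
    pathways: Mapping[str, frozenset[str] | set[str]],
    expressed: Iterable[str],
) -> pd.DataFrame:
    """Pathway occupancy of DEGs: % of expressed pathway genes that are
    differential per (treatment, timepoint, direction).

    Pathways without expressed genes are omitted; a gene belonging to
    several pathways counts once in each.
    """
    expressed_set = set(expressed)
    contrasts = (
        deg_table[["treatment", "timepoint"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    contrasts = [(c.treatment, int(c.timepoint)) for c in contrasts]
    degs = deg_table[deg_table["is_deg"]]
    hit_sets: dict[tuple[str, int, str], set[str]] = {}
    for row in degs.itertuples():
        key = (row.treatment, int(row.timepoint), row.direction)
        hit_sets.setdefault(key, set()).add(row.gene)
    rows = []
    for pathway in sorted(pathways):
        members = set(pathways[pathway]) & expressed_set
        if not members:
            continue
        for treatment, timepoint in contrasts:
            for direction in (UP_INFESTED, UP_CONTROL):
                hits = hit_sets.get((treatment, timepoint, direction), set())
                numerator = len(members & hits)
                rows.append(
                    {
                        "pathway": pathway,
                        "treatment": treatment,
                        "timepoint": timepoint,
                        "direction": direction,
                        "numerator": numerator,
                        "denominator": len(members),
                        "percent": 100.0 * numerator / len(members),
                    }
                )
    return pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)


def metabolite_occupancy(
    da_results: pd.DataFrame,
    pathways: Mapping[str, frozenset[str] | set[str]],
) -> pd.DataFrame:
    """Pathway occupancy of differentially abundant metabolites.

    The denominator is the number of detected metabolites (those present in
    the differential-abundance table) in the pathway; pathways with none
    are omitted.
    """
    detected = set(da_results["metabolite"])
    contrasts = (
        da_results[["treatment", "timepoint"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    contrasts = [(c.treatment, int(c.timepoint)) for c in contrasts]
    sig = da_results[da_results["significant"]]
    hit_sets: dict[tuple[str, int, str], set[str]] = {}
    for row in sig.itertuples():
        key = (row.treatment, int(row.timepoint), row.direction)
        hit_sets.setdefault(key, set()).add(row.metabolite)
    rows = []
    for pathway in sorted(pathways):
        members = set(pathways[pathway]) & detected
        if not members:
            continue
        for treatment, timepoint in contrasts:
            for direction in (UP_INFESTED, UP_CONTROL):
                hits = hit_sets.get((treatment, timepoint, direction), set())
                numerator = len(members & hits)
                rows.append(
                    {
                        "pathway": pathway,
                        "treatment": treatment,
                        "timepoint": timepoint,
                        "direction": direction,
                        "numerator": numerator,
                        "denominator": len(members),
                        "percent": 100.0 * numerator / len(members),
                    }
                )
    return pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)
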