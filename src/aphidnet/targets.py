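"""Target transcription-factor selection and TOM subnetwork extraction.

A TF is a *target* of its module when it satisfies three criteria:

1. it lies in the top decile of module membership (kME) within its module;
2. its peak expression (maximum over the treatment x timepoint condition
   means) reaches the 75th percentile of peak expression over all expressed
   genes in the network;
3. it is differentially expressed, in the profile-matched direction, in at
   least one of the contrasts where its module is active.

The module's "active" contrasts and their signs are read off its eigengene:
a (treatment, timepoint) cell is active when the eigengene's deviation from
the same-timepoint control reaches half of the module's maximal deviation.
For each selected TF the subnetwork is the top 1% of that TF's TOM scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix, GeneAnnotation, SampleDesign
from .expression import UP_CONTROL, UP_INFESTED
from .network import ModuleAssignment, NetworkModel

__all__ = [
    "Subnetwork",
    "module_top_kme",
    "peak_expression",
    "module_activity",
    "select_target_tfs",
    "tf_subnetwork",
    "top_module_genes",
    "tf_family_composition",
]

TARGET_TF_COLUMNS = [
    "gene", "module", "kme", "peak_expr", "delta", "c1", "c2", "c3", "selected",
]


def _top_with_ties(scores: pd.Series, count: int) -> pd.Index:
    """The ``count`` highest-scoring items, including boundary ties."""
    if count <= 0 or scores.empty:
        return scores.index[:0]
    count = min(count, len(scores))
    threshold = scores.sort_values(ascending=False).iloc[count - 1]
    return scores.index[scores >= threshold]


def module_top_kme(
    assignment: ModuleAssignment, q: float = 0.10
) -> dict[int, pd.Index]:
    """Per module, the ceil(q * n) genes of highest own-module kME.

    Boundary ties are all included, so a set can exceed ceil(q * n).
    """
    if not 0 < q < 1:
        raise ConfigError("q must be in (0, 1)")
    out: dict[int, pd.Index] = {}
    for label in assignment.labels:
        members = assignment.members(label)
        scores = assignment.kme.loc[members, label]
        out[label] = _top_with_ties(scores, math.ceil(q * len(members)))
    return out


def peak_expression(norm: ExpressionMatrix, design: SampleDesign) -> pd.Series:
    """Per gene, the maximum over condition means of normalized expression."""
    cell_means = []
    for treatment, timepoint in design.cells():
        samples = [
            s for s in design.samples_for(treatment, timepoint) if s in norm.samples
        ]
        if samples:
            cell_means.append(norm.data[samples].mean(axis=1))
    peaks = pd.concat(cell_means, axis=1).max(axis=1)
    peaks.name = "peak_expr"
    return peaks


def module_activity(
    assignment: ModuleAssignment,
    design: SampleDesign,
    activity_fraction: float = 0.5,
) -> dict[int, list[tuple[str, int, int]]]:
    """Active (treatment, timepoint, sign) cells per module.

    For each infested-vs-control contrast the module eigengene's mean
    difference is computed; cells whose absolute difference reaches
    ``activity_fraction`` of the module's maximum are active, signed by the
    direction of the difference.
    """
    if not 0 < activity_fraction <= 1:
        raise ConfigError("activity_fraction must be in (0, 1]")
    out: dict[int, list[tuple[str, int, int]]] = {}
    for label in assignment.labels:
        eigen = assignment.eigengenes[label]
        deltas: list[tuple[str, int, float]] = []
        for treatment in design.infested:
            for timepoint in design.timepoints:
                group = design.samples_for(treatment, timepoint)
                control = design.samples_for(design.control, timepoint)
                if not group or not control:
                    continue
                delta = eigen[group].mean() - eigen[control].mean()
                deltas.append((treatment, timepoint, float(delta)))
        if not deltas:
            out[label] = []
            continue
        peak = max(abs(d) for _, _, d in deltas)
        out[label] = [
            (t, tp, 1 if d > 0 else -1)
            for t, tp, d in deltas
            if peak > 0 and abs(d) >= activity_fraction * peak
        ]
    return out


def select_target_tfs(
    annotation: GeneAnnotation,
    assignment: ModuleAssignment,
    norm: ExpressionMatrix,
    design: SampleDesign,
    deg_table: pd.DataFrame,
    expressed: pd.Index,
    q_kme: float = 0.10,
    peak_pct: float = 0.75,
    activity_fraction: float = 0.5,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Apply the three-criterion cascade to every module TF.

    Returns the selected TFs sorted by module and decreasing |delta| (the
    control-vs-infested expression difference at the module's peak
    contrast).  With ``keep_all`` the full evaluation table is returned,
    including TFs that fail one or more criteria.
    """
    if not 0 < peak_pct < 1:
        raise ConfigError("peak_pct must be in (0, 1)")
    top_sets = module_top_kme(assignment, q=q_kme)
    peaks = peak_expression(norm, design)
    peak_cutoff = float(np.quantile(peaks.loc[expressed], peak_pct))
    activity = module_activity(assignment, design, activity_fraction)

    deg_hits = {
        (row.gene, row.treatment, int(row.timepoint)): row.direction
        for row in deg_table.itertuples()
        if row.is_deg
    }

    rows = []
    tf_set = set(annotation.tf_genes)
    for label in assignment.labels:
        members = assignment.members(label)
        active = activity[label]
        peak_cell = None
        if active:
            # cell with the largest |eigengene delta| for the delta report
            eigen = assignment.eigengenes[label]
            best = max(
                active,
                key=lambda cell: abs(
                    eigen[design.samples_for(cell[0], cell[1])].mean()
                    - eigen[design.samples_for(design.control, cell[1])].mean()
                ),
            )
            peak_cell = best
        for gene in members:
            if gene not in tf_set:
                continue
            c1 = gene in top_sets[label]
            c2 = bool(peaks[gene] >= peak_cutoff)
            c3 = any(
                deg_hits.get((gene, t, tp))
                == (UP_INFESTED if sign > 0 else UP_CONTROL)
                for t, tp, sign in active
            )
            if peak_cell is not None:
                t, tp, _ = peak_cell
                group = [
                    s for s in design.samples_for(t, tp) if s in norm.samples
                ]
                control = [
                    s for s in design.samples_for(design.control, tp)
                    if s in norm.samples
                ]
                delta = float(
                    norm.data.loc[gene, group].mean()
                    - norm.data.loc[gene, control].mean()
                )
            else:
                delta = 0.0
            rows.append(
                {
                    "gene": gene,
                    "module": label,
                    "kme": float(assignment.kme.at[gene, label]),
                    "peak_expr": float(peaks[gene]),
                    "delta": delta,
                    "c1": c1,
                    "c2": c2,
                    "c3": c3,
                    "selected": c1 and c2 and c3,
                }
            )
    table = pd.DataFrame(rows, columns=TARGET_TF_COLUMNS)
    table["abs_delta"] = table["delta"].abs()
    table = table.sort_values(
        ["module", "abs_delta", "gene"], ascending=[True, False, True]
    ).drop(columns="abs_delta").reset_index(drop=True)
    if keep_all:
        return table
    return table[table["selected"]].reset_index(drop=True)


@dataclass
class Subnetwork:
    """A target TF with the genes in the top 1% of its TOM scores."""

    tf: str
    members: pd.Series  # member gene -> TOM score to the TF
    cutoff: float

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> pd.Index:
        return self.members.index


def tf_subnetwork(network: NetworkModel, tf: str, q: float = 0.01) -> Subnetwork:
    """Top ``q`` fraction of TOM scores to the TF, boundary ties included.

    The member count is ceil(q * (N - 1)) plus any genes tied with the
    boundary score; the TF itself is excluded.
    """
    if not 0 < q < 1:
        raise ConfigError("q must be in (0, 1)")
    scores = network.tom_row(tf).drop(tf)
    count = math.ceil(q * len(scores))
    chosen = _top_with_ties(scores, count)
    members = scores.loc[chosen].sort_values(ascending=False)
    return Subnetwork(tf=tf, members=members, cutoff=float(members.iloc[-1]))


def top_module_genes(
    assignment: ModuleAssignment, n: int = 200
) -> dict[int, pd.DataFrame]:
    """Per module, the top-n genes by own-module kME with ranks."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    out: dict[int, pd.DataFrame] = {}
    for label in assignment.labels:
        members = assignment.members(label)
        scores = assignment.kme.loc[members, label].sort_values(ascending=False)
        top = scores.iloc[:n]
        out[label] = pd.DataFrame(
            {
                "gene": top.index,
                "kme": top.to_numpy(),
                "rank": np.arange(1, len(top) + 1),
            }
        )
    return out


def tf_family_composition(
    annotation: GeneAnnotation, gene_sets: dict[int, pd.Index]
) -> pd.DataFrame:
    """Fraction of each TF family among the TFs of each module gene set.

    Modules whose set contains no TF are omitted; fractions sum to 1 per
    emitted module.
    """
    rows = []
    tf_set = set(annotation.tf_genes)
    for label, genes in gene_sets.items():
        tfs = [g for g in genes if g in tf_set]
        if not tfs:
            continue
        counts: dict[str, int] = {}
        for gene in tfs:
            family = annotation.family_of(gene)
            counts[family] = counts.get(family, 0) + 1
        for family in sorted(counts):
            rows.append(
                {
                    "module": label,
                    "family": family,
                    "n_tfs": counts[family],
                    "fraction": counts[family] / len(tfs),
                }
            )
    return pd.DataFrame(rows, columns=["module", "family", "n_tfs", "fraction"])
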