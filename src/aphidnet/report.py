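"""Reporting helpers: z-score matrices and the TF x pathway grid."""

from __future__ import annotations

import pandas as pd

from .containers import ConfigError, ExpressionMatrix

__all__ = ["zscore_table", "tf_pathway_grid", "module_profile_summary"]


def zscore_table(
    norm: ExpressionMatrix, genes
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores across samples (sample sd, ddof 1).

    Constant genes cannot be standardized; they are excluded and returned
    in the flagged list.
    """
    genes = pd.Index(genes)
    missing = genes.difference(norm.genes)
    if len(missing):
        raise ConfigError(f"genes absent from matrix: {list(missing)[:5]}")
    sub = norm.data.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    flagged = list(sub.index[sd == 0])
    keep = sub.index[sd > 0]
    z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, flagged


def tf_pathway_grid(
    subnet_enrichment: pd.DataFrame, target_tfs: pd.DataFrame
) -> pd.DataFrame:
    """Pathways x target-TF grid of member-gene counts with significance.

    ``subnet_enrichment`` must carry a ``unit`` column holding the TF gene
    id.  Columns follow module order and, within a module, the target-TF
    |delta| ranking of ``target_tfs``; cells are the pathway overlap counts
    and ``*`` marks raw p <= 0.05.  Returned as a long-form pivot with one
    row per pathway and a (module, tf) column per target TF.
    """
    order = list(target_tfs["gene"])
    frame = subnet_enrichment[subnet_enrichment["unit"].isin(order)]
    counts = frame.pivot_table(
        index="pathway", columns="unit", values="k", aggfunc="first"
    )
    sig = frame.pivot_table(
        index="pathway", columns="unit", values="significant", aggfunc="first"
    ).fillna(False)
    present = [tf for tf in order if tf in counts.columns]
    counts = counts[present]
    sig = sig[present]
    module_of = dict(zip(target_tfs["gene"], target_tfs["module"]))
    cells = counts.fillna(0).astype(int).astype(str)
    cells = cells.where(~sig.astype(bool), cells + "*")
    cells.columns = [f"M{module_of[tf]}:{tf}" for tf in present]
    cells.index.name = "pathway"
    return cells.reset_index()


def module_profile_summary(eigengenes: pd.DataFrame, design) -> pd.DataFrame:
    """Mean eigengene per (treatment, timepoint) cell for every module."""
    rows = []
    for label in eigengenes.columns:
        for treatment, timepoint in design.cells():
            samples = design.samples_for(treatment, timepoint)
            rows.append(
                {
                    "module": int(label),
                    "treatment": treatment,
                    "timepoint": timepoint,
                    "mean_eigengene": float(eigengenes.loc[samples, label].mean()),
                }
            )
    return pd.DataFrame(rows)
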