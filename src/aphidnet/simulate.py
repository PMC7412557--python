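"""Synthetic expression, annotation, and metabolite generators.

The generator plants the six co-expression module profiles observed in
aphid-infested switchgrass (greenbug, GB, and yellow sugarcane aphid, YSA,
over 5/10/15 days after infestation) into a negative-binomial count matrix,
together with hub transcription factors, pathway enrichments, and four
metabolite response sets.  Every downstream stage of the pipeline can then
be tested against the planted ground truth without any external data.

Model
-----
Each module ``m`` has a condition signal ``s_m(treatment, timepoint)`` on the
log2 scale (0 in controls).  A per-sample eigenprofile is drawn as

    e_m[s] = s_m(treatment_s, timepoint_s) * effect_size + N(0, shared_sd)

and each member gene ``g`` with loading ``l_g`` has log2 mean
``baseline_g + l_g * e_m[s] + N(0, gene_sd)``; counts are negative binomial
around ``2 ** log2mean`` with a fixed dispersion.  The replicate-noise
variance ``noise_sd**2`` is split between the shared eigenprofile component
(coherent biological variation of the module) and the per-gene component.
Background genes have loading 0 and carry only the per-gene noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    ExpressionMatrix,
    GeneAnnotation,
    MetaboliteTable,
    SampleDesign,
)

__all__ = [
    "ModuleProfile",
    "SyntheticTruth",
    "table1_profiles",
    "generate_design",
    "generate_expression",
    "generate_annotations",
    "generate_metabolites",
]

BACKGROUND = "background"

#: Transcription-factor families used for cosmetic labelling of planted TFs.
TF_FAMILIES = ("WRKY", "NAC", "MYB", "bHLH", "bZIP", "AP2/ERF", "C2H2", "FAR1")


@dataclass(frozen=True)
class ModuleProfile:
    """A module label plus its (treatment, timepoint) -> log2 signal map.

    Signals are in units of ``effect_size``; cells absent from the map
    (including every control cell) have signal 0.
    """

    label: str
    signal: Mapping[tuple[str, int], float]

    def at(self, treatment: str, timepoint: int) -> float:
        return float(self.signal.get((treatment, int(timepoint)), 0.0))


def table1_profiles(
    timepoints: Sequence[int] = (5, 10, 15),
    gb: str = "GB",
    ysa: str = "YSA",
) -> tuple[ModuleProfile, ...]:
    """The six qualitative module profiles of the aphid-infestation study.

    * M1 - up in controls, down under both aphids at every timepoint
    * M7 - up at the earliest timepoint under both aphids
    * M2 - up early under GB and late under YSA
    * M3 - up under GB at all timepoints, not under YSA
    * M4 - up under GB at all timepoints and under YSA late
    * M6 - up under YSA at all timepoints, not under GB
    """
    t5, t10, t15 = (int(t) for t in timepoints)
    return (
        ModuleProfile("M1", {(a, t): -1.0 for a in (gb, ysa) for t in (t5, t10, t15)}),
        ModuleProfile("M7", {(gb, t5): 1.0, (ysa, t5): 1.0}),
        ModuleProfile("M2", {(gb, t5): 1.0, (ysa, t15): 1.0}),
        ModuleProfile("M3", {(gb, t5): 1.0, (gb, t10): 1.0, (gb, t15): 1.0}),
        ModuleProfile(
            "M4",
            {(gb, t5): 1.0, (gb, t10): 1.0, (gb, t15): 1.0, (ysa, t15): 1.0},
        ),
        ModuleProfile("M6", {(ysa, t5): 1.0, (ysa, t10): 1.0, (ysa, t15): 1.0}),
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth backing the generated tables."""

    module_of: dict[str, str]
    loading: dict[str, float]
    hubs: dict[str, tuple[str, ...]]
    module_pathway: dict[str, str] = field(default_factory=dict)
    metabolite_set: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    effect_size: float = 0.0
    noise_sd: float = 0.0
    dispersion: float = 0.0

    @property
    def modules(self) -> list[str]:
        return list(self.hubs)

    def members(self, label: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == label]

    @property
    def hub_genes(self) -> list[str]:
        return [g for hubs in self.hubs.values() for g in hubs]

    def to_json(self) -> str:
        payload = {
            "module_of": self.module_of,
            "loading": self.loading,
            "hubs": {m: list(h) for m, h in self.hubs.items()},
            "module_pathway": self.module_pathway,
            "metabolite_set": self.metabolite_set,
            "seed": self.seed,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "dispersion": self.dispersion,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            module_of=payload["module_of"],
            loading=payload["loading"],
            hubs={m: tuple(h) for m, h in payload["hubs"].items()},
            module_pathway=payload.get("module_pathway", {}),
            metabolite_set=payload.get("metabolite_set", {}),
            seed=payload.get("seed", 0),
            effect_size=payload.get("effect_size", 0.0),
            noise_sd=payload.get("noise_sd", 0.0),
            dispersion=payload.get("dispersion", 0.0),
        )


def generate_design(
    n_reps: int = 3,
    timepoints: Sequence[int] = (5, 10, 15),
    treatments: Sequence[str] = ("control", "GB", "YSA"),
    control: str = "control",
) -> SampleDesign:
    """Fully crossed treatment x timepoint x replicate design."""
    if not timepoints or not treatments:
        raise ConfigError("timepoints and treatments must be non-empty")
    if n_reps < 2:
        raise ConfigError("at least 2 replicates are required")
    if list(treatments).count(control) != 1:
        raise ConfigError(f"treatments must include exactly one {control!r}")
    rows = []
    for treatment in treatments:
        for timepoint in timepoints:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample": f"{treatment}_d{int(timepoint):02d}_r{rep}",
                        "treatment": treatment,
                        "timepoint": int(timepoint),
                        "replicate": rep,
                    }
                )
    table = pd.DataFrame(rows).set_index("sample")
    return SampleDesign(table=table, control=control)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_expression(
    profiles: Sequence[ModuleProfile] | None = None,
    n_genes_per_module: int = 150,
    n_background: int = 1100,
    design: SampleDesign | None = None,
    effect_size: float = 3.0,
    noise_sd: float = 0.3,
    dispersion: float = 0.02,
    seed: int = 1,
    baseline_range: tuple[float, float] = (6.0, 10.0),
    member_loading_range: tuple[float, float] = (0.4, 0.7),
    hub_loading_range: tuple[float, float] = (0.95, 1.0),
    n_hubs_per_module: int = 3,
    shared_noise_fraction: float = 0.25,
    hub_baseline_range: tuple[float, float] = (10.0, 11.0),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Plant module profiles into a negative-binomial count matrix.

    ``noise_sd`` is the total replicate-noise standard deviation on the
    log2 scale; a ``shared_noise_fraction`` share of its variance is drawn
    once per sample and module (coherent biological variation of the module
    eigenprofile) and the rest independently per gene and sample.  The
    first ``n_hubs_per_module`` genes of each module are its designated hub
    transcription factors and draw loadings from ``hub_loading_range``; the
    remaining members draw from ``member_loading_range``.  Background genes
    have loading 0 and vary only through per-gene noise and counting noise.
    """
    if profiles is None:
        profiles = table1_profiles()
    if design is None:
        design = generate_design()
    if n_genes_per_module <= 0 or n_background < 0:
        raise ConfigError("gene counts per module must be positive")
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be positive")
    if effect_size < 0:
        raise ConfigError("effect_size must be non-negative")
    if n_hubs_per_module >= n_genes_per_module:
        raise ConfigError("n_hubs_per_module must be below the module size")
    if not 0 <= shared_noise_fraction <= 1:
        raise ConfigError("shared_noise_fraction must be in [0, 1]")
    shared_sd = noise_sd * np.sqrt(shared_noise_fraction)
    gene_sd = noise_sd * np.sqrt(1.0 - shared_noise_fraction)

    rng = np.random.default_rng(seed)
    samples = list(design.samples)
    conditions = [
        (design.table.at[s, "treatment"], int(design.table.at[s, "timepoint"]))
        for s in samples
    ]

    gene_counter = 0
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    loading_of: dict[str, float] = {}
    hubs: dict[str, tuple[str, ...]] = {}

    for profile in profiles:
        ids = [f"g{gene_counter + i:05d}" for i in range(n_genes_per_module)]
        gene_counter += n_genes_per_module
        eigenprofile = np.array(
            [profile.at(t, tp) * effect_size for t, tp in conditions]
        ) + rng.normal(0.0, shared_sd, size=len(samples))
        loadings = np.empty(n_genes_per_module)
        loadings[:n_hubs_per_module] = rng.uniform(
            *hub_loading_range, size=n_hubs_per_module
        )
        loadings[n_hubs_per_module:] = rng.uniform(
            *member_loading_range, size=n_genes_per_module - n_hubs_per_module
        )
        baseline = rng.uniform(*baseline_range, size=n_genes_per_module)
        baseline[:n_hubs_per_module] = rng.uniform(
            *hub_baseline_range, size=n_hubs_per_module
        )
        log2_mean = (
            baseline[:, None]
            + loadings[:, None] * eigenprofile[None, :]
            + rng.normal(0.0, gene_sd, size=(n_genes_per_module, len(samples)))
        )
        blocks.append(_nb_counts(rng, 2.0 ** log2_mean, dispersion))
        gene_ids.extend(ids)
        hubs[profile.label] = tuple(ids[:n_hubs_per_module])
        for g, l in zip(ids, loadings):
            module_of[g] = profile.label
            loading_of[g] = float(l)

    if n_background:
        ids = [f"g{gene_counter + i:05d}" for i in range(n_background)]
        baseline = rng.uniform(*baseline_range, size=n_background)
        log2_mean = baseline[:, None] + rng.normal(
            0.0, gene_sd, size=(n_background, len(samples))
        )
        blocks.append(_nb_counts(rng, 2.0 ** log2_mean, dispersion))
        gene_ids.extend(ids)
        for g in ids:
            module_of[g] = BACKGROUND
            loading_of[g] = 0.0

    counts = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(gene_ids, name="gene"), columns=samples
    )
    truth = SyntheticTruth(
        module_of=module_of,
        loading=loading_of,
        hubs=hubs,
        seed=int(seed),
        effect_size=float(effect_size),
        noise_sd=float(noise_sd),
        dispersion=float(dispersion),
    )
    return ExpressionMatrix(data=counts, scale="counts"), truth


def generate_annotations(
    truth: SyntheticTruth,
    n_pathways: int = 40,
    pathway_size: int = 50,
    enrichment_fraction: float = 0.9,
    seed: int = 1,
    n_background_tfs: int = 30,
    families: Sequence[str] = TF_FAMILIES,
) -> GeneAnnotation:
    """Pathway memberships and TF flags consistent with the planted truth.

    The first ``len(truth.modules)`` pathways are planted: each draws
    ``enrichment_fraction`` of its members from one module and the rest
    uniformly from outside it.  Remaining pathways sample the whole gene
    universe uniformly.  Planted hub genes are flagged as TFs; a set of
    background decoy TFs (loading 0) is flagged as well so that selection
    precision is measurable.  ``truth.module_pathway`` is filled in place.
    """
    if not 0 < enrichment_fraction <= 1:
        raise ConfigError("enrichment_fraction must be in (0, 1]")
    universe = list(truth.module_of)
    if pathway_size > len(universe):
        raise ConfigError("pathway_size exceeds the gene universe")
    if n_pathways < len(truth.modules):
        raise ConfigError("need at least one pathway per planted module")

    rng = np.random.default_rng(seed)
    pathways: dict[str, frozenset[str]] = {}
    truth.module_pathway.clear()
    for i, label in enumerate(truth.modules):
        members = truth.members(label)
        n_inside = min(int(round(enrichment_fraction * pathway_size)), len(members))
        n_inside = min(n_inside, pathway_size - 1)  # keep >= 1 gene outside
        if n_inside < 5:
            raise ConfigError("planted pathways need >= 5 genes inside the module")
        outside = [g for g in universe if truth.module_of[g] != label]
        chosen = list(rng.choice(members, size=n_inside, replace=False))
        chosen += list(
            rng.choice(outside, size=pathway_size - n_inside, replace=False)
        )
        pid = f"pw{i + 1:03d}"
        pathways[pid] = frozenset(chosen)
        truth.module_pathway[label] = pid
    for i in range(len(truth.modules), n_pathways):
        pid = f"pw{i + 1:03d}"
        pathways[pid] = frozenset(
            rng.choice(universe, size=pathway_size, replace=False)
        )

    background = [g for g in universe if truth.module_of[g] == BACKGROUND]
    n_decoys = min(n_background_tfs, len(background))
    decoys = list(rng.choice(background, size=n_decoys, replace=False))
    tf_genes = list(truth.hub_genes) + decoys
    fams = rng.choice(list(families), size=len(tf_genes))

    table = pd.DataFrame(
        {
            "is_tf": False,
            "tf_family": "",
        },
        index=pd.Index(universe, name="gene"),
    )
    table.loc[tf_genes, "is_tf"] = True
    table.loc[tf_genes, "tf_family"] = fams
    return GeneAnnotation(table=table, pathways=pathways)


#: Natural-log fold multipliers of the four planted metabolite response sets.
#: Set 1 rises under GB only (peak 10 DAI); set 2 under YSA only (peak 15
#: DAI); sets 3 and 4 rise under both aphids with GB- and YSA-biased
#: magnitudes respectively.
METABOLITE_SET_SHAPES: dict[str, dict[tuple[str, int], float]] = {
    "set1": {("GB", 5): 0.6, ("GB", 10): 1.0, ("GB", 15): 0.6},
    "set2": {("YSA", 5): 0.2, ("YSA", 10): 0.5, ("YSA", 15): 1.0},
    "set3": {
        ("GB", 5): 0.6, ("GB", 10): 1.0, ("GB", 15): 0.8,
        ("YSA", 5): 0.3, ("YSA", 10): 0.5, ("YSA", 15): 0.7,
    },
    "set4": {
        ("GB", 5): 0.3, ("GB", 10): 0.5, ("GB", 15): 0.6,
        ("YSA", 5): 0.4, ("YSA", 10): 0.7, ("YSA", 15): 1.0,
    },
}


def generate_metabolites(
    design: SampleDesign | None = None,
    n_per_set: int = 25,
    n_null: int = 100,
    effect_size: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 1,
    pathway_ids: Sequence[str] | None = None,
    truth: SyntheticTruth | None = None,
) -> MetaboliteTable:
    """Lognormal metabolite abundances with four planted response sets.

    Abundances are ``exp(base + shape * effect_size + N(0, noise_sd))`` on
    the natural-log scale; ``n_null`` metabolites carry no treatment signal.
    Each metabolite is assigned one pathway from ``pathway_ids`` (defaults
    to ``pw001``..``pw040``).  When ``truth`` is given its
    ``metabolite_set`` map is filled in place.
    """
    if design is None:
        design = generate_design()
    if n_per_set < 1:
        raise ConfigError("n_per_set must be >= 1")
    if n_null < 0:
        raise ConfigError("n_null must be >= 0")
    if pathway_ids is None:
        pathway_ids = [f"pw{i + 1:03d}" for i in range(40)]

    rng = np.random.default_rng(seed)
    samples = list(design.samples)
    conditions = [
        (design.table.at[s, "treatment"], int(design.table.at[s, "timepoint"]))
        for s in samples
    ]

    rows: list[np.ndarray] = []
    ids: list[str] = []
    set_of: dict[str, str] = {}
    counter = 0
    for set_label, shape in METABOLITE_SET_SHAPES.items():
        for _ in range(n_per_set):
            mid = f"met{counter:04d}"
            counter += 1
            base = rng.uniform(np.log(1e3), np.log(1e6))
            signal = np.array([shape.get(c, 0.0) for c in conditions])
            log_ab = base + signal * effect_size + rng.normal(
                0.0, noise_sd, size=len(samples)
            )
            rows.append(np.exp(log_ab))
            ids.append(mid)
            set_of[mid] = set_label
    for _ in range(n_null):
        mid = f"met{counter:04d}"
        counter += 1
        base = rng.uniform(np.log(1e3), np.log(1e6))
        log_ab = base + rng.normal(0.0, noise_sd, size=len(samples))
        rows.append(np.exp(log_ab))
        ids.append(mid)
        set_of[mid] = "null"

    assigned = rng.choice(list(pathway_ids), size=len(ids))
    pathways: dict[str, set[str]] = {}
    for mid, pid in zip(ids, assigned):
        pathways.setdefault(str(pid), set()).add(mid)

    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="metabolite"), columns=samples
    )
    if truth is not None:
        truth.metabolite_set.clear()
        truth.metabolite_set.update(set_of)
    table = MetaboliteTable(
        data=data, pathways={k: frozenset(v) for k, v in pathways.items()}
    )
    # stash the planted sets for callers without a truth object
    table.planted_sets = set_of  # type: ignore[attr-defined]
    return table
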