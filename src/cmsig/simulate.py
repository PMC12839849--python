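"""Synthetic multi-subtype cohort generator.

Emulates the statistical structure the analysis pipeline assumes about a
colorectal-cancer cohort: four consensus-subtype expression programs planted
as disjoint gene blocks, subtype-dependent exponential survival hazards
(the mesenchymal-like fourth subtype carries the poor prognosis), a bank of
gene sets enriched for each program plus 28 disjoint "immune cell" sets two
of which sit inside the immune-like first program, and optional radiomic
features linearly loaded on pathway activity. Ground truth is returned for
recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .io import NOLBL, ClinicalTable, ExpressionMatrix, GeneSetCollection

SUBTYPES = ("CMS1", "CMS2", "CMS3", "CMS4")

#: Labeled-subtype proportions of the discovery cohort (immune, canonical,
#: metabolic, mesenchymal), renormalized over labeled samples.
DEFAULT_PROPORTIONS = (0.15, 0.45, 0.14, 0.26)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Expression is log-scale: gene g in sample j is
    ``baseline_g + program_effect * 1[g in program(subtype_j)] + N(0, noise_sd^2)``.
    Survival is exponential with rate ``baseline_hazard * exp(gamma_subtype)``,
    censored by an independent Uniform(0, censoring_window) time and an
    administrative horizon at ``censoring_window``.
    """

    n_samples: int = 600
    n_genes: int = 2000
    subtype_proportions: tuple = DEFAULT_PROPORTIONS
    genes_per_program: int = 100
    program_effect: float = 2.0
    noise_sd: float = 1.0
    baseline_mean_range: tuple = (2.0, 12.0)
    # per-subtype log hazard multipliers; the fourth subtype is the
    # poor-prognosis one (hazard ratio 2.5 vs baseline)
    hazard_log_multipliers: tuple = (0.0, -0.2, 0.0, math.log(2.5))
    baseline_hazard: float = 0.015  # events per month
    censoring_window: float = 120.0  # months
    n_background_sets: int = 20
    sets_per_program: int = 5
    program_set_size: int = 50
    background_set_size: int = 50
    immune_set_size: int = 10
    n_immune_sets: int = 28
    n_radiomic: int = 21
    n_radiomic_linked: int = 16
    radiomic_loading: float = 1.5
    radiomic_noise_sd: float = 1.0
    label_masking_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.subtype_proportions, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must be 4 non-negatives summing to 1")
        if 4 * self.genes_per_program > self.n_genes:
            raise ValueError("4 * genes_per_program must not exceed n_genes")
        if self.noise_sd <= 0 or self.radiomic_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.baseline_hazard <= 0 or self.censoring_window <= 0:
            raise ValueError("baseline_hazard and censoring_window must be positive")
        n_immune_genes = self.n_immune_sets * self.immune_set_size
        # 26 immune sets live outside the programs, 2 inside program 1
        outside = (self.n_immune_sets - 2) * self.immune_set_size
        if 4 * self.genes_per_program + outside > self.n_genes:
            raise ValueError("not enough genes for programs plus immune sets")
        if 2 * self.immune_set_size > self.genes_per_program:
            raise ValueError("immune sets embedded in program 1 do not fit")
        del n_immune_genes


@dataclass
class SyntheticTruth:
    """Planted ground truth used by recovery tests."""

    subtype: np.ndarray  # true subtype per sample, before label masking
    program_genes: dict[str, tuple[str, ...]]  # subtype -> gene ids
    hazard_log_multipliers: dict[str, float]
    immune_program_sets: tuple[str, ...]  # immune sets embedded in CMS1 program
    immune_set_names: tuple[str, ...]
    radiomic_loadings: dict[str, str] = field(default_factory=dict)  # feature -> program

    def all_program_genes(self) -> set[str]:
        return set().union(*map(set, self.program_genes.values()))

    def to_json(self, path) -> None:
        doc = {
            "subtype": list(self.subtype),
            "program_genes": {k: list(v) for k, v in self.program_genes.items()},
            "hazard_log_multipliers": self.hazard_log_multipliers,
            "immune_program_sets": list(self.immune_program_sets),
            "immune_set_names": list(self.immune_set_names),
            "radiomic_loadings": self.radiomic_loadings,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # one spawned stream per component, so adding a component never perturbs
    # the draws of the others
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, SyntheticTruth]:
    """Generate one cohort: expression, survival, gene sets, ground truth.

    Deterministic given ``config.seed``. The clinical table's ``subtype``
    column has a fraction ``label_masking_rate`` of labels replaced by
    ``NOLBL``; the unmasked truth lives in :class:`SyntheticTruth`.
    """
    cfg = config
    rng_assign, rng_expr, rng_surv, rng_sets, rng_mask = _child_rngs(cfg.seed, 5)

    n, G = cfg.n_samples, cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(n)]

    subtype_idx = rng_assign.choice(4, size=n, p=np.asarray(cfg.subtype_proportions))
    subtype = np.array([SUBTYPES[k] for k in subtype_idx], dtype=object)

    # disjoint program blocks at the head of the gene list
    m = cfg.genes_per_program
    program_genes = {
        SUBTYPES[k]: tuple(gene_ids[k * m : (k + 1) * m]) for k in range(4)
    }

    lo, hi = cfg.baseline_mean_range
    baseline = rng_expr.uniform(lo, hi, size=G)
    values = baseline[:, None] + rng_expr.normal(0.0, cfg.noise_sd, size=(G, n))
    for k in range(4):
        block = slice(k * m, (k + 1) * m)
        values[block, :] += cfg.program_effect * (subtype_idx == k)

    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    # exponential survival with planted log-hazard multipliers
    gamma = np.asarray(cfg.hazard_log_multipliers, dtype=float)
    rate = cfg.baseline_hazard * np.exp(gamma[subtype_idx])
    event_time = rng_surv.exponential(1.0 / rate)
    censor_time = np.minimum(
        rng_surv.uniform(0.0, cfg.censoring_window, size=n), cfg.censoring_window
    )
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # guard the positive-time invariant

    masked = subtype.copy()
    if cfg.label_masking_rate > 0:
        mask = rng_mask.random(n) < cfg.label_masking_rate
        masked[mask] = NOLBL

    clinical = ClinicalTable(
        sample_ids,
        time,
        event,
        masked,
        np.array(["synthetic"] * n, dtype=object),
        "months",
    )

    sets, descriptions = {}, {}
    # program-enriched sets: >=80% members from the program's block
    n_core = int(math.ceil(0.8 * cfg.program_set_size))
    non_program_pool = np.array(gene_ids[4 * m :])
    for k, st in enumerate(SUBTYPES):
        pool = np.array(program_genes[st])
        for s in range(cfg.sets_per_program):
            core = rng_sets.choice(pool, size=min(n_core, len(pool)), replace=False)
            n_fill = cfg.program_set_size - len(core)
            fill = rng_sets.choice(non_program_pool, size=n_fill, replace=False)
            name = f"{st}_PROGRAM_SET_{s + 1}"
            sets[name] = tuple(core) + tuple(fill)
            descriptions[name] = f"synthetic set enriched for the {st} program"
    # background sets: random draws from all genes
    for b in range(cfg.n_background_sets):
        draw = rng_sets.choice(np.array(gene_ids), size=cfg.background_set_size, replace=False)
        name = f"BACKGROUND_SET_{b + 1}"
        sets[name] = tuple(draw)
        descriptions[name] = "synthetic background set"
    # 28 disjoint immune-cell sets; the first two are embedded in the
    # CMS1-like program so immune infiltration tracks that subtype
    immune_names = []
    cms1_block = list(program_genes["CMS1"])
    outside_pool = list(gene_ids[4 * m :])
    rng_sets.shuffle(outside_pool)
    cursor = 0
    for i in range(cfg.n_immune_sets):
        name = f"IMMUNE_CELL_{i + 1:02d}"
        if i < 2:
            members = cms1_block[i * cfg.immune_set_size : (i + 1) * cfg.immune_set_size]
        else:
            members = outside_pool[cursor : cursor + cfg.immune_set_size]
            cursor += cfg.immune_set_size
        sets[name] = tuple(members)
        descriptions[name] = "synthetic immune cell program"
        immune_names.append(name)

    collection = GeneSetCollection(sets, descriptions)
    truth = SyntheticTruth(
        subtype=subtype,
        program_genes=program_genes,
        hazard_log_multipliers={st: float(gamma[k]) for k, st in enumerate(SUBTYPES)},
        immune_program_sets=tuple(immune_names[:2]),
        immune_set_names=tuple(immune_names),
    )
    return expr, clinical, collection, truth


def pathway_activity(expr: ExpressionMatrix, genes) -> np.ndarray:
    """Standardized mean expression of ``genes`` per sample (z across samples)."""
    idx = [expr.gene_ids.index(g) for g in genes]
    act = expr.values[idx, :].mean(axis=0)
    sd = act.std()
    if sd == 0:
        return act - act.mean()
    return (act - act.mean()) / sd


def simulate_radiomic(
    expr: ExpressionMatrix, truth: SyntheticTruth, config: SimulationConfig
) -> "pd.DataFrame":
    """Simulate a samples x radiomic-feature matrix.

    The first ``n_radiomic_linked`` features load on the four program
    activities (round-robin): ``r = loading * activity + N(0, noise^2)``;
    the rest are pure noise. Records feature -> program in ``truth``.
    """
    import pandas as pd

    if len(truth.subtype) != expr.n_samples:
        raise ValueError(
            f"sample mismatch: truth covers {len(truth.subtype)} samples, "
            f"expression has {expr.n_samples}"
        )
    cfg = config
    rng = _child_rngs(cfg.seed, 6)[5]
    n = expr.n_samples
    acts = {st: pathway_activity(expr, truth.program_genes[st]) for st in SUBTYPES}
    cols, names = [], []
    truth.radiomic_loadings.clear()
    for f in range(cfg.n_radiomic):
        name = f"RAD{f + 1:03d}"
        noise = rng.normal(0.0, cfg.radiomic_noise_sd, size=n)
        if f < cfg.n_radiomic_linked:
            st = SUBTYPES[f % 4]
            cols.append(cfg.radiomic_loading * acts[st] + noise)
            truth.radiomic_loadings[name] = st
        else:
            cols.append(noise)
        names.append(name)
    frame = pd.DataFrame(np.column_stack(cols), index=expr.sample_ids, columns=names)
    return frame
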