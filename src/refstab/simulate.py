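"""Synthetic Ct tables and count matrices with known stability structure.

The Ct generator emulates a two-strain reference-gene validation study:
a full factorial of strain x condition x timepoint "cells", biological
duplicates per cell and technical duplicates per biological sample. Each
gene's Ct is

    Ct(g, cell, bio, tech) = base_ct(g) + condition_effect(g, cell)
                             + bio_noise + tech_noise + loading_shift

with all noise Normal on the Ct (log-abundance) scale. The per-sample
loading shift is shared by every gene of a biological sample and models
RNA-input / RT-efficiency variation — exactly the nuisance that
reference-gene normalization exists to remove, which makes invariance
tests on this generator meaningful.

The count generator draws negative-binomial counts around per-condition
means scaled by log-normal library-size factors, the canonical bulk
RNA-seq generative model compatible with median-of-ratios normalization.

All randomness flows from a single integer seed; no global random state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CT_COLUMNS, CountMatrix, CtTable

#: condition labels of the default cultivation design: five carbon sources
#: plus ER stress (lactose + DTT) and osmotic stress (glucose + NaCl)
DEFAULT_CONDITIONS = (
    "glucose",
    "lactose",
    "xylan",
    "glycerin",
    "cellulose",
    "lactose-DTT",
    "glucose-NaCl",
)


@dataclass
class CtDesign:
    """Factorial layout of a qPCR validation experiment.

    Defaults mirror a two-strain study sampling seven cultivation
    conditions at an early and a late growth stage in biological and
    technical duplicates: 2 x 7 x 2 x 2 x 2 = 112 measurements per gene.
    """

    strains: Sequence[str] = ("QM6a", "Rut-C30")
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    timepoints: Sequence[str] = ("early", "late")
    bio_reps: int = 2
    tech_reps: int = 2

    def __post_init__(self) -> None:
        if min(len(self.strains), len(self.conditions), len(self.timepoints)) < 1:
            raise ValidationError("design needs at least one strain/condition/timepoint")
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValidationError("replicate counts must be >= 1")

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        """All (strain, condition, timepoint) combinations."""
        return list(itertools.product(self.strains, self.conditions, self.timepoints))

    @property
    def measurements_per_gene(self) -> int:
        return len(self.cells) * self.bio_reps * self.tech_reps


@dataclass
class CtGeneSpec:
    """Generative parameters of one gene on the Ct scale.

    cond_sd is the SD of the per-(strain, condition, timepoint) expression
    effect — the *biological regulation* a reference gene should not have.
    bio_sd and tech_sd are replicate noise; fixed_effects, when given, maps
    (strain, condition, timepoint) to a deterministic Ct offset and replaces
    the random condition effect (missing cells get 0).
    """

    gene_id: str
    base_ct: float = 22.0
    cond_sd: float = 0.0
    bio_sd: float = 0.0
    tech_sd: float = 0.0
    fixed_effects: Mapping[tuple[str, str, str], float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.base_ct < 45.0):
            raise ValidationError(f"{self.gene_id}: base_ct must lie in (0, 45)")
        for name in ("cond_sd", "bio_sd", "tech_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.gene_id}: {name} must be >= 0")

    def total_sd(self, tech_reps: int) -> float:
        """Expected per-sample variability after technical averaging."""
        return math.sqrt(self.cond_sd**2 + self.bio_sd**2 + self.tech_sd**2 / tech_reps)


@dataclass
class CountGeneSpec:
    """Generative parameters of one gene in a count matrix."""

    gene_id: str
    mu_by_condition: Mapping[str, float]
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mu_by_condition.values()):
            raise ValidationError(f"{self.gene_id}: all condition means must be > 0")
        if self.dispersion < 0:
            raise ValidationError(f"{self.gene_id}: dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Injected parameters and the implied ground-truth stability order."""

    seed: int
    gene_params: dict[str, dict] = field(default_factory=dict)
    expected_stability_order: list[str] = field(default_factory=list)
    realized_condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    loading_shifts: dict[str, float] = field(default_factory=dict)
    stable_genes: list[str] = field(default_factory=list)
    true_mean_cv: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "gene_params": self.gene_params,
            "expected_stability_order": self.expected_stability_order,
            "realized_condition_effects": self.realized_condition_effects,
            "loading_shifts": self.loading_shifts,
            "stable_genes": self.stable_genes,
            "true_mean_cv": self.true_mean_cv,
        }


def _cell_label(cell: tuple[str, str, str]) -> str:
    return "|".join(cell)


def sample_id(strain: str, condition: str, timepoint: str, bio_rep: int) -> str:
    return f"{strain}.{condition}.{timepoint}.b{bio_rep}"


def generate_ct_dataset(
    design: CtDesign,
    genes: Sequence[CtGeneSpec],
    loading_sd: float = 0.5,
    seed: int = 0,
) -> tuple[CtTable, SyntheticTruth]:
    """Simulate a replicate-resolved Ct table for the given design.

    Identical seed => bit-identical output. The returned truth records the
    injected parameters, the realized per-cell condition effects, the
    per-sample loading shifts and the expected stability order (ascending
    sqrt(cond_sd^2 + bio_sd^2 + tech_sd^2 / tech_reps), ties by gene id).
    """
    if loading_sd < 0:
        raise ValidationError("loading_sd must be >= 0")
    if len({g.gene_id for g in genes}) != len(genes):
        raise ValidationError("duplicate gene ids in spec list")
    rng = np.random.default_rng(seed)
    cells = design.cells
    n_cells, n_bio, n_tech = len(cells), design.bio_reps, design.tech_reps

    loading = rng.normal(0.0, loading_sd, size=(n_cells, n_bio)) if loading_sd > 0 \
        else np.zeros((n_cells, n_bio))

    truth = SyntheticTruth(seed=int(seed))
    rows: list[tuple] = []
    for spec in genes:
        if spec.fixed_effects is not None:
            cond_eff = np.array([float(spec.fixed_effects.get(c, 0.0)) for c in cells])
        elif spec.cond_sd > 0:
            cond_eff = rng.normal(0.0, spec.cond_sd, size=n_cells)
        else:
            cond_eff = np.zeros(n_cells)
        bio_noise = rng.normal(0.0, spec.bio_sd, size=(n_cells, n_bio)) \
            if spec.bio_sd > 0 else np.zeros((n_cells, n_bio))
        tech_noise = rng.normal(0.0, spec.tech_sd, size=(n_cells, n_bio, n_tech)) \
            if spec.tech_sd > 0 else np.zeros((n_cells, n_bio, n_tech))
        ct = (
            spec.base_ct
            + cond_eff[:, None, None]
            + bio_noise[:, :, None]
            + tech_noise
            + loading[:, :, None]
        )
        for ci, (strain, condition, timepoint) in enumerate(cells):
            for b in range(n_bio):
                sid = sample_id(strain, condition, timepoint, b + 1)
                for t in range(n_tech):
                    rows.append(
                        (sid, spec.gene_id, float(ct[ci, b, t]), t + 1, b + 1,
                         strain, condition, timepoint)
                    )
        truth.gene_params[spec.gene_id] = {
            "base_ct": spec.base_ct,
            "cond_sd": spec.cond_sd,
            "bio_sd": spec.bio_sd,
            "tech_sd": spec.tech_sd,
            "fixed_effects": (
                {_cell_label(k): v for k, v in spec.fixed_effects.items()}
                if spec.fixed_effects is not None else None
            ),
            "total_sd": spec.total_sd(n_tech),
        }
        truth.realized_condition_effects[spec.gene_id] = {
            _cell_label(c): float(e) for c, e in zip(cells, cond_eff)
        }
    for ci, cell in enumerate(cells):
        for b in range(n_bio):
            truth.loading_shifts[sample_id(*cell, b + 1)] = float(loading[ci, b])
    truth.expected_stability_order = sorted(
        (g.gene_id for g in genes),
        key=lambda gid: (truth.gene_params[gid]["total_sd"], gid),
    )
    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    return CtTable(df), truth


def generate_count_matrix(
    genes: Sequence[CountGeneSpec],
    samples_per_condition: int = 2,
    library_scale_sd: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a raw count matrix: NB(mu * library factor, dispersion).

    Library factors are log-normal (natural-log SD ``library_scale_sd``).
    Dispersion follows the var = mu + dispersion * mu^2 parameterisation;
    dispersion 0 degrades to Poisson. The truth records each gene's
    across-condition CV of true means.
    """
    if samples_per_condition < 1:
        raise ValidationError("samples_per_condition must be >= 1")
    if library_scale_sd < 0:
        raise ValidationError("library_scale_sd must be >= 0")
    conditions = list(genes[0].mu_by_condition)
    for g in genes:
        if list(g.mu_by_condition) != conditions:
            raise ValidationError("all genes must share the same condition set")
    rng = np.random.default_rng(seed)
    n_cond, n_rep = len(conditions), samples_per_condition
    samples = [f"{c}.r{r + 1}" for c in conditions for r in range(n_rep)]
    cond_of_sample = np.repeat(np.arange(n_cond), n_rep)

    mu = np.array([[g.mu_by_condition[c] for c in conditions] for g in genes])
    alpha = np.array([g.dispersion for g in genes])
    lib = np.exp(rng.normal(0.0, library_scale_sd, size=len(samples))) \
        if library_scale_sd > 0 else np.ones(len(samples))
    mean = mu[:, cond_of_sample] * lib[None, :]

    counts = np.empty_like(mean)
    pos = alpha > 0
    if pos.any():
        lam = rng.gamma(1.0 / alpha[pos, None], mean[pos] * alpha[pos, None])
        counts[pos] = rng.poisson(lam)
    if (~pos).any():
        counts[~pos] = rng.poisson(mean[~pos])

    values = pd.DataFrame(
        counts.astype(float),
        index=pd.Index([g.gene_id for g in genes], name="gene"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {"condition": [conditions[c] for c in cond_of_sample],
         "replicate": [int(r % n_rep) + 1 for r in range(len(samples))]},
        index=pd.Index(samples, name="sample"),
    )
    truth = SyntheticTruth(seed=int(seed))
    for g, row in zip(genes, mu):
        cv = float(np.std(row, ddof=1) / np.mean(row)) if n_cond > 1 else 0.0
        truth.gene_params[g.gene_id] = {
            "mu_by_condition": dict(g.mu_by_condition),
            "dispersion": g.dispersion,
        }
        truth.true_mean_cv[g.gene_id] = cv
    truth.loading_shifts = {s: float(f) for s, f in zip(samples, lib)}
    truth.expected_stability_order = sorted(
        truth.true_mean_cv, key=lambda gid: (truth.true_mean_cv[gid], gid)
    )
    return CountMatrix(values, sample_meta=meta), truth


def default_gene_panel() -> list[CtGeneSpec]:
    """Seven-gene validation panel: five stable candidates plus two
    classically used but condition-regulated genes (actin- and sar1-like).

    Condition-effect SDs (cycles): the five candidates 0.05-0.15, the
    actin analogue 0.8 and the sar1 analogue 1.2, with 0.15 biological and
    0.10 technical replicate noise for all genes.
    """
    noise = dict(bio_sd=0.15, tech_sd=0.10)
    return [
        CtGeneSpec("bzp1", base_ct=26.0, cond_sd=0.05, **noise),
        CtGeneSpec("tpc1", base_ct=24.0, cond_sd=0.08, **noise),
        CtGeneSpec("ubi1", base_ct=23.0, cond_sd=0.10, **noise),
        CtGeneSpec("sas3", base_ct=25.0, cond_sd=0.12, **noise),
        CtGeneSpec("cue1", base_ct=25.0, cond_sd=0.15, **noise),
        CtGeneSpec("act1", base_ct=20.0, cond_sd=0.80, **noise),
        CtGeneSpec("sar1", base_ct=22.0, cond_sd=1.20, **noise),
    ]


def default_count_panel(
    n_genes: int = 2000,
    n_stable: int = 25,
    n_conditions: int = 14,
    seed: int = 0,
) -> tuple[list[CountGeneSpec], list[str]]:
    """Count-matrix panel emulating a heterogeneous public-dataset compendium.

    ``n_stable`` designated stable genes have a condition-constant mean drawn
    log-uniformly from [500, 5000] and dispersion 0.01; the remaining
    background genes get a base mean log-uniform in [10, 10^4], per-condition
    log-normal swings (natural-log SD 0.5) and dispersion uniform in
    [0.05, 0.2]. Returns (specs, stable gene ids).
    """
    if n_stable > n_genes:
        raise ValidationError("n_stable cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    conditions = [f"c{i + 1:02d}" for i in range(n_conditions)]
    specs: list[CountGeneSpec] = []
    stable_ids: list[str] = []
    for i in range(n_stable):
        gid = f"stable{i + 1:03d}"
        mu = float(10 ** rng.uniform(np.log10(500), np.log10(5000)))
        specs.append(CountGeneSpec(gid, {c: mu for c in conditions}, dispersion=0.01))
        stable_ids.append(gid)
    for i in range(n_genes - n_stable):
        gid = f"g{i + 1:04d}"
        base = float(10 ** rng.uniform(1, 4))
        swings = np.exp(rng.normal(0.0, 0.5, size=n_conditions))
        mu = {c: float(base * s) for c, s in zip(conditions, swings)}
        specs.append(CountGeneSpec(gid, mu, dispersion=float(rng.uniform(0.05, 0.2))))
    return specs, stable_ids
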