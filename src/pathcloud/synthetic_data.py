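"""Synthetic young/old cohorts, pathway clouds and drug libraries.

Everything the scoring and screening pipeline consumes can be generated
here with known ground truth, so the whole package is testable without
external downloads.  The generative model:

* per-gene baseline intensities are log-normal (``exp(N(log_mean,
  log_sd))``), a standard positive-valued expression model;
* young samples are i.i.d. draws of the baseline times log-scale
  measurement noise ``exp(N(0, noise_sd))``;
* old samples additionally carry planted per-pathway fold-shifts applied
  coherently with each member's ARR sign — for an "activated" pathway,
  activators go up by the fold and repressors down by its reciprocal
  (reversed for "repressed") — emulating coordinated pathway activation
  and down-regulation during aging;
* the drug library contains an exact antidote (reciprocal fold-changes to
  every planted shift), a partial antidote, random-target distractors and
  a null drug, all labelled in the truth record.

Pathways are non-overlapping gene blocks by default so planted PAS signal
is attributable to a single pathway.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .drug_screen import DrugProfile, DrugTargetEffect, write_drug_library
from .expression_data import ExpressionStudy, write_expression
from .pathway_model import GeneRole, PathwayCloud, RoleAnnotatedPathway, write_pathway_file

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_study",
    "simulate_drug_library",
    "write_fixture_dir",
]

DIRECTIONS = ("activated", "repressed")

#: ARR weights sampled for pathway members and their probabilities.  Zero
#: weights are excluded: a planted shift direction is undefined for genes
#: that are both activator and repressor.
_ARR_CHOICES = (1.0, -1.0, 0.5, -0.5)
_ARR_PROBS = (0.4, 0.3, 0.15, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults describe the reference screening experiment: a 50-gene
    transcriptome, five non-overlapping 8-gene pathways, five young and
    five old samples, one pathway planted "activated" with a 4-fold shift,
    no measurement noise, and a 12-drug library (10 random distractors,
    the exact antidote, a null drug; a partial antidote can be added).
    """

    n_genes: int = 50
    n_young: int = 5
    n_old: int = 5
    n_pathways: int = 5
    genes_per_pathway: int = 8
    log_mean: float = 3.0   # natural-log mean of baseline intensities
    log_sd: float = 1.0     # natural-log SD of baseline intensities
    noise_sd: float = 0.0   # log-scale measurement noise SD
    n_perturbed: int = 1
    fold_shift: float = 4.0
    direction: str = "activated"
    n_distractors: int = 10
    targets_per_drug: int = 3
    include_antidote: bool = True
    include_partial_antidote: bool = False
    include_null: bool = True
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_young", "n_old", "n_pathways",
                     "genes_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_young < 2:
            raise ValueError("need at least 2 young samples")
        if self.fold_shift <= 0:
            raise ValueError("fold_shift must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.n_perturbed > self.n_pathways:
            raise ValueError("cannot perturb more pathways than exist")
        if (not self.allow_overlap
                and self.genes_per_pathway * self.n_pathways > self.n_genes):
            raise ValueError(
                "genes_per_pathway * n_pathways exceeds n_genes with "
                "overlap disabled"
            )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``gene_shift`` maps each perturbed gene to its planted multiplicative
    shift; this is also the expected OYR of that gene (noise is mean-zero
    on the log scale, so the observed OYR fluctuates around it).
    ``drug_labels`` is filled by :func:`simulate_drug_library`.
    """

    seed: int
    perturbed: dict[str, tuple[str, float]]  # pathway_id -> (direction, fold)
    gene_shift: dict[str, float]
    drug_labels: dict[str, str] = field(default_factory=dict)

    @property
    def expected_oyr(self) -> Mapping[str, float]:
        return dict(self.gene_shift)


def simulate_study(config: SimulationConfig,
                   ) -> tuple[ExpressionStudy, PathwayCloud, SimulationTruth]:
    """Generate a young/old study, its pathway cloud and the ground truth.

    Deterministic in ``config.seed``: the same config always yields
    identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    # Pathway membership: random non-overlapping blocks by default.
    if config.allow_overlap:
        membership = [
            sorted(rng.choice(config.n_genes, size=config.genes_per_pathway,
                              replace=False))
            for _ in range(config.n_pathways)
        ]
    else:
        permuted = rng.permutation(config.n_genes)
        membership = [
            sorted(permuted[i * config.genes_per_pathway:
                            (i + 1) * config.genes_per_pathway])
            for i in range(config.n_pathways)
        ]

    pathways = []
    for p, rows in enumerate(membership):
        arr = rng.choice(_ARR_CHOICES, size=len(rows), p=_ARR_PROBS)
        members = tuple(
            GeneRole(gene=genes[row], arr=float(a))
            for row, a in zip(rows, arr)
        )
        pathways.append(
            RoleAnnotatedPathway(
                pathway_id=f"PW{p:02d}", name=f"simulated pathway {p}",
                members=members,
            )
        )
    cloud = PathwayCloud(
        pathways=tuple(pathways),
        provenance=f"simulated (seed={config.seed})",
    )

    # Planted perturbations: fold-shift coherent with each member's ARR sign.
    perturbed_idx = sorted(
        rng.choice(config.n_pathways, size=config.n_perturbed, replace=False)
    )
    shift = np.ones(config.n_genes)
    perturbed: dict[str, tuple[str, float]] = {}
    for p in perturbed_idx:
        pathway = pathways[p]
        perturbed[pathway.pathway_id] = (config.direction, config.fold_shift)
        up = config.direction == "activated"
        for member in pathway.members:
            row = genes.index(member.gene)
            raise_gene = (member.arr > 0) == up
            shift[row] *= (config.fold_shift if raise_gene
                           else 1.0 / config.fold_shift)

    baseline = np.exp(
        rng.normal(config.log_mean, config.log_sd, size=config.n_genes)
    )

    def noisy(n_samples: int) -> np.ndarray:
        if config.noise_sd == 0:
            return np.ones((config.n_genes, n_samples))
        return np.exp(
            rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        )

    young = baseline[:, None] * noisy(config.n_young)
    old = (baseline * shift)[:, None] * noisy(config.n_old)

    young_ids = [f"young_{i:02d}" for i in range(config.n_young)]
    old_ids = [f"old_{i:02d}" for i in range(config.n_old)]
    study = ExpressionStudy(
        genes=tuple(genes),
        samples=tuple(young_ids + old_ids),
        values=np.hstack([young, old]),
        cohort={**{s: "young" for s in young_ids},
                **{s: "old" for s in old_ids}},
    )
    truth = SimulationTruth(
        seed=config.seed,
        perturbed=perturbed,
        gene_shift={
            genes[i]: float(shift[i])
            for i in range(config.n_genes) if shift[i] != 1.0
        },
    )
    return study, cloud, truth


def simulate_drug_library(truth: SimulationTruth,
                          config: SimulationConfig) -> list[DrugProfile]:
    """Generate the drug library matching a simulated study.

    Contains, per the config: the exact antidote (reciprocal of every
    planted gene shift), an optional partial antidote (half the targets),
    ``n_distractors`` random-target drugs with fold-changes in {0.5, 2},
    and a null drug (all fold-changes 1).  Labels are written into
    ``truth.drug_labels``.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng([config.seed % (2 ** 31), 7919])
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    shifted = sorted(truth.gene_shift)
    drugs: list[DrugProfile] = []
    labels: dict[str, str] = {}

    if config.include_antidote:
        drugs.append(DrugProfile(
            drug_id="antidote",
            effects=tuple(
                DrugTargetEffect(gene=g, fold_change=1.0 / truth.gene_shift[g])
                for g in shifted
            ),
        ))
        labels["antidote"] = "antidote"
    if config.include_partial_antidote and len(shifted) >= 2:
        half = shifted[: len(shifted) // 2]
        drugs.append(DrugProfile(
            drug_id="antidote_partial",
            effects=tuple(
                DrugTargetEffect(gene=g, fold_change=1.0 / truth.gene_shift[g])
                for g in half
            ),
        ))
        labels["antidote_partial"] = "partial_antidote"
    for d in range(config.n_distractors):
        targets = rng.choice(config.n_genes,
                             size=min(config.targets_per_drug, config.n_genes),
                             replace=False)
        folds = rng.choice([0.5, 2.0], size=len(targets))
        drug_id = f"distractor_{d:02d}"
        drugs.append(DrugProfile(
            drug_id=drug_id,
            effects=tuple(
                DrugTargetEffect(gene=genes[t], fold_change=float(f))
                for t, f in zip(sorted(targets), folds)
            ),
        ))
        labels[drug_id] = "distractor"
    if config.include_null:
        null_targets = shifted or genes[:1]
        drugs.append(DrugProfile(
            drug_id="null",
            effects=tuple(
                DrugTargetEffect(gene=g, fold_change=1.0) for g in null_targets
            ),
        ))
        labels["null"] = "null"

    truth.drug_labels = labels
    return drugs


def write_fixture_dir(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Simulate a study and write all pipeline inputs to a directory.

    Writes ``expr.tsv``, ``meta.tsv``, ``cloud.tsv``, ``drugs.tsv`` and
    ``truth.json`` (config, perturbations, per-gene shifts, drug labels).
    Returns the directory path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study, cloud, truth = simulate_study(config)
    drugs = simulate_drug_library(truth, config)
    write_expression(study, out_dir / "expr.tsv", out_dir / "meta.tsv")
    write_pathway_file(cloud, out_dir / "cloud.tsv")
    write_drug_library(drugs, out_dir / "drugs.tsv")
    payload = {
        "config": dataclasses.asdict(config),
        "seed": truth.seed,
        "perturbed_pathways": {
            pid: {"direction": direction, "fold": fold}
            for pid, (direction, fold) in truth.perturbed.items()
        },
        "gene_shift": truth.gene_shift,
        "drug_labels": truth.drug_labels,
    }
    (out_dir / "truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out_dir
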