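"""In-silico drug application and geroprotector ranking.

A drug is modelled as multiplicative fold-changes on the expression of its
target genes (< 1 inhibition, > 1 activation) — the minimal transcriptome
model for compounds with known molecular targets.  Applying a drug rescales
the *old* samples only; the screen then rescores the treated study and
ranks drugs (and, optionally, unordered pairs, combined as the gene-wise
product of fold-changes) by the treated cumulative disturbance ``D`` of the
mean-of-old PAS profile — the best geroprotector candidate is the one that
brings the pathway-cloud activation pattern of old samples closest to the
young state (all PAS values near zero).

Ranking by treated D and ranking by disturbance reduction delta give the
same order for a fixed study; treated D is used because it stays
well-defined when baselines differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression_data import ExpressionStudy
from .pas_engine import ScoringConfig, score_study
from .pathway_model import PathwayCloud

__all__ = [
    "DrugTargetEffect",
    "DrugProfile",
    "RankedDrug",
    "read_drug_library",
    "write_drug_library",
    "apply_drug",
    "combine_drugs",
    "screen_drugs",
    "report_screen",
    "read_screen_report",
]

#: Default fold-changes when a library gives only a direction.
DIRECTION_FOLDS = {"inhibit": 0.5, "activate": 2.0}

#: Pair screening is exhaustive; refuse libraries beyond this size.
DEFAULT_MAX_PAIR_LIBRARY = 200


@dataclass(frozen=True)
class DrugTargetEffect:
    """Multiplicative effect of a drug on one target gene."""

    gene: str
    fold_change: float

    def __post_init__(self) -> None:
        gene = self.gene.strip().upper()
        if not gene:
            raise ValueError("target gene must be non-empty")
        object.__setattr__(self, "gene", gene)
        fc = float(self.fold_change)
        if not (fc > 0 and np.isfinite(fc)):
            raise ValueError(
                f"fold_change must be positive and finite, got {self.fold_change!r}"
            )
        object.__setattr__(self, "fold_change", fc)


@dataclass(frozen=True)
class DrugProfile:
    """A drug's target genes with their fold-change effects."""

    drug_id: str
    effects: tuple[DrugTargetEffect, ...]

    def __post_init__(self) -> None:
        if not self.drug_id.strip():
            raise ValueError("drug_id must be non-empty")
        effects = tuple(self.effects)
        genes = [e.gene for e in effects]
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(
                f"drug {self.drug_id}: multiple effects on gene(s) {', '.join(dup)}"
            )
        object.__setattr__(self, "effects", effects)

    @property
    def fold_by_gene(self) -> dict[str, float]:
        return {e.gene: e.fold_change for e in self.effects}


@dataclass(frozen=True)
class RankedDrug:
    """One row of a screening ranking."""

    drug_id: str
    baseline_disturbance: float
    treated_disturbance: float
    delta: float  # baseline - treated, exactly
    rank: int


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def read_drug_library(path: str | Path) -> list[DrugProfile]:
    """Read a drug-library TSV.

    Columns: ``drug_id``, ``gene`` and either ``fold_change`` (positive
    float) or ``direction`` in {inhibit, activate} mapped to the default
    folds 0.5 / 2.0.
    """
    table = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene": str},
                        keep_default_na=False)
    for col in ("drug_id", "gene"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "fold_change" in table.columns:
        folds = table["fold_change"].astype(float)
    elif "direction" in table.columns:
        unknown = set(table["direction"]) - set(DIRECTION_FOLDS)
        if unknown:
            raise ValueError(
                f"{path}: unknown direction(s) {sorted(unknown)}; "
                f"expected {sorted(DIRECTION_FOLDS)}"
            )
        folds = table["direction"].map(DIRECTION_FOLDS)
    else:
        raise ValueError(f"{path}: need a 'fold_change' or 'direction' column")

    profiles: list[DrugProfile] = []
    for drug_id, group in table.assign(_fold=folds).groupby("drug_id", sort=False):
        effects = tuple(
            DrugTargetEffect(gene=g, fold_change=f)
            for g, f in zip(group["gene"], group["_fold"])
        )
        profiles.append(DrugProfile(drug_id=str(drug_id), effects=effects))
    if not profiles:
        raise ValueError(f"{path}: empty drug library")
    return profiles


def write_drug_library(drugs: Sequence[DrugProfile], path: str | Path) -> None:
    rows = [
        {"drug_id": d.drug_id, "gene": e.gene, "fold_change": e.fold_change}
        for d in drugs
        for e in d.effects
    ]
    pd.DataFrame(rows, columns=["drug_id", "gene", "fold_change"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Drug application and screening
# ---------------------------------------------------------------------------

def apply_drug(study: ExpressionStudy, drug: DrugProfile) -> ExpressionStudy:
    """Apply a drug to the old samples of a study.

    Each measured target gene's value is multiplied by its fold-change in
    every *old* sample; young samples are untouched.  Returns a new study
    (the input is not modified); unmeasured targets are skipped.
    """
    values = study.values.copy()
    gene_index = {g: i for i, g in enumerate(study.genes)}
    old_cols = [study.sample_index(s) for s in study.old_samples]
    for effect in drug.effects:
        row = gene_index.get(effect.gene)
        if row is None:
            continue
        values[row, old_cols] *= effect.fold_change
    return study.with_values(values)


def combine_drugs(first: DrugProfile, second: DrugProfile,
                  drug_id: str | None = None) -> DrugProfile:
    """Combine two drugs by gene-wise product of fold-changes."""
    folds = dict(first.fold_by_gene)
    for gene, fold in second.fold_by_gene.items():
        folds[gene] = folds.get(gene, 1.0) * fold
    combined_id = drug_id or "+".join(sorted((first.drug_id, second.drug_id)))
    return DrugProfile(
        drug_id=combined_id,
        effects=tuple(
            DrugTargetEffect(gene=g, fold_change=f)
            for g, f in sorted(folds.items())
        ),
    )


def screen_drugs(study: ExpressionStudy, cloud: PathwayCloud,
                 drugs: Sequence[DrugProfile],
                 config: ScoringConfig = ScoringConfig(),
                 pairs: bool = False,
                 max_pair_library: int = DEFAULT_MAX_PAIR_LIBRARY,
                 ) -> list[RankedDrug]:
    """Rank drugs (and optionally unordered pairs) by treated disturbance.

    Every candidate is applied to the old samples, the study is rescored,
    and candidates are sorted by ascending treated D (mean-of-old profile
    under the configured norm), ties broken by drug_id.  The no-drug
    baseline D is reported in every row.
    """
    if not drugs:
        raise ValueError("need at least one drug to screen")
    ids = [d.drug_id for d in drugs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate drug_id(s): {', '.join(dup)}")
    if len(cloud) == 0:
        raise ValueError("empty pathway cloud: nothing to score")
    if pairs and len(drugs) > max_pair_library:
        raise ValueError(
            f"pair screening capped at {max_pair_library} drugs "
            f"({len(drugs)} given)"
        )

    baseline = score_study(study, cloud, config).mean_disturbance

    candidates: list[DrugProfile] = list(drugs)
    if pairs:
        candidates += [
            combine_drugs(a, b) for a, b in itertools.combinations(drugs, 2)
        ]

    scored = []
    for candidate in candidates:
        treated = score_study(
            apply_drug(study, candidate), cloud, config
        ).mean_disturbance
        scored.append((candidate.drug_id, treated))
    scored.sort(key=lambda item: (item[1], item[0]))
    return [
        RankedDrug(
            drug_id=drug_id,
            baseline_disturbance=baseline,
            treated_disturbance=treated,
            delta=baseline - treated,
            rank=rank,
        )
        for rank, (drug_id, treated) in enumerate(scored, start=1)
    ]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ("rank", "drug_id", "baseline_D", "treated_D", "delta")


def report_screen(ranking: Sequence[RankedDrug], path: str | Path) -> None:
    """Write a ranking as a deterministic TSV (header + one row per drug)."""
    if not ranking:
        raise ValueError("refusing to write an empty ranking")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in ranking:
            handle.write(
                f"{row.rank}\t{row.drug_id}\t{row.baseline_disturbance:.10g}"
                f"\t{row.treated_disturbance:.10g}\t{row.delta:.10g}\n"
            )


def read_screen_report(path: str | Path) -> list[RankedDrug]:
    """Read back a screening report (for round-trip checks and tooling)."""
    table = pd.read_csv(path, sep="\t", dtype={"drug_id": str},
                        keep_default_na=False)
    missing = set(_REPORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        RankedDrug(
            drug_id=str(row.drug_id),
            baseline_disturbance=float(row.baseline_D),
            treated_disturbance=float(row.treated_D),
            delta=float(row.delta),
            rank=int(row.rank),
        )
        for row in table.itertuples(index=False)
    ]
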