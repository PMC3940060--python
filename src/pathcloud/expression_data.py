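"""Expression matrices with young/old cohort labels.

The scoring engine compares each *old* sample against reference statistics
computed from the *young* cohort: the per-gene arithmetic mean (the
denominator of the old-to-young ratio) and the per-gene sample standard
deviation (the yardstick of the 2-SD tolerance criterion).  Expression
values are linear-scale, non-negative intensities; at least two young
samples are required so the SD is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "ExpressionStudy",
    "YoungReference",
    "read_expression",
    "write_expression",
    "normalize",
    "young_reference",
]

COHORTS = ("young", "old")
NORMALIZATION_METHODS = ("none", "median_scale", "quantile")


@dataclass(frozen=True)
class ExpressionStudy:
    """Gene x sample expression matrix plus cohort assignment.

    Invariants enforced at construction: values are finite and >= 0, gene
    and sample identifiers are unique, every sample has a cohort label in
    ``{"young", "old"}``, and there are >= 2 young and >= 1 old samples.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples)
    cohort: Mapping[str, str]

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        samples = tuple(str(s) for s in self.samples)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(genes)) != len(genes):
            raise ValueError("gene symbols must be unique")
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        cohort = dict(self.cohort)
        missing = [s for s in samples if s not in cohort]
        if missing:
            raise ValueError(f"samples without cohort label: {missing}")
        bad = sorted({c for c in cohort.values() if c not in COHORTS})
        if bad:
            raise ValueError(
                f"cohort labels must be in {COHORTS}, found {bad}"
            )
        n_young = sum(1 for s in samples if cohort[s] == "young")
        n_old = sum(1 for s in samples if cohort[s] == "old")
        if n_young < 2:
            raise ValueError(
                "need at least 2 young samples (young SD undefined otherwise)"
            )
        if n_old < 1:
            raise ValueError("need at least 1 old sample")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cohort", cohort)

    @property
    def young_samples(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.cohort[s] == "young")

    @property
    def old_samples(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.cohort[s] == "old")

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def sample_values(self, sample_id: str) -> np.ndarray:
        """Expression vector (per gene) of one sample."""
        return self.values[:, self.sample_index(sample_id)]

    def young_values(self) -> np.ndarray:
        cols = [self.sample_index(s) for s in self.young_samples]
        return self.values[:, cols]

    def with_values(self, values: np.ndarray) -> "ExpressionStudy":
        """Copy of the study with a replaced value matrix."""
        return ExpressionStudy(
            genes=self.genes,
            samples=self.samples,
            values=np.asarray(values, dtype=float),
            cohort=dict(self.cohort),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes),
                            columns=list(self.samples))


@dataclass(frozen=True)
class YoungReference:
    """Per-gene mean and sample SD (ddof=1) over the young cohort."""

    genes: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (len(self.genes),) or sd.shape != (len(self.genes),):
            raise ValueError("mean/sd must be one value per gene")
        if np.any(mean < 0) or np.any(sd < 0):
            raise ValueError("young mean and SD must be non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    def for_gene(self, gene: str) -> tuple[float, float]:
        i = self.genes.index(gene)
        return float(self.mean[i]), float(self.sd[i])


def young_reference(study: ExpressionStudy) -> YoungReference:
    """Per-gene arithmetic mean and sample SD over young samples only.

    The SD uses the n-1 denominator; sample order does not matter.
    """
    young = study.young_values()
    return YoungReference(
        genes=study.genes,
        mean=young.mean(axis=1),
        sd=young.std(axis=1, ddof=1),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path,
                    metadata_path: str | Path) -> ExpressionStudy:
    """Read an expression TSV and its sample metadata TSV.

    The matrix has a ``gene`` first column and one column per sample; the
    metadata has columns ``sample_id`` and ``cohort``.  Samples present in
    the matrix but absent from the metadata are an error, as are negative
    values, unknown cohort labels and fewer than 2 young samples.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if matrix.columns[0] != "gene":
        raise ValueError(
            f"{matrix_path}: first column must be 'gene', "
            f"found {matrix.columns[0]!r}"
        )
    matrix = matrix.set_index("gene")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str,
                       keep_default_na=False)
    for col in ("sample_id", "cohort"):
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: missing column {col!r}")
    cohort = dict(zip(meta["sample_id"], meta["cohort"]))
    unlabeled = [s for s in matrix.columns if s not in cohort]
    if unlabeled:
        raise ValueError(
            f"samples in matrix but not in metadata: {unlabeled}"
        )
    return ExpressionStudy(
        genes=tuple(matrix.index),
        samples=tuple(matrix.columns),
        values=matrix.to_numpy(dtype=float),
        cohort={s: cohort[s] for s in matrix.columns},
    )


def write_expression(study: ExpressionStudy,
                     matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    """Write a study as matrix + metadata TSVs (inverse of read_expression)."""
    frame = study.to_frame()
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame({
        "sample_id": list(study.samples),
        "cohort": [study.cohort[s] for s in study.samples],
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(study: ExpressionStudy, method: str = "none") -> ExpressionStudy:
    """Normalize all samples jointly.

    ``none``
        Identity; the study is assumed pre-normalized (the default contract).
    ``median_scale``
        Rescale each sample so all sample medians equal the median of the
        sample medians (lower median on even counts, so with two samples
        the larger one is scaled down to the smaller's median).
    ``quantile``
        Classic quantile normalization: each sample's sorted values are
        replaced by the mean sorted profile across samples.
    """
    if method == "none":
        return study
    if method == "median_scale":
        medians = np.median(study.values, axis=0)
        if np.any(medians <= 0):
            raise ValueError("median_scale requires positive sample medians")
        target = float(np.sort(medians)[(len(medians) - 1) // 2])
        return study.with_values(study.values * (target / medians))
    if method == "quantile":
        order = np.argsort(study.values, axis=0, kind="stable")
        sorted_values = np.take_along_axis(study.values, order, axis=0)
        reference = sorted_values.mean(axis=1)
        out = np.empty_like(study.values)
        np.put_along_axis(out, order, reference[:, None], axis=0)
        return study.with_values(out)
    raise ValueError(
        f"unknown normalization method {method!r}; "
        f"expected one of {NORMALIZATION_METHODS}"
    )
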