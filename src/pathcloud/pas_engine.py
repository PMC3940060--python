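"""Pathway activation scoring: OYR, BTIF, PAS, SPCD and cloud disturbance.

The model treats every activator/repressor gene of a pathway as equally
important (signal-transduction proteins operate far from saturation, so a
linear approximation is adequate).  The multiplicative disturbance
estimator for one pathway is

    SPCD = prod_i AGEL_i / prod_j RGEL_j

where ``AGEL``/``RGEL`` are expression levels of activators and repressors.
Taking logarithms turns this into the additive *pathway activation
strength*:

    PAS_p = sum_n ARR_n * BTIF_n * log(OYR_n)

with, per member gene *n*,

* ``OYR``  -- old-to-young ratio: old expression level divided by the mean
  expression of the normalized young cohort (floored at ``epsilon`` on both
  sides, so it is strictly positive);
* ``BTIF`` -- beyond-tolerance-interval flag: 1 only when the OYR lies
  outside (2/3, 3/2) *and* the old level deviates from the young mean by
  more than two young-cohort standard deviations (both strict);
* ``ARR``  -- the discrete activator/repressor weight in
  {-1, -0.5, 0, 0.5, 1}.

A sample's *disturbance* ``D`` is an L1 or L2 norm of its PAS vector over
the cloud; the screening objective downstream is to drive ``D`` toward
zero.  Old samples are scored individually and averaged at the PAS level
("mean-of-old" profile), preserving per-patient profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_data import ExpressionStudy, YoungReference, young_reference
from .pathway_model import PathwayCloud, RoleAnnotatedPathway

__all__ = [
    "ScoringConfig",
    "GeneScore",
    "PASProfile",
    "DisturbanceReport",
    "compute_oyr",
    "compute_btif",
    "compute_gene_scores",
    "compute_pas",
    "compute_spcd",
    "compute_disturbance",
    "score_study",
    "MEAN_OF_OLD",
]

#: Profile id used for the cohort-level (PAS-averaged) profile.
MEAN_OF_OLD = "mean-of-old"

UPPER_TOLERANCE = 1.5       # OYR above this is out of tolerance
LOWER_TOLERANCE = 2.0 / 3.0  # OYR below this is out of tolerance
SD_MULTIPLE = 2.0            # deviation must exceed this many young SDs

NORMS = ("L1", "L2")
ZERO_SD_POLICIES = ("infinite", "always_fail")


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable knobs of the scoring engine.

    epsilon
        Expression floor applied before ratios and logarithms so OYR is
        strictly positive and finite (handles zero intensities).
    log_base
        Base of the PAS logarithm.  Changing it rescales every PAS by a
        constant factor, so rankings are unaffected; 10 by default.
    norm
        Disturbance norm over the PAS vector: "L1" (sum of absolute
        values, default) or "L2" (Euclidean).
    zero_sd_policy
        What the 2-SD criterion means when the young SD is 0:
        "infinite" (default) treats any nonzero deviation as infinitely
        many SDs, so the criterion passes; "always_fail" makes it fail.
    """

    epsilon: float = 1e-6
    log_base: float = 10.0
    norm: str = "L1"
    zero_sd_policy: str = "infinite"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        if self.norm not in NORMS:
            raise ValueError(f"norm must be one of {NORMS}")
        if self.zero_sd_policy not in ZERO_SD_POLICIES:
            raise ValueError(
                f"zero_sd_policy must be one of {ZERO_SD_POLICIES}"
            )


@dataclass(frozen=True)
class GeneScore:
    """Per-gene scoring record for one old sample."""

    gene: str
    oyr: float
    btif: int
    deviation_sd: float


@dataclass(frozen=True)
class PASProfile:
    """Per-pathway activation strengths for one old sample (or mean-of-old)."""

    sample_id: str
    pas: Mapping[str, float]

    def values_array(self) -> np.ndarray:
        return np.array(list(self.pas.values()), dtype=float)


@dataclass(frozen=True)
class DisturbanceReport:
    """Scoring output: per-sample profiles, cohort profile and disturbances."""

    profiles: tuple[PASProfile, ...]
    mean_profile: PASProfile
    disturbance: Mapping[str, float]   # sample id (incl. mean-of-old) -> D
    norm: str
    skipped_genes: Mapping[str, int]   # pathway -> members absent from study
    unmeasured_pathways: tuple[str, ...]

    @property
    def mean_disturbance(self) -> float:
        """Disturbance of the mean-of-old profile (the screening objective)."""
        return float(self.disturbance[MEAN_OF_OLD])

    def to_frame(self) -> pd.DataFrame:
        """Pathways x (per-sample PAS, pas_mean) table."""
        data = {p.sample_id: list(p.pas.values()) for p in self.profiles}
        data["pas_mean"] = list(self.mean_profile.pas.values())
        index = list(self.mean_profile.pas.keys())
        return pd.DataFrame(data, index=pd.Index(index, name="pathway_id"))


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def compute_oyr(old_value: float, young_mean: float,
                floor: float = 1e-6) -> float:
    """Old-to-young expression ratio with an epsilon floor.

    Both the old level and the young mean are floored at ``floor`` before
    dividing, so the result is strictly positive and finite.
    """
    if old_value < 0 or young_mean < 0:
        raise ValueError("expression levels must be non-negative")
    return max(float(old_value), floor) / max(float(young_mean), floor)


def _deviation_sd(old_value: float, young_mean: float, young_sd: float,
                  zero_sd_policy: str = "infinite") -> float:
    """Deviation of the old level from the young mean, in young-SD units."""
    diff = abs(float(old_value) - float(young_mean))
    if young_sd > 0:
        return diff / float(young_sd)
    if diff == 0:
        return 0.0
    return math.inf if zero_sd_policy == "infinite" else 0.0


def compute_btif(oyr: float, old_value: float, young_mean: float,
                 young_sd: float,
                 zero_sd_policy: str = "infinite") -> int:
    """Beyond-tolerance-interval flag for one gene.

    Returns 1 iff the two criteria hold simultaneously, with strict
    inequalities: the ratio is above 3/2 or below 2/3, and the old level
    differs from the young mean by more than two young SDs.  A ratio of
    exactly 3/2 or 2/3 is within tolerance.
    """
    if young_sd < 0:
        raise ValueError("young SD must be non-negative")
    outside = oyr > UPPER_TOLERANCE or oyr < LOWER_TOLERANCE
    deviated = _deviation_sd(
        old_value, young_mean, young_sd, zero_sd_policy
    ) > SD_MULTIPLE
    return int(outside and deviated)


def compute_gene_scores(old_values: Sequence[float] | np.ndarray,
                        reference: YoungReference,
                        config: ScoringConfig = ScoringConfig(),
                        ) -> dict[str, GeneScore]:
    """Score every gene of one old sample against the young reference."""
    old = np.asarray(old_values, dtype=float)
    if old.shape != (len(reference.genes),):
        raise ValueError("old sample must have one value per reference gene")
    if np.any(old < 0):
        raise ValueError("expression levels must be non-negative")
    eps = config.epsilon
    oyr = np.maximum(old, eps) / np.maximum(reference.mean, eps)
    diff = np.abs(old - reference.mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(reference.sd > 0, diff / reference.sd, 0.0)
    zero_sd = reference.sd == 0
    if config.zero_sd_policy == "infinite":
        dev = np.where(zero_sd & (diff > 0), np.inf, dev)
    outside = (oyr > UPPER_TOLERANCE) | (oyr < LOWER_TOLERANCE)
    btif = (outside & (dev > SD_MULTIPLE)).astype(int)
    return {
        gene: GeneScore(gene=gene, oyr=float(oyr[i]), btif=int(btif[i]),
                        deviation_sd=float(dev[i]))
        for i, gene in enumerate(reference.genes)
    }


# ---------------------------------------------------------------------------
# Pathway-level quantities
# ---------------------------------------------------------------------------

def compute_pas(pathway: RoleAnnotatedPathway,
                scores: Mapping[str, GeneScore],
                log_base: float = 10.0) -> float:
    """Pathway activation strength: sum of ARR * BTIF * log(OYR).

    Member genes absent from ``scores`` (unmeasured) are skipped; the
    caller counts them.  The result is 0 when no member is beyond
    tolerance, positive when flagged activators are up / repressors down,
    and finite because OYR is floored away from zero.
    """
    log_b = math.log(log_base)
    total = 0.0
    for member in pathway.members:
        score = scores.get(member.gene)
        if score is None:
            continue
        if score.btif:
            total += member.arr * math.log(score.oyr) / log_b
    return total


def compute_spcd(activator_levels: Iterable[float],
                 repressor_levels: Iterable[float],
                 floor: float = 1e-6) -> float:
    """Multiplicative disturbance estimator for one pathway.

    Product of (floored) activator expression levels divided by the product
    of (floored) repressor levels.  Evaluated as exp of a log-sum so large
    pathways cannot overflow; its log equals the additive PAS form with all
    ARR at +/-1 and all flags raised.
    """
    log_total = 0.0
    for level in activator_levels:
        if level < 0:
            raise ValueError("expression levels must be non-negative")
        log_total += math.log(max(float(level), floor))
    for level in repressor_levels:
        if level < 0:
            raise ValueError("expression levels must be non-negative")
        log_total -= math.log(max(float(level), floor))
    return math.exp(log_total)


def compute_disturbance(profile: PASProfile | Sequence[float] | np.ndarray,
                        norm: str = "L1") -> float:
    """Cumulative disturbance D of a PAS vector: L1 or L2 norm.

    Zero iff every PAS value is zero.
    """
    if isinstance(profile, PASProfile):
        values = profile.values_array()
    else:
        values = np.asarray(profile, dtype=float)
    if norm == "L1":
        return float(np.sum(np.abs(values)))
    if norm == "L2":
        return float(np.sqrt(np.sum(values ** 2)))
    raise ValueError(f"unknown norm {norm!r}; expected one of {NORMS}")


# ---------------------------------------------------------------------------
# Study-level scoring
# ---------------------------------------------------------------------------

def score_study(study: ExpressionStudy, cloud: PathwayCloud,
                config: ScoringConfig = ScoringConfig()) -> DisturbanceReport:
    """Score every old sample of a study against a pathway cloud.

    Produces one PAS profile per old sample plus a mean-of-old profile
    (arithmetic mean of the per-sample PAS values, pathway-wise), and the
    cumulative disturbance D of each profile under the configured norm.
    Pathway members absent from the expression matrix are skipped and
    counted; pathways with no measured member score 0 and are flagged
    unmeasured.
    """
    if len(cloud) == 0:
        raise ValueError("empty pathway cloud: nothing to score")
    reference = young_reference(study)
    measured = set(study.genes)
    skipped = {
        p.pathway_id: sum(1 for g in p.member_genes if g not in measured)
        for p in cloud
    }
    unmeasured = tuple(
        p.pathway_id for p in cloud
        if all(g not in measured for g in p.member_genes)
    )

    profiles: list[PASProfile] = []
    for sample in study.old_samples:
        scores = compute_gene_scores(
            study.sample_values(sample), reference, config
        )
        pas = {
            p.pathway_id: compute_pas(p, scores, log_base=config.log_base)
            for p in cloud
        }
        profiles.append(PASProfile(sample_id=sample, pas=pas))

    mean_pas = {
        pid: float(np.mean([prof.pas[pid] for prof in profiles]))
        for pid in cloud.pathway_ids
    }
    mean_profile = PASProfile(sample_id=MEAN_OF_OLD, pas=mean_pas)

    disturbance = {
        prof.sample_id: compute_disturbance(prof, norm=config.norm)
        for prof in profiles
    }
    disturbance[MEAN_OF_OLD] = compute_disturbance(
        mean_profile, norm=config.norm
    )
    return DisturbanceReport(
        profiles=tuple(profiles),
        mean_profile=mean_profile,
        disturbance=disturbance,
        norm=config.norm,
        skipped_genes=skipped,
        unmeasured_pathways=unmeasured,
    )
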