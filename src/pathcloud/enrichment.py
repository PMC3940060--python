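"""Over-representation analysis (ORA) for building the pathway cloud.

Given a list of longevity-candidate genes and a collection of pathway gene
sets, each pathway is tested for over-representation with the
hypergeometric upper tail (the probability of drawing at least the
observed overlap when sampling the candidate list from the gene universe),
and p-values are adjusted with the Benjamini-Hochberg step-up FDR.

Thresholds follow the screening procedure this package implements: a
minimum overlap of 2 candidate genes and a 0.01 p-value cutoff by default.
The gene universe size is a required, explicit parameter: published
enrichment p-values depend on the source database's universe, so hiding a
default would make results irreproducible.

A bundled reference table (44 KEGG pathways with their background sizes
and overlaps against a 226-gene longevity candidate list) ships as package
data; ``build_reference_cloud`` synthesizes a pathway cloud realizing those
counts so the percentage computation can be exercised end to end.  Some
printed ``%`` cells of that reference table are inconsistent with their own
counts (e.g. Ribosome: 21/136 = 15.4 but printed 15.7), pointing to an
undisclosed effective background upstream; this module always recomputes
the percentage from the counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .pathway_model import GeneRole, PathwayCloud, RoleAnnotatedPathway

__all__ = [
    "ORAResult",
    "hypergeom_pvalue",
    "bh_fdr",
    "overlap_percent",
    "run_ora",
    "ora_to_frame",
    "load_reference_enrichment_table",
    "build_reference_cloud",
]

DEFAULT_MIN_OVERLAP = 2
DEFAULT_P_CUTOFF = 0.01


@dataclass(frozen=True)
class ORAResult:
    """One pathway's enrichment record."""

    pathway_id: str
    pathway_name: str
    background_count: int   # genes in the pathway
    overlap_count: int      # genes shared with the candidate list
    overlap_percent: float  # 100 * overlap / background, 1 decimal
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_count <= self.background_count):
            raise ValueError("overlap must lie in [0, background]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        if not (self.p_value <= self.fdr <= 1):
            raise ValueError("FDR must lie in [p, 1]")


def hypergeom_pvalue(universe_size: int, pathway_size: int,
                     list_size: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts candidate-list genes among the pathway's members when the
    list of ``list_size`` genes is drawn without replacement from a
    universe of ``universe_size`` genes of which ``pathway_size`` belong
    to the pathway.  The observed overlap is included in the tail, so the
    result lies in (0, 1] and equals 1 when overlap is 0.
    """
    n_universe, n_pathway = int(universe_size), int(pathway_size)
    n_list, k = int(list_size), int(overlap)
    if not (0 <= n_pathway <= n_universe and 0 <= n_list <= n_universe):
        raise ValueError("pathway and list sizes must lie in [0, universe]")
    if not (0 <= k <= min(n_pathway, n_list)):
        raise ValueError("overlap must lie in [0, min(pathway, list)]")
    return float(hypergeom.sf(k - 1, n_universe, n_pathway, n_list))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Empty input gives an empty list.  Adjusted values are never below the
    raw p-value and never above 1.
    """
    p = list(p_values)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def overlap_percent(overlap: int, background: int) -> float:
    """100 * overlap / background, rounded half-away-from-zero to 1 decimal.

    Integer arithmetic keeps the rounding exact (no binary-float half
    cases): the value in tenths of a percent is
    floor(1000 * overlap / background + 1/2).
    """
    if background <= 0:
        raise ValueError("background must be positive")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    tenths = (2000 * int(overlap) + int(background)) // (2 * int(background))
    return tenths / 10.0


def run_ora(gene_list: Iterable[str], cloud: PathwayCloud,
            universe_size: int,
            min_overlap: int = DEFAULT_MIN_OVERLAP,
            p_cutoff: float = DEFAULT_P_CUTOFF) -> list[ORAResult]:
    """Test every pathway of the cloud for over-representation.

    Pathways with overlap below ``min_overlap`` are excluded *before*
    testing; BH FDR is computed over all tested pathways; rows are then
    kept when p <= ``p_cutoff`` (so a cutoff of 1 disables the filter) and
    sorted by descending overlap percentage, then ascending p, then
    pathway_id.  Filters only remove rows — they never alter statistics.
    """
    genes = {g.strip().upper() for g in gene_list if g.strip()}
    if not genes:
        raise ValueError("empty gene list")
    list_size = len(genes)
    max_pathway = max((len(p) for p in cloud), default=0)
    if universe_size < max(max_pathway, list_size):
        raise ValueError(
            "universe size must be >= every pathway size and the list size"
        )

    tested: list[tuple[RoleAnnotatedPathway, int, float]] = []
    for pathway in cloud:
        overlap = sum(1 for g in pathway.member_genes if g in genes)
        if overlap < min_overlap:
            continue
        p = hypergeom_pvalue(universe_size, len(pathway), list_size, overlap)
        tested.append((pathway, overlap, p))

    adjusted = bh_fdr([p for _, _, p in tested])
    results = [
        ORAResult(
            pathway_id=pathway.pathway_id,
            pathway_name=pathway.name,
            background_count=len(pathway),
            overlap_count=overlap,
            overlap_percent=overlap_percent(overlap, len(pathway)),
            p_value=p,
            fdr=fdr,
        )
        for (pathway, overlap, p), fdr in zip(tested, adjusted)
        if p <= p_cutoff
    ]
    results.sort(
        key=lambda r: (-r.overlap_percent, r.p_value, r.pathway_id)
    )
    return results


def ora_to_frame(results: Sequence[ORAResult]) -> pd.DataFrame:
    """Tabulate ORA results (one row per pathway, enrichment columns)."""
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "pathway_name": [r.pathway_name for r in results],
            "background_genes": [r.background_count for r in results],
            "overlap": [r.overlap_count for r in results],
            "percent": [r.overlap_percent for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Bundled reference enrichment table
# ---------------------------------------------------------------------------

def load_reference_enrichment_table() -> pd.DataFrame:
    """Load the bundled 44-pathway longevity enrichment summary.

    Columns: pathway_id, pathway_name, background_genes (pathway size),
    candidate_overlap (overlap with the 226-gene longevity candidate
    list), and the published percent/p/FDR values for reference.
    """
    resource = importlib.resources.files("pathcloud").joinpath(
        "data/aging_pathway_enrichment.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return pd.read_csv(path, sep="\t")


def build_reference_cloud(list_size: int = 226,
                          ) -> tuple[PathwayCloud, frozenset[str]]:
    """Synthesize a cloud realizing the reference table's counts.

    Returns a synthetic pathway cloud plus a synthetic candidate gene list
    such that every pathway has exactly its published background size and
    overlap with the list.  Overlapping members are drawn from a shared
    pool of candidate symbols (``CAND0001``...), the remainder are
    pathway-private fillers; gene symbols carry no biological meaning.
    All ARR weights are set to 1 — ORA ignores roles.
    """
    table = load_reference_enrichment_table()
    max_overlap = int(table["candidate_overlap"].max())
    if list_size < max_overlap:
        raise ValueError("candidate list smaller than the largest overlap")
    candidates = [f"CAND{i:04d}" for i in range(1, list_size + 1)]
    pathways = []
    for row in table.itertuples(index=False):
        background = int(row.background_genes)
        overlap = int(row.candidate_overlap)
        shared = candidates[:overlap]
        private = [
            f"{row.pathway_id.upper()}_FILL{j:04d}"
            for j in range(1, background - overlap + 1)
        ]
        members = tuple(GeneRole(gene=g, arr=1.0) for g in shared + private)
        pathways.append(
            RoleAnnotatedPathway(
                pathway_id=str(row.pathway_id),
                name=str(row.pathway_name),
                members=members,
            )
        )
    cloud = PathwayCloud(
        pathways=tuple(pathways),
        provenance=(
            "synthetic cloud realizing the bundled reference enrichment "
            "counts (shared candidate pool + private filler genes)"
        ),
    )
    return cloud, frozenset(candidates)
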