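"""Tumor purity from somatic SNV read counts and purity-adjusted copy number.

Purity model: somatic SNVs are treated as heterozygous variants of a single
major clone.  A site with ``v`` variant reads out of ``n`` then implies that
``2v`` of the ``n`` reads came from tumor cells (``v`` variant plus ``v``
expected wild-type reads), so the per-site purity estimate is ``2 v / n``;
the sample estimate aggregates per-site values (median by default) and is
clipped to at most 1.  Samples without somatic SNVs fall back to the cohort
median.

Copy number: per-gene tumor/normal coverage fold ratios are normalized by
each library's total read bases, then corrected for the normal-cell
admixture by inverting the two-component mixture ``r = p*C/2 + (1-p)``:
``adj = (r - (1-p)) / p`` (floored at 0).  The adjusted ratio estimates
``C/2``; a gene is called gained at ``adj >= 2.0`` (``C >= 4``) and lost at
``adj <= 0.5`` (``C <= 1``), inclusive thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import GeneCoverageTable

logger = logging.getLogger(__name__)

DEFAULT_PURITY_FLOOR = 0.1


class PurityEstimationError(ValueError):
    """No somatic SNVs available and no cohort fallback supplied."""


@dataclass
class PurityEstimate:
    sample_id: str
    purity: float
    n_snvs_used: int
    method: str  # "snv_vaf" or "cohort_median_fallback"

    def __post_init__(self) -> None:
        if (self.method == "cohort_median_fallback") != (self.n_snvs_used == 0):
            raise ValueError("fallback method iff zero SNVs used")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass
class CnvThresholds:
    gain: float = 2.0
    loss: float = 0.5

    def validate(self) -> None:
        if not 0 <= self.loss < self.gain:
            raise ValueError("need 0 <= loss < gain")


@dataclass
class CopyCall:
    gene: str
    raw_ratio: float
    norm_ratio: float
    adj_ratio: float
    status: str  # gain / loss / neutral


def estimate_purity(
    snvs: list[tuple[int, int]],
    fallback_median: float | None = None,
    sample_id: str = "",
    agg: str = "median",
) -> PurityEstimate:
    """Purity from somatic SNV (variant_reads, depth) pairs.

    ``agg`` selects the aggregation across sites: ``median`` (default),
    ``mean``, or ``pooled`` (2 * sum(v) / sum(n), i.e. counts pooled before
    the heterozygote inversion).
    """
    if not snvs:
        if fallback_median is None:
            raise PurityEstimationError(
                f"sample {sample_id or '<unnamed>'}: no somatic SNVs and no cohort fallback"
            )
        return PurityEstimate(sample_id, fallback_median, 0, "cohort_median_fallback")
    if any(n <= 0 for _, n in snvs):
        raise ValueError("every SNV must have depth > 0")
    per_site = np.array([2.0 * v / n for v, n in snvs])
    if agg == "median":
        estimate = float(np.median(per_site))
    elif agg == "mean":
        estimate = float(per_site.mean())
    elif agg == "pooled":
        estimate = 2.0 * sum(v for v, _ in snvs) / sum(n for _, n in snvs)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    return PurityEstimate(sample_id, min(estimate, 1.0), len(snvs), "snv_vaf")


def cohort_median(estimates: list[PurityEstimate]) -> float:
    """Median purity over SNV-based estimates (even counts average the two
    central values); used as the fallback for samples without somatic SNVs."""
    values = [e.purity for e in estimates if e.method == "snv_vaf"]
    if not values:
        raise ValueError("no SNV-based purity estimates to take a median of")
    return float(np.median(values))


def normalized_fold_ratio(
    tumor: GeneCoverageTable, normal: GeneCoverageTable, gene: str
) -> float:
    """Tumor/normal fold ratio of per-gene read-base *proportions*, i.e.
    normalized for the total read bases obtained from each library."""
    if normal.read_bases.get(gene, 0) <= 0:
        raise ZeroDivisionError(f"gene {gene} has zero normal coverage")
    return tumor.proportion(gene) / normal.proportion(gene)


def adjust_for_purity(
    norm_ratio: float, purity: float, purity_floor: float = DEFAULT_PURITY_FLOOR
) -> float:
    """Invert the tumor/normal mixture so the ratio reflects tumor cells only.

    Below ``purity_floor`` the inversion amplifies coverage noise more than
    ten-fold and is refused.
    """
    if purity < purity_floor:
        raise ValueError(
            f"purity {purity:.3f} below floor {purity_floor}; adjustment unstable"
        )
    return max(0.0, (norm_ratio - (1.0 - purity)) / purity)


def call_cnv(adj_ratio: float, thresholds: CnvThresholds | None = None) -> str:
    thresholds = thresholds or CnvThresholds()
    thresholds.validate()
    if adj_ratio < 0:
        raise ValueError("adjusted ratio must be >= 0")
    if adj_ratio >= thresholds.gain:
        return "gain"
    if adj_ratio <= thresholds.loss:
        return "loss"
    return "neutral"


def call_gene_cnvs(
    tumor: GeneCoverageTable,
    normal: GeneCoverageTable,
    purity: float,
    thresholds: CnvThresholds | None = None,
    purity_floor: float = DEFAULT_PURITY_FLOOR,
    adjust: bool = True,
) -> list[CopyCall]:
    """Fold ratio, normalization, purity adjustment and gain/loss status for
    every gene in the coverage tables; zero-normal-coverage genes are
    excluded with a logged reason."""
    calls: list[CopyCall] = []
    for gene in tumor.read_bases:
        if normal.read_bases.get(gene, 0) <= 0:
            logger.warning("gene %s uncallable: zero normal coverage", gene)
            continue
        raw = tumor.read_bases[gene] / normal.read_bases[gene]
        norm = normalized_fold_ratio(tumor, normal, gene)
        adj = adjust_for_purity(norm, purity, purity_floor) if adjust else norm
        calls.append(CopyCall(gene, raw, norm, adj, call_cnv(adj, thresholds)))
    return calls
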