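"""Somatic SNV/indel detection and filtering for paired tumor/normal panels.

Detection applies three per-sample conditions to every non-reference allele
at a covered site: at least ``min_variant_reads`` supporting reads (default
2), mean base quality of the supporting reads at least ``min_mean_baseq``
(default phred 20), and allele fraction at least ``min_vaf`` (default 20%).
All thresholds are inclusive.

Somatic filtering then checks four conditions against the matched normal and
a polymorphism catalogue: (1) the variant is nonsynonymous coding; (2) the
variant allele count in the normal is zero; (3) the normal has at least 10
wild-type reads at the position; (4) the allele is not a known dbSNP
polymorphism.  Every candidate, accepted or not, carries a full audit of the
four decisions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .panel import GeneModel, PanelDesign, VariantPlacementError, apply_variant

logger = logging.getLogger(__name__)

#: Somatic filter conditions in the order they are evaluated and audited.
SOMATIC_CONDITIONS = (
    "nonsynonymous",
    "normal_variant_zero",
    "normal_wildtype_depth",
    "not_in_dbsnp",
)

NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "inframe_indel"})


@dataclass
class CallingThresholds:
    """Inclusive thresholds for detection (first three fields) and for the
    matched-normal somatic conditions (last two)."""

    min_variant_reads: int = 2
    min_mean_baseq: float = 20.0
    min_vaf: float = 0.20
    min_normal_wt_reads: int = 10
    max_normal_variant_reads: int = 0

    def validate(self) -> None:
        for name in (
            "min_variant_reads",
            "min_mean_baseq",
            "min_vaf",
            "min_normal_wt_reads",
            "max_normal_variant_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.min_vaf <= 1:
            raise ValueError("min_vaf must be in [0, 1]")


@dataclass
class VariantCandidate:
    """A non-reference allele passing per-sample detection."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_reads: int
    depth: int
    mean_baseq: float

    @property
    def vaf(self) -> float:
        return self.variant_reads / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SomaticCall:
    """A tumor candidate with matched-normal evidence and its filter audit."""

    candidate: VariantCandidate
    normal_variant_reads: int
    normal_wt_reads: int
    in_dbsnp: bool
    gene: str | None
    consequence: str
    nmd_predicted: bool
    filter_audit: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return all(ok for _, ok in self.filter_audit)

    @property
    def first_failed_condition(self) -> str | None:
        for condition, ok in self.filter_audit:
            if not ok:
                return condition
        return None


def detect_variants(sites, thresholds: CallingThresholds | None = None) -> list[VariantCandidate]:
    """Scan per-site allele counts and return candidates passing the three
    detection conditions.  Zero-depth sites are skipped with a warning."""
    thresholds = thresholds or CallingThresholds()
    thresholds.validate()
    candidates: list[VariantCandidate] = []
    for site in sites:
        depth = site.depth
        if depth == 0:
            logger.warning(
                "skipping zero-depth site %s:%d in %s", site.chrom, site.pos, site.sample_id
            )
            continue
        for allele, count in site.allele_counts.items():
            if allele == site.ref_allele or count == 0:
                continue
            baseq = site.mean_baseq.get(allele, 0.0)
            if (
                count >= thresholds.min_variant_reads
                and baseq >= thresholds.min_mean_baseq
                and count / depth >= thresholds.min_vaf
            ):
                candidates.append(
                    VariantCandidate(
                        site.sample_id, site.chrom, site.pos, site.ref_allele,
                        allele, count, depth, baseq,
                    )
                )
    return candidates


def annotate_consequence(
    candidate: VariantCandidate, gene_model: GeneModel
) -> tuple[str, bool]:
    """Coding consequence of a candidate and its NMD prediction.

    SNVs are classified synonymous/missense/nonsense by codon translation on
    the coding strand; indels are frameshift when their length is not a
    multiple of 3, otherwise in-frame.  NMD is predicted when the first stop
    codon of the mutated CDS ends more than 50 nt upstream of the last
    exon-exon junction.  Positions outside the CDS are noncoding.
    """
    try:
        mutated, junction = apply_variant(gene_model, candidate.pos, candidate.ref, candidate.alt)
    except VariantPlacementError:
        return "noncoding", False
    if candidate.alt.startswith(("+", "-")):
        indel_len = len(candidate.alt) - 1
        consequence = "frameshift" if indel_len % 3 else "inframe_indel"
    else:
        ref_protein = str(Seq(gene_model.cds_sequence).translate())
        alt_protein = str(Seq(mutated).translate())
        if alt_protein == ref_protein:
            consequence = "synonymous"
        else:
            i = next(k for k in range(len(ref_protein)) if ref_protein[k] != alt_protein[k])
            consequence = "nonsense" if alt_protein[i] == "*" else "missense"
    trimmed = mutated[: len(mutated) - len(mutated) % 3]
    protein = str(Seq(trimmed).translate())
    stop = protein.find("*")
    nmd = stop >= 0 and junction - 3 * (stop + 1) > 50
    return consequence, nmd


def filter_somatic(
    tumor: list[VariantCandidate],
    normal_sites,
    dbsnp: set[tuple[str, int, str, str]],
    panel: PanelDesign,
    thresholds: CallingThresholds | None = None,
) -> list[SomaticCall]:
    """Apply the four somatic conditions to tumor candidates.

    Returns one :class:`SomaticCall` per candidate; accepted calls are those
    whose audit shows all four conditions passing.  A candidate position
    missing from the normal table is treated as zero normal coverage (fails
    the wild-type depth condition).
    """
    thresholds = thresholds or CallingThresholds()
    thresholds.validate()
    normal_by_pos = {(s.chrom, s.pos): s for s in normal_sites}
    calls: list[SomaticCall] = []
    for cand in tumor:
        gene_model = panel.find_gene(cand.chrom, cand.pos)
        if gene_model is None:
            gene_name, consequence, nmd = None, "noncoding", False
        else:
            gene_name = gene_model.name
            consequence, nmd = annotate_consequence(cand, gene_model)
        normal = normal_by_pos.get((cand.chrom, cand.pos))
        n_var = normal.count(cand.alt) if normal is not None else 0
        n_wt = normal.count(cand.ref) if normal is not None else 0
        in_dbsnp = cand.key in dbsnp
        audit = [
            ("nonsynonymous", consequence in NONSYNONYMOUS),
            ("normal_variant_zero", n_var <= thresholds.max_normal_variant_reads),
            ("normal_wildtype_depth", n_wt >= thresholds.min_normal_wt_reads),
            ("not_in_dbsnp", not in_dbsnp),
        ]
        calls.append(
            SomaticCall(cand, n_var, n_wt, in_dbsnp, gene_name, consequence, nmd, audit)
        )
    return calls


def accepted_calls(calls: list[SomaticCall]) -> list[SomaticCall]:
    return [c for c in calls if c.accepted]


def find_recurrent(calls: list[SomaticCall]) -> dict[tuple[str, int, str, str], int]:
    """Variants accepted in two or more patients, counting each patient once
    even if duplicate rows carry the same variant."""
    patients_by_variant: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)
    for call in calls:
        patients_by_variant[call.candidate.key].add(call.candidate.sample_id)
    return {
        key: len(samples)
        for key, samples in patients_by_variant.items()
        if len(samples) >= 2
    }
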