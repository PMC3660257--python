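"""Synthetic paired tumor/normal panel cohorts with fully known truth.

The generator emulates the data a targeted capture experiment delivers after
alignment: per-site allele read counts with mean base qualities, and per-gene
read-base coverage totals, for matched tumor and normal samples.  Truth
(per-sample purity, per-gene integer copy states, planted somatic variants,
germline SNPs, MSI marker instability) is recorded so every downstream stage
can be scored.

Read model: site depth is negative-binomial (capture data are overdispersed
relative to Poisson); variant reads are binomial given depth.  A clonal
heterozygous somatic variant in a gene with tumor copy number ``C`` carried
by one copy has expected allele fraction ``p / (p*C + 2*(1-p))`` at tumor
purity ``p`` (``p/2`` when copy-neutral); expected tumor coverage of the gene
scales by ``p*C/2 + (1-p)``.  Germline SNPs appear in both samples at allele
fraction 0.5 (het) or 1.0 (hom) and are all members of the simulated dbSNP
catalogue; substitution errors hit each non-reference base at
``error_rate/3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .panel import GeneModel, PanelDesign, apply_variant

MSI_MARKERS = ("D2S123", "D5S346", "D17S250", "BAT25", "BAT26")

_BASES = ("A", "C", "G", "T")

# standard genetic code, used for the generator's own truth classification
_CODONS = {}
_BASES4 = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES4 for b in _BASES4 for c in _BASES4
):
    _CODONS[_a + _b + _c] = _AA[_i]


def _translate(cds: str) -> str:
    return "".join(_CODONS[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def classify_coding_change(
    original_cds: str, mutated_cds: str, mutated_junction: int, indel_length: int
) -> tuple[str, bool]:
    """Classify a coding edit and predict nonsense-mediated decay.

    ``indel_length`` is 0 for an SNV, otherwise the net inserted (+) or
    deleted (-) length.  NMD is predicted when the first stop codon of the
    mutated CDS ends more than 50 nt upstream of the last exon-exon junction
    (both in mutated coordinates); the natural terminator always lies
    downstream of the junction and therefore never triggers the rule.
    """
    if indel_length != 0:
        consequence = "frameshift" if abs(indel_length) % 3 else "inframe_indel"
    else:
        ref_protein = _translate(original_cds)
        alt_protein = _translate(mutated_cds)
        if alt_protein == ref_protein:
            consequence = "synonymous"
        else:
            diff = next(i for i in range(len(ref_protein)) if ref_protein[i] != alt_protein[i])
            consequence = "nonsense" if alt_protein[diff] == "*" else "missense"
    protein = _translate(mutated_cds)
    stop_index = protein.find("*")
    nmd = False
    if stop_index >= 0:
        stop_end_nt = 3 * (stop_index + 1)
        nmd = mutated_junction - stop_end_nt > 50
    return consequence, nmd


@dataclass
class SiteCounts:
    """Allele read counts at one position of one sample.

    ``allele_counts`` keys are A/C/G/T plus ``+SEQ`` insertions and ``-SEQ``
    deletions; ``mean_baseq`` holds the mean phred base quality of the reads
    supporting each observed allele.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    allele_counts: dict[str, int]
    mean_baseq: dict[str, float]

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    def count(self, allele: str) -> int:
        return self.allele_counts.get(allele, 0)


@dataclass
class GeneCoverageTable:
    """Per-gene read-base totals for one sample, plus the library total."""

    sample_id: str
    read_bases: dict[str, int]
    total_read_bases: int

    def proportion(self, gene: str) -> float:
        return self.read_bases[gene] / self.total_read_bases


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the reference colorectal cohort: 60 tumor/normal pairs on
    a 183-gene (~1 Mb) panel at ~175x mean coverage, tumor purity 0.42-1.0,
    10% MSI-H patients.
    """

    n_patients: int = 60
    depth_mean: float = 175.0
    depth_dispersion: float = 8.0
    purity_range: tuple[float, float] = (0.42, 1.0)
    snvs_per_tumor: float = 6.0
    indel_fraction: float = 0.07
    germline_snp_rate: float = 2e-4
    error_rate: float = 1e-4
    error_sites_per_sample: int = 30
    cnv_gene_fraction: float = 0.04
    copy_states: tuple[int, ...] = (0, 1, 3, 4, 5, 6)
    coverage_cv: float = 0.05
    msi_h_fraction: float = 0.10
    msi_l_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"purity_range must lie in (0, 1], got {self.purity_range}")
        for name in (
            "snvs_per_tumor",
            "indel_fraction",
            "germline_snp_rate",
            "error_rate",
            "cnv_gene_fraction",
            "coverage_cv",
            "msi_h_fraction",
            "msi_l_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be > 0")
        if self.msi_h_fraction + self.msi_l_fraction > 1:
            raise ValueError("msi_h_fraction + msi_l_fraction must be <= 1")
        if not all(c >= 0 for c in self.copy_states):
            raise ValueError("copy states must be >= 0")


@dataclass
class PlantedVariant:
    patient: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    nmd: bool
    true_vaf: float


@dataclass
class PlantedSNP:
    patient: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    rsid: str


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort."""

    purity: dict[str, float]
    copy_number: dict[str, dict[str, int]]
    somatic_variants: list[PlantedVariant]
    germline_snps: list[PlantedSNP]
    msi_markers: dict[str, tuple[bool, ...]]

    def copy_state(self, patient: str, gene: str) -> int:
        return self.copy_number.get(patient, {}).get(gene, 2)


@dataclass
class SyntheticCohort:
    panel: PanelDesign
    config: CohortConfig
    patients: list[str]
    site_counts: dict[str, list[SiteCounts]]  # sample_id -> sites
    coverage: dict[str, GeneCoverageTable]  # sample_id -> table
    dbsnp: list[tuple[str, int, str, str, str]]  # chrom, pos, ref, alt, rsid
    msi_markers: dict[str, tuple[bool, ...]]
    truth: TruthSet

    @property
    def dbsnp_set(self) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, _ in self.dbsnp}

    def tumor_sample(self, patient: str) -> str:
        return f"{patient}-T"

    def normal_sample(self, patient: str) -> str:
        return f"{patient}-N"


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = re.match(r"chr(\d+)$", chrom)
    return (int(m.group(1)), "") if m else (10**9, chrom)


def _mean_baseq(rng: np.random.Generator, mu: float, sigma: float, n_reads: int) -> float:
    """Mean phred quality over ``n_reads`` supporting reads: per-read
    qualities ~ Normal(mu, sigma), so the mean concentrates as 1/sqrt(n)."""
    q = rng.normal(mu, sigma / np.sqrt(max(n_reads, 1)))
    return float(np.clip(q, 2.0, 40.0))


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _make_site(
    rng: np.random.Generator,
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str | None,
    vaf: float,
    depth_mean: float,
    cfg: CohortConfig,
) -> SiteCounts:
    """Draw one site's allele counts: variant binomial at ``vaf``, residual
    substitution error on the remaining bases, reference gets the rest."""
    n = _nb_depth(rng, depth_mean, cfg.depth_dispersion)
    counts: dict[str, int] = {}
    quals: dict[str, float] = {}
    v = int(rng.binomial(n, vaf)) if alt is not None and vaf > 0 else 0
    budget = n - v
    for base in _BASES:
        if base == ref or base == alt:
            continue
        e = min(int(rng.binomial(n, cfg.error_rate / 3)), budget)
        if e > 0:
            counts[base] = e
            quals[base] = round(_mean_baseq(rng, 18.0, 6.0, e), 1)
            budget -= e
    if v > 0:
        counts[alt] = v
        quals[alt] = round(_mean_baseq(rng, 32.0, 4.0, v), 1)
    if budget > 0:
        counts[ref] = budget
        quals[ref] = round(_mean_baseq(rng, 32.0, 4.0, budget), 1)
    return SiteCounts(sample_id, chrom, pos, ref, counts, quals)


def _assign_msi(rng: np.random.Generator, msi_h_fraction: float, msi_l_fraction: float) -> tuple[bool, ...]:
    u = rng.random()
    if u < msi_h_fraction:
        n_unstable = int(rng.integers(2, 6))
    elif u < msi_h_fraction + msi_l_fraction:
        n_unstable = 1
    else:
        n_unstable = 0
    unstable = rng.choice(5, size=n_unstable, replace=False)
    return tuple(i in set(unstable.tolist()) for i in range(5))


def simulate_msi_markers(
    n_patients: int, msi_h_fraction: float, seed: int, msi_l_fraction: float = 0.10
) -> dict[str, tuple[bool, ...]]:
    """Instability calls at the five reference microsatellite markers
    (D2S123, D5S346, D17S250, BAT25, BAT26) for each patient."""
    if not 0 <= msi_h_fraction <= 1:
        raise ValueError("msi_h_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return {
        f"P{i + 1:02d}": _assign_msi(rng, msi_h_fraction, msi_l_fraction)
        for i in range(n_patients)
    }


def _draw_panel_position(
    rng: np.random.Generator, panel: PanelDesign, weights: np.ndarray
) -> tuple[GeneModel, int]:
    gene = panel.genes[int(rng.choice(len(panel.genes), p=weights))]
    offset = int(rng.integers(0, gene.cds_length))
    return gene, offset


def _plant_somatic(
    rng: np.random.Generator,
    panel: PanelDesign,
    weights: np.ndarray,
    patient: str,
    purity: float,
    copies: dict[str, int],
    blocked: set[tuple[str, int]],
    cfg: CohortConfig,
) -> PlantedVariant | None:
    """One somatic SNV/indel at a fresh exonic position of a non-deleted gene."""
    for _ in range(50):
        gene, offset = _draw_panel_position(rng, panel, weights)
        copy_state = copies.get(gene.name, 2)
        if copy_state == 0:
            continue
        pos = gene.exon_offset_to_genomic(offset)
        if (gene.chrom, pos) in blocked:
            continue
        ref = gene.genomic_cds[offset]
        if rng.random() < cfg.indel_fraction:
            length = int(rng.choice([1, 2, 3], p=[0.6, 0.25, 0.15]))
            if rng.random() < 0.3:  # insertion
                seq = "".join(rng.choice(_BASES, size=length))
                alt = "+" + seq
            else:
                if gene.genomic_to_exon_offset(pos + length) != offset + length:
                    continue  # deletion would cross an exon edge
                alt = "-" + gene.genomic_cds[offset + 1 : offset + 1 + length]
        else:
            alt = str(rng.choice([b for b in _BASES if b != ref]))
        try:
            mutated, junction = apply_variant(gene, pos, ref, alt)
        except ValueError:
            continue
        indel_len = 0
        if alt.startswith("+"):
            indel_len = len(alt) - 1
        elif alt.startswith("-"):
            indel_len = -(len(alt) - 1)
        consequence, nmd = classify_coding_change(
            gene.cds_sequence, mutated, junction, indel_len
        )
        vaf = purity / (purity * copy_state + 2 * (1 - purity))
        blocked.add((gene.chrom, pos))
        return PlantedVariant(
            patient, gene.name, gene.chrom, pos, ref, alt, consequence, nmd, vaf
        )
    return None


def simulate_cohort(panel: PanelDesign, cfg: CohortConfig) -> SyntheticCohort:
    """Simulate a full paired cohort over ``panel`` under ``cfg``.

    Deterministic for a fixed config: a single seeded generator drives every
    draw and patients are processed in order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array([g.cds_length for g in panel.genes], dtype=float)
    weights = lengths / lengths.sum()

    # Panel-wide polymorphism catalogue: germline SNPs recur across patients
    # and all of them are dbSNP members.  Pool is 5x the per-patient load so
    # most catalogue sites are absent from any given genome.
    pool_size = int(rng.poisson(panel.total_target_bases * cfg.germline_snp_rate * 5))
    snp_pool: list[tuple[GeneModel, int, str, str, str]] = []
    used_positions: set[tuple[str, int]] = set()
    for i in range(pool_size):
        gene, offset = _draw_panel_position(rng, panel, weights)
        pos = gene.exon_offset_to_genomic(offset)
        if (gene.chrom, pos) in used_positions:
            continue
        used_positions.add((gene.chrom, pos))
        ref = gene.genomic_cds[offset]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        snp_pool.append((gene, pos, ref, alt, f"rs{900000 + i}"))
    carry_prob = 1.0 / 5.0

    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    purity: dict[str, float] = {}
    copy_number: dict[str, dict[str, int]] = {}
    somatic: list[PlantedVariant] = []
    germline: list[PlantedSNP] = []
    site_counts: dict[str, list[SiteCounts]] = {}
    coverage: dict[str, GeneCoverageTable] = {}
    msi: dict[str, tuple[bool, ...]] = {}

    n_cnv_genes = int(round(cfg.cnv_gene_fraction * len(panel.genes)))
    blocked = set(used_positions)

    for patient in patients:
        p = float(rng.uniform(*cfg.purity_range))
        purity[patient] = round(p, 4)
        p = purity[patient]

        copies: dict[str, int] = {}
        if n_cnv_genes and cfg.copy_states:
            chosen = rng.choice(len(panel.genes), size=n_cnv_genes, replace=False)
            for gi in sorted(chosen.tolist()):
                copies[panel.genes[gi].name] = int(rng.choice(cfg.copy_states))
        copy_number[patient] = copies

        my_snps: list[PlantedSNP] = []
        for gene, pos, ref, alt, rsid in snp_pool:
            if rng.random() >= carry_prob:
                continue
            zyg = "hom" if rng.random() < 1 / 3 else "het"
            my_snps.append(PlantedSNP(patient, gene.name, gene.chrom, pos, ref, alt, zyg, rsid))
        germline.extend(my_snps)

        n_somatic = int(rng.poisson(cfg.snvs_per_tumor))
        my_somatic: list[PlantedVariant] = []
        for _ in range(n_somatic):
            pv = _plant_somatic(rng, panel, weights, patient, p, copies, blocked, cfg)
            if pv is not None:
                my_somatic.append(pv)
        somatic.extend(my_somatic)

        err_sites: list[tuple[str, int, str]] = []
        for _ in range(cfg.error_sites_per_sample):
            gene, offset = _draw_panel_position(rng, panel, weights)
            pos = gene.exon_offset_to_genomic(offset)
            if (gene.chrom, pos) in blocked:
                continue
            err_sites.append((gene.chrom, pos, gene.genomic_cds[offset]))

        # assemble per-site specs: (chrom, pos, ref, alt, tumor_vaf, normal_vaf, gene)
        specs: list[tuple[str, int, str, str | None, float, float, str | None]] = []
        for s in my_snps:
            vaf = 1.0 if s.zygosity == "hom" else 0.5
            specs.append((s.chrom, s.pos, s.ref, s.alt, vaf, vaf, s.gene))
        for v in my_somatic:
            specs.append((v.chrom, v.pos, v.ref, v.alt, v.true_vaf, 0.0, v.gene))
        for chrom, pos, ref in err_sites:
            specs.append((chrom, pos, ref, None, 0.0, 0.0, None))
        specs.sort(key=lambda t: (chrom_sort_key(t[0]), t[1]))

        t_id, n_id = f"{patient}-T", f"{patient}-N"
        t_sites: list[SiteCounts] = []
        n_sites: list[SiteCounts] = []
        for chrom, pos, ref, alt, t_vaf, n_vaf, gene_name in specs:
            c = copies.get(gene_name, 2) if gene_name else 2
            t_factor = p * c / 2 + (1 - p)
            t_sites.append(
                _make_site(rng, t_id, chrom, pos, ref, alt, t_vaf, cfg.depth_mean * t_factor, cfg)
            )
            n_sites.append(
                _make_site(rng, n_id, chrom, pos, ref, alt, n_vaf, cfg.depth_mean, cfg)
            )
        site_counts[t_id] = t_sites
        site_counts[n_id] = n_sites

        shape = 1.0 / max(cfg.coverage_cv, 1e-9) ** 2
        t_bases: dict[str, int] = {}
        n_bases: dict[str, int] = {}
        for g in panel.genes:
            c = copies.get(g.name, 2)
            t_factor = p * c / 2 + (1 - p)
            noise_t = rng.gamma(shape, 1.0 / shape)
            noise_n = rng.gamma(shape, 1.0 / shape)
            n_bases[g.name] = max(int(round(g.cds_length * cfg.depth_mean * noise_n)), 1)
            t_bases[g.name] = int(round(g.cds_length * cfg.depth_mean * t_factor * noise_t))
        # fixed on-target rate: off-target bases inflate both library totals
        # by the same factor, which the proportion normalization cancels
        for sid, bases in ((t_id, t_bases), (n_id, n_bases)):
            total = int(round(sum(bases.values()) / 0.75))
            coverage[sid] = GeneCoverageTable(sid, bases, total)

        msi[patient] = _assign_msi(rng, cfg.msi_h_fraction, cfg.msi_l_fraction)

    dbsnp = sorted(
        ((g.chrom, pos, ref, alt, rsid) for g, pos, ref, alt, rsid in snp_pool),
        key=lambda t: (chrom_sort_key(t[0]), t[1], t[3]),
    )
    truth = TruthSet(purity, copy_number, somatic, germline, msi)
    return SyntheticCohort(
        panel=panel,
        config=cfg,
        patients=patients,
        site_counts=site_counts,
        coverage=coverage,
        dbsnp=dbsnp,
        msi_markers=msi,
        truth=truth,
    )
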