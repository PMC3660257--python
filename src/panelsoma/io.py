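"""On-disk formats: pileup-like TSV, coverage TSV, panel BED + gene models,
dbSNP TSV, MSI marker TSV, truth JSON, and somatic VCF 4.2.

Coordinate conventions: BED on disk is 0-based half-open; everything in
memory is 1-based inclusive.  Variant alleles use the pileup notation
(A/C/G/T, ``+SEQ`` insertion after the position, ``-SEQ`` deletion of the
following bases) internally and standard anchored alleles in VCF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pysam

from .calling import SomaticCall
from .panel import GeneModel, PanelDesign, PanelValidationError
from .synthetic import (
    MSI_MARKERS,
    GeneCoverageTable,
    SiteCounts,
    SyntheticCohort,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pileup-like site counts

def write_site_counts(sites: list[SiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\tallele\tcount\tmean_baseq\n")
        for site in sites:
            for allele in sorted(site.allele_counts):
                fh.write(
                    f"{site.sample_id}\t{site.chrom}\t{site.pos}\t{site.ref_allele}\t"
                    f"{allele}\t{site.allele_counts[allele]}\t{site.mean_baseq[allele]:g}\n"
                )


def read_site_counts(path: str | Path) -> list[SiteCounts]:
    sites: dict[tuple[str, str, int], SiteCounts] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample", "chrom", "pos", "ref"]:
            raise ValueError(f"{path}: not a site-counts TSV")
        for line in fh:
            sample, chrom, pos, ref, allele, count, baseq = line.rstrip("\n").split("\t")
            key = (sample, chrom, int(pos))
            site = sites.get(key)
            if site is None:
                site = sites[key] = SiteCounts(sample, chrom, int(pos), ref, {}, {})
            site.allele_counts[allele] = int(count)
            site.mean_baseq[allele] = float(baseq)
    return sorted(sites.values(), key=lambda s: (chrom_sort_key(s.chrom), s.pos))


# ---------------------------------------------------------------------------
# per-gene coverage

def write_coverage(table: GeneCoverageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample={table.sample_id}\n")
        fh.write(f"#total_read_bases={table.total_read_bases}\n")
        fh.write("gene\tread_bases\n")
        for gene in table.read_bases:
            fh.write(f"{gene}\t{table.read_bases[gene]}\n")


def read_coverage(path: str | Path) -> GeneCoverageTable:
    sample = ""
    total = 0
    bases: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#sample="):
                sample = line.split("=", 1)[1]
            elif line.startswith("#total_read_bases="):
                total = int(line.split("=", 1)[1])
            elif line and not line.startswith("gene\t"):
                gene, n = line.split("\t")
                bases[gene] = int(n)
    table = GeneCoverageTable(sample, bases, total)
    if table.total_read_bases < sum(bases.values()):
        raise ValueError(f"{path}: total_read_bases below per-gene sum")
    return table


# ---------------------------------------------------------------------------
# panel: BED (0-based half-open) + gene-model TSV

def write_panel(panel: PanelDesign, bed_path: str | Path, model_path: str | Path) -> None:
    with open(bed_path, "w") as bed:
        for gene in panel.genes:
            for start, end in gene.cds_intervals:
                bed.write(f"{gene.chrom}\t{start - 1}\t{end}\t{gene.name}\n")
    with open(model_path, "w") as fh:
        fh.write("gene\tstrand\tlast_junction_offset\tcds_sequence\n")
        for gene in panel.genes:
            fh.write(
                f"{gene.name}\t{gene.strand}\t{gene.last_junction_offset}\t{gene.cds_sequence}\n"
            )


def read_panel(bed_path: str | Path, model_path: str | Path) -> PanelDesign:
    intervals: dict[str, list[tuple[int, int]]] = {}
    chroms: dict[str, str] = {}
    with open(bed_path) as bed:
        any_line = False
        for line in bed:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            any_line = True
            chrom, start, end, name = line.split()[:4]
            intervals.setdefault(name, []).append((int(start) + 1, int(end)))
            chroms[name] = chrom
    if not any_line:
        raise PanelValidationError(f"{bed_path}: no targets")
    genes: list[GeneModel] = []
    with open(model_path) as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise PanelValidationError(f"{model_path}: missing header")
        for line in fh:
            name, strand, junction, cds = line.rstrip("\n").split("\t")
            if name not in intervals:
                raise PanelValidationError(f"gene {name} in model but not in BED")
            genes.append(
                GeneModel(
                    name=name,
                    chrom=chroms[name],
                    strand=strand,
                    cds_intervals=sorted(intervals[name]),
                    cds_sequence=cds,
                    last_junction_offset=int(junction),
                )
            )
    model_names = {g.name for g in genes}
    missing = set(intervals) - model_names
    if missing:
        raise PanelValidationError(f"BED genes missing from model: {sorted(missing)}")
    panel = PanelDesign(genes=genes)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# dbSNP and MSI marker tables

def write_dbsnp(entries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\trsid\n")
        for chrom, pos, ref, alt, rsid in entries:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{rsid}\n")


def read_dbsnp(path: str | Path) -> set[tuple[str, int, str, str]]:
    members: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, ref, alt, _ = line.rstrip("\n").split("\t")
            members.add((chrom, int(pos), ref, alt))
    return members


def write_msi_markers(markers: dict[str, tuple[bool, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient\t" + "\t".join(MSI_MARKERS) + "\n")
        for patient, vector in markers.items():
            fh.write(patient + "\t" + "\t".join(str(int(v)) for v in vector) + "\n")


def read_msi_markers(path: str | Path) -> dict[str, tuple[bool, ...]]:
    markers: dict[str, tuple[bool, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[1:]) != MSI_MARKERS:
            raise ValueError(f"{path}: expected marker columns {MSI_MARKERS}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            markers[fields[0]] = tuple(bool(int(v)) for v in fields[1:6])
    return markers


# ---------------------------------------------------------------------------
# truth JSON

def write_truth(cohort: SyntheticCohort, path: str | Path) -> None:
    truth = cohort.truth
    payload = {
        "purity": truth.purity,
        "copy_number": truth.copy_number,
        "somatic_variants": [asdict(v) for v in truth.somatic_variants],
        "germline_snps": [asdict(s) for s in truth.germline_snps],
        "msi_markers": {p: list(map(int, v)) for p, v in truth.msi_markers.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# VCF 4.2

@dataclass
class VcfCall:
    """The fields the somatic VCF writer emits, in pileup allele notation."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    nmd: bool
    vaf: float
    tumor_depth: int
    tumor_alt_reads: int
    normal_variant_reads: int
    normal_wt_reads: int
    filter: str


def _vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    if alt.startswith("+"):
        return pos, ref, ref + alt[1:]
    if alt.startswith("-"):
        return pos, ref + alt[1:], ref
    return pos, ref, alt


def _pileup_alleles(ref: str, alt: str) -> tuple[str, str]:
    if len(ref) == 1 and len(alt) == 1:
        return ref, alt
    if len(alt) > len(ref) and alt.startswith(ref):
        return ref, "+" + alt[len(ref):]
    if len(ref) > len(alt) and ref.startswith(alt):
        return alt, "-" + ref[len(alt):]
    raise ValueError(f"cannot express {ref}>{alt} in pileup notation")


def _vcf_header(panel: PanelDesign, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=panelsoma')
    chrom_max: dict[str, int] = {}
    for gene in panel.genes:
        chrom_max[gene.chrom] = max(chrom_max.get(gene.chrom, 0), gene.span[1] + 10_000)
    for chrom in sorted(chrom_max, key=chrom_sort_key):
        header.contigs.add(chrom, length=chrom_max[chrom])
    header.info.add("SOMATIC", 0, "Flag", "Accepted somatic call")
    header.info.add("VAF", 1, "Float", "Tumor variant allele fraction")
    header.info.add("GENE", 1, "String", "Panel gene")
    header.info.add("CSQ", 1, "String", "Coding consequence")
    header.info.add("NMD", 0, "Flag", "Premature stop predicted to trigger nonsense-mediated decay")
    header.info.add("TDP", 1, "Integer", "Tumor depth")
    header.info.add("TAD", 1, "Integer", "Tumor variant reads")
    header.info.add("NVR", 1, "Integer", "Normal variant reads")
    header.info.add("NWT", 1, "Integer", "Normal wild-type reads")
    header.info.add("SAMPLE", 1, "String", "Tumor sample id")
    for name, desc in (
        ("nonsynonymous", "Not a nonsynonymous coding variant"),
        ("normal_variant_zero", "Variant reads present in matched normal"),
        ("normal_wildtype_depth", "Insufficient wild-type reads in matched normal"),
        ("not_in_dbsnp", "Known dbSNP polymorphism"),
    ):
        header.filters.add(name, None, None, desc)
    return header


def write_vcf(
    calls: list[SomaticCall],
    path: str | Path,
    panel: PanelDesign,
    sample_id: str,
    include_rejected: bool = True,
) -> None:
    """Write somatic calls as VCF 4.2; rejected candidates carry the first
    failing condition in FILTER.  Input is sorted if needed (with a warning)."""
    ordered = sorted(
        calls, key=lambda c: (chrom_sort_key(c.candidate.chrom), c.candidate.pos, c.candidate.alt)
    )
    if [c.candidate.pos for c in ordered] != [c.candidate.pos for c in calls]:
        logger.warning("VCF input for %s was unsorted; sorting", sample_id)
    header = _vcf_header(panel, sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in ordered:
            if not include_rejected and not call.accepted:
                continue
            cand = call.candidate
            pos, ref, alt = _vcf_alleles(cand.pos, cand.ref, cand.alt)
            record = vcf.new_record(
                contig=cand.chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            record.info["VAF"] = round(cand.vaf, 6)
            record.info["GENE"] = call.gene or "."
            record.info["CSQ"] = call.consequence
            record.info["TDP"] = cand.depth
            record.info["TAD"] = cand.variant_reads
            record.info["NVR"] = call.normal_variant_reads
            record.info["NWT"] = call.normal_wt_reads
            record.info["SAMPLE"] = cand.sample_id
            if call.nmd_predicted:
                record.info["NMD"] = True
            if call.accepted:
                record.info["SOMATIC"] = True
                record.filter.add("PASS")
            else:
                record.filter.add(call.first_failed_condition)
            vcf.write(record)


def read_vcf(path: str | Path) -> list[VcfCall]:
    calls: list[VcfCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            ref, alt = _pileup_alleles(record.ref, record.alts[0])
            calls.append(
                VcfCall(
                    sample_id=record.info.get("SAMPLE", ""),
                    chrom=record.chrom,
                    pos=record.pos,
                    ref=ref,
                    alt=alt,
                    gene=record.info.get("GENE", "."),
                    consequence=record.info.get("CSQ", ""),
                    nmd=bool(record.info.get("NMD", False)),
                    vaf=round(float(record.info["VAF"]), 6),
                    tumor_depth=int(record.info["TDP"]),
                    tumor_alt_reads=int(record.info["TAD"]),
                    normal_variant_reads=int(record.info["NVR"]),
                    normal_wt_reads=int(record.info["NWT"]),
                    filter=";".join(record.filter.keys()) or "PASS",
                )
            )
    return calls


def vcf_call_fields(call: SomaticCall) -> VcfCall:
    """The VcfCall view of a SomaticCall — what a write/read round trip
    should return for it."""
    cand = call.candidate
    return VcfCall(
        sample_id=cand.sample_id,
        chrom=cand.chrom,
        pos=cand.pos,
        ref=cand.ref,
        alt=cand.alt,
        gene=call.gene or ".",
        consequence=call.consequence,
        nmd=call.nmd_predicted,
        vaf=round(cand.vaf, 6),
        tumor_depth=cand.depth,
        tumor_alt_reads=cand.variant_reads,
        normal_variant_reads=call.normal_variant_reads,
        normal_wt_reads=call.normal_wt_reads,
        filter="PASS" if call.accepted else call.first_failed_condition,
    )
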