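"""Targeted-panel design: gene models with CDS coordinates and sequence.

A panel is a set of capture targets covering all coding exons of a list of
cancer genes (by default 183 genes, ~1 Mb of target).  Each gene carries its
CDS intervals in genomic coordinates (1-based inclusive), the coding-strand
CDS sequence, and the offset of the last exon-exon junction, which is needed
to predict nonsense-mediated decay for truncating variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Genes highlighted in colorectal-cancer panel reports; used to give the
#: simulated panel readable names.  Remaining genes are named GENE###.
HEADLINE_GENES = [
    "APC", "TP53", "KRAS", "TTN", "FBXW7", "SMAD4", "MAFB", "GNAS", "SRC",
    "TOP1", "RECQL4", "SMAD2", "MAP2K4", "BCL2", "WRN", "DCC", "ERBB2",
    "EGFR", "PIK3CA", "PTEN", "BRCA1", "BRCA2", "ACVR2A", "MLH1", "MSH6",
    "SPTAN1", "TGFBR2", "JAK1", "EWSR1", "BLM", "NRAS", "BRAF", "HRAS",
    "RAF1", "MSH2", "PMS2", "CTNNB1", "PIK3R1", "ATM", "RB1",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PanelValidationError(ValueError):
    """A gene model or panel violates a structural invariant."""


@dataclass
class GeneModel:
    """One panel gene: CDS intervals, coding sequence, NMD junction offset.

    ``cds_intervals`` are 1-based inclusive ``[start, end]`` pairs in
    ascending genomic order.  ``cds_sequence`` is given on the coding strand;
    for minus-strand genes it is the reverse complement of the concatenated
    genomic exon sequence.  ``last_junction_offset`` is the distance (nt,
    from the CDS start in coding orientation) of the final exon-exon
    junction; 0 for single-exon genes.
    """

    name: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str
    last_junction_offset: int

    def __post_init__(self) -> None:
        self.cds_intervals = [tuple(iv) for iv in self.cds_intervals]

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def genomic_cds(self) -> str:
        """CDS on the forward genomic strand (exons concatenated 5'->3' of
        the genome, not of the transcript)."""
        if self.strand == "+":
            return self.cds_sequence
        return reverse_complement(self.cds_sequence)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(s <= pos <= e for s, e in self.cds_intervals)

    def genomic_to_exon_offset(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based offset into the concatenated
        genomic exon string, or None if the position is intronic/outside."""
        off = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                return off + (pos - start)
            off += end - start + 1
        return None

    def exon_offset_to_genomic(self, offset: int) -> int:
        off = 0
        for start, end in self.cds_intervals:
            length = end - start + 1
            if offset < off + length:
                return start + (offset - off)
            off += length
        raise IndexError(f"offset {offset} outside CDS of {self.name}")

    def coding_offset(self, exon_offset: int) -> int:
        """Coding-strand CDS coordinate (0-based) for a genomic exon offset."""
        if self.strand == "+":
            return exon_offset
        return self.cds_length - 1 - exon_offset

    def ref_base(self, pos: int) -> str:
        """Forward-strand reference base at a genomic position inside the CDS."""
        off = self.genomic_to_exon_offset(pos)
        if off is None:
            raise ValueError(f"{self.chrom}:{pos} not in CDS of {self.name}")
        return self.genomic_cds[off]

    def validate(self) -> None:
        if len(self.cds_sequence) % 3 != 0:
            raise PanelValidationError(
                f"{self.name}: CDS length {len(self.cds_sequence)} not divisible by 3"
            )
        if self.strand not in ("+", "-"):
            raise PanelValidationError(f"{self.name}: bad strand {self.strand!r}")
        if not self.cds_sequence.startswith("ATG"):
            raise PanelValidationError(f"{self.name}: CDS does not start with ATG")
        if self.cds_sequence[-3:] not in STOP_CODONS:
            raise PanelValidationError(f"{self.name}: CDS does not end with a stop codon")
        total = 0
        prev_end = -1
        for start, end in self.cds_intervals:
            if end < start:
                raise PanelValidationError(f"{self.name}: empty interval [{start},{end}]")
            if start <= prev_end:
                raise PanelValidationError(f"{self.name}: overlapping/unsorted intervals")
            total += end - start + 1
            prev_end = end
        if total != len(self.cds_sequence):
            raise PanelValidationError(
                f"{self.name}: interval total {total} != CDS length {len(self.cds_sequence)}"
            )
        if not 0 <= self.last_junction_offset < max(len(self.cds_sequence), 1):
            raise PanelValidationError(f"{self.name}: bad last_junction_offset")


@dataclass
class PanelDesign:
    """An ordered collection of gene models forming the capture design."""

    genes: list[GeneModel]
    total_target_bases: int = 0
    _by_name: dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.total_target_bases:
            self.total_target_bases = sum(g.cds_length for g in self.genes)
        self._by_name = {g.name: g for g in self.genes}

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def gene(self, name: str) -> GeneModel:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def find_gene(self, chrom: str, pos: int) -> GeneModel | None:
        for g in self.genes:
            if g.contains(chrom, pos):
                return g
        return None

    def validate(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise PanelValidationError("duplicate gene names in panel")
        for g in self.genes:
            g.validate()
        if self.total_target_bases != sum(g.cds_length for g in self.genes):
            raise PanelValidationError("total_target_bases inconsistent with genes")
        if self.total_target_bases <= 0:
            raise PanelValidationError("no targets")


class VariantPlacementError(ValueError):
    """Variant cannot be applied to the gene model (intronic, exon-spanning,
    or reference mismatch)."""


def apply_variant(gene: GeneModel, pos: int, ref: str, alt: str) -> tuple[str, int]:
    """Apply a forward-strand variant to a gene and return the mutated
    coding-strand CDS together with the last-junction offset in mutated
    coordinates.

    ``alt`` is an SNV base, an insertion ``+SEQ`` (inserted after ``pos``) or
    a deletion ``-SEQ`` (bases ``pos+1 .. pos+len(SEQ)`` removed), all on the
    forward genomic strand — the pileup convention used throughout.  Indels
    must lie within a single exon.
    """
    o = gene.genomic_to_exon_offset(pos)
    if o is None:
        raise VariantPlacementError(f"{gene.chrom}:{pos} outside CDS of {gene.name}")
    genomic = gene.genomic_cds
    n = len(genomic)
    # exon-exon boundary expressed in genomic-concat coordinates
    if gene.last_junction_offset == 0:
        boundary = None
    elif gene.strand == "+":
        boundary = gene.last_junction_offset
    else:
        boundary = n - gene.last_junction_offset
    if alt.startswith("+"):
        seq = alt[1:]
        if gene.genomic_to_exon_offset(pos + 1) != o + 1:
            raise VariantPlacementError(f"insertion after {pos} not inside one exon")
        ins_at = o + 1
        mutated = genomic[:ins_at] + seq + genomic[ins_at:]
        if boundary is not None and boundary > ins_at:
            boundary += len(seq)
    elif alt.startswith("-"):
        seq = alt[1:]
        for k in range(1, len(seq) + 1):
            if gene.genomic_to_exon_offset(pos + k) != o + k:
                raise VariantPlacementError(f"deletion after {pos} spans an exon edge")
        if genomic[o + 1 : o + 1 + len(seq)] != seq:
            raise VariantPlacementError(
                f"deletion sequence mismatch at {gene.chrom}:{pos}"
            )
        mutated = genomic[: o + 1] + genomic[o + 1 + len(seq) :]
        if boundary is not None and boundary > o + 1:
            boundary -= len(seq)
    else:
        if genomic[o] != ref:
            raise VariantPlacementError(
                f"reference mismatch at {gene.chrom}:{pos}: model {genomic[o]}, given {ref}"
            )
        mutated = genomic[:o] + alt + genomic[o + 1 :]
    if boundary is None:
        junction = 0
    elif gene.strand == "+":
        junction = boundary
    else:
        junction = len(mutated) - boundary
    coding = mutated if gene.strand == "+" else reverse_complement(mutated)
    return coding, junction


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG start, sense internal codons, one stop at the end."""
    internal = rng.choice(_SENSE_CODONS, size=max(n_codons - 2, 0))
    stop = rng.choice(STOP_CODONS)
    return "ATG" + "".join(internal) + stop


def make_panel(
    n_genes: int = 183,
    mean_cds_length: int = 5400,
    seed: int = 0,
    genes_per_chrom: int = 10,
) -> PanelDesign:
    """Simulate a capture panel of ``n_genes`` multi-exon gene models.

    CDS lengths are gamma-distributed around ``mean_cds_length`` (so the
    default 183-gene panel targets ~1 Mb), exon counts Poisson-distributed,
    and strands random.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor: dict[str, int] = {}
    for i in range(n_genes):
        name = HEADLINE_GENES[i] if i < len(HEADLINE_GENES) else f"GENE{i + 1:03d}"
        chrom = f"chr{i // genes_per_chrom + 1}"
        n_codons = max(int(round(rng.gamma(4.0, mean_cds_length / 3 / 4.0))), 100)
        cds = _random_cds(rng, n_codons)
        cds_len = len(cds)
        n_exons = 1 + rng.poisson(7)
        # random partition of the CDS into exon lengths >= 10 nt
        while n_exons > 1 and cds_len < 10 * n_exons:
            n_exons -= 1
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(10, cds_len - 9), size=n_exons - 1, replace=False))
            bounds = [0, *cuts.tolist(), cds_len]
            exon_lengths = np.diff(bounds)
            if (exon_lengths < 10).any():  # rare collision of cut points
                exon_lengths = np.full(n_exons, cds_len // n_exons)
                exon_lengths[-1] += cds_len - exon_lengths.sum()
        else:
            exon_lengths = np.array([cds_len])
        start = cursor.get(chrom, 1000) + int(rng.integers(5_000, 20_000))
        intervals = []
        pos = start
        for length in exon_lengths:
            intervals.append((pos, pos + int(length) - 1))
            pos += int(length) + int(rng.integers(100, 2_000))
        cursor[chrom] = intervals[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        # junction between the penultimate and final coding exon
        if len(intervals) == 1:
            junction = 0
        elif strand == "+":
            junction = cds_len - int(exon_lengths[-1])
        else:
            junction = cds_len - int(exon_lengths[0])
        genes.append(
            GeneModel(
                name=name,
                chrom=chrom,
                strand=strand,
                cds_intervals=intervals,
                cds_sequence=cds,
                last_junction_offset=junction,
            )
        )
    panel = PanelDesign(genes=genes)
    panel.validate()
    return panel
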