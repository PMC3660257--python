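"""Variant detection thresholds, consequence annotation, somatic filtering.

The somatic filter is cross-checked against a literal, independently coded
re-check of the four conditions (nonsynonymous, clean normal, covered
normal, not in dbSNP) on randomized candidates.
"""

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, strategies as st

import panelsoma as ps
from panelsoma.calling import NONSYNONYMOUS, CallingThresholds, accepted_calls
from panelsoma.panel import GeneModel, reverse_complement
from panelsoma.synthetic import SiteCounts

_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _aa(codon: str) -> str:
    return _FWD.get(codon, "*")


def _site(sample, chrom, pos, ref, counts, quals):
    return SiteCounts(sample, chrom, pos, ref, counts, quals)


# ---------------------------------------------------------------------------
# detection

@pytest.mark.parametrize(
    "var_reads,depth,baseq,expect",
    [
        (1, 100, 30.0, False),   # below the two-read minimum
        (25, 100, 25.0, True),   # all conditions comfortably met
        (19, 100, 30.0, False),  # allele fraction 19% < 20%
        (20, 100, 20.0, True),   # inclusive boundaries: exactly 20/100 at Q20
        (25, 100, 19.9, False),  # quality just under the inclusive bound
    ],
)
def test_detection_thresholds(var_reads, depth, baseq, expect):
    site = _site("S", "chr1", 100, "A",
                 {"A": depth - var_reads, "C": var_reads},
                 {"A": 33.0, "C": baseq})
    candidates = ps.detect_variants([site])
    assert bool(candidates) is expect
    if expect:
        assert candidates[0].vaf == pytest.approx(var_reads / depth)


def test_zero_depth_site_skipped_with_warning(caplog):
    site = _site("S", "chr1", 5, "A", {}, {})
    with caplog.at_level("WARNING"):
        assert ps.detect_variants([site]) == []
    assert "zero-depth" in caplog.text


@given(
    d_reads=st.integers(0, 3),
    d_baseq=st.floats(0, 10),
    d_vaf=st.floats(0, 0.2),
    seed=st.integers(0, 50),
)
def test_raising_detection_thresholds_never_adds_candidates(d_reads, d_baseq, d_vaf, seed):
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(30):
        depth = int(rng.integers(1, 120))
        v = int(rng.integers(0, depth + 1))
        sites.append(
            _site("S", "chr1", i + 1, "A",
                  {"A": depth - v, "G": v},
                  {"A": 33.0, "G": float(rng.uniform(5, 40))})
        )
    base = CallingThresholds()
    tighter = CallingThresholds(
        min_variant_reads=base.min_variant_reads + d_reads,
        min_mean_baseq=base.min_mean_baseq + d_baseq,
        min_vaf=min(base.min_vaf + d_vaf, 1.0),
    )
    loose = {c.key for c in ps.detect_variants(sites, base)}
    tight = {c.key for c in ps.detect_variants(sites, tighter)}
    assert tight <= loose


# ---------------------------------------------------------------------------
# consequence annotation

def _simple_gene(strand="+", two_exons=False):
    cds = "ATGAAACAATAT" + "GCT" * 40 + "TAA"  # M K Q Y A*40 stop
    if two_exons:
        intervals = [(101, 160), (301, 375)]
        junction = 60 if strand == "+" else len(cds) - 60
    else:
        intervals = [(101, 100 + len(cds))]
        junction = 0
    return GeneModel("G", "chr9", strand, intervals, cds, junction)


def _cand(gene, coding_pos, alt_coding):
    """Candidate for a coding-strand SNV/indel expressed genomically."""
    exon_off = coding_pos if gene.strand == "+" else gene.cds_length - 1 - coding_pos
    pos = gene.exon_offset_to_genomic(exon_off)
    ref = gene.genomic_cds[exon_off]
    if gene.strand == "+" or alt_coding.startswith(("+", "-")):
        alt = alt_coding
    else:
        alt = _COMP[alt_coding]
    return ps.VariantCandidate("S", gene.chrom, pos, ref, alt, 30, 100, 33.0)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_snv_consequences_by_codon_translation(strand):
    gene = _simple_gene(strand)
    # CAA (Gln, codon 3) -> TAA stop
    cons, _ = ps.annotate_consequence(_cand(gene, 6, "T"), gene)
    assert cons == "nonsense"
    # AAA -> AAG: both lysine
    cons, _ = ps.annotate_consequence(_cand(gene, 5, "G"), gene)
    assert cons == "synonymous"
    # AAA -> ACA: missense
    cons, _ = ps.annotate_consequence(_cand(gene, 4, "C"), gene)
    assert cons == "missense"


def test_indel_consequences_and_nmd():
    gene = _simple_gene("+", two_exons=True)
    # 3-bp deletion: one amino acid dropped
    cand = _cand(gene, 11, "-" + gene.cds_sequence[12:15])
    cons, nmd = ps.annotate_consequence(cand, gene)
    assert (cons, nmd) == ("inframe_indel", False)
    # 1-bp deletion near the start: frameshift; NMD decided by brute-force
    # retranslation of the shifted CDS against the 50-nt junction rule
    cand = _cand(gene, 11, "-" + gene.cds_sequence[12])
    cons, nmd = ps.annotate_consequence(cand, gene)
    assert cons == "frameshift"
    shifted = gene.cds_sequence[:12] + gene.cds_sequence[13:]
    protein = "".join(
        _aa(shifted[i : i + 3]) for i in range(0, len(shifted) - 2, 3)
    )
    stop = protein.find("*")
    junction = gene.last_junction_offset - 1  # deletion upstream shifts it
    expected_nmd = stop >= 0 and junction - 3 * (stop + 1) > 50
    assert nmd == expected_nmd


def test_nonsense_far_from_last_junction_triggers_nmd():
    gene = _simple_gene("+", two_exons=True)
    cons, nmd = ps.annotate_consequence(_cand(gene, 6, "T"), gene)
    # stop ends at nt 9; junction at 60; 51 nt upstream -> NMD predicted
    assert (cons, nmd) == ("nonsense", True)


def test_position_outside_cds_is_noncoding():
    gene = _simple_gene("+")
    cand = ps.VariantCandidate("S", "chr9", 50, "A", "T", 30, 100, 33.0)
    assert ps.annotate_consequence(cand, gene) == ("noncoding", False)


# ---------------------------------------------------------------------------
# somatic filter

def test_somatic_filter_conditions(small_panel):
    gene = small_panel.genes[0]
    # find a missense SNV on gene 0
    cand = None
    for off in range(3, gene.cds_length - 3):
        ref = gene.genomic_cds[off]
        for alt in "ACGT":
            if alt == ref:
                continue
            c = ps.VariantCandidate(
                "T1", gene.chrom, gene.exon_offset_to_genomic(off), ref, alt, 30, 100, 33.0
            )
            if ps.annotate_consequence(c, gene)[0] == "missense":
                cand = c
                break
        if cand:
            break
    clean_normal = _site("N1", cand.chrom, cand.pos, cand.ref, {cand.ref: 50}, {cand.ref: 33.0})

    calls = ps.filter_somatic([cand], [clean_normal], set(), small_panel)
    assert calls[0].accepted and calls[0].consequence == "missense"

    dirty = _site("N1", cand.chrom, cand.pos, cand.ref,
                  {cand.ref: 50, cand.alt: 1}, {cand.ref: 33.0, cand.alt: 30.0})
    calls = ps.filter_somatic([cand], [dirty], set(), small_panel)
    assert not calls[0].accepted
    assert calls[0].first_failed_condition == "normal_variant_zero"

    shallow = _site("N1", cand.chrom, cand.pos, cand.ref, {cand.ref: 9}, {cand.ref: 33.0})
    calls = ps.filter_somatic([cand], [shallow], set(), small_panel)
    assert calls[0].first_failed_condition == "normal_wildtype_depth"

    calls = ps.filter_somatic([cand], [clean_normal], {cand.key}, small_panel)
    assert calls[0].first_failed_condition == "not_in_dbsnp"

    # position not covered by the normal at all: treated as zero coverage
    calls = ps.filter_somatic([cand], [], set(), small_panel)
    assert calls[0].first_failed_condition == "normal_wildtype_depth"


def test_audit_conservation(small_cohort):
    """Every candidate is either accepted or rejected with a reason."""
    panel = small_cohort.panel
    for patient in small_cohort.patients:
        cands = ps.detect_variants(small_cohort.site_counts[f"{patient}-T"])
        calls = ps.filter_somatic(
            cands, small_cohort.site_counts[f"{patient}-N"],
            small_cohort.dbsnp_set, panel,
        )
        assert len(calls) == len(cands)
        rejected = [c for c in calls if not c.accepted]
        assert len(accepted_calls(calls)) + len(rejected) == len(cands)
        assert all(c.first_failed_condition is not None for c in rejected)
        assert all(len(c.filter_audit) == 4 for c in calls)


def _oracle_consequence(panel, cand):
    """Independent annotation: interval scan + codon lookup, no shared code."""
    gene = None
    for g in panel.genes:
        if g.chrom == cand.chrom and any(s <= cand.pos <= e for s, e in g.cds_intervals):
            gene = g
            break
    if gene is None:
        return "noncoding"
    if cand.alt.startswith(("+", "-")):
        length = len(cand.alt) - 1
        if cand.alt.startswith("-"):
            offsets = []
            for k in range(1, length + 1):
                off = 0
                found = None
                for s, e in gene.cds_intervals:
                    if s <= cand.pos + k <= e:
                        found = off + cand.pos + k - s
                    off += e - s + 1
                offsets.append(found)
            base_off = gene.genomic_to_exon_offset(cand.pos)
            if any(o is None or o != base_off + k + 1 for k, o in enumerate(offsets)):
                return "noncoding"  # spans an exon edge
        return "frameshift" if length % 3 else "inframe_indel"
    off = 0
    exon_offset = None
    for s, e in gene.cds_intervals:
        if s <= cand.pos <= e:
            exon_offset = off + cand.pos - s
        off += e - s + 1
    coding_pos = exon_offset if gene.strand == "+" else gene.cds_length - 1 - exon_offset
    alt_coding = cand.alt if gene.strand == "+" else _COMP[cand.alt]
    codon_start = coding_pos - coding_pos % 3
    codon = gene.cds_sequence[codon_start : codon_start + 3]
    mutated = list(codon)
    mutated[coding_pos % 3] = alt_coding
    before, after = _aa(codon), _aa("".join(mutated))
    if before == after:
        return "synonymous"
    return "nonsense" if after == "*" else "missense"


def _oracle_filter(panel, cand, normal_sites, dbsnp):
    """Literal re-check of the four somatic conditions."""
    if _oracle_consequence(panel, cand) not in (
        "missense", "nonsense", "frameshift", "inframe_indel"
    ):
        return False
    normal = next(
        (s for s in normal_sites if (s.chrom, s.pos) == (cand.chrom, cand.pos)), None
    )
    n_var = normal.allele_counts.get(cand.alt, 0) if normal else 0
    n_wt = normal.allele_counts.get(cand.ref, 0) if normal else 0
    if n_var != 0:
        return False
    if n_wt < 10:
        return False
    if (cand.chrom, cand.pos, cand.ref, cand.alt) in dbsnp:
        return False
    return True


def make_random_candidates(panel, n, seed):
    """Randomized candidates with randomized normal evidence and dbSNP
    membership, spanning accept and every reject branch."""
    rng = np.random.default_rng(seed)
    candidates, normal_sites, dbsnp = [], [], set()
    used: set[tuple[str, int]] = set()
    while len(candidates) < n:
        i = len(candidates)
        gene = panel.genes[int(rng.integers(len(panel.genes)))]
        if rng.random() < 0.05:  # off-target position
            pos = gene.span[1] + int(rng.integers(1, 500))
            ref, alt = "A", "C"
        else:
            off = int(rng.integers(gene.cds_length))
            pos = gene.exon_offset_to_genomic(off)
            ref = gene.genomic_cds[off]
            r = rng.random()
            if r < 0.12:
                alt = "+" + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            elif r < 0.24:
                length = int(rng.integers(1, 4))
                alt = "-" + gene.genomic_cds[off + 1 : off + 1 + length]
                if len(alt) == 1:
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if (gene.chrom, pos) in used:  # one pileup row per position
            continue
        used.add((gene.chrom, pos))
        depth = int(rng.integers(20, 300))
        v = max(int(depth * rng.uniform(0.2, 0.6)), 2)
        candidates.append(
            ps.VariantCandidate(f"S{i}", gene.chrom, pos, ref, alt, v, depth, 33.0)
        )
        u = rng.random()
        if u < 0.15:
            pass  # normal not covered
        else:
            n_depth = int(rng.integers(0, 200))
            n_var = int(rng.choice([0, 0, 0, 1, 2]))
            counts = {}
            quals = {}
            if n_depth > 0:
                counts[ref] = n_depth
                quals[ref] = 33.0
            if n_var > 0:
                counts[alt] = n_var
                quals[alt] = 25.0
            normal_sites.append(SiteCounts("N", gene.chrom, pos, ref, counts, quals))
        if rng.random() < 0.2:
            dbsnp.add((gene.chrom, pos, ref, alt))
    return candidates, normal_sites, dbsnp


def test_filter_agrees_with_brute_force_oracle(small_panel):
    candidates, normal_sites, dbsnp = make_random_candidates(small_panel, 1000, seed=99)
    calls = ps.filter_somatic(candidates, normal_sites, dbsnp, small_panel)
    mismatches = [
        (call.candidate.key, call.first_failed_condition)
        for call, cand in zip(calls, candidates)
        if call.accepted != _oracle_filter(small_panel, cand, normal_sites, dbsnp)
    ]
    assert mismatches == []


def test_lowering_normal_tolerance_never_adds_calls(small_cohort):
    panel = small_cohort.panel
    cands = ps.detect_variants(small_cohort.site_counts["P01-T"])
    loose = CallingThresholds(max_normal_variant_reads=2, min_normal_wt_reads=5)
    tight = CallingThresholds(max_normal_variant_reads=0, min_normal_wt_reads=15)
    normals = small_cohort.site_counts["P01-N"]
    loose_set = {
        c.candidate.key
        for c in accepted_calls(ps.filter_somatic(cands, normals, set(), panel, loose))
    }
    tight_set = {
        c.candidate.key
        for c in accepted_calls(ps.filter_somatic(cands, normals, set(), panel, tight))
    }
    assert tight_set <= loose_set


# ---------------------------------------------------------------------------
# recovery and recurrence

def test_planted_variant_recovery_and_snp_exclusion():
    """Nearly all planted clonal nonsynonymous variants with VAF >= 0.25 are
    accepted; germline dbSNP polymorphisms never pass the somatic filter."""
    panel = ps.make_panel(40, 4000, seed=11)
    cfg = ps.CohortConfig(n_patients=120, snvs_per_tumor=10, seed=11)
    cohort = ps.simulate_cohort(panel, cfg)
    planted = [
        v for v in cohort.truth.somatic_variants
        if v.consequence in NONSYNONYMOUS and v.true_vaf >= 0.25
    ]
    called = 0
    snp_passes = 0
    for patient in cohort.patients:
        cands = ps.detect_variants(cohort.site_counts[f"{patient}-T"])
        calls = ps.filter_somatic(
            cands, cohort.site_counts[f"{patient}-N"], cohort.dbsnp_set, panel
        )
        acc = {c.candidate.key for c in accepted_calls(calls)}
        called += sum(
            (v.chrom, v.pos, v.ref, v.alt) in acc
            for v in planted
            if v.patient == patient
        )
        snp_keys = {
            (s.chrom, s.pos, s.ref, s.alt)
            for s in cohort.truth.germline_snps
            if s.patient == patient
        }
        snp_passes += len(acc & snp_keys)
    assert len(planted) > 300
    assert called / len(planted) >= 0.99
    assert snp_passes == 0


def test_find_recurrent_counts_patients_not_rows(small_panel):
    gene = small_panel.genes[0]
    pos = gene.exon_offset_to_genomic(10)
    ref = gene.genomic_cds[10]
    alt = "A" if ref != "A" else "G"

    def call(sample):
        cand = ps.VariantCandidate(sample, gene.chrom, pos, ref, alt, 30, 100, 33.0)
        return ps.SomaticCall(cand, 0, 50, False, gene.name, "missense", False,
                              [("nonsynonymous", True)])

    assert ps.find_recurrent([call("P1"), call("P2")]) == {
        (gene.chrom, pos, ref, alt): 2
    }
    assert ps.find_recurrent([call("P1")]) == {}
    # duplicate rows from one patient count once
    assert ps.find_recurrent([call("P1"), call("P1")]) == {}
    assert ps.find_recurrent([call("P1"), call("P1"), call("P2")]) == {
        (gene.chrom, pos, ref, alt): 2
    }
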