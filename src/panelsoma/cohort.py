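"""Cohort-level summarization: alteration matrix, frequencies, burden,
MSI association, pathway flags and actionability reporting.

The central object is the patient x gene alteration matrix, whose cells hold
the set of alteration types observed (point mutation, indel, copy gain, copy
loss).  A patient is "altered" in a gene when the cell is non-empty — union
semantics, so a gene hit by both an indel and a copy loss still counts once.

Association of gene alteration with MSI status (MSI-H vs MSS/MSI-L) uses the
two-sided Fisher exact test (minimum-likelihood rule); mutation/CNV burden is
compared between MSI groups with Welch's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .msi import MSI_H

ALTERATION_TYPES = ("point_mutation", "indel", "cn_gain", "cn_loss")

#: Gain-of-function RAS/RAF pathway set: activating mutations of the RAS/RAF
#: oncogenes, or copy gain of HRAS / RAF1.
DEFAULT_GENE_SETS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "RAS/RAF": [
        ("KRAS", ("point_mutation",)),
        ("NRAS", ("point_mutation",)),
        ("BRAF", ("point_mutation",)),
        ("HRAS", ("cn_gain",)),
        ("RAF1", ("cn_gain",)),
    ],
}


@dataclass
class ActionabilityRule:
    treatment_label: str
    gene: str
    alteration_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alteration_types:
            raise ValueError("rule needs at least one alteration type")
        bad = set(self.alteration_types) - set(ALTERATION_TYPES)
        if bad:
            raise ValueError(f"unknown alteration types {sorted(bad)}")


#: Alteration/treatment pairings of the default actionability report.
DEFAULT_ACTIONABILITY_RULES = [
    ActionabilityRule("ERBB2 directed treatment", "ERBB2", ("cn_gain", "point_mutation", "indel")),
    ActionabilityRule("EGFR directed treatment", "EGFR", ("cn_gain",)),
    ActionabilityRule("PI3K inhibitor", "PIK3CA", ("point_mutation", "indel")),
    ActionabilityRule("PI3K inhibitor", "PTEN", ("cn_loss", "point_mutation", "indel")),
    ActionabilityRule("PARP inhibitor", "BRCA1", ("cn_loss", "point_mutation", "indel")),
    ActionabilityRule("PARP inhibitor", "BRCA2", ("cn_loss", "point_mutation", "indel")),
]


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


@dataclass
class AlterationMatrix:
    """Patient x gene map of alteration-type sets."""

    patients: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, patient: str, gene: str, alteration: str) -> None:
        if patient not in self._patient_set:
            raise KeyError(f"unknown patient {patient}")
        if gene not in self._gene_set:
            raise KeyError(f"gene {gene} not in panel")
        if alteration not in ALTERATION_TYPES:
            raise ValueError(f"unknown alteration type {alteration}")
        self.cells.setdefault((patient, gene), set()).add(alteration)

    def __post_init__(self) -> None:
        self._patient_set = set(self.patients)
        self._gene_set = set(self.genes)

    def cell(self, patient: str, gene: str) -> set[str]:
        return self.cells.get((patient, gene), set())

    def is_altered(self, patient: str, gene: str) -> bool:
        return bool(self.cell(patient, gene))

    def altered_patients(self, gene: str) -> list[str]:
        return [p for p in self.patients if self.is_altered(p, gene)]


def build_alteration_matrix(
    patients: list[str],
    genes: list[str],
    somatic_calls: list[tuple[str, str, str]],
    cnv_calls: list[tuple[str, str, str]],
) -> AlterationMatrix:
    """Combine mutation and copy-number events into one matrix.

    ``somatic_calls`` are (patient, gene, kind) with kind ``snv``/``indel``;
    ``cnv_calls`` are (patient, gene, status) with status ``gain``/``loss``
    (neutral entries are ignored).  Repeated events of one type collapse.
    """
    matrix = AlterationMatrix(patients=list(patients), genes=list(genes))
    for patient, gene, kind in somatic_calls:
        matrix.add(patient, gene, "indel" if kind == "indel" else "point_mutation")
    for patient, gene, status in cnv_calls:
        if status == "neutral":
            continue
        matrix.add(patient, gene, f"cn_{status}")
    return matrix


def _percent(count: int, total: int) -> int:
    """Integer percentage, rounded half-up as in printed frequency tables."""
    return int(math.floor(100.0 * count / total + 0.5))


def gene_frequency_table(matrix: AlterationMatrix) -> list[tuple[str, int, int]]:
    """Per-gene (gene, n_altered, percent) sorted by descending frequency."""
    if not matrix.patients:
        raise ValueError("frequency table needs at least one patient")
    total = len(matrix.patients)
    rows = [
        (gene, len(matrix.altered_patients(gene))) for gene in matrix.genes
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return [(gene, n, _percent(n, total)) for gene, n in rows]


def burden_summary(counts_per_patient: dict[str, int]) -> dict:
    """Cohort median and range of a per-patient count (mutations, mutated
    genes, CNV genes, ...)."""
    values = list(counts_per_patient.values())
    if not values:
        return {"per_patient": {}, "median": float("nan"), "range": (0, 0)}
    return {
        "per_patient": dict(counts_per_patient),
        "median": float(np.median(values)),
        "range": (int(min(values)), int(max(values))),
    }


def fisher_association(
    matrix: AlterationMatrix, msi_classes: dict[str, str], gene: str
) -> ContingencyResult:
    """Two-sided Fisher exact test of gene alteration vs MSI-H status.

    Rows: altered / not altered; columns: MSI-H / MSS+MSI-L.  The odds ratio
    is the sample odds ratio ad/bc (infinite when bc = 0).
    """
    groups = {True: [], False: []}
    for patient in matrix.patients:
        groups[msi_classes[patient] == MSI_H].append(patient)
    if not groups[True] or not groups[False]:
        raise ValueError("both MSI groups must be non-empty")
    a = sum(matrix.is_altered(p, gene) for p in groups[True])
    b = len(groups[True]) - a
    c = sum(matrix.is_altered(p, gene) for p in groups[False])
    d = len(groups[False]) - c
    return fisher_exact_2x2(((a, b), (c, d)))


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher exact p for a 2x2 table by the minimum-likelihood
    rule (sum of all fixed-margin tables no more probable than the observed
    one, with 1e-7 relative tolerance on the comparison)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p))


def burden_ttest(
    counts_per_patient: dict[str, int], msi_classes: dict[str, str]
) -> dict:
    """Welch two-sample t-test of a per-patient burden, MSI-H vs MSS/MSI-L."""
    high = [v for p, v in counts_per_patient.items() if msi_classes[p] == MSI_H]
    other = [v for p, v in counts_per_patient.items() if msi_classes[p] != MSI_H]
    if len(high) < 2 or len(other) < 2:
        raise ValueError("each MSI group needs at least 2 patients")
    if np.var(high) == 0 and np.var(other) == 0 and np.mean(high) == np.mean(other):
        t, p = 0.0, 1.0  # degenerate constant groups: no evidence either way
    else:
        t, p = stats.ttest_ind(high, other, equal_var=False)
    return {
        "mean_msi_h": float(np.mean(high)),
        "mean_mss_msi_l": float(np.mean(other)),
        "t": float(t),
        "p_two_sided": float(p),
    }


def pathway_flags(
    matrix: AlterationMatrix,
    gene_sets: dict[str, list[tuple[str, tuple[str, ...]]]] | None = None,
) -> dict[str, set[str]]:
    """Per-patient set of flagged pathways: a pathway is flagged when any
    member gene shows a qualifying alteration type."""
    gene_sets = gene_sets if gene_sets is not None else DEFAULT_GENE_SETS
    flags: dict[str, set[str]] = {p: set() for p in matrix.patients}
    for name, members in gene_sets.items():
        for gene, types in members:
            if gene not in matrix._gene_set:
                continue
            for patient in matrix.patients:
                if matrix.cell(patient, gene) & set(types):
                    flags[patient].add(name)
    return flags


def actionability_report(
    matrix: AlterationMatrix, rules: list[ActionabilityRule] | None = None
) -> dict[str, list[str]]:
    """Patients matched by each candidate-treatment rule set; a patient is
    listed once per treatment no matter how many rules match."""
    rules = rules if rules is not None else DEFAULT_ACTIONABILITY_RULES
    report: dict[str, list[str]] = {}
    for rule in rules:
        matched = report.setdefault(rule.treatment_label, [])
        if rule.gene not in matrix._gene_set:
            continue
        for patient in matrix.patients:
            if patient in matched:
                continue
            if matrix.cell(patient, rule.gene) & set(rule.alteration_types):
                matched.append(patient)
    for label in report:
        report[label] = sorted(set(report[label]), key=matrix.patients.index)
    return report
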