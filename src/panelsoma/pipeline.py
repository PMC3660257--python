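"""End-to-end pipeline: simulate or ingest a cohort, call somatic variants,
estimate purity, call copy number, type MSI, and summarize the cohort.

Outputs are plain-text reports in the chosen directory: per-patient somatic
VCFs, purity TSV, per-gene CNV TSVs, MSI TSV, gene frequency table,
MSI-association table, actionability table and a JSON summary with per-stage
record counts.  Given a fixed seed a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as psio
from .calling import (
    CallingThresholds,
    SomaticCall,
    accepted_calls,
    detect_variants,
    filter_somatic,
    find_recurrent,
)
from .cohort import (
    DEFAULT_ACTIONABILITY_RULES,
    DEFAULT_GENE_SETS,
    actionability_report,
    build_alteration_matrix,
    burden_summary,
    burden_ttest,
    fisher_association,
    gene_frequency_table,
    pathway_flags,
)
from .msi import MSI_H, classify_msi
from .panel import make_panel
from .purity_cnv import (
    CnvThresholds,
    CopyCall,
    PurityEstimate,
    cohort_median,
    call_gene_cnvs,
    estimate_purity,
)
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and sample."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_all`.

    ``mode`` is ``simulate`` (generate a synthetic cohort from ``cohort``)
    or ``ingest`` (read panel/dbSNP/MSI/manifest files from disk).
    """

    out_dir: str = "panelsoma_report"
    seed: int = 0
    mode: str = "simulate"
    n_genes: int = 183
    mean_cds_length: int = 5400
    cohort: CohortConfig = field(default_factory=CohortConfig)
    calling: CallingThresholds = field(default_factory=CallingThresholds)
    cnv: CnvThresholds = field(default_factory=CnvThresholds)
    purity_floor: float = 0.1
    purity_agg: str = "median"
    # ingest-mode paths
    panel_bed: str | None = None
    panel_model: str | None = None
    dbsnp: str | None = None
    msi: str | None = None
    manifest: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.calling.validate()
        self.cnv.validate()
        if self.mode == "ingest":
            paths = [self.panel_bed, self.panel_model, self.dbsnp, self.msi]
            paths += [entry.get(k) for entry in self.manifest for k in (
                "tumor_pileup", "normal_pileup", "tumor_coverage", "normal_coverage")]
            for p in paths:
                if p is None:
                    raise ValueError("ingest mode requires panel, dbsnp, msi and manifest paths")
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            for entry in self.manifest:
                if "id" not in entry:
                    raise ValueError("manifest entries need an 'id'")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key == "cohort":
            cfg.cohort = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            })
        elif key == "calling":
            cfg.calling = CallingThresholds(**value)
        elif key == "cnv":
            cfg.cnv = CnvThresholds(**value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def _load_ingested(cfg: PipelineConfig) -> SyntheticCohort:
    panel = psio.read_panel(cfg.panel_bed, cfg.panel_model)
    dbsnp = psio.read_dbsnp(cfg.dbsnp)
    msi = psio.read_msi_markers(cfg.msi)
    patients, site_counts, coverage = [], {}, {}
    for entry in cfg.manifest:
        patient = entry["id"]
        patients.append(patient)
        site_counts[f"{patient}-T"] = psio.read_site_counts(entry["tumor_pileup"])
        site_counts[f"{patient}-N"] = psio.read_site_counts(entry["normal_pileup"])
        coverage[f"{patient}-T"] = psio.read_coverage(entry["tumor_coverage"])
        coverage[f"{patient}-N"] = psio.read_coverage(entry["normal_coverage"])
    from .synthetic import TruthSet

    return SyntheticCohort(
        panel=panel,
        config=cfg.cohort,
        patients=patients,
        site_counts=site_counts,
        coverage=coverage,
        dbsnp=[(c, p, r, a, ".") for c, p, r, a in sorted(dbsnp)],
        msi_markers=msi,
        truth=TruthSet({}, {}, [], [], {}),
    )


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage and write the report directory; returns its path."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    # stage 1: simulate or ingest
    if config.mode == "simulate":
        panel = make_panel(config.n_genes, config.mean_cds_length, seed=config.seed)
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = simulate_cohort(panel, cohort_cfg)
        sim_dir = out / "input"
        sim_dir.mkdir(exist_ok=True)
        psio.write_panel(cohort.panel, sim_dir / "panel.bed", sim_dir / "gene_models.tsv")
        psio.write_dbsnp(cohort.dbsnp, sim_dir / "dbsnp.tsv")
        psio.write_msi_markers(cohort.msi_markers, sim_dir / "msi_markers.tsv")
        psio.write_truth(cohort, sim_dir / "truth.json")
    else:
        cohort = _load_ingested(config)
    panel = cohort.panel
    dbsnp = cohort.dbsnp_set
    counts["cohort"] = {
        "patients": len(cohort.patients),
        "panel_genes": len(panel.genes),
        "dbsnp_entries": len(cohort.dbsnp),
    }

    # stage 2: somatic calling
    vcf_dir = out / "calls"
    vcf_dir.mkdir(exist_ok=True)
    all_calls: dict[str, list[SomaticCall]] = {}
    n_candidates = n_accepted = 0
    for patient in cohort.patients:
        t_id, n_id = f"{patient}-T", f"{patient}-N"
        if n_id not in cohort.site_counts:
            raise PipelineError(f"calling: patient {patient} has no normal sample")
        try:
            candidates = detect_variants(cohort.site_counts[t_id], config.calling)
            calls = filter_somatic(
                candidates, cohort.site_counts[n_id], dbsnp, panel, config.calling
            )
        except Exception as exc:  # noqa: BLE001 - stage/sample context required
            raise PipelineError(f"calling: patient {patient}: {exc}") from exc
        all_calls[patient] = calls
        n_candidates += len(candidates)
        n_accepted += len(accepted_calls(calls))
        psio.write_vcf(calls, vcf_dir / f"{patient}.vcf", panel, t_id)
    counts["calling"] = {
        "candidates": n_candidates,
        "accepted": n_accepted,
        "rejected": n_candidates - n_accepted,
    }

    # stage 3: purity and copy number
    purities: dict[str, PurityEstimate] = {}
    for patient, calls in all_calls.items():
        snvs = [
            (c.candidate.variant_reads, c.candidate.depth)
            for c in accepted_calls(calls)
            if not c.candidate.alt.startswith(("+", "-"))
        ]
        if snvs:
            purities[patient] = estimate_purity(snvs, sample_id=patient, agg=config.purity_agg)
    snv_based = list(purities.values())
    fallback = cohort_median(snv_based) if snv_based else None
    for patient in cohort.patients:
        if patient not in purities:
            if fallback is None:
                raise PipelineError(f"purity: patient {patient}: no SNVs and empty cohort")
            purities[patient] = estimate_purity(
                [], fallback_median=fallback, sample_id=patient
            )
    with open(out / "purity.tsv", "w") as fh:
        fh.write("patient\tpurity\tn_snvs\tmethod\n")
        for patient in cohort.patients:
            e = purities[patient]
            fh.write(f"{patient}\t{e.purity:.4f}\t{e.n_snvs_used}\t{e.method}\n")
    counts["purity"] = {
        "snv_based": sum(e.method == "snv_vaf" for e in purities.values()),
        "fallback": sum(e.method == "cohort_median_fallback" for e in purities.values()),
        "cohort_median": round(fallback, 4) if fallback is not None else None,
    }

    cnv_dir = out / "cnv"
    cnv_dir.mkdir(exist_ok=True)
    cnv_calls: dict[str, list[CopyCall]] = {}
    for patient in cohort.patients:
        try:
            calls = call_gene_cnvs(
                cohort.coverage[f"{patient}-T"],
                cohort.coverage[f"{patient}-N"],
                purities[patient].purity,
                config.cnv,
                config.purity_floor,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"cnv: patient {patient}: {exc}") from exc
        cnv_calls[patient] = calls
        with open(cnv_dir / f"{patient}.tsv", "w") as fh:
            fh.write("gene\traw_ratio\tnorm_ratio\tadj_ratio\tstatus\n")
            for c in calls:
                fh.write(
                    f"{c.gene}\t{c.raw_ratio:.4f}\t{c.norm_ratio:.4f}\t{c.adj_ratio:.4f}\t{c.status}\n"
                )
    counts["cnv"] = {
        "gain_events": sum(c.status == "gain" for cs in cnv_calls.values() for c in cs),
        "loss_events": sum(c.status == "loss" for cs in cnv_calls.values() for c in cs),
    }

    # stage 4: MSI typing
    msi_classes = {p: classify_msi(v) for p, v in cohort.msi_markers.items()}
    with open(out / "msi.tsv", "w") as fh:
        fh.write("patient\t" + "\t".join(psio.MSI_MARKERS) + "\tmsi_class\n")
        for patient in cohort.patients:
            vector = cohort.msi_markers[patient]
            fh.write(
                patient + "\t" + "\t".join(str(int(v)) for v in vector)
                + f"\t{msi_classes[patient]}\n"
            )
    counts["msi"] = {
        "MSI-H": sum(c == "MSI-H" for c in msi_classes.values()),
        "MSI-L": sum(c == "MSI-L" for c in msi_classes.values()),
        "MSS": sum(c == "MSS" for c in msi_classes.values()),
    }

    # stage 5: cohort summarization
    somatic_rows = [
        (p, c.gene, "indel" if c.candidate.alt.startswith(("+", "-")) else "snv")
        for p, calls in all_calls.items()
        for c in accepted_calls(calls)
    ]
    cnv_rows = [
        (p, c.gene, c.status) for p, calls in cnv_calls.items() for c in calls
    ]
    matrix = build_alteration_matrix(
        cohort.patients, panel.gene_names, somatic_rows, cnv_rows
    )
    freq = gene_frequency_table(matrix)
    with open(out / "gene_frequency.tsv", "w") as fh:
        fh.write("gene\tn_altered\tpercent\n")
        for gene, n, pct in freq:
            fh.write(f"{gene}\t{n}\t{pct}\n")

    mutations_per_patient = {
        p: len(accepted_calls(calls)) for p, calls in all_calls.items()
    }
    mutated_genes_per_patient = {
        p: len({c.gene for c in accepted_calls(calls)}) for p, calls in all_calls.items()
    }
    cnv_genes_per_patient = {
        p: sum(c.status != "neutral" for c in calls) for p, calls in cnv_calls.items()
    }
    burden = {
        "mutations": burden_summary(mutations_per_patient),
        "mutated_genes": burden_summary(mutated_genes_per_patient),
        "cnv_genes": burden_summary(cnv_genes_per_patient),
    }

    associations = []
    have_both_groups = 0 < counts["msi"]["MSI-H"] < len(cohort.patients)
    if have_both_groups:
        for gene, n_altered, _ in freq:
            if n_altered == 0:
                continue
            result = fisher_association(matrix, msi_classes, gene)
            associations.append((gene, result))
        associations.sort(key=lambda t: (t[1].p_two_sided, t[0]))
        with open(out / "msi_association.tsv", "w") as fh:
            fh.write(
                "gene\taltered_msi_h\tn_msi_h\taltered_mss_msi_l\tn_mss_msi_l\todds_ratio\tp_two_sided\n"
            )
            for gene, r in associations:
                (a, b), (c, d) = r.table
                orr = "inf" if r.odds_ratio == float("inf") else f"{r.odds_ratio:.4g}"
                fh.write(f"{gene}\t{a}\t{a + b}\t{c}\t{c + d}\t{orr}\t{r.p_two_sided:.6g}\n")

    ttests = {}
    if have_both_groups and 2 <= counts["msi"]["MSI-H"] <= len(cohort.patients) - 2:
        ttests = {
            "mutated_genes": burden_ttest(mutated_genes_per_patient, msi_classes),
            "cnv_genes": burden_ttest(cnv_genes_per_patient, msi_classes),
        }

    flags = pathway_flags(matrix, DEFAULT_GENE_SETS)
    treatments = actionability_report(matrix, DEFAULT_ACTIONABILITY_RULES)
    with open(out / "actionability.tsv", "w") as fh:
        fh.write("treatment\tn_patients\tpatients\n")
        for label in sorted(treatments):
            patients = treatments[label]
            fh.write(f"{label}\t{len(patients)}\t{','.join(patients)}\n")

    recurrent = find_recurrent(
        [c for calls in all_calls.values() for c in accepted_calls(calls)]
    )

    report = {
        "seed": config.seed,
        "stage_counts": counts,
        "burden": burden,
        "msi_ttests": ttests,
        "recurrent_variants": {
            f"{c}:{p}:{r}>{a}": n for (c, p, r, a), n in sorted(recurrent.items())
        },
        "pathway_flag_counts": {
            name: sum(name in f for f in flags.values())
            for name in sorted({n for f in flags.values() for n in f} | set(DEFAULT_GENE_SETS))
        },
        "actionability": {label: len(p) for label, p in sorted(treatments.items())},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out)
    return out
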