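"""End-to-end pipeline: simulate -> discover -> annotate -> classify -> stats.

Each stage logs record counts in and out so every filter's attrition is
auditable, and a run manifest captures the configuration snapshot, seed,
output digests and per-stage counts; re-running with the manifest's
config and seed reproduces byte-identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .classify import (
    ClassifierConfig,
    GroupAssignment,
    PoleAssessment,
    assign_cohort,
    detect_hypermutated,
    pathway_pattern,
    pole_hotspot_assessment,
)
from .discovery import DiscoveryConfig, discover_somatic
from .filtering import FilterConfig, SampleSummary, summarize_sample, tier_sample
from .io import (
    write_annotation_db,
    write_clinical_table,
    write_somatic_callset,
    write_variant_table,
)
from .model import ValidationError
from .panel import POLE
from .simulate import Cohort, CohortConfig, make_annotation_fixture, simulate_cohort
from .stats import ComparisonTable, build_comparison_table

log = logging.getLogger("endopanel")


@dataclass(slots=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    @classmethod
    def from_mapping(cls, payload: dict) -> "PipelineConfig":
        """Build a config from a (YAML-parsed) nested mapping.

        Only recognised keys are accepted; counts given under
        ``cohort.counts`` replace the default composition wholesale.
        """
        cfg = cls()
        if not isinstance(payload, dict):
            raise ValidationError("config must be a mapping")
        cfg.seed = int(payload.get("seed", cfg.seed))
        cohort = payload.get("cohort", {})
        if "counts" in cohort:
            counts = {str(k): int(v) for k, v in cohort["counts"].items()}
            cfg.cohort = CohortConfig(counts=counts)
        for key, value in cohort.items():
            if key in ("recurrence_prob_eac", "recurrence_prob_usc"):
                setattr(cfg.cohort, key, float(value))
        for section, target in (("discovery", cfg.discovery),
                                ("filters", cfg.filters),
                                ("classifier", cfg.classifier)):
            for key, value in payload.get(section, {}).items():
                if not hasattr(target, key):
                    raise ValidationError(f"unknown {section} option {key!r}")
                current = getattr(target, key)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(target, key, type(current)(value) if not isinstance(current, tuple) else value)
        return cfg

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "cohort": {
                "counts": dict(self.cohort.counts),
                "recurrence_prob_eac": self.cohort.recurrence_prob_eac,
                "recurrence_prob_usc": self.cohort.recurrence_prob_usc,
            },
            "discovery": asdict(self.discovery),
            "filters": asdict(self.filters),
            "classifier": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.classifier).items()
            },
        }


@dataclass(slots=True)
class PipelineResult:
    cohort: Cohort
    summaries: list[SampleSummary]
    assignments: list[GroupAssignment]
    hypermutated: set[str]
    pole: dict[str, PoleAssessment]
    patterns: dict[str, str]
    tables: dict[str, ComparisonTable]
    outdir: Optional[Path] = None


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyse_cohort(cohort: Cohort, cfg: PipelineConfig, annotation_db=None):
    """Run discovery, tiering, classification and stats on a cohort.

    Returns (summaries, assignments, hypermutated ids, POLE assessments,
    pathway patterns, comparison tables, per-sample artifacts).
    """
    if annotation_db is None:
        annotation_db = make_annotation_fixture(cohort, seed=cfg.seed)
    artifacts = {}
    summaries: list[SampleSummary] = []
    for pair in cohort.pairs:
        callset = discover_somatic(pair.tumor, pair.normal, cfg=cfg.discovery)
        retained = [v for v in callset.retained() if v.gene != POLE]
        tiered, syn_scored, removed = tier_sample(retained, annotation_db, cfg.filters)
        summary = summarize_sample(
            pair.sample_id, retained, tiered,
            collapse_complements=cfg.classifier.collapse_complements,
        )
        summaries.append(summary)
        pole_calls = [v for v in pair.tumor if v.gene == POLE]
        pole = pole_hotspot_assessment(pair.sample_id, pole_calls, annotation_db,
                                       cfg.classifier)
        artifacts[pair.sample_id] = {
            "callset": callset, "tiered": tiered, "synonymous": syn_scored,
            "removed": removed, "pole": pole,
        }
        log.info(
            "sample %s: %d tumor calls -> %d retained somatic -> %d tiered "
            "(%d pathogenic, %d candidate)",
            pair.sample_id, len(pair.tumor), len(retained), len(tiered),
            summary.n_pathogenic, summary.n_candidate,
        )

    hyper = detect_hypermutated(summaries, cfg.classifier)
    for s in summaries:
        s.hypermutated = s.sample_id in hyper
    assignments = assign_cohort(summaries, cfg.classifier)
    patterns = {s.sample_id: pathway_pattern(s, cfg.classifier).value for s in summaries}
    pole = {sid: artifacts[sid]["pole"] for sid in artifacts}
    tables = {
        "histology": build_comparison_table(cohort.clinical, summaries, "histology"),
        "grade_histology": build_comparison_table(cohort.clinical, summaries, "grade_histology"),
        "hypermutation": build_comparison_table(cohort.clinical, summaries, "hypermutation"),
    }
    return summaries, assignments, hyper, pole, patterns, tables, artifacts


def _write_summaries(summaries: list[SampleSummary], path: Path) -> None:
    from .classify import SPECTRUM_CLASSES
    from .filtering import TRACKED_GENES

    with open(path, "w", encoding="utf-8") as fh:
        head = [
            "sample_id", "n_unfiltered", "n_unfiltered_snv", "n_unfiltered_indel",
            *[f"spectrum_{c.replace('>', '_')}" for c in SPECTRUM_CLASSES],
            "n_filtered_snv", "n_filtered_indel", "n_pathogenic", "n_candidate",
            "n_path_plus_cand", *[f"hit_{g}" for g in TRACKED_GENES], "hypermutated",
        ]
        fh.write("\t".join(head) + "\n")
        for s in summaries:
            row = [
                s.sample_id, s.n_unfiltered, s.n_unfiltered_snv, s.n_unfiltered_indel,
                *[s.spectrum[c] for c in SPECTRUM_CLASSES],
                s.n_filtered_snv, s.n_filtered_indel, s.n_pathogenic, s.n_candidate,
                s.n_path_plus_cand,
                *["true" if s.gene_hits[g] else "false" for g in TRACKED_GENES],
                "true" if s.hypermutated else "false",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_summaries(path) -> list[SampleSummary]:
    """Read a summary TSV written by the pipeline back into objects."""
    from .classify import SPECTRUM_CLASSES
    from .filtering import TRACKED_GENES
    import csv

    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                SampleSummary(
                    sample_id=row["sample_id"],
                    n_unfiltered=int(row["n_unfiltered"]),
                    n_unfiltered_snv=int(row["n_unfiltered_snv"]),
                    n_unfiltered_indel=int(row["n_unfiltered_indel"]),
                    spectrum={
                        c: int(row[f"spectrum_{c.replace('>', '_')}"])
                        for c in SPECTRUM_CLASSES
                    },
                    n_filtered_snv=int(row["n_filtered_snv"]),
                    n_filtered_indel=int(row["n_filtered_indel"]),
                    n_pathogenic=int(row["n_pathogenic"]),
                    n_candidate=int(row["n_candidate"]),
                    gene_hits={g: row[f"hit_{g}"] == "true" for g in TRACKED_GENES},
                    hypermutated=row["hypermutated"] == "true",
                )
            )
    return out


def _write_assignments(assignments, hyper, patterns, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\thypermutated\tpathway_pattern\t"
                 "thresholds\tfired_rules\n")
        for a in assignments:
            t = a.thresholds_used
            thr = f"burden>{t.burden_gt};C>A>{t.ca_gt};C>G<{t.cg_lt};{t.source}"
            fh.write(
                f"{a.sample_id}\t{a.group}\t"
                f"{'true' if a.sample_id in hyper else 'false'}\t"
                f"{patterns[a.sample_id]}\t{thr}\t{' | '.join(a.fired_rules)}\n"
            )


def run_pipeline(
    cfg: Optional[PipelineConfig] = None,
    outdir="pipeline_out",
) -> PipelineResult:
    """Run the full chain on a synthetic cohort and write all outputs."""
    if cfg is None:
        cfg = PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "variants").mkdir(exist_ok=True)
    (outdir / "somatic").mkdir(exist_ok=True)

    log.info("simulating cohort: %s (seed %d)", cfg.cohort.counts, cfg.seed)
    cohort = simulate_cohort(cfg.cohort, seed=cfg.seed)
    db = make_annotation_fixture(cohort, seed=cfg.seed)

    for pair in cohort.pairs:
        write_variant_table(pair.tumor, outdir / "variants" / f"{pair.sample_id}.tumor.tsv")
        write_variant_table(pair.normal, outdir / "variants" / f"{pair.sample_id}.normal.tsv")
    write_annotation_db(db, outdir / "annotation_db.tsv")
    write_clinical_table(cohort.clinical, outdir / "clinical.tsv")

    summaries, assignments, hyper, pole, patterns, tables, artifacts = analyse_cohort(
        cohort, cfg, annotation_db=db
    )
    for sid, art in artifacts.items():
        write_somatic_callset(art["callset"], outdir / "somatic" / f"{sid}.somatic.tsv")

    _write_summaries(summaries, outdir / "sample_summaries.tsv")
    _write_assignments(assignments, hyper, patterns, outdir / "group_assignments.tsv")
    with open(outdir / "pole_assessments.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tstatus\tn_examined\tvariants\n")
        for sid in sorted(pole):
            a = pole[sid]
            names = ",".join(v.hgvs_p for v in a.examined) or "."
            fh.write(f"{sid}\t{a.status.value}\t{len(a.examined)}\t{names}\n")

    truth_payload = {
        sid: {
            "profile": t.profile_label,
            "truth_group": t.truth_group,
            "hypermutated": t.hypermutated,
            "drivers": {e: list(k) for e, k in t.planted_drivers.items()},
            "pole": {e: list(k) for e, k in t.planted_pole.items()},
            "n_artifacts": len(t.artifact_keys),
        }
        for sid, t in cohort.truth.samples.items()
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)

    _write_tables(tables, outdir / "comparison_tables.json")

    manifest = {
        "tool": "endopanel",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.snapshot(),
        "stage_counts": {
            "samples": len(cohort.pairs),
            "tumor_calls": sum(len(p.tumor) for p in cohort.pairs),
            "retained_somatic": sum(s.n_unfiltered for s in summaries),
            "pathogenic": sum(s.n_pathogenic for s in summaries),
            "candidate": sum(s.n_candidate for s in summaries),
            "hypermutated": len(hyper),
        },
        "outputs": {
            str(p.relative_to(outdir)): _digest(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        cohort=cohort, summaries=summaries, assignments=assignments,
        hypermutated=hyper, pole=pole, patterns=patterns, tables=tables,
        outdir=outdir,
    )


def _write_tables(tables: dict[str, ComparisonTable], path: Path) -> None:
    payload = {}
    for key, table in tables.items():
        payload[key] = {
            "strata": list(table.strata),
            "rows": [
                {
                    "covariate": r.covariate,
                    "summaries": r.stratum_summaries,
                    "or": None if r.or_result is None or r.or_result.is_na
                    else {
                        "point": r.or_result.or_point,
                        "ci_low": r.or_result.ci_low,
                        "ci_high": r.or_result.ci_high,
                    },
                    "p_value": r.p_value,
                    "test": r.test,
                }
                for r in table.rows
            ],
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def render_report(outdir) -> str:
    """Render a human-readable run report from pipeline outputs.

    Regeneration from the same outputs is idempotent.
    """
    outdir = Path(outdir)
    required = ["group_assignments.tsv", "sample_summaries.tsv",
                "pole_assessments.tsv", "comparison_tables.json", "manifest.json"]
    for name in required:
        if not (outdir / name).exists():
            raise ValidationError(f"missing pipeline output {name} in {outdir}")

    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    summaries = read_summaries(outdir / "sample_summaries.tsv")
    groups: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    with open(outdir / "group_assignments.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            sid, group = line.split("\t")[:2]
            groups[int(group)].append(sid)

    lines = [
        "endopanel run report",
        "====================",
        f"version {manifest['version']}, seed {manifest['seed']}",
        "",
        "Molecular group assignment",
        "--------------------------",
    ]
    labels = {
        1: "Group 1 (POLE-ultramutated-like)",
        2: "Group 2 (MSI-like, MMR hit)",
        3: "Group 3 (TP53, no MMR hit)",
        4: "Group 4 (all others)",
    }
    for g in (1, 2, 3, 4):
        members = ", ".join(groups[g]) if groups[g] else "(none)"
        lines.append(f"{labels[g]}: n={len(groups[g])}  {members}")
    lines += ["", "Per-sample burden and tiering", "-" * 29]
    lines.append("sample\tunfiltered\tSNV\tpathogenic\tcandidate\thypermutated")
    for s in summaries:
        lines.append(
            f"{s.sample_id}\t{s.n_unfiltered}\t{s.n_unfiltered_snv}\t"
            f"{s.n_pathogenic}\t{s.n_candidate}\t{'yes' if s.hypermutated else 'no'}"
        )
    lines += ["", "POLE assessment", "-" * 15]
    with open(outdir / "pole_assessments.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            sid, status, _n, names = line.rstrip("\n").split("\t")
            if status != "none":
                lines.append(f"{sid}: {status} ({names})")
    with open(outdir / "comparison_tables.json", encoding="utf-8") as fh:
        tables = json.load(fh)
    for key, table in sorted(tables.items()):
        lines += ["", f"Comparison by {key}", "-" * (14 + len(key))]
        header = "covariate" + "".join(f"\t{s}" for s in table["strata"]) + "\tOR (95% CI)\tp"
        lines.append(header)
        for row in table["rows"]:
            cells = [row["covariate"]]
            cells += [row["summaries"].get(s, ".") for s in table["strata"]]
            if row["or"] is None:
                cells.append("N/A")
            else:
                cells.append(
                    f"{row['or']['point']:.2f} "
                    f"({row['or']['ci_low']:.2f}-{row['or']['ci_high']:.2f})"
                )
            cells.append("." if row["p_value"] is None else f"{row['p_value']:.3g}")
            lines.append("\t".join(cells))
    report = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report, encoding="utf-8")
    return report
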