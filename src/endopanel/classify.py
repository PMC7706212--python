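"""Substitution spectra, hypermutation detection, molecular group
assignment, POLE hotspot assessment, and pathway patterning.

Molecular groups are surrogates for the four genomically defined classes
of endometrial carcinoma:

* **Group 1** (POLE-ultramutated-like): very high unfiltered somatic
  burden with a C>A-rich / C>G-poor substitution spectrum. Fixed
  thresholds: burden > 570, C>A > 9, C>G < 1; quartile mode instead
  resolves the burden and C>A cutoffs at the cohort's 75th percentile
  and the C>G cutoff at the 25th percentile.
* **Group 2** (MSI-like): any somatic hit in MSH2, MSH6, MLH1 or PMS2.
* **Group 3** (serous-like): a TP53 hit without a mismatch-repair hit.
* **Group 4**: everything else.

Spectra are strand-collapsed to the six pyrimidine-reference classes by
default (G>T counts as C>A, and so on), because a substitution and its
reverse complement are the same biological event read from opposite
strands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np

from .model import (
    AnnotationDB,
    ClinVarAssertion,
    Domain,
    Effect,
    NONSYNONYMOUS_EFFECTS,
    Region,
    ValidationError,
    VariantCall,
)
from .panel import MMR_GENES, PI3K_GENES, TP53

if TYPE_CHECKING:  # pragma: no cover
    from .filtering import SampleSummary

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Reverse-complement mapping of purine-reference classes onto the six
#: canonical pyrimidine-reference classes.
COLLAPSE_MAP = {
    "G>T": "C>A", "G>C": "C>G", "G>A": "C>T",
    "A>T": "T>A", "A>G": "T>C", "A>C": "T>G",
}


@dataclass(slots=True)
class ClassifierConfig:
    mode: str = "fixed"  # "fixed" or "quartile"
    burden_gt: float = 570.0
    ca_gt: float = 9.0
    cg_lt: float = 1.0
    quantile_convention: str = "nearest-rank"
    mmr_genes: tuple[str, ...] = MMR_GENES
    pi3k_genes: tuple[str, ...] = PI3K_GENES
    tp53_gene: str = TP53
    pole_hotspots: tuple[str, ...] = ("p.Pro286Arg", "p.Val411Leu")
    pole_p_max: float = 0.05  # inclusive: <= 0.05 examined
    collapse_complements: bool = True
    precedence: tuple[int, int, int, int] = (1, 2, 3, 4)
    hypermutation_mode: str = "gap"  # "gap" or "fixed"
    hypermutation_fixed_cutoff: float = 184.0
    hypermutation_min_rel_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "quartile"):
            raise ValidationError(f"unknown classifier mode {self.mode!r}")
        if sorted(self.precedence) != [1, 2, 3, 4]:
            raise ValidationError("precedence must be a permutation of 1..4")
        if min(self.burden_gt, self.ca_gt, self.cg_lt) < 0:
            raise ValidationError("thresholds must be >= 0")


@dataclass(slots=True)
class ResolvedThresholds:
    burden_gt: float
    ca_gt: float
    cg_lt: float
    source: str  # "fixed" or "quartile:<convention>"


@dataclass(slots=True)
class GroupAssignment:
    sample_id: str
    group: int
    fired_rules: list[str] = field(default_factory=list)
    thresholds_used: Optional[ResolvedThresholds] = None


def substitution_spectrum(
    snvs: Iterable[VariantCall], collapse: bool = True
) -> dict[str, int]:
    """Count SNVs into substitution classes.

    With ``collapse`` (the default) the six pyrimidine-reference classes
    are returned; otherwise all twelve raw ``ref>alt`` classes appear as
    keys (canonical six always present). Non-SNV input is an error.
    """
    counts: dict[str, int] = {k: 0 for k in SPECTRUM_CLASSES}
    for v in snvs:
        if not v.is_snv:
            raise ValidationError(
                f"substitution_spectrum expects SNVs, got {v.var_class.value} at "
                f"{v.chrom}:{v.pos}"
            )
        cls = f"{v.ref}>{v.alt}"
        if collapse:
            cls = COLLAPSE_MAP.get(cls, cls)
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def nearest_rank_quantile(values: Sequence[float], p: float) -> float:
    """Nearest-rank quantile: the ceil(p*n)-th smallest observation."""
    if not values:
        raise ValidationError("quantile of empty sequence")
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"quantile level {p} outside (0, 1]")
    ordered = sorted(values)
    rank = int(np.ceil(p * len(ordered)))
    return float(ordered[rank - 1])


_QUANTILE_CONVENTIONS = {
    "nearest-rank": nearest_rank_quantile,
    "linear": lambda values, p: float(np.quantile(np.asarray(values, dtype=float), p)),
}


def quartile_thresholds(
    summaries: Sequence["SampleSummary"],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ResolvedThresholds:
    """Resolve quartile-mode thresholds from a cohort.

    Burden and C>A cutoffs are the cohort 75th percentiles; the C>G
    cutoff is the 25th percentile. Cohorts below 4 samples cannot
    define quartile groups.
    """
    if len(summaries) < 4:
        raise ValidationError(f"quartile thresholds need >= 4 samples, got {len(summaries)}")
    try:
        q = _QUANTILE_CONVENTIONS[cfg.quantile_convention]
    except KeyError:
        raise ValidationError(
            f"unknown quantile convention {cfg.quantile_convention!r}"
        ) from None
    burdens = [s.n_unfiltered for s in summaries]
    ca = [s.spectrum["C>A"] for s in summaries]
    cg = [s.spectrum["C>G"] for s in summaries]
    return ResolvedThresholds(
        burden_gt=q(burdens, 0.75),
        ca_gt=q(ca, 0.75),
        cg_lt=q(cg, 0.25),
        source=f"quartile:{cfg.quantile_convention}",
    )


def resolve_thresholds(
    cfg: ClassifierConfig,
    summaries: Optional[Sequence["SampleSummary"]] = None,
) -> ResolvedThresholds:
    if cfg.mode == "fixed":
        return ResolvedThresholds(
            burden_gt=cfg.burden_gt, ca_gt=cfg.ca_gt, cg_lt=cfg.cg_lt, source="fixed"
        )
    if summaries is None:
        raise ValidationError("quartile mode needs cohort summaries")
    return quartile_thresholds(summaries, cfg)


def assign_group(
    summary: "SampleSummary",
    thresholds: ResolvedThresholds,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> GroupAssignment:
    """Assign one sample to its molecular group.

    Groups are tested in ``cfg.precedence`` order (default 1, 2, 3, 4)
    and the first satisfied rule wins; Group 4 is the unconditional
    fallback. Quartile-mode thresholds must be resolved once per cohort
    and then applied per sample, so permuting cohort order can never
    change an assignment.
    """
    if not summary.spectrum:
        raise ValidationError(f"sample {summary.sample_id} has no spectrum")
    mmr_hit = any(summary.gene_hits.get(g, False) for g in cfg.mmr_genes)
    tp53_hit = summary.gene_hits.get(cfg.tp53_gene, False)
    trace: list[str] = []

    def rule(group: int) -> bool:
        if group == 1:
            ok = (
                summary.n_unfiltered > thresholds.burden_gt
                and summary.spectrum["C>A"] > thresholds.ca_gt
                and summary.spectrum["C>G"] < thresholds.cg_lt
            )
            if ok:
                trace.append(
                    f"group1: burden {summary.n_unfiltered} > {thresholds.burden_gt}, "
                    f"C>A {summary.spectrum['C>A']} > {thresholds.ca_gt}, "
                    f"C>G {summary.spectrum['C>G']} < {thresholds.cg_lt}"
                )
            return ok
        if group == 2:
            if mmr_hit:
                hits = [g for g in cfg.mmr_genes if summary.gene_hits.get(g)]
                trace.append(f"group2: MMR hit in {','.join(hits)}")
            return mmr_hit
        if group == 3:
            ok = tp53_hit and not mmr_hit
            if ok:
                trace.append("group3: TP53 hit without MMR hit")
            return ok
        trace.append("group4: no prior rule fired")
        return True

    for group in cfg.precedence:
        if rule(group):
            return GroupAssignment(
                sample_id=summary.sample_id, group=group,
                fired_rules=trace, thresholds_used=thresholds,
            )
    raise AssertionError("group 4 fallback must always fire")  # pragma: no cover


def assign_cohort(
    summaries: Sequence["SampleSummary"],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[GroupAssignment]:
    """Resolve thresholds once, then assign every sample."""
    thresholds = resolve_thresholds(cfg, summaries)
    return [assign_group(s, thresholds, cfg) for s in summaries]


def detect_hypermutated(
    summaries: Sequence["SampleSummary"],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> set[str]:
    """Flag hypermutated samples from post-review SNV burdens.

    The default rule formalises outlier detection by eye: sort the
    post-quality-review SNV counts, find the largest relative gap
    between consecutive values in the region above the cohort median,
    and flag everything above that gap when the gap is at least
    ``hypermutation_min_rel_gap`` (a cohort with no such break yields no
    flags). Because counts are post-review, samples whose raw burden was
    inflated by sequencing-error calls are judged on their surviving
    calls only. A fixed-cutoff mode is available for calibrated panels.
    """
    if len(summaries) < 5:
        raise ValidationError(f"hypermutation detection needs >= 5 samples, got {len(summaries)}")
    counts = {s.sample_id: s.n_unfiltered_snv for s in summaries}
    if cfg.hypermutation_mode == "fixed":
        return {sid for sid, c in counts.items() if c >= cfg.hypermutation_fixed_cutoff}
    if cfg.hypermutation_mode != "gap":
        raise ValidationError(f"unknown hypermutation mode {cfg.hypermutation_mode!r}")
    ordered = sorted(counts.values())
    median = float(np.median(ordered))
    best_gap = 0.0
    cut: Optional[float] = None
    for lo, hi in zip(ordered, ordered[1:]):
        if lo < median:
            continue
        rel = (hi - lo) / max(lo, 1.0)
        if rel > best_gap:
            best_gap = rel
            cut = (lo + hi) / 2.0
    if cut is None or best_gap < cfg.hypermutation_min_rel_gap:
        return set()
    return {sid for sid, c in counts.items() if c > cut}


class PoleStatus(str, enum.Enum):
    """Per-sample POLE assessment, ordered from most to least severe."""

    HOTSPOT = "hotspot"
    OTHER_PATHOGENIC = "other_pathogenic"
    UNKNOWN_IN_DOMAIN = "unknown_in_domain"
    UNKNOWN_OUTSIDE_DOMAIN = "unknown_outside_domain"
    BENIGN_ONLY = "benign_only"
    NONE = "none"


_POLE_SEVERITY = (
    PoleStatus.HOTSPOT,
    PoleStatus.OTHER_PATHOGENIC,
    PoleStatus.UNKNOWN_IN_DOMAIN,
    PoleStatus.UNKNOWN_OUTSIDE_DOMAIN,
    PoleStatus.BENIGN_ONLY,
)


@dataclass(slots=True)
class PoleAssessment:
    sample_id: str
    status: PoleStatus
    examined: list[VariantCall] = field(default_factory=list)
    per_variant: list[tuple[VariantCall, PoleStatus]] = field(default_factory=list)


def _classify_pole_variant(
    v: VariantCall, db: AnnotationDB, cfg: ClassifierConfig
) -> PoleStatus:
    if v.hgvs_p in cfg.pole_hotspots:
        return PoleStatus.HOTSPOT
    clinvar = db.lookup(v).clinvar
    if clinvar is ClinVarAssertion.PATHOGENIC:
        return PoleStatus.OTHER_PATHOGENIC
    if clinvar is ClinVarAssertion.BENIGN:
        return PoleStatus.BENIGN_ONLY
    if v.domain is Domain.FUNCTIONAL:
        return PoleStatus.UNKNOWN_IN_DOMAIN
    return PoleStatus.UNKNOWN_OUTSIDE_DOMAIN


def pole_hotspot_assessment(
    sample_id: str,
    pole_variants: Iterable[VariantCall],
    db: AnnotationDB,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> PoleAssessment:
    """Assess a sample's POLE add-on sequencing output.

    Calls are first filtered to caller p-value <= 0.05, exonic region
    and non-synonymous effect; each survivor is classified against the
    exonuclease-domain hotspot list (p.Pro286Arg, p.Val411Leu), the
    ClinVar assertion, and the protein-domain flag. The sample status is
    the most severe per-variant status; the severity ordering below
    "hotspot" is reported metadata, not a claim about biology.
    """
    examined = [
        v
        for v in pole_variants
        if v.caller_p <= cfg.pole_p_max
        and v.region is Region.EXONIC
        and v.effect in NONSYNONYMOUS_EFFECTS
        and v.effect is not Effect.SYNONYMOUS
    ]
    per_variant = [(v, _classify_pole_variant(v, db, cfg)) for v in examined]
    statuses = {s for _, s in per_variant}
    status = next((s for s in _POLE_SEVERITY if s in statuses), PoleStatus.NONE)
    return PoleAssessment(
        sample_id=sample_id, status=status, examined=examined, per_variant=per_variant
    )


class PathwayPattern(str, enum.Enum):
    PI3K_ONLY = "pi3k_only"
    TP53_ONLY = "tp53_only"
    BOTH = "both"
    NEITHER = "neither"


def pathway_pattern(
    summary: "SampleSummary", cfg: ClassifierConfig = ClassifierConfig()
) -> PathwayPattern:
    """PI3-kinase-pathway versus TP53 mutation pattern for one sample."""
    pi3k = any(summary.gene_hits.get(g, False) for g in cfg.pi3k_genes)
    tp53 = summary.gene_hits.get(cfg.tp53_gene, False)
    if pi3k and tp53:
        return PathwayPattern.BOTH
    if pi3k:
        return PathwayPattern.PI3K_ONLY
    if tp53:
        return PathwayPattern.TP53_ONLY
    return PathwayPattern.NEITHER
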