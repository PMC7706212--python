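"""Filtering cascade, pathogenicity tiering, and per-sample summaries.

After discovery, retained somatic calls pass through:

1. **Standard filters** — drop calls with caller p-value > 0.05 or
   population minor allele frequency > 1%; route synonymous calls to a
   separate predictor stream (they are scored, never tiered).
2. **Missense impact prediction** — SIFT < 0.05 calls deleterious,
   PolyPhen-2 >= 0.5 calls deleterious; concordantly benign calls
   (SIFT > 0.05 AND PolyPhen < 0.5) are filtered out, discordant calls
   are retained for further investigation.
3. **Tier assignment** — *pathogenic* on a ClinVar pathogenic assertion
   or a COSMIC occurrence count > 500; *candidate* on deleterious
   functional prediction, a COSMIC count of 1-500, or a driver-INDEL
   catalog overlap; everything else without annotation evidence is a
   variant of uncertain significance (VUS). A ClinVar *benign* assertion
   dominates and removes the call from the pathogenic/candidate streams.
4. **Synonymous scoring** — the mean of the TraP, SilVA and FATHMM-MKL
   scores; a mean strictly greater than 0.308 flags predicted
   deleterious synonymous change.

All threshold comparisons are strict exactly as printed: "> 0.05",
"> 1%", "> 500", "> 0.308". A COSMIC count of exactly 500 falls to the
candidate clause; exactly 0.05 / 1% / 0.308 are retained / retained /
not deleterious.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    AnnotationDB,
    AnnotationRecord,
    ClinVarAssertion,
    DbcidStatus,
    Effect,
    VarClass,
    ValidationError,
    VariantCall,
)
from .classify import substitution_spectrum, SPECTRUM_CLASSES
from .panel import MMR_GENES, PI3K_GENES, TP53


class Impact(str, enum.Enum):
    BENIGN_CONCORDANT = "benign_concordant"
    DELETERIOUS_CONCORDANT = "deleterious_concordant"
    DISCORDANT = "discordant"
    NOT_APPLICABLE = "not_applicable"


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    CANDIDATE = "candidate"
    VUS = "vus"
    FILTERED_OUT = "filtered_out"


class FilterReason(str, enum.Enum):
    CALLER_P = "caller_p"
    MAF = "maf"
    SYNONYMOUS_ROUTED = "synonymous_routed"
    BENIGN_PREDICTION = "benign_prediction"


class IndelDriverStatus(str, enum.Enum):
    DRIVER_EXACT = "driver_exact"
    DRIVER_OVERLAP = "driver_overlap"
    NONE = "none"


@dataclass(slots=True)
class FilterConfig:
    caller_p_max: float = 0.05   # strict: removed when caller_p > this
    maf_max: float = 0.01        # strict: removed when pop_maf > this
    cosmic_pathogenic_gt: int = 500
    prdsm_deleterious_gt: float = 0.308
    sift_deleterious_lt: float = 0.05
    polyphen_deleterious_ge: float = 0.5


@dataclass(slots=True)
class TieredVariant:
    variant: VariantCall
    annotation: AnnotationRecord
    impact: Impact
    tier: Tier
    filter_reasons: list[FilterReason] = field(default_factory=list)
    trace: list[str] = field(default_factory=list)
    indel_status: IndelDriverStatus = IndelDriverStatus.NONE
    clinvar_benign: bool = False


@dataclass(slots=True)
class PrdsmResult:
    """Mean-of-three synonymous pathogenicity score; unscored when any
    component predictor is missing."""

    score: Optional[float]
    deleterious: Optional[bool]
    scored: bool


@dataclass(slots=True)
class SampleSummary:
    """The per-sample attrition ledger every comparison table is built on."""

    sample_id: str
    n_unfiltered: int = 0
    n_unfiltered_snv: int = 0
    n_unfiltered_indel: int = 0
    spectrum: dict[str, int] = field(default_factory=dict)
    n_filtered_snv: int = 0
    n_filtered_indel: int = 0
    n_pathogenic: int = 0
    n_candidate: int = 0
    gene_hits: dict[str, bool] = field(default_factory=dict)
    hypermutated: bool = False

    @property
    def n_path_plus_cand(self) -> int:
        return self.n_pathogenic + self.n_candidate

    def validate(self) -> None:
        if sum(self.spectrum.values()) != self.n_unfiltered_snv:
            raise ValidationError("spectrum counts must sum to n_unfiltered_snv")
        if self.n_filtered_snv > self.n_unfiltered_snv:
            raise ValidationError("n_filtered_snv exceeds n_unfiltered_snv")


def apply_standard_filters(
    variants: Iterable[VariantCall],
    db: AnnotationDB,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[VariantCall], list[VariantCall], list[tuple[VariantCall, list[FilterReason]]]]:
    """Standard filters: caller p-value, population MAF, synonymous routing.

    Returns ``(kept, synonymous_stream, removed)`` where ``removed``
    pairs each dropped call with its reasons. A synonymous call that also
    fails p/MAF is removed (with all applicable reasons) rather than
    routed.
    """
    kept: list[VariantCall] = []
    synonymous: list[VariantCall] = []
    removed: list[tuple[VariantCall, list[FilterReason]]] = []
    for v in variants:
        rec = db.lookup(v)
        reasons: list[FilterReason] = []
        if v.caller_p > cfg.caller_p_max:
            reasons.append(FilterReason.CALLER_P)
        if rec.pop_maf > cfg.maf_max:
            reasons.append(FilterReason.MAF)
        if reasons:
            removed.append((v, reasons))
        elif v.effect is Effect.SYNONYMOUS:
            synonymous.append(v)
        else:
            kept.append(v)
    return kept, synonymous, removed


def predict_missense_impact(
    sift: Optional[float],
    polyphen: Optional[float],
    cfg: FilterConfig = FilterConfig(),
) -> Impact:
    """Concordance call from the two missense predictors.

    Benign-concordant iff SIFT > 0.05 and PolyPhen < 0.5;
    deleterious-concordant iff SIFT < 0.05 and PolyPhen >= 0.5; anything
    else (including boundary SIFT exactly 0.05) is discordant. Missing
    either score yields ``not_applicable`` (the call is retained).
    """
    if sift is None or polyphen is None:
        return Impact.NOT_APPLICABLE
    for name, v in (("sift", sift), ("polyphen", polyphen)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} score {v} outside [0, 1]")
    if sift > cfg.sift_deleterious_lt and polyphen < cfg.polyphen_deleterious_ge:
        return Impact.BENIGN_CONCORDANT
    if sift < cfg.sift_deleterious_lt and polyphen >= cfg.polyphen_deleterious_ge:
        return Impact.DELETERIOUS_CONCORDANT
    return Impact.DISCORDANT


def _has_deleterious_call(rec: AnnotationRecord, cfg: FilterConfig) -> bool:
    sift_del = rec.sift is not None and rec.sift < cfg.sift_deleterious_lt
    pp_del = rec.polyphen is not None and rec.polyphen >= cfg.polyphen_deleterious_ge
    return sift_del or pp_del


def assess_indel(indel: VariantCall, db: AnnotationDB) -> IndelDriverStatus:
    """Driver-INDEL catalog assessment.

    ``driver_exact`` on an exact allele entry; ``driver_overlap`` when a
    catalog interval for the same gene intersects the INDEL's span but
    the alleles differ; otherwise ``none``.
    """
    if indel.var_class not in (VarClass.INS, VarClass.DEL):
        raise ValidationError(f"assess_indel needs an INS/DEL, got {indel.var_class.value}")
    rec = db.lookup(indel)
    if rec.dbcid.status is DbcidStatus.EXACT:
        return IndelDriverStatus.DRIVER_EXACT
    span_start = indel.pos
    span_end = indel.pos + max(len(indel.ref), 1) - 1
    for entry in db.overlap_entries(indel.gene):
        if entry.start <= span_end and span_start <= entry.end:
            return IndelDriverStatus.DRIVER_OVERLAP
    return IndelDriverStatus.NONE


def tier_variant(
    variant: VariantCall,
    annotation: AnnotationRecord,
    impact: Impact,
    cfg: FilterConfig = FilterConfig(),
    indel_status: IndelDriverStatus = IndelDriverStatus.NONE,
) -> TieredVariant:
    """Assign the pathogenic / candidate / VUS tier to a filtered call.

    Rule order (each clause recorded in the trace):

    1. ClinVar pathogenic -> pathogenic (dominates predictor scores).
    2. ClinVar benign -> removed from the pathogenic/candidate streams
       (reported benign-annotated, tier ``filtered_out``).
    3. Benign-concordant predictors -> filtered out.
    4. COSMIC count > 500 -> pathogenic.
    5. Driver-INDEL catalog: exact entry -> pathogenic, overlap -> candidate.
    6. Deleterious predictor evidence (concordant, or discordant with at
       least one deleterious call) -> candidate.
    7. COSMIC count 1-500 -> candidate.
    8. Otherwise -> VUS.
    """
    trace: list[str] = []
    reasons: list[FilterReason] = []
    tv = TieredVariant(
        variant=variant, annotation=annotation, impact=impact,
        tier=Tier.VUS, filter_reasons=reasons, trace=trace,
        indel_status=indel_status,
    )
    if annotation.clinvar is ClinVarAssertion.PATHOGENIC:
        trace.append("clinvar_pathogenic")
        tv.tier = Tier.PATHOGENIC
        return tv
    if annotation.clinvar is ClinVarAssertion.BENIGN:
        trace.append("clinvar_benign")
        tv.clinvar_benign = True
        tv.tier = Tier.FILTERED_OUT
        reasons.append(FilterReason.BENIGN_PREDICTION)
        return tv
    if impact is Impact.BENIGN_CONCORDANT:
        trace.append("benign_concordant_prediction")
        tv.tier = Tier.FILTERED_OUT
        reasons.append(FilterReason.BENIGN_PREDICTION)
        return tv
    if annotation.cosmic_count > cfg.cosmic_pathogenic_gt:
        trace.append(f"cosmic_gt_{cfg.cosmic_pathogenic_gt}")
        tv.tier = Tier.PATHOGENIC
        return tv
    if indel_status is IndelDriverStatus.DRIVER_EXACT:
        trace.append("dbcid_exact")
        tv.tier = Tier.PATHOGENIC
        return tv
    if indel_status is IndelDriverStatus.DRIVER_OVERLAP:
        trace.append("dbcid_overlap")
        tv.tier = Tier.CANDIDATE
        return tv
    if impact is Impact.DELETERIOUS_CONCORDANT or (
        impact is Impact.DISCORDANT and _has_deleterious_call(annotation, cfg)
    ):
        trace.append("deleterious_prediction")
        tv.tier = Tier.CANDIDATE
        return tv
    if 1 <= annotation.cosmic_count <= cfg.cosmic_pathogenic_gt:
        trace.append("cosmic_1_to_500")
        tv.tier = Tier.CANDIDATE
        return tv
    trace.append("no_annotative_evidence")
    tv.tier = Tier.VUS
    return tv


def score_synonymous(
    trap: Optional[float],
    silva: Optional[float],
    fathmm: Optional[float],
    cfg: FilterConfig = FilterConfig(),
) -> PrdsmResult:
    """Mean of the three synonymous predictors; deleterious iff > 0.308."""
    scores = (trap, silva, fathmm)
    if any(s is None for s in scores):
        return PrdsmResult(score=None, deleterious=None, scored=False)
    for name, s in zip(("trap", "silva", "fathmm"), scores):
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"{name} score {s} outside [0, 1]")
    mean = sum(scores) / 3.0
    return PrdsmResult(score=mean, deleterious=mean > cfg.prdsm_deleterious_gt, scored=True)


def tier_sample(
    retained: list[VariantCall],
    db: AnnotationDB,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[TieredVariant], list[tuple[VariantCall, PrdsmResult]],
           list[tuple[VariantCall, list[FilterReason]]]]:
    """Run the full cascade on one sample's retained somatic calls.

    Returns (tiered non-synonymous calls, scored synonymous calls,
    calls removed by the standard filters).
    """
    kept, synonymous, removed = apply_standard_filters(retained, db, cfg)
    tiered: list[TieredVariant] = []
    for v in kept:
        rec = db.lookup(v)
        if v.effect is Effect.MISSENSE:
            impact = predict_missense_impact(rec.sift, rec.polyphen, cfg)
        else:
            impact = Impact.NOT_APPLICABLE
        indel_status = assess_indel(v, db) if v.is_indel else IndelDriverStatus.NONE
        tiered.append(tier_variant(v, rec, impact, cfg, indel_status))
    syn_scored = [
        (v, score_synonymous(db.lookup(v).trap, db.lookup(v).silva, db.lookup(v).fathmm, cfg))
        for v in synonymous
    ]
    return tiered, syn_scored, removed


#: Genes whose hit status feeds the molecular group assignment.
TRACKED_GENES = PI3K_GENES + MMR_GENES + (TP53,)


def summarize_sample(
    sample_id: str,
    retained: list[VariantCall],
    tiered: list[TieredVariant],
    collapse_complements: bool = True,
) -> SampleSummary:
    """Fold one sample's discovery and tiering output into its summary row.

    ``retained`` is the post-review unfiltered somatic call list;
    ``tiered`` the cascade output for the same sample. Filtered counts
    include VUS-tier calls (everything surviving the benign filters),
    so filtered >= pathogenic + candidate always holds. Gene hit flags
    are set by pathogenic- or candidate-tier calls only.
    """
    snvs = [v for v in retained if v.is_snv]
    indels = [v for v in retained if v.is_indel]
    spectrum = substitution_spectrum(snvs, collapse=collapse_complements)
    surviving = [t for t in tiered if t.tier in (Tier.PATHOGENIC, Tier.CANDIDATE, Tier.VUS)]
    gene_hits = {g: False for g in TRACKED_GENES}
    n_path = n_cand = 0
    for t in tiered:
        if t.tier is Tier.PATHOGENIC:
            n_path += 1
        elif t.tier is Tier.CANDIDATE:
            n_cand += 1
        if t.tier in (Tier.PATHOGENIC, Tier.CANDIDATE) and t.variant.gene in gene_hits:
            gene_hits[t.variant.gene] = True
    summary = SampleSummary(
        sample_id=sample_id,
        n_unfiltered=len(retained),
        n_unfiltered_snv=len(snvs),
        n_unfiltered_indel=len(indels),
        spectrum={k: spectrum[k] for k in SPECTRUM_CLASSES},
        n_filtered_snv=sum(1 for t in surviving if t.variant.is_snv),
        n_filtered_indel=sum(1 for t in surviving if t.variant.is_indel),
        n_pathogenic=n_path,
        n_candidate=n_cand,
        gene_hits=gene_hits,
    )
    summary.validate()
    return summary
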