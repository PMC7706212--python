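"""Two-workflow somatic variant discovery with programmatic review.

The discovery stage reproduces a paired tumor/normal subtraction workflow
and a single-sample curation workflow, merges their outputs, verifies
single-workflow calls against raw caller evidence, and then applies a
programmatic stand-in for visual sequence-level review: calls flagged as
poor quality or sequencing error are excluded, and calls visibly present
in the matched normal are excluded as germline. Survivors are the
sample's *unfiltered somatic variants* — the quantity every downstream
burden, spectrum and classification rule consumes.

The visual-review criteria of the original workflow are qualitative; the
numeric stand-ins here (``germline_af``, ``min_depth``) are explicit,
documented configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Collection, Optional

from .model import (
    Quality,
    SampleVariantSet,
    Tissue,
    ValidationError,
    VariantCall,
    VariantKey,
)


class Provenance(str, enum.Enum):
    PAIRED_ONLY = "paired_only"
    SINGLE_ONLY = "single_only"
    BOTH = "both"


class Review(str, enum.Enum):
    RETAINED = "retained"
    EXCLUDED_QUALITY = "excluded_quality"
    EXCLUDED_GERMLINE = "excluded_germline"
    EXCLUDED_UNVERIFIED = "excluded_unverified"


@dataclass(slots=True)
class DiscoveryConfig:
    """Numeric stand-ins for the qualitative review criteria.

    germline_af
        A call whose allele fraction in the matched normal is at or above
        this value is deemed visibly present in the normal, hence
        germline. Default 0.10.
    min_depth
        Minimum read depth for the normal-tissue evidence to count as
        informative when judging germline presence. Default 20.
    """

    germline_af: float = 0.10
    min_depth: int = 20


@dataclass(slots=True)
class ReviewedCall:
    """A somatic candidate with its workflow provenance and review fate."""

    variant: VariantCall
    provenance: Provenance
    review: Review = Review.RETAINED


@dataclass(slots=True)
class SomaticCallSet:
    sample_id: str
    calls: list[ReviewedCall] = field(default_factory=list)

    def retained(self) -> list[VariantCall]:
        return [c.variant for c in self.calls if c.review is Review.RETAINED]

    def excluded(self, reason: Review) -> list[VariantCall]:
        return [c.variant for c in self.calls if c.review is reason]

    def __len__(self) -> int:
        return len(self.calls)


def _check_pair(tumor: SampleVariantSet, normal: SampleVariantSet) -> None:
    if tumor.tissue is not Tissue.TUMOR or normal.tissue is not Tissue.NORMAL:
        raise ValidationError(
            f"expected (tumor, normal) sets, got ({tumor.tissue.value}, "
            f"{normal.tissue.value})"
        )


def _normal_evidence(
    variant: VariantCall,
    normal_by_key: dict[VariantKey, VariantCall],
    cfg: DiscoveryConfig,
) -> Optional[float]:
    """Best available allele fraction for this site in the matched normal.

    Prefers the direct NT call when its depth is informative; falls back
    to the paired caller's normal-fraction field when that was observed.
    Returns None when there is no usable evidence.
    """
    best: Optional[float] = None
    nt = normal_by_key.get(variant.key)
    if nt is not None and nt.depth >= cfg.min_depth:
        best = nt.own_af
    if variant.normal_af_observed:
        best = variant.normal_af if best is None else max(best, variant.normal_af)
    return best


def paired_somatic(
    tumor: SampleVariantSet,
    normal: SampleVariantSet,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> list[VariantCall]:
    """Paired (two-sample) workflow: tumor minus matched normal.

    A tumor call is somatic if the site is absent from the normal, or
    present at an allele fraction below ``cfg.germline_af`` (a trace of
    tumor contamination in the normal does not make a call germline).
    """
    _check_pair(tumor, normal)
    normal_by_key = normal.by_key()
    out: list[VariantCall] = []
    for v in tumor:
        evidence = _normal_evidence(v, normal_by_key, cfg)
        if evidence is None or evidence < cfg.germline_af:
            out.append(v)
    return out


def single_sample_somatic(
    tumor: SampleVariantSet,
    normal: SampleVariantSet,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> list[VariantCall]:
    """Single-sample workflow: calls unique to the tumor specimen.

    No allele-fraction subtraction is applied — any call whose key also
    appears in the normal set is dropped. Low-quality tumor-unique calls
    are kept here; the downstream review stage resolves them.
    """
    _check_pair(tumor, normal)
    normal_keys = set(normal.by_key())
    return [v for v in tumor if v.key not in normal_keys]


def merge_workflows(
    paired: list[VariantCall],
    single: list[VariantCall],
    caller_evidence: Collection[VariantKey],
    sample_id: Optional[str] = None,
) -> SomaticCallSet:
    """Union of both workflows with caller-evidence verification.

    Calls found by both workflows are trusted. A call found by only one
    workflow must be present in the raw caller output
    (``caller_evidence``); otherwise it is marked ``excluded_unverified``
    and does not warrant further investigation.
    """
    ids = {v.sample_id for v in paired} | {v.sample_id for v in single}
    if len(ids) > 1:
        raise ValidationError(f"merge_workflows saw multiple sample_ids: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    elif ids and {sample_id} != ids:
        raise ValidationError(f"sample_id {sample_id!r} does not match calls {sorted(ids)}")

    paired_keys = {v.key for v in paired}
    single_keys = {v.key for v in single}
    merged: dict[VariantKey, ReviewedCall] = {}
    for v in paired + single:
        if v.key in merged:
            continue
        if v.key in paired_keys and v.key in single_keys:
            prov = Provenance.BOTH
        elif v.key in paired_keys:
            prov = Provenance.PAIRED_ONLY
        else:
            prov = Provenance.SINGLE_ONLY
        review = Review.RETAINED
        if prov is not Provenance.BOTH and v.key not in caller_evidence:
            review = Review.EXCLUDED_UNVERIFIED
        merged[v.key] = ReviewedCall(variant=v, provenance=prov, review=review)
    return SomaticCallSet(sample_id=sample_id, calls=list(merged.values()))


def quality_review(
    callset: SomaticCallSet,
    normal: SampleVariantSet,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> SomaticCallSet:
    """Programmatic stand-in for sequence-level visual review.

    Poor-quality calls (``low_quality`` or ``sequencing_error`` flags)
    are excluded first; calls visibly present in the matched normal at or
    above the germline threshold are excluded as germline. The operation
    is idempotent and never resurrects previously excluded calls.
    """
    normal_by_key = normal.by_key()
    out: list[ReviewedCall] = []
    for call in callset.calls:
        if call.review is not Review.RETAINED:
            out.append(call)
            continue
        v = call.variant
        if v.quality in (Quality.LOW_QUALITY, Quality.SEQUENCING_ERROR):
            out.append(replace(call, review=Review.EXCLUDED_QUALITY))
            continue
        evidence = _normal_evidence(v, normal_by_key, cfg)
        if evidence is not None and evidence >= cfg.germline_af:
            out.append(replace(call, review=Review.EXCLUDED_GERMLINE))
            continue
        out.append(call)
    return SomaticCallSet(sample_id=callset.sample_id, calls=out)


def discover_somatic(
    tumor: SampleVariantSet,
    normal: SampleVariantSet,
    caller_evidence: Optional[Collection[VariantKey]] = None,
    cfg: DiscoveryConfig = DiscoveryConfig(),
) -> SomaticCallSet:
    """Full discovery chain: paired + single workflows, merge, review.

    When ``caller_evidence`` is None, every tumor call is treated as
    present in the raw caller output (nothing can be excluded as
    unverified).
    """
    if caller_evidence is None:
        caller_evidence = {v.key for v in tumor}
    paired = paired_somatic(tumor, normal, cfg)
    single = single_sample_somatic(tumor, normal, cfg)
    merged = merge_workflows(paired, single, caller_evidence, sample_id=tumor.sample_id)
    return quality_review(merged, normal, cfg)
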