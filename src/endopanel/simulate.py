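"""Synthetic paired tumor/normal cohorts with ground-truth labels.

The generator emulates the statistical structure a targeted tumor/normal
endometrial-carcinoma study hands to the analysis: per-sample unfiltered
somatic burden (Poisson, non-hypermutated rate ~65-75, hypermutated
~345), six-class substitution spectra calibrated to the published
per-stratum medians (hypermutated samples C>A- and C>T-rich), driver
events planted by histology (PTEN/PIK3CA frequent in endometrioid, TP53
in serous, mismatch-repair hits co-occurring with POLE hotspots in
hypermutated tumors), germline variants shared between tumor and normal
at concordant allele fractions, sequencing-artifact contamination, and
clinical covariates drawn from the published contingency structure.

Every planted event is recorded in a :class:`CohortTruth` so that every
downstream stage can be scored against what was actually simulated.
Generation is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .model import (
    AnnotationDB,
    AnnotationRecord,
    ClinicalRecord,
    DbcidEntry,
    DbcidStatus,
    Domain,
    Effect,
    Histology,
    PanelDefinition,
    Quality,
    Region,
    SampleVariantSet,
    Stage,
    Tissue,
    ValidationError,
    VariantCall,
    VariantKey,
    VitalStatus,
)
from .classify import SPECTRUM_CLASSES, COLLAPSE_MAP
from .panel import MMR_GENES, POLE, default_panel, pole_panel

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Driver event catalog
# --------------------------------------------------------------------------

@dataclass(slots=True, frozen=True)
class DriverSpec:
    gene: str
    var_class: str
    effect: Effect
    hgvs_c: str
    hgvs_p: str
    ref: str
    alt: str
    offset: int            # position offset inside the gene's target region
    domain: Domain = Domain.UNKNOWN
    # annotation evidence attached by the fixture builder
    clinvar: str = "absent"
    cosmic: int = 0
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    dbcid_exact: bool = False


DRIVER_CATALOG: dict[str, DriverSpec] = {
    "PTEN_R130G": DriverSpec("PTEN", "SNV", Effect.MISSENSE, "c.388C>G", "p.Arg130Gly",
                             "C", "G", 388, cosmic=800, sift=0.0, polyphen=0.99),
    "PTEN_Y317fs": DriverSpec("PTEN", "DEL", Effect.FRAMESHIFT, "c.950_953delTACT",
                              "p.Tyr317ThrfsTer23", "ATACT", "A", 950,
                              clinvar="pathogenic", dbcid_exact=True),
    "PIK3CA_H1047R": DriverSpec("PIK3CA", "SNV", Effect.MISSENSE, "c.3140A>G",
                                "p.His1047Arg", "A", "G", 3140,
                                clinvar="pathogenic", cosmic=3000, sift=0.0, polyphen=1.0),
    "PIK3CA_E109del": DriverSpec("PIK3CA", "DEL", Effect.NONFRAMESHIFT_INDEL,
                                 "c.325_327delGAA", "p.Glu109del", "AGAA", "A", 325,
                                 dbcid_exact=True),
    "PIK3R1_del": DriverSpec("PIK3R1", "DEL", Effect.FRAMESHIFT, "c.1690_1693delACTT",
                             "p.Thr564fs", "GACTT", "G", 1690),
    "PIK3R3_mis": DriverSpec("PIK3R3", "SNV", Effect.MISSENSE, "c.502C>T", "p.Arg168Cys",
                             "C", "T", 502, cosmic=8, sift=0.01, polyphen=0.97),
    "TP53_R273H": DriverSpec("TP53", "SNV", Effect.MISSENSE, "c.818G>A", "p.Arg273His",
                             "G", "A", 818, clinvar="pathogenic", cosmic=900,
                             sift=0.0, polyphen=1.0),
    "MLH1_mis": DriverSpec("MLH1", "SNV", Effect.MISSENSE, "c.1852A>G", "p.Lys618Glu",
                           "A", "G", 1852, cosmic=12, sift=0.02, polyphen=0.93),
    "MSH2_E580X": DriverSpec("MSH2", "SNV", Effect.NONSENSE, "c.1738G>T", "p.Glu580Ter",
                             "G", "T", 1738, clinvar="pathogenic", cosmic=4),
    "MSH6_mis": DriverSpec("MSH6", "SNV", Effect.MISSENSE, "c.3646C>T", "p.Arg1216Cys",
                           "C", "T", 3646, cosmic=9, sift=0.01, polyphen=0.91),
    "PMS2_mis": DriverSpec("PMS2", "SNV", Effect.MISSENSE, "c.137G>T", "p.Ser46Ile",
                           "G", "T", 137, cosmic=6, sift=0.03, polyphen=0.88),
    "POLE_P286R": DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.857C>G", "p.Pro286Arg",
                             "C", "G", 857, domain=Domain.FUNCTIONAL,
                             clinvar="pathogenic", cosmic=120, sift=0.0, polyphen=1.0),
    "POLE_V411L": DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.1231G>T", "p.Val411Leu",
                             "G", "T", 1231, domain=Domain.FUNCTIONAL,
                             clinvar="pathogenic", cosmic=95, sift=0.0, polyphen=0.99),
    # the stoploss call planted when a hypermutated sample misses both hotspots
    "POLE_X2287W": DriverSpec("POLE", "SNV", Effect.STOPLOSS, "c.6860A>G", "p.Ter2287Trp",
                              "A", "G", 6860, domain=Domain.OUTSIDE),
}

#: How a per-gene driver probability maps onto concrete catalog events.
_GENE_EVENT_CHOICES: dict[str, tuple[tuple[str, float], ...]] = {
    "PTEN": (("PTEN_R130G", 0.7), ("PTEN_Y317fs", 0.3)),
    "PIK3CA": (("PIK3CA_H1047R", 0.85), ("PIK3CA_E109del", 0.15)),
    "PIK3R1": (("PIK3R1_del", 1.0),),
    "PIK3R3": (("PIK3R3_mis", 1.0),),
    "TP53": (("TP53_R273H", 1.0),),
    "MLH1": (("MLH1_mis", 1.0),),
    "MSH2": (("MSH2_E580X", 1.0),),
    "MSH6": (("MSH6_mis", 1.0),),
    "PMS2": (("PMS2_mis", 1.0),),
    "POLE_P286R": (("POLE_P286R", 1.0),),
    "POLE_V411L": (("POLE_V411L", 1.0),),
}

#: Non-hotspot POLE variants (benign or of unknown significance, within and
#: outside the functional domains) scattered over hypermutated samples.
POLE_PASSENGER_CATALOG: tuple[DriverSpec, ...] = (
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.6418G>A", "p.Glu2140Lys", "G", "A", 6418,
               domain=Domain.OUTSIDE),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.5591T>G", "p.Ile1864Ser", "T", "G", 5591,
               domain=Domain.OUTSIDE),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.3632A>G", "p.Asp1211Gly", "A", "G", 3632,
               domain=Domain.FUNCTIONAL),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.1588G>A", "p.Asp530Asn", "G", "A", 1588,
               domain=Domain.FUNCTIONAL),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.1367C>T", "p.Ala456Val", "C", "T", 1367,
               domain=Domain.FUNCTIONAL, clinvar="benign"),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.755C>T", "p.Ala252Val", "C", "T", 755,
               domain=Domain.FUNCTIONAL, clinvar="benign"),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.453T>G", "p.Asn151Lys", "T", "G", 453,
               domain=Domain.OUTSIDE),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.292T>G", "p.Leu98Val", "T", "G", 292,
               domain=Domain.OUTSIDE),
)

#: The two benign exonic catalytic-domain variants seen in non-hypermutated
#: and control samples; p.Asn1396Ser is benign by assertion yet called
#: deleterious by SIFT, a deliberate discordance the tiering must survive.
POLE_BENIGN_CATALOG: tuple[DriverSpec, ...] = (
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.4187A>G", "p.Asn1396Ser", "A", "G", 4187,
               domain=Domain.FUNCTIONAL, clinvar="benign", sift=0.01, polyphen=0.12),
    DriverSpec("POLE", "SNV", Effect.MISSENSE, "c.6820C>G", "p.Leu2274Val", "C", "G", 6820,
               domain=Domain.FUNCTIONAL, clinvar="benign", sift=0.44, polyphen=0.08),
)

#: dbCID loci reported for overlapping-but-non-identical INDELs.
DBCID_OVERLAP_LOCI: tuple[tuple[str, int, int], ...] = (
    ("PIK3R1", 1685, 1700),
    ("TP53", 740, 760),
    ("PTEN", 200, 215),
)


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------

@dataclass(slots=True)
class SimulationProfile:
    """Generating distribution for one tumor archetype."""

    label: str
    truth_group: int
    burden_rate: float
    spectrum_probs: dict[str, float]
    driver_probs: dict[str, float]
    indel_fraction: float
    artifact_fraction: float
    germline_rate: float
    histology: Histology
    grade: Optional[int]
    hypermutated: bool = False
    low_quality_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.histology = Histology(self.histology)
        probs = [self.spectrum_probs.get(k, 0.0) for k in SPECTRUM_CLASSES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"spectrum_probs for {self.label} must be >= 0 and sum to 1"
            )
        for name, p in self.driver_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"driver prob {name}={p} outside [0, 1]")
        for name in ("indel_fraction", "artifact_fraction", "low_quality_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.burden_rate < 0 or self.germline_rate < 0:
            raise ValidationError("rates must be >= 0")


def _spectrum(medians: dict[str, float]) -> dict[str, float]:
    total = sum(medians.values())
    return {k: medians[k] / total for k in SPECTRUM_CLASSES}

# Per-stratum six-class medians drive the default spectra.
_SPEC_NONHYPER = _spectrum({"C>A": 6, "C>G": 2, "C>T": 9, "T>A": 4, "T>C": 7, "T>G": 4})
_SPEC_G1 = _spectrum({"C>A": 5.5, "C>G": 2.5, "C>T": 9.5, "T>A": 3, "T>C": 5.5, "T>G": 4})
_SPEC_G2 = _spectrum({"C>A": 5.5, "C>G": 1, "C>T": 8.5, "T>A": 5.5, "T>C": 7.5, "T>G": 7})
_SPEC_USC = _spectrum({"C>A": 5, "C>G": 2, "C>T": 6, "T>A": 4, "T>C": 5, "T>G": 4})
_SPEC_HYPER = _spectrum({"C>A": 63, "C>G": 3, "C>T": 49.5, "T>A": 5.5, "T>C": 19.5, "T>G": 18})

_EAC_BASE_DRIVERS = {"PIK3R1": 0.15, "PIK3R3": 0.05}


def default_profiles() -> dict[str, SimulationProfile]:
    """The six tumor archetypes at their study-calibrated defaults."""
    return {
        "EAC_G1": SimulationProfile(
            label="EAC_G1", truth_group=4, burden_rate=65.0,
            spectrum_probs=_SPEC_G1,
            driver_probs={"PTEN": 0.83, "PIK3CA": 0.67, "TP53": 0.02, **_EAC_BASE_DRIVERS},
            indel_fraction=0.06, artifact_fraction=0.02, germline_rate=25.0,
            histology=Histology.EAC, grade=1,
        ),
        "EAC_G2": SimulationProfile(
            label="EAC_G2", truth_group=4, burden_rate=75.0,
            spectrum_probs=_SPEC_G2,
            driver_probs={"PTEN": 0.70, "PIK3CA": 0.70, "TP53": 0.20, **_EAC_BASE_DRIVERS},
            indel_fraction=0.06, artifact_fraction=0.02, germline_rate=25.0,
            histology=Histology.EAC, grade=2,
        ),
        "EAC_G3_POLE": SimulationProfile(
            label="EAC_G3_POLE", truth_group=1, burden_rate=345.0,
            spectrum_probs=_SPEC_HYPER,
            driver_probs={
                "PTEN": 0.90, "PIK3CA": 0.80, "PIK3R1": 0.30, "PIK3R3": 0.10,
                "TP53": 0.30, "MLH1": 0.30, "MSH2": 0.35, "MSH6": 0.30, "PMS2": 0.25,
                "POLE_P286R": 0.667, "POLE_V411L": 0.167,
            },
            indel_fraction=0.02, artifact_fraction=0.02, germline_rate=25.0,
            histology=Histology.EAC, grade=3, hypermutated=True,
        ),
        "EAC_G3_nonPOLE": SimulationProfile(
            label="EAC_G3_nonPOLE", truth_group=4, burden_rate=62.0,
            spectrum_probs=_SPEC_NONHYPER,
            driver_probs={"PTEN": 0.95, "PIK3CA": 0.85, "TP53": 0.15,
                          "PIK3R1": 0.20, "PIK3R3": 0.05},
            indel_fraction=0.06, artifact_fraction=0.02, germline_rate=25.0,
            histology=Histology.EAC, grade=3,
        ),
        "USC": SimulationProfile(
            label="USC", truth_group=3, burden_rate=63.0,
            spectrum_probs=_SPEC_USC,
            driver_probs={"PTEN": 0.15, "PIK3CA": 0.23, "TP53": 0.77,
                          "PIK3R1": 0.05, "PIK3R3": 0.02},
            indel_fraction=0.06, artifact_fraction=0.02, germline_rate=25.0,
            histology=Histology.USC, grade=None,
        ),
        # raw burden inside the hypermutated range, but dominated by
        # sequencing-error calls that the review stage strips
        "artifact_heavy": SimulationProfile(
            label="artifact_heavy", truth_group=4, burden_rate=310.0,
            spectrum_probs=_SPEC_NONHYPER,
            driver_probs={"PTEN": 0.90, "PIK3CA": 0.80, "TP53": 0.15,
                          "PIK3R1": 0.20, "PIK3R3": 0.05},
            indel_fraction=0.06, artifact_fraction=0.72, germline_rate=25.0,
            histology=Histology.EAC, grade=3,
        ),
    }


#: Default per-profile sample counts mirroring a 47-sample cohort:
#: 12 grade-1 + 10 grade-2 + 12 grade-3 endometrioid (6 hypermutated,
#: 2 artifact-dominated) + 13 serous.
DEFAULT_COUNTS: dict[str, int] = {
    "EAC_G1": 12,
    "EAC_G2": 10,
    "EAC_G3_POLE": 6,
    "EAC_G3_nonPOLE": 4,
    "artifact_heavy": 2,
    "USC": 13,
}


@dataclass(slots=True)
class CohortConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    profiles: dict[str, SimulationProfile] = field(default_factory=default_profiles)
    # recurrence probabilities are exposed so the clinical generator's 2x2
    # margins can be configured directly
    recurrence_prob_eac: float = 7 / 34
    recurrence_prob_usc: float = 8 / 13

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative sample count for {label}")
            if n > 0 and label not in self.profiles:
                raise ValidationError(f"no profile defined for {label}")


# --------------------------------------------------------------------------
# Truth bookkeeping
# --------------------------------------------------------------------------

@dataclass(slots=True)
class SampleTruth:
    sample_id: str
    profile_label: str
    truth_group: int
    hypermutated: bool
    histology: Histology
    grade: Optional[int]
    planted_drivers: dict[str, VariantKey] = field(default_factory=dict)
    planted_pole: dict[str, VariantKey] = field(default_factory=dict)
    artifact_keys: set[VariantKey] = field(default_factory=set)
    germline_keys: set[VariantKey] = field(default_factory=set)


@dataclass(slots=True)
class CohortTruth:
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    def group_partition(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {1: set(), 2: set(), 3: set(), 4: set()}
        for sid, t in self.samples.items():
            out[t.truth_group].add(sid)
        return out

    def hypermutated_ids(self) -> set[str]:
        return {sid for sid, t in self.samples.items() if t.hypermutated}

    def of_profile(self, label: str) -> set[str]:
        return {sid for sid, t in self.samples.items() if t.profile_label == label}


@dataclass(slots=True)
class SamplePair:
    sample_id: str
    profile_label: str
    tumor: SampleVariantSet
    normal: SampleVariantSet


@dataclass(slots=True)
class Cohort:
    pairs: list[SamplePair]
    truth: CohortTruth
    clinical: list[ClinicalRecord]


# --------------------------------------------------------------------------
# Sample-level generation
# --------------------------------------------------------------------------

_SNV_EFFECTS = (Effect.MISSENSE, Effect.SYNONYMOUS, Effect.NONSENSE,
                Effect.SPLICE, Effect.OTHER)
_SNV_EFFECT_P = (0.55, 0.25, 0.05, 0.05, 0.10)


def _driver_call(sample_id: str, spec: DriverSpec, panel: PanelDefinition,
                 rng: np.random.Generator) -> VariantCall:
    chrom, start, _end = panel.gene_regions[spec.gene]
    return VariantCall(
        sample_id=sample_id, tissue=Tissue.TUMOR,
        chrom=chrom, pos=start + spec.offset,
        ref=spec.ref, alt=spec.alt, gene=spec.gene,
        var_class=spec.var_class, effect=spec.effect,
        hgvs_c=spec.hgvs_c, hgvs_p=spec.hgvs_p,
        tumor_af=float(rng.uniform(0.2, 0.7)),
        normal_af=0.0, normal_af_observed=True,
        depth=int(max(50, rng.poisson(600))),
        caller_p=float(rng.uniform(0.0, 0.04)),
        quality=Quality.PASS, region=Region.EXONIC, domain=spec.domain,
    )


def _passenger_alleles(cls6: str, rng: np.random.Generator) -> tuple[str, str]:
    # half the calls are reported on the purine strand, so the raw
    # 12-class spectrum exercises the complement collapse
    if rng.random() < 0.5:
        for raw, collapsed in COLLAPSE_MAP.items():
            if collapsed == cls6:
                return raw.split(">")[0], raw.split(">")[1]
    return cls6.split(">")[0], cls6.split(">")[1]


def _random_position(panel: PanelDefinition, genes: list[str],
                     rng: np.random.Generator) -> tuple[str, str, int]:
    gene = genes[int(rng.integers(len(genes)))]
    chrom, start, end = panel.gene_regions[gene]
    return gene, chrom, int(rng.integers(start, end + 1))


def simulate_sample(
    profile: SimulationProfile,
    seed: RngLike,
    sample_id: str = "S01",
    panel: Optional[PanelDefinition] = None,
) -> tuple[SampleVariantSet, SampleVariantSet, SampleTruth]:
    """Generate one paired (tumor, normal) call set plus its truth record.

    The tumor set holds germline calls (shared with the normal at
    concordant allele fractions), Poisson-count somatic passengers with
    multinomial substitution classes and uniform panel positions,
    planted driver events, planted POLE add-on calls, and a configured
    fraction of sequencing-artifact calls. Identical seeds give
    identical output.
    """
    rng = _rng(seed)
    if panel is None:
        panel = _combined_default_panel()
    genes = sorted(g for g in panel.gene_regions if g != POLE)
    if not genes:
        raise ValidationError("panel has no usable gene regions")

    tumor_calls: list[VariantCall] = []
    normal_calls: list[VariantCall] = []
    used: set[VariantKey] = set()
    truth = SampleTruth(
        sample_id=sample_id, profile_label=profile.label,
        truth_group=profile.truth_group, hypermutated=profile.hypermutated,
        histology=profile.histology, grade=profile.grade,
    )

    def claim(call: VariantCall) -> bool:
        if call.key in used:
            return False
        used.add(call.key)
        return True

    # ---- germline variants, shared T/NT at concordant fractions
    n_germ = int(rng.poisson(profile.germline_rate))
    for _ in range(n_germ):
        for _attempt in range(20):
            gene, chrom, pos = _random_position(panel, genes, rng)
            base_af = 1.0 if rng.random() < 0.2 else 0.5
            ref, alt = _passenger_alleles(
                SPECTRUM_CLASSES[int(rng.integers(6))], rng
            )
            af_t = float(np.clip(base_af + rng.normal(0, 0.04), 0.05, 1.0))
            af_n = float(np.clip(base_af + rng.normal(0, 0.04), 0.05, 1.0))
            effect = (Effect.SYNONYMOUS if rng.random() < 0.4
                      else Effect.MISSENSE if rng.random() < 0.8 else Effect.OTHER)
            call = VariantCall(
                sample_id=sample_id, tissue=Tissue.TUMOR, chrom=chrom, pos=pos,
                ref=ref, alt=alt, gene=gene, var_class="SNV", effect=effect,
                tumor_af=af_t, normal_af=af_n, normal_af_observed=True,
                depth=int(max(50, rng.poisson(500))),
                caller_p=float(rng.uniform(0, 0.05)),
            )
            if claim(call):
                tumor_calls.append(call)
                normal_calls.append(
                    replace(call, tissue=Tissue.NORMAL, tumor_af=0.0,
                            normal_af=af_n, depth=int(max(50, rng.poisson(500))))
                )
                truth.germline_keys.add(call.key)
                break

    # ---- somatic passengers
    n_somatic = int(rng.poisson(profile.burden_rate))
    n_indel = int(rng.binomial(n_somatic, profile.indel_fraction))
    n_snv = n_somatic - n_indel
    class_counts = rng.multinomial(n_snv, [profile.spectrum_probs[k] for k in SPECTRUM_CLASSES])
    classes: list[str] = []
    for cls, count in zip(SPECTRUM_CLASSES, class_counts):
        classes.extend([cls] * int(count))
    rng.shuffle(classes)

    def somatic_common(rng) -> dict:
        u = rng.random()
        if u < profile.artifact_fraction:
            quality = Quality.SEQUENCING_ERROR
        elif u < profile.artifact_fraction + profile.low_quality_fraction:
            quality = Quality.LOW_QUALITY
        else:
            quality = Quality.PASS
        contaminated = rng.random() < 0.08
        return dict(
            tumor_af=float(rng.uniform(0.1, 0.9)),
            normal_af=float(rng.uniform(0.0, 0.05)) if contaminated else 0.0,
            normal_af_observed=True,
            depth=int(max(50, rng.poisson(500))),
            # roughly a third of passenger calls carry a caller p-value
            # above the 0.05 filter, part of the ~87% unfiltered-to-filtered
            # attrition the cascade is expected to produce
            caller_p=(float(rng.uniform(0.0, 0.045)) if rng.random() < 0.65
                      else float(rng.uniform(0.055, 0.9))),
            quality=quality,
        )

    for cls in classes:
        for _attempt in range(20):
            gene, chrom, pos = _random_position(panel, genes, rng)
            ref, alt = _passenger_alleles(cls, rng)
            fields = somatic_common(rng)
            effect = rng.choice(len(_SNV_EFFECTS), p=_SNV_EFFECT_P)
            call = VariantCall(
                sample_id=sample_id, tissue=Tissue.TUMOR, chrom=chrom, pos=pos,
                ref=ref, alt=alt, gene=gene, var_class="SNV",
                effect=_SNV_EFFECTS[int(effect)], **fields,
            )
            if claim(call):
                tumor_calls.append(call)
                if call.quality is Quality.SEQUENCING_ERROR:
                    truth.artifact_keys.add(call.key)
                break

    bases = "ACGT"
    for _ in range(n_indel):
        for _attempt in range(20):
            gene, chrom, pos = _random_position(panel, genes, rng)
            anchor = bases[int(rng.integers(4))]
            chunk = "".join(bases[int(i)] for i in rng.integers(0, 4, size=int(rng.integers(1, 5))))
            if rng.random() < 0.5:
                ref, alt, vc = anchor + chunk, anchor, "DEL"
            else:
                ref, alt, vc = anchor, anchor + chunk, "INS"
            effect = (Effect.FRAMESHIFT if len(chunk) % 3 else Effect.NONFRAMESHIFT_INDEL)
            fields = somatic_common(rng)
            call = VariantCall(
                sample_id=sample_id, tissue=Tissue.TUMOR, chrom=chrom, pos=pos,
                ref=ref, alt=alt, gene=gene, var_class=vc, effect=effect, **fields,
            )
            if claim(call):
                tumor_calls.append(call)
                if call.quality is Quality.SEQUENCING_ERROR:
                    truth.artifact_keys.add(call.key)
                break

    # ---- planted drivers (per-gene probabilities -> concrete catalog events)
    for gene_event, prob in profile.driver_probs.items():
        if rng.random() >= prob:
            continue
        choices = _GENE_EVENT_CHOICES[gene_event]
        names = [c[0] for c in choices]
        weights = [c[1] for c in choices]
        event = names[int(rng.choice(len(names), p=weights))]
        spec = DRIVER_CATALOG[event]
        call = _driver_call(sample_id, spec, panel, rng)
        if call.key in used:  # evict the colliding passenger, keep the driver
            tumor_calls = [c for c in tumor_calls if c.key != call.key]
            normal_calls = [c for c in normal_calls if c.key != call.key]
            truth.artifact_keys.discard(call.key)
            truth.germline_keys.discard(call.key)
        used.add(call.key)
        tumor_calls.append(call)
        if spec.gene == POLE:
            truth.planted_pole[event] = call.key
        else:
            truth.planted_drivers[event] = call.key

    # every hypermutated tumor carries a POLE mutation: fall back to the
    # stoploss call when both hotspots missed, and add non-hotspot POLE calls
    if profile.hypermutated:
        if not truth.planted_pole:
            spec = DRIVER_CATALOG["POLE_X2287W"]
            call = _driver_call(sample_id, spec, panel, rng)
            if claim(call):
                tumor_calls.append(call)
                truth.planted_pole["POLE_X2287W"] = call.key
        n_extra = int(rng.poisson(1.5))
        picks = rng.choice(len(POLE_PASSENGER_CATALOG), size=min(n_extra, len(POLE_PASSENGER_CATALOG)),
                           replace=False)
        for i in picks:
            spec = POLE_PASSENGER_CATALOG[int(i)]
            call = _driver_call(sample_id, spec, panel, rng)
            if claim(call):
                tumor_calls.append(call)
    elif rng.random() < 0.15:
        # an occasional benign exonic POLE variant in non-hypermutated samples
        spec = POLE_BENIGN_CATALOG[int(rng.integers(len(POLE_BENIGN_CATALOG)))]
        call = _driver_call(sample_id, spec, panel, rng)
        if claim(call):
            tumor_calls.append(call)

    # truth group follows what was actually planted
    if profile.hypermutated:
        truth.truth_group = 1
    elif any(DRIVER_CATALOG[e].gene in MMR_GENES for e in truth.planted_drivers):
        truth.truth_group = 2
    elif any(DRIVER_CATALOG[e].gene == "TP53" for e in truth.planted_drivers):
        truth.truth_group = 3
    else:
        truth.truth_group = 4

    tumor = SampleVariantSet(sample_id=sample_id, tissue=Tissue.TUMOR,
                             panel_id=panel.panel_id, variants=tumor_calls)
    normal = SampleVariantSet(sample_id=sample_id, tissue=Tissue.NORMAL,
                              panel_id=panel.panel_id, variants=normal_calls)
    return tumor, normal, truth


_combined_panel_cache: Optional[PanelDefinition] = None


def _combined_default_panel() -> PanelDefinition:
    """The tumor panel plus the POLE add-on as one lookup structure."""
    global _combined_panel_cache
    if _combined_panel_cache is None:
        base = default_panel()
        pole = pole_panel()
        _combined_panel_cache = PanelDefinition(
            panel_id=base.panel_id,
            gene_symbols=base.gene_symbols | pole.gene_symbols,
            target_regions=base.target_regions + pole.target_regions,
            amplicon_count=base.amplicon_count + pole.amplicon_count,
            covered_kb=base.covered_kb + pole.covered_kb,
            exonic_coverage_fraction=base.exonic_coverage_fraction,
            gene_regions={**base.gene_regions, **pole.gene_regions},
        )
    return _combined_panel_cache


# --------------------------------------------------------------------------
# Clinical covariates
# --------------------------------------------------------------------------

# Per-histology covariate probabilities matching the published
# contingency structure (counts over 34 endometrioid / 13 serous).
_CLINICAL = {
    Histology.EAC: dict(
        age_mean=60.9, age_sd=11.2, parity_rate=1.8,
        race_p={"White": 0.324, "Black": 0.177, "Asian": 0.088, "Hispanic": 0.206,
                "Other": 0.205},
        stage_p={"I": 0.647, "II": 0.118, "III": 0.206, "IV": 0.029},
        lvsi=0.324, pelvic_nodes=0.118, para_aortic_nodes=0.059,
        cervix=0.206, ovaries=0.118,
        chemo=0.353, ebrt=0.324, brachy=0.412,
        pfs_median=37.5, pfs_sigma=0.6,
        vital_p={"alive": 0.794, "dead": 0.029, "lost": 0.177},
        myo_mean=30.0,
    ),
    Histology.USC: dict(
        age_mean=70.7, age_sd=7.0, parity_rate=4.2,
        race_p={"White": 0.154, "Black": 0.615, "Asian": 0.0, "Hispanic": 0.154,
                "Other": 0.077},
        stage_p={"I": 0.077, "II": 0.308, "III": 0.615, "IV": 0.0},
        lvsi=0.538, pelvic_nodes=0.385, para_aortic_nodes=0.462,
        cervix=0.769, ovaries=0.154,
        chemo=1.0, ebrt=0.846, brachy=0.769,
        pfs_median=15.0, pfs_sigma=0.7,
        vital_p={"alive": 0.539, "dead": 0.231, "lost": 0.230},
        myo_mean=50.0,
    ),
}


def simulate_clinical(
    truth: SampleTruth,
    rng: np.random.Generator,
    recurrence_prob_eac: float = 7 / 34,
    recurrence_prob_usc: float = 8 / 13,
) -> ClinicalRecord:
    """Draw one patient's covariates from the per-histology structure."""
    p = _CLINICAL[truth.histology]
    races = sorted(p["race_p"])
    race = str(rng.choice(races, p=[p["race_p"][r] / sum(p["race_p"].values()) for r in races]))
    stages = ("I", "II", "III", "IV")
    stage = str(rng.choice(stages, p=[p["stage_p"][s] for s in stages]))
    vitals = ("alive", "dead", "lost")
    vital = str(rng.choice(vitals, p=[p["vital_p"][v] / sum(p["vital_p"].values()) for v in vitals]))
    rec_p = (recurrence_prob_usc if truth.histology is Histology.USC
             else recurrence_prob_eac)
    return ClinicalRecord(
        sample_id=truth.sample_id,
        histology=truth.histology,
        grade=truth.grade if truth.histology is Histology.EAC else None,
        age=float(np.clip(rng.normal(p["age_mean"], p["age_sd"]), 30, 95)),
        parity=int(rng.poisson(p["parity_rate"])),
        race=race,
        stage=Stage(stage),
        lvsi=bool(rng.random() < p["lvsi"]),
        myoinvasion_pct=float(np.clip(rng.normal(p["myo_mean"], 25), 0, 100)),
        site_flags={
            "pelvic_nodes": bool(rng.random() < p["pelvic_nodes"]),
            "para_aortic_nodes": bool(rng.random() < p["para_aortic_nodes"]),
            "cervix": bool(rng.random() < p["cervix"]),
            "ovaries": bool(rng.random() < p["ovaries"]),
        },
        chemo=bool(rng.random() < p["chemo"]),
        ebrt=bool(rng.random() < p["ebrt"]),
        brachy=bool(rng.random() < p["brachy"]),
        recurrence=bool(rng.random() < rec_p),
        pfs_months=float(p["pfs_median"] * rng.lognormal(0.0, p["pfs_sigma"])),
        vital=VitalStatus(vital),
    )


# --------------------------------------------------------------------------
# Cohort-level generation and the annotation fixture
# --------------------------------------------------------------------------

def simulate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> Cohort:
    """Generate a full paired cohort: variant sets, truth, clinical table."""
    if config is None:
        config = CohortConfig()
    root = np.random.SeedSequence(seed)
    n_total = sum(config.counts.values())
    streams = root.spawn(n_total + 1)
    clin_rng = np.random.default_rng(streams[-1])

    pairs: list[SamplePair] = []
    truth = CohortTruth()
    clinical: list[ClinicalRecord] = []
    idx = 0
    for label in sorted(config.counts):
        for _ in range(config.counts[label]):
            sid = f"S{idx + 1:02d}"
            rng = np.random.default_rng(streams[idx])
            tumor, normal, st = simulate_sample(config.profiles[label], rng, sample_id=sid)
            pairs.append(SamplePair(sample_id=sid, profile_label=label,
                                    tumor=tumor, normal=normal))
            truth.samples[sid] = st
            clinical.append(
                simulate_clinical(st, clin_rng,
                                  config.recurrence_prob_eac, config.recurrence_prob_usc)
            )
            idx += 1
    return Cohort(pairs=pairs, truth=truth, clinical=clinical)


def _catalog_record(spec: DriverSpec, panel: PanelDefinition) -> AnnotationRecord:
    chrom, start, _end = panel.gene_regions[spec.gene]
    return AnnotationRecord(
        gene=spec.gene, hgvs_c=spec.hgvs_c,
        chrom=chrom, pos=start + spec.offset, ref=spec.ref, alt=spec.alt,
        sift=spec.sift, polyphen=spec.polyphen,
        clinvar=spec.clinvar, cosmic_count=spec.cosmic,
        dbcid=DbcidEntry(status=DbcidStatus.EXACT, gene=spec.gene)
        if spec.dbcid_exact else DbcidEntry(),
    )


def make_annotation_fixture(
    cohort: Cohort,
    seed: int = 0,
    panel: Optional[PanelDefinition] = None,
) -> AnnotationDB:
    """Build the annotation database the tiering cascade will consult.

    Catalog events (planted drivers, POLE variants, driver-INDEL loci)
    get records matching their curated evidence, so planted events tier
    as intended. Passenger calls receive background evidence: missense
    calls get SIFT/PolyPhen scores (uniform, so roughly half are
    concordantly benign), synonymous calls get the three synonymous
    predictor scores, a small fraction of calls get population MAF above
    1% or modest catalog occurrence counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA))) if isinstance(seed, int) else seed
    if panel is None:
        panel = _combined_default_panel()
    db = AnnotationDB()
    for spec in DRIVER_CATALOG.values():
        db.add(_catalog_record(spec, panel))
    for spec in POLE_PASSENGER_CATALOG + POLE_BENIGN_CATALOG:
        db.add(_catalog_record(spec, panel))
    for gene, start, end in DBCID_OVERLAP_LOCI:
        chrom, gstart, _gend = panel.gene_regions[gene]
        db.add(
            AnnotationRecord(
                gene=gene, hgvs_c=f"dbcid:{gene}:{start}-{end}",
                dbcid=DbcidEntry(status=DbcidStatus.OVERLAP, gene=gene,
                                 start=gstart + start, end=gstart + end),
            )
        )

    annotated: set[VariantKey] = {r.coord_key for r in db.records if r.has_coord_key}
    for pair in cohort.pairs:
        st = cohort.truth.samples[pair.sample_id]
        for v in pair.tumor:
            if v.key in annotated:
                continue
            annotated.add(v.key)
            if v.key in st.germline_keys:
                db.add(AnnotationRecord(
                    gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    pop_maf=float(rng.uniform(0.02, 0.4)),
                ))
                continue
            if v.effect is Effect.MISSENSE:
                # most passenger missense calls score concordantly benign;
                # a minority get uniform scores and may look deleterious
                if rng.random() < 0.82:
                    sift = float(rng.uniform(0.06, 1.0))
                    polyphen = float(rng.uniform(0.0, 0.49))
                else:
                    sift = float(rng.uniform())
                    polyphen = float(rng.uniform())
                rec = AnnotationRecord(
                    gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    sift=sift, polyphen=polyphen,
                )
            elif v.effect is Effect.SYNONYMOUS:
                rec = AnnotationRecord(
                    gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    trap=float(rng.beta(1.0, 3.5)),
                    silva=float(rng.beta(1.0, 3.5)),
                    fathmm=float(rng.beta(1.0, 3.5)),
                )
            elif rng.random() < 0.10:
                rec = AnnotationRecord(
                    gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    cosmic_count=int(rng.integers(1, 40)),
                )
            else:
                continue
            if rng.random() < 0.35:
                # population-polymorphism leakage removed by the MAF filter
                rec.pop_maf = float(rng.uniform(0.011, 0.1))
            if rec.sift is not None and rng.random() < 0.03:
                rec.cosmic_count = int(rng.integers(1, 50))
            db.add(rec)
    return db
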