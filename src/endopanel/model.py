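"""Core domain types for tumor/normal targeted-panel variant analysis.

The types here mirror what a targeted amplicon sequencing workflow hands
downstream: per-sample variant call sets for tumor (T) and matched
non-tumor (NT) tissue, an annotation database carrying external evidence
(SIFT, PolyPhen-2, ClinVar, COSMIC occurrence counts, population allele
frequency, synonymous-variant predictor scores, driver-INDEL catalog
entries), the panel definition itself, and per-patient clinical records.

Coordinates are 1-based and fully closed, with VCF-style allele
representation (multi-base ref/alt for INDELs anchored at the first
base). Allele fractions, caller p-values and all predictor scores live in
[0, 1]; violations raise :class:`ValidationError` at construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class VarClass(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


class Effect(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    STOPLOSS = "stoploss"
    SPLICE = "splice"
    OTHER = "other"


#: Variant effects that change the protein sequence; synonymous calls are
#: routed to a separate predictor stream and never counted here.
NONSYNONYMOUS_EFFECTS = frozenset(
    {
        Effect.MISSENSE,
        Effect.NONSENSE,
        Effect.FRAMESHIFT,
        Effect.NONFRAMESHIFT_INDEL,
        Effect.STOPLOSS,
        Effect.SPLICE,
    }
)


class Quality(str, enum.Enum):
    PASS = "pass"
    LOW_QUALITY = "low_quality"
    SEQUENCING_ERROR = "sequencing_error"


class Region(str, enum.Enum):
    EXONIC = "exonic"
    NON_EXONIC = "non_exonic"


class Domain(str, enum.Enum):
    """Protein-domain context, used by the POLE hotspot assessment."""

    FUNCTIONAL = "functional_domain"
    OUTSIDE = "outside_domain"
    UNKNOWN = "unknown"


class ClinVarAssertion(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNCERTAIN = "uncertain"
    ABSENT = "absent"


VariantKey = tuple[str, int, str, str]

_BASES = frozenset("ACGTN")


@dataclass(slots=True)
class VariantCall:
    """One called variant in one tissue of one sample.

    ``tumor_af``/``normal_af`` follow the paired-caller convention: a
    tumor-tissue call carries its own fraction in ``tumor_af`` and, when
    the paired workflow observed the site in the matched normal, the
    normal fraction in ``normal_af``; a normal-tissue call carries its
    fraction in ``normal_af``. ``normal_af_observed`` distinguishes a
    measured absence (0.0, observed) from missing data (0.0, unobserved)
    so germline logic can tell "tested, absent" from "no data".
    """

    sample_id: str
    tissue: Tissue
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    var_class: VarClass
    effect: Effect
    hgvs_c: str = "."
    hgvs_p: str = "."
    tumor_af: float = 0.0
    normal_af: float = 0.0
    normal_af_observed: bool = False
    depth: int = 0
    caller_p: float = 0.0
    quality: Quality = Quality.PASS
    region: Region = Region.EXONIC
    domain: Domain = Domain.UNKNOWN

    def __post_init__(self) -> None:
        self.tissue = Tissue(self.tissue)
        self.var_class = VarClass(self.var_class)
        self.effect = Effect(self.effect)
        self.quality = Quality(self.quality)
        self.region = Region(self.region)
        self.domain = Domain(self.domain)
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        bad = (set(self.ref) | set(self.alt)) - _BASES
        if bad:
            raise ValidationError(f"non-nucleotide characters {sorted(bad)} in alleles")
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        if is_snv != (self.var_class is VarClass.SNV):
            raise ValidationError(
                f"var_class {self.var_class.value} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        for name in ("tumor_af", "normal_af", "caller_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def own_af(self) -> float:
        """Allele fraction in the tissue the call belongs to."""
        return self.tumor_af if self.tissue is Tissue.TUMOR else self.normal_af

    @property
    def is_snv(self) -> bool:
        return self.var_class is VarClass.SNV

    @property
    def is_indel(self) -> bool:
        return self.var_class in (VarClass.INS, VarClass.DEL)


@dataclass(slots=True)
class SampleVariantSet:
    """All calls for one tissue of one sample; keys are unique."""

    sample_id: str
    tissue: Tissue
    panel_id: str
    variants: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tissue = Tissue(self.tissue)
        seen: set[VariantKey] = set()
        for v in self.variants:
            if v.tissue is not self.tissue:
                raise ValidationError(
                    f"variant {v.chrom}:{v.pos} tissue {v.tissue.value} != set "
                    f"tissue {self.tissue.value}"
                )
            if v.key in seen:
                raise ValidationError(f"duplicate variant key {v.key} in {self.sample_id}")
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.variants)

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {v.key: v for v in self.variants}


@dataclass(slots=True)
class PanelDefinition:
    """Targeted panel: gene symbols plus 1-based closed target regions."""

    panel_id: str
    gene_symbols: frozenset[str]
    target_regions: list[tuple[str, int, int]]
    amplicon_count: int = 0
    covered_kb: float = 0.0
    exonic_coverage_fraction: float = 0.0
    gene_regions: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValidationError("panel must declare at least one gene symbol")
        for chrom, start, end in self.target_regions:
            if end < start or start < 1:
                raise ValidationError(f"degenerate target region {chrom}:{start}-{end}")


class DbcidStatus(str, enum.Enum):
    EXACT = "exact_entry"
    OVERLAP = "overlap_entry"
    ABSENT = "absent"


@dataclass(slots=True, frozen=True)
class DbcidEntry:
    """Driver-INDEL catalog evidence attached to an annotation record.

    ``exact_entry`` means the catalog lists this precise allele;
    ``overlap_entry`` carries the catalog locus (gene, start, end) that a
    different allele may intersect.
    """

    status: DbcidStatus = DbcidStatus.ABSENT
    gene: str = "."
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", DbcidStatus(self.status))
        if self.status is DbcidStatus.OVERLAP and self.end < self.start:
            raise ValidationError(f"degenerate dbCID interval {self.start}-{self.end}")


def _check_score(name: str, v: Optional[float]) -> None:
    if v is not None and not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name} = {v} outside [0, 1]")


@dataclass(slots=True)
class AnnotationRecord:
    """External evidence for one variant, keyed by coordinates and/or HGVS."""

    gene: str = "."
    hgvs_c: str = "."
    chrom: str = "."
    pos: int = 0
    ref: str = "."
    alt: str = "."
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    clinvar: ClinVarAssertion = ClinVarAssertion.ABSENT
    cosmic_count: int = 0
    pop_maf: float = 0.0
    trap: Optional[float] = None
    silva: Optional[float] = None
    fathmm: Optional[float] = None
    dbcid: DbcidEntry = field(default_factory=DbcidEntry)

    def __post_init__(self) -> None:
        self.clinvar = ClinVarAssertion(self.clinvar)
        if not self.has_coord_key and not self.has_hgvs_key:
            raise ValidationError("annotation record needs a coordinate or (gene, hgvs_c) key")
        for name in ("sift", "polyphen", "trap", "silva", "fathmm"):
            _check_score(name, getattr(self, name))
        if not 0.0 <= self.pop_maf <= 1.0:
            raise ValidationError(f"pop_maf = {self.pop_maf} outside [0, 1]")
        if self.cosmic_count < 0:
            raise ValidationError(f"cosmic_count must be >= 0, got {self.cosmic_count}")

    @property
    def has_coord_key(self) -> bool:
        return self.chrom != "." and self.pos >= 1 and self.ref != "." and self.alt != "."

    @property
    def has_hgvs_key(self) -> bool:
        return self.gene != "." and self.hgvs_c != "."

    @property
    def coord_key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def hgvs_key(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)

    @property
    def is_absent(self) -> bool:
        """True for the sentinel returned on a failed lookup."""
        return (
            self.sift is None
            and self.polyphen is None
            and self.clinvar is ClinVarAssertion.ABSENT
            and self.cosmic_count == 0
            and self.pop_maf == 0.0
            and self.trap is None
            and self.silva is None
            and self.fathmm is None
            and self.dbcid.status is DbcidStatus.ABSENT
        )


def absent_record(variant: VariantCall) -> AnnotationRecord:
    """Sentinel record for a variant with no annotation evidence."""
    return AnnotationRecord(
        gene=variant.gene,
        hgvs_c=variant.hgvs_c if variant.hgvs_c != "." else ".",
        chrom=variant.chrom,
        pos=variant.pos,
        ref=variant.ref,
        alt=variant.alt,
    )


class AnnotationDB:
    """Deterministic lookup of annotation evidence.

    Lookup prefers the coordinate key and falls back to (gene, hgvs_c);
    a miss on both returns an explicit absent-record sentinel rather
    than ``None``, so downstream rules can treat "no evidence" uniformly.
    Per-gene dbCID overlap intervals are kept separately so that INDELs
    whose exact allele is not cataloged can still be matched by locus.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = ()) -> None:
        self._by_coord: dict[VariantKey, AnnotationRecord] = {}
        self._by_hgvs: dict[tuple[str, str], AnnotationRecord] = {}
        self.records: list[AnnotationRecord] = []
        for rec in records:
            self.add(rec)

    def add(self, rec: AnnotationRecord) -> None:
        self.records.append(rec)
        if rec.has_coord_key:
            self._by_coord[rec.coord_key] = rec
        if rec.has_hgvs_key:
            self._by_hgvs[rec.hgvs_key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, variant: VariantCall) -> AnnotationRecord:
        rec = self._by_coord.get(variant.key)
        if rec is None:
            rec = self._by_hgvs.get((variant.gene, variant.hgvs_c))
        return rec if rec is not None else absent_record(variant)

    def overlap_entries(self, gene: str) -> list[DbcidEntry]:
        """All dbCID overlap intervals recorded for ``gene``."""
        out = []
        for rec in self.records:
            e = rec.dbcid
            if e.status is DbcidStatus.OVERLAP and e.gene == gene:
                out.append(e)
        return out


class Histology(str, enum.Enum):
    EAC = "EAC"
    USC = "USC"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DEAD = "dead"
    LOST = "lost"


#: Metastatic-site flags carried by every clinical record.
SITE_FLAGS = ("pelvic_nodes", "para_aortic_nodes", "cervix", "ovaries")


@dataclass(slots=True)
class ClinicalRecord:
    """Clinicopathologic covariates for one patient.

    Serous carcinomas are high grade by definition; ``grade`` is None for
    USC records (the per-grade stratification applies to endometrioid
    tumors only).
    """

    sample_id: str
    histology: Histology
    grade: Optional[int]
    age: float
    parity: int
    race: str
    stage: Stage
    lvsi: bool
    myoinvasion_pct: float
    site_flags: dict[str, bool] = field(default_factory=dict)
    chemo: bool = False
    ebrt: bool = False
    brachy: bool = False
    recurrence: bool = False
    pfs_months: float = 0.0
    vital: VitalStatus = VitalStatus.ALIVE

    def __post_init__(self) -> None:
        self.histology = Histology(self.histology)
        self.stage = Stage(self.stage)
        self.vital = VitalStatus(self.vital)
        if self.histology is Histology.EAC and self.grade not in (1, 2, 3):
            raise ValidationError(f"EAC record {self.sample_id} needs grade 1/2/3")
        if self.histology is Histology.USC and self.grade is not None:
            raise ValidationError("USC records carry grade = None (high grade by definition)")
        if self.pfs_months < 0:
            raise ValidationError("pfs_months must be >= 0")
        if not 0.0 <= self.myoinvasion_pct <= 100.0:
            raise ValidationError("myoinvasion_pct outside [0, 100]")
        if self.parity < 0:
            raise ValidationError("parity must be >= 0")
        for k in SITE_FLAGS:
            self.site_flags.setdefault(k, False)
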