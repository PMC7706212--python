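"""Readers and writers for the package's plain-text exchange formats.

Canonical formats are UTF-8 TSV with fixed headers and "." for absent
values. Every reader validates rows as it goes and reports malformed rows
with their line number; every reader/writer pair round-trips field for
field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

from .model import (
    AnnotationDB,
    AnnotationRecord,
    ClinicalRecord,
    DbcidEntry,
    DbcidStatus,
    SampleVariantSet,
    SITE_FLAGS,
    Tissue,
    ValidationError,
    VariantCall,
)

PathLike = Union[str, Path]

VARIANT_COLUMNS = (
    "sample_id", "tissue", "chrom", "pos", "ref", "alt", "gene", "var_class",
    "effect", "hgvs_c", "hgvs_p", "tumor_af", "normal_af",
    "normal_af_observed", "depth", "caller_p", "quality", "region", "domain",
)

ANNOTATION_COLUMNS = (
    "gene", "hgvs_c", "chrom", "pos", "ref", "alt", "sift", "polyphen",
    "clinvar", "cosmic_count", "pop_maf", "trap", "silva", "fathmm",
    "dbcid_status", "dbcid_gene", "dbcid_start", "dbcid_end",
)

CLINICAL_COLUMNS = (
    "sample_id", "histology", "grade", "age", "parity", "race", "stage",
    "lvsi", "myoinvasion_pct", *SITE_FLAGS, "chemo", "ebrt", "brachy",
    "recurrence", "pfs_months", "vital",
)

_MISSING = "."


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "value"):  # Enum
        return str(value.value)
    return str(value)


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {token!r}")


def _parse_float(token: str, default: Optional[float] = None) -> Optional[float]:
    if token == _MISSING or token == "":
        return default
    return float(token)


def _check_header(header, required, path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValidationError(f"{path}: header missing columns {missing}")


def read_variant_table(path: PathLike, tissue: Union[Tissue, str]) -> SampleVariantSet:
    """Read a per-sample variant TSV into a validated call set.

    The file's tissue column must agree with ``tissue``; any malformed
    row raises a :class:`ValidationError` naming the line.
    """
    tissue = Tissue(tissue)
    variants: list[VariantCall] = []
    sample_id = ""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, VARIANT_COLUMNS, path)
        for row in reader:
            lineno = reader.line_num
            try:
                call = VariantCall(
                    sample_id=row["sample_id"],
                    tissue=row["tissue"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    var_class=row["var_class"],
                    effect=row["effect"],
                    hgvs_c=row["hgvs_c"],
                    hgvs_p=row["hgvs_p"],
                    tumor_af=_parse_float(row["tumor_af"], 0.0),
                    normal_af=_parse_float(row["normal_af"], 0.0),
                    normal_af_observed=_parse_bool(row["normal_af_observed"]),
                    depth=int(row["depth"]),
                    caller_p=_parse_float(row["caller_p"], 0.0),
                    quality=row["quality"],
                    region=row["region"],
                    domain=row["domain"],
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            variants.append(call)
            sample_id = call.sample_id
    return SampleVariantSet(
        sample_id=sample_id, tissue=tissue, panel_id="", variants=variants
    )


def write_variant_table(varset: SampleVariantSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in varset.variants:
            writer.writerow([_fmt(getattr(v, c)) for c in VARIANT_COLUMNS])


def _record_from_mapping(m: dict) -> AnnotationRecord:
    dbcid = DbcidEntry(
        status=DbcidStatus(m.get("dbcid_status", "absent") or "absent"),
        gene=m.get("dbcid_gene", ".") or ".",
        start=int(m.get("dbcid_start") or 0),
        end=int(m.get("dbcid_end") or 0),
    )
    clinvar = m.get("clinvar", "absent")
    return AnnotationRecord(
        gene=m.get("gene", ".") or ".",
        hgvs_c=m.get("hgvs_c", ".") or ".",
        chrom=m.get("chrom", ".") or ".",
        pos=int(m.get("pos") or 0),
        ref=m.get("ref", ".") or ".",
        alt=m.get("alt", ".") or ".",
        sift=m.get("sift"),
        polyphen=m.get("polyphen"),
        clinvar=clinvar if clinvar else "absent",
        cosmic_count=int(m.get("cosmic_count") or 0),
        pop_maf=float(m.get("pop_maf") or 0.0),
        trap=m.get("trap"),
        silva=m.get("silva"),
        fathmm=m.get("fathmm"),
        dbcid=dbcid,
    )


def load_annotation_db(path: PathLike) -> AnnotationDB:
    """Load the annotation fixture database from TSV or JSON.

    JSON holds a list of record objects; TSV uses ``ANNOTATION_COLUMNS``.
    Scores outside [0, 1] are hard errors.
    """
    path = Path(path)
    db = AnnotationDB()
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        for i, m in enumerate(payload):
            try:
                db.add(_record_from_mapping(m))
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}: record {i}: {exc}") from exc
        return db
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, ANNOTATION_COLUMNS, path)
        for row in reader:
            lineno = reader.line_num
            m = {
                k: (None if v in (_MISSING, "") else v) for k, v in row.items()
            }
            for score in ("sift", "polyphen", "trap", "silva", "fathmm"):
                if m.get(score) is not None:
                    m[score] = float(m[score])
            try:
                db.add(_record_from_mapping(m))
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return db


def write_annotation_db(db: AnnotationDB, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = []
        for rec in db.records:
            payload.append(
                {
                    "gene": rec.gene,
                    "hgvs_c": rec.hgvs_c,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "sift": rec.sift,
                    "polyphen": rec.polyphen,
                    "clinvar": rec.clinvar.value,
                    "cosmic_count": rec.cosmic_count,
                    "pop_maf": rec.pop_maf,
                    "trap": rec.trap,
                    "silva": rec.silva,
                    "fathmm": rec.fathmm,
                    "dbcid_status": rec.dbcid.status.value,
                    "dbcid_gene": rec.dbcid.gene,
                    "dbcid_start": rec.dbcid.start,
                    "dbcid_end": rec.dbcid.end,
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for rec in db.records:
            writer.writerow(
                [
                    rec.gene, rec.hgvs_c, rec.chrom,
                    rec.pos if rec.pos else _MISSING,
                    rec.ref, rec.alt,
                    _fmt(rec.sift), _fmt(rec.polyphen), rec.clinvar.value,
                    rec.cosmic_count, rec.pop_maf,
                    _fmt(rec.trap), _fmt(rec.silva), _fmt(rec.fathmm),
                    rec.dbcid.status.value, rec.dbcid.gene,
                    rec.dbcid.start, rec.dbcid.end,
                ]
            )


SOMATIC_COLUMNS = VARIANT_COLUMNS + ("provenance", "review")


def write_somatic_callset(callset, path: PathLike) -> None:
    """Write a reviewed somatic call set (variant columns + provenance/review)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SOMATIC_COLUMNS)
        for call in callset.calls:
            row = [_fmt(getattr(call.variant, c)) for c in VARIANT_COLUMNS]
            row += [call.provenance.value, call.review.value]
            writer.writerow(row)


def read_somatic_callset(path: PathLike):
    """Read a reviewed somatic call set written by :func:`write_somatic_callset`."""
    from .discovery import Provenance, Review, ReviewedCall, SomaticCallSet

    path = Path(path)
    calls = []
    sample_id = ""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, SOMATIC_COLUMNS, path)
        for row in reader:
            lineno = reader.line_num
            try:
                variant = VariantCall(
                    sample_id=row["sample_id"],
                    tissue=row["tissue"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    var_class=row["var_class"],
                    effect=row["effect"],
                    hgvs_c=row["hgvs_c"],
                    hgvs_p=row["hgvs_p"],
                    tumor_af=_parse_float(row["tumor_af"], 0.0),
                    normal_af=_parse_float(row["normal_af"], 0.0),
                    normal_af_observed=_parse_bool(row["normal_af_observed"]),
                    depth=int(row["depth"]),
                    caller_p=_parse_float(row["caller_p"], 0.0),
                    quality=row["quality"],
                    region=row["region"],
                    domain=row["domain"],
                )
                calls.append(
                    ReviewedCall(
                        variant=variant,
                        provenance=Provenance(row["provenance"]),
                        review=Review(row["review"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            sample_id = variant.sample_id
    return SomaticCallSet(sample_id=sample_id, calls=calls)


def read_clinical_table(path: PathLike) -> list[ClinicalRecord]:
    """Read the clinical covariate TSV with categorical validation."""
    path = Path(path)
    records: list[ClinicalRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, CLINICAL_COLUMNS, path)
        for row in reader:
            lineno = reader.line_num
            try:
                grade = None if row["grade"] in (_MISSING, "", "NA") else int(row["grade"])
                rec = ClinicalRecord(
                    sample_id=row["sample_id"],
                    histology=row["histology"],
                    grade=grade,
                    age=float(row["age"]),
                    parity=int(row["parity"]),
                    race=row["race"],
                    stage=row["stage"],
                    lvsi=_parse_bool(row["lvsi"]),
                    myoinvasion_pct=float(row["myoinvasion_pct"]),
                    site_flags={k: _parse_bool(row[k]) for k in SITE_FLAGS},
                    chemo=_parse_bool(row["chemo"]),
                    ebrt=_parse_bool(row["ebrt"]),
                    brachy=_parse_bool(row["brachy"]),
                    recurrence=_parse_bool(row["recurrence"]),
                    pfs_months=float(row["pfs_months"]),
                    vital=row["vital"],
                )
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_clinical_table(records: list[ClinicalRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            row = [
                r.sample_id, r.histology.value,
                _MISSING if r.grade is None else r.grade,
                r.age, r.parity, r.race, r.stage.value,
                _fmt(r.lvsi), r.myoinvasion_pct,
                *[_fmt(r.site_flags[k]) for k in SITE_FLAGS],
                _fmt(r.chemo), _fmt(r.ebrt), _fmt(r.brachy),
                _fmt(r.recurrence), r.pfs_months, r.vital.value,
            ]
            writer.writerow(row)
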