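"""Shared randomized fixture builders and oracle-agreement counters.

Used by the unit tests and by the acceptance machinery to measure
agreement between the staged pipeline and the flat brute-force oracles
on randomized small fixtures.
"""

from __future__ import annotations

import numpy as np

from endopanel.discovery import discover_somatic
from endopanel.filtering import tier_sample
from endopanel.model import (
    AnnotationDB,
    AnnotationRecord,
    DbcidEntry,
    DbcidStatus,
    SampleVariantSet,
    VariantCall,
)

from oracles import oracle_discovery_status, oracle_tier


def tumor_call(pos, *, ref="C", alt="A", normal_af=0.0, observed=True,
               quality="pass", depth=500, caller_p=0.01, effect="missense",
               var_class="SNV", gene="PTEN"):
    return VariantCall(
        sample_id="S01", tissue="tumor", chrom="chr1", pos=pos, ref=ref, alt=alt,
        gene=gene, var_class=var_class, effect=effect, tumor_af=0.4,
        normal_af=normal_af, normal_af_observed=observed, depth=depth,
        caller_p=caller_p, quality=quality,
    )


def normal_call(pos, *, ref="C", alt="A", af=0.5, depth=500):
    return VariantCall(
        sample_id="S01", tissue="normal", chrom="chr1", pos=pos, ref=ref, alt=alt,
        gene="PTEN", var_class="SNV", effect="missense", tumor_af=0.0,
        normal_af=af, normal_af_observed=True, depth=depth, caller_p=0.01,
    )


def random_discovery_pair(rng, n_max=20):
    """Random overlapping tumor/normal call lists exercising every rule."""
    tumor_calls, normal_calls = [], []
    for i in range(int(rng.integers(1, n_max + 1))):
        pos = 100 + i
        tumor_calls.append(
            tumor_call(
                pos,
                normal_af=float(rng.choice([0.0, 0.03, 0.15, 0.5])),
                observed=bool(rng.random() < 0.7),
                quality=str(rng.choice(["pass", "pass", "low_quality",
                                        "sequencing_error"])),
            )
        )
        if rng.random() < 0.4:
            normal_calls.append(
                normal_call(pos, af=float(rng.choice([0.0, 0.02, 0.08, 0.12, 0.5])),
                            depth=int(rng.choice([5, 500])))
            )
    return tumor_calls, normal_calls


def discovery_mismatches(tumor_calls, normal_calls, evidence) -> int:
    """Count per-variant disagreements between the chain and the oracle."""
    tumor = SampleVariantSet("S01", "tumor", "P", tumor_calls)
    normal = SampleVariantSet("S01", "normal", "P", normal_calls)
    callset = discover_somatic(tumor, normal, caller_evidence=evidence)
    got = {c.variant.key: c.review.value for c in callset.calls}
    normal_by_key = normal.by_key()
    bad = 0
    for v in tumor_calls:
        expected = oracle_discovery_status(v, normal_by_key, evidence)
        if got.get(v.key, "absent") != expected:
            bad += 1
    return bad


def random_tier_fixture(rng, n=30):
    """Random retained-somatic calls with random annotation evidence."""
    variants = []
    records = []
    for i in range(n):
        is_indel = rng.random() < 0.2
        effect = (
            str(rng.choice(["frameshift", "nonframeshift_indel"])) if is_indel
            else str(rng.choice(["missense", "missense", "synonymous", "nonsense",
                                 "splice", "other"]))
        )
        v = tumor_call(
            100 + i,
            ref="AT" if is_indel else "C",
            alt="A" if is_indel else "T",
            var_class="DEL" if is_indel else "SNV",
            effect=effect,
            caller_p=float(rng.choice([0.01, 0.04, 0.05, 0.06, 0.5])),
            gene=str(rng.choice(["PTEN", "MSH2", "TP53", "KRAS"])),
        )
        variants.append(v)
        if rng.random() < 0.85:
            records.append(
                AnnotationRecord(
                    gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    sift=None if rng.random() < 0.3 else float(rng.random()),
                    polyphen=None if rng.random() < 0.3 else float(rng.random()),
                    clinvar=str(rng.choice(["absent", "absent", "pathogenic",
                                            "benign", "uncertain"])),
                    cosmic_count=int(rng.choice([0, 0, 3, 499, 500, 501, 900])),
                    pop_maf=float(rng.choice([0.0, 0.005, 0.01, 0.011, 0.2])),
                    trap=float(rng.random()), silva=float(rng.random()),
                    fathmm=float(rng.random()),
                )
            )
    db = AnnotationDB(records)
    if rng.random() < 0.5:
        db.add(
            AnnotationRecord(
                gene="PTEN", hgvs_c="dbcid:PTEN",
                dbcid=DbcidEntry(status=DbcidStatus.OVERLAP, gene="PTEN",
                                 start=int(rng.integers(90, 130)),
                                 end=int(rng.integers(130, 170))),
            )
        )
    return variants, db


def tiering_mismatches(variants, db) -> int:
    """Count disagreements between the cascade and the flat truth table."""
    tiered, syn, removed = tier_sample(variants, db)
    got = {t.variant.key: t.tier.value for t in tiered}
    got.update({v.key: "synonymous" for v, _ in syn})
    got.update({v.key: "removed" for v, _ in removed})
    bad = 0
    for v in variants:
        rec = db.lookup(v)
        overlaps = False
        if v.is_indel:
            span = (v.pos, v.pos + len(v.ref) - 1)
            overlaps = any(
                e.start <= span[1] and span[0] <= e.end
                for e in db.overlap_entries(v.gene)
            )
        expected = oracle_tier(
            effect=v.effect.value, caller_p=v.caller_p, pop_maf=rec.pop_maf,
            sift=rec.sift, polyphen=rec.polyphen, clinvar=rec.clinvar.value,
            cosmic=rec.cosmic_count, is_indel=v.is_indel,
            dbcid_exact=rec.dbcid.status.value == "exact_entry",
            dbcid_overlaps=overlaps,
        )
        if got[v.key] != expected:
            bad += 1
    return bad


def rule_engine_agreement(n_fixtures: int, seed: int = 0) -> tuple[int, int]:
    """Run mixed randomized fixtures; return (agreeing, total)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_fixtures):
        kind = int(rng.integers(3))
        if kind == 0:
            tumor_calls, normal_calls = random_discovery_pair(rng)
            evidence = {v.key for v in tumor_calls if rng.random() < 0.8}
            bad = discovery_mismatches(tumor_calls, normal_calls, evidence)
        elif kind == 1:
            variants, db = random_tier_fixture(rng, n=int(rng.integers(1, 51)))
            bad = tiering_mismatches(variants, db)
        else:
            bad = group_assignment_mismatches(rng, cases=25)
        agree += bad == 0
    return agree, n_fixtures


def group_assignment_mismatches(rng, cases=25) -> int:
    from endopanel.classify import ResolvedThresholds, assign_group
    from endopanel.filtering import SampleSummary

    from oracles import oracle_group

    fixed = ResolvedThresholds(570.0, 9.0, 1.0, "fixed")
    genes = ("PTEN", "PIK3CA", "TP53", "MLH1", "MSH2", "MSH6", "PMS2")
    bad = 0
    for _ in range(cases):
        ca = int(rng.integers(0, 30))
        cg = int(rng.integers(0, 5))
        burden = max(int(rng.integers(0, 800)), ca + cg)
        hits = {g: bool(rng.random() < 0.3) for g in genes}
        s = SampleSummary(
            sample_id="S", n_unfiltered=burden, n_unfiltered_snv=burden,
            spectrum={"C>A": ca, "C>G": cg, "C>T": burden - ca - cg,
                      "T>A": 0, "T>C": 0, "T>G": 0},
            gene_hits=hits,
        )
        mmr = any(hits[g] for g in ("MLH1", "MSH2", "MSH6", "PMS2"))
        expected = oracle_group(burden, ca, cg, mmr, hits["TP53"])
        if assign_group(s, fixed).group != expected:
            bad += 1
    return bad
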