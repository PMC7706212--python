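"""Univariate clinical statistics: 2x2 odds ratios with Woolf/Wald
confidence intervals, chi-square / Fisher exact tests, t-test /
Mann-Whitney comparisons, and stratified comparison tables.

The odds ratio is the cross-product ``(a*d)/(b*c)`` with the log-scale
normal-approximation interval ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c +
1/d))`` — identical to the Wald interval from a univariate logistic
regression on a single binary covariate, which is why the closed form is
used instead of an iterative fit. Cells are oriented with the serous
(USC) stratum as exposure and endometrioid (EAC) as reference: *a* =
USC with outcome, *b* = USC without, *c* = EAC with, *d* = EAC without.
Any zero cell makes the ratio incalculable and is reported as N/A (no
continuity correction by default, matching the convention of reporting
perfectly-predicting subgroups as N/A; a Haldane-Anscombe correction is
available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import ClinicalRecord, Histology, Stage, ValidationError
from .classify import nearest_rank_quantile
from .filtering import SampleSummary

# Exact two-sided 95% normal quantile (1.959964), as used by standard
# logistic-regression software; the conventional shorthand 1.96 shifts
# wide intervals by a visible amount in the second decimal.
Z_95 = float(sps.norm.ppf(0.975))


@dataclass(slots=True)
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    or_point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    method: str
    na_reason: Optional[str] = None

    @property
    def is_na(self) -> bool:
        return self.or_point is None


def odds_ratio(
    a: int, b: int, c: int, d: int,
    z: float = Z_95,
    haldane: bool = False,
    p_value: bool = False,
) -> ContingencyResult:
    """Cross-product odds ratio with the Woolf/Wald 95% interval.

    A zero cell yields an N/A result unless ``haldane`` adds 0.5 to
    every cell. ``p_value`` optionally attaches the two-sided Fisher
    exact p for the same table.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValidationError(f"negative cell count in {cells}")
    p = fisher_exact_p(a, b, c, d) if p_value else None
    if 0 in cells and not haldane:
        return ContingencyResult(
            a, b, c, d, None, None, None, p, method="woolf_wald",
            na_reason="zero cell: subgroup predicts outcome perfectly",
        )
    fa, fb, fc, fd = (x + 0.5 for x in cells) if haldane else map(float, cells)
    point = (fa * fd) / (fb * fc)
    se = math.sqrt(1.0 / fa + 1.0 / fb + 1.0 / fc + 1.0 / fd)
    log_or = math.log(point)
    return ContingencyResult(
        a, b, c, d,
        or_point=point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=p,
        method="woolf_wald" + ("_haldane" if haldane else ""),
    )


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(slots=True)
class CategoricalTest:
    p_value: Optional[float]
    test: str
    na_reason: Optional[str] = None


def compare_categorical(
    table: Sequence[Sequence[int]],
    force: Optional[str] = None,
    expected_min: float = 5.0,
) -> CategoricalTest:
    """Chi-square or Fisher exact test on an r x c count table.

    Fisher's exact test is used for 2x2 tables whenever any expected
    cell is below ``expected_min`` (or when forced); the chi-square test
    (without continuity correction) otherwise. A zero row or column
    margin makes the comparison degenerate and is reported as N/A.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValidationError("contingency table must be a 2-D array of counts >= 0")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return CategoricalTest(None, "none", na_reason="zero margin")
    expected = np.outer(row, col) / t.sum()
    use_fisher = force == "fisher" or (
        force is None and t.shape == (2, 2) and (expected < expected_min).any()
    )
    if use_fisher:
        if t.shape != (2, 2):
            raise ValidationError("Fisher exact test implemented for 2x2 tables only")
        return CategoricalTest(fisher_exact_p(*t.astype(int).ravel()), "fisher")
    chi2 = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return CategoricalTest(float(sps.chi2.sf(chi2, dof)), "chi_square")


@dataclass(slots=True)
class ContinuousTest:
    p_value: float
    statistic: float
    test: str


def compare_continuous(
    x: Sequence[float],
    y: Sequence[float],
    test: str = "mannwhitney",
) -> ContinuousTest:
    """Two-sample comparison of a continuous covariate.

    Defaults to the Mann-Whitney U test with normal approximation
    (continuity-corrected, tie-corrected); ``test="ttest"`` selects the
    two-sample t-test instead, and ``test="mannwhitney_exact"`` the
    exact U distribution (no ties).
    """
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    if test == "ttest":
        stat, p = sps.ttest_ind(x, y)
        return ContinuousTest(float(p), float(stat), "ttest")
    if test in ("mannwhitney", "mannwhitney_exact"):
        method = "exact" if test == "mannwhitney_exact" else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return ContinuousTest(float(res.pvalue), float(res.statistic), test)
    raise ValidationError(f"unknown test {test!r}")


@dataclass(slots=True)
class DistributionSummary:
    style: str  # "mean_sd" or "median_iqr"
    center: float
    spread_low: float
    spread_high: float

    def __str__(self) -> str:
        if self.style == "mean_sd":
            return f"{self.center:.1f} ± {self.spread_high:.1f}"
        return f"{self.center:g} ({self.spread_low:g}, {self.spread_high:g})"


def summarize_distribution(values: Sequence[float], style: str = "median_iqr") -> DistributionSummary:
    """Mean +/- SD, or median with nearest-rank quartiles."""
    if len(values) == 0:
        raise ValidationError("cannot summarize an empty sample")
    arr = np.asarray(values, dtype=float)
    if style == "mean_sd":
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return DistributionSummary("mean_sd", float(arr.mean()), sd, sd)
    if style == "median_iqr":
        return DistributionSummary(
            "median_iqr",
            float(np.median(arr)),
            nearest_rank_quantile(list(arr), 0.25),
            nearest_rank_quantile(list(arr), 0.75),
        )
    raise ValidationError(f"unknown summary style {style!r}")


@dataclass(slots=True)
class ComparisonRow:
    covariate: str
    stratum_summaries: dict[str, str]
    or_result: Optional[ContingencyResult]
    p_value: Optional[float]
    test: str


@dataclass(slots=True)
class ComparisonTable:
    stratify_by: str
    strata: tuple[str, ...]
    rows: list[ComparisonRow] = field(default_factory=list)


def _dichotomous_row(
    name: str,
    exposed: Sequence[bool],
    reference: Sequence[bool],
    strata: tuple[str, str],
) -> ComparisonRow:
    a = sum(exposed)
    b = len(exposed) - a
    c = sum(reference)
    d = len(reference) - c
    res = odds_ratio(a, b, c, d)
    test = compare_categorical([[a, b], [c, d]])
    summaries = {
        strata[0]: f"{a} ({100 * a / max(len(exposed), 1):.1f})",
        strata[1]: f"{c} ({100 * c / max(len(reference), 1):.1f})",
    }
    return ComparisonRow(name, summaries, res, test.p_value, test.test)


def _continuous_row(
    name: str,
    groups: dict[str, list[float]],
    test: str,
    style: str,
) -> ComparisonRow:
    summaries = {k: str(summarize_distribution(v, style)) for k, v in groups.items() if v}
    vals = [v for v in groups.values() if len(v) >= 2]
    if len(vals) == 2:
        t = compare_continuous(vals[0], vals[1], test=test)
        return ComparisonRow(name, summaries, None, t.p_value, t.test)
    if len(vals) > 2:
        res = sps.kruskal(*vals)
        return ComparisonRow(name, summaries, None, float(res.pvalue), "kruskal")
    return ComparisonRow(name, summaries, None, None, "none")


#: Variant-count covariates reported for every stratification, in the
#: row order of the published summary tables.
COUNT_COVARIATES = (
    ("Unfiltered somatic variants", lambda s: s.n_unfiltered),
    ("Unfiltered somatic SNVs", lambda s: s.n_unfiltered_snv),
    ("SNV C>A", lambda s: s.spectrum["C>A"]),
    ("SNV C>G", lambda s: s.spectrum["C>G"]),
    ("SNV C>T", lambda s: s.spectrum["C>T"]),
    ("SNV T>A", lambda s: s.spectrum["T>A"]),
    ("SNV T>C", lambda s: s.spectrum["T>C"]),
    ("SNV T>G", lambda s: s.spectrum["T>G"]),
    ("Filtered somatic SNVs", lambda s: s.n_filtered_snv),
    ("Filtered somatic INDELs", lambda s: s.n_filtered_indel),
    ("Pathogenic somatic variants", lambda s: s.n_pathogenic),
    ("Candidate somatic variants", lambda s: s.n_candidate),
    ("Pathogenic plus candidate somatic variants", lambda s: s.n_path_plus_cand),
)

GENE_RATE_COVARIATES = ("PTEN", "PIK3CA", "TP53")


def _strata_of(
    clinical: dict[str, ClinicalRecord],
    summaries: dict[str, SampleSummary],
    stratify_by: str,
) -> dict[str, list[str]]:
    strata: dict[str, list[str]] = {}
    for sid in summaries:
        rec = clinical.get(sid)
        if stratify_by == "histology":
            if rec is None:
                continue
            key = rec.histology.value
        elif stratify_by == "grade_histology":
            if rec is None:
                continue
            key = "USC" if rec.histology is Histology.USC else f"Grade {rec.grade} EAC"
        elif stratify_by == "hypermutation":
            key = "Hypermutated" if summaries[sid].hypermutated else "Non-hypermutated"
        else:
            raise ValidationError(f"unknown stratification {stratify_by!r}")
        strata.setdefault(key, []).append(sid)
    order = {
        "histology": ("EAC", "USC"),
        "grade_histology": ("Grade 1 EAC", "Grade 2 EAC", "Grade 3 EAC", "USC"),
        "hypermutation": ("Non-hypermutated", "Hypermutated"),
    }[stratify_by]
    return {k: strata.get(k, []) for k in order if strata.get(k)}


def build_comparison_table(
    clinical: Sequence[ClinicalRecord],
    summaries: Sequence[SampleSummary],
    stratify_by: str = "histology",
) -> ComparisonTable:
    """Build a stratified comparison table of molecular and clinical rows.

    For the two-stratum histology comparison, dichotomous clinical
    covariates get a USC-versus-EAC odds ratio; variant-count covariates
    are compared by rank test (the count distributions are skewed), age
    by t-test. Strata with no samples are omitted; dichotomous rows with
    a zero cell keep their N/A odds ratio but remain in the table.
    """
    clin = {r.sample_id: r for r in clinical}
    summ = {s.sample_id: s for s in summaries}
    strata = _strata_of(clin, summ, stratify_by)
    if not strata:
        raise ValidationError("no resolvable samples for stratification")
    names = tuple(strata)
    table = ComparisonTable(stratify_by=stratify_by, strata=names)

    for name, getter in COUNT_COVARIATES:
        groups = {k: [float(getter(summ[sid])) for sid in sids] for k, sids in strata.items()}
        table.rows.append(_continuous_row(name, groups, "mannwhitney", "median_iqr"))
    for gene in GENE_RATE_COVARIATES:
        if len(names) == 2:
            exposed, reference = (
                [summ[sid].gene_hits.get(gene, False) for sid in strata[names[-1]]],
                [summ[sid].gene_hits.get(gene, False) for sid in strata[names[0]]],
            )
            table.rows.append(
                _dichotomous_row(f"{gene} mutation", exposed, reference, (names[-1], names[0]))
            )

    if stratify_by == "histology" and set(names) == {"EAC", "USC"}:
        usc = [clin[sid] for sid in strata["USC"]]
        eac = [clin[sid] for sid in strata["EAC"]]
        table.rows.append(
            _continuous_row(
                "Age (years)",
                {"EAC": [r.age for r in eac], "USC": [r.age for r in usc]},
                "ttest", "mean_sd",
            )
        )
        table.rows.append(
            _continuous_row(
                "Parity",
                {"EAC": [float(r.parity) for r in eac], "USC": [float(r.parity) for r in usc]},
                "mannwhitney", "median_iqr",
            )
        )
        dichotomous = [
            ("Stage III-IV", lambda r: r.stage in (Stage.III, Stage.IV)),
            ("Lymphovascular invasion", lambda r: r.lvsi),
            ("Pelvic lymph nodes", lambda r: r.site_flags["pelvic_nodes"]),
            ("Cervix involvement", lambda r: r.site_flags["cervix"]),
            ("Chemotherapy", lambda r: r.chemo),
            ("External beam radiation therapy", lambda r: r.ebrt),
            ("Brachytherapy", lambda r: r.brachy),
            ("Recurrence or progression", lambda r: r.recurrence),
        ]
        for name, pred in dichotomous:
            table.rows.append(
                _dichotomous_row(
                    name, [pred(r) for r in usc], [pred(r) for r in eac], ("USC", "EAC")
                )
            )
        table.rows.append(
            _continuous_row(
                "Progression free survival (months)",
                {"EAC": [r.pfs_months for r in eac], "USC": [r.pfs_months for r in usc]},
                "mannwhitney", "median_iqr",
            )
        )
    return table
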