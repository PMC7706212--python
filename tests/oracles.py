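"""Independent brute-force oracles for cross-checking the pipeline.

Everything here is deliberately written as flat, per-item rule
evaluation or exhaustive enumeration — no shared code with the package
beyond its data containers — so agreement between the two routes is
evidence that the staged implementation encodes the intended rules.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from endopanel.model import Quality

# ---------------------------------------------------------------------------
# Discovery: one flat decision per tumor variant
# ---------------------------------------------------------------------------


def oracle_discovery_status(
    v, normal_by_key, caller_evidence, germline_af=0.10, min_depth=20
) -> str:
    """Fate of one tumor call under the full discovery chain.

    Returns one of: absent, retained, excluded_quality,
    excluded_germline, excluded_unverified.
    """
    nt = normal_by_key.get(v.key)
    evidence = None
    if nt is not None and nt.depth >= min_depth:
        evidence = nt.normal_af
    if v.normal_af_observed:
        evidence = v.normal_af if evidence is None else max(evidence, v.normal_af)

    in_paired = evidence is None or evidence < germline_af
    in_single = nt is None
    if not in_paired and not in_single:
        return "absent"
    both = in_paired and in_single
    if not both and v.key not in caller_evidence:
        return "excluded_unverified"
    if v.quality in (Quality.LOW_QUALITY, Quality.SEQUENCING_ERROR):
        return "excluded_quality"
    if evidence is not None and evidence >= germline_af:
        return "excluded_germline"
    return "retained"


# ---------------------------------------------------------------------------
# Filtering / tiering: one flat truth table per variant
# ---------------------------------------------------------------------------


def oracle_tier(
    *,
    effect: str,
    caller_p: float,
    pop_maf: float,
    sift,
    polyphen,
    clinvar: str,
    cosmic: int,
    is_indel: bool = False,
    dbcid_exact: bool = False,
    dbcid_overlaps: bool = False,
) -> str:
    """Fate of one retained somatic call through filters and tiering.

    Returns one of: removed, synonymous, pathogenic, candidate, vus,
    filtered_out.
    """
    if caller_p > 0.05 or pop_maf > 0.01:
        return "removed"
    if effect == "synonymous":
        return "synonymous"
    if clinvar == "pathogenic":
        return "pathogenic"
    if clinvar == "benign":
        return "filtered_out"
    missense_scored = effect == "missense" and sift is not None and polyphen is not None
    if missense_scored and sift > 0.05 and polyphen < 0.5:
        return "filtered_out"
    if cosmic > 500:
        return "pathogenic"
    if is_indel and dbcid_exact:
        return "pathogenic"
    if is_indel and dbcid_overlaps:
        return "candidate"
    if missense_scored and (sift < 0.05 or polyphen >= 0.5):
        return "candidate"
    if 1 <= cosmic <= 500:
        return "candidate"
    return "vus"


def oracle_group(
    burden: int, ca: int, cg: int, mmr_hit: bool, tp53_hit: bool,
    burden_gt=570.0, ca_gt=9.0, cg_lt=1.0,
) -> int:
    if burden > burden_gt and ca > ca_gt and cg < cg_lt:
        return 1
    if mmr_hit:
        return 2
    if tp53_hit:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    1 + 1e-7 relative tolerance on the tie comparison).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(x: int) -> float:
        return _log_binom(r1, x) + _log_binom(r2, c1 - x) - _log_binom(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_p(x))
        if p <= p_obs * (1.0 + 1e-7):
            total += p
    return min(total, 1.0)


def chi2_p_textbook(table) -> float:
    """Pearson chi-square p from the closed-form statistic (no correction)."""
    from scipy.stats import chi2 as chi2_dist

    rows = len(table)
    cols = len(table[0])
    n = float(sum(sum(r) for r in table))
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / n
            stat += (table[i][j] - expected) ** 2 / expected
    return float(chi2_dist.sf(stat, (rows - 1) * (cols - 1)))


@lru_cache(maxsize=None)
def mann_whitney_u_distribution(n: int, m: int) -> tuple[int, dict[int, int]]:
    """Exact null distribution of U by exhaustive rank enumeration.

    Returns (number of arrangements, counts per achievable U of the
    first sample) for tie-free data.
    """
    counts: dict[int, int] = {}
    total = 0
    offset = n * (n + 1) // 2
    for positions in itertools.combinations(range(1, n + m + 1), n):
        u = sum(positions) - offset
        counts[u] = counts.get(u, 0) + 1
        total += 1
    return total, counts


def mann_whitney_exact_p(n: int, m: int, u: int) -> float:
    """Exact two-sided p: P(U at least as extreme as observed), using the
    symmetry of the null distribution about n*m/2."""
    total, counts = mann_whitney_u_distribution(n, m)
    center = n * m / 2.0
    dev = abs(u - center)
    tail = sum(cnt for val, cnt in counts.items() if abs(val - center) >= dev - 1e-12)
    return min(tail / total, 1.0)


def nearest_rank_quantile_oracle(values, p: float) -> float:
    """Sort-based nearest-rank quantile: walk the sorted list until at
    least a fraction p of observations is covered."""
    ordered = sorted(values)
    n = len(ordered)
    covered = 0
    for v in ordered:
        covered += 1
        if covered / n >= p - 1e-12:
            return float(v)
    return float(ordered[-1])


def wald_or_ci(a, b, c, d, z=1.959963984540054):
    """Closed-form log-scale odds-ratio interval, written independently."""
    point = (a * d) / (b * c)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-half), point * math.exp(half)
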