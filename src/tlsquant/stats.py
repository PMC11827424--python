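"""Correlation suite, Foxp3+ presence analysis, and patient rankings.

Cross-subset proliferation coupling is assessed with Spearman rank
correlation between the Ki-67+ fractions of the four lymphocyte subsets,
either across individual TLS domains (the canonical route) or across
sections after pooling each section's domains (the whole-section route).
Rho is the Pearson correlation of average ranks, so it is invariant under
any strictly monotone transform of either axis — in particular identical
before and after the log10 scaling used for display.  Two-sided p-values
use the t approximation for n ≥ 10 and exact permutation enumeration
below that.

Domains with fewer than 50 lymphocytes are removed before correlation
analyses only (never from rankings or area summaries) so that each data
point rests on an adequate denominator.

Patients are ranked by B-cell proliferation two ways: ``per_domain_mean``
(mean over the patient's domains of the per-domain B Ki-67+ fraction, one
vote per domain) and ``pooled`` (B Ki-67+ fraction of the patient's pooled
counts).  ``compare_rankings`` reports their concordance (rank rho,
Spearman footrule, top-k overlap).

Per-domain correlations ignore the within-patient clustering of domains;
results carry a caveat note rather than a mixed-model correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import SectionSummary, ki67_fraction
from .phenotyping import SUBSETS
from .qualification import TLSDomain

#: note attached to per-domain correlation results
CLUSTERING_CAVEAT = (
    "per-domain points are clustered within patients; p-values assume independence"
)

#: permutation/t-approximation crossover sample size
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CorrelationResult:
    x_variable: str
    y_variable: str
    n_points: int
    rho: float
    p_value: float
    level: str = "domain"
    scale_note: str = "log10 scaling is display-only; rho computed on raw values"
    insufficient: bool = False
    caveat: str = ""


@dataclass
class RankingResult:
    method: str  # "per_domain_mean" | "pooled"
    patient_ids: list[str]  # descending measure, ties by patient id
    measure: dict[str, float]


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    n = len(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _spearman_rho(x, y[list(perm)])
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(
    x, y, x_name: str = "x", y_name: str = "y", level: str = "domain"
) -> CorrelationResult:
    """Spearman rank correlation with two-sided p.

    Pairs containing non-finite values (the missing-value sentinel) are
    dropped; ``n_points`` reflects the drops.  Fewer than 3 usable pairs,
    or an all-constant vector, yields an insufficient/NaN result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult(
            x_name, y_name, n, float("nan"), float("nan"), level, insufficient=True
        )
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return CorrelationResult(
            x_name, y_name, n, float("nan"), float("nan"), level, insufficient=True
        )
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(x, y, rho)
    else:
        p = _t_approx_p(rho, n)
    return CorrelationResult(x_name, y_name, n, rho, p, level)


def filter_domains_for_correlation(
    domains: list[TLSDomain], min_cells: int = 50
) -> list[TLSDomain]:
    """Drop domains with fewer than ``min_cells`` lymphocytes.

    Applied only on correlation paths; rankings and area summaries use all
    qualified domains.
    """
    return [d for d in domains if d.composition.n_lymph >= min_cells]


def domain_ki67_table(domains: list[TLSDomain]) -> pd.DataFrame:
    """Per-domain Ki-67 fractions and non-proliferating Treg presence."""
    rows = []
    for d in domains:
        row = {"domain_id": d.domain_id, "section_id": d.section_id}
        for subset in SUBSETS:
            row[f"ki67_frac_{subset}"] = ki67_fraction(d.composition, subset)
        n_lymph = d.composition.n_lymph
        row["treg_ki67neg_presence"] = (
            d.composition.counts["CD4Treg_Ki67neg"] / n_lymph if n_lymph else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise(frame: pd.DataFrame, level: str, caveat: str = "") -> list[CorrelationResult]:
    results = []
    for a, b in itertools.combinations(SUBSETS, 2):
        res = spearman(
            frame[f"ki67_frac_{a}"],
            frame[f"ki67_frac_{b}"],
            x_name=f"ki67_frac_{a}",
            y_name=f"ki67_frac_{b}",
            level=level,
        )
        res.caveat = caveat
        results.append(res)
    return results


def ki67_correlation_suite(
    domains: list[TLSDomain] | None = None,
    summaries: list[SectionSummary] | None = None,
    level: str = "domain",
    min_cells: int = 50,
) -> list[CorrelationResult]:
    """All pairwise Ki-67 correlations among the four subsets.

    ``level="domain"``: one point per (filtered) domain.
    ``level="section"``: one point per section, fractions taken on the
    pooled composition.
    """
    if level == "domain":
        if domains is None:
            raise ValueError("domain-level suite needs domains")
        kept = filter_domains_for_correlation(domains, min_cells)
        frame = pd.DataFrame(
            {
                f"ki67_frac_{s}": [ki67_fraction(d.composition, s) for d in kept]
                for s in SUBSETS
            }
        )
        return _pairwise(frame, level, caveat=CLUSTERING_CAVEAT)
    if level == "section":
        if summaries is None:
            raise ValueError("section-level suite needs summaries")
        frame = pd.DataFrame(
            {
                f"ki67_frac_{s}": [ki67_fraction(sm.pooled, s) for sm in summaries]
                for s in SUBSETS
            }
        )
        return _pairwise(frame, level)
    raise ValueError(f"unknown level {level!r}")


def treg_presence_analysis(
    domains: list[TLSDomain], min_cells: int = 50
) -> list[CorrelationResult]:
    """Non-proliferating Foxp3+ CD4 presence vs other subsets' Ki-67.

    x = (Ki-67− CD4Treg count) / n_lymph per filtered domain; y = the
    Ki-67+ fraction of B, CD4Tconv and CD8T.  Returns three results.
    """
    kept = filter_domains_for_correlation(domains, min_cells)
    table = domain_ki67_table(kept)
    results = []
    for subset in ("B", "CD4Tconv", "CD8T"):
        res = spearman(
            table["treg_ki67neg_presence"] if len(table) else [],
            table[f"ki67_frac_{subset}"] if len(table) else [],
            x_name="treg_ki67neg_presence",
            y_name=f"ki67_frac_{subset}",
            level="domain",
        )
        res.caveat = CLUSTERING_CAVEAT
        results.append(res)
    return results


def _patient_measures(summaries: list[SectionSummary], method: str) -> dict[str, float]:
    by_patient: dict[str, list[SectionSummary]] = {}
    for s in summaries:
        by_patient.setdefault(s.patient_id, []).append(s)
    measures: dict[str, float] = {}
    for pid, secs in by_patient.items():
        if method == "per_domain_mean":
            # weight each section's mean by its domain count => mean over
            # all of the patient's domains, one vote per domain
            num = 0.0
            den = 0
            for s in secs:
                v = s.mean_per_domain_ki67.get("B", float("nan"))
                if s.n_domains and not math.isnan(v):
                    num += v * s.n_domains
                    den += s.n_domains
            measures[pid] = num / den if den else float("nan")
        elif method == "pooled":
            pooled = secs[0].pooled
            for s in secs[1:]:
                pooled = pooled + s.pooled
            measures[pid] = ki67_fraction(pooled, "B")
        else:
            raise ValueError(f"unknown ranking method {method!r}")
    return measures


def rank_patients(summaries: list[SectionSummary], method: str = "per_domain_mean") -> RankingResult:
    """Rank patients by B-cell Ki-67+ measure, descending; ties by id.

    Patients whose measure is undefined (no B cells in any domain) sort
    last, in id order.
    """
    measures = _patient_measures(summaries, method)
    ordered = sorted(
        measures,
        key=lambda pid: (
            math.isnan(measures[pid]),
            -(measures[pid] if not math.isnan(measures[pid]) else 0.0),
            pid,
        ),
    )
    return RankingResult(method, ordered, measures)


def compare_rankings(a: RankingResult, b: RankingResult, k: int = 8) -> dict:
    """Concordance between two rankings of the same patients.

    Reports Spearman rho on rank positions, the Spearman footrule (sum of
    absolute rank displacements), and the size of the top-``k`` overlap.
    """
    if set(a.patient_ids) != set(b.patient_ids):
        diff = sorted(set(a.patient_ids) ^ set(b.patient_ids))
        raise ValueError(f"rankings cover different patients: {diff}")
    n = len(a.patient_ids)
    rank_a = {pid: i for i, pid in enumerate(a.patient_ids)}
    rank_b = {pid: i for i, pid in enumerate(b.patient_ids)}
    pids = sorted(rank_a)
    ra = np.array([rank_a[p] for p in pids], dtype=float)
    rb = np.array([rank_b[p] for p in pids], dtype=float)
    res = spearman(ra, rb, "rank_a", "rank_b", level="ranking")
    footrule = int(np.abs(ra - rb).sum())
    k_eff = min(k, n)
    overlap = len(set(a.patient_ids[:k_eff]) & set(b.patient_ids[:k_eff]))
    return {
        "n_patients": n,
        "rank_rho": res.rho,
        "rank_rho_p": res.p_value,
        "footrule": footrule,
        "top_k": k_eff,
        "top_k_overlap": overlap,
        "method_a": a.method,
        "method_b": b.method,
    }


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabulate correlation results for output."""
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "x": r.x_variable,
                "y": r.y_variable,
                "n": r.n_points,
                "rho": r.rho,
                "p_value": r.p_value,
                "insufficient": r.insufficient,
                "caveat": r.caveat,
            }
            for r in results
        ],
        columns=["level", "x", "y", "n", "rho", "p_value", "insufficient", "caveat"],
    )


def ranking_table(rankings: list[RankingResult]) -> pd.DataFrame:
    """Tabulate rankings (one row per method × patient)."""
    rows = []
    for r in rankings:
        for pos, pid in enumerate(r.patient_ids, start=1):
            rows.append(
                {
                    "method": r.method,
                    "rank": pos,
                    "patient_id": pid,
                    "b_ki67_measure": r.measure[pid],
                }
            )
    return pd.DataFrame(rows, columns=["method", "rank", "patient_id", "b_ki67_measure"])
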