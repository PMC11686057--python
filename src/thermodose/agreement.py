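"""Agreement and descriptive statistics for paired lesion volumes.

Computes the method-comparison statistics between the
thermometry-predicted lethal volume and the day-1 ablation-zone volume:
Pearson correlation with a Fisher-z confidence interval, Bland-Altman
limits of agreement, an independent-samples comparison of subgroup
correlations, a two-sided Fisher exact test for 2x2 artifact tables,
and ordinal grade summaries.

Printed renderings follow the convention of the clinical report this
mirrors: decimals are truncated, not rounded (85.185 % renders as
"85.1"), and grade spreads use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError

Z975 = stats.norm.ppf(0.975)

COHORT_COLUMNS = [
    "lesion_id",
    "predicted_volume_mm3",
    "ablation_volume_mm3",
    "quality_grade",
    "movement_grade",
    "shape_grade",
    "cirrhosis",
    "lobe",
    "respiratory_triggered",
    "excluded",
    "exclusion_reason",
]


def truncate(x: float, decimals: int = 1) -> float:
    """Truncate (not round) toward zero at the given decimal place."""
    f = 10.0**decimals
    return math.trunc(round(x * f, 9)) / f


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

@dataclass
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    level: float = 0.95


def pearson_with_ci(x, y, level: float = 0.95) -> PearsonResult:
    """Sample Pearson r with Fisher-z CI and two-sided t-based p.

    CI: tanh(atanh(r) +- z_{(1+level)/2} / sqrt(n - 3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be paired 1D arrays")
    n = x.size
    if n < 3:
        raise UsageError("Pearson correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise UsageError("volumes must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UsageError("correlation undefined: zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) < 1.0 and n > 3:
        h = stats.norm.ppf((1 + level) / 2) / math.sqrt(n - 3)
        lo, hi = math.tanh(math.atanh(r) - h), math.tanh(math.atanh(r) + h)
    else:
        lo = hi = r
    return PearsonResult(r, lo, hi, float(p), n, level)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    k: float
    n: int


def bland_altman(x, y, k: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements (d = x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be paired 1D arrays")
    if x.size < 2:
        raise UsageError("Bland-Altman requires n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - k * sd, mean + k * sd, k, x.size)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Independent-samples Fisher-z test of two correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal p.  Lesion-level clustering within patients is ignored.
    """
    if n1 < 4 or n2 < 4:
        raise UsageError("comparing correlations requires n >= 4 per group")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise UsageError("|r| = 1 makes the Fisher transform infinite")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, the two-sided p is the total probability of all
    tables whose hypergeometric probability does not exceed that of the
    observed table (the "probability <= observed" rule).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise UsageError("table must be 2x2")
    if np.any(t < 0):
        raise UsageError("table cells must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


@dataclass
class GradeSummary:
    n: int
    mean: float
    sd: float
    counts: dict[int, int]
    percentages: dict[int, float]
    printed: dict[str, object]


def summarize_grades(counts: Mapping[int, int]) -> GradeSummary:
    """Weighted mean, sample SD and per-grade percentages from grade counts."""
    counts = {int(g): int(c) for g, c in counts.items()}
    if any(c < 0 for c in counts.values()):
        raise UsageError("grade counts must be nonnegative")
    n = sum(counts.values())
    if n < 1:
        raise UsageError("at least one graded lesion required")
    grades = np.array(sorted(counts))
    cs = np.array([counts[g] for g in grades], dtype=float)
    mean = float((grades * cs).sum() / n)
    ss = float((cs * (grades - mean) ** 2).sum())
    sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    pct = {int(g): 100.0 * counts[g] / n for g in grades}
    printed = {
        "mean": truncate(mean, 2),
        "sd": truncate(sd, 2),
        "percentages": {int(g): truncate(v, 1) for g, v in pct.items()},
    }
    return GradeSummary(n, mean, sd, counts, pct, printed)


# ---------------------------------------------------------------------------
# Cohort table and full report
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-lesion paired volumes, ordinal grades and subgroup flags."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise UsageError(f"cohort table missing columns: {missing}")
        analyzed = self.analyzed
        for col in ("quality_grade", "movement_grade", "shape_grade"):
            g = analyzed[col].to_numpy()
            if len(g) and (np.any(g < 1) or np.any(g > 5) or np.any(g != np.round(g))):
                raise UsageError(f"{col} must contain integers in 1-5")
        v = analyzed[["predicted_volume_mm3", "ablation_volume_mm3"]].to_numpy()
        if len(v) and np.any(~(v > 0)):
            raise UsageError("analyzed lesions must have positive volumes")
        excl = self.data[self.data["excluded"].astype(bool)]
        if len(excl) and excl["exclusion_reason"].isna().any():
            raise UsageError("excluded lesions must carry an exclusion reason")

    @property
    def analyzed(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"].astype(bool)]

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


def _median_iqr(v: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}


@dataclass
class AgreementReport:
    pearson: PearsonResult | None
    bland_altman: BlandAltmanResult | None
    predicted_volume: dict | None
    ablation_volume: dict | None
    subgroup_cirrhosis: dict | None
    grade_summaries: dict
    exclusions: dict
    n_analyzed: int
    gaps: dict[str, str]

    def to_dict(self) -> dict:
        def conv(v):
            if hasattr(v, "__dataclass_fields__"):
                return asdict(v)
            return v

        return {k: conv(v) for k, v in asdict(self).items()}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float, **kw)

    def to_text(self) -> str:
        lines = [f"Analyzed lesions: {self.n_analyzed}"]
        if self.pearson:
            p = self.pearson
            lines.append(
                f"Pearson r = {p.r:.3f} (95% CI {p.ci_low:.3f}-{p.ci_high:.3f}), "
                f"p = {p.p:.2g}, n = {p.n}"
            )
        if self.bland_altman:
            b = self.bland_altman
            lines.append(
                f"Bland-Altman: mean diff {b.mean_diff:.0f} mm3, SD {b.sd_diff:.0f}, "
                f"LoA ({b.loa_low:.0f}, {b.loa_high:.0f})"
            )
        for name, s in self.grade_summaries.items():
            lines.append(
                f"{name}: mean {s['printed']['mean']} +- {s['printed']['sd']} (n={s['n']})"
            )
        ex = self.exclusions
        lines.append(
            f"Excluded: {ex['n_excluded']}/{ex['n_total']} ({ex['printed_pct']}%)"
        )
        for k, v in self.gaps.items():
            lines.append(f"[gap] {k}: {v}")
        return "\n".join(lines)


def cohort_report(cohort: CohortTable, level: float = 0.95) -> AgreementReport:
    """All agreement and descriptive statistics for a cohort.

    Per-statistic failures (too few lesions, zero variance, missing
    subgroups) are recorded as named gaps rather than aborting the
    report.  Excluded lesions contribute only to the exclusion summary.
    """
    gaps: dict[str, str] = {}
    an = cohort.analyzed
    x = an["predicted_volume_mm3"].to_numpy(dtype=float)
    y = an["ablation_volume_mm3"].to_numpy(dtype=float)

    pearson = ba = pred = abl = None
    try:
        if len(x) < 3:
            raise UsageError("insufficient n for correlation (need >= 3 analyzed lesions)")
        pearson = pearson_with_ci(x, y, level)
    except UsageError as e:
        gaps["pearson"] = str(e)
    try:
        ba = bland_altman(x, y)
    except UsageError as e:
        gaps["bland_altman"] = str(e)
    if len(x):
        pred = _median_iqr(x)
        abl = _median_iqr(y)
    else:
        gaps["volumes"] = "no analyzed lesions"

    subgroup = None
    try:
        flags = an["cirrhosis"].astype(bool).to_numpy()
        g1, g2 = np.flatnonzero(flags), np.flatnonzero(~flags)
        if len(g1) < 4 or len(g2) < 4:
            raise UsageError("subgroups need >= 4 lesions each")
        p1 = pearson_with_ci(x[g1], y[g1], level)
        p2 = pearson_with_ci(x[g2], y[g2], level)
        z, p = compare_correlations(p1.r, p1.n, p2.r, p2.n)
        subgroup = {
            "r_cirrhosis": p1.r, "n_cirrhosis": p1.n,
            "r_no_cirrhosis": p2.r, "n_no_cirrhosis": p2.n,
            "z": z, "p": p,
        }
    except UsageError as e:
        gaps["subgroup_cirrhosis"] = str(e)

    summaries = {}
    for name, col in [
        ("thermometry_quality", "quality_grade"),
        ("movement_artifacts", "movement_grade"),
        ("shape_match", "shape_grade"),
    ]:
        try:
            counts = an[col].value_counts().to_dict()
            summaries[name] = asdict(summarize_grades(counts))
        except UsageError as e:
            gaps[name] = str(e)

    n_total = len(cohort.data)
    n_exc = int(cohort.data["excluded"].astype(bool).sum())
    pct = 100.0 * n_exc / n_total if n_total else 0.0
    reasons = (
        cohort.data.loc[cohort.data["excluded"].astype(bool), "exclusion_reason"]
        .value_counts().to_dict()
    )
    exclusions = {
        "n_excluded": n_exc, "n_total": n_total,
        "pct": pct, "printed_pct": truncate(pct, 1),
        "reasons": {str(k): int(v) for k, v in reasons.items()},
    }
    return AgreementReport(
        pearson=pearson, bland_altman=ba,
        predicted_volume=pred, ablation_volume=abl,
        subgroup_cirrhosis=subgroup, grade_summaries=summaries,
        exclusions=exclusions, n_analyzed=len(an), gaps=gaps,
    )
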