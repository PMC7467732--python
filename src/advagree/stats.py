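"""Inferential layer: t-tests with Cohen's d, repeated-measures ANOVA with
partial eta-squared, minimal-detectable-effect computation, and report assembly.

Conventions: all tests are two-tailed at alpha = .05 unless stated otherwise;
the two-sample test pools variances by default (Welch available), matching the
degrees of freedom convention t(n1 + n2 - 2) of the analyses this layer
reproduces. The two-way repeated-measures ANOVA (both factors within) is
delegated to pingouin; with 2-level factors no sphericity correction applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AnovaResult",
    "one_sample_test",
    "one_sample_test_from_stats",
    "two_sample_test",
    "two_sample_test_from_stats",
    "rm_anova",
    "detectable_effect",
    "summarize",
]


@dataclass(frozen=True)
class TestResult:
    """A t-test outcome: statistic, dof, two-tailed p, Cohen's d."""

    statistic: float
    dof: float
    p_value: float
    effect_size: float
    kind: str = "t"


@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA effect: F, dofs, p, partial eta-squared."""

    effect: str
    statistic: float
    dof_num: int
    dof_den: int
    p_value: float
    effect_size: float  # partial eta squared


def one_sample_test_from_stats(mean: float, sd: float, n: int, mu0: float) -> TestResult:
    """One-sample t-test computed from summary statistics.

    t = (mean - mu0) / (sd / sqrt(n)) with dof n - 1; d = (mean - mu0) / sd.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not sd > 0:
        raise ValueError("zero variance: one-sample t-test undefined")
    t = (mean - mu0) / (sd / np.sqrt(n))
    dof = n - 1
    p = 2.0 * sps.t.sf(abs(t), dof)
    return TestResult(float(t), float(dof), float(p), float((mean - mu0) / sd), "one-sample t")


def one_sample_test(values, mu0: float) -> TestResult:
    """Two-tailed one-sample t-test of ``values`` against ``mu0`` with Cohen's d."""
    x = np.asarray(values, dtype=float)
    return one_sample_test_from_stats(x.mean(), x.std(ddof=1), len(x), mu0)


def two_sample_test_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    pooled: bool = True,
) -> TestResult:
    """Independent two-sample t-test from summary statistics (pooled or Welch).

    Pooled: t with dof n_a + n_b - 2 and d = mean difference / pooled SD.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = sd_a**2, sd_b**2
    diff = mean_a - mean_b
    if pooled:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        if not sp2 > 0:
            raise ValueError("zero pooled variance: t-test undefined")
        se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        dof = n_a + n_b - 2
        d = diff / np.sqrt(sp2)
    else:
        se = np.sqrt(va / n_a + vb / n_b)
        if not se > 0:
            raise ValueError("zero variance: t-test undefined")
        dof = se**4 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
        d = diff / np.sqrt((va + vb) / 2)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), dof)
    kind = "two-sample t (pooled)" if pooled else "two-sample t (Welch)"
    return TestResult(float(t), float(dof), float(p), float(d), kind)


def two_sample_test(a, b, pooled: bool = True) -> TestResult:
    """Two-tailed independent two-sample t-test with Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return two_sample_test_from_stats(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), pooled=pooled
    )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list,
) -> list[AnovaResult]:
    """Two-way repeated-measures ANOVA (both factors within-participant).

    ``data`` is long format with one aggregated value per participant x cell.
    Requires a complete crossing for every participant (no imputation); returns
    an :class:`AnovaResult` per main effect and the interaction, with partial
    eta-squared = SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    if len(within) != 2:
        raise ValueError("expected exactly 2 within-participant factors")
    cells = data.groupby([subject] + list(within), observed=True).size()
    n_cells = int(np.prod([data[f].nunique() for f in within]))
    per_subject = cells.groupby(level=0).size()
    if (per_subject != n_cells).any() or (cells != 1).any():
        raise ValueError("incomplete or duplicated participant x condition cells")
    res = pg.rm_anova(
        data=data, dv=dv, within=list(within), subject=subject, detailed=True, effsize="np2"
    )
    out = []
    for _, row in res.iterrows():
        out.append(
            AnovaResult(
                effect=str(row["Source"]),
                statistic=float(row["F"]),
                dof_num=int(row["ddof1"]),
                dof_den=int(row["ddof2"]),
                p_value=float(row["p_unc"]),
                effect_size=float(row["np2"]),
            )
        )
    return out


def _power_two_tailed_t(d: float, n: int, alpha: float, design: str) -> float:
    """Power of a two-tailed t-test at effect size d (within: paired, n pairs;
    between: two groups of n each)."""
    if design == "within":
        dof = n - 1
        ncp = d * np.sqrt(n)
    elif design == "between":
        dof = 2 * n - 2
        ncp = d * np.sqrt(n / 2.0)
    else:
        raise ValueError("design must be 'within' or 'between'")
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    power = sps.nct.sf(tcrit, dof, ncp) + sps.nct.cdf(-tcrit, dof, ncp)
    if np.isnan(power):  # scipy's nct loses accuracy at large ncp; there power ~ 1
        power = sps.norm.sf(tcrit - ncp) + sps.norm.cdf(-tcrit - ncp)
    return float(power)


def detectable_effect(
    n: int, alpha: float = 0.05, power: float = 0.8, design: str = "within"
) -> float:
    """Smallest Cohen's d detectable at the given n, alpha and power.

    Solves power(d) = target on the noncentral t distribution of the two-tailed
    test: paired/within (dof n-1, ncp d*sqrt(n)) or between-subjects with n per
    group (dof 2n-2, ncp d*sqrt(n/2)).
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    if _power_two_tailed_t(10.0, n, alpha, design) < power:
        raise ValueError("requested power unreachable at this n")
    from scipy.optimize import brentq

    return float(brentq(lambda d: _power_two_tailed_t(d, n, alpha, design) - power, 0.0, 10.0))


# ---------------------------------------------------------------------------
# report assembly


def summarize(
    experiments: dict,
    *,
    extra: dict | None = None,
) -> dict:
    """Assemble a report document from fitted agreement results.

    ``experiments`` maps an experiment id to an
    :class:`~advagree.agreement.AgreementResults` (or an equivalent dict).
    The report carries a Table-1-style row per experiment (mean agreement, mean
    agreeing-image count, chance), the counting metric with its blindfolded
    expectation, and the per-image appendix records; it round-trips through
    JSON losslessly.
    """
    rows = []
    details = {}
    for exp_id, res in experiments.items():
        d = res if isinstance(res, dict) else res.to_dict()
        details[exp_id] = d
        rows.append(
            {
                "experiment": exp_id,
                "mean_agreement_pct": round(d["mean_agreement_pct"], 2),
                "mean_agreeing_images": round(d["mean_agreeing_images"], 2),
                "n_trials": d["n_trials"],
                "chance_pct": round(d["chance_pct"], 2),
                "counting_metric_pct": None
                if d["counting_metric_pct"] is None
                else round(d["counting_metric_pct"], 2),
            }
        )
    return {
        "table": rows,
        "experiments": details,
        "extra": extra or {},
    }


def save_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def load_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
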