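"""Gated two-sample testing and the longitudinal healthy-vs-DDD comparisons.

Test selection follows the study procedure: the Shapiro-Wilk test checks
normality of each sample and the Bartlett test checks homogeneity of
variance; if all three gates pass (p > 0.05), an unpaired two-sample Student
t-test (equal variances) is used, otherwise the two-sided Mann-Whitney U test
(exact null distribution for n <= 8 without ties, normal approximation with
tie correction otherwise). Significance is declared at p < alpha (0.05).

No multiple-testing correction is applied (raw p-values are reported together
with the number of contrasts), tests are unpaired, and no values are excluded
by default — :func:`exclude_aberrant` offers |z| > 3 and 1.5*IQR rules for
explicit use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "select_and_run_test",
    "exclude_aberrant",
    "longitudinal_analysis",
    "DEFAULT_CONTRASTS",
]

GATE_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "student_t" or "mann_whitney"
    p_value: float
    significant: bool
    shapiro_p: tuple[float, float]
    bartlett_p: float
    n: tuple[int, int]
    alpha: float = 0.05


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return np.nan  # constant sample: normality gate fails
    return float(sps.shapiro(x).pvalue)


def select_and_run_test(
    sample_a,
    sample_b,
    alpha: float = 0.05,
    force: str | None = None,
) -> ComparisonResult:
    """Run the gated two-sample comparison.

    ``force`` ("student_t" or "mann_whitney") bypasses the gates, e.g. to
    reproduce a known branch. Identical zero-variance samples fall through to
    the Mann-Whitney branch with p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must contain at least 3 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    sh_a, sh_b = _shapiro_p(a), _shapiro_p(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        bart = np.nan
    else:
        bart = float(sps.bartlett(a, b).pvalue)

    if force is None:
        gates_pass = (
            np.isfinite(sh_a) and sh_a > GATE_ALPHA
            and np.isfinite(sh_b) and sh_b > GATE_ALPHA
            and np.isfinite(bart) and bart > GATE_ALPHA
        )
        test = "student_t" if gates_pass else "mann_whitney"
    elif force in ("student_t", "mann_whitney"):
        test = force
    else:
        raise ValueError(f"unknown force value {force!r}")

    if test == "student_t":
        p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p = 1.0  # identical constant samples: no evidence of a shift
        else:
            ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)

    return ComparisonResult(
        test_used=test, p_value=p, significant=bool(p < alpha),
        shapiro_p=(sh_a, sh_b), bartlett_p=bart, n=(len(a), len(b)), alpha=alpha,
    )


def exclude_aberrant(values, rule: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Partition values into (kept, excluded) under an outlier rule.

    Rules: ``none`` (default — no exclusion criterion is assumed), ``z3``
    (jackknifed |z-score| > 3: each value is scored against the mean and SD
    of the *other* values, since the ordinary z-score of n samples is
    bounded by (n-1)/sqrt(n) and can never flag an outlier in a small
    group) and ``iqr`` (outside the quartiles +/- 1.5*IQR).
    """
    v = np.asarray(values, dtype=float)
    if rule == "none":
        keep = np.ones(v.shape, dtype=bool)
    elif rule == "z3":
        keep = np.ones(v.shape, dtype=bool)
        if len(v) >= 3:
            for i in range(len(v)):
                rest = np.delete(v, i)
                sd = np.std(rest, ddof=1)
                dev = abs(v[i] - rest.mean())
                keep[i] = dev <= 3 * sd if sd > 0 else dev == 0
    elif rule == "iqr":
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    else:
        raise ValueError(f"unknown rule {rule!r}; expected none, z3 or iqr")
    return v[keep], v[~keep]


#: Contrast templates: (name, fixed keys of group A, fixed keys of group B).
#: Timepoint contrasts run within each (maturity, state); state contrasts
#: within each maturity at W1/W2; maturity contrasts within each state and
#: timepoint.
DEFAULT_CONTRASTS = (
    ("D0_vs_W1", {"timepoint": "D0"}, {"timepoint": "W1"}, ("maturity", "state")),
    ("D0_vs_W2", {"timepoint": "D0"}, {"timepoint": "W2"}, ("maturity", "state")),
    ("W1_vs_W2", {"timepoint": "W1"}, {"timepoint": "W2"}, ("maturity", "state")),
    ("healthy_vs_ddd_W1", {"state": "healthy", "timepoint": "W1"},
     {"state": "ddd", "timepoint": "W1"}, ("maturity",)),
    ("healthy_vs_ddd_W2", {"state": "healthy", "timepoint": "W2"},
     {"state": "ddd", "timepoint": "W2"}, ("maturity",)),
    ("mature_vs_immature", {"maturity": "mature"}, {"maturity": "immature"},
     ("state", "timepoint")),
)


def _cell_values(table: pd.DataFrame, fixed: dict) -> np.ndarray:
    sel = np.ones(len(table), dtype=bool)
    for col, val in fixed.items():
        sel &= table[col] == val
    return table.loc[sel, "value"].to_numpy(dtype=float)


def longitudinal_analysis(
    quant_table: pd.DataFrame,
    alpha: float = 0.05,
    contrasts=DEFAULT_CONTRASTS,
    exclusion_rule: str = "none",
) -> pd.DataFrame:
    """Run every contrast for every quantifiable (structure, metric) cell.

    ``quant_table`` is the long per-replicate table from
    :func:`dvcqmri.quant.quantify_study`. Returns one row per contrast with
    the test used, the p-value, the gate p-values and the group means. A
    contrast whose cells are absent from the table raises ``ValueError``
    naming it; cells that simply do not exist for a stratum (e.g. a missing
    arm) are skipped.
    """
    results = []
    quant_table = quant_table[quant_table["quantifiable"]]
    groups = quant_table.groupby(["structure", "metric"], sort=False)
    for (structure, metric), sub in groups:
        for name, fa, fb, strata_cols in contrasts:
            strata = sub[list(strata_cols)].drop_duplicates().to_dict("records")
            for stratum in strata:
                va = _cell_values(sub, fa | stratum)
                vb = _cell_values(sub, fb | stratum)
                if len(va) == 0 or len(vb) == 0:
                    # the contrast is not part of this design
                    continue
                if len(va) < 3 or len(vb) < 3:
                    raise ValueError(
                        f"contrast {name} for {structure}/{metric} {stratum} "
                        f"has insufficient cells (n={len(va)}, {len(vb)})")
                va, _ = exclude_aberrant(va, exclusion_rule)
                vb, _ = exclude_aberrant(vb, exclusion_rule)
                res = select_and_run_test(va, vb, alpha=alpha)
                results.append({
                    "structure": structure, "metric": metric, "contrast": name,
                    **{f"stratum_{k}": v for k, v in stratum.items()},
                    "mean_a": float(np.mean(va)), "mean_b": float(np.mean(vb)),
                    "n_a": len(va), "n_b": len(vb),
                    "test_used": res.test_used, "p_value": res.p_value,
                    "significant": res.significant,
                    "shapiro_p_a": res.shapiro_p[0], "shapiro_p_b": res.shapiro_p[1],
                    "bartlett_p": res.bartlett_p,
                })
    out = pd.DataFrame(results)
    if len(out):
        out["n_contrasts"] = len(out)  # context for the uncorrected p-values
    return out
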