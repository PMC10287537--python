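"""Rank and linear correlation tests and the four-scenario classifier.

Kendall's tau is computed as tau-b (tie-corrected) with the
normal-approximation Z statistic built from the tie-adjusted variance of
the concordance score S — the convention of R's ``cor.test`` and of the
semipartial-correlation packages used in comparative transcriptomics.
The semipartial (part) correlation removes a control variable's
association from exactly one of the two variables of interest; here the
control is each gene copy's DNA abundance and it is removed from the
transcript-abundance side.
"""

from __future__ import annotations

import math
from typing import List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ClassificationResult,
    DegenerateInputError,
    InputError,
    TestResult,
)

DEFAULT_ALPHA = 0.05
#: Overcompensation ratio threshold on R = (focal RNA:DNA) / (reference
#: RNA:DNA). Chosen so a 3%->23% DNA->RNA shift (ratio ~7.7 against a
#: neutral reference) flags while a 21%->10% shift (ratio ~0.48) does not.
DEFAULT_THETA_OVER = 2.0


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if not np.isfinite(arr).all():
        raise InputError(f"{name} contains non-finite values")
    return arr


def _tau_b_parts(x: np.ndarray, y: np.ndarray):
    """Concordance score S, tau-b, and the tie-adjusted variance of S."""
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    s = float((dx * dy).sum()) / 2.0

    def tie_counts(v: np.ndarray) -> np.ndarray:
        _, c = np.unique(v, return_counts=True)
        return c[c > 1].astype(float)

    tx, ty = tie_counts(x), tie_counts(y)
    n0 = n * (n - 1) / 2.0
    n1 = float((tx * (tx - 1) / 2.0).sum())
    n2 = float((ty * (ty - 1) / 2.0).sum())
    if n1 >= n0 or n2 >= n0:
        raise DegenerateInputError("zero variance in a rank-test input")
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))

    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = float((ty * (ty - 1) * (2 * ty + 5)).sum())
    v1 = float((tx * (tx - 1)).sum()) * float((ty * (ty - 1)).sum()) / (
        2.0 * n * (n - 1)
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            float((tx * (tx - 1) * (tx - 2)).sum())
            * float((ty * (ty - 1) * (ty - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    return s, tau, var_s


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall's tau-b with normal-approximation Z and two-sided p."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise InputError("x and y differ in length")
    if len(xa) < 3:
        raise DegenerateInputError("need n >= 3 for a rank correlation")
    s, tau, var_s = _tau_b_parts(xa, ya)
    z = s / math.sqrt(var_s) if var_s > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(
        method="kendall", estimate=tau, statistic=z, p=float(p), n=len(xa)
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson's r with t = r sqrt(nu) / sqrt(1 - r^2), nu = n - 2."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise InputError("x and y differ in length")
    if len(xa) < 3:
        raise DegenerateInputError("need n >= 3 for a correlation test")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    r = float(stats.pearsonr(xa, ya).statistic)
    nu = len(xa) - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(nu) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df=nu))
    return TestResult(
        method="pearson", estimate=r, statistic=t, p=p, n=len(xa), df=nu
    )


def semipartial_estimate(t_xy: float, t_xz: float, t_yz: float) -> float:
    """Semipartial coefficient from the three pairwise taus.

    ``(t_xy - t_yz * t_xz) / sqrt(1 - t_xz^2)``: the control's association
    is removed from x only.
    """
    if abs(t_xz) >= 1.0 - 1e-12:
        raise DegenerateInputError(
            "control variable is perfectly rank-correlated with x"
        )
    return (t_xy - t_yz * t_xz) / math.sqrt(1.0 - t_xz * t_xz)


def semipartial_kendall(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> TestResult:
    """Semipartial Kendall correlation of x and y, removing z from x.

    ``sp = (tau_xy - tau_yz * tau_xz) / sqrt(1 - tau_xz^2)`` with all
    pairwise taus tie-corrected (tau-b); the Z statistic uses
    ``Z = sp * sqrt(9 (n-gn)(n-1-gn) / (2 (2(n-gn)+5)))`` with gn = 1
    controlled variable and a two-sided normal p-value.
    """
    xa, ya, za = _as_array(x, "x"), _as_array(y, "y"), _as_array(z, "z")
    if not (len(xa) == len(ya) == len(za)):
        raise InputError("x, y and z differ in length")
    n = len(xa)
    if n < 4:
        raise DegenerateInputError("need n >= 4 for a semipartial correlation")
    t_xy = kendall_tau(xa, ya).estimate
    t_xz = kendall_tau(xa, za).estimate
    t_yz = kendall_tau(ya, za).estimate
    sp = semipartial_estimate(t_xy, t_xz, t_yz)
    gn = 1
    z_stat = sp * math.sqrt(
        9.0 * (n - gn) * (n - 1 - gn) / (2.0 * (2.0 * (n - gn) + 5.0))
    )
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return TestResult(
        method="semipartial_kendall",
        estimate=sp,
        statistic=z_stat,
        p=p,
        n=n,
        gn=gn,
    )


# ---------------------------------------------------------------------------
# Aggregation and composite tests

def sum_homolog_tpm(
    expr: pd.DataFrame, system=None
) -> pd.Series:
    """Total TPM per homolog family: the sum over each family's copies.

    ``expr`` is the per-copy table from :func:`dosagecomp.quantify.tpm`.
    If a :class:`SymbiontSystem` is supplied, every copy must map to one of
    its families.
    """
    if expr["family_id"].isna().any():
        bad = expr.index[expr["family_id"].isna()][0]
        raise InputError(f"copy {bad!r} maps to no family")
    if system is not None:
        orphan = set(expr["family_id"]) - set(system.retention)
        if orphan:
            raise InputError(f"copies of unknown families {sorted(orphan)[:5]}")
    return expr.groupby("family_id")["tpm"].sum().rename("total_tpm").sort_index()


def _mean_over_replicates(
    values: Union[pd.Series, pd.DataFrame, Sequence]
) -> pd.Series:
    """Plain mean across replicate Series (or pass a single one through)."""
    if isinstance(values, pd.DataFrame):
        values = values["dosage"] if "dosage" in values else values.iloc[:, 0]
    if isinstance(values, pd.Series):
        return values.astype(float)
    reps = [
        (v["dosage"] if isinstance(v, pd.DataFrame) and "dosage" in v else v)
        for v in values
    ]
    reps = [pd.Series(v).astype(float) for v in reps]
    return pd.concat(reps, axis=1).mean(axis=1)


def dosage_expression_test(
    dosages, totals, replicates: Optional[Sequence] = None
) -> TestResult:
    """Kendall test of family relative dosage against summed family TPM.

    ``dosages`` and ``totals`` may each be a single family-indexed Series
    (or dosage DataFrame) or a sequence of biological replicates, which
    are averaged with a plain mean before the test. Alternatively
    ``replicates`` may carry ``(dosage, total_tpm)`` pairs, one per
    biological replicate. Only families present in both averaged tables
    enter.
    """
    if replicates is not None:
        dosages = [r[0] for r in replicates]
        totals = [r[1] for r in replicates]
    d = _mean_over_replicates(dosages)
    t = _mean_over_replicates(totals)
    shared = d.index.intersection(t.index)
    if len(shared) < 3:
        raise DegenerateInputError(
            f"only {len(shared)} families shared between dosage and TPM tables"
        )
    return kendall_tau(d[shared].to_numpy(), t[shared].to_numpy())


def cross_species_correlation(
    expr_a: pd.Series,
    expr_b: pd.Series,
    homolog_map: Optional[Mapping[str, str]] = None,
) -> TestResult:
    """Pearson correlation of homolog log10 TPM between two symbionts.

    ``homolog_map`` maps A's family ids to B's (identity by default).
    Families with zero TPM in either symbiont are excluded before the log
    transform; ``n`` reflects the surviving intersection.
    """
    if homolog_map is not None:
        expr_a = expr_a[expr_a.index.isin(homolog_map)].rename(
            index=dict(homolog_map)
        )
    shared = expr_a.index.intersection(expr_b.index)
    if not len(shared):
        raise InputError("no shared homolog families")
    a = expr_a[shared].astype(float)
    b = expr_b[shared].astype(float)
    keep = (a > 0) & (b > 0)
    if keep.sum() < 3:
        raise DegenerateInputError("fewer than 3 homologs with nonzero TPM")
    return pearson(np.log10(a[keep].to_numpy()), np.log10(b[keep].to_numpy()))


# ---------------------------------------------------------------------------
# Scenario classification

def classify_scenario(
    r_ratio: Union[float, Mapping[str, float]],
    total_test: TestResult,
    sp_test: TestResult,
    alpha: float = DEFAULT_ALPHA,
    theta_over: float = DEFAULT_THETA_OVER,
) -> ClassificationResult:
    """Call the transcriptional-response scenario from the evidence triple.

    Rules, in order: (1) R >= theta_over -> overcompensation; (2) a
    significantly negative semipartial correlation -> complementation;
    (3) no semipartial signal but a significantly positive total
    dosage-expression correlation -> subdivision; (4) otherwise
    disruption/indeterminate. A significantly *positive* semipartial is
    annotated rather than classified (lineage-specific losses biased
    toward lowly expressed genes produce it without any compensation).
    """
    if isinstance(r_ratio, Mapping):
        r_ratio = float(r_ratio["R"])
    annotations: List[str] = []
    if sp_test.p < alpha and sp_test.estimate > 0:
        annotations.append("positive_semipartial")
    if r_ratio >= theta_over:
        label = "overcompensation"
    elif sp_test.p < alpha and sp_test.estimate < 0:
        label = "complementation"
    elif sp_test.p >= alpha and total_test.p < alpha and total_test.estimate > 0:
        label = "subdivision"
    else:
        label = "disruption/indeterminate"
    return ClassificationResult(
        label=label,
        r_ratio=float(r_ratio),
        total_test=total_test,
        sp_test=sp_test,
        alpha=alpha,
        theta_over=theta_over,
        annotations=annotations,
    )
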