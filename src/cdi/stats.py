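"""Validation statistics: ICC(3,1), SRM, Spearman, ordinal trend test.

* ``icc_3_1`` — Shrout-Fleiss two-way mixed, single-measure, consistency
  intraclass correlation from the subjects x measurements ANOVA decomposition
  (the intra-rater reliability model).
* ``srm`` — standardized response mean, mean change / SD of change; negative
  values indicate decline.
* ``spearman_rho`` — rank correlation with tie-averaged ranks and a
  t-approximation p-value (exact permutation available for tiny n).
* ``trend_test`` — Jonckheere-Terpstra test for an ordered alternative across
  ordinal grade groups, with a seeded permutation p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateRatingsError(ValueError):
    """Ratings carry no variance: ICC undefined."""


def icc_3_1(ratings: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, single measure, consistency.

    ``ratings`` is an (n_subjects, k_measurements) matrix with no missing
    cells. Computed as (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)
    where MS_error comes from the residual after removing subject and
    measurement (column) effects; a fixed column offset therefore does not
    lower the coefficient.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D (subjects x measurements) matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 measurements")
    if np.isnan(x).any():
        raise ValueError("ratings must have no missing cells")
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise DegenerateRatingsError("degenerate ratings")
    subj_means = x.mean(axis=1)
    meas_means = x.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    resid = x - subj_means[:, None] - meas_means[None, :] + grand
    ss_err = (resid**2).sum()
    if ss_err < 1e-12 * ss_total:  # numerically perfect consistency
        ss_err = 0.0
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_subj + (k - 1) * ms_err
    if denom == 0:
        raise DegenerateRatingsError("degenerate ratings")
    return float((ms_subj - ms_err) / denom)


def srm(changes: Sequence[float]) -> float:
    """Standardized response mean of per-knee change scores (sign preserved)."""
    c = np.asarray(changes, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 change scores")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("no variance in change")
    return float(c.mean() / sd)


def spearman_rho(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks.

    ``method='t'`` uses the t-approximation with n-2 df (appropriate at the
    cohort sizes used here); ``method='exact'`` runs a full permutation test,
    intended for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    if method == "t":
        res = sps.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        # full enumeration of pairings; intended for n <= 10
        from itertools import permutations

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)

        def rank_corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))

        rho = rank_corr(rx, ry)
        perms = np.array(list(permutations(ry)))
        a = rx - rx.mean()
        b = perms - perms.mean(axis=1, keepdims=True)
        rhos = (b @ a) / np.sqrt((a @ a) * (b * b).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    raise ValueError(f"unknown method {method!r}")


def _jt_statistic(values: np.ndarray, w_upper: np.ndarray) -> float:
    """JT = sum over ordered group pairs of Mann-Whitney counts (ties = 1/2)."""
    gt = values[None, :] > values[:, None]
    eq = values[None, :] == values[:, None]
    return float(((gt + 0.5 * eq) * w_upper).sum())


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    direction: str  # "increasing" | "decreasing" | "none"
    n_permutations: int
    seed: int | None


def trend_test(
    groups: Sequence[Sequence[float]],
    n_permutations: int = 10000,
    seed: int | None = 0,
    mode: str = "permutation",
) -> TrendTestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    ``groups`` must be ordered by increasing grade. The two-sided p-value
    comes from a seeded label permutation (default) or from the normal
    approximation with tie correction (``mode='asymptotic'``). ``direction``
    reports the side of the observed statistic relative to its null mean.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    values = np.concatenate(groups)
    labels = np.repeat(np.arange(len(groups)), sizes)
    w_upper = (labels[None, :] > labels[:, None]).astype(float)
    jt_obs = _jt_statistic(values, w_upper)
    jt_mean = (n * n - (sizes**2).sum()) / 4.0
    if jt_obs > jt_mean:
        direction = "increasing"
    elif jt_obs < jt_mean:
        direction = "decreasing"
    else:
        direction = "none"

    if mode == "asymptotic":
        # tie-corrected null variance (standard JT large-sample form)
        _, counts = np.unique(values, return_counts=True)
        t3 = (counts**3 - counts).sum()
        var = (
            n * (n - 1) * (2 * n + 5)
            - ((sizes * (sizes - 1) * (2 * sizes + 5)).sum())
        ) / 72.0
        var -= t3 * ((sizes * (sizes - 1)).sum()) / (36.0 * n * (n - 1))
        var = max(var, 1e-12)
        z = (jt_obs - jt_mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        return TrendTestResult(jt_obs, min(p, 1.0), direction, 0, seed)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    dev_obs = abs(jt_obs - jt_mean)
    n_extreme = 0
    chunk = max(1, int(2_000_000 // (n * n)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm_vals = np.empty((m, n))
        for i in range(m):
            perm_vals[i] = values[rng.permutation(n)]
        gt = perm_vals[:, None, :] > perm_vals[:, :, None]
        eq = perm_vals[:, None, :] == perm_vals[:, :, None]
        jt_perm = ((gt + 0.5 * eq) * w_upper[None]).sum(axis=(1, 2))
        n_extreme += int(np.count_nonzero(np.abs(jt_perm - jt_mean) >= dev_obs - 1e-9))
        done += m
    p = (1 + n_extreme) / (1 + n_permutations)
    return TrendTestResult(jt_obs, float(min(p, 1.0)), direction, n_permutations, seed)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

CDI_COLUMNS = ("femur_cdi", "tibia_cdi", "total_cdi")


@dataclass
class ValidationReport:
    """All validation statistics of one measured cohort, serializable."""

    icc: dict[str, float]
    srm: dict[str, float]
    spearman: dict[str, dict[str, tuple[float, float]]]  # cdi -> covariate -> (rho, p)
    trend_p: dict[str, dict[str, float]]  # grade variable -> cdi -> p
    per_grade_means: pd.DataFrame
    rank_pairs: pd.DataFrame
    n_permutations: int = 10000
    seed: int | None = 0
    extra: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "icc": self.icc,
            "srm": self.srm,
            "spearman": {
                c: {k: list(v) for k, v in d.items()} for c, d in self.spearman.items()
            },
            "trend_p": self.trend_p,
            "per_grade_means": self.per_grade_means.to_dict(orient="list"),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def build_validation_report(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    reliability: dict[str, np.ndarray],
    covariates: Sequence[str] = ("jsw_mm", "hka_deg"),
    grade_vars: Sequence[str] = ("jsn", "kl"),
    n_permutations: int = 10000,
    seed: int | None = 0,
) -> ValidationReport:
    """Assemble the full validation report of a measured cohort.

    ``baseline``/``followup`` carry one row per knee with CDI values and
    covariates (columns femur_cdi, tibia_cdi, total_cdi, jsn, kl, plus the
    requested covariates), aligned on ``knee_id``. ``reliability`` maps each
    CDI column to an (n, 2) ratings matrix of repeated measurements.
    """
    b = baseline.set_index("knee_id").sort_index()
    f = followup.set_index("knee_id").sort_index()
    common = b.index.intersection(f.index)
    b, f = b.loc[common], f.loc[common]

    icc = {c: icc_3_1(reliability[c]) for c in CDI_COLUMNS if c in reliability}
    srm_values = {c: srm((f[c] - b[c]).to_numpy()) for c in CDI_COLUMNS}
    spearman: dict[str, dict[str, tuple[float, float]]] = {}
    for c in CDI_COLUMNS:
        spearman[c] = {}
        for cov in covariates:
            if cov in b.columns:
                spearman[c][cov] = spearman_rho(b[c].to_numpy(), b[cov].to_numpy())
    trend_p: dict[str, dict[str, float]] = {}
    for gv in grade_vars:
        if gv not in b.columns:
            continue
        trend_p[gv] = {}
        for c in CDI_COLUMNS:
            levels = sorted(b[gv].unique())
            groups = [b.loc[b[gv] == lev, c].to_numpy() for lev in levels]
            groups = [g for g in groups if g.size >= 2]
            if len(groups) < 3:
                trend_p[gv][c] = float("nan")
                continue
            res = trend_test(groups, n_permutations=n_permutations, seed=seed)
            trend_p[gv][c] = res.p_value
    per_grade = (
        b.groupby("jsn")[list(CDI_COLUMNS)].mean().reset_index()
        if "jsn" in b.columns
        else pd.DataFrame()
    )
    rank_cols = [c for c in (*CDI_COLUMNS, *covariates) if c in b.columns]
    rank_pairs = b[rank_cols].rank(method="average").reset_index()
    return ValidationReport(
        icc=icc,
        srm=srm_values,
        spearman=spearman,
        trend_p=trend_p,
        per_grade_means=per_grade,
        rank_pairs=rank_pairs,
        n_permutations=n_permutations,
        seed=seed,
    )
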