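"""Time-resolved association analysis (r-charts), FDR control and group contrasts.

The central object is the *r-chart*: for each of the 48 clock-aligned 30-min
bins, the Pearson correlation across participants between a scalar outcome
(BMI, leptin, cortisol...) and the participants' mean light exposure in that
bin (log10-floored blue irradiance by default).  The 48 per-bin p-values are
corrected with Benjamini–Hochberg FDR (q = 0.1 by default), and the time
course r(t) is itself summarised by a cosinor fit whose acrophase locates the
clock time of strongest association.

Also here: the group 95%-CI window detector (maximal wrap-around run of bins
where two groups' confidence intervals are disjoint, used to delimit the
evening exposure window separating BMI groups), the Fisher z test comparing
correlation strength between independent groups, per-stratum r-charts, and a
thin covariate-adjusted association wrapper around OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateError, InsufficientDataError, ParameterError
from .io import N_BINS, DailyProfile
from .rhythmometry import CosinorFit, cosinor_from_arrays

MIN_N_PER_BIN = 4


def _profile_matrix(profiles) -> np.ndarray:
    """Stack per-participant profiles into an (n, 48) matrix (NaN = missing)."""
    rows = []
    for p in profiles:
        if isinstance(p, DailyProfile):
            vals = p.values.copy()
            vals[p.n_contrib == 0] = np.nan
            rows.append(vals)
        else:
            rows.append(np.asarray(p, dtype=float))
    mat = np.vstack(rows) if rows else np.empty((0, N_BINS))
    if mat.shape[1] != N_BINS:
        raise ParameterError(f"profiles must have {N_BINS} bins")
    return mat


def bh_fdr(p_values, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class RChart:
    """48-bin correlation profile with FDR flags and a cosinor fit to r(t)."""

    bins: pd.DataFrame  # columns: bin, mid_hour, r, p, n, evaluable, sig_raw, sig_fdr
    cosinor_of_r: CosinorFit | None
    q: float
    outcome: str = ""
    method: str = "pearson"


def compute_rchart(
    profiles,
    outcome,
    q: float = 0.1,
    method: str = "pearson",
    outcome_name: str = "",
) -> RChart:
    """Per-bin correlation of a scalar outcome with binned exposure.

    ``profiles`` is a sequence of :class:`DailyProfile` (or (n, 48) arrays);
    ``outcome`` one scalar per participant.  Bins with fewer than 4 complete
    pairs are flagged not evaluable.  BH-FDR is applied across the evaluable
    bins only, within this 48-bin family.
    """
    mat = _profile_matrix(profiles)
    y = np.asarray(outcome, dtype=float)
    if len(y) != mat.shape[0]:
        raise ParameterError("outcome length must match the number of profiles")
    y_ok = np.isfinite(y)
    if y_ok.sum() >= 2 and np.nanstd(y[y_ok]) == 0:
        raise DegenerateError("outcome is constant; correlations are undefined")

    mids = DailyProfile.bin_midpoints_hours()
    r = np.full(N_BINS, np.nan)
    p = np.full(N_BINS, np.nan)
    n = np.zeros(N_BINS, dtype=int)
    evaluable = np.zeros(N_BINS, dtype=bool)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown method {method!r}")
    for b in range(N_BINS):
        x = mat[:, b]
        ok = np.isfinite(x) & y_ok
        n[b] = int(ok.sum())
        if n[b] < MIN_N_PER_BIN:
            continue
        if np.std(x[ok]) == 0:
            continue  # constant exposure in this bin: not evaluable
        res = corr(x[ok], y[ok])
        r[b], p[b] = float(res[0]), float(res[1])
        evaluable[b] = np.isfinite(r[b])

    sig_raw = np.zeros(N_BINS, dtype=bool)
    sig_fdr = np.zeros(N_BINS, dtype=bool)
    if evaluable.any():
        sig_raw[evaluable] = p[evaluable] < 0.05
        sig_fdr[evaluable] = bh_fdr(p[evaluable], q)

    cos_fit = None
    if evaluable.sum() >= 4:
        cos_fit = cosinor_from_arrays(mids[evaluable], r[evaluable])
    bins = pd.DataFrame(
        {
            "bin": np.arange(N_BINS),
            "mid_hour": mids,
            "r": r,
            "p": p,
            "n": n,
            "evaluable": evaluable,
            "significant_raw": sig_raw,
            "significant_fdr": sig_fdr,
        }
    )
    return RChart(bins=bins, cosinor_of_r=cos_fit, q=q, outcome=outcome_name, method=method)


@dataclass
class CIWindow:
    """Maximal wrap-around run of bins with disjoint group 95% CIs."""

    start_bin: int | None
    end_bin: int | None  # inclusive, circular
    bins: list[int]
    threshold_curve: dict[int, float]  # bin → upper CI bound of the lower-mean group
    groups: tuple[str, str]
    level: float

    @property
    def empty(self) -> bool:
        return self.start_bin is None

    @property
    def start_hour(self) -> float | None:
        return None if self.empty else self.start_bin * 0.5

    @property
    def end_hour(self) -> float | None:
        """Clock hour at the end of the last window bin (exclusive bound)."""
        return None if self.empty else ((self.end_bin + 1) * 0.5) % 24.0


def _group_ci(mat: np.ndarray, level: float):
    """Per-bin mean and t-based CI for one group's profile matrix."""
    n = np.sum(np.isfinite(mat), axis=0)
    mean = np.full(N_BINS, np.nan)
    lo = np.full(N_BINS, np.nan)
    hi = np.full(N_BINS, np.nan)
    for b in range(N_BINS):
        x = mat[:, b]
        x = x[np.isfinite(x)]
        if len(x) < 2:
            continue
        m = x.mean()
        se = x.std(ddof=1) / np.sqrt(len(x))
        tcrit = stats.t.ppf(0.5 + level / 2.0, len(x) - 1)
        mean[b], lo[b], hi[b] = m, m - tcrit * se, m + tcrit * se
    return mean, lo, hi, n


def _circular_runs(flags: np.ndarray):
    """Maximal circular runs of True as (start, length) pairs."""
    n = len(flags)
    if flags.all():
        return [(0, n)]
    runs = []
    idx = np.flatnonzero(~flags)
    start = None
    ext = np.concatenate([flags, flags])
    i = (idx[0] + 1) % n  # start scanning right after a False
    seen = 0
    pos = idx[0] + 1
    while seen < n:
        if ext[pos]:
            if start is None:
                start = pos
        else:
            if start is not None:
                runs.append((start % n, pos - start))
                start = None
        pos += 1
        seen += 1
    if start is not None:
        runs.append((start % n, pos - start))
    return runs


def ci_window(
    profiles_a,
    profiles_b,
    level: float = 0.95,
    groups: tuple[str, str] = ("A", "B"),
) -> CIWindow:
    """Detect the maximal clock window of non-overlapping group CIs.

    Per bin, each group's mean exposure gets a t-based CI on its own variance
    (no pooling); a bin qualifies when the two intervals are disjoint.  The
    returned window is the longest contiguous circular run of qualifying
    bins; ties break to the earliest start in clock order beginning at 12:00,
    so evening windows crossing midnight stay contiguous.  The threshold
    curve is the upper CI bound of the lower-mean group inside the window.
    """
    if not 0 < level < 1:
        raise ParameterError("level must lie in (0, 1)")
    mat_a = _profile_matrix(profiles_a)
    mat_b = _profile_matrix(profiles_b)
    mean_a, lo_a, hi_a, n_a = _group_ci(mat_a, level)
    mean_b, lo_b, hi_b, n_b = _group_ci(mat_b, level)
    if np.all(n_a < 2) or np.all(n_b < 2):
        raise InsufficientDataError("each group needs ≥ 2 contributors in some bin")

    both = np.isfinite(lo_a) & np.isfinite(lo_b)
    disjoint = both & ((lo_a > hi_b) | (lo_b > hi_a))
    if not disjoint.any():
        return CIWindow(None, None, [], {}, groups, level)

    runs = _circular_runs(disjoint)
    # longest run; ties → earliest start scanning clockwise from 12:00 (bin 24)
    def tie_key(run):
        start, length = run
        return (-length, (start - 24) % N_BINS)

    start, length = min(runs, key=tie_key)
    start = int(start)
    bins = [int((start + k) % N_BINS) for k in range(int(length))]
    threshold = {}
    for b in bins:
        if mean_a[b] <= mean_b[b]:
            threshold[b] = float(hi_a[b])
        else:
            threshold[b] = float(hi_b[b])
    return CIWindow(
        start_bin=start,
        end_bin=bins[-1],
        bins=bins,
        threshold_curve=threshold,
        groups=groups,
        level=level,
    )


def compare_correlations(r1: float, n1: int, r2: float, n2: int):
    """Fisher z test for equality of two independent correlations.

    Returns ``(z, p_two_sided)`` with
    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise DegenerateError("|r| must be < 1 for the Fisher z transform")
        if n < 4:
            raise InsufficientDataError("each group needs n ≥ 4")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def stratified_rchart(
    profiles,
    outcome,
    strata,
    q: float = 0.1,
    method: str = "pearson",
) -> dict:
    """Per-stratum r-charts on an identical bin grid.

    Strata with fewer than 4 members map to ``None`` (not evaluable); the
    remaining strata are still returned.
    """
    mat = _profile_matrix(profiles)
    y = np.asarray(outcome, dtype=float)
    strata = np.asarray(strata)
    out = {}
    for label in pd.unique(strata):
        sel = strata == label
        if sel.sum() < MIN_N_PER_BIN:
            out[label] = None
            continue
        out[label] = compute_rchart(
            mat[sel], y[sel], q=q, method=method, outcome_name=str(label)
        )
    return out


def adjusted_association(outcome, predictor, covariates: pd.DataFrame):
    """Standardized OLS coefficient of ``predictor`` adjusted for covariates.

    Categorical covariates (sex, population) are dummy-coded; ``outcome`` and
    ``predictor`` are z-scored so the returned coefficient is standardized.
    This wraps routine regression to reproduce the adjusted-association
    columns of the cohort tables; it is not a novel method.

    Returns ``(beta_standardized, p_value)``.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cov = pd.get_dummies(pd.DataFrame(covariates), drop_first=True, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(cov.to_numpy()).all(axis=1)
    y, x, cov = y[ok], x[ok], cov.loc[ok]
    k = cov.shape[1]
    if len(y) < k + 3:
        raise InsufficientDataError("too few complete cases for the adjusted model")
    if np.std(y) == 0 or np.std(x) == 0:
        raise DegenerateError("constant outcome or predictor")
    yz = (y - y.mean()) / y.std(ddof=0)
    xz = (x - x.mean()) / x.std(ddof=0)
    X = np.column_stack([np.ones(len(y)), xz, cov.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateError("collinear design matrix (rank deficient)")
    fit = OLS(yz, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
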