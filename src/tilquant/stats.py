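"""Cohort-level statistics: paired nonparametric comparisons, rank
correlations, ROC-derived cutpoints, Kaplan-Meier estimation and log-rank
tests.

Conventions
-----------
* All tests are two-sided.
* Wilcoxon signed-rank drops zero differences (classic convention; Pratt
  zero-handling available) and uses the exact permutation null for up to 25
  non-zero pairs, otherwise a normal approximation with continuity and tie
  corrections.
* The Kaplan-Meier median is the smallest observed time at which the
  estimated survival falls to <= 0.5; if that never happens the median is
  "not reached" (``math.inf`` with ``median_reached=False``).
* The ROC-optimal cutpoint maximizes Youden's J = sensitivity +
  specificity - 1 over every midpoint between adjacent sorted unique
  values; ties are broken toward the more balanced split, then toward the
  smaller cutoff.  "Test-positive" means value >= cutoff and the outcome
  for sensitivity is the event flag (vital status at end of follow-up).
* Because optimizing the cutpoint inflates the log-rank type-I error,
  :func:`dichotomized_survival` can additionally report a
  permutation-calibrated p-value (feature labels permuted, the whole
  cutpoint + log-rank pipeline rerun).
* No multiple-testing correction is applied by default;
  :func:`bh_adjust` provides Benjamini-Hochberg on request.

Months are the survival unit; convert day-based follow-up with
``days / 30.44``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .model import InsufficientDataError, SurvivalRecord, ValidationError

DAYS_PER_MONTH = 30.44

#: Non-zero-pair count up to which the exact Wilcoxon null is enumerated.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class TestResult:
    """Outcome of a hypothesis test; ``n`` counts usable observations."""

    statistic: float
    p_value: float
    n: int
    method: str
    two_sided: bool = True
    estimate: float | None = None  # rho for correlations


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_null_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of the positive-rank sum, on a half-integer lattice.

    Mid-ranks are multiples of 0.5, so doubling them gives integers; the
    pmf over the doubled rank-sum is built by convolution over the 2^n
    equally likely sign assignments.
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    *,
    zero_method: str = "wilcox",
) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    ``a`` may be the vector of differences (``b=None``) or the first member
    of each pair.  Pairs where either value is missing are dropped
    listwise.  Zero differences are dropped (``zero_method="wilcox"``,
    default) or kept in the ranking but never counted in the statistic
    (``"pratt"``).  If every difference is zero the result is degenerate
    with p = 1.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    d = d[np.isfinite(d)]
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        return TestResult(
            statistic=0.0, p_value=1.0, n=0, method="wilcoxon signed-rank (degenerate)"
        )
    if zero_method == "wilcox":
        d = d[nonzero]
        ranks = sps.rankdata(np.abs(d))
    else:
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[nonzero]
        d = d[nonzero]
    n = len(d)
    w_plus = float(ranks[d > 0].sum())
    mu = float(ranks.sum()) / 2.0
    if n <= WILCOXON_EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_null_cdf(doubled)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "wilcoxon signed-rank (exact)"
    else:
        var = float((ranks**2).sum()) / 4.0  # tie-corrected: sum r_i^2 / 4
        sd = math.sqrt(var)
        diff = w_plus - mu
        z = (diff - 0.5 * np.sign(diff)) / sd if sd > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "wilcoxon signed-rank (normal approx)"
    return TestResult(statistic=w_plus, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman's rho: Pearson correlation of mid-ranks, t-approximation p.

    Missing values are removed listwise; fewer than 4 complete pairs raise
    :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return TestResult(
            statistic=float("nan"), p_value=float("nan"), n=n,
            method="spearman (constant input)", estimate=float("nan"),
        )
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(abs(rho) - 1.0) < 1e-12:  # snap float dust on perfect monotone data
        rho = math.copysign(1.0, rho)
    if abs(rho) == 1.0:
        p = 0.0
        t = math.inf * np.sign(rho)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(
        statistic=float(t), p_value=p, n=n, method="spearman", estimate=rho
    )


# ---------------------------------------------------------------------------
# ROC-optimal cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """ROC-optimal dichotomization threshold (value >= cutoff is "high").

    ``direction`` records which side of the cutoff predicts the event:
    ``">="`` means high values are event-positive, ``"<"`` means low values
    are (a protective marker).  Sensitivity/specificity/J refer to that
    orientation, so J is always >= 0 at the optimum.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_above: int
    n_below: int
    direction: str = ">="


def roc_cutpoint(values: Sequence[float], outcome: Sequence[int]) -> CutpointResult:
    """Youden-optimal cutoff over every midpoint between adjacent unique values.

    ``outcome`` is binary (1 = event).  Both test orientations (value >=
    cutoff predicts the event, or value < cutoff does) are evaluated and
    the cutoff maximizing Youden's J = sensitivity + specificity - 1 is
    returned; ties in J are broken toward the cutoff yielding more
    balanced groups, then toward the smaller cutoff.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    ok = np.isfinite(values)
    values, outcome = values[ok], outcome[ok]
    n = len(values)
    n_pos = int((outcome == 1).sum())
    n_neg = int((outcome == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("both outcome classes must be present")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise InsufficientDataError("constant feature: no valid split")
    order = np.argsort(values, kind="stable")
    sv = values[order]
    so = outcome[order]
    # boundary k separates sv[:k] (below) from the rest, cutoff midway
    # between consecutive distinct values
    change = np.flatnonzero(np.diff(sv) > 0) + 1  # first index of each new value
    cutoffs = (sv[change - 1] + sv[change]) / 2.0
    cum_pos = np.cumsum(so == 1)
    cum_neg = np.cumsum(so == 0)
    pos_below = cum_pos[change - 1]
    neg_below = cum_neg[change - 1]
    sens_ge = (n_pos - pos_below) / n_pos
    spec_ge = neg_below / n_neg
    j_ge = sens_ge + spec_ge - 1.0  # "<" orientation has J = -j_ge
    j_best = np.abs(j_ge)
    balance = np.abs(n - 2 * change)  # |n_above - n_below|
    best = np.lexsort((cutoffs, balance, -j_best))[0]
    if j_ge[best] >= 0:
        direction, sens, spec = ">=", sens_ge[best], spec_ge[best]
    else:
        direction, sens, spec = "<", 1.0 - sens_ge[best], 1.0 - spec_ge[best]
    return CutpointResult(
        cutoff=float(cutoffs[best]),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j_best[best]),
        n_above=int(n - change[best]),
        n_below=int(change[best]),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMOutput:
    """Product-limit survival estimate for one group."""

    times: np.ndarray  # event-ordered unique observed times
    survival: np.ndarray  # S(t) just after each time
    median: float  # months; math.inf when not reached
    median_reached: bool
    n: int
    n_events: int
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


_MEDIAN_TOL = 1e-9  # float slack when testing S(t) <= 0.5


def km_estimate(records: Sequence[SurvivalRecord], label: str = "") -> KMOutput:
    """Kaplan-Meier product-limit estimator.

    At tied times deaths are processed before censorings.  The median is
    the smallest observed time with S(t) <= 0.5, else "not reached".
    """
    if len(records) == 0:
        raise InsufficientDataError("need at least one record")
    t = np.array([r.os_months for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("survival times must be finite and >= 0")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n_at_risk = len(t) - np.searchsorted(t, uniq, side="left")
    deaths = np.array([(e[t == u] == 1).sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - deaths / n_at_risk
    surv = np.cumprod(factors)
    below = np.flatnonzero(surv <= 0.5 + _MEDIAN_TOL)
    if len(below):
        median = float(uniq[below[0]])
        reached = True
    else:
        median = math.inf
        reached = False
    return KMOutput(
        times=uniq,
        survival=surv,
        median=median,
        median_reached=reached,
        n=len(t),
        n_events=int(e.sum()),
        label=label,
    )


def log_rank(groups: Sequence[Sequence[SurvivalRecord]]) -> TestResult:
    """k-group log-rank chi-square test (k >= 2, every group nonempty)."""
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise InsufficientDataError("empty group")
    times = [np.array([r.os_months for r in g], dtype=float) for g in groups]
    events = [np.array([r.event for r in g], dtype=int) for g in groups]
    chi2, df = _log_rank_arrays(times, events)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return TestResult(
        statistic=float(chi2),
        p_value=p,
        n=int(sum(len(g) for g in groups)),
        method=f"log-rank ({len(groups)} groups)",
    )


def _log_rank_arrays(
    times: Sequence[np.ndarray], events: Sequence[np.ndarray]
) -> tuple[float, int]:
    """Log-rank statistic from per-group time/event arrays.

    Sums the hypergeometric observed-minus-expected vector and its
    covariance over the pooled event times; the chi-square uses the first
    k-1 groups.
    """
    k = len(times)
    all_t = np.concatenate(times)
    all_e = np.concatenate(events)
    event_times = np.unique(all_t[all_e == 1])
    if len(event_times) == 0:
        return 0.0, k - 1
    # at-risk and death counts per group at each event time
    nj = np.empty((len(event_times), k))
    dj = np.empty((len(event_times), k))
    for j in range(k):
        ts = np.sort(times[j])
        nj[:, j] = len(ts) - np.searchsorted(ts, event_times, side="left")
        dt = np.sort(times[j][events[j] == 1])
        dj[:, j] = np.searchsorted(dt, event_times, side="right") - np.searchsorted(
            dt, event_times, side="left"
        )
    n_tot = nj.sum(axis=1)
    d_tot = dj.sum(axis=1)
    expected = dj.sum(axis=0) - (d_tot[:, None] * nj / n_tot[:, None]).sum(axis=0)
    # covariance of the O-E vector summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = nj / n_tot[:, None]
        mult = d_tot * (n_tot - d_tot) / np.where(n_tot > 1, n_tot - 1, 1.0)
    cov = np.zeros((k, k))
    for j in range(k):
        for l in range(j, k):
            diag = frac[:, j] * ((j == l) - frac[:, l])
            cov[j, l] = cov[l, j] = float((mult * diag).sum())
    oe = expected[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chi2 = float(oe @ np.linalg.solve(v, oe))
    except np.linalg.LinAlgError:
        chi2 = float(oe @ np.linalg.pinv(v) @ oe)
    return max(chi2, 0.0), k - 1


# ---------------------------------------------------------------------------
# Dichotomized survival analysis
# ---------------------------------------------------------------------------

@dataclass
class DichotomizedSurvival:
    """Cutpoint + per-group KM + log-rank for one feature.

    ``degenerate`` flags features that could not be split (constant value,
    single outcome class or an empty group); no test is reported then.
    ``permutation_p`` calibrates the log-rank p for the cutpoint
    optimization by permuting feature labels and rerunning the full
    cutpoint + log-rank pipeline.
    """

    feature: str
    cutpoint: CutpointResult | None
    km_high: KMOutput | None
    km_low: KMOutput | None
    logrank: TestResult | None
    permutation_p: float | None = None
    degenerate: bool = False
    reason: str = ""


def dichotomized_survival(
    feature_values: Mapping[str, float],
    records: Sequence[SurvivalRecord],
    *,
    feature_name: str = "feature",
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
    horizon: float | None = None,
) -> DichotomizedSurvival:
    """Optimal-cutpoint survival stratification of one per-patient feature.

    ``feature_values`` maps patient_id -> value; patients missing from
    either input (or with NaN feature) are dropped listwise.  The ROC
    outcome is the event flag (vital status at end of follow-up); pass
    ``horizon`` to use death-by-a-fixed-time instead.  Groups are high
    (value >= cutoff) vs low.
    """
    recs = [
        r
        for r in records
        if r.patient_id in feature_values
        and np.isfinite(feature_values[r.patient_id])
    ]
    vals = np.array([feature_values[r.patient_id] for r in recs], dtype=float)
    if horizon is None:
        evts = np.array([r.event for r in recs], dtype=int)
    else:
        evts = np.array(
            [int(r.event == 1 and r.os_months <= horizon) for r in recs], dtype=int
        )
    try:
        cut = roc_cutpoint(vals, evts)
    except InsufficientDataError as err:
        return DichotomizedSurvival(
            feature=feature_name, cutpoint=None, km_high=None, km_low=None,
            logrank=None, degenerate=True, reason=str(err),
        )
    hi = [r for r, v in zip(recs, vals) if v >= cut.cutoff]
    lo = [r for r, v in zip(recs, vals) if v < cut.cutoff]
    if not hi or not lo:
        return DichotomizedSurvival(
            feature=feature_name, cutpoint=cut, km_high=None, km_low=None,
            logrank=None, degenerate=True, reason="empty group after split",
        )
    km_hi = km_estimate(hi, label="high")
    km_lo = km_estimate(lo, label="low")
    lr = log_rank([hi, lo])
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        t = np.array([r.os_months for r in recs], dtype=float)
        e = np.array([r.event for r in recs], dtype=int)
        hits = 0
        usable = 0
        for _ in range(n_permutations):
            pv = rng.permutation(vals)
            try:
                pcut = roc_cutpoint(pv, evts)
            except InsufficientDataError:
                continue
            mask = pv >= pcut.cutoff
            if mask.all() or not mask.any():
                continue
            chi2, _ = _log_rank_arrays([t[mask], t[~mask]], [e[mask], e[~mask]])
            usable += 1
            if chi2 >= lr.statistic - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (usable + 1) if usable else None
    return DichotomizedSurvival(
        feature=feature_name,
        cutpoint=cut,
        km_high=km_hi,
        km_low=km_lo,
        logrank=lr,
        permutation_p=perm_p,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
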