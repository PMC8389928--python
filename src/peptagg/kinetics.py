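"""Nucleation and aggregation-kinetics analysis.

Aggregation runs fall into three kinetic modes: *no-aggregation* (the
monomer count fluctuates around its initial value and only transient
small oligomers appear), *nucleated* (a lag phase during which small
oligomers equilibrate with monomers ends at the nucleation time t*,
after which the monomer count drops sigmoidally) and *downhill*
(monomers decay from t = 0 with no lag).

Three estimators quantify nucleated kinetics:

* change-point (CP) analysis of the monomer curve — a two-segment
  piecewise-linear fit whose breakpoint marks the end of the lag phase;
* mean first-passage times (MFPT) of the largest-cluster size m(t),
  fitted with the sigmoid-plus-growth form
  ``tau(m) = tau*/2 [1 + erf(Z sqrt(pi) (m - m*))] + H(m - m*)(m - m*)/G``
  yielding the critical nucleus size m*, growth rate G, Zeldovich factor
  Z and average nucleation time tau*;
* the transition probability matrix (TPM) of m(t): with
  ``P_growth(m) = P(m -> m+1) - P(m -> m-1)``, the critical nucleus is
  the smallest size whose growth probability is non-negative.

Monomer curves are compared on a common master scale,
``N_m_sc = (N_m - N_eq) / (N_lag - N_eq)`` against ``(t - t*)/t_half``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf

__all__ = [
    "MonomerKinetics",
    "NucleationEstimates",
    "ChangePoint",
    "MFPTFit",
    "TPMResult",
    "ModeResult",
    "analyze_monomer_kinetics",
    "scale_monomer_curve",
    "change_point_lag",
    "mfpt_curve",
    "mfpt_model",
    "fit_mfpt",
    "tpm_analysis",
    "classify_mode",
]


class NoAggregationSignal(ValueError):
    """The lag and equilibrium plateaus coincide; scaling is undefined."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge."""


# ---------------------------------------------------------------------------
# change-point analysis


@dataclass
class ChangePoint:
    """Result of the two-segment lag-time analysis.

    ``t_star is None`` means no change point (no significant decay);
    ``fired`` is true when a genuine lag phase precedes the decay;
    ``t_star == 0`` with ``fired`` false flags downhill decay.
    """

    t_star: float | None
    index: int | None
    slope_pre: float | None
    slope_post: float | None
    fired: bool


def _segment_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, sse)."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(res[0]) if len(res) else float(np.sum((y - A @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def change_point_lag(
    times: np.ndarray,
    n_m: np.ndarray,
    *,
    min_segment: int = 5,
    slope_ratio: float = 5.0,
    noise_sigmas: float = 3.0,
) -> ChangePoint:
    """Two-segment piecewise-linear lag-time estimator.

    The breakpoint minimising the total squared error is accepted as the
    nucleation time when the post-break slope magnitude exceeds
    ``slope_ratio`` times the pre-break slope magnitude (a "large change
    of the slope").  If the monomer curve shows no decay beyond
    ``noise_sigmas`` times the point noise, there is no change point; if
    it decays but without a flat lag segment, the decay is downhill and
    t* = 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(n_m, dtype=float)
    n = len(t)
    if n < 2 * min_segment:
        raise ValueError(
            f"trajectory of {n} points is shorter than twice the minimum "
            f"segment length ({min_segment})"
        )
    # significance of the overall decay against point-to-point noise
    head = float(np.mean(y[:min_segment]))
    tail = float(np.mean(y[-min_segment:]))
    sigma = float(np.std(np.diff(y)) / np.sqrt(2.0)) or 1e-12
    if head - tail < noise_sigmas * sigma * np.sqrt(2.0 / min_segment):
        return ChangePoint(None, None, None, None, False)

    # the two-segment model describes lag + decay; cut off the trailing
    # equilibrium plateau so its corner cannot attract the breakpoint
    near_eq = y <= tail + 0.25 * (head - tail)
    end = int(np.argmax(near_eq)) + 1 if near_eq.any() else n
    end = min(max(end, 4 * min_segment), n)
    if end < 2 * min_segment:
        return ChangePoint(0.0, 0, None, None, False)
    tw, yw = t[:end], y[:end]

    best = (np.inf, min_segment)
    for bp in range(min_segment, end - min_segment + 1):
        _, _, sse1 = _segment_fit(tw[:bp], yw[:bp])
        _, _, sse2 = _segment_fit(tw[bp:], yw[bp:])
        if sse1 + sse2 < best[0]:
            best = (sse1 + sse2, bp)
    bp = best[1]
    s1, _, _ = _segment_fit(tw[:bp], yw[:bp])
    s2, _, _ = _segment_fit(tw[bp:], yw[bp:])
    scale = (np.max(y) - np.min(y)) / (t[-1] - t[0])  # overall decay slope scale
    fired = s2 < 0 and abs(s2) >= slope_ratio * max(abs(s1), 1e-3 * scale)
    if fired:
        return ChangePoint(float(t[bp]), bp, s1, s2, True)
    return ChangePoint(0.0, 0, s1, s2, False)


# ---------------------------------------------------------------------------
# monomer-curve summary and master-curve scaling


@dataclass
class MonomerKinetics:
    """Ensemble-averaged monomer curve and its plateau/lag summary."""

    times: np.ndarray
    n_m_mean: np.ndarray
    n_m_lag: float
    n_m_eq: float
    t_star: float | None
    t_half: float | None
    change_point: ChangePoint | None = None


def analyze_monomer_kinetics(
    times: np.ndarray,
    n_m: np.ndarray,
    *,
    eq_fraction: float = 0.2,
    cp_kwargs: dict | None = None,
) -> MonomerKinetics:
    """Summarise an ensemble of monomer trajectories.

    ``n_m`` is (n_repeats, n_frames) or a single (n_frames,) curve; the
    ensemble mean is analysed.  The lag plateau is the average monomer
    count over [0, t*) (the initial value when the decay is downhill),
    the equilibrium plateau the average over the final ``eq_fraction``
    of the run, and the half-time the first time after t* at which the
    mean curve drops below half the lag plateau.
    """
    t = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(n_m, dtype=float)).mean(axis=0)
    kw = dict(cp_kwargs or {})
    kw.setdefault("min_segment", max(2, min(5, len(t) // 4)))
    if len(t) < 2 * kw["min_segment"]:
        cp = ChangePoint(None, None, None, None, False)  # too short to tell
    else:
        cp = change_point_lag(t, y, **kw)
    n_eq = float(np.mean(y[-max(1, int(len(y) * eq_fraction)) :]))
    if cp.t_star is None:
        n_lag = float(np.mean(y))
        return MonomerKinetics(t, y, n_lag, n_eq, None, None, cp)
    if cp.fired and cp.index and cp.index > 0:
        n_lag = float(np.mean(y[: cp.index]))
    else:
        n_lag = float(np.mean(y[: max(1, len(y) // 50)]))
    t_half = None
    after = t >= cp.t_star
    below = after & (y <= 0.5 * n_lag)
    if np.any(below):
        t_half = float(t[np.argmax(below)])
    return MonomerKinetics(t, y, n_lag, n_eq, cp.t_star, t_half, cp)


def scale_monomer_curve(km: MonomerKinetics) -> tuple[np.ndarray, np.ndarray]:
    """Master-curve scaling of a monomer trajectory.

    Returns ``(scaled_time, scaled_n_m)`` with
    ``N_sc = (N_m - N_eq)/(N_lag - N_eq)`` (lag plateau -> 1,
    equilibrium plateau -> 0) and time shifted by t* then divided by the
    half-time.  Raises when the plateaus coincide (no aggregation).
    """
    if not km.n_m_lag > km.n_m_eq:
        raise NoAggregationSignal(
            "lag and equilibrium plateaus coincide; nothing aggregated"
        )
    scaled = (km.n_m_mean - km.n_m_eq) / (km.n_m_lag - km.n_m_eq)
    t_star = km.t_star or 0.0
    t_half = km.t_half if km.t_half and km.t_half > t_star else None
    shifted = km.times - t_star
    if t_half is not None:
        shifted = shifted / (t_half - t_star)
    return shifted, scaled


# ---------------------------------------------------------------------------
# mean first-passage times


def mfpt_curve(
    trajectories: list[tuple[np.ndarray, np.ndarray]],
    max_size: int | None = None,
) -> pd.DataFrame:
    """Mean first-passage time of the largest cluster versus target size.

    ``trajectories`` is a list of ``(times, m)`` pairs, one per repeat.
    For each target size the first time m(t) *reaches* (>=, so
    coalescence jumps count) that size is recorded; repeats that never
    reach a size are excluded there and the surviving count reported.

    Returns a DataFrame with columns ``m, tau, n_reached, n_repeats``;
    ``tau`` is nondecreasing in m by construction.
    """
    if not trajectories:
        raise ValueError("need at least one repeat")
    tops = [int(np.max(m)) for _, m in trajectories]
    top = max_size if max_size is not None else max(tops)
    rows = []
    for target in range(1, top + 1):
        passages = []
        for times, m in trajectories:
            hit = np.asarray(m) >= target
            if hit.any():
                passages.append(float(np.asarray(times)[np.argmax(hit)]))
        if passages:
            rows.append(
                (target, float(np.mean(passages)), len(passages), len(trajectories))
            )
    return pd.DataFrame(rows, columns=["m", "tau", "n_reached", "n_repeats"])


def mfpt_model(m, m_star: float, growth_rate: float, zeldovich: float, tau_star: float):
    """Sigmoid-plus-linear-growth first-arrival model tau(m)."""
    m = np.asarray(m, dtype=float)
    sig = 0.5 * tau_star * (1.0 + erf(zeldovich * np.sqrt(np.pi) * (m - m_star)))
    growth = np.where(m > m_star, (m - m_star) / growth_rate, 0.0)
    return sig + growth


@dataclass
class MFPTFit:
    """Fitted nucleation parameters from the MFPT curve."""

    m_star: float
    growth_rate: float  # peptides / time-unit of the input
    zeldovich: float
    tau_star: float
    cost: float
    success: bool

    def __iter__(self):
        return iter((self.m_star, self.growth_rate, self.zeldovich, self.tau_star))


def fit_mfpt(
    m: np.ndarray,
    tau: np.ndarray,
    *,
    p0: tuple[float, float, float, float] | None = None,
) -> MFPTFit:
    """Nonlinear least-squares fit of the MFPT model.

    Initial guesses are read off the curve (the steepest-ascent point
    for m*, twice the mid-value for tau*, the tail slope for 1/G); a few
    alternative m* starts guard against the kink at the step term.
    """
    m = np.asarray(m, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(m) < 5:
        raise ValueError("MFPT curve too short to fit four parameters")
    scale = max(float(np.max(tau)), 1e-12)

    def residuals(x):
        return mfpt_model(m, *x) - tau

    grad = np.gradient(tau, m)
    i_infl = int(np.argmax(grad))
    starts = []
    if p0 is not None:
        starts.append(np.asarray(p0, dtype=float))
    k = max(2, len(m) // 4)
    tail_slope = (tau[-1] - tau[-k]) / (m[-1] - m[-k]) if m[-1] > m[-k] else scale
    g0 = 1.0 / max(tail_slope, 1e-9 * scale)
    for m0 in {m[i_infl], np.quantile(m, 0.25), np.quantile(m, 0.5)}:
        t0 = max(2.0 * float(np.interp(m0, m, tau)), 1e-6 * scale)
        z0 = min(max(float(np.max(grad)) / t0, 1e-3), 2.0)
        starts.append(np.array([m0, g0, z0, t0]))

    lower = [float(np.min(m)), 1e-12, 1e-6, 1e-12]
    upper = [float(np.max(m)), np.inf, 10.0, np.inf]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("MFPT fit failed from every starting point")
    fit = MFPTFit(*best.x, cost=float(best.cost), success=bool(best.success))
    if not best.success:
        raise FitFailureError(
            f"MFPT fit did not converge (residual cost {best.cost:.3g})"
        )
    return fit


# ---------------------------------------------------------------------------
# transition probability matrix


@dataclass
class TPMResult:
    """Row-normalised transition matrix of largest-cluster sizes."""

    states: np.ndarray  # observed m values with outgoing transitions
    matrix: np.ndarray  # (n_states, n_states) row-stochastic
    table: pd.DataFrame  # m, P_f, P_b, P_growth, n_transitions
    m_star: int | None
    excluded_states: np.ndarray  # observed m without outgoing transitions


def tpm_analysis(
    series: np.ndarray | list[np.ndarray],
    *,
    count_jumps: str = "denominator",
    min_state: int = 2,
) -> TPMResult:
    """Estimate the transition probability matrix of m(t).

    ``series`` is one largest-cluster-size series sampled at a fixed
    stride, or a list of such series (repeats are pooled).  Transition
    counts between consecutive samples are row-normalised;
    ``P_f(m) = P(m -> m+1)``, ``P_b(m) = P(m -> m-1)`` and the critical
    nucleus is the smallest ``m >= min_state`` with
    ``P_growth(m) = P_f - P_b >= 0``.

    Multi-step jumps (cluster coalescence, |dm| > 1) enter the row
    denominator but not the P_f/P_b numerators under the default
    ``count_jumps="denominator"``; with ``"sign"`` they are collapsed
    onto the m+-1 counts by their sign.
    """
    if count_jumps not in ("denominator", "sign"):
        raise ValueError("count_jumps must be 'denominator' or 'sign'")
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    series = [np.asarray(s, dtype=np.int64) for s in series]
    if not series or all(len(s) < 2 for s in series):
        raise ValueError("need at least one series with two samples")
    top = max(int(s.max()) for s in series)
    counts = np.zeros((top + 1, top + 1))
    for s in series:
        np.add.at(counts, (s[:-1], s[1:]), 1.0)

    row_totals = counts.sum(axis=1)
    observed = np.flatnonzero(row_totals > 0)
    matrix = np.zeros_like(counts[observed][:, observed])
    matrix = counts[np.ix_(observed, observed)] / row_totals[observed, None]

    rows = []
    for mval in observed:
        total = row_totals[mval]
        if count_jumps == "sign":
            up = counts[mval, mval + 1 :].sum()
            down = counts[mval, :mval].sum()
        else:
            up = counts[mval, mval + 1] if mval + 1 <= top else 0.0
            down = counts[mval, mval - 1] if mval - 1 >= 0 else 0.0
        rows.append((int(mval), up / total, down / total, int(total)))
    table = pd.DataFrame(rows, columns=["m", "P_f", "P_b", "n_transitions"])
    table["P_growth"] = table["P_f"] - table["P_b"]

    eligible = table[(table["m"] >= min_state) & (table["P_growth"] >= 0)]
    m_star = int(eligible["m"].min()) if len(eligible) else None
    excluded = np.setdiff1d(
        np.unique(np.concatenate(series)), observed
    )  # states only ever visited at a series end
    return TPMResult(observed, matrix, table, m_star, excluded)


# ---------------------------------------------------------------------------
# kinetic-mode classification


@dataclass
class ModeResult:
    """Kinetic-mode label with the evidence used to assign it."""

    mode: str  # "no-aggregation" | "nucleated" | "downhill"
    change_point: ChangePoint
    stable_cluster: bool
    size_threshold: int
    min_lag: float


def classify_mode(
    times: np.ndarray,
    n_m: np.ndarray,
    m_max: np.ndarray,
    n_chains: int,
    *,
    size_fraction: float = 0.25,
    min_size: int = 4,
    tail_fraction: float = 0.25,
    persistence: float = 0.8,
    min_lag_fraction: float = 0.05,
    cp_kwargs: dict | None = None,
) -> ModeResult:
    """Assign one of the three kinetic modes to an ensemble.

    A "stable large cluster" is present when at least ``persistence`` of
    the final ``tail_fraction`` of frames have (ensemble-mean) M_max at
    or above ``max(min_size, size_fraction * n_chains)``.  The run is
    *no-aggregation* when neither a stable cluster nor a change point is
    found; *nucleated* when the change-point analysis fires at a lag of
    at least ``min_lag_fraction`` of the run; *downhill* otherwise.
    All thresholds are explicit parameters and echoed in the result.
    """
    t = np.asarray(times, dtype=float)
    nm_mean = np.atleast_2d(np.asarray(n_m, dtype=float)).mean(axis=0)
    mm_mean = np.atleast_2d(np.asarray(m_max, dtype=float)).mean(axis=0)

    threshold = max(min_size, int(np.ceil(size_fraction * n_chains)))
    tail = mm_mean[-max(1, int(len(mm_mean) * tail_fraction)) :]
    stable = float(np.mean(tail >= threshold)) >= persistence

    kw = dict(cp_kwargs or {})
    kw.setdefault("min_segment", max(2, min(5, len(t) // 4)))
    if len(t) < 2 * kw["min_segment"]:
        cp = ChangePoint(None, None, None, None, False)  # too short to tell
    else:
        cp = change_point_lag(t, nm_mean, **kw)
    min_lag = min_lag_fraction * (t[-1] - t[0])

    if not stable and not cp.fired:
        mode = "no-aggregation"
    elif cp.fired and cp.t_star is not None and cp.t_star >= min_lag:
        mode = "nucleated"
    else:
        mode = "downhill"
    return ModeResult(mode, cp, stable, threshold, min_lag)


# ---------------------------------------------------------------------------
# bundled estimates


@dataclass
class NucleationEstimates:
    """All nucleation quantities for one (epsilon, k_theta) condition."""

    m_star_tpm: int | None = None
    m_star_mfpt: float | None = None
    tau_cp: float | None = None
    tau_mfpt: float | None = None
    growth_rate: float | None = None
    zeldovich: float | None = None
    n_nucleated_repeats: int = 0
    n_repeats: int = 0
    mode: str | None = None

    def to_dict(self) -> dict:
        return {
            "m_star_TPM": self.m_star_tpm,
            "m_star_MFPT": self.m_star_mfpt,
            "tau_CP": self.tau_cp,
            "tau_MFPT": self.tau_mfpt,
            "G": self.growth_rate,
            "Z": self.zeldovich,
            "n_nucleated_repeats": self.n_nucleated_repeats,
            "n_repeats": self.n_repeats,
            "mode": self.mode,
        }
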