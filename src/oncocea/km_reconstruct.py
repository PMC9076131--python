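"""Pseudo-IPD reconstruction from digitized Kaplan–Meier curves.

Published trial figures give only the KM curve coordinates and a
numbers-at-risk table, but survival extrapolation needs individual
(time, event) records.  This module implements the standard iterative
reconstruction: within each at-risk interval the number of censorings is
estimated (censor times spread uniformly), events are allocated at the
coordinate drop times so the implied product-limit curve tracks the input,
and the censoring count is adjusted until the implied number at risk matches
the published count at the next interval boundary.

The product-limit estimator itself is delegated to lifelines; a thin
step-function wrapper keeps evaluation right-continuous and vectorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

log = logging.getLogger(__name__)

MAX_SWEEPS = 100  # adjustment sweeps per at-risk interval


# ---------------------------------------------------------------------------
# containers

@dataclass
class IPDSet:
    """Individual patient records (time in months, event indicator) for one
    arm/endpoint."""

    times: np.ndarray
    events: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.size == 0:
            raise ValueError("IPDSet needs at least one record")
        if np.any(self.times < 0):
            raise ValueError("negative times")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm: str = "", endpoint: str = "") -> "IPDSet":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(),
                   arm=arm, endpoint=endpoint)


@dataclass
class DigitizedCurve:
    """Digitized KM coordinates plus the figure's numbers-at-risk table."""

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n_at_risk: np.ndarray = field(default_factory=lambda: np.array([]))
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)

    @property
    def has_risk_table(self) -> bool:
        return self.risk_times.size > 0

    def validate(self) -> None:
        if self.times.size < 2:
            raise ValueError("curve needs at least 2 coordinates")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("coordinate times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise ValueError("curve must start at (0, 1)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival outside [0, 1]")
        if self.has_risk_table:
            if np.any(np.diff(self.risk_times) <= 0):
                raise ValueError("risk-table times must be strictly increasing")
            if np.any(np.diff(self.n_at_risk) > 0):
                raise ValueError("inconsistent risk table: count increases")
            if np.any(self.n_at_risk < 0):
                raise ValueError("negative at-risk count")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        curve = pd.DataFrame({"time_months": self.times, "survival": self.survival})
        risk = pd.DataFrame({"time_months": self.risk_times,
                             "n_at_risk": self.n_at_risk})
        return curve, risk

    def to_csv(self, curve_path, risk_path=None) -> None:
        curve, risk = self.to_frames()
        curve.to_csv(curve_path, index=False)
        if risk_path is not None:
            risk.to_csv(risk_path, index=False)

    @classmethod
    def from_csv(cls, curve_path, risk_path=None, arm: str = "",
                 endpoint: str = "") -> "DigitizedCurve":
        df = pd.read_csv(curve_path)
        points = list(zip(df["time_months"], df["survival"]))
        risk = None
        if risk_path is not None:
            rdf = pd.read_csv(risk_path)
            risk = list(zip(rdf["time_months"], rdf["n_at_risk"]))
        return preprocess_curve(points, risk, arm=arm, endpoint=endpoint)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_curve(raw_points, risk_table=None, arm: str = "",
                     endpoint: str = "") -> DigitizedCurve:
    """Clean digitization artefacts and return a validated curve.

    Points are sorted by time, survival clamped to [0, 1], monotone
    non-increase enforced by a running minimum, duplicate times collapsed to
    the lower survival value, and a (0, 1.0) anchor prepended if missing.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (time, survival) points")
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    if np.all(pts[:, 0] == pts[0, 0]):
        raise ValueError("all points share one time")

    t, s = pts[:, 0], np.clip(pts[:, 1], 0.0, 1.0)
    # duplicate times -> keep the lower survival value
    keep_t, keep_s = [], []
    for ti, si in zip(t, s):
        if keep_t and ti == keep_t[-1]:
            keep_s[-1] = min(keep_s[-1], si)
        else:
            keep_t.append(ti)
            keep_s.append(si)
    t = np.asarray(keep_t)
    s = np.minimum.accumulate(np.asarray(keep_s))

    if t[0] != 0.0 or s[0] != 1.0:
        if t[0] == 0.0:
            s[0] = 1.0  # anchor survival at 1 at time zero
        else:
            t = np.insert(t, 0, 0.0)
            s = np.insert(s, 0, 1.0)

    risk_times = n_at_risk = np.array([])
    if risk_table is not None:
        rt = np.asarray(risk_table, dtype=float)
        if rt.size == 0:
            raise ValueError("risk table is empty")
        rt = rt[np.argsort(rt[:, 0], kind="stable")]
        risk_times, n_at_risk = rt[:, 0], rt[:, 1]

    curve = DigitizedCurve(t, s, risk_times, n_at_risk, arm=arm,
                           endpoint=endpoint)
    curve.validate()
    return curve


# ---------------------------------------------------------------------------
# product-limit estimation

class StepFunction:
    """Right-continuous step function t -> value."""

    def __init__(self, times, values, initial: float = 1.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.initial = float(initial)

    def __call__(self, t):
        tt = np.asarray(t, dtype=float)
        if np.any(tt < 0):
            raise ValueError("negative time")
        idx = np.searchsorted(self.times, tt, side="right") - 1
        out = np.where(idx < 0, self.initial, self.values[np.maximum(idx, 0)])
        return float(out) if np.isscalar(t) else out


def km_estimate(ipd: IPDSet) -> StepFunction:
    """Product-limit survival estimate as a right-continuous step function."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(dtype=float),
                        sf.iloc[:, 0].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# reconstruction

def _spread_times(a: float, b: float, k: int) -> np.ndarray:
    """k censor times equally spaced strictly inside (a, b)."""
    if k <= 0:
        return np.array([])
    j = np.arange(1, k + 1, dtype=float)
    return a + j * (b - a) / (k + 1)


def reconstruct_ipd(curve: DigitizedCurve, total_events: int | None = None
                    ) -> IPDSet:
    """Reconstruct pseudo-IPD whose KM estimate tracks the digitized curve.

    Within each at-risk interval censorings are assumed uniform; their count
    is adjusted (up to ``MAX_SWEEPS`` sweeps) until the implied number at
    risk matches the published count at the next boundary.  Events are
    allocated at the coordinate drop times by tracking the product-limit
    identity.  If ``total_events`` is given, the event count is rescaled to
    match it by largest-remainder adjustment in the final interval.

    Without a risk table the degenerate mode assumes no censoring before the
    last coordinate and administratively censors all survivors there.
    """
    curve.validate()
    t = curve.times
    s = curve.survival
    K = len(t)

    if curve.has_risk_table:
        risk_times = curve.risk_times
        n_risk = curve.n_at_risk.astype(float).copy()
    else:
        log.warning("no risk table: assuming no censoring before the last "
                    "coordinate and administrative censoring at %.3g", t[-1])
        n0 = total_events if total_events is not None else None
        if n0 is None:
            # choose the smallest n reproducing the curve's smallest drop
            drops = -np.diff(s)
            min_drop = drops[drops > 1e-12].min() if np.any(drops > 1e-12) else 1.0
            n0 = max(int(round(1.0 / min_drop)), 1)
        risk_times = np.array([0.0])
        n_risk = np.array([float(n0)])

    # interval i covers coordinates with risk_times[i] <= t < risk_times[i+1]
    lower = np.searchsorted(t, risk_times, side="left")
    lower = np.clip(lower, 0, K - 1)
    nint = len(risk_times)
    upper = np.empty(nint, dtype=int)
    upper[:-1] = lower[1:] - 1
    upper[-1] = K - 1

    d = np.zeros(K)          # events allocated at each coordinate
    cen = np.zeros(K)        # censorings allocated after each coordinate
    n_hat = np.zeros(K + 1)  # implied at-risk entering each coordinate
    n_hat[lower[0]] = n_risk[0]
    km_hat = np.ones(K)
    last_event_idx = 0       # coordinate of the last positive event count

    def _sweep_interval(i: int, ncens: int, last: int) -> tuple[float, int]:
        """Allocate ncens censorings and the implied events in interval i;
        return (implied n at risk at next boundary, last event index)."""
        lo, hi = lower[i], upper[i]
        if hi < lo:  # interval holds no coordinates (sparse curve tail)
            return n_hat[lo], last
        nxt = t[lower[i + 1]] if i + 1 < nint else t[-1]
        cen_t = _spread_times(t[lo], nxt, ncens)
        # distribute censorings among coordinate sub-intervals [t_k, t_{k+1})
        cen[lo:hi + 1] = 0
        for ct in cen_t:
            k = np.searchsorted(t[lo:hi + 2] if hi + 1 < K else t[lo:hi + 1],
                                ct, side="right") - 1 + lo
            k = min(max(k, lo), hi)
            cen[k] += 1
        for k in range(lo, hi + 1):
            avail = max(n_hat[k], 0.0)
            if k == 0:
                d[k] = 0.0
                km_hat[k] = 1.0
            else:
                prev = km_hat[last]
                d[k] = round(avail * (1.0 - s[k] / prev)) if prev > 0 else 0.0
                d[k] = min(max(d[k], 0.0), avail)
                km_hat[k] = prev * (1.0 - d[k] / avail) if avail > 0 else 0.0
            cen[k] = min(cen[k], avail - d[k])  # cannot censor the departed
            n_hat[k + 1] = avail - d[k] - cen[k]
            if d[k] > 0:
                last = k
        return n_hat[hi + 1], last

    def _adjust_interval(i: int, ncens0: int, last: int,
                         target: float) -> tuple[float, int]:
        """Iterate the censor count until the implied at-risk count matches
        the target, keeping the best (smallest |gap|) allocation seen."""
        max_cens = int(max(n_hat[lower[i]], 0))
        ncens = int(np.clip(ncens0, 0, max_cens))
        best = None  # (|gap|, ncens)
        seen = set()
        for _ in range(MAX_SWEEPS):
            implied, _ = _sweep_interval(i, ncens, last)
            gap = implied - target
            if best is None or abs(gap) < best[0]:
                best = (abs(gap), ncens)
            if gap == 0 or ncens in seen:
                break
            seen.add(ncens)
            ncens = int(np.clip(ncens + gap, 0, max_cens))
        else:
            log.warning("interval %d: at-risk match not exact after %d "
                        "sweeps (best gap %g)", i, MAX_SWEEPS, best[0])
        implied, last = _sweep_interval(i, best[1], last)
        return implied, last

    for i in range(nint - 1):
        lo = lower[i]
        s_lo = s[lo] if s[lo] > 0 else 1.0
        guess = int(round(n_risk[i] * s[lower[i + 1]] / s_lo - n_risk[i + 1]))
        implied, last_event_idx = _adjust_interval(i, guess, last_event_idx,
                                                   n_risk[i + 1])
        if implied < n_risk[i + 1]:
            n_risk[i + 1] = implied  # published count unreachable; follow curve

    # final interval: censoring rate carried over from earlier intervals
    i = nint - 1
    lo, hi = lower[i], upper[i]
    if nint > 1 and t[hi] > t[lo]:
        span_prev = t[lower[i]] - t[lower[0]]
        rate = cen[:lo].sum() / span_prev if span_prev > 0 else 0.0
        ncens = int(min(round(rate * (t[hi] - t[lo])), max(n_hat[lo], 0)))
    else:
        ncens = 0
    _, last_event_idx = _sweep_interval(i, ncens, last_event_idx)

    if total_events is not None:
        _rescale_events(d, n_hat, s, int(total_events))

    return _emit_records(curve, t, d, cen, n_hat, risk_times, nint, lower,
                         upper)


def _rescale_events(d, n_hat, s, total_events: int) -> None:
    """Largest-remainder rescaling of allocated events to a published total."""
    cur = d.sum()
    if cur == total_events or cur == 0:
        return
    target = float(total_events)
    frac = d * target / cur
    new = np.floor(frac)
    rem = frac - new
    short = int(round(target - new.sum()))
    # earliest-time-first among the largest remainders
    order = np.lexsort((np.arange(len(d)), -rem))
    for k in order[:max(short, 0)]:
        new[k] += 1
    np.copyto(d, np.minimum(new, np.maximum(n_hat[:-1], 0)))


def _emit_records(curve, t, d, cen, n_hat, risk_times, nint, lower, upper):
    times, events = [], []
    K = len(t)
    for k in range(K):
        times.extend([t[k]] * int(d[k]))
        events.extend([1] * int(d[k]))
        if cen[k] > 0:
            upper_t = t[k + 1] if k + 1 < K else t[k]
            cts = _spread_times(t[k], upper_t, int(cen[k]))
            if cts.size == 0:
                cts = np.full(int(cen[k]), t[k])
            times.extend(cts.tolist())
            events.extend([0] * int(cen[k]))
    # survivors at end of follow-up: administrative censoring at last time
    leftover = int(round(max(n_hat[K], 0.0)))
    if leftover > 0:
        times.extend([t[-1]] * leftover)
        events.extend([0] * leftover)
    return IPDSet(np.asarray(times), np.asarray(events), arm=curve.arm,
                  endpoint=curve.endpoint)


def reconstruction_error(curve: DigitizedCurve, ipd: IPDSet
                         ) -> tuple[float, float]:
    """(max, mean) absolute deviation between the curve and KM(ipd) at the
    curve's own coordinates."""
    km = km_estimate(ipd)
    dev = np.abs(km(curve.times) - curve.survival)
    return float(dev.max()), float(dev.mean())
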