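"""Critical breakdown time from LSCC traces.

The collapse of the largest strongly connected component is treated as
a percolation transition with time as the tuning parameter.  Near the
transition the LSCC fraction follows a power law

    f(T) ~ a * (Tc - T)**beta,        T < Tc,

so for each candidate (Tc, beta) on a grid, f is linearly regressed on
(Tc - T)**beta over the near-transition window and the candidate with
maximal R^2 is selected.  The mean-field percolation value is
beta = 1.  Finite networks break down early; fitting Tc at several
sizes N and regressing Tc on 1/N extrapolates the intercept to the
infinite-size critical time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decay import SimulationTrace


class NoTransitionError(RuntimeError):
    """The trace never shows an LSCC breakdown."""


class InsufficientDataError(RuntimeError):
    """Too few usable points (or sizes) for a fit."""


DEFAULT_BETA_GRID = (0.5, 1.0, 1.5, 2.0)
DEFAULT_WINDOW = (0.01, 0.3)


@dataclass(frozen=True)
class CriticalFit:
    """Power-law fit of one LSCC trace near its breakdown."""

    n: int                 # network size
    tc: float              # critical day maximising R^2
    beta: float            # selected scaling exponent
    r_squared: float
    prefactor: float       # fitted amplitude a
    window: tuple          # (f_min, f_max) used
    n_points: int


@dataclass(frozen=True)
class FiniteSizeResult:
    """1/N extrapolation of fitted critical times."""

    fits: tuple
    tc_infinity: float     # intercept of tc vs 1/N
    slope: float
    fit_r_squared: float


def breakdown_day(trace: SimulationTrace, threshold: float | None = None
                  ) -> float | None:
    """First day at which f drops to the breakdown threshold.

    Default threshold ``2/N``: the LSCC has been reduced to (at most) a
    trivial pair, i.e. it has ceased to exist at network scale.
    Returns ``None`` if the trace never reaches it.
    """
    if threshold is None:
        threshold = 2.0 / trace.node_count
    below = np.flatnonzero(trace.f <= threshold)
    if below.size == 0:
        return None
    return float(trace.t[below[0]])


def fit_tc(trace: SimulationTrace, tc_grid=None,
           beta_grid=DEFAULT_BETA_GRID, window=DEFAULT_WINDOW) -> CriticalFit:
    """Select (Tc, beta) maximising R^2 of the near-transition fit.

    For every grid candidate, the trace points with
    ``f_min <= f <= f_max`` and ``T < Tc`` are fitted by least squares
    to ``a * (Tc - T)**beta`` (a line through the origin in the
    transformed coordinate -- the power law vanishes at Tc, so there is
    no intercept; with one, Tc would be unidentifiable at beta = 1).
    R^2 = 1 - SS_res / SS_tot, clamped to [0, 1].  ``beta = 1`` is
    always included in the grid.  The default Tc grid spans integer
    days from 30 before to 10 after the observed breakdown day.
    """
    t = trace.t.astype(float)
    f = trace.f.astype(float)
    f_min, f_max = window
    if tc_grid is None:
        bd = breakdown_day(trace)
        if bd is None:
            raise NoTransitionError("LSCC never breaks down within the trace")
        tc_grid = np.arange(max(1.0, bd - 30.0), bd + 10.0 + 0.5)
    tc_grid = np.asarray(tc_grid, dtype=float)
    if tc_grid.size == 0:
        raise InsufficientDataError("empty tc grid")
    beta_grid = sorted(set(float(b) for b in beta_grid) | {1.0})

    in_window = (f >= f_min) & (f <= f_max)
    best = None
    for tc in tc_grid:
        sel = in_window & (t < tc)
        if np.count_nonzero(sel) < 5:
            continue
        ts, fs = t[sel], f[sel]
        ss_tot = float(np.sum((fs - fs.mean()) ** 2))
        for beta in beta_grid:
            x = (tc - ts) ** beta
            xx = float(x @ x)
            if xx == 0.0:
                continue
            a = float(x @ fs) / xx
            ss_res = float(np.sum((fs - a * x) ** 2))
            if ss_tot > 0:
                r2 = min(1.0, max(0.0, 1.0 - ss_res / ss_tot))
            else:
                r2 = 1.0 if ss_res == 0.0 else 0.0
            if best is None or r2 > best.r_squared:
                best = CriticalFit(n=trace.node_count, tc=float(tc),
                                   beta=float(beta), r_squared=r2,
                                   prefactor=a,
                                   window=(f_min, f_max),
                                   n_points=int(len(ts)))
    if best is None:
        raise InsufficientDataError(
            "fewer than 5 usable trace points in the fit window")
    return best


def fit_tc_ensemble(traces, tc_grid=None, beta_grid=DEFAULT_BETA_GRID,
                    window=DEFAULT_WINDOW) -> CriticalFit:
    """Fit every realization separately and aggregate.

    Fitting the *ensemble-mean* trace biases the exponent upward:
    realizations break down on different days, so averaging smears the
    near-transition tail into a convex curve that a larger beta fits
    better.  Per-realization fits avoid that bias; the aggregate
    reports the modal beta, the mean Tc and the mean R^2.

    Realizations whose collapse is too steep to leave five usable
    points inside the window are skipped; at least half of the traces
    must remain fittable.
    """
    traces = list(traces)
    fits = []
    for tr in traces:
        try:
            fits.append(fit_tc(tr, tc_grid=tc_grid, beta_grid=beta_grid,
                               window=window))
        except InsufficientDataError:
            continue
    if len(fits) < max(1, (len(traces) + 1) // 2):
        raise InsufficientDataError(
            f"only {len(fits)} of {len(traces)} traces have enough "
            "near-transition points to fit")
    votes: dict[float, int] = {}
    for fit in fits:
        votes[fit.beta] = votes.get(fit.beta, 0) + 1
    beta = min(votes, key=lambda b: (-votes[b], b))
    return CriticalFit(
        n=fits[0].n,
        tc=float(np.mean([fit.tc for fit in fits])),
        beta=float(beta),
        r_squared=float(np.mean([fit.r_squared for fit in fits])),
        prefactor=float(np.mean([fit.prefactor for fit in fits])),
        window=tuple(window),
        n_points=int(np.mean([fit.n_points for fit in fits])),
    )


def extrapolate_tc(fits) -> FiniteSizeResult:
    """Ordinary least squares of fitted Tc on 1/N; intercept = Tc(inf)."""
    fits = tuple(fits)
    sizes = {fit.n for fit in fits}
    if len(sizes) < 3:
        raise InsufficientDataError(
            "need fits at >= 3 distinct network sizes")
    x = np.array([1.0 / fit.n for fit in fits])
    y = np.array([fit.tc for fit in fits])
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    return FiniteSizeResult(fits=fits, tc_infinity=float(res.intercept),
                            slope=float(res.slope), fit_r_squared=r2)
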