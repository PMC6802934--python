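"""Single-channel gating statistics and radiotracer-flux normalization.

The single-channel chain is the classical planar-bilayer workflow: current
levels from a two-Gaussian fit of the all-points amplitude histogram,
half-amplitude threshold idealization with a dead time, open probability as
the open-time fraction, unitary conductance as the slope of the i-V line,
and dwell-time distributions fitted as left-truncated exponential mixtures
by EM, with BIC for choosing the number of components.

Flux analysis normalizes channel-mediated tracer uptake to the
valinomycin-mediated maximum (liposome capacity) after background
subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    LevelDetectionError,
)

__all__ = [
    "CurrentTrace",
    "LevelFit",
    "IdealizedTrace",
    "DwellMixtureModel",
    "DwellMixtureResults",
    "FluxTimeCourse",
    "detect_levels",
    "idealize",
    "open_probability",
    "unitary_conductance",
    "fit_dwell_mixture",
    "select_components",
    "flux_normalize",
    "relative_activity",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurrentTrace:
    """A sampled single-channel current record.

    ``current`` in pA, ``fs`` sampling rate in Hz, ``filter_hz`` the analog
    low-pass corner (must respect Nyquist), ``voltage`` the holding
    potential in mV.
    """

    current: np.ndarray
    fs: float
    filter_hz: float = 2000.0
    voltage: float = 0.0

    def __post_init__(self):
        cur = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "current", cur)
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be > 0")
        if cur.size < 2:
            raise InvalidParameterError("trace needs >= 2 samples")
        if self.filter_hz >= self.fs / 2:
            raise InvalidParameterError("filter corner must be below Nyquist (fs/2)")

    @property
    def duration_s(self) -> float:
        return self.current.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.current.size) / self.fs


@dataclass(frozen=True)
class LevelFit:
    """Closed/open current levels from the all-points histogram."""

    closed_level: float
    open_level: float
    i_unitary: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class IdealizedTrace:
    """Alternating open/closed events from threshold idealization.

    ``events`` is an ordered list of ``(state, duration_ms)`` with states in
    {"open", "closed"}; durations sum to the trace span and events shorter
    than ``dead_time`` have been merged into their neighbours.
    """

    events: list
    dead_time: float  # ms

    def __post_init__(self):
        for (s1, _), (s2, _) in zip(self.events, self.events[1:]):
            if s1 == s2:
                raise InvalidParameterError("events must alternate states")

    def durations(self, state: str) -> np.ndarray:
        return np.array([d for s, d in self.events if s == state])

    @property
    def total_ms(self) -> float:
        return float(sum(d for _, d in self.events))

    def resynthesize(self, levels: tuple, fs: float) -> np.ndarray:
        """Rebuild a noiseless sample sequence from the event list."""
        closed, open_ = levels
        n = int(round(self.total_ms / 1000.0 * fs))
        out = np.empty(n)
        pos = 0.0
        for state, dur in self.events:
            i0 = int(round(pos / 1000.0 * fs))
            i1 = int(round((pos + dur) / 1000.0 * fs))
            out[i0:i1] = open_ if state == "open" else closed
            pos += dur
        return out


# ---------------------------------------------------------------------------
# level detection
# ---------------------------------------------------------------------------


def _two_gaussians(x, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-((x - mu1) ** 2) / (2 * s1**2)) + a2 * np.exp(
        -((x - mu2) ** 2) / (2 * s2**2)
    )


def detect_levels(trace: CurrentTrace) -> LevelFit:
    """Closed and open current levels from a two-Gaussian histogram fit.

    The all-points histogram (Freedman–Diaconis binning) must be bimodal;
    the two Gaussian means are the levels and ``i_unitary`` their absolute
    separation.  The level of smaller magnitude is taken as closed
    (baseline-corrected traces).  Traces that are discrete (noiseless) are
    resolved exactly from their two dominant values.
    """
    x = trace.current
    uniq, counts_u = np.unique(x, return_counts=True)
    if uniq.size == 1:
        raise LevelDetectionError("constant trace: no second level to detect")
    if uniq.size <= 4:
        # effectively noiseless record: the two most common values are the levels
        top = uniq[np.argsort(counts_u)[::-1][:2]]
        lo, hi = sorted(map(float, top), key=abs)
        return LevelFit(lo, hi, abs(hi - lo), {"method": "discrete"})

    # robust split of the two amplitude clusters: iterate the midpoint
    # threshold between the cluster means (1-D two-means)
    c_lo, c_hi = float(x.min()), float(x.max())
    for _ in range(50):
        t = 0.5 * (c_lo + c_hi)
        below, above = x < t, x >= t
        if not below.any() or not above.any():
            raise LevelDetectionError("amplitude clusters collapsed; unimodal trace?")
        n_lo, n_hi = float(x[below].mean()), float(x[above].mean())
        if abs(n_lo - c_lo) < 1e-12 and abs(n_hi - c_hi) < 1e-12:
            break
        c_lo, c_hi = n_lo, n_hi

    counts, edges = np.histogram(x, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = max(3, counts.size // 50)
    smooth = np.convolve(counts, np.ones(width) / width, mode="same")
    i_lo = int(np.argmin(np.abs(centers - c_lo)))
    i_hi = int(np.argmin(np.abs(centers - c_hi)))
    if i_hi - i_lo < 2:
        raise LevelDetectionError("amplitude clusters unresolved at histogram scale")
    peak_lo, peak_hi = smooth[i_lo], smooth[i_hi]
    valley = smooth[i_lo : i_hi + 1].min()
    if valley > 0.7 * min(peak_lo, peak_hi):
        raise LevelDetectionError(
            "all-points histogram is unimodal; trace must span both levels"
        )
    s0 = max((c_hi - c_lo) / 6.0, edges[1] - edges[0])
    p0 = [float(peak_lo), c_lo, s0, float(peak_hi), c_hi, s0]
    try:
        popt, _ = optimize.curve_fit(
            _two_gaussians, centers, counts, p0=p0, maxfev=5000
        )
    except RuntimeError as exc:
        raise LevelDetectionError(f"two-Gaussian histogram fit failed: {exc}") from None
    mu = sorted([float(popt[1]), float(popt[4])], key=abs)
    closed_level, open_level = mu
    resid = counts - _two_gaussians(centers, *popt)
    return LevelFit(
        closed_level,
        open_level,
        abs(open_level - closed_level),
        {
            "method": "two-gaussian",
            "sigmas": [abs(float(popt[2])), abs(float(popt[5]))],
            "residual_norm": float(np.linalg.norm(resid)),
            "n_bins": int(centers.size),
        },
    )


# ---------------------------------------------------------------------------
# idealization
# ---------------------------------------------------------------------------


def idealize(
    trace: CurrentTrace, levels: tuple | LevelFit | None = None, dead_time: float = 0.3
) -> IdealizedTrace:
    """Half-amplitude threshold idealization with dead-time merging.

    The threshold is the midpoint of the closed and open levels; threshold
    crossings define events, and events shorter than ``dead_time`` (ms) are
    merged into their neighbours until none remain.  States alternate by
    construction and durations sum exactly to the trace span.
    """
    if levels is None:
        levels = detect_levels(trace)
    if isinstance(levels, LevelFit):
        closed, open_ = levels.closed_level, levels.open_level
    else:
        closed, open_ = levels
    span_ms = trace.current.size / trace.fs * 1000.0
    if dead_time >= span_ms:
        raise InvalidParameterError("dead_time exceeds the trace span")
    thresh = 0.5 * (closed + open_)
    openside = (trace.current > thresh) if open_ > closed else (trace.current < thresh)
    change = np.flatnonzero(openside[1:] != openside[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [openside.size]))
    dt_ms = 1000.0 / trace.fs
    events = [
        ["open" if openside[s] else "closed", (e - s) * dt_ms]
        for s, e in zip(starts, ends)
    ]
    # merge sub-dead-time events into neighbours (shortest first)
    while len(events) > 1:
        durs = [d for _, d in events]
        i = int(np.argmin(durs))
        if durs[i] >= dead_time:
            break
        if 0 < i < len(events) - 1:
            events[i - 1][1] += events[i][1] + events[i + 1][1]
            del events[i : i + 2]
        elif i == 0:
            events[1][1] += events[0][1]
            del events[0]
        else:
            events[-2][1] += events[-1][1]
            del events[-1]
    return IdealizedTrace([(s, float(d)) for s, d in events], dead_time=dead_time)


def open_probability(ideal: IdealizedTrace) -> float:
    """Fraction of total time spent in the open state."""
    total = ideal.total_ms
    if total <= 0:
        raise InsufficientDataError("empty idealized trace")
    return float(sum(d for s, d in ideal.events if s == "open") / total)


def unitary_conductance(iv: Sequence[tuple]) -> tuple[float, float]:
    """Slope conductance (pS) and reversal potential (mV) from i-V pairs.

    ``iv`` is a sequence of (voltage mV, unitary current pA); a least-squares
    line gives gamma = slope x 1000 (pA/mV -> pS) and reversal =
    -intercept/slope.
    """
    v = np.array([p[0] for p in iv], dtype=float)
    i = np.array([p[1] for p in iv], dtype=float)
    if np.unique(v).size < 3:
        raise InsufficientDataError("need >= 3 distinct voltages")
    res = stats.linregress(v, i)
    if res.slope == 0:
        raise FitFailureError("zero slope: reversal potential undefined")
    return float(res.slope * 1000.0), float(-res.intercept / res.slope)


# ---------------------------------------------------------------------------
# dwell-time mixtures
# ---------------------------------------------------------------------------


@dataclass
class DwellMixtureResults:
    """Exponential-mixture fit of dwell durations.

    ``components`` is a list of (mean_ms, weight) sorted by increasing mean,
    reported in the *untruncated* parameterization (weights corrected for
    the dead-time truncation).  ``loglik`` and ``bic`` refer to the
    truncated likelihood actually maximised.
    """

    components: list
    n_events: int
    loglik: float
    bic: float
    dead_time: float
    converged: bool
    n_iter: int
    degenerate: bool = False
    loglik_trace: np.ndarray = field(default=None, repr=False)

    @property
    def means(self) -> np.ndarray:
        return np.array([m for m, _ in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    def summary(self) -> str:
        lines = [
            f"Exponential dwell-time mixture (k={len(self.components)}, "
            f"n={self.n_events}, dead time {self.dead_time:g} ms)",
            "=" * 56,
            f"{'component':<12}{'mean (ms)':>12}{'weight':>10}",
        ]
        for j, (m, w) in enumerate(self.components, 1):
            lines.append(f"{j:<12}{m:>12.3f}{w:>10.3f}")
        lines.append(f"log-likelihood {self.loglik:.3f}   BIC {self.bic:.3f}")
        if self.degenerate:
            lines.append("WARNING: degenerate fit (components collapsed)")
        return "\n".join(lines)

    def plot(self, durations=None, ax=None):
        """Log-binned dwell histogram with the fitted mixture density."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if durations is not None:
            d = np.asarray(durations, dtype=float)
            bins = np.logspace(np.log10(d.min()), np.log10(d.max()), 30)
            ax.hist(d, bins=bins, density=True, alpha=0.4, label="dwells")
        t = np.logspace(
            np.log10(max(self.dead_time, self.means.min() / 50)),
            np.log10(self.means.max() * 5),
            200,
        )
        pdf = np.zeros_like(t)
        for m, w in self.components:
            pdf += w / m * np.exp(-t / m)
        ax.plot(t, pdf, label="mixture fit")
        ax.set_xscale("log")
        ax.set_xlabel("dwell (ms)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class DwellMixtureModel:
    """Maximum-likelihood exponential mixture for left-truncated dwells.

    Durations below the recording dead time are unobservable, so the
    likelihood is conditioned on ``t >= dead_time``.  Because exponentials
    are memoryless the shifted data ``t - dead_time`` follow an ordinary
    exponential mixture with the same component means and reweighted
    mixture proportions; EM runs on the shifted data and the weights are
    un-truncated afterwards, ``w_j ∝ w'_j exp(dead_time / tau_j)``.
    """

    def __init__(self, durations, k: int, dead_time: float = 0.0):
        d = np.asarray(durations, dtype=float).ravel()
        if k < 1:
            raise InvalidParameterError("k must be >= 1")
        if dead_time < 0:
            raise InvalidParameterError("dead_time must be >= 0")
        d = d[d >= dead_time]
        if d.size < 10 * k:
            raise InsufficientDataError(
                f"{d.size} events >= dead time; need >= {10 * k} for k={k}"
            )
        self.durations = d
        self.k = int(k)
        self.dead_time = float(dead_time)

    def _init_params(self):
        s = np.sort(self.durations - self.dead_time)
        s = np.maximum(s, 1e-12)
        # quantile-sliced means: scale-equivariant and spread across the range
        groups = np.array_split(s, self.k)
        means = np.array([max(g.mean(), 1e-12) for g in groups])
        weights = np.full(self.k, 1.0 / self.k)
        return means, weights

    def fit(self, tol: float = 1e-10, max_iter: int = 2000) -> DwellMixtureResults:
        s = self.durations - self.dead_time
        n = s.size
        means, weights = self._init_params()
        ll_trace = []
        ll_old = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            # E step in log space for numerical safety
            log_dens = np.log(weights)[:, None] - np.log(means)[:, None] - s[None, :] / means[:, None]
            log_norm = np.logaddexp.reduce(log_dens, axis=0)
            resp = np.exp(log_dens - log_norm[None, :])
            ll = float(np.sum(log_norm))
            ll_trace.append(ll)
            # M step
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            means = np.maximum(resp @ s / nk, 1e-12)
            weights = nk / n
            # scale-invariant stop: log-lik *changes* are invariant under
            # rescaling durations, |ll| itself is not
            if abs(ll - ll_old) < tol * max(1.0, float(n)):
                converged = True
                break
            ll_old = ll
        if not converged and self.k > 1:
            raise FitFailureError(
                "EM did not converge",
                diagnostics={"loglik_trace": ll_trace[-20:], "n_iter": it},
            )
        # undo the truncation reweighting: w_j ∝ w'_j exp(dead_time / tau_j)
        raw = weights * np.exp(np.minimum(self.dead_time / means, 700.0))
        weights_untrunc = raw / raw.sum()
        order = np.argsort(means)
        means, weights_untrunc = means[order], weights_untrunc[order]
        degenerate = bool(
            self.k > 1
            and np.any(np.diff(means) < 1e-6 * means[:-1].clip(min=1e-12))
        )
        n_params = 2 * self.k - 1
        bic = -2.0 * ll + n_params * math.log(n)
        return DwellMixtureResults(
            components=[(float(m), float(w)) for m, w in zip(means, weights_untrunc)],
            n_events=n,
            loglik=ll,
            bic=float(bic),
            dead_time=self.dead_time,
            converged=converged,
            n_iter=it,
            degenerate=degenerate,
            loglik_trace=np.asarray(ll_trace),
        )


def fit_dwell_mixture(durations, k: int, dead_time: float = 0.0) -> DwellMixtureResults:
    """Convenience wrapper: ``DwellMixtureModel(durations, k, dead_time).fit()``."""
    return DwellMixtureModel(durations, k, dead_time).fit()


def select_components(
    durations, dead_time: float = 0.0, k_max: int = 4
) -> DwellMixtureResults:
    """Scan k = 1..k_max exponential components, return the best fit by BIC."""
    best = None
    for k in range(1, k_max + 1):
        try:
            res = DwellMixtureModel(durations, k, dead_time).fit()
        except (InsufficientDataError, FitFailureError):
            continue
        if res.degenerate:
            continue
        if best is None or res.bic < best.bic:
            best = res
    if best is None:
        raise FitFailureError("no mixture size admitted a non-degenerate fit")
    return best


# ---------------------------------------------------------------------------
# flux
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxTimeCourse:
    """Radiotracer uptake counts over time with controls.

    ``background`` is the matched no-protein count level; ``valinomycin``
    the ionophore-mediated maximal uptake (liposome capacity).
    """

    times: np.ndarray
    counts: np.ndarray
    background: float
    valinomycin: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidParameterError("times and counts must be matched 1-D arrays")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise InvalidParameterError("times must be nonnegative and increasing")
        if self.valinomycin <= self.background:
            raise InvalidParameterError(
                "valinomycin counts must exceed background (capacity undefined)"
            )


def flux_normalize(fc: FluxTimeCourse) -> np.ndarray:
    """Valinomycin-normalized uptake: (counts - bg) / (valinomycin - bg)."""
    return (fc.counts - fc.background) / (fc.valinomycin - fc.background)


def relative_activity(normalized_at_120s: dict, reference: str) -> dict:
    """Per-lipid activity relative to the reference lipid's uptake."""
    if reference not in normalized_at_120s:
        raise InvalidParameterError(f"reference lipid {reference!r} missing")
    ref = normalized_at_120s[reference]
    if ref <= 0:
        raise InvalidParameterError("reference uptake must be > 0")
    return {k: float(v / ref) for k, v in normalized_at_120s.items()}
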