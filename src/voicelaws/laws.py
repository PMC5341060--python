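"""The four empirical laws, their threshold collapses and exponent relations.

For one event sequence at one threshold Theta the package measures:

* energy law ("Gutenberg-Richter"): the density P_Theta(E) of token energies,
  a power law E^(-phi) saturated by an exponential cutoff;
* Zipf's law: N_Theta(n), the number of types occurring exactly n times,
  decaying as n^(-zeta); the rank form n(r) ~ r^(-z) satisfies zeta = 1 + 1/z;
* Heaps' law: sublinear vocabulary growth V ~ L^alpha along the token stream;
* brevity law: type frequency against the type's mean token duration,
  M_Theta(t), monotonically decreasing with initial decay exponent beta.

Each law carries a *collapse* rescaling that removes the trivial dependence
on Theta: curves measured at different thresholds fall on one master curve
when the signal is threshold-invariant (the self-organized-criticality
signature), and fail to collapse for randomized surrogates.  The energy law
uses the moment rescaling E -> E<E>/<E^2>, P -> P <E^2>^2/<E>^3; Zipf uses
n -> n V/L with N/V on the ordinate (which preserves the sum rules
sum N = V, sum nN = L); Heaps rescales by its endpoint (L_max, V_max);
brevity rescales duration by the mean token duration with frequencies
already summing to one.  Collapse quality is scored as the mean pairwise
vertical offset between log-log interpolants on common support (0 = perfect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, ParameterError
from .powerlaw_fit import PowerLawMLE, log_bin
from .segmentation import EventSequence
from .symbolization import TypeSequence

__all__ = [
    "LawCurve",
    "ExponentSet",
    "LogLogSlope",
    "energy_distribution",
    "zipf_spectrum",
    "heaps_curve",
    "brevity_table",
    "collapse_curves",
    "exponent_relations",
    "heaps_exponent",
    "brevity_exponent",
    "zipf_exponent",
]


@dataclass
class LawCurve:
    """One empirical law at one threshold, plus its collapse-rescaled twin."""

    law_id: str                       # energy | zipf | heaps | brevity
    theta_percent: float | None
    x: np.ndarray
    y: np.ndarray
    x_rescaled: np.ndarray | None = None
    y_rescaled: np.ndarray | None = None
    moments: tuple[float, float] | None = None   # (<E>, <E^2>) for the energy law

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ParameterError("x and y must be 1-D arrays of equal length")
        if self.x.size > 1 and np.any(np.diff(self.x) <= 0):
            raise ParameterError("x must be strictly increasing")
        if np.any(self.y < 0):
            raise ParameterError("y must be nonnegative")


@dataclass
class ExponentSet:
    """The scaling exponents of the four laws, fitted or derived.

    ``provenance`` records per field whether the value was measured
    ("fitted") or filled in through an exponent identity ("derived").
    """

    phi: float | None = None          # energy-release exponent
    zeta: float | None = None         # Zipf spectrum exponent, N(n) ~ n^-zeta
    z: float | None = None            # Zipf rank exponent, n(r) ~ r^-z
    alpha: float | None = None        # Heaps growth exponent
    alpha_prime: float | None = None  # collapsed Heaps exponent, alpha/(1+alpha)
    beta: float | None = None         # brevity decay exponent
    provenance: dict = field(default_factory=dict)


# ------------------------------------------------------------------ law curves

def energy_distribution(events: EventSequence, ratio: float = 1.25) -> LawCurve:
    """Log-binned normalized density of token energies, with moments."""
    energies = events.token_energies
    if energies.size < 2:
        raise DegenerateDataError(
            f"need >= 2 tokens for a distribution, got {energies.size}")
    binned = log_bin(energies, ratio=ratio)
    return LawCurve(
        law_id="energy",
        theta_percent=events.threshold.theta_percent,
        x=binned.centers,
        y=binned.density,
        moments=(float(np.mean(energies)), float(np.mean(energies ** 2))),
    )


def zipf_spectrum(t: TypeSequence, theta_percent: float | None = None) -> LawCurve:
    """N(n): number of types that occur exactly n times.

    Satisfies sum_n N(n) = V and sum_n n N(n) = L exactly.
    """
    if t.L == 0:
        raise DegenerateDataError("empty type sequence")
    _, occ = np.unique(t.labels, return_counts=True)
    n_vals, n_counts = np.unique(occ, return_counts=True)
    return LawCurve(law_id="zipf", theta_percent=theta_percent,
                    x=n_vals.astype(np.float64), y=n_counts.astype(np.float64))


def heaps_curve(t: TypeSequence, theta_percent: float | None = None) -> LawCurve:
    """Vocabulary growth V(k): distinct types among the first k tokens."""
    if t.L == 0:
        raise DegenerateDataError("empty type sequence")
    # first occurrence flag per position, then cumulative count
    _, first_idx = np.unique(t.labels, return_index=True)
    new_type = np.zeros(t.L, dtype=np.int64)
    new_type[first_idx] = 1
    growth = np.cumsum(new_type)
    return LawCurve(law_id="heaps", theta_percent=theta_percent,
                    x=np.arange(1, t.L + 1, dtype=np.float64),
                    y=growth.astype(np.float64))


def brevity_table(
    t: TypeSequence, events: EventSequence, theta_percent: float | None = None
) -> LawCurve:
    """Type frequency versus the type's mean token duration, M_Theta(t).

    One row per type: the mean duration of its tokens (abscissa) and its
    relative frequency (ordinate, summing to one).  Types whose mean
    durations coincide exactly are merged.  A brevity law shows as a
    decreasing trend.
    """
    if t.L == 0:
        raise DegenerateDataError("empty type sequence")
    durations = events.token_durations_s
    if durations.size != t.L:
        raise ParameterError("type sequence and event sequence are misaligned")
    labels, inv = np.unique(t.labels, return_inverse=True)
    counts = np.bincount(inv)
    mean_dur = np.bincount(inv, weights=durations) / counts
    freq = counts / t.L

    order = np.argsort(mean_dur)
    xs, ys = mean_dur[order], freq[order]
    # merge exact duration ties so x stays strictly increasing
    uniq, inv2 = np.unique(xs, return_inverse=True)
    merged = np.bincount(inv2, weights=ys)
    if theta_percent is None and events.threshold is not None:
        theta_percent = events.threshold.theta_percent
    return LawCurve(law_id="brevity", theta_percent=theta_percent,
                    x=uniq, y=merged)


# -------------------------------------------------------------------- collapse

def _rescale(curve: LawCurve) -> LawCurve:
    x, y = curve.x, curve.y
    if curve.law_id == "energy":
        if curve.moments is None:
            raise ParameterError("energy curve lacks moments for the collapse")
        m1, m2 = curve.moments
        xr = x * m1 / m2
        yr = y * m2 ** 2 / m1 ** 3
    elif curve.law_id == "zipf":
        V = float(np.sum(y))
        L = float(np.sum(x * y))
        xr = x * V / L           # occurrences per mean tokens-per-type
        yr = y / V               # preserves sum N = V as unit mass
    elif curve.law_id == "heaps":
        xr = x / x[-1]
        yr = y / y[-1]
    elif curve.law_id == "brevity":
        mean_dur = float(np.sum(x * y) / np.sum(y))
        xr = x / mean_dur
        yr = y / np.sum(y)
    else:
        raise ParameterError(f"unknown law_id {curve.law_id!r}")
    return replace(curve, x_rescaled=xr, y_rescaled=yr)


def _pair_offset(a: LawCurve, b: LawCurve) -> float:
    """Median |log10 y_a - log10 y_b| over the common rescaled log-x support.

    The median (rather than the trapezoidal mean) keeps the score from being
    dominated by the sparsely populated histogram tail, where log-density
    estimates fluctuate by large factors even for well-collapsed curves.
    """
    def loggy(c: LawCurve) -> tuple[np.ndarray, np.ndarray]:
        keep = (c.y_rescaled > 0) & (c.x_rescaled > 0)
        return np.log10(c.x_rescaled[keep]), np.log10(c.y_rescaled[keep])

    xa, ya = loggy(a)
    xb, yb = loggy(b)
    lo, hi = max(xa.min(), xb.min()), min(xa.max(), xb.max())
    if hi <= lo:  # disjoint supports: fall back to offset of median levels
        return float(abs(np.median(ya) - np.median(yb)))
    grid = np.linspace(lo, hi, 200)
    fa = np.interp(grid, xa, ya)
    fb = np.interp(grid, xb, yb)
    return float(np.median(np.abs(fa - fb)))


def collapse_curves(curves: list[LawCurve]) -> tuple[list[LawCurve], float]:
    """Apply the law's collapse rescaling to every curve; score the overlap.

    Returns the rescaled curves and the mean pairwise vertical log-offset on
    common support (0 = perfect collapse, and 0 by convention for a single
    curve).  Lower is better; surrogate signals score visibly worse than
    threshold-invariant ones.
    """
    if not curves:
        raise ParameterError("no curves to collapse")
    ids = {c.law_id for c in curves}
    if len(ids) > 1:
        raise ParameterError(f"cannot collapse mixed laws {sorted(ids)}")
    rescaled = [_rescale(c) for c in curves]
    if len(rescaled) == 1:
        return rescaled, 0.0
    offsets = [
        _pair_offset(rescaled[i], rescaled[j])
        for i in range(len(rescaled))
        for j in range(i + 1, len(rescaled))
    ]
    return rescaled, float(np.mean(offsets))


# ---------------------------------------------------------- exponent relations

def _set_derived(es: ExponentSet, name: str, value: float, how: str) -> bool:
    if getattr(es, name) is None:
        setattr(es, name, value)
        es.provenance.setdefault(name, f"derived ({how})")
        return True
    return False


def exponent_relations(known: ExponentSet) -> ExponentSet:
    """Fill derivable exponents from the defining identities.

    zeta = 1 + 1/z,   zeta = 1 + alpha,   alpha' = alpha/(1 + alpha),
    and the prediction z ~ phi (used only when no measured Zipf exponent is
    available).  Purely algebraic; fitted values are never overwritten.
    """
    es = ExponentSet(**{k: getattr(known, k) for k in
                        ("phi", "zeta", "z", "alpha", "alpha_prime", "beta")},
                     provenance=dict(known.provenance))
    for name in ("phi", "zeta", "z", "alpha", "alpha_prime", "beta"):
        if getattr(es, name) is not None:
            es.provenance.setdefault(name, "fitted")

    if es.z is not None and es.z <= 0:
        raise ParameterError(f"rank exponent z must be positive, got {es.z}")
    if es.alpha_prime is not None and es.alpha_prime >= 1:
        raise ParameterError(
            f"collapsed Heaps exponent must be < 1, got {es.alpha_prime}")

    # prediction from the energy law only when Zipf was not measured
    if es.z is None and es.zeta is None and es.phi is not None:
        _set_derived(es, "z", es.phi, "z ~ phi prediction")

    changed = True
    while changed:
        changed = False
        if es.zeta is None and es.z is not None:
            changed |= _set_derived(es, "zeta", 1.0 + 1.0 / es.z, "zeta = 1 + 1/z")
        if es.z is None and es.zeta is not None:
            if es.zeta <= 1:
                raise ParameterError(f"zeta must exceed 1 to invert, got {es.zeta}")
            changed |= _set_derived(es, "z", 1.0 / (es.zeta - 1.0), "zeta = 1 + 1/z")
        if es.alpha is None and es.zeta is not None:
            changed |= _set_derived(es, "alpha", es.zeta - 1.0, "zeta = 1 + alpha")
        if es.zeta is None and es.alpha is not None:
            changed |= _set_derived(es, "zeta", 1.0 + es.alpha, "zeta = 1 + alpha")
        if es.alpha_prime is None and es.alpha is not None:
            changed |= _set_derived(
                es, "alpha_prime", es.alpha / (1.0 + es.alpha),
                "alpha' = alpha/(1+alpha)")
        if es.alpha is None and es.alpha_prime is not None:
            changed |= _set_derived(
                es, "alpha", es.alpha_prime / (1.0 - es.alpha_prime),
                "alpha' = alpha/(1+alpha)")
    return es


# ------------------------------------------------------------- slope estimators

class LogLogSlope(BaseEstimator):
    """Least-squares slope of log10 y against log10 x.

    Attributes after ``fit``: ``slope_``, ``intercept_``, ``stderr_``.
    """

    def fit(self, X, y) -> "LogLogSlope":
        x = np.asarray(X, dtype=np.float64).ravel()
        yv = np.asarray(y, dtype=np.float64).ravel()
        keep = (x > 0) & (yv > 0)
        x, yv = x[keep], yv[keep]
        if x.size < 3:
            raise DegenerateDataError("need >= 3 positive points for a slope")
        lx, ly = np.log10(x), np.log10(yv)
        (self.slope_, self.intercept_), cov = np.polyfit(lx, ly, 1, cov=True)
        self.stderr_ = float(np.sqrt(cov[0, 0]))
        return self


def heaps_exponent(
    curve: LawCurve, window: tuple[float, float] | None = None, n_points: int = 200
) -> float:
    """Heaps growth exponent alpha from a vocabulary-growth curve.

    Slope of log V against log L over the pre-saturation window, by default
    L in [10, 0.1 L_max].  The curve is subsampled at log-spaced L so the
    dense large-L region does not dominate the regression.
    """
    if curve.law_id != "heaps":
        raise ParameterError("expected a heaps curve")
    L_max = curve.x[-1]
    lo, hi = window if window is not None else (10.0, 0.1 * L_max)
    ks = np.unique(np.round(np.geomspace(max(lo, 1), min(hi, L_max), n_points))
                   .astype(np.int64))
    ks = ks[(ks >= 1) & (ks <= L_max)]
    fit = LogLogSlope().fit(ks, curve.y[ks - 1])
    return float(fit.slope_)


def brevity_exponent(
    curve: LawCurve, window: tuple[float, float] | None = None
) -> float:
    """Brevity decay exponent beta (positive) from a frequency-duration table.

    Fitted on the initial decay region: by default durations up to the
    median tabulated duration.
    """
    if curve.law_id != "brevity":
        raise ParameterError("expected a brevity curve")
    if window is None:
        window = (0.0, float(np.median(curve.x)))
    keep = (curve.x >= window[0]) & (curve.x <= window[1])
    fit = LogLogSlope().fit(curve.x[keep], curve.y[keep])
    return float(-fit.slope_)


def zipf_exponent(curve: LawCurve, discrete: bool = True,
                  xmin: float | None = 1.0) -> float:
    """Zipf spectrum exponent zeta by MLE on the occurrence counts.

    The spectrum N(n) is expanded back into one occurrence count per type
    and fitted as a (by default discrete) power-law sample.
    """
    if curve.law_id != "zipf":
        raise ParameterError("expected a zipf spectrum")
    samples = np.repeat(curve.x, curve.y.astype(np.int64))
    est = PowerLawMLE(xmin=xmin, discrete=discrete).fit(samples)
    return float(est.exponent_)
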