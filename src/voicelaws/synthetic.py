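"""Seedable generators with known ground truth for every pipeline stage.

The headline generator, :func:`synth_voice_signal`, emulates the statistical
skeleton the thresholding method assumes of voiced audio: an alternation of

* silence gaps whose durations follow a power law (exponent 2 by default,
  with an exponential cutoff around half a second at 16 kHz) and whose
  sample values sit at a low background-noise floor, and
* voice events whose *integrated* above-floor energies follow a power law
  of exponent ``phi_true`` with an exponential cutoff, spread over a
  duration T proportional to E^(1/duration_coupling) (default coupling 2,
  the usual avalanche geometry E ~ T^2, which also makes longer events carry
  more energy — the brevity-compatible direction), with lognormal scatter
  around the coupling law so the per-sample energy marginal spans several
  decades, under a unimodal raised-cosine within-event profile (so an event
  contributes at most one token at any threshold).

The generator returns its intended event list, so segmentation can be
checked against ground truth, plus the threshold percentage at which the
resolved energy separates floor from events exactly.

Also here: inverse-CDF continuous power-law sampling (with optional
exponential cutoff by rejection), exact discrete (zeta) power-law sampling,
i.i.d. Zipf-distributed token streams for Heaps/Zipf testing, and a
synthetic brevity table with a known decay exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta as hurwitz_zeta

from .errors import ParameterError
from .laws import LawCurve
from .signal_io import EnergySeries
from .symbolization import TypeSequence

__all__ = [
    "SynthSpec",
    "SynthGroundTruth",
    "powerlaw_samples",
    "zeta_samples",
    "synth_voice_signal",
    "zipf_stream",
    "brevity_synth",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def powerlaw_samples(
    exponent: float,
    xmin: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    cutoff: float | None = None,
) -> np.ndarray:
    """Continuous power-law samples p(x) ~ x^-exponent, x >= xmin.

    Inverse-CDF sampling x = xmin (1-u)^(-1/(exponent-1)); an exponential
    cutoff scale is applied by rejection with acceptance exp(-(x-xmin)/cutoff).
    """
    if exponent <= 1:
        raise ParameterError(f"exponent must exceed 1, got {exponent}")
    if xmin <= 0:
        raise ParameterError(f"xmin must be positive, got {xmin}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if cutoff is not None and cutoff <= xmin:
        raise ParameterError(f"cutoff {cutoff} must exceed xmin {xmin}")
    rng = _rng(seed)
    inv_exp = -1.0 / (exponent - 1.0)
    if cutoff is None:
        return xmin * (1.0 - rng.random(n)) ** inv_exp
    out = np.empty(0)
    while out.size < n:
        batch = max(2 * (n - out.size), 1000)
        x = xmin * (1.0 - rng.random(batch)) ** inv_exp
        keep = rng.random(batch) < np.exp(-(x - xmin) / cutoff)
        out = np.concatenate([out, x[keep]])
    return out[:n]


def zeta_samples(
    exponent: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    xmin: int = 1,
    table_max: int = 1_000_000,
) -> np.ndarray:
    """Discrete power-law (Hurwitz-zeta) samples, P(k) ~ k^-exponent, k >= xmin.

    Exact inverse-CDF sampling from a tabulated pmf up to ``table_max``; the
    (tiny) mass beyond the table is drawn from the continuous tail
    approximation and rounded.
    """
    if exponent <= 1:
        raise ParameterError(f"exponent must exceed 1, got {exponent}")
    rng = _rng(seed)
    k = np.arange(xmin, table_max + 1, dtype=np.float64)
    z_norm = hurwitz_zeta(exponent, xmin)
    cdf = np.cumsum(k ** -exponent) / z_norm
    u = rng.random(n)
    out = xmin + np.searchsorted(cdf, u).astype(np.float64)
    over = u > cdf[-1]
    if np.any(over):
        u2 = rng.random(int(over.sum()))
        out[over] = np.floor(
            (table_max + 0.5) * (1.0 - u2) ** (-1.0 / (exponent - 1.0)) + 0.5)
    return out


@dataclass
class SynthSpec:
    """Parameters of the synthetic voiced signal (defaults: speech-like at
    16 kHz, energy exponent 1.15 with a three-decade scaling range)."""

    phi_true: float = 1.15            # event-energy power-law exponent
    cutoff_scale: float = 1e6         # exponential cutoff of event energies
    energy_xmin: float = 1000.0       # smallest event energy; the unit is set
                                      # so that the default type bin width
                                      # resolves the smallest event into 1000
                                      # bins, giving the multi-decade dynamic
                                      # range voiced signals display
    silence_exponent: float = 2.0     # gap-duration power-law exponent
    silence_xmin_samples: int = 16    # shortest gap (1 ms at 16 kHz)
    silence_cutoff_samples: float = 2000.0   # gap cutoff (~1/8 s at 16 kHz)
    event_count: int = 5000
    duration_coupling: float = 2.0    # E ~ T^coupling (T = scale * E^(1/c))
    duration_scale: float = 64.0      # samples per unit E^(1/coupling):
                                      # events span ~4-130 ms, so voice
                                      # occupies ~90% of samples as the
                                      # threshold convention presumes
    duration_sigma: float = 1.0       # lognormal scatter of event durations
                                      # around the coupling law; spreads the
                                      # per-sample marginal over decades while
                                      # keeping events unimodal
    amplitude_sigma: float = 0.0      # optional lognormal within-event texture
                                      # (makes events multimodal: they then
                                      # fragment at intermediate thresholds)
    rate: float = 16000.0
    floor_level: float = 1e-6         # background-noise ceiling in silences
    profile_floor: float = 0.1        # raised-cosine pedestal
    profile_clip: float = 0.02        # hard lower clip of unnormalized weights,
                                      # keeps event samples well above the floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi_true <= 1:
            raise ParameterError(f"phi_true must exceed 1, got {self.phi_true}")
        if self.event_count < 0:
            raise ParameterError("event_count must be >= 0")
        if self.cutoff_scale <= self.energy_xmin:
            raise ParameterError(
                f"cutoff_scale {self.cutoff_scale} must exceed "
                f"energy_xmin {self.energy_xmin}")
        if self.duration_coupling <= 0 or self.duration_scale <= 0:
            raise ParameterError("duration coupling/scale must be positive")


@dataclass
class SynthGroundTruth:
    """The generator's intended event list and the threshold that recovers it."""

    token_starts: np.ndarray
    token_lengths: np.ndarray
    token_energies: np.ndarray
    design_theta_percent: float | None   # resolves exactly between floor and events
    spec: SynthSpec


def synth_voice_signal(spec: SynthSpec) -> tuple[EnergySeries, SynthGroundTruth]:
    """Build an energy series of alternating power-law gaps and events."""
    rng = np.random.default_rng(spec.seed)
    n_ev = spec.event_count

    gap_lens = np.maximum(
        np.round(powerlaw_samples(
            spec.silence_exponent, spec.silence_xmin_samples, n_ev + 1, rng,
            cutoff=spec.silence_cutoff_samples)).astype(np.int64),
        1,
    )
    if n_ev == 0:
        values = rng.uniform(0.0, spec.floor_level, int(gap_lens[0]))
        series = EnergySeries(values, spec.rate, source_label="synthetic-voice")
        gt = SynthGroundTruth(
            token_starts=np.empty(0, np.int64), token_lengths=np.empty(0, np.int64),
            token_energies=np.empty(0), design_theta_percent=None, spec=spec)
        return series, gt

    energies = powerlaw_samples(
        spec.phi_true, spec.energy_xmin, n_ev, rng, cutoff=spec.cutoff_scale)
    mean_T = (spec.duration_scale
              * (energies / spec.energy_xmin) ** (1.0 / spec.duration_coupling))
    if spec.duration_sigma > 0:
        mean_T = mean_T * rng.lognormal(0.0, spec.duration_sigma, n_ev)
    ev_lens = np.clip(np.round(mean_T).astype(np.int64), 2, int(spec.rate))

    total = int(gap_lens.sum() + ev_lens.sum())
    values = np.empty(total)
    starts = np.empty(n_ev, dtype=np.int64)
    pos = 0
    for i in range(n_ev):
        g = int(gap_lens[i])
        values[pos:pos + g] = rng.uniform(0.0, spec.floor_level, g)
        pos += g
        T = int(ev_lens[i])
        starts[i] = pos
        w = (1.0 - np.cos(2.0 * np.pi * (np.arange(T) + 0.5) / T)) / 2.0
        w += spec.profile_floor
        if spec.amplitude_sigma > 0:
            w *= rng.lognormal(0.0, spec.amplitude_sigma, T)
        w = np.maximum(w, spec.profile_clip)
        w /= w.sum()
        values[pos:pos + T] = energies[i] * w
        pos += T
    g = int(gap_lens[-1])
    values[pos:pos + g] = rng.uniform(0.0, spec.floor_level, g)

    n_sil = int(gap_lens.sum())
    # percentage that resolves the threshold to the largest floor sample:
    # rank floor(q N)+1 = n_sil  =>  q = (n_sil - 0.5)/N
    design_theta = 100.0 * (1.0 - (n_sil - 0.5) / total)
    series = EnergySeries(values, spec.rate, source_label="synthetic-voice")
    gt = SynthGroundTruth(
        token_starts=starts, token_lengths=ev_lens, token_energies=energies,
        design_theta_percent=design_theta, spec=spec)
    return series, gt


def zipf_stream(
    z: float,
    length: int,
    vocab: int | None = None,
    seed: int | np.random.Generator | None = None,
    table_max: int = 1_000_000,
) -> TypeSequence:
    """I.i.d. token stream with rank-frequency p(r) ~ r^-z.

    With a finite ``vocab`` the law is normalized over that many ranks.
    ``vocab=None`` emulates an unbounded vocabulary (z > 1 required for
    normalizability): the first ``table_max`` ranks are sampled exactly from
    the zeta-normalized law, and draws falling in the remaining tail mass —
    ranks so deep that two draws practically never coincide — each receive a
    fresh unique label.  For z near 1 that tail carries a sizable share of
    the mass, which is exactly what keeps vocabulary growth close to linear
    before the asymptotic L^(1/z) regime.
    """
    if z < 0:
        raise ParameterError(f"z must be >= 0, got {z}")
    if length < 1:
        raise ParameterError(f"length must be >= 1, got {length}")
    rng = _rng(seed)
    if vocab is not None:
        ranks = np.arange(1, vocab + 1, dtype=np.float64)
        cdf = np.cumsum(ranks ** -z)
        cdf /= cdf[-1]
        labels = np.searchsorted(cdf, rng.random(length))
        return TypeSequence(labels=labels.astype(np.int64))

    if z <= 1:
        raise ParameterError("unbounded vocabulary requires z > 1")
    ranks = np.arange(1, table_max + 1, dtype=np.float64)
    cdf = np.cumsum(ranks ** -z) / hurwitz_zeta(z, 1)   # ends below 1: tail mass
    labels = np.searchsorted(cdf, rng.random(length)).astype(np.int64)
    deep = labels == table_max
    labels[deep] = table_max + np.arange(int(deep.sum()))
    return TypeSequence(labels=labels)


def brevity_synth(
    beta: float,
    n_types: int,
    seed: int | np.random.Generator | None = None,
    duration_exponent: float = 1.8,
    duration_xmin_s: float = 0.005,
) -> LawCurve:
    """Synthetic brevity table with a known decay exponent.

    Type mean-durations are drawn from a power law (5 ms lower scale,
    intraphoneme-to-phoneme range); frequencies are assigned proportional to
    t^-beta and normalized, so the table decays with exponent exactly beta
    in expectation.
    """
    if beta <= 1:
        raise ParameterError(f"beta must exceed 1, got {beta}")
    if n_types < 2:
        raise ParameterError("need at least two types")
    rng = _rng(seed)
    t = np.sort(powerlaw_samples(duration_exponent, duration_xmin_s, n_types, rng))
    freq = t ** -beta
    freq /= freq.sum()
    # merge exact ties (measure-zero for continuous draws, but be safe)
    uniq, inv = np.unique(t, return_inverse=True)
    merged = np.bincount(inv, weights=freq)
    return LawCurve(law_id="brevity", theta_percent=None, x=uniq, y=merged)
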