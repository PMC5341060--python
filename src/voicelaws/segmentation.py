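"""Threshold segmentation of an energy series into voice events and silences.

The single free parameter of the whole method is the energy threshold Theta,
declared as the percentage of samples that remain at/above the resolved
energy level: Theta = 80% means 20% of the samples fall strictly below it.
A *token* (voice event) is a maximal run of consecutive samples with
eps(t) > threshold, carrying the duple (E_v, T_v): E_v is the instantaneous
energy summed over the run and T_v its duration.  Maximal runs at/below the
threshold are silence events of duration tau.  Samples exactly at the
threshold count as silence (the defining inequality is strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, ParameterError
from .signal_io import EnergySeries

__all__ = [
    "ThresholdSpec",
    "Token",
    "SilenceGap",
    "EventSequence",
    "resolve_threshold",
    "extract_events",
    "segment",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A percentage threshold and the energy value it resolves to."""

    theta_percent: float
    resolved_energy: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_percent < 100.0:
            raise ParameterError(
                f"theta_percent must lie in (0, 100), got {self.theta_percent}"
            )


@dataclass(frozen=True)
class Token:
    """One voice event: a maximal above-threshold run."""

    start_index: int
    length_samples: int
    duration_s: float
    energy: float


@dataclass(frozen=True)
class SilenceGap:
    """One silence event: a maximal at/below-threshold run."""

    start_index: int
    length_samples: int
    duration_s: float


@dataclass
class EventSequence:
    """Ordered tokens and silence gaps tiling one energy series at one threshold."""

    threshold: ThresholdSpec
    tokens: list[Token]
    silences: list[SilenceGap]
    series_length: int
    rate: float
    boundary_policy: str = "keep"
    n_dropped_edge_runs: int = 0

    @property
    def token_energies(self) -> np.ndarray:
        return np.array([t.energy for t in self.tokens], dtype=np.float64)

    @property
    def token_durations_s(self) -> np.ndarray:
        return np.array([t.duration_s for t in self.tokens], dtype=np.float64)

    @property
    def token_lengths(self) -> np.ndarray:
        return np.array([t.length_samples for t in self.tokens], dtype=np.int64)

    @property
    def silence_durations_s(self) -> np.ndarray:
        return np.array([s.duration_s for s in self.silences], dtype=np.float64)

    def to_frame(self):
        """Tokens and silences as one tidy DataFrame, in series order
        (columns: start_index, length_samples, duration_s, energy, kind,
        theta_percent; silences carry no energy)."""
        import pandas as pd

        rows = [
            (t.start_index, t.length_samples, t.duration_s, t.energy, "token")
            for t in self.tokens
        ] + [
            (s.start_index, s.length_samples, s.duration_s, np.nan, "silence")
            for s in self.silences
        ]
        rows.sort()
        df = pd.DataFrame(
            rows, columns=["start_index", "length_samples", "duration_s",
                           "energy", "kind"])
        df["theta_percent"] = self.threshold.theta_percent
        return df

    def __len__(self) -> int:
        return len(self.tokens)


def resolve_threshold(e: EnergySeries, theta_percent: float) -> ThresholdSpec:
    """Resolve a percentage threshold into an energy level.

    Returns the order statistic of rank floor(q*N) + 1 with
    q = (100 - theta_percent)/100, so that the fraction of samples strictly
    below the resolved energy is as close to q as ties permit and never
    exceeds q.  With theta_percent -> 100 the resolved energy is the series
    minimum (nothing falls below).
    """
    if not 0.0 < theta_percent < 100.0:
        raise ParameterError(f"theta_percent must lie in (0, 100), got {theta_percent}")
    values = e.values
    if values.max() == values.min():
        raise DegenerateDataError(
            "constant energy series: every value is tied, threshold undefined"
        )
    n = values.size
    q = (100.0 - theta_percent) / 100.0
    rank = int(np.floor(q * n))  # 0-based index of the (rank+1)-th smallest
    resolved = float(np.partition(values, rank)[rank])
    return ThresholdSpec(theta_percent=theta_percent, resolved_energy=resolved)


def _run_bounds(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal True-runs of a boolean mask."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return starts, ends - starts


def extract_events(
    e: EnergySeries, t: ThresholdSpec, boundary_policy: str = "keep"
) -> EventSequence:
    """Cut the series into tokens (eps > threshold) and silences (eps <= threshold).

    With ``boundary_policy="drop"`` the first and last run — which touch the
    series edge and are therefore truncated by the recording window — are
    removed from the token/silence lists; the number of removed runs is kept
    in ``n_dropped_edge_runs``.  Zero tokens is a legal outcome.
    """
    if boundary_policy not in ("keep", "drop"):
        raise ParameterError(f"boundary_policy must be keep|drop, got {boundary_policy}")
    values = e.values
    rate = e.rate
    mask = values > t.resolved_energy

    tok_starts, tok_lens = _run_bounds(mask)
    sil_starts, sil_lens = _run_bounds(~mask)

    # integrated energy per token via prefix sums
    if tok_starts.size:
        csum = np.concatenate(([0.0], np.cumsum(values)))
        tok_energy = csum[tok_starts + tok_lens] - csum[tok_starts]
    else:
        tok_energy = np.empty(0)

    dropped = 0
    if boundary_policy == "drop":
        n = values.size

        def edge(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
            return (starts == 0) | (starts + lens == n)

        tok_edge = edge(tok_starts, tok_lens) if tok_starts.size else np.empty(0, bool)
        sil_edge = edge(sil_starts, sil_lens) if sil_starts.size else np.empty(0, bool)
        dropped = int(tok_edge.sum()) + int(sil_edge.sum())
        tok_starts, tok_lens, tok_energy = (
            tok_starts[~tok_edge], tok_lens[~tok_edge], tok_energy[~tok_edge])
        sil_starts, sil_lens = sil_starts[~sil_edge], sil_lens[~sil_edge]

    tokens = [
        Token(int(s), int(l), l / rate, float(en))
        for s, l, en in zip(tok_starts, tok_lens, tok_energy)
    ]
    silences = [
        SilenceGap(int(s), int(l), l / rate) for s, l in zip(sil_starts, sil_lens)
    ]
    return EventSequence(
        threshold=t,
        tokens=tokens,
        silences=silences,
        series_length=values.size,
        rate=rate,
        boundary_policy=boundary_policy,
        n_dropped_edge_runs=dropped,
    )


def segment(
    e: EnergySeries, theta_percent: float, boundary_policy: str = "keep"
) -> EventSequence:
    """Convenience: resolve the threshold and extract events in one call."""
    return extract_events(e, resolve_threshold(e, theta_percent), boundary_policy)
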