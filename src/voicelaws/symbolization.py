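"""Mapping tokens to types by binning their integrated energies.

A *type* is the abstract "word" of the method: the equivalence class of all
tokens whose integrated energy E_v falls in the same bin.  The default is
linear binning with bin size b = 0.01 (in the units of the energy series,
i.e. squared normalized amplitude summed over samples): bin k collects
energies in the half-open interval [E0 + k*b, E0 + (k+1)*b).  The origin E0
defaults to the minimum observed token energy.  Two tokens in the same bin
share a type even when their durations differ.  Logarithmic type binning is
available as an alternative convention (bin width then counts decades:
k = floor(log10(E/E0)/b)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ParameterError
from .segmentation import EventSequence

__all__ = ["TypeSequence", "VocabularyStats", "assign_types", "vocabulary_stats"]


@dataclass
class TypeSequence:
    """Ordered type labels for a token stream, with vocabulary bookkeeping."""

    labels: np.ndarray                 # one integer bin label per token, in order
    bin_width: float | None = None     # None for symbol streams not born from binning
    origin: float | None = None
    binning: str = "linear"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ParameterError("labels must be 1-D")
        if self.labels.size and self.labels.min() < 0:
            raise ParameterError("labels must be nonnegative")

    @property
    def L(self) -> int:
        """Total number of tokens."""
        return int(self.labels.size)

    @property
    def V(self) -> int:
        """Vocabulary: number of distinct types."""
        return int(np.unique(self.labels).size)

    @property
    def type_token_ratio(self) -> float:
        return self.V / self.L

    def to_frame(self, events: "EventSequence | None" = None):
        """Token-order labels as a DataFrame (token_index, label, and — when
        the originating event sequence is passed — energy and duration_s)."""
        import pandas as pd

        df = pd.DataFrame({"token_index": np.arange(self.L), "label": self.labels})
        if events is not None:
            df["energy"] = events.token_energies
            df["duration_s"] = events.token_durations_s
        return df

    def __len__(self) -> int:
        return self.L


@dataclass(frozen=True)
class VocabularyStats:
    V: int
    L: int
    type_token_ratio: float


def _half_open_bins(x: np.ndarray, origin: float, width: float) -> np.ndarray:
    """floor((x - origin)/width) with exact half-open edges.

    Plain floating floor can put a value sitting exactly on a bin edge in the
    lower bin (e.g. (0.015-0.005)/0.01 -> 0.999...8); the correction below
    enforces [origin + k*w, origin + (k+1)*w) against the computed edges
    themselves.
    """
    k = np.floor((x - origin) / width).astype(np.int64)
    k += x >= origin + (k + 1) * width   # edge value belongs to the upper bin
    k -= x < origin + k * width
    return k


def assign_types(
    events: EventSequence,
    bin_width: float = 0.01,
    origin: float | str = "min-energy",
    binning: str = "linear",
) -> TypeSequence:
    """Assign an energy-bin label (the type) to every token, in token order."""
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    if binning not in ("linear", "log"):
        raise ParameterError(f"binning must be linear|log, got {binning}")
    energies = events.token_energies
    if energies.size == 0:
        raise DegenerateDataError("no tokens to symbolize")

    if binning == "log":
        if np.any(energies <= 0):
            raise ParameterError("log binning requires strictly positive energies")
        x = np.log10(energies)
        e0 = float(x.min()) if origin == "min-energy" else float(np.log10(origin))
    else:
        x = energies
        e0 = float(x.min()) if origin == "min-energy" else float(origin)
    if np.any(x < e0):
        raise ParameterError("explicit origin exceeds the smallest token energy")

    labels = _half_open_bins(x, e0, bin_width)
    origin_out = e0 if binning == "linear" else 10.0 ** e0
    return TypeSequence(labels=labels, bin_width=bin_width, origin=origin_out,
                        binning=binning)


def vocabulary_stats(t: TypeSequence) -> VocabularyStats:
    """Vocabulary size V, token count L and the type/token ratio V/L."""
    if t.L == 0:
        raise DegenerateDataError("empty type sequence")
    return VocabularyStats(V=t.V, L=t.L, type_token_ratio=t.V / t.L)
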