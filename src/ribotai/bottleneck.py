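"""Bottleneck scan and the analytic ribosome traffic-jam condition.

The bottleneck of a coding sequence is the fixed-length window of ``n`` codons
whose harmonic mean of codon weights ``w`` is minimal — equivalently, since
1/w is the codon's translation time, the window with the largest mean time.
Its strength is the mean 1/w inside the window; the relative forms divide the
start index by the number of possible windows and the strength by the
gene-wide mean time, so genes of different lengths and compositions compare.

The window size defaults to 21 codons, derived from the mean center-to-center
spacing of ribosomes on bacterial polysomes (21.6 nm at 0.34 nm per base,
i.e. about 21 codons); the bare ribosome footprint is 10 codons.

Under fast initiation, a trailing ribosome separated by ``H`` codons collides
with the leader iff some window of ``H`` codons takes strictly longer to
translate than the first window plus the initiation assembly time ``B``:
``Tw(k, H) > Tw(1, H) + B``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codon_model import CodingSequence, CodonWeightTable, time_profile

__all__ = [
    "DEFAULT_WINDOW_N",
    "RIBOSOME_SPACING_NM",
    "NM_PER_BASE",
    "BottleneckResult",
    "JamPrediction",
    "GeneTooShortError",
    "find_bottleneck",
    "window_size_from_spacing",
    "predict_jam",
]

RIBOSOME_SPACING_NM = 21.6
NM_PER_BASE = 0.34
DEFAULT_WINDOW_N = 21


class GeneTooShortError(ValueError):
    """Gene has fewer codons than the scan window."""


@dataclass(frozen=True)
class BottleneckResult:
    """Location and strength of a gene's slowest-translated window.

    ``location_k`` is 1-based (first codon of the window), so
    ``relative_location = location_k / (length_l - window_n + 1)`` lies in
    (0, 1].  ``strength`` is the mean 1/w inside the window (>= 1);
    ``relative_strength`` divides it by the gene-wide mean 1/w.
    """

    gene_id: str
    length_l: int
    window_n: int
    location_k: int
    strength: float
    relative_location: float
    relative_strength: float


@dataclass(frozen=True)
class JamPrediction:
    """Outcome of the analytic traffic-jam condition Tw(k,H) > Tw(1,H) + B."""

    jam: bool
    argmax_k: int
    max_window_time: float
    reference_time: float


def _window_sums(times: np.ndarray, n: int) -> np.ndarray:
    # per-window direct summation (not a cumsum difference), so results and
    # tie-breaks are bit-identical to summing each slice independently
    return np.lib.stride_tricks.sliding_window_view(times, n).sum(axis=1)


def find_bottleneck(
    seq: CodingSequence, weights: CodonWeightTable, n: int = DEFAULT_WINDOW_N
) -> BottleneckResult:
    """Locate the window of ``n`` codons with minimal harmonic-mean weight.

    Ties are broken toward the leftmost (most proximal) window.  Raises
    :class:`GeneTooShortError` when the gene has fewer than ``n`` codons.
    """
    if n < 1:
        raise ValueError(f"window size must be >= 1, got {n}")
    l = seq.length_l
    if l < n:
        raise GeneTooShortError(
            f"gene {seq.id!r} has {l} codons, shorter than window n={n}"
        )
    times = time_profile(seq, weights)
    sums = _window_sums(times, n)
    # minimal harmonic mean of w == maximal summed time; argmax is leftmost.
    idx = int(np.argmax(sums))
    strength = float(sums[idx] / n)
    return BottleneckResult(
        gene_id=seq.id,
        length_l=l,
        window_n=n,
        location_k=idx + 1,
        strength=strength,
        relative_location=(idx + 1) / (l - n + 1),
        relative_strength=strength / float(times.mean()),
    )


def window_size_from_spacing(
    distance_nm: float = RIBOSOME_SPACING_NM, nm_per_base: float = NM_PER_BASE
) -> int:
    """Convert a ribosome-to-ribosome distance to a window size in codons."""
    if distance_nm <= 0 or nm_per_base <= 0:
        raise ValueError("distance and nm-per-base must both be positive")
    return round(distance_nm / nm_per_base / 3)


def predict_jam(profile: Sequence[float], H: int, B: float) -> JamPrediction:
    """Evaluate the traffic-jam condition on a per-codon time profile.

    A jam forms iff ``max_k Tw(k, H) > Tw(1, H) + B`` with strict inequality
    (at equality the trailing ribosome arrives exactly on time).  ``B`` is the
    ribosome assembly time on the start codon, in the same units as the
    profile; the argmax is the leftmost maximizing window, 1-based.
    """
    times = np.asarray(profile, dtype=float)
    if H < 1:
        raise ValueError(f"window H must be >= 1, got {H}")
    if times.size < H:
        raise ValueError(
            f"profile of length {times.size} is shorter than window H={H}"
        )
    if B < 0:
        raise ValueError(f"assembly time B must be >= 0, got {B}")
    sums = _window_sums(times, H)
    idx = int(np.argmax(sums))
    reference = float(sums[0] + B)
    max_time = float(sums[idx])
    return JamPrediction(
        jam=bool(max_time > reference),
        argmax_k=idx + 1,
        max_window_time=max_time,
        reference_time=reference,
    )
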