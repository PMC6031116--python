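"""GC skew, replication origin/terminus prediction, and circularization.

Bacterial chromosomes replicating bidirectionally from a single origin show
compositional strand asymmetry: the leading strand is G-rich, so the GC skew
(G - C)/(G + C) computed in sliding windows switches sign at the origin and
terminus.  The cumulative skew curve therefore has a global minimum at the
origin and a global maximum at the terminus.  A clean single-trough /
single-peak cumulative curve on a circularized assembly is evidence that the
assembly is correct, and the predicted origin is a natural coordinate to
rotate the genome start to.

Circularization here is the curation step of recognizing a terminal overlap
on a linear scaffold — the assembly walked around the circle and repeated
its own start — and trimming one copy of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoordinateError, DegenerateProfileError, DomainError


@dataclass
class SkewProfile:
    """Windowed GC skew along a sequence.

    ``positions`` are 1-based start coordinates of each window (strictly
    increasing); ``skew`` is (G - C)/(G + C) per window with N and A/T bases
    excluded from the counts; ``cumulative`` is the running sum of window
    skews.
    """

    window: int
    step: int
    seq_length: int
    circular: bool
    positions: np.ndarray
    skew: np.ndarray
    cumulative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "skew": self.skew,
                "cumulative": self.cumulative,
            }
        )


@dataclass(frozen=True)
class OriTerCall:
    """Predicted replication origin and terminus (1-based window centres)."""

    ori_pos: int
    ter_pos: int
    amplitude: float


def gc_skew(
    seq: str, window: int = 1000, step: int = 10, circular: bool = False
) -> SkewProfile:
    """Compute per-window and cumulative GC skew.

    Windows of ``window`` bp advance by ``step`` bp; with ``circular`` they
    wrap across the sequence end.  Bases other than G and C (including N and
    ambiguity codes) are excluded from the ratio; a window with no G or C
    gets skew 0.
    """
    if window < 1 or step < 1:
        raise DomainError(f"window and step must be >= 1, got {window}, {step}")
    n = len(seq)
    if n == 0:
        raise DomainError("empty sequence")
    if not circular and window > n:
        raise DomainError(
            f"window {window} exceeds sequence length {n} in linear mode"
        )

    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    if circular:
        is_g = np.concatenate([is_g, is_g])
        is_c = np.concatenate([is_c, is_c])
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    g = cum_g[starts + window] - cum_g[starts]
    c = cum_c[starts + window] - cum_c[starts]
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return SkewProfile(
        window=window,
        step=step,
        seq_length=n,
        circular=circular,
        positions=starts + 1,
        skew=skew,
        cumulative=np.cumsum(skew),
    )


def predict_ori_ter(profile: SkewProfile, invert: bool = False) -> OriTerCall:
    """Locate the replication origin and terminus from cumulative GC skew.

    Convention: the origin sits at the global minimum of the cumulative skew
    and the terminus at the global maximum (leading strand G-rich); pass
    ``invert=True`` for organisms with the opposite bias.  Ties break to the
    smallest coordinate.  Reported coordinates are window centres, wrapped
    around the sequence end for circular profiles.
    """
    cum = -profile.cumulative if invert else profile.cumulative
    if len(cum) == 0:
        raise DegenerateProfileError("empty skew profile")
    amplitude = float(cum.max() - cum.min())
    if amplitude < 1e-12:
        raise DegenerateProfileError(
            "cumulative skew is flat; no replication signal to call"
        )

    def centre(idx: int) -> int:
        start0 = int(profile.positions[idx]) - 1
        return (start0 + profile.window // 2) % profile.seq_length + 1

    return OriTerCall(
        ori_pos=centre(int(np.argmin(cum))),
        ter_pos=centre(int(np.argmax(cum))),
        amplitude=amplitude,
    )


def rotate_to_origin(seq: str, ori_pos: int) -> str:
    """Rotate a circular sequence so it starts at ``ori_pos`` (1-based)."""
    if not 1 <= ori_pos <= len(seq):
        raise CoordinateError(
            f"origin position {ori_pos} outside sequence of length {len(seq)}"
        )
    return seq[ori_pos - 1 :] + seq[: ori_pos - 1]


@dataclass(frozen=True)
class CircularizationResult:
    """Outcome of terminal-overlap trimming; not-circular is a value, not an error."""

    circular: bool
    sequence: str
    overlap_len: int
    mismatches: int


def circularize(
    seq: str,
    min_overlap: int = 100,
    max_mismatch_rate: float = 0.02,
    max_overlap: int | None = None,
) -> CircularizationResult:
    """Detect and trim a terminal overlap on a linear scaffold.

    Scans overlap lengths from ``max_overlap`` (default: half the sequence,
    capped at 20 kb) down to ``min_overlap`` for a prefix/suffix pair whose
    Hamming mismatch rate is at most ``max_mismatch_rate``; the longest such
    overlap wins and one copy is trimmed from the end.
    """
    if min_overlap < 10:
        raise DomainError(f"min_overlap must be >= 10, got {min_overlap}")
    n = len(seq)
    if max_overlap is None:
        max_overlap = min(n // 2, 20_000)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for k in range(min(max_overlap, n // 2), min_overlap - 1, -1):
        mism = int(np.count_nonzero(arr[:k] != arr[n - k :]))
        if mism <= max_mismatch_rate * k:
            return CircularizationResult(
                circular=True, sequence=seq[: n - k], overlap_len=k, mismatches=mism
            )
    return CircularizationResult(
        circular=False, sequence=seq, overlap_len=0, mismatches=0
    )
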