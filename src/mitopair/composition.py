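"""Strand compositional statistics: AT skew and GC content.

AT skew is (#A - #T) / (#A + #T) on the given strand; GC content is
(#G + #C) over all countable bases. Both are computed genome-wide and in
sliding windows (default 300 bp window, 25 bp step, matching the standard
circular-map presentation for mitogenomes). N bases never enter a count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class GlobalComposition:
    at_skew: float | None  # None when #A + #T == 0
    gc_content: float


def _counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in "ACGT"}


def global_composition(seq: str) -> GlobalComposition:
    """Genome-wide AT skew and GC content of one strand."""
    if not seq:
        raise CompositionError("empty sequence")
    c = _counts(seq.upper())
    total = sum(c.values())
    if total == 0:
        raise CompositionError("no countable (non-N) bases")
    at = c["A"] + c["T"]
    skew = (c["A"] - c["T"]) / at if at else None
    return GlobalComposition(at_skew=skew, gc_content=(c["G"] + c["C"]) / total)


@dataclass
class CompositionProfile:
    """Per-window AT-skew / GC-content track."""

    window_bp: int
    step_bp: int
    window_starts: np.ndarray  # 0-based
    at_skew: np.ndarray  # NaN where #A+#T == 0 in the window
    gc_content: np.ndarray
    global_at_skew: float | None
    global_gc: float

    def __len__(self) -> int:
        return len(self.window_starts)

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table; window_start is reported 1-based."""
        return pd.DataFrame({
            "window_start": self.window_starts + 1,
            "at_skew": self.at_skew,
            "gc_content": self.gc_content,
        })


def windowed_composition(genome: AnnotatedGenome | str,
                         window_bp: int = 300, step_bp: int = 25,
                         offset: int = 0) -> CompositionProfile:
    """Sliding-window composition profile.

    On a circular genome windows wrap modulo the length and there are
    ceil(L / step) of them; on a linear genome only fully contained windows
    are emitted. Windows are anchored at ``offset`` (default: position 0 of
    the record as deposited).
    """
    if isinstance(genome, AnnotatedGenome):
        seq, circular = genome.seq, genome.topology == "circular"
    else:
        seq, circular = genome.upper(), False
    if window_bp <= 0 or step_bp <= 0:
        raise CompositionError("window and step must be positive")
    L = len(seq)
    if not circular and window_bp > L:
        raise CompositionError(
            f"window {window_bp} exceeds linear genome length {L}")
    if circular:
        starts = np.arange(offset, offset + L, step_bp) % L
        ext = seq + seq[:min(window_bp, L)]
    else:
        starts = np.arange(offset, L - window_bp + 1, step_bp)
        ext = seq
    arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    cums = {b: np.concatenate(([0], np.cumsum(arr == ord(b))))
            for b in "ACGT"}
    eff_window = min(window_bp, L) if circular else window_bp
    n_wrap = 0 if circular else None
    if circular and window_bp > L:
        # full extra turns contribute whole-genome counts
        n_wrap = window_bp // L if window_bp % L else window_bp // L - 1
        eff_window = window_bp - n_wrap * L

    def wcount(base: str) -> np.ndarray:
        c = cums[base]
        out = c[starts + eff_window] - c[starts]
        if circular and n_wrap:
            out = out + n_wrap * c[L]
        return out

    a, c_, g, t = (wcount(b) for b in "ACGT")
    with np.errstate(invalid="ignore", divide="ignore"):
        at = (a + t).astype(float)
        skew = np.where(at > 0, (a - t) / np.where(at > 0, at, 1), np.nan)
        tot = (a + c_ + g + t).astype(float)
        gc = np.where(tot > 0, (g + c_) / np.where(tot > 0, tot, 1), np.nan)
    gcomp = global_composition(seq)
    return CompositionProfile(
        window_bp=window_bp, step_bp=step_bp, window_starts=starts,
        at_skew=skew, gc_content=gc,
        global_at_skew=gcomp.at_skew, global_gc=gcomp.gc_content,
    )
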