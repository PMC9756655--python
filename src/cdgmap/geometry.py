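"""Chromosome geometry: ori placement and ori-anchored gene coordinates.

Genes are mapped onto a 0-100% circle with the replication origin at 0 and
the terminus — assumed diametrically opposite ori on these circular
replicons — at 50. When no curated ori is supplied, a cumulative GC-skew
estimator places it: the leading strand of bacterial chromosomes is G-rich,
so the cumulative (G-C) running sum attains its minimum at ori and its
maximum near ter.
"""

from __future__ import annotations

import numpy as np

from .model import CdgmapError, GeneLocus, NormalizedPosition, OriCall

#: default skew window (bp)
DEFAULT_SKEW_WINDOW = 1000
#: two local minima closer than this fraction of the skew range -> ambiguous
AMBIGUITY_FRACTION = 0.05


def cumulative_gc_skew(sequence: str) -> np.ndarray:
    """Per-base cumulative skew S(i) = sum over j<=i of sign(base_j),
    with G -> +1, C -> -1, A/T/other -> 0."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    signs = np.zeros(arr.shape, dtype=np.int64)
    signs[arr == ord("G")] = 1
    signs[arr == ord("C")] = -1
    return np.cumsum(signs)


def estimate_ori_gcskew(
    sequence: str,
    window: int = DEFAULT_SKEW_WINDOW,
    replicon_id: str = "",
) -> OriCall:
    """Locate ori as the global minimum of the windowed cumulative GC skew.

    The per-base cumulative skew pins down the switch point exactly; the
    call is reported at window resolution as the midpoint (1-based) of the
    window containing that global minimum. Ambiguity is judged on the
    windowed curve: the call is flagged ambiguous when its two lowest
    (circular) local minima lie within 5% of the full skew range of each
    other — including the degenerate flat-skew case.

    Requires ``len(sequence) >= 10 * window``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(sequence)
    if n < 10 * window:
        raise CdgmapError(
            f"sequence length {n} shorter than 10 windows ({10 * window} bp)"
        )
    per_base = cumulative_gc_skew(sequence)
    # cumulative skew sampled at the end of each full window
    n_windows = n // window
    s = per_base[np.arange(1, n_windows + 1) * window - 1].astype(float)

    rng_span = float(s.max() - s.min())
    base_argmin = int(np.argmin(per_base))  # 0-based index of the switch
    win_idx = min(base_argmin // window, n_windows - 1)
    # window win_idx covers bases [win_idx*window+1, (win_idx+1)*window]
    ori = win_idx * window + window // 2 + 1

    ambiguous = False
    if rng_span == 0.0:
        ambiguous = True
    else:
        prev = np.roll(s, 1)
        nxt = np.roll(s, -1)
        is_min = (s < prev) & (s < nxt)  # strict circular local minima
        minima = np.sort(s[is_min])
        if minima.size == 0:
            ambiguous = True
        elif minima.size >= 2 and (minima[1] - minima[0]) < AMBIGUITY_FRACTION * rng_span:
            ambiguous = True

    return OriCall(replicon_id=replicon_id, ori=ori, method="gc_skew", ambiguous=ambiguous)


def ter_from_ori(ori: int, length_bp: int) -> int:
    """Terminus position, assumed opposite ori on the circle:
    ter = ((ori - 1 + floor(L/2)) mod L) + 1."""
    if not (1 <= ori <= length_bp):
        raise ValueError(f"ori {ori} outside [1, {length_bp}]")
    return (ori - 1 + length_bp // 2) % length_bp + 1


def normalized_position(locus: GeneLocus, ori: int, length_bp: int) -> NormalizedPosition:
    """Gene midpoint on the ori-anchored 0-100% scale.

    The representative point is the CDS midpoint on the unwrapped circle
    (wrap-around genes were normalized to start..end+L at read time, so the
    midpoint is already correct on the circle); the value is the clockwise
    arc fraction from ori, in percent.
    """
    if not (1 <= ori <= length_bp):
        raise ValueError(f"ori {ori} outside [1, {length_bp}]")
    m = locus.midpoint
    value = 100.0 * (((m - ori) % length_bp) / length_bp)
    if value >= 100.0:  # guard against float round-up at the seam
        value -= 100.0
    return NormalizedPosition(value)
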