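"""Spectral cleaning and the modified cosine score.

The cleaning operators reproduce the standard feature-based molecular
networking pre-processing: removal of fragment ions within +/-17 Da of the
precursor, and a rolling window filter keeping the top six fragments per
+/-50 Da window.  The modified cosine aligns peaks either directly or offset
by the precursor-mass difference, under a one-to-one assignment that
maximizes the summed products of sqrt-intensity weights.

Boundary convention: "within +/- W Da" is a closed interval (``<=``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra_io import Spectrum


@dataclass
class SimilarityParams:
    """Tolerances and thresholds of the networking step (all in Da except
    the unitless cosine threshold)."""

    precursor_removal_window: float = 17.0
    window_size: float = 50.0
    top_k_in_window: int = 6
    fragment_tol: float = 0.02
    precursor_tol: float = 0.02
    min_matched_peaks: int = 4
    min_cosine: float = 0.7
    #: peak-assignment strategy: "exact" (maximum-weight bipartite matching)
    #: or "greedy" (descending pairwise product, GNPS-style)
    assignment: str = "exact"

    def __post_init__(self) -> None:
        if min(self.precursor_removal_window, self.window_size,
               self.fragment_tol, self.precursor_tol) <= 0:
            raise ValueError("tolerances and windows must be > 0")
        if self.top_k_in_window < 1:
            raise ValueError("top_k_in_window must be >= 1")
        if self.assignment not in ("exact", "greedy"):
            raise ValueError(f"unknown assignment {self.assignment!r}")


def precursor_window_filter(s: Spectrum, window: float = 17.0) -> Spectrum:
    """Drop fragment peaks within ``window`` Da of the precursor (both
    sides, closed interval); other peaks and their order are untouched."""
    if window <= 0:
        raise ValueError("window must be > 0")
    keep = np.abs(s.mz - s.precursor_mz) > window
    return s.replace_peaks(s.peaks[keep])


def window_filter(s: Spectrum, window: float = 50.0, k: int = 6) -> Spectrum:
    """Keep a peak iff it ranks among the top ``k`` intensities within the
    +/-``window`` Da window centered on its own m/z.

    Intensity ties are broken in favor of the lower m/z, which makes the
    filter deterministic; it is also idempotent.
    """
    if window <= 0 or k < 1:
        raise ValueError("window must be > 0 and k >= 1")
    n = len(s.peaks)
    if n <= k:
        return s.replace_peaks(s.peaks.copy())
    mz, inten = s.mz, s.intensity
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        in_win = np.abs(mz - mz[i]) <= window
        idx = np.nonzero(in_win)[0]
        # rank by descending intensity then ascending m/z
        order = idx[np.lexsort((mz[idx], -inten[idx]))]
        keep[i] = i in order[:k]
    return s.replace_peaks(s.peaks[keep])


def clean_spectrum(s: Spectrum, params: SimilarityParams | None = None) -> Spectrum:
    """Apply both networking filters (precursor removal, then window
    filter) with the configured parameters."""
    p = params or SimilarityParams()
    return window_filter(precursor_window_filter(s, p.precursor_removal_window),
                         p.window_size, p.top_k_in_window)


def normalize_peaks(s: Spectrum) -> np.ndarray:
    """Square-root intensity weights scaled to unit Euclidean norm.

    Square-root weighting damps the dominance of base peaks and is the
    convention used by GNPS-style cosines, so scores stay comparable.
    """
    if len(s.peaks) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    w = np.sqrt(s.intensity)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return w / norm


def _candidate_pairs(a: Spectrum, b: Spectrum, wa: np.ndarray, wb: np.ndarray,
                     fragment_tol: float) -> list[tuple[int, int, float]]:
    """All (i, j, weight-product) pairs matchable directly or via the
    precursor-mass shift."""
    shift = a.precursor_mz - b.precursor_mz
    pairs: list[tuple[int, int, float]] = []
    for i, j in itertools.product(range(len(wa)), range(len(wb))):
        d_direct = abs(a.mz[i] - b.mz[j])
        d_shift = abs(a.mz[i] - (b.mz[j] + shift))
        if d_direct <= fragment_tol or d_shift <= fragment_tol:
            pairs.append((i, j, wa[i] * wb[j]))
    return pairs


def _assign_exact(pairs, n_a, n_b):
    cost = np.zeros((n_a, n_b))
    allowed = np.zeros((n_a, n_b), dtype=bool)
    for i, j, w in pairs:
        cost[i, j] = max(cost[i, j], w)
        allowed[i, j] = True
    rows, cols = linear_sum_assignment(cost, maximize=True)
    return [(i, j, cost[i, j]) for i, j in zip(rows, cols) if allowed[i, j]]


def _assign_greedy(pairs):
    chosen = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for i, j, w in sorted(pairs, key=lambda t: (-t[2], t[0], t[1])):
        if i not in used_a and j not in used_b:
            chosen.append((i, j, w))
            used_a.add(i)
            used_b.add(j)
    return chosen


def modified_cosine(a: Spectrum, b: Spectrum,
                    params: SimilarityParams | None = None) -> tuple[float, int]:
    """Modified cosine score and matched-peak count between two spectra.

    Peaks pair up when their m/z agree within ``fragment_tol`` either
    directly or after shifting by the precursor-mass difference; a
    one-to-one assignment maximizing the summed products of unit-norm
    sqrt-intensity weights gives the score.  Symmetric in its arguments and
    bounded in [0, 1].  Empty spectra score (0.0, 0).
    """
    p = params or SimilarityParams()
    if len(a.peaks) == 0 or len(b.peaks) == 0:
        return 0.0, 0
    # canonical argument order makes the result exactly symmetric,
    # including the matched-peak count under score ties
    if (b.precursor_mz, b.feature_id) < (a.precursor_mz, a.feature_id):
        a, b = b, a
    wa, wb = normalize_peaks(a), normalize_peaks(b)
    pairs = _candidate_pairs(a, b, wa, wb, p.fragment_tol)
    if not pairs:
        return 0.0, 0
    if p.assignment == "exact":
        chosen = _assign_exact(pairs, len(wa), len(wb))
    else:
        chosen = _assign_greedy(pairs)
    score = float(sum(w for _, _, w in chosen))
    return min(score, 1.0), len(chosen)
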