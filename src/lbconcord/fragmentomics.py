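"""Fragment-size (electropherogram) AUC analysis.

Cell-free DNA is dominated by ~167 bp mononucleosome-protected fragments,
while vesicle-carried DNA includes much longer fragments (up to several
kb).  The analysis integrates the bioanalyzer signal over two fixed
windows — short fragments 100–250 bp and long fragments 250–5500 bp — and
reports each as a percentage of the total DNA content (AUC over
100–5500 bp).  Marker peaks outside 100–5500 bp are excluded from the
total.  Integration is trapezoidal with linear interpolation at window
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import FragmentTrace

logger = logging.getLogger("lbconcord")

SHORT_WINDOW = (100.0, 250.0)
LONG_WINDOW = (250.0, 5500.0)
TOTAL_WINDOW = (100.0, 5500.0)


def auc_range(trace: FragmentTrace, lo: float, hi: float) -> float:
    """Trapezoidal integral of the trace signal over [lo, hi] (signal·bp).

    The signal is linearly interpolated at the window edges; the part of
    the window outside the trace support contributes nothing.  An empty
    intersection yields 0 with a warning.
    """
    if not lo < hi:
        raise ValueError(f"window must satisfy lo < hi, got [{lo}, {hi}]")
    sizes, signal = trace.sizes_bp, trace.signal
    lo_eff = max(lo, float(sizes[0]))
    hi_eff = min(hi, float(sizes[-1]))
    if lo_eff >= hi_eff:
        logger.warning("window [%s, %s] does not intersect trace support "
                       "[%s, %s]", lo, hi, sizes[0], sizes[-1])
        return 0.0
    inside = (sizes > lo_eff) & (sizes < hi_eff)
    xs = np.concatenate(([lo_eff], sizes[inside], [hi_eff]))
    ys = np.interp(xs, sizes, signal)
    return float(np.trapezoid(ys, xs))


@dataclass
class FragmentFractions:
    short_auc: float
    long_auc: float
    short_percent: float
    long_percent: float


def long_fragment_fraction(trace: FragmentTrace) -> FragmentFractions:
    """Short (100–250 bp) and long (250–5500 bp) AUC shares of total DNA.

    Percentages are relative to the AUC over 100–5500 bp, so
    short% + long% = 100.  A zero total AUC is an error (no DNA signal in
    the analysis window).
    """
    short_auc = auc_range(trace, *SHORT_WINDOW)
    long_auc = auc_range(trace, *LONG_WINDOW)
    total = short_auc + long_auc
    if total <= 0.0:
        raise ValueError("total AUC over 100–5500 bp is zero; "
                         "fragment fractions undefined")
    return FragmentFractions(
        short_auc=short_auc, long_auc=long_auc,
        short_percent=100.0 * short_auc / total,
        long_percent=100.0 * long_auc / total)
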