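"""Exact Wilcoxon signed-rank test and normalized local sensitivity indices.

The Wilcoxon test is the paired, non-parametric comparison used for the
with/without-AAI planning results and for the PBPK-vs-CDR dose comparison:
zero differences are dropped, tied absolute differences receive average
ranks, and the two-sided p-value is obtained by full enumeration of the 2^n
sign assignments conditional on the observed |d| ranks (exact for n <= 20).

The sensitivity index of an output D with respect to a parameter P over a
scaling range (a, b) is SI = [(D(b P0) - D(a P0)) / D_ref] / [(b P0 - a P0) /
P_ref] with the lower-endpoint reference convention D_ref = D(a P0),
P_ref = a P0, so that an exactly linear response gives SI = 1 on every
range; the baseline-P0 reference is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["WilcoxonResult", "SensitivityResult", "wilcoxon_exact",
           "sensitivity_indices", "DEFAULT_SCALE_RANGES"]

#: the four scaling ranges (a, b): 100->10, 10->1, 1->0.1, 0.1->0.01
DEFAULT_SCALE_RANGES = ((100.0, 10.0), (10.0, 1.0), (1.0, 0.1), (0.1, 0.01))


@dataclass
class WilcoxonResult:
    n_effective: int
    W: float                  # sum of ranks of positive differences
    p_two_sided: float
    method: str = "exact-enumeration"
    zero_handling: str = "zero differences dropped before ranking"


def wilcoxon_exact(pairs) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired observations.

    ``pairs`` is a sequence of (x, y); differences d = x - y.  For more than
    20 non-zero differences the enumeration (2^n terms) is refused.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
        raise ValueError("need a non-empty sequence of (x, y) pairs")
    d = pairs[:, 0] - pairs[:, 1]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(n_effective=0, W=0.0, p_two_sided=1.0)
    if n > 20:
        raise ValueError(f"exact enumeration limited to 20 non-zero pairs, got {n}")
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())

    # distribution of W+ over all sign assignments, conditional on |d| ranks
    codes = np.arange(2 ** n, dtype=np.uint32)
    signs = (codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1
    w_all = signs @ ranks
    eps = 1e-9
    p_le = np.mean(w_all <= w_obs + eps)
    p_ge = np.mean(w_all >= w_obs - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(n_effective=n, W=w_obs, p_two_sided=float(p))


@dataclass
class SensitivityResult:
    parameter: str
    scale_range: tuple[float, float]
    si: float
    baseline_output: float
    error: str | None = None


def sensitivity_indices(evaluator, baseline_value: float, parameter: str,
                        ranges=DEFAULT_SCALE_RANGES, *,
                        reference: str = "lower") -> list[SensitivityResult]:
    """One-at-a-time normalized sensitivity of ``evaluator`` (a callable
    mapping the parameter value to the output, all other parameters held
    fixed) around ``baseline_value``.

    ``reference`` = "lower" uses the lower endpoint of each range as
    (D_ref, P_ref); "baseline" uses (D(P0), P0).
    """
    if reference not in ("lower", "baseline"):
        raise ValueError("reference must be 'lower' or 'baseline'")
    d0 = evaluator(baseline_value) if reference == "baseline" else None
    out: list[SensitivityResult] = []
    cache: dict[float, float] = {}

    def ev(scale: float) -> float:
        if scale not in cache:
            cache[scale] = float(evaluator(scale * baseline_value))
        return cache[scale]

    for a, b in ranges:
        try:
            da, db = ev(a), ev(b)
            if reference == "lower":
                d_ref, p_ref = da, a * baseline_value
            else:
                d_ref, p_ref = d0, baseline_value
            dd = (db - da) / d_ref
            dp = (b - a) * baseline_value / p_ref
            out.append(SensitivityResult(parameter=parameter, scale_range=(a, b),
                                         si=dd / dp, baseline_output=d_ref))
        except Exception as exc:  # per-range failure, others still returned
            out.append(SensitivityResult(parameter=parameter, scale_range=(a, b),
                                         si=float("nan"), baseline_output=float("nan"),
                                         error=str(exc)))
    return out
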