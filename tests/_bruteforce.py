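"""Independent brute-force evaluators used as oracles by the test suite.

Implemented with plain Python arithmetic (no numpy, no imports from the
package's selection code) so they constitute a second, independent encoding
of the selection rules and the binomial tail.
"""

from math import comb


def _floor(v: float, floor: float) -> float:
    return v if v > floor else floor


def brute_select(ref, test, floor=0.01, min_fpkm=1.0, coding=True):
    """Evaluate the full per-gene selection rule set step by step.

    Returns (selected, method, signed_fc, fpkm_diff); method is None when
    not selected.  Screen: protein-coding and >= min_fpkm in at least one
    compared sample.  Low-variability rule: both within-set floored max/min
    ratios strictly under 2, then the signed ratio of plain averages must
    reach 2-fold.  Range-separation rule (only for genes failing the
    variability gate): non-overlapping ranges, fold change and difference
    between the nearer extremes, 2-fold threshold.
    """
    ref = [float(v) for v in ref]
    test = [float(v) for v in test]
    if not coding or max(ref + test) < min_fpkm:
        return False, None, None, None

    def range_ratio(vals):
        return _floor(max(vals), floor) / _floor(min(vals), floor)

    if range_ratio(ref) < 2.0 and range_ratio(test) < 2.0:
        rm = sum(ref) / len(ref)
        tm = sum(test) / len(test)
        r = _floor(tm, floor) / _floor(rm, floor)
        fc = r if r >= 1.0 else -1.0 / r
        if abs(fc) >= 2.0:
            return True, "DELV", fc, tm - rm
        return False, None, None, None

    if min(test) > max(ref):
        fc = _floor(min(test), floor) / _floor(max(ref), floor)
        diff = min(test) - max(ref)
    elif max(test) < min(ref):
        fc = -(_floor(min(ref), floor) / _floor(max(test), floor))
        diff = max(test) - min(ref)
    else:
        return False, None, None, None
    if abs(fc) >= 2.0:
        return True, "SRMM", fc, diff
    return False, None, None, None


def brute_binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
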