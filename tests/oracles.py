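"""Independent re-implementations used as test oracles.

Everything here is deliberately written from the printed formulas with no
imports from the package under test, so that agreement between the two code
paths is meaningful.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

# ---------------------------------------------------------------------------
# direct-formula eGFR oracles
# ---------------------------------------------------------------------------
# Inputs: sex ("male"/"female"), age (y), cr (mg/dL), cysc (mg/L),
# bun (mg/dL), alb (g/dL), weight (kg), height (cm).
# Output: mL/min per 1.73 m^2.


def _bsa(weight: float, height: float) -> float:
    return weight**0.425 * height**0.725 * 0.007184


def cockcroft_gault(sex, age, cr, weight, height) -> float:
    v = (140.0 - age) * weight / (cr * 72.0)
    if sex == "female":
        v *= 0.85
    return v * 1.73 / _bsa(weight, height)


def mdrd(sex, age, cr, bun, alb) -> float:
    v = 170.0 * cr**-0.999 * age**-0.176 * bun**-0.170 * alb**0.318
    return v * 0.762 if sex == "female" else v


def abbrev_mdrd(sex, age, cr) -> float:
    v = 175.0 * cr**-1.154 * age**-0.203
    return v * 0.742 if sex == "female" else v


def cn_mdrd(sex, age, cr, bun, alb) -> float:
    return mdrd(sex, age, cr, bun, alb) * 1.202


def cn_abbrev_mdrd(sex, age, cr) -> float:
    v = 170.0 * cr**-0.999 * age**-0.176 * 1.202
    return v * 0.762 if sex == "female" else v


def ckd_epi_cr(sex, age, cr) -> float:
    if sex == "male":
        if cr <= 0.9:
            return 141.0 * (cr / 0.9) ** -0.411 * 0.993**age
        return 141.0 * (cr / 0.9) ** -1.209 * 0.993**age
    if cr <= 0.7:
        return 144.0 * (cr / 0.7) ** -0.329 * 0.993**age
    return 144.0 * (cr / 0.7) ** -1.209 * 0.993**age


def ckd_epi_cysc(sex, age, cysc) -> float:
    a = -0.499 if cysc <= 0.8 else -1.328
    v = 133.0 * (cysc / 0.8) ** a * 0.996**age
    return v * 0.932 if sex == "female" else v


def ckd_epi_cr_cysc(sex, age, cr, cysc) -> float:
    if sex == "male":
        c, knot = 135.0, 0.9
        a = -0.207 if cr <= 0.9 else -0.601
    else:
        c, knot = 130.0, 0.7
        a = -0.248 if cr <= 0.7 else -0.601
    b = -0.375 if cysc <= 0.8 else -0.711
    return c * (cr / knot) ** a * (cysc / 0.8) ** b * 0.995**age


def asian_ckd_epi_cr(sex, age, cr) -> float:
    if sex == "male":
        if cr <= 0.9:
            return 149.0 * (cr / 0.9) ** -0.415 * 0.993**age
        return 149.0 * (cr / 0.9) ** -1.210 * 0.993**age
    if cr <= 0.7:
        return 151.0 * (cr / 0.7) ** -0.328 * 0.993**age
    return 151.0 * (cr / 0.7) ** -1.210 * 0.993**age


def bis2(sex, age, cr, cysc) -> float:
    v = 767.0 * cysc**-0.610 * cr**-0.400 * age**-0.570
    return v * 0.870 if sex == "female" else v


def macisaac(cysc) -> float:
    return 86.700 / cysc - 4.200


def ruijin(sex, age, cr) -> float:
    v = 234.960 * cr**-0.926 * age**-0.280
    return v * 0.828 if sex == "female" else v


def xiangya(sex, age, cr_umol) -> float:
    v = 2374.780 * cr_umol**-0.54753 * age**-0.25011
    return v * 0.8526126 if sex == "female" else v


def oracle_value(equation: str, *, sex, age, cr, cysc, bun, alb, weight, height) -> float:
    """Dispatch by equation id string; cr in mg/dL, bun mg/dL, alb g/dL."""
    if equation == "cockcroft_gault":
        return cockcroft_gault(sex, age, cr, weight, height)
    if equation == "mdrd":
        return mdrd(sex, age, cr, bun, alb)
    if equation == "abbrev_mdrd":
        return abbrev_mdrd(sex, age, cr)
    if equation == "cn_mdrd":
        return cn_mdrd(sex, age, cr, bun, alb)
    if equation == "cn_abbrev_mdrd":
        return cn_abbrev_mdrd(sex, age, cr)
    if equation == "ckd_epi_cr":
        return ckd_epi_cr(sex, age, cr)
    if equation == "ckd_epi_cysc":
        return ckd_epi_cysc(sex, age, cysc)
    if equation == "ckd_epi_cr_cysc":
        return ckd_epi_cr_cysc(sex, age, cr, cysc)
    if equation == "asian_ckd_epi_cr":
        return asian_ckd_epi_cr(sex, age, cr)
    if equation == "bis2":
        return bis2(sex, age, cr, cysc)
    if equation == "macisaac":
        return macisaac(cysc)
    if equation == "ruijin":
        return ruijin(sex, age, cr)
    if equation == "xiangya":
        return xiangya(sex, age, cr * 88.4)
    raise ValueError(equation)


# ---------------------------------------------------------------------------
# brute-force split oracle
# ---------------------------------------------------------------------------

def _entropy_counts(counts: Dict) -> float:
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def _gain(labels: Sequence, left_idx: List[int], right_idx: List[int]) -> float:
    parent: Dict = {}
    for lab in labels:
        parent[lab] = parent.get(lab, 0) + 1
    left: Dict = {}
    for i in left_idx:
        left[labels[i]] = left.get(labels[i], 0) + 1
    right: Dict = {}
    for i in right_idx:
        right[labels[i]] = right.get(labels[i], 0) + 1
    n = len(labels)
    g = _entropy_counts(parent) - (
        len(left_idx) * _entropy_counts(left) + len(right_idx) * _entropy_counts(right)
    ) / n
    return max(g, 0.0)


def brute_force_best_split(
    columns: Dict[str, Tuple[str, Sequence]],
    labels: Sequence,
    *,
    min_samples_leaf: int = 1,
) -> Optional[Tuple[str, str, object, float]]:
    """Exhaustively enumerate every admissible split.

    ``columns`` maps variable name -> ("numeric"|"categorical", values).
    Returns (variable, kind, threshold-or-left-set, gain) with the same
    deterministic tie rules as the implementation: maximal gain (tolerance
    1e-12), then smallest variable name, then smallest threshold / smallest
    sorted left-category tuple; categorical partitions are canonicalized so
    the left side contains the lexicographically smallest level.
    """
    tol = 1e-12
    n = len(labels)
    best = None  # (gain, var, kindflag, key, payload)
    for var in sorted(columns):
        kind, values = columns[var]
        if kind == "numeric":
            vals = sorted(set(float(v) for v in values))
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2.0
                left = [i for i in range(n) if float(values[i]) <= thr]
                right = [i for i in range(n) if float(values[i]) > thr]
                if len(left) < min_samples_leaf or len(right) < min_samples_leaf:
                    continue
                g = _gain(labels, left, right)
                cand = (g, var, 0, thr, thr)
                best = _better(best, cand, tol)
        else:
            levels = sorted(set(str(v) for v in values))
            if len(levels) < 2:
                continue
            pinned, rest = levels[0], levels[1:]
            for r in range(0, len(rest)):
                for combo in itertools.combinations(rest, r):
                    left_set = frozenset((pinned,) + combo)
                    if len(left_set) == len(levels):
                        continue
                    left = [i for i in range(n) if str(values[i]) in left_set]
                    right = [i for i in range(n) if str(values[i]) not in left_set]
                    if len(left) < min_samples_leaf or len(right) < min_samples_leaf:
                        continue
                    g = _gain(labels, left, right)
                    cand = (g, var, 1, tuple(sorted(left_set)), left_set)
                    best = _better(best, cand, tol)
    if best is None:
        return None
    g, var, kindflag, _key, payload = best
    return var, ("numeric_threshold" if kindflag == 0 else "categorical_subset"), payload, g


def _better(best, cand, tol):
    if best is None:
        return cand
    if cand[0] > best[0] + tol:
        return cand
    if cand[0] < best[0] - tol:
        return best
    # tie: smaller (variable, kindflag, key)
    return cand if cand[1:4] < best[1:4] else best


# ---------------------------------------------------------------------------
# naive metric oracles
# ---------------------------------------------------------------------------

def naive_rmse(pred: Sequence[float], actual: Sequence[float]) -> float:
    s = 0.0
    for p, a in zip(pred, actual):
        s += (p - a) ** 2
    return math.sqrt(s / len(pred))


def naive_mae(pred: Sequence[float], actual: Sequence[float]) -> float:
    return sum(abs(p - a) for p, a in zip(pred, actual)) / len(pred)
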