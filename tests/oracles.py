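"""Independent brute-force oracles, written before the implementations they
check and kept free of any fatiguelab imports."""

from __future__ import annotations

import math


def grey_oracle(reference, factors, phi=0.5, preprocess="init_transform", denom="n"):
    """Step-by-step grey correlation degrees with plain Python loops.

    reference: list of floats; factors: dict name -> list of floats.
    Returns dict name -> gamma.
    """

    def init(seq):
        return [v / seq[0] for v in seq]

    def norm(seq):
        lo, hi = min(seq), max(seq)
        return [(v - lo) / (hi - lo) for v in seq]

    def prep(seq):
        seq = list(map(float, seq))
        if preprocess == "init_transform":
            return init(seq)
        if preprocess == "normalize":
            return norm(seq)
        if preprocess == "both":
            return init(norm(seq))
        return seq

    ref = prep(reference)
    n = len(ref)
    deltas = {}
    for name, seq in factors.items():
        f = prep(seq)
        deltas[name] = [abs(ref[k] - f[k]) for k in range(n)]

    min_min = min(min(d) for d in deltas.values())
    max_max = max(max(d) for d in deltas.values())

    gammas = {}
    for name, d in deltas.items():
        if max_max == 0:
            xi = [1.0] * n
        else:
            xi = [(min_min + phi * max_max) / (dk + phi * max_max) for dk in d]
        gammas[name] = sum(xi) / (n if denom == "n" else n - 1)
    return gammas


def rrsd_oracle(rr):
    """Two-pass population SD."""
    n = len(rr)
    mean = sum(rr) / n
    return math.sqrt(sum((v - mean) ** 2 for v in rr) / n)


def stage_metrics_oracle(matrix):
    """Count-based two-stage rates from expanded (actual, predicted) pairs.

    Returns nested dict {stage1: {...}, stage2: {...}} with None for
    undefined rates, mirroring the published worked-example conventions.
    """
    pairs = []
    for a in (1, 2, 3):
        for p in (1, 2, 3):
            pairs.extend([(a, p)] * int(matrix[a - 1][p - 1]))

    def div(num, den):
        return None if den == 0 else num / den

    n3 = sum(1 for a, _ in pairs if a == 3)
    n12 = sum(1 for a, _ in pairs if a != 3)
    s1 = {
        "sensitivity": div(sum(1 for a, p in pairs if a == 3 and p == 3), n3),
        "specificity": div(sum(1 for a, p in pairs if a != 3 and p == a), n12),
        "accuracy": div(sum(1 for a, p in pairs if (a == 3 and p == 3) or (a != 3 and p == a)), len(pairs)),
        "precision": div(
            sum(1 for a, p in pairs if a == 3 and p == 3),
            sum(1 for _, p in pairs if p == 3),
        ),
        "fp_rate": div(sum(1 for a, p in pairs if a != 3 and p == 3), n12),
        "fn_rate": div(sum(1 for a, p in pairs if a == 3 and p != 3), n3),
    }
    n1 = sum(1 for a, _ in pairs if a == 1)
    n2 = sum(1 for a, _ in pairs if a == 2)
    s2 = {
        "sensitivity": div(sum(1 for a, p in pairs if a == 2 and p == 2), n2),
        "specificity": div(sum(1 for a, p in pairs if a == 1 and p == 1), n1),
        "accuracy": div(
            sum(1 for a, p in pairs if a in (1, 2) and p == a), n1 + n2
        ),
        "precision": div(
            sum(1 for a, p in pairs if a == 2 and p == 2),
            sum(1 for a, p in pairs if a in (1, 2) and p == 2),
        ),
        "fp_rate": div(sum(1 for a, p in pairs if a == 1 and p == 2), n1),
        "fn_rate": div(sum(1 for a, p in pairs if a == 2 and p == 1), n2),
    }
    return {"stage1": s1, "stage2": s2}
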