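import pytest

from idrconstraint import (
    DisorderRegion,
    ProteinRecord,
    build_partition,
)


@pytest.fixture
def tiny_protein():
    return ProteinRecord("P1", "GENE1", 10)


@pytest.fixture
def tiny_partition(tiny_protein):
    """Protein of length 10 with one disordered region 3-5."""
    region = DisorderRegion("r1", "P1", 3, 5)
    return build_partition([tiny_protein], [region]), region


def brute_force_fisher_p(a, b, c, d):
    """Exhaustive two-sided Fisher p: enumerate every table with the observed
    margins and sum hypergeometric probabilities <= the observed one."""
    from math import comb

    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: comb(c1, k) * comb(n - c1, r1 - k) / denom for k in support}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-12))


def brute_force_average_precision(labels, scores):
    """AP by direct iteration of the definition with tied-score grouping."""
    import numpy as np

    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels, dtype=float)[order]
    s = np.asarray(scores, dtype=float)[order]
    n_pos = y.sum()
    ap, prev_recall, seen, tp = 0.0, 0.0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += y[j]
            seen += 1
            j += 1
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / seen)
        prev_recall = recall
        i = j
    return ap
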