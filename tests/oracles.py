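"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles (enumeration,
closed forms, scipy references) without touching the implementation paths it
checks.
"""

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats


def pooled_t(case: np.ndarray, ctrl: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t, case minus control."""
    n1, n2 = len(case), len(ctrl)
    v1, v2 = np.var(case, ddof=1), np.var(ctrl, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return float((case.mean() - ctrl.mean()) / sqrt(sp2 * (1 / n1 + 1 / n2)))


def exhaustive_cmi(zvalues, labels, gene_order, signs, max_k=20, denominator="j"):
    """Evaluate every DEG prefix activity and return (K, activity, tscores).

    ``gene_order`` indexes rows of ``zvalues`` ranked by descending |t|;
    ``signs`` are the per-gene t-score signs. Ties in the arg-max go to the
    smallest prefix; if no prefix has positive t, |t| decides.
    """
    tvals, acts = [], []
    for j in range(1, min(len(gene_order), max_k) + 1):
        div = j if denominator == "j" else sqrt(j)
        act = sum(zvalues[g] * s for g, s in zip(gene_order[:j], signs[:j])) / div
        acts.append(act)
        tvals.append(pooled_t(act[labels == 1], act[labels == -1]))
    tvals = np.asarray(tvals)
    if np.max(tvals) > 0:
        k = int(np.argmax(tvals)) + 1
    else:
        k = int(np.argmax(np.abs(tvals))) + 1
    return k, acts[k - 1], tvals


def pair_count_auc(scores, y) -> float:
    """Mann-Whitney AUC by O(n^2) concordant-pair counting; ties count 1/2."""
    pos = [s for s, yi in zip(scores, y) if yi == 1]
    neg = [s for s, yi in zip(scores, y) if yi == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def enumerate_hypergeom_tail(n, m, j, k) -> float:
    """P(overlap > k) by exhaustive enumeration of all C(n, j) signatures."""
    universe = range(n)
    reference = set(range(m))
    hits = sum(1 for draw in combinations(universe, j)
               if len(reference & set(draw)) > k)
    return hits / comb(n, j)


def welch_or_pooled_p(case, ctrl) -> float:
    return float(stats.ttest_ind(case, ctrl, equal_var=True).pvalue)
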