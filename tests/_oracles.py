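"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: metrics
are recomputed sample-by-sample with explicit loops, and Shapley values are
obtained by exact subset enumeration with factorial weights.
"""

from math import factorial

import numpy as np

N = 17


def brute_force_f1(pred, lab):
    out = []
    for g in range(N):
        tp = fp = fn = 0
        for p, l in zip(pred[:, g], lab[:, g]):
            tp += int(p and l)
            fp += int(p and not l)
            fn += int(not p and l)
        out.append(np.nan if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn))
    return np.array(out)


def brute_force_perfect_match(pred, lab):
    rows = {}
    for i in range(pred.shape[0]):
        g = int(lab[i].sum())
        exact = bool((pred[i] == lab[i]).all())
        n, k = rows.get(g, (0, 0))
        rows[g] = (n + 1, k + int(exact))
    return {g: (n, k, k / n) for g, (n, k) in rows.items()}


def brute_force_fpr_fnr(pred, lab):
    buckets = {}
    for i in range(pred.shape[0]):
        fp = tn = fn = tp = 0
        for p, l in zip(pred[i], lab[i]):
            tp += int(p and l)
            fp += int(p and not l)
            tn += int(not p and not l)
            fn += int(not p and l)
        g = int(lab[i].sum())
        fprs, fnrs = buckets.setdefault(g, ([], []))
        if fp + tn:
            fprs.append(fp / (fp + tn))
        if fn + tp:
            fnrs.append(fn / (fn + tp))
    return {
        g: (
            np.mean(fprs) if fprs else np.nan,
            np.mean(fnrs) if fnrs else np.nan,
        )
        for g, (fprs, fnrs) in buckets.items()
    }


def exact_shapley_subsets(f, x, starts, stops):
    """Exact Shapley values by enumerating all 2^n segment subsets."""
    n = len(starts)
    fact = [factorial(i) for i in range(n + 1)]
    # value of every coalition, batched
    masks = np.arange(2**n)
    batch = np.zeros((2**n, x.size), dtype=x.dtype)
    for s in range(n):
        rows = (masks >> s) & 1 == 1
        batch[rows, starts[s] : stops[s]] = x[starts[s] : stops[s]]
    values = f(batch)
    phi = np.zeros(n)
    for i in range(n):
        for m in range(2**n):
            if (m >> i) & 1:
                continue
            size = bin(m).count("1")
            w = fact[size] * fact[n - size - 1] / fact[n]
            phi[i] += w * (values[m | (1 << i)] - values[m])
    return phi
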