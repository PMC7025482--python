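"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive each quantity from its definition (exhaustive
enumeration, pairwise counting) and share no code with the package
implementation they check.
"""

import itertools

import numpy as np


def gini_impurity(y):
    y = np.asarray(y)
    p1 = y.mean()
    return 1.0 - p1 ** 2 - (1 - p1) ** 2


def exhaustive_best_gain(frame, y, min_bucket):
    """Maximal observed-fraction-scaled Gini gain over EVERY numeric
    threshold and EVERY proper category subset, by full enumeration."""
    y = np.asarray(y)
    n_node = len(y)
    best = 0.0
    for name in frame.columns:
        col = frame[name]
        obs = col.notna().to_numpy()
        nobs = int(obs.sum())
        if nobs < 2:
            continue
        yo = y[obs]
        parent = gini_impurity(yo)
        f_obs = nobs / n_node

        def child_gain(left_mask):
            nl = int(left_mask.sum())
            nr = nobs - nl
            if nl < min_bucket or nr < min_bucket:
                return None
            return (parent - (nl / nobs) * gini_impurity(yo[left_mask])
                    - (nr / nobs) * gini_impurity(yo[~left_mask])) * f_obs

        if col.dtype == object:
            levels = sorted(col.dropna().unique())
            vals = col[obs].to_numpy()
            for r in range(1, len(levels)):
                for subset in itertools.combinations(levels, r):
                    g = child_gain(np.isin(vals, subset))
                    if g is not None and g > best:
                        best = g
        else:
            vals = col[obs].to_numpy(dtype=float)
            for t in np.unique(vals)[:-1]:
                g = child_gain(vals <= t)
                if g is not None and g > best:
                    best = g
    return best


def pairwise_auc(labels, scores):
    """Mann-Whitney U statistic with half credit for ties, by explicit
    double loop over all (positive, negative) pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
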