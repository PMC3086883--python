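"""Independent brute-force oracles shared by the test suite.

Everything here is written from the mathematical definitions alone —
enumeration, dynamic programming or generic constrained optimization —
and never calls into the implementation paths it checks.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def string_oracle(s, t, d):
    """Count matching k-mers at matching offsets, k = 1..d, skipping any
    substring containing 'X'."""
    total = 0
    for k in range(1, d + 1):
        for i in range(len(s) - k + 1):
            u, v = s[i:i + k], t[i:i + k]
            if u == v and "X" not in u:
                total += 1
    return total


def spectrum_profile(s, dprime, g):
    """Explicit gapped-pattern profile: pattern = (length, wildcard position
    tuple, literal residues); wildcards interior-only, each placement its own
    feature; 'X' never matches a literal."""
    profile = {}
    for m in range(1, dprime + 1):
        for n_wild in range(0, min(g, max(m - 2, 0)) + 1):
            for wild in itertools.combinations(range(1, m - 1), n_wild):
                for start in range(len(s) - m + 1):
                    chunk = s[start:start + m]
                    lit = "".join(c for j, c in enumerate(chunk)
                                  if j not in wild)
                    if "X" in lit:
                        continue
                    key = (m, wild, lit)
                    profile[key] = profile.get(key, 0) + 1
    return profile


def spectrum_oracle(s, t, dprime, g):
    ps, pt = spectrum_profile(s, dprime, g), spectrum_profile(t, dprime, g)
    return sum(v * pt.get(k, 0) for k, v in ps.items())


def qp_oracle(K, y, C):
    """Generic constrained-QP solve of the soft-margin SVM dual (SLSQP);
    returns (alphas, dual objective)."""
    n = len(y)
    Q = np.outer(y, y) * K
    res = minimize(
        fun=lambda a: 0.5 * a @ Q @ a - a.sum(),
        x0=np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.x, -res.fun


def auc_pair_oracle(scores, labels):
    """O(n^2) Mann-Whitney oracle: average over all (pos, neg) pairs of
    1 / 0.5 / 0 for win / tie / loss."""
    pos = [s for s, l in zip(scores, labels) if l > 0]
    neg = [s for s, l in zip(scores, labels) if l <= 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
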