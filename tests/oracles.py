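"""Independent likelihood oracles for the EM tests.

These never call the EM path: the multilocus likelihood is rebuilt from
scratch by brute-force phase enumeration, and maximized either on a
vectorised simplex grid (tiny cases) or by direct numerical
optimization over a softmax parametrisation with seeded restarts.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def brute_force_configs(genotype):
    """All unordered compatible phase pairs by exhaustive assignment.

    Enumerates every per-locus allele ordering (2^h of them) and
    collapses unordered duplicates — deliberately redundant relative to
    the pinned-first-het enumeration it is used to check.
    """
    g = list(genotype)
    options = []
    for x in g:
        if x == 1:
            options.append([(0, 1), (1, 0)])
        else:
            a = x // 2
            options.append([(a, a)])
    seen = set()
    for combo in itertools.product(*options):
        a = tuple(p[0] for p in combo)
        b = tuple(p[1] for p in combo)
        seen.add((min(a, b), max(a, b)))
    return sorted(seen)


def loglik_bruteforce(dosage_rows, haplotypes, freqs):
    """Observed-data log-likelihood via brute-force enumeration."""
    idx = {h: i for i, h in enumerate(haplotypes)}
    f = np.asarray(freqs, dtype=float)
    ll = 0.0
    for g in dosage_rows:
        total = 0.0
        for a, b in brute_force_configs(g):
            if a in idx and b in idx:
                total += (2.0 if a != b else 1.0) * f[idx[a]] * f[idx[b]]
        if total <= 0:
            return -np.inf
        ll += np.log(total)
    return ll


def maximize_loglik(dosage_rows, haplotypes, n_restarts=50, seed=0):
    """Best log-likelihood over the frequency simplex (softmax + L-BFGS)."""
    K = len(haplotypes)

    def neg(x):
        e = np.exp(x - x.max())
        return -loglik_bruteforce(dosage_rows, haplotypes, e / e.sum())

    rng = np.random.default_rng(seed)
    best = None
    for start in [np.zeros(K)] + [rng.normal(size=K) for _ in range(n_restarts)]:
        r = minimize(neg, start, method="L-BFGS-B")
        if best is None or r.fun < best.fun:
            best = r
    e = np.exp(best.x - best.x.max())
    return -best.fun, e / e.sum()


def grid_max_loglik(dosage_rows, haplotypes, step=0.02):
    """Exhaustive simplex-grid maximizer for very small haplotype sets."""
    K = len(haplotypes)
    m = int(round(1.0 / step))
    best = -np.inf
    best_f = None
    for comp in itertools.combinations_with_replacement(range(K), m):
        f = np.bincount(comp, minlength=K) / m
        ll = loglik_bruteforce(dosage_rows, haplotypes, f)
        if ll > best:
            best, best_f = ll, f
    return best, best_f
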