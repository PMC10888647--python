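"""Brute-force oracles shared by the unit and acceptance suites.

These are deliberately independent of the implementations they check:
full enumeration only.
"""

import itertools

import numpy as np


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann–Whitney by enumerating all labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(pooled)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    obs = u_stat(x, y)
    mean = n * (m - n) / 2
    us = np.array([
        u_stat(pooled[list(idx)], np.delete(pooled, list(idx)))
        for idx in itertools.combinations(range(m), n)
    ])
    p = float(np.mean(np.abs(us - mean) >= abs(obs - mean) - 1e-12))
    return obs, p


def ora_enumeration_oracle(markers, pathway, universe):
    """P(hits >= observed) by exhaustive enumeration of draws."""
    eff = markers & universe
    hits = len(eff & pathway)
    tot = ge = 0
    for draw in itertools.combinations(sorted(universe), len(eff)):
        tot += 1
        ge += len(set(draw) & pathway) >= hits
    return ge / tot
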