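"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own code paths: slip feasibility is
decided by expanding every concrete primer variant and comparing characters,
and the PCR model is run molecule-by-molecule as a plain list.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_feasible(
    primer_seq: str,
    template: str,
    start: int,
    window: tuple[int, int] = (-1, 4),
    anchor_len: int = 5,
) -> list[int]:
    """All slips where some expanded variant's 3' anchor matches exactly."""
    L = len(primer_seq)
    variants = ["".join(v) for v in itertools.product(*(IUPAC[c] for c in primer_seq))]
    feasible = []
    for s in range(window[0], window[1] + 1):
        lo = start + s + L - anchor_len
        hi = start + s + L
        if lo < 0 or hi > len(template):
            continue
        tgt = template[lo:hi]
        if any(v[L - anchor_len:] == tgt for v in variants):
            feasible.append(s)
    return feasible


def naive_pcr_unslipped_fraction(
    q: float, e: float, c: int, n0: int, seed: int, cap: int = 200_000
) -> float:
    """Molecule-list PCR simulation, forward-only, unlimited capacity.

    Each molecule is a cumulative offset; copies slip +1 with probability q.
    The pool is truncated by uniform subsampling when it exceeds ``cap``.
    """
    rng = np.random.default_rng(seed)
    pool = [0] * n0
    for _ in range(c):
        copies = []
        for k in pool:
            if rng.random() < e:
                copies.append(k + 1 if rng.random() < q else k)
        pool.extend(copies)
        if len(pool) > cap:
            idx = rng.choice(len(pool), size=cap, replace=False)
            pool = [pool[i] for i in idx]
    return sum(1 for k in pool if k == 0) / len(pool)


def welch_p(a, b) -> float:
    """Two-sided Welch t-test p value from the textbook formulas."""
    import math

    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * tdist.sf(abs(t), df)
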