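"""Independent reference implementations (oracles) used by the tests.

Everything here is written from first principles — naive, O(n^2)/O(n^3)
or enumeration-based — and deliberately shares no code with the package,
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# naive character-by-character pileup base-string parser

def naive_parse_line(bases: str, quals: str, ref: str, min_baseq: int) -> dict:
    """Reference parser: walk the base string one character at a time and
    tally A/C/G/T counts of quality-passing substitution calls."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    qpos = 0
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            num = ""
            i += 1
            while bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        q = ord(quals[qpos]) - 33
        qpos += 1
        call = None
        if ch in ".,":
            call = ref
        elif ch.upper() in "ACGT":
            call = ch.upper()
        # '*', '>', '<', 'N'/'n' consume a quality but are not counted
        if call is not None and q >= min_baseq:
            counts[call] += 1
        i += 1
    assert qpos == len(quals)
    return counts


def random_pileup_line(rng: np.random.Generator, ref: str = "T") -> tuple[str, str]:
    """Generate a random but grammatical (bases, quals) pair."""
    n_reads = int(rng.integers(1, 40))
    bases = []
    quals = []
    alphabet = [".", ",", "A", "C", "G", "a", "c", "g", "N", "n", "*", ">", "<"]
    for k in range(n_reads):
        tok = str(rng.choice(alphabet))
        if rng.random() < 0.15:
            tok = "^" + chr(int(rng.integers(33, 90))) + tok
        if rng.random() < 0.1:
            tok = tok + "$"
        if rng.random() < 0.15:  # indel suffix after the base
            ln = int(rng.integers(1, 12))
            ins = "".join(rng.choice(list("ACGTacgt"), size=ln))
            tok = tok + ("+" if rng.random() < 0.5 else "-") + str(ln) + ins
        bases.append(tok)
        quals.append(chr(int(rng.integers(33, 75))))
    return "".join(bases), "".join(quals)


# ---------------------------------------------------------------------------
# exact hypergeometric enumeration for the Fisher test

def fisher_enumeration(n_bg: int, n_query: int, n_term: int, k: int,
                       two_sided: bool = True) -> float:
    """Exact Fisher p by full enumeration of possible overlap values."""
    lo = max(0, n_query + n_term - n_bg)
    hi = min(n_query, n_term)
    denom = comb(n_bg, n_query)
    pmf = {j: comb(n_term, j) * comb(n_bg - n_term, n_query - j) / denom
           for j in range(lo, hi + 1)}
    if two_sided:
        cutoff = pmf[k] * (1 + 1e-9)
        return sum(p for p in pmf.values() if p <= cutoff)
    return sum(p for j, p in pmf.items() if j >= k)


# ---------------------------------------------------------------------------
# brute-force Benjamini-Hochberg

def bh_bruteforce(pvals: np.ndarray) -> np.ndarray:
    """q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = min(1.0, running)
    return q


# ---------------------------------------------------------------------------
# O(n^3) agglomerative average linkage on a precomputed distance matrix

def average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage agglomeration (UPGMA on an
    arbitrary dissimilarity), sorted ascending."""
    clusters: dict[int, list[int]] = {i: [i] for i in range(dist.shape[0])}
    heights = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


# ---------------------------------------------------------------------------
# OLS by explicit normal equations

def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(beta, se) for y ~ X via (X'X)^-1 X'y and the classical variance."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se
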