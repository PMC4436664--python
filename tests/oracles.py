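"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the element definitions /
first principles, without reusing the package's algorithms, so tests can
compare two independent routes to the same answer.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# dot-bracket enumeration and decomposition scanning


def enumerate_dotbrackets(n: int) -> list[str]:
    """All balanced strings over '.', '(', ')' of length exactly n."""
    out: list[str] = []

    def rec(s: str, depth: int):
        if len(s) == n:
            if depth == 0:
                out.append(s)
            return
        rec(s + ".", depth)
        if n - len(s) > depth:
            rec(s + "(", depth + 1)
        if depth:
            rec(s + ")", depth - 1)

    rec("", 0)
    return out


class LonelyPair(Exception):
    pass


def scan_decomposition(db: str):
    """Literal corner-definition decomposition of a nested dot-bracket.

    Returns (stems, elements): stems as a set of corner quadruples,
    elements as a set of (kind, anchor, nucleotide tuple) including
    empty connectors (anchor = position of the preceding corner).
    Raises LonelyPair for isolated pairs.
    """
    n = len(db)
    partner = {}
    stack = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            i = stack.pop()
            partner[i] = pos
            partner[pos] = i
    arcs = {(i, partner[i]) for i in partner if i < partner[i]}

    stems = set()
    for i, j in sorted(arcs):
        if (i - 1, j + 1) in arcs:
            continue  # not the outermost pair of its run
        c1, c4 = i, j
        k = 0
        while (i + k + 1, j - k - 1) in arcs:
            k += 1
        stems.add((c1, i + k, j - k, c4))
    if any(c1 == c2 for c1, c2, c3, c4 in stems):
        raise LonelyPair(db)

    paired = sorted(partner)
    elements = set()

    def rng(a, b):
        return tuple(range(a, b + 1)) if a <= b else ()

    # 5' and 3' unpaired regions
    if not paired:
        if n:
            elements.add(("five_prime", 0, rng(1, n)))
        return stems, elements
    if paired[0] > 1:
        elements.add(("five_prime", 0, rng(1, paired[0] - 1)))
    if paired[-1] < n:
        elements.add(("three_prime", paired[-1], rng(paired[-1] + 1, n)))

    # hairpins: inner region of a stem with no paired nucleotide inside
    corner_role = {}
    for c1, c2, c3, c4 in stems:
        corner_role[c1] = ("c1", (c1, c2, c3, c4))
        corner_role[c2] = ("c2", (c1, c2, c3, c4))
        corner_role[c3] = ("c3", (c1, c2, c3, c4))
        corner_role[c4] = ("c4", (c1, c2, c3, c4))
    for c1, c2, c3, c4 in stems:
        if not any(c2 < p < c3 for p in paired):
            elements.add(("hairpin", c2, rng(c2 + 1, c3 - 1)))

    # gaps between consecutive paired positions, classified by corners
    gaps = {}
    for a, b in zip(paired, paired[1:]):
        if partner[a] == b:  # hairpin (possibly empty), already handled
            continue
        role_a, stem_a = corner_role.get(a, (None, None))
        role_b, stem_b = corner_role.get(b, (None, None))
        if role_a is None or role_b is None:
            continue  # interior of a stem run: consecutive paired
        if stem_a == stem_b:
            c1, c2, c3, c4 = stem_a
            if (c1 <= a < b <= c2) or (c3 <= a < b <= c4):
                continue  # both positions on the same stem strand
        gaps[(a, b)] = (role_a, stem_a, role_b, stem_b)

    consumed = set()
    # interior loops: both the c2->c1 and the matching c4->c3 gap exist
    for (a, b), (ra, sa, rb, sb) in gaps.items():
        if ra == "c2" and rb == "c1":
            back = (sb[3], sa[2])  # c4(inner stem) -> c3(outer stem)
            if back in gaps:
                nts = rng(a + 1, b - 1) + rng(back[0] + 1, back[1] - 1)
                elements.add(("interior_loop", a, nts))
                consumed.add((a, b))
                consumed.add(back)
    for (a, b) in gaps:
        if (a, b) in consumed:
            continue
        elements.add(("multiloop_segment", a, rng(a + 1, b - 1)))

    return stems, elements


def max_noncrossing_pairs(pairs: list[tuple[int, int]]) -> int:
    """Largest pairwise non-crossing subset, by exhaustive enumeration."""
    best = 0
    for r in range(len(pairs), 0, -1):
        if r <= best:
            break
        for sub in itertools.combinations(pairs, r):
            ok = True
            for (i, j), (k, l) in itertools.combinations(sub, 2):
                lo, hi = ((i, j), (k, l)) if i < k else ((k, l), (i, j))
                if lo[0] < hi[0] < lo[1] < hi[1]:
                    ok = False
                    break
            if ok:
                best = max(best, r)
                break
    return best


# ---------------------------------------------------------------------------
# numeric oracles


def kde_density_1d(x, samples, h):
    """Plain-loop Gaussian kernel sum."""
    total = 0.0
    for s in samples:
        total += np.exp(-0.5 * ((x - s) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    return total / len(samples)


def kde_density_nd(x, samples, hs):
    """Plain-loop product-kernel Gaussian sum in d dimensions."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for s in np.asarray(samples, dtype=float):
        term = 1.0
        for xd, sd, h in zip(x, s, hs):
            term *= np.exp(-0.5 * ((xd - sd) / h) ** 2) / (
                h * np.sqrt(2 * np.pi)
            )
        total += term
    return total / len(samples)


def segment_distance_bruteforce(p0, p1, q0, q1, n_grid: int = 201):
    """Min distance between two segments: dense grid + local refinement."""
    p0, p1, q0, q1 = (np.asarray(v, dtype=float) for v in (p0, p1, q0, q1))
    ss = np.linspace(0, 1, n_grid)

    def dist(v):
        s, t = np.clip(v, 0, 1)
        return np.linalg.norm((p0 + s * (p1 - p0)) - (q0 + t * (q1 - q0)))

    P = p0[None, :] + ss[:, None] * (p1 - p0)[None, :]
    Q = q0[None, :] + ss[:, None] * (q1 - q0)[None, :]
    d2 = ((P[:, None, :] - Q[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    res = minimize(
        dist,
        [ss[i], ss[j]],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14},
    )
    return min(float(res.fun), float(np.sqrt(d2[i, j])))


def _euler(a, b, c):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


def superpose_bruteforce(P, Q, n_grid: int = 14):
    """Min RMSD over rotations: euler-angle grid + local refinement."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(angles):
        R = _euler(*angles)
        return float(np.sqrt(((Qc @ R.T - Pc) ** 2).sum(axis=1).mean()))

    best = (np.inf, None)
    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    half = np.linspace(0, np.pi, n_grid)
    for a in grid:
        for b in half:
            for c in grid:
                val = rmsd_of((a, b, c))
                if val < best[0]:
                    best = (val, (a, b, c))
    res = minimize(
        rmsd_of,
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000},
    )
    return min(best[0], float(res.fun))
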