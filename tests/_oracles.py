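"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: GPR rules are generated
and evaluated as plain nested tuples, and linear programs are checked by
exhaustive vertex enumeration of the flux polytope (tractable for the <=6
reaction networks used in the tests).
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

# -- GPR reference ----------------------------------------------------------


def random_gpr_tuple(rng, genes, depth):
    """Random rule as nested tuples: ('gene', g) | ('and'|'or', [children])."""
    if depth <= 0 or rng.random() < 0.35:
        return ("gene", genes[rng.integers(len(genes))])
    op = "and" if rng.random() < 0.5 else "or"
    n = int(rng.integers(2, 4))
    return (op, [random_gpr_tuple(rng, genes, depth - 1) for _ in range(n)])


_AND_SPELLINGS = ["and", "AND", "&", "&&"]
_OR_SPELLINGS = ["or", "OR", "|", "||"]


def render_gpr(node, rng) -> str:
    """Render a tuple rule to a string with randomised operator spellings."""
    kind = node[0]
    if kind == "gene":
        return node[1]
    spellings = _AND_SPELLINGS if kind == "and" else _OR_SPELLINGS
    op = f" {spellings[rng.integers(len(spellings))]} "
    parts = []
    for child in node[1]:
        text = render_gpr(child, rng)
        if child[0] != "gene":
            text = f"({text})"
        parts.append(text)
    return op.join(parts)


def ref_eval(node, abundances, missing_policy="skip"):
    """Recursive reference evaluation: and -> min, or -> sum; None = undefined."""
    kind = node[0]
    if kind == "gene":
        if node[1] in abundances:
            return float(abundances[node[1]])
        return 0.0 if missing_policy == "zero" else None
    vals = [
        v
        for child in node[1]
        if (v := ref_eval(child, abundances, missing_policy)) is not None
    ]
    if not vals:
        return None
    return min(vals) if kind == "and" else sum(vals)


def tuple_genes(node):
    if node[0] == "gene":
        return {node[1]}
    out = set()
    for child in node[1]:
        out |= tuple_genes(child)
    return out


# -- LP reference: exhaustive vertex enumeration ----------------------------


def enumerate_vertices(S, lb, ub, extra_ineq=None, tol=1e-8):
    """All vertices of {v : S v = 0, lb <= v <= ub, G v <= h}.

    ``extra_ineq`` is an optional (G, h) pair.  A vertex activates n
    linearly independent constraints; equalities are always active, so every
    choice of (n - rank S) inequality rows is tried.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    rows = []  # (a, b) meaning a @ v == b when active; inequality a @ v <= b
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append((e.copy(), ub[i]))
        rows.append((-e, -lb[i]))
    if extra_ineq is not None:
        G, h = extra_ineq
        G = np.atleast_2d(np.asarray(G, dtype=float))
        for g_row, h_val in zip(G, np.atleast_1d(h)):
            rows.append((np.asarray(g_row, dtype=float), float(h_val)))

    r = np.linalg.matrix_rank(S) if S.size else 0
    k = n - r
    vertices = []
    for picked in combinations(range(len(rows)), k):
        A = np.vstack([S] + [rows[i][0] for i in picked]) if S.size else np.vstack(
            [rows[i][0] for i in picked]
        )
        b = np.concatenate([np.zeros(S.shape[0])] + [[rows[i][1]] for i in picked])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > tol:
            continue
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            continue
        if extra_ineq is not None:
            G, h = extra_ineq
            if np.any(np.atleast_2d(G) @ v > np.atleast_1d(h) + tol):
                continue
        if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
            vertices.append(v)
    return vertices


def oracle_fba(S, lb, ub, c):
    """(status, optimum) by enumerating polytope vertices."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return "infeasible", None
    c = np.asarray(c, dtype=float)
    return "optimal", max(float(c @ v) for v in vertices)


def oracle_fva(S, lb, ub, c, gamma, z0, reaction_indices):
    """Per-reaction (min, max) flux with c @ v >= gamma * z0 enforced."""
    c = np.asarray(c, dtype=float)
    extra = (-c.reshape(1, -1), np.array([-gamma * z0]))
    vertices = enumerate_vertices(S, lb, ub, extra_ineq=extra)
    assert vertices, "constrained polytope unexpectedly empty"
    out = {}
    for j in reaction_indices:
        vals = [float(v[j]) for v in vertices]
        out[j] = (min(vals), max(vals))
    return out


def random_toy_network(rng, max_mets=4, max_rxns=6):
    """Random small network with 0 in every bound interval (so v=0 feasible)."""
    m = int(rng.integers(1, max_mets + 1))
    n = int(rng.integers(2, max_rxns + 1))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    S[rng.random(size=S.shape) < 0.4] = 0.0
    lb = rng.choice([-5.0, -2.0, 0.0], size=n)
    ub = rng.choice([0.0, 3.0, 5.0, 8.0], size=n)
    c = rng.choice([0.0, 0.0, 1.0, 2.0, -1.0], size=n)
    if not np.any(c):
        c[n - 1] = 1.0
    return S, lb, ub, c
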