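"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity with the most literal algorithm
available (explicit flood fill, O(n^3) Lance-Williams agglomeration,
exhaustive label-assignment enumeration, transitive closure), sharing no
code with the package paths it checks.
"""

import itertools
import math

import numpy as np


def flood_fill_components(nodes, edges):
    """Connected components by explicit stack-based flood fill."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def naive_ward(x):
    """O(n^3) Ward agglomeration via the Lance-Williams distance update.

    Returns (merge_heights_sorted, cophenetic_matrix). Initial distances are
    Euclidean; the update for merging clusters i, j against k is
    sqrt(((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2) / (n_i+n_j+n_k)).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    d = {
        (i, j): math.dist(x[i], x[j])
        for i in range(n) for j in range(i + 1, n)
    }
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    next_id = n
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: kv[1])
        heights.append(dij)
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dij
        merged = clusters[i] + clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        new_d = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            val = math.sqrt(
                ((ni + nk) * dik ** 2 + (nj + nk) * djk ** 2 - nk * dij ** 2)
                / (ni + nj + nk)
            )
            new_d[k] = val
        del clusters[i], clusters[j]
        d = {
            (a, b): v for (a, b), v in d.items()
            if a not in (i, j) and b not in (i, j)
        }
        clusters[next_id] = merged
        for k, v in new_d.items():
            d[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return sorted(heights), coph


def pooled_t(ha, hb):
    """Textbook pooled two-sample t, written independently of the package."""
    m, n = len(ha), len(hb)
    mean_a = sum(ha) / m
    mean_b = sum(hb) / n
    var_a = sum((v - mean_a) ** 2 for v in ha) / (m - 1)
    var_b = sum((v - mean_b) ** 2 for v in hb) / (n - 1)
    sp = math.sqrt(((m - 1) * var_a + (n - 1) * var_b) / (m + n - 2))
    denom = sp * math.sqrt(1 / n + 1 / m)
    diff = mean_a - mean_b
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


def exhaustive_permutation_p(column, labels, alternative="signed",
                             pseudocount=False, tie_policy="strict"):
    """Empirical p by enumerating every balanced label assignment."""
    labels = list(labels)
    classes = list(dict.fromkeys(labels))
    a_positions = [i for i, lab in enumerate(labels) if lab == classes[0]]
    m = len(a_positions)
    def _t(combo):
        ha = [column[i] for i in combo]
        hb = [column[i] for i in range(len(labels)) if i not in combo]
        t = pooled_t(ha, hb)
        return t if math.isinf(t) else round(t, 9)  # shared tie convention

    t_obs = _t(a_positions)
    t_null = [_t(c) for c in itertools.combinations(range(len(labels)), m)]
    if t_obs < 0:
        b = sum(t < t_obs for t in t_null)
    else:
        b = sum(t > t_obs for t in t_null)
    ties = sum(t == t_obs for t in t_null)
    if tie_policy == "mid":
        num = b + 0.5 * ties
    elif tie_policy == "inclusive":
        num = b + ties
    else:
        num = b
    big = len(t_null)
    p = (num + 1) / (big + 1) if pseudocount else num / big
    if alternative == "two-sided":
        p = min(1.0, 2.0 * p)
    return p


def transitive_ancestor_closure(parents):
    """term -> set of all ancestors, by repeated expansion to fixpoint."""
    closure = {t: set(ps) for t, ps in parents.items()}
    changed = True
    while changed:
        changed = False
        for t in closure:
            extra = set()
            for p in closure[t]:
                extra |= closure.get(p, set())
            if not extra <= closure[t]:
                closure[t] |= extra
                changed = True
    return closure
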