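"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions (explicit loops, no shared
code with the package) so oracle/implementation agreement is meaningful.
"""

from __future__ import annotations


def bh_stepup(p_values):
    """BH adjusted p-values straight from the step-up definition, O(n^2)."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = order[later_pos - 1]
            candidates.append(p[j] * m / later_pos)
        q[i] = min(1.0, min(candidates))
    return q


def components_union_find(nodes, edges):
    """Connected components via union-find; returns list of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def components_bfs(nodes, edges):
    """Connected components by explicit breadth-first traversal."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def expand_neighborhood(nodes, edges, inputs):
    """One-step expansion by enumeration: expanded node set + induced edges."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    expanded = set(inputs)
    for n in inputs:
        expanded |= adj[n]
    induced = {frozenset((u, v)) for u, v in edges if u in expanded and v in expanded}
    return expanded, induced


def seed_partner_counts(nodes, edges, seeds):
    """Per-node count of distinct adjacent seed nodes, by enumeration."""
    counts = {}
    for n in nodes:
        partners = set()
        for u, v in edges:
            if u == n and v in seeds:
                partners.add(v)
            if v == n and u in seeds:
                partners.add(u)
        counts[n] = len(partners)
    return counts
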