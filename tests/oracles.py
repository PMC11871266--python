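"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and networkx's
d-separation): d-separation is decided by enumerating every undirected
path and applying the textbook blocking rules; backdoor sets by exhaustive
subset search over observed non-descendants.
"""

from itertools import combinations


def _descendants(edges, node):
    children = {}
    for p, c in edges:
        children.setdefault(p, set()).add(c)
    seen, stack = set(), [node]
    while stack:
        for ch in children.get(stack.pop(), ()):
            if ch not in seen:
                seen.add(ch)
                stack.append(ch)
    return seen


def _all_paths(edges, a, b):
    """All simple undirected paths a..b as lists of (node, arrived_forward)."""
    nbrs = {}
    for p, c in edges:
        nbrs.setdefault(p, []).append((c, True))    # p -> c traversed forward
        nbrs.setdefault(c, []).append((p, False))   # c -> p traversed backward
    paths = []

    def walk(node, path, dirs):
        if node == b:
            paths.append((list(path), list(dirs)))
            return
        for nxt, fwd in nbrs.get(node, ()):
            if nxt not in path:
                path.append(nxt)
                dirs.append(fwd)
                walk(nxt, path, dirs)
                path.pop()
                dirs.pop()

    walk(a, [a], [])
    return paths


def path_blocked(edges, path, dirs, given):
    """Textbook blocking: non-collider in Z blocks; collider blocks unless
    it or a descendant is in Z."""
    for i in range(1, len(path) - 1):
        # dirs[i-1] True: path[i-1] -> path[i]; dirs[i] False: path[i] <- path[i+1].
        # Collider at i means both arrows point into path[i].
        is_collider = dirs[i - 1] and not dirs[i]
        node = path[i]
        if is_collider:
            if node not in given and not (_descendants(edges, node) & set(given)):
                return True
        else:
            if node in given:
                return True
    return False


def d_separated_oracle(edges, a, b, given):
    for path, dirs in _all_paths(edges, a, b):
        if not path_blocked(edges, path, dirs, set(given)):
            return False
    return True


def backdoor_sets_oracle(nodes_observed, edges, exposure, outcome):
    """(all_valid, minimal) frozensets via exhaustive enumeration."""
    desc = _descendants(edges, exposure)
    candidates = sorted(set(n for n, obs in nodes_observed.items() if obs)
                        - {exposure, outcome} - desc)
    backdoor_edges = [(p, c) for p, c in edges if p != exposure]
    valid = []
    for r in range(len(candidates) + 1):
        for combo in combinations(candidates, r):
            z = frozenset(combo)
            if d_separated_oracle(backdoor_edges, exposure, outcome, z):
                valid.append(z)
    minimal = [z for z in valid if not any(w < z for w in valid)]
    return set(valid), set(minimal)


def random_dag(rng, n_nodes, edge_prob=0.4, unobserved_prob=0.25):
    """A random DAG over X0..X{n-1} in topological order, with roles."""
    names = [f"X{i}" for i in range(n_nodes)]
    edges = [(names[i], names[j]) for i in range(n_nodes)
             for j in range(i + 1, n_nodes) if rng.random() < edge_prob]
    exposure, outcome = rng.choice(n_nodes, size=2, replace=False)
    exposure, outcome = names[exposure], names[outcome]
    observed = {nm: (nm in (exposure, outcome)) or rng.random() > unobserved_prob
                for nm in names}
    return names, edges, observed, exposure, outcome
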