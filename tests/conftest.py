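import numpy as np
import pytest

from crossbeta import AnalysisConfig, BuildSpec, build_barrel, build_sheet


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def hexamer_barrel():
    return build_barrel(BuildSpec("barrel", 6, seed=11))


@pytest.fixture
def anti_hexamer_sheet():
    return build_sheet(BuildSpec("antiparallel_sheet", 6, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_hbonds(frame, dist_cutoff=3.5, angle_cutoff=120.0):
    """All-pairs donor/acceptor scan with plain Python arithmetic."""
    from crossbeta.model import minimum_image

    found = set()
    for ci, pi in enumerate(frame.peptides):
        for ri, resi in enumerate(pi.residues):
            n, h = resi.atom("N"), resi.atom("H")
            if n is None or h is None or resi.is_proline:
                continue
            for cj, pj in enumerate(frame.peptides):
                for rj, resj in enumerate(pj.residues):
                    if (ci, ri) == (cj, rj):
                        continue
                    if ci == cj and abs(ri - rj) < 2:
                        continue
                    o = resj.atom("O")
                    if o is None or resj.atom("C") is None:
                        continue
                    dvec = minimum_image(o.position - n.position, frame.box_edge)
                    d = float(np.linalg.norm(dvec))
                    if d > dist_cutoff:
                        continue
                    o_eff = n.position + dvec
                    v1 = n.position - h.position
                    v2 = o_eff - h.position
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if ang >= angle_cutoff:
                        found.add(((ci, ri), (cj, rj)))
    return found


def transitive_closure_components(n_nodes, edges):
    """Connected components by repeated relabelling (no graph library)."""
    label = list(range(n_nodes))
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            low = min(label[u], label[v])
            for w in (u, v):
                if label[w] != low:
                    label[w] = low
                    changed = True
    groups = {}
    for node, lab in enumerate(label):
        groups.setdefault(lab, []).append(node)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g))


def brute_force_is_closed(n_nodes, edges, min_size=4):
    """Barrel closure oracle: degree >= 2 everywhere, no bridge, size >= 4."""
    if n_nodes < min_size:
        return False
    degree = [0] * n_nodes
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    if any(d < 2 for d in degree):
        return False

    def connected(edge_list):
        if n_nodes == 0:
            return True
        adj = {i: set() for i in range(n_nodes)}
        for u, v in edge_list:
            adj[u].add(v)
            adj[v].add(u)
        seen = {0}
        stack = [0]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == n_nodes

    if not connected(edges):
        return False
    for i in range(len(edges)):
        if not connected(edges[:i] + edges[i + 1:]):
            return False  # bridge found
    return True
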