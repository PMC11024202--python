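"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with plain Python loops, BFS and
set arithmetic — no scipy.ndimage, no networkx algorithms — so that it
exercises the definitions directly rather than sharing machinery with the
package code it checks.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# patches / landscape metrics


def flood_fill_patches(values, connectivity=8):
    """List of (class_code, frozenset of (r, c)) maximal components."""
    rows, cols = len(values), len(values[0])
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    patches = []
    for r in range(rows):
        for c in range(cols):
            if (r, c) in seen:
                continue
            code = values[r][c]
            stack = [(r, c)]
            comp = set()
            seen.add((r, c))
            while stack:
                cr, cc = stack.pop()
                comp.add((cr, cc))
                for dr, dc in nbrs:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols \
                            and (nr, nc) not in seen \
                            and values[nr][nc] == code:
                        seen.add((nr, nc))
                        stack.append((nr, nc))
            patches.append((code, frozenset(comp)))
    return patches


def patch_perimeter(values, comp):
    """Cell edges of the patch facing a different class or the border."""
    rows, cols = len(values), len(values[0])
    per = 0
    for (r, c) in comp:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                per += 1
            elif values[nr][nc] != values[r][c]:
                per += 1
    return per


def like_adjacencies(values, code):
    """Single-counted rook adjacencies between cells of one class."""
    rows, cols = len(values), len(values[0])
    g = 0
    for r in range(rows):
        for c in range(cols):
            if values[r][c] != code:
                continue
            if r + 1 < rows and values[r + 1][c] == code:
                g += 1
            if c + 1 < cols and values[r][c + 1] == code:
                g += 1
    return g


def adjacency_counts(values):
    """Double-counted rook adjacency counts {(code_a, code_b): n}."""
    rows, cols = len(values), len(values[0])
    g = {}
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((1, 0), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    a, b = values[r][c], values[nr][nc]
                    g[(a, b)] = g.get((a, b), 0) + 1
                    g[(b, a)] = g.get((b, a), 0) + 1
    return g


def max_like_adjacencies(area):
    n = int(math.isqrt(area))
    m = area - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def class_metrics_bruteforce(values, cell_size=30.0):
    """CA/NP/LPI/LSI/COHESION/AI per class code, by direct formula."""
    rows, cols = len(values), len(values[0])
    z = rows * cols
    cell_km2 = cell_size**2 / 1e6
    patches = flood_fill_patches(values, 8)
    by_class = {}
    for code, comp in patches:
        by_class.setdefault(code, []).append(comp)
    out = {}
    for code, comps in by_class.items():
        areas = [len(c) for c in comps]
        perims = [patch_perimeter(values, c) for c in comps]
        a_i = sum(areas)
        g = like_adjacencies(values, code)
        mg = max_like_adjacencies(a_i)
        out[code] = {
            "CA": a_i * cell_km2,
            "NP": len(comps),
            "LPI": 100.0 * max(areas) * cell_km2 / (z * cell_km2),
            "LSI": 0.25 * sum(perims) / math.sqrt(a_i),
            "COHESION": 100.0
            * (1 - sum(perims) / sum(p * math.sqrt(a) for p, a in zip(perims, areas)))
            / (1 - 1 / math.sqrt(z)),
            "AI": 100.0 * g / mg if mg > 0 else 100.0,
        }
    return out


def landscape_metrics_bruteforce(values, cell_size=30.0):
    """LPI/FRAC_AM/CONTAG/COHESION/SHDI/SHEI/LSI by direct formula."""
    rows, cols = len(values), len(values[0])
    z = rows * cols
    patches = flood_fill_patches(values, 8)
    areas = [len(c) for _, c in patches]
    perims = [patch_perimeter(values, c) for _, c in patches]

    codes = sorted({values[r][c] for r in range(rows) for c in range(cols)})
    counts = {
        code: sum(values[r][c] == code for r in range(rows) for c in range(cols))
        for code in codes
    }
    p = {code: counts[code] / z for code in codes}
    m = len(codes)

    shdi = -sum(pi * math.log(pi) for pi in p.values() if pi > 0)
    shei = 0.0 if m == 1 else shdi / math.log(m)

    a_m2 = [a * cell_size**2 for a in areas]
    p_m = [pe * cell_size for pe in perims]
    frac_am = sum(
        (1.0 if math.log(am) == 0 else 2 * math.log(0.25 * pm) / math.log(am)) * am
        for am, pm in zip(a_m2, p_m)
    ) / sum(a_m2)

    if m == 1:
        contag = 100.0
    else:
        g = adjacency_counts(values)
        total = 0.0
        for i in codes:
            row_sum = sum(g.get((i, k), 0) for k in codes)
            for k in codes:
                if row_sum == 0:
                    continue
                pq = p[i] * g.get((i, k), 0) / row_sum
                if pq > 0:
                    total += pq * math.log(pq)
        contag = 100.0 * (1 + total / (2 * math.log(m)))

    # total edge, single count, incl. border
    total_edge = 0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((1, 0), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    if values[nr][nc] != values[r][c]:
                        total_edge += 1
    total_edge += 2 * rows + 2 * cols

    cohesion = (
        100.0
        * (1 - sum(perims) / sum(pe * math.sqrt(a) for pe, a in zip(perims, areas)))
        / (1 - 1 / math.sqrt(z))
    )
    return {
        "LPI": 100.0 * max(areas) / z,
        "FRAC_AM": frac_am,
        "CONTAG": contag,
        "COHESION": cohesion,
        "SHDI": shdi,
        "SHEI": shei,
        "LSI": 0.25 * total_edge / math.sqrt(z),
    }


# ---------------------------------------------------------------------------
# graphs


def max_product_path(n, p_direct, i, j):
    """Maximum product of stepwise probabilities over all simple paths
    from i to j on the complete graph with direct probabilities p_direct."""
    if i == j:
        return 1.0
    best = 0.0
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = [i, *mid, j]
            prod = 1.0
            for a, b in zip(path[:-1], path[1:]):
                prod *= p_direct[a][b]
            best = max(best, prod)
    return best


def pc_bruteforce(areas, p_direct, a_l):
    n = len(areas)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += areas[i] * areas[j] * max_product_path(n, p_direct, i, j)
    return total / a_l**2


def giant_component_unionfind(n_nodes, edges):
    """Largest component size via union-find over explicit edge list."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    sizes = {}
    for x in range(n_nodes):
        r = find(x)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) if sizes else 0


def all_paths_min_cost(resistance, start, end, cell_km=0.03):
    """Minimum path cost by exhaustive DFS over all simple 8-connected
    paths on a small grid; cost = sum of step length x mean resistance."""
    rows, cols = len(resistance), len(resistance[0])
    best = [math.inf]

    def dfs(r, c, visited, cost):
        if cost >= best[0]:
            return
        if (r, c) == end:
            best[0] = cost
            return
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and (nr, nc) not in visited:
                    step = cell_km * (math.sqrt(2) if dr and dc else 1.0)
                    w = step * 0.5 * (resistance[r][c] + resistance[nr][nc])
                    visited.add((nr, nc))
                    dfs(nr, nc, visited, cost + w)
                    visited.remove((nr, nc))

    dfs(start[0], start[1], {start}, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# MSPA per-cell definitions


def _cheb_within(cells, radius, rows, cols):
    """All in-bounds cells within Chebyshev distance radius of the set."""
    out = set()
    for (r, c) in cells:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    out.add((nr, nc))
    return out


def _components(cells, connectivity, rows, cols):
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    cells = set(cells)
    comps = []
    while cells:
        start = cells.pop()
        comp = {start}
        stack = [start]
        while stack:
            r, c = stack.pop()
            for dr, dc in nbrs:
                n = (r + dr, c + dc)
                if n in cells:
                    cells.remove(n)
                    comp.add(n)
                    stack.append(n)
        comps.append(frozenset(comp))
    return comps


def mspa_bruteforce(fg, edge_width=1):
    """Per-cell MSPA classification by direct definition checking.

    Returns a dict (r, c) -> class name for every cell; background cells
    map to 'background'.
    """
    rows, cols = len(fg), len(fg[0])
    fg_cells = {(r, c) for r in range(rows) for c in range(cols) if fg[r][c]}
    bg_cells = {(r, c) for r in range(rows) for c in range(cols)} - fg_cells
    w = edge_width

    # core: full Chebyshev-w neighbourhood in bounds and foreground
    core = set()
    for (r, c) in fg_cells:
        ok = True
        for dr in range(-w, w + 1):
            for dc in range(-w, w + 1):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) \
                        or (nr, nc) not in fg_cells:
                    ok = False
        if ok:
            core.add((r, c))

    out = {cell: "background" for cell in bg_cells}
    for cell in core:
        out[cell] = "core"

    # islets: fg components without core
    fg_comps = _components(fg_cells, 8, rows, cols)
    islet = set()
    for comp in fg_comps:
        if not comp & core:
            islet |= comp
    for cell in islet:
        out[cell] = "islet"

    # exterior vs interior background (4-connectivity from border)
    exterior = set()
    for comp in _components(bg_cells, 4, rows, cols):
        if any(r in (0, rows - 1) or c in (0, cols - 1) for r, c in comp):
            exterior |= comp
    interior = bg_cells - exterior

    near_core = _cheb_within(core, w, rows, cols)
    near_ext = _cheb_within(exterior, w, rows, cols)
    # beyond-border area counts as exterior background
    for r in range(rows):
        for c in range(cols):
            if r < w or c < w or r >= rows - w or c >= cols - w:
                near_ext.add((r, c))

    ring = (fg_cells - core - islet) & near_core
    for cell in ring:
        out[cell] = "edge" if cell in near_ext else "perforation"

    # core patch labels and their rings
    core_comps = _components(core, 8, rows, cols)
    ring_owner = {}
    for k, comp in enumerate(core_comps):
        zone = _cheb_within(comp, w, rows, cols) & ring
        for cell in zone:
            ring_owner.setdefault(cell, set()).add(k)

    nbrs8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
             if (dr, dc) != (0, 0)]
    cb = fg_cells - core - islet - ring
    for comp in _components(cb, 8, rows, cols):
        touch = set()
        for (r, c) in comp:
            for dr, dc in nbrs8:
                n = (r + dr, c + dc)
                if n not in comp:
                    touch.add(n)
        reached = set()
        for k, ccomp in enumerate(core_comps):
            if touch & ccomp:
                reached.add(k)
        for cell in touch & ring:
            reached |= ring_owner.get(cell, set())
        if len(reached) >= 2:
            label = "bridge"
        elif len(reached) == 1:
            k = next(iter(reached))
            attach = set(core_comps[k]) | {c for c in ring
                                           if k in ring_owner.get(c, set())}
            contact = {cell for cell in comp
                       if any((cell[0] + dr, cell[1] + dc) in attach
                              for dr, dc in nbrs8)}
            zones = _components(contact, 8, rows, cols)
            label = "loop" if len(zones) >= 2 else "branch"
        else:
            label = "branch"
        for cell in comp:
            out[cell] = label
    return out
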