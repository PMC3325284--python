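"""Independent brute-force reference implementations used to check the
package's fast paths.  Everything here is deliberately naive: per-column
loops, itertools enumeration, exhaustive labelings."""

from __future__ import annotations

from itertools import combinations, product

RESIDUES = set("ACGT")


def is_residue(c: str) -> bool:
    return c in RESIDUES


def retained_columns(seqs, start, end, policy):
    cols = []
    for c in range(start, end + 1):
        chars = [s[c - 1] for s in seqs]
        if policy == "pairwise" or all(is_residue(ch) for ch in chars):
            cols.append(c)
    return cols


def segregating_sites(seqs, start, end, policy):
    count = 0
    for c in retained_columns(seqs, start, end, policy):
        states = {s[c - 1] for s in seqs if is_residue(s[c - 1])}
        if len(states) >= 2:
            count += 1
    return count


def nucleotide_diversity(seqs, start, end, policy):
    cols = retained_columns(seqs, start, end, policy)
    total, n_pairs = 0.0, 0
    for a, b in combinations(seqs, 2):
        comparable = [
            c for c in cols if is_residue(a[c - 1]) and is_residue(b[c - 1])
        ]
        if not comparable:
            continue
        d = sum(1 for c in comparable if a[c - 1] != b[c - 1])
        total += d / len(comparable)
        n_pairs += 1
    return None if n_pairs == 0 else total / n_pairs


def gap_events(seqs):
    events = set()
    for s in seqs:
        run_start = None
        for i, ch in enumerate(s, start=1):
            if ch == "-" and run_start is None:
                run_start = i
            elif ch != "-" and run_start is not None:
                events.add((run_start, i - 1))
                run_start = None
        if run_start is not None:
            events.add((run_start, len(s)))
    return sorted(events)


def indel_events(seqs, start, end):
    return sum(1 for s, _e in gap_events(seqs) if start <= s <= end)


def interval_union(intervals, max_gap):
    ivals = sorted(intervals)
    if not ivals:
        return []
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def mean_and_sample_std(values):
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5


# --- parsimony -------------------------------------------------------------


def _shape_edges(shape, n_taxa):
    """Edges of the unrooted tree encoded by a rooted-at-taxon-0 shape.

    Nodes: 0..n_taxa-1 are leaves; internal nodes get ids n_taxa, n_taxa+1...
    Returns (edges, n_internal)."""
    edges = []
    counter = [n_taxa]

    def build(node):
        if isinstance(node, int):
            return node
        my_id = counter[0]
        counter[0] += 1
        left = build(node[0])
        right = build(node[1])
        edges.append((my_id, left))
        edges.append((my_id, right))
        return my_id

    root = build(shape)
    edges.append((root, 0))
    return edges, counter[0] - n_taxa


def fitch_bruteforce(shape, rows):
    """Minimum changes over all internal-state labelings, per column summed.

    Leaves with gap/ambiguity allow any state at zero extra cost beyond the
    edge match test (wildcards)."""
    n_taxa = len(rows)
    edges, n_internal = _shape_edges(shape, n_taxa)
    total = 0
    for col in range(len(rows[0])):
        leaf_sets = []
        for r in rows:
            ch = r[col].upper()
            leaf_sets.append({ch} if ch in RESIDUES else set("ACGT"))
        best = None
        for assignment in product("ACGT", repeat=n_internal):
            state = {n_taxa + i: assignment[i] for i in range(n_internal)}
            cost = 0
            for a, b in edges:
                if a >= n_taxa and b >= n_taxa:
                    cost += state[a] != state[b]
                else:
                    internal, leaf = (a, b) if a >= n_taxa else (b, a)
                    cost += state[internal] not in leaf_sets[leaf]
            if best is None or cost < best:
                best = cost
        total += best
    return total


def p_distance(a, b):
    comparable = [
        (x, y) for x, y in zip(a.upper(), b.upper())
        if x in RESIDUES and y in RESIDUES
    ]
    if not comparable:
        raise ValueError("no comparable sites")
    return sum(1 for x, y in comparable if x != y) / len(comparable)
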