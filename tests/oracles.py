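"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (definition-level scans,
quadratic greedy selection, exhaustive enumeration) without touching the
package's index/selection machinery, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import numpy as np


def find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence starts of ``needle`` in ``haystack``."""
    out = []
    k = haystack.find(needle)
    while k != -1:
        out.append(k)
        k = haystack.find(needle, k + 1)
    return out


def brute_matching_statistics(ref: str, other: str) -> list[int]:
    """Quadratic scan: longest substring of ``ref`` starting at each position
    that occurs anywhere in ``other``."""
    n = len(ref)
    out = []
    for i in range(n):
        length = 0
        while i + length < n and ref[i : i + length + 1] in other:
            length += 1
        out.append(length)
    return out


def all_common_subwords(ref: str, target: str) -> dict[str, tuple[list[int], list[int]]]:
    """Every distinct substring of ``ref`` that also occurs in ``target``,
    with full occurrence lists in both strings."""
    words: dict[str, tuple[list[int], list[int]]] = {}
    n = len(ref)
    for i in range(n):
        for length in range(1, n - i + 1):
            w = ref[i : i + length]
            if w in words:
                continue
            if w in target:
                words[w] = (find_all(ref, w), find_all(target, w))
            else:
                break  # no right-extension of a non-occurring word occurs
    return words


def irredundant_words(ref: str, target: str) -> set[str]:
    """Literal coverage test: a common subword is irredundant iff at least one
    of its occurrences (either host) is not contained in an occurrence
    interval of a different common subword."""
    words = all_common_subwords(ref, target)
    ids = {w: k for k, w in enumerate(words)}
    host_arrays = []
    for h in (0, 1):
        starts, ends, wid = [], [], []
        for w, occs in words.items():
            for i in occs[h]:
                starts.append(i)
                ends.append(i + len(w))
                wid.append(ids[w])
        host_arrays.append(
            (np.array(starts), np.array(ends), np.array(wid))
        )
    out: set[str] = set()
    for w, occs in words.items():
        length = len(w)
        my = ids[w]
        for h in (0, 1):
            starts, ends, wid = host_arrays[h]
            for i in occs[h]:
                if len(starts) == 0:
                    covered = False
                else:
                    covered = bool(
                        np.any(
                            (starts <= i) & (ends >= i + length) & (wid != my)
                        )
                    )
                if not covered:
                    out.add(w)
                    break
            if w in out:
                break
    return out


def _first_occurrence_key(occs: tuple[list[int], list[int]]) -> tuple[int, int]:
    if occs[0]:
        return (0, min(occs[0]))
    return (1, min(occs[1]))


def priority_order(words: dict[str, tuple[list[int], list[int]]]) -> list[str]:
    return sorted(words, key=lambda w: (-len(w), _first_occurrence_key(words[w])))


def underlying_greedy(
    words: dict[str, tuple[list[int], list[int]]]
) -> list[tuple[str, list[int], list[int]]]:
    """Quadratic greedy selection: walk the priority order; an occurrence is
    untied iff its interval overlaps no previously accepted untied occurrence
    (nor an earlier untied occurrence of the same word); keep words that
    retain at least one untied occurrence per host."""
    accepted: dict[int, list[tuple[int, int]]] = {0: [], 1: []}
    members: list[tuple[str, list[int], list[int]]] = []
    for w in priority_order(words):
        length = len(w)
        untied: tuple[list[int], list[int]] = ([], [])
        for h in (0, 1):
            for i in sorted(words[w][h]):
                lo, hi = i, i + length - 1
                if any(a <= hi and lo <= b for a, b in accepted[h]):
                    continue
                if any(
                    j <= hi and lo <= j + length - 1 for j in untied[h]
                ):
                    continue
                untied[h].append(i)
        if untied[0] and untied[1]:
            members.append((w, untied[0], untied[1]))
            for h in (0, 1):
                accepted[h].extend((i, i + length - 1) for i in untied[h])
    return members


def right_branching_common_substrings(s1: str, s2: str, concat: str) -> set[str]:
    """Common substrings of ``s1``/``s2`` that have at least two distinct
    right extensions in the terminated concatenation (i.e. that a generalized
    suffix tree represents as an explicit node)."""
    out = set()
    for w, _ in all_common_subwords(s1, s2).items():
        ext = set()
        for i in find_all(concat, w):
            ext.add(concat[i + len(w)] if i + len(w) < len(concat) else "$")
        if len(ext) >= 2:
            out.add(w)
    return out


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_binary_tree_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random unrooted binary topology with positive branch lengths."""
    clauses = {label: f"{label}:{rng.uniform(0.1, 1.0):.6f}" for label in labels}
    active = list(labels)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        merged = f"({clauses[a]},{clauses[b]}):{rng.uniform(0.1, 1.0):.6f}"
        key = f"__{a}"
        clauses[key] = merged
        active = [x for x in active if x not in (a, b)] + [key]
    a, b, c = active
    return f"({clauses[a]},{clauses[b]},{clauses[c]});"


def tree_path_length_matrix(newick: str, labels: list[str]) -> np.ndarray:
    """Additive matrix of leaf-to-leaf path lengths, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    k = len(labels)
    out = np.zeros((k, k))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(k):
        for j in range(i + 1, k):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return out


def dendropy_rf(newick1: str, newick2: str) -> int:
    """Robinson-Foulds symmetric difference via dendropy's bitmask encoding
    (independent of the package's frozenset-based implementation)."""
    import dendropy
    from dendropy.calculate import treecompare

    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=newick1, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    t2 = dendropy.Tree.get(
        data=newick2, schema="newick", taxon_namespace=ns, preserve_underscores=True
    )
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)
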