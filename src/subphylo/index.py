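"""Generalized suffix structure over a sequence pair.

The index concatenates the reference and the target (plain or extended) with
unique joiner symbols, builds a suffix array by numpy prefix doubling, derives
the LCP array (Kasai), and folds both into an explicit suffix tree: nodes with
parent links, string depths, color masks (which input reaches the node), and
subtree suffix-array intervals. On top of that it answers the queries the
discovery algorithms need:

* per suffix position, the lowest ancestor carrying both colors (this is at
  once the matching statistic and the right-maximal subword at that position);
* enumeration of all both-colored internal nodes;
* the deepest ancestor whose string depth does not exceed a given length
  (a plain parent walk stands in for a weighted-ancestor structure);
* after irredundant marking, the nearest irredundant ancestor of any node.
"""

from __future__ import annotations

import numpy as np

from subphylo.seqio import ExtendedSequence, GenomeSequence, SequenceLike

# Joiner/terminator code points, beyond every sentinel and separator pool.
_JOINER = chr(0x10FFFE - 2)
_TERMINATOR = chr(0x10FFFE - 1)

COLOR_REF = 1
COLOR_TARGET = 2
COLOR_BOTH = COLOR_REF | COLOR_TARGET


def _codes(text: str) -> np.ndarray:
    """Code-point array of ``text`` (uint32, one entry per character)."""
    return np.frombuffer(text.encode("utf-32-le"), dtype=np.uint32).astype(np.int64)


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling with numpy lexsort; O(n log n)."""
    n = len(codes)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while rank[sa[-1]] < n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed) - 1
        rank = new_rank
        k *= 2
    return sa


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm: lcp[i] = LCP(suffix sa[i-1], suffix sa[i]); lcp[0] = 0."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    c = codes.tolist()
    rk = rank.tolist()
    salist = sa.tolist()
    h = 0
    for i in range(n):
        r = rk[i]
        if r > 0:
            j = salist[r - 1]
            while i + h < n and j + h < n and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


class PairIndex:
    """Suffix tree over a (reference, target) pair with colored nodes."""

    def __init__(self, reference: GenomeSequence, target: SequenceLike) -> None:
        self.reference = reference
        self.target = target
        ref_text = reference.residues
        tgt_text = target.residues
        self.n_ref = len(ref_text)
        self.n_target = len(tgt_text)
        # reference | joiner | target | terminator
        self.concat = ref_text + _JOINER + tgt_text + _TERMINATOR
        self.target_offset = self.n_ref + 1
        codes = _codes(self.concat)
        self.sa = suffix_array(codes)
        self.lcp = lcp_array(codes, self.sa)
        self._build_tree()
        self._annotate()
        # Irredundant marking state (filled by mark_irredundant).
        self.irredundant: list[bool] | None = None
        self.prec: list[int] | None = None
        self._seed_node: list[int] | None = None

    # ------------------------------------------------------------------ build

    def _build_tree(self) -> None:
        N = len(self.concat)
        sa = self.sa.tolist()
        lcp = self.lcp.tolist()
        parent = [-1]
        sdepth = [0]
        sa_ix = [0]  # one suffix-array index whose suffix passes through the node
        leafflag = [False]
        leaf_id = [0] * N  # by suffix-array order

        def add(d: int, six: int, par: int, is_leaf: bool) -> int:
            parent.append(par)
            sdepth.append(d)
            sa_ix.append(six)
            leafflag.append(is_leaf)
            return len(parent) - 1

        v = add(N - sa[0], 0, 0, True)
        leaf_id[0] = v
        prev = v
        for i in range(1, N):
            h = lcp[i]
            last = prev
            p = parent[prev]
            while sdepth[p] > h:
                last = p
                p = parent[p]
            if sdepth[p] == h:
                attach = p
            else:
                w = add(h, sa_ix[last], p, False)
                parent[last] = w
                attach = w
            leaf = add(N - sa[i], i, attach, True)
            leaf_id[i] = leaf
            prev = leaf

        self.parent = parent
        self.sdepth = sdepth
        self._sa_ix = sa_ix
        self.is_leaf = leafflag
        self._leaf_by_sa = leaf_id
        self.n_nodes = len(parent)
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(1, self.n_nodes):
            children[parent[v]].append(v)
        self.children = children
        # leaf node id for each starting position of the concatenation
        self.leaf_of_pos = [0] * N
        for k in range(N):
            self.leaf_of_pos[sa[k]] = leaf_id[k]

    def _annotate(self) -> None:
        """Post-order: color masks and SA intervals. Pre-order: lowest
        both-colored ancestor per suffix position."""
        N = len(self.concat)
        n_ref, off = self.n_ref, self.target_offset
        sa = self.sa.tolist()
        color = [0] * self.n_nodes
        lb = [0] * self.n_nodes
        rb = [0] * self.n_nodes
        # leaf colors by the region the suffix starts in
        for k in range(N):
            v = self._leaf_by_sa[k]
            pos = sa[k]
            if pos < n_ref:
                color[v] = COLOR_REF
            elif off <= pos < off + self.n_target:
                color[v] = COLOR_TARGET
            lb[v] = k
            rb[v] = k + 1
        # iterative post-order over internal nodes
        stack = [(0, False)]
        while stack:
            v, done = stack.pop()
            if self.is_leaf[v]:
                continue
            if done:
                c = 0
                l, r = N, -1
                for u in self.children[v]:
                    c |= color[u]
                    if lb[u] < l:
                        l = lb[u]
                    if rb[u] > r:
                        r = rb[u]
                color[v] = c
                lb[v], rb[v] = l, r
            else:
                stack.append((v, True))
                for u in self.children[v]:
                    stack.append((u, False))
        self.color = color
        self.lb = lb
        self.rb = rb
        # pre-order: deepest both-colored node on the root path, per position
        bca = [0] * N
        ms = [0] * N
        stack2 = [(0, 0)]
        while stack2:
            v, cur = stack2.pop()
            if color[v] == COLOR_BOTH and self.sdepth[v] > 0:
                cur = v
            if self.is_leaf[v]:
                pos = sa[lb[v]]
                bca[pos] = cur
                ms[pos] = self.sdepth[cur]
            else:
                for u in self.children[v]:
                    stack2.append((u, cur))
        self._bca_by_pos = bca
        self._ms_by_pos = ms

    # ---------------------------------------------------------------- queries

    def word(self, node: int) -> str:
        """String spelled on the root path of ``node``."""
        start = self.sa[self._sa_ix[node]]
        return self.concat[start : start + self.sdepth[node]]

    def bicolored_nodes(self) -> list[int]:
        """Internal nodes of positive depth reached by both inputs."""
        return [
            v
            for v in range(1, self.n_nodes)
            if not self.is_leaf[v] and self.color[v] == COLOR_BOTH and self.sdepth[v] > 0
        ]

    def lowest_bicolored_ancestor(self, pos: int) -> int:
        """Lowest both-colored ancestor of the suffix starting at concat
        position ``pos`` (0 = root, meaning no common prefix)."""
        return self._bca_by_pos[pos]

    def matching_statistics_reference(self) -> list[int]:
        """Per reference position, the longest-match length against the target."""
        return self._ms_by_pos[: self.n_ref]

    def matching_statistics_target(self) -> list[int]:
        """Per target position (local coordinates), longest match against the
        reference. Separator positions inside an extended target are 0."""
        off = self.target_offset
        return self._ms_by_pos[off : off + self.n_target]

    def ms_concat(self) -> list[int]:
        return self._ms_by_pos

    def ancestor_with_depth_at_most(self, node: int, d: int) -> int:
        """Deepest ancestor-or-self of ``node`` with string depth <= ``d``."""
        v = node
        while self.sdepth[v] > d:
            v = self.parent[v]
        return v

    def occurrence_positions(self, node: int) -> tuple[list[int], list[int]]:
        """All occurrence starts of the node's word, split by host.

        Reference positions are 0-based in the reference; target positions are
        0-based local to the target residues. Both lists are sorted.
        """
        n_ref, off = self.n_ref, self.target_offset
        span = self.sa[self.lb[node] : self.rb[node]]
        ref = np.sort(span[span < n_ref]).tolist()
        tgt = np.sort(span[span >= off] - off).tolist()
        return ref, tgt

    def concat_pos(self, host_is_ref: bool, local: int) -> int:
        return local if host_is_ref else self.target_offset + local

    def split_pos(self, pos: int) -> tuple[bool, int]:
        """Concat position -> (host_is_ref, host-local position)."""
        if pos < self.n_ref:
            return True, pos
        return False, pos - self.target_offset

    # ----------------------------------------------------- irredundant layer

    def mark_irredundant(self, nodes: list[int]) -> None:
        """Mark the irredundant nodes and precompute the prec links.

        ``prec[v]`` is the nearest strict ancestor of ``v`` that is
        irredundant (-1 if none); every leaf's suffix position is seeded to the
        location list of its closest irredundant ancestor.
        """
        irred = [False] * self.n_nodes
        for v in nodes:
            irred[v] = True
        prec = [-1] * self.n_nodes
        seed = [-1] * len(self.concat)
        sa = self.sa.tolist()
        stack = [(0, -1)]
        while stack:
            v, closest = stack.pop()
            prec[v] = closest
            here = v if irred[v] else closest
            if self.is_leaf[v]:
                seed[sa[self.lb[v]]] = here
            else:
                for u in self.children[v]:
                    stack.append((u, here))
        self.irredundant = irred
        self.prec = prec
        self._seed_node = seed

    def seed_lists(self) -> list[int]:
        """Per concat position, the node whose pending list receives it."""
        if self._seed_node is None:
            raise RuntimeError("mark_irredundant() has not been called")
        return self._seed_node

    def nearest_irredundant_prefix(self, node: int, d: int) -> int:
        """Deepest irredundant ancestor-or-self of ``node`` with depth <= ``d``
        and depth >= 1; -1 if there is none."""
        if self.irredundant is None or self.prec is None:
            raise RuntimeError("mark_irredundant() has not been called")
        v = node if self.irredundant[node] else self.prec[node]
        while v != -1 and self.sdepth[v] > d:
            v = self.prec[v]
        if v == -1 or v == 0 or self.sdepth[v] < 1:
            return -1
        return v


def build_index(reference: GenomeSequence, target: SequenceLike) -> PairIndex:
    """Build the pair index; see :class:`PairIndex` for the query contract."""
    return PairIndex(reference, target)
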