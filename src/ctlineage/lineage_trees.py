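"""Genealogy reconstruction from methylation haplotypes and binarised CCFs.

Two routes to a lineage tree are provided:

* **Epigenetic**: per-sample haplotype populations are resampled to a
  fixed size (100 draws with replacement), compared pairwise by an
  iterative minimal Hamming pairing (repeatedly record the globally
  shortest remaining haplotype pair, remove it, and sum the recorded
  distances), a synthetic fully unmethylated reference population is
  appended, and a neighbour-joining tree is built from the resulting
  distance matrix, rooted on the unmethylated reference.

* **Genetic**: mutations are binarised at a cancer-cell-fraction
  threshold (CCF >= 0.2) and a maximum-parsimony sample tree is built —
  exactly (branch and bound) at desk scale, by seeded NNI hill-climbing
  from a neighbour-joining start beyond that — rooted on the germline
  (all-zero) profile, with edge lengths assigned by the ACCTRAN
  (accelerated transformation) criterion, which pushes ambiguous state
  changes rootward.

The module also classifies metastatic seeding: a sample is *polyclonally*
seeded only when it contains mutation clusters that are not
hierarchically related (neither ancestral to the other), at a presence
threshold of CCF >= 0.2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from ctlineage.clock_haplotypes import EmptyTableError, HaplotypeTable

logger = logging.getLogger(__name__)

UNMETHYLATED_REF = "unmethylated_ref"


@dataclass
class HaplotypeSample:
    """A fixed-size resample of one sample's haplotype population."""

    sample_id: str
    haplotypes: list[str]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("a haplotype sample cannot be empty")
        L = len(self.haplotypes[0])
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("all haplotypes must share one length")

    @property
    def n_draws(self) -> int:
        return len(self.haplotypes)

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])

    def as_array(self) -> np.ndarray:
        return np.array([[int(c) for c in h] for h in self.haplotypes],
                        dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# resampling and greedy pairing

def resample_haplotypes(table: HaplotypeTable, n_draws: int = 100,
                        seed: int | np.random.Generator = 0
                        ) -> HaplotypeSample:
    """Draw ``n_draws`` haplotypes with replacement, weighted by counts."""
    if table.total == 0:
        raise EmptyTableError(
            f"cannot resample empty table for {table.sample_id!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    bits = sorted(table.counts)
    probs = np.array([table.counts[b] for b in bits], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(bits), size=n_draws, replace=True, p=probs)
    return HaplotypeSample(sample_id=table.sample_id,
                           haplotypes=[bits[i] for i in idx])


def make_unmethylated_reference(L: int, n_draws: int = 100
                                ) -> HaplotypeSample:
    """Synthetic fully unmethylated reference population (the tree root)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return HaplotypeSample(sample_id=UNMETHYLATED_REF,
                           haplotypes=["0" * L] * n_draws)


def greedy_pair_distance(A: HaplotypeSample, B: HaplotypeSample) -> int:
    """Iterative minimal Hamming pairing distance between two populations.

    The Hamming distance of every haplotype combination between the two
    samples is computed; iteratively, the globally shortest remaining
    pair is recorded and removed from consideration, until none remain;
    the recorded distances are summed.

    Ties among equally short remaining pairs are broken by the
    lexicographically smallest index pair after putting the two samples
    into a canonical order (sorted haplotype lists), which makes the
    result deterministic and exactly symmetric in (A, B) — the choice
    among tied pairs can change the sum, so a fixed rule is required.
    """
    if A.n_draws != B.n_draws:
        raise ValueError("samples must hold equally many haplotypes")
    if A.length != B.length:
        raise ValueError("haplotype lengths differ between samples")
    first, second = sorted((A, B), key=lambda s: sorted(s.haplotypes))
    a = HaplotypeSample(first.sample_id,
                        sorted(first.haplotypes)).as_array()
    b = HaplotypeSample(second.sample_id,
                        sorted(second.haplotypes)).as_array()
    D = (a[:, None, :] != b[None, :, :]).sum(axis=2).astype(np.int64)
    n = D.shape[0]
    big = np.iinfo(np.int64).max
    total = 0
    for _ in range(n):
        flat = int(np.argmin(D))          # first occurrence = smallest (i, j)
        i, j = divmod(flat, n)
        total += int(D[i, j])
        D[i, :] = big
        D[:, j] = big
    return total


def similarity_matrix(tables: list[HaplotypeTable], n_draws: int = 100,
                      seed: int = 0, include_reference: bool = True,
                      resample_per: str = "sample") -> DistanceMatrix:
    """Pairwise greedy-pairing distances between resampled populations.

    By default each sample is resampled once and that resample is reused
    across all pairwise comparisons, so the matrix is internally
    consistent; ``resample_per="pair"`` draws a fresh resample for each
    comparison instead.  With ``include_reference`` a fully unmethylated
    synthetic population is appended under the label
    ``"unmethylated_ref"``.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    lengths = {t.n_sites for t in tables}
    loci = {t.locus.name for t in tables}
    if len(lengths) != 1 or len(loci) != 1:
        raise ValueError("samples must share one locus and site set")
    if resample_per not in ("sample", "pair"):
        raise ValueError("resample_per must be 'sample' or 'pair'")
    L = lengths.pop()
    ss = np.random.SeedSequence(seed)
    if resample_per == "sample":
        rngs = [np.random.default_rng(s) for s in ss.spawn(len(tables))]
        samples = [resample_haplotypes(t, n_draws, rng)
                   for t, rng in zip(tables, rngs)]
        if include_reference:
            samples.append(make_unmethylated_reference(L, n_draws))
        n = len(samples)
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = D[j, i] = greedy_pair_distance(samples[i], samples[j])
        labels = [s.sample_id for s in samples]
    else:
        entities: list = list(tables)
        if include_reference:
            entities.append(None)  # reference sentinel
        n = len(entities)
        pair_seeds = iter(ss.spawn(n * (n - 1) // 2))
        D = np.zeros((n, n))
        labels = [t.sample_id if t is not None else UNMETHYLATED_REF
                  for t in entities]
        for i, j in itertools.combinations(range(n), 2):
            rng = np.random.default_rng(next(pair_seeds))
            si = (resample_haplotypes(entities[i], n_draws, rng)
                  if entities[i] is not None
                  else make_unmethylated_reference(L, n_draws))
            sj = (resample_haplotypes(entities[j], n_draws, rng)
                  if entities[j] is not None
                  else make_unmethylated_reference(L, n_draws))
            D[i, j] = D[j, i] = greedy_pair_distance(si, sj)
    return DistanceMatrix(labels=labels, values=D,
                          meta={"n_draws": n_draws, "seed": seed,
                                "resample_per": resample_per})


# ---------------------------------------------------------------------------
# neighbour joining

def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Classical Saitou–Nei neighbour joining.

    Negative branch lengths are clamped to zero (the clamped deficit is
    logged).  When the label ``"unmethylated_ref"`` is present the tree
    is rooted on its pendant edge.
    """
    if len(D.labels) < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    dm = _SkbioDM(D.values, ids=D.labels)
    raw = nj(dm, neg_as_zero=False)
    deficit = sum(min(n.length, 0.0) for n in raw.traverse()
                  if n.length is not None)
    if deficit < 0:
        logger.info("clamped %.4g of negative NJ branch length", -deficit)
    tree = nj(dm, neg_as_zero=True)
    if UNMETHYLATED_REF in D.labels:
        ref = tree.find(UNMETHYLATED_REF)
        tree = tree.root_at(ref, above=True, reset=True)
    return tree


# ---------------------------------------------------------------------------
# binarisation and parsimony

def binarize_ccf(ccf: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Binarise a mutations × samples CCF matrix: 1 iff CCF >= threshold."""
    values = ccf.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("CCF values must be finite")
    return (ccf >= threshold).astype(int)


def _matrix_and_labels(matrix, labels=None):
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=np.int64), list(matrix.columns)
    arr = np.asarray(matrix, dtype=np.int64)
    if labels is None:
        raise ValueError("labels required with an ndarray matrix")
    return arr, list(labels)


def fitch_score(matrix, tree: TreeNode, labels: list[str] | None = None
                ) -> int:
    """Small-parsimony change count of binary characters on a fixed tree.

    ``matrix`` is characters × leaves (DataFrame columns or ``labels``
    name the leaves).  Multifurcating nodes are handled with Hartigan's
    generalisation, which coincides with Fitch on binary nodes.
    """
    arr, labs = _matrix_and_labels(matrix, labels)
    col = {name: i for i, name in enumerate(labs)}
    tip_names = {t.name for t in tree.tips()}
    if tip_names != set(labs):
        raise ValueError("tree leaves do not match matrix columns")
    score, _ = _hartigan_up(tree, arr, col)
    return score


def _hartigan_up(tree: TreeNode, arr: np.ndarray, col: dict[str, int]):
    """Bottom-up pass; returns (total changes, per-node vote arrays)."""
    votes: dict[int, np.ndarray] = {}  # id(node) -> (n_chars, 2) vote counts
    score = 0
    for node in tree.postorder():
        if node.is_tip():
            states = arr[:, col[node.name]]
            v = np.zeros((arr.shape[0], 2), dtype=np.int64)
            v[np.arange(arr.shape[0]), states] = 1
            votes[id(node)] = v
        else:
            child_sets = []
            for c in node.children:
                vc = votes[id(c)]
                child_sets.append((vc == vc.max(axis=1, keepdims=True))
                                  .astype(np.int64))
            v = np.sum(child_sets, axis=0)
            k = v.max(axis=1)
            score += int((len(node.children) - k).sum())
            votes[id(node)] = v
    return score, votes


def _tuple_fitch(sub, X):
    """Fitch on a nested-tuple subtree; X is (n_chars,) -> bitmask arrays."""
    if isinstance(sub, (int, np.integer)):
        return X[:, sub], 0
    a, b = sub
    sa, ca = _tuple_fitch(a, X)
    sb, cb = _tuple_fitch(b, X)
    inter = sa & sb
    changed = inter == 0
    states = np.where(changed, sa | sb, inter)
    return states, ca + cb + int(changed.sum())


def _tuple_score(T, X):
    """Parsimony score of the unrooted tree (leaf 0, T)."""
    s, c = _tuple_fitch(T, X)
    extra = int(((s & X[:, 0]) == 0).sum())
    return c + extra


def _tuple_edges(T, k):
    """All trees obtained by inserting leaf ``k`` on each edge of (0, T)."""
    yield (T, k)  # the edge between leaf 0 and the root of T
    if isinstance(T, tuple):
        a, b = T
        for sub in _tuple_edges(a, k):
            yield (sub, b)
        for sub in _tuple_edges(b, k):
            yield (a, sub)


def _bb_search(X, n_leaves):
    """Exact branch-and-bound over unrooted binary topologies."""
    best = {"score": None, "tree": None}

    def recurse(T, next_leaf):
        score = _tuple_score(T, X)
        if best["score"] is not None and score >= best["score"]:
            return
        if next_leaf == n_leaves:
            best["score"], best["tree"] = score, T
            return
        for T2 in _tuple_edges(T, next_leaf):
            recurse(T2, next_leaf + 1)

    recurse((1, 2), 3) if n_leaves > 3 else None
    if n_leaves == 3:
        best["score"], best["tree"] = _tuple_score((1, 2), X), (1, 2)
    return best["tree"], best["score"]


def _nni_neighbors(T):
    """All NNI rearrangements of the unrooted tree (0, T)."""
    out = []

    def walk(sub, rebuild):
        if not isinstance(sub, tuple):
            return
        a, b = sub
        # NNI across the edge above (a, b) when it has a sibling context
        walk(a, lambda s: rebuild((s, b)))
        walk(b, lambda s: rebuild((a, s)))
        # swaps across the internal edge between sub and each tuple child
        for child, other in ((a, b), (b, a)):
            if isinstance(child, tuple):
                x, y = child
                out.append(rebuild(((x, other), y)))
                out.append(rebuild((x, (y, other))))

    walk(T, lambda s: s)
    return out


def _random_tree(n_leaves, rng):
    order = list(rng.permutation(np.arange(1, n_leaves)))
    T = (int(order[0]), int(order[1]))
    for k in order[2:]:
        choices = list(_tuple_edges(T, int(k)))
        T = choices[rng.integers(len(choices))]
    return T


def _nj_start_tuple(arr, n_leaves):
    """Starting topology from NJ on Hamming distances between profiles."""
    prof = arr.T  # leaves × characters
    D = (prof[:, None, :] != prof[None, :, :]).sum(axis=2).astype(float)
    ids = [str(i) for i in range(n_leaves)]
    tree = nj(_SkbioDM(D, ids=ids), neg_as_zero=True)
    tree = tree.root_at(tree.find("0"), above=True)

    def to_tuple(node):
        if node.is_tip():
            return int(node.name)
        parts = [to_tuple(c) for c in node.children]
        T = parts[0]
        for p in parts[1:]:
            T = (T, p)
        return T

    others = [c for c in tree.children if not (c.is_tip() and c.name == "0")]
    T = to_tuple(others[0]) if len(others) == 1 else None
    if T is None:
        parts = [to_tuple(c) for c in others]
        T = parts[0]
        for p in parts[1:]:
            T = (T, p)
    return T


def _tuple_to_treenode(T, labels):
    def build(sub):
        if isinstance(sub, (int, np.integer)):
            return TreeNode(name=labels[int(sub)])
        a, b = sub
        return TreeNode(children=[build(a), build(b)])
    root = TreeNode(children=[TreeNode(name=labels[0]), build(T)])
    return root


def max_parsimony_tree(matrix, labels: list[str] | None = None,
                       max_exhaustive_leaves: int = 9, seed: int = 0,
                       n_restarts: int = 25,
                       outgroup: str | None = None
                       ) -> tuple[TreeNode, int]:
    """Maximum-parsimony tree for a binary characters × leaves matrix.

    For up to ``max_exhaustive_leaves`` leaves the minimum over all
    unrooted binary topologies is found exactly by branch and bound;
    beyond that, NNI hill-climbing from a neighbour-joining start plus
    ``n_restarts`` seeded random restarts is used.  When ``outgroup``
    names a leaf (e.g. an all-zero germline profile) the tree is rooted
    on its pendant edge; otherwise the returned tree is arbitrarily
    rooted on the first leaf's pendant edge.

    Returns ``(tree, parsimony score)``.
    """
    arr, labs = _matrix_and_labels(matrix, labels)
    n = len(labs)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    X = np.left_shift(1, arr)  # state bitmasks: 0 -> 1, 1 -> 2
    if n <= max_exhaustive_leaves:
        T, score = _bb_search(X, n)
    else:
        rng = np.random.default_rng(seed)
        starts = [_nj_start_tuple(arr, n)]
        starts += [_random_tree(n, rng) for _ in range(n_restarts - 1)]
        best_T, best_s = None, None
        for T in starts:
            s = _tuple_score(T, X)
            improved = True
            while improved:
                improved = False
                for T2 in _nni_neighbors(T):
                    s2 = _tuple_score(T2, X)
                    if s2 < s:
                        T, s = T2, s2
                        improved = True
                        break
            if best_s is None or s < best_s:
                best_T, best_s = T, s
        T, score = best_T, best_s
    tree = _tuple_to_treenode(T, labs)
    if outgroup is not None:
        if outgroup not in labs:
            raise ValueError(f"outgroup {outgroup!r} not among leaves")
        tree = tree.root_at(tree.find(outgroup), above=True, reset=True)
    return tree, score


def acctran_edge_lengths(tree: TreeNode, matrix,
                         labels: list[str] | None = None) -> TreeNode:
    """Assign edge lengths by the ACCTRAN criterion.

    States are chosen from the bottom-up parsimony state sets, keeping
    the parent's state whenever it is admissible — which places ambiguous
    changes as close to the root as possible (accelerated
    transformation).  Each edge's length is the number of characters
    changing along it; the lengths sum exactly to the parsimony score.
    The tree must be rooted (bifurcating root); at a fully ambiguous root
    the unmethylated/germline state 0 is preferred.
    """
    if len(tree.children) != 2:
        raise ValueError("tree is unrooted: root it first "
                         "(e.g. on the unmethylated/germline outgroup)")
    arr, labs = _matrix_and_labels(matrix, labels)
    col = {name: i for i, name in enumerate(labs)}
    tree = tree.copy()
    _, votes = _hartigan_up(tree, arr, col)
    # Hartigan "upper sets": states with maximal votes
    upper = {k: (v == v.max(axis=1, keepdims=True)) for k, v in votes.items()}
    state: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        up = upper[id(node)]
        if node.is_root():
            s = np.where(up[:, 0], 0, 1)  # prefer ancestral 0 on ambiguity
        else:
            p = state[id(node.parent)]
            keep = up[np.arange(arr.shape[0]), p].astype(bool)
            forced = np.where(up[:, 0], 0, 1)
            s = np.where(keep, p, forced)
            node.length = float((s != p).sum())
        state[id(node)] = s
    tree.length = None
    return tree


# ---------------------------------------------------------------------------
# cluster projection and seeding classification

@dataclass
class ClusterAssignment:
    """A mutation cluster with per-sample mean CCFs."""

    cluster_id: str
    mutation_ids: tuple[str, ...]
    mean_ccf: dict[str, float]

    def __post_init__(self) -> None:
        for s, v in self.mean_ccf.items():
            if not (0.0 <= v <= 1.5):  # slack above 1 for CCF noise
                raise ValueError(
                    f"cluster {self.cluster_id}: CCF {v} in sample {s} "
                    "outside [0, 1.5]")

    def present_in(self, threshold: float = 0.2) -> set[str]:
        return {s for s, v in self.mean_ccf.items() if v >= threshold}


def cluster_tree_compatibility(clusters: list[ClusterAssignment],
                               tree: TreeNode,
                               presence_threshold: float = 0.2
                               ) -> dict[str, dict]:
    """Project clusters onto a sample tree.

    A cluster is *compatible* when the set of leaves in which it is
    present (mean CCF >= threshold) forms a clade of the rooted tree (or
    the full leaf set — the trunk); otherwise it conflicts with the tree.
    """
    leaves = frozenset(t.name for t in tree.tips())
    clades = {leaves}
    for node in tree.postorder():
        if not node.is_tip():
            clades.add(frozenset(t.name for t in node.tips()))
        else:
            clades.add(frozenset([node.name]))
    out = {}
    for cl in clusters:
        present = frozenset(cl.present_in(presence_threshold)) & leaves
        compatible = present in clades or present == leaves
        out[cl.cluster_id] = {"compatible": compatible,
                              "leaves": set(present)}
    return out


def derive_cluster_ancestry(clusters: list[ClusterAssignment],
                            presence_threshold: float = 0.2,
                            tol: float = 1e-9) -> dict[str, set[str]]:
    """Infer the ancestor relation from CCF nesting (pigeonhole).

    Cluster A is taken as an ancestor of cluster B when A is present in
    every sample where B is present and A's mean CCF is >= B's in all of
    them.  Returns ``ancestors[cluster_id] -> set of ancestor ids``.
    """
    anc: dict[str, set[str]] = {c.cluster_id: set() for c in clusters}
    for a in clusters:
        for b in clusters:
            if a.cluster_id == b.cluster_id:
                continue
            pb = b.present_in(presence_threshold)
            if not pb:
                continue
            if all(a.mean_ccf.get(s, 0.0) >= b.mean_ccf[s] - tol
                   for s in pb) and pb <= a.present_in(presence_threshold):
                anc[b.cluster_id].add(a.cluster_id)
    return anc


def detect_polyclonal_seeding(clusters: list[ClusterAssignment],
                              presence_threshold: float = 0.2,
                              ancestry: dict[str, set[str]] | None = None
                              ) -> dict[str, dict]:
    """Classify each sample as monoclonally or polyclonally seeded.

    A metastasis is polyclonally seeded only when it is founded by cells
    carrying mutations from clusters that are **not hierarchically
    related**: the sample is flagged polyclonal iff at least two clusters
    are present (mean CCF >= threshold) that are mutually unrelated in
    the cluster ancestry partial order.  The ancestry may be supplied
    (``ancestry[c]`` = set of ancestors of ``c``, e.g. from a clone
    tree) or is derived from CCF nesting.

    Raises ``ValueError`` when the supplied ancestry contains a cycle.
    """
    if ancestry is None:
        ancestry = derive_cluster_ancestry(clusters, presence_threshold)
    for c, anc in ancestry.items():
        if c in anc:
            raise ValueError(f"ancestry cycle at cluster {c}")
    for a in ancestry:
        for b in ancestry:
            if a != b and a in ancestry.get(b, set()) \
                    and b in ancestry.get(a, set()):
                raise ValueError(f"ancestry cycle between {a} and {b}")
    samples = sorted({s for c in clusters for s in c.mean_ccf})
    out = {}
    for s in samples:
        present = [c for c in clusters
                   if c.mean_ccf.get(s, 0.0) >= presence_threshold]
        unrelated_pairs = [
            (a.cluster_id, b.cluster_id)
            for a, b in itertools.combinations(present, 2)
            if a.cluster_id not in ancestry.get(b.cluster_id, set())
            and b.cluster_id not in ancestry.get(a.cluster_id, set())]
        out[s] = {
            "verdict": "polyclonal" if unrelated_pairs else "monoclonal",
            "clusters": [c.cluster_id for c in present],
            "unrelated_pairs": unrelated_pairs,
        }
    return out
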