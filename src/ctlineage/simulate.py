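"""Synthetic clonal evolution with genetic and epigenetic markers.

The generator produces a rooted clone tree, evolves a methylation clock
along it by per-CpG, per-cell-division stochastic flips (epimutations —
methyltransferase errors that occur orders of magnitude more often than
DNA point mutations), assigns SNVs to branches under the infinite-sites
assumption, and mixes clone populations into sequencing-like outputs:

* per-sample methylation haplotype tables (multinomial reads over the
  clone-fraction-weighted cell mixture, with normal contamination
  modelled as fully unmethylated molecules),
* per-sample somatic variant records with binomial read noise and the
  matching ground-truth CCF matrix,
* ctDNA feature vectors that are known weighted mixtures of the tissue
  profiles.

Every generator is deterministic for a fixed seed, so the whole pipeline
can be validated against ground truth at desk scale.

Methylation model
-----------------
Each CpG flips independently at each cell division: unmethylated ->
methylated with probability ``mu_gain`` and back with ``mu_loss``.  After
``t`` divisions from the unmethylated state the expected methylation is
``pi * (1 - (1 - mu_gain - mu_loss)**t)`` with stationary level
``pi = mu_gain / (mu_gain + mu_loss)`` — the two-state Markov chain
closed form, used to draw end states directly without iterating
divisions.  A clone is modelled as the expansion of ``cells_per_clone``
distinct cell lineages: a clone's founder cell is drawn from its parent's
population, drifts for the branch's division count, and the population
then diversifies for ``expansion_divisions`` further divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ctlineage.clock_haplotypes import ClockLocus, HaplotypeTable
from ctlineage.snv_ccf import SampleCall, VariantRecord


@dataclass
class CloneTree:
    """A rooted clone genealogy.

    ``parents[i]`` is the parent clone of clone ``i`` (None for the
    founder), ``divisions[i]`` the number of cell divisions along the
    branch into clone ``i`` (for the root: divisions since the founder
    cell), and ``branch_snvs[i]`` the SNV ids acquired on that branch.
    Under infinite sites each clone's SNV set is the union along its
    ancestry, so SNV sets are nested.
    """

    parents: tuple[int | None, ...]
    divisions: tuple[int, ...]
    branch_snvs: tuple[frozenset[int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.parents)
        roots = [i for i, p in enumerate(self.parents) if p is None]
        if len(roots) != 1:
            raise ValueError("exactly one founder clone required")
        if any(d < 0 for d in self.divisions):
            raise ValueError("division counts must be >= 0")
        for i, p in enumerate(self.parents):
            if p is not None and not (0 <= p < n and p != i):
                raise ValueError(f"bad parent pointer for clone {i}")
        if not self.branch_snvs:
            self.branch_snvs = tuple(frozenset() for _ in range(n))

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    @property
    def root(self) -> int:
        return next(i for i, p in enumerate(self.parents) if p is None)

    def children(self, clone: int) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p == clone]

    def ancestry(self, clone: int) -> list[int]:
        """Path from the root to ``clone`` (inclusive)."""
        path = [clone]
        while self.parents[path[-1]] is not None:
            path.append(self.parents[path[-1]])
        return path[::-1]

    def snv_profile(self, clone: int) -> frozenset[int]:
        out: set[int] = set()
        for c in self.ancestry(clone):
            out |= self.branch_snvs[c]
        return frozenset(out)

    def all_snvs(self) -> list[int]:
        return sorted({s for b in self.branch_snvs for s in b})

    def to_newick(self) -> str:
        def rec(c: int) -> str:
            kids = self.children(c)
            label = f"clone{c}:{self.divisions[c]}"
            if not kids:
                return label
            return "(" + ",".join(rec(k) for k in kids) + ")" + label
        return rec(self.root) + ";"


@dataclass
class SimulatedSample:
    """A tissue (or plasma) sample as a clone mixture.

    ``clone_fractions`` are fractions of *all* cells; the remainder to 1
    is normal contamination, so the tumour purity equals the fraction
    sum.
    """

    sample_id: str
    clone_fractions: dict[int, float]
    depth: int = 1000

    def __post_init__(self) -> None:
        total = sum(self.clone_fractions.values())
        if any(f < 0 for f in self.clone_fractions.values()):
            raise ValueError("clone fractions must be >= 0")
        if total > 1 + 1e-9:
            raise ValueError("clone fractions must sum to <= 1")

    @property
    def purity(self) -> float:
        return sum(self.clone_fractions.values())

    @property
    def normal_fraction(self) -> float:
        return 1.0 - self.purity


# ---------------------------------------------------------------------------
# clone tree

def simulate_clone_tree(n_clones: int, divisions_per_branch=(50, 500),
                        snvs_per_branch: int = 20, seed: int = 0,
                        parents: tuple[int | None, ...] | None = None
                        ) -> CloneTree:
    """Random rooted clone tree with per-branch divisions and SNVs.

    Each non-root clone attaches to a uniformly chosen earlier clone
    (pass ``parents`` to fix the topology).  ``divisions_per_branch`` is
    a fixed integer or an inclusive (low, high) range sampled uniformly.
    SNV ids are assigned sequentially per branch — the infinite-sites
    assumption, so each mutation arises exactly once.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    rng = np.random.default_rng(seed)
    if parents is None:
        parents = (None,) + tuple(int(rng.integers(0, i))
                                  for i in range(1, n_clones))
    if np.isscalar(divisions_per_branch):
        divisions = tuple(int(divisions_per_branch)
                          for _ in range(n_clones))
    else:
        lo, hi = divisions_per_branch
        divisions = tuple(int(rng.integers(lo, hi + 1))
                          for _ in range(n_clones))
    counter = 0
    branch_snvs = []
    for _ in range(n_clones):
        branch_snvs.append(frozenset(range(counter, counter +
                                           snvs_per_branch)))
        counter += snvs_per_branch
    return CloneTree(parents=parents, divisions=divisions,
                     branch_snvs=tuple(branch_snvs))


# ---------------------------------------------------------------------------
# epimutation drift

def expected_methylation(t, mu_gain: float, mu_loss: float,
                         start: int = 0) -> float:
    """Closed-form per-CpG methylation probability after ``t`` divisions."""
    rate = mu_gain + mu_loss
    if rate == 0:
        return float(start)
    pi = mu_gain / rate
    lam = (1.0 - rate) ** np.asarray(t, dtype=float)
    return pi + (start - pi) * lam


def _drift(states: np.ndarray, t: int, mu_gain: float, mu_loss: float,
           rng: np.random.Generator) -> np.ndarray:
    """Evolve 0/1 state arrays for ``t`` divisions (closed-form draw)."""
    if t == 0 or (mu_gain == 0 and mu_loss == 0):
        return states.copy()
    p_one = expected_methylation(t, mu_gain, mu_loss,
                                 start=states.astype(float))
    return (rng.random(states.shape) < p_one).astype(np.uint8)


def evolve_methylation(tree: CloneTree, n_cpgs: int = 16,
                       mu_gain: float = 0.002, mu_loss: float = 0.002,
                       founder_state: np.ndarray | None = None,
                       cells_per_clone: int = 50,
                       expansion_divisions: int = 5,
                       seed: int = 0) -> dict[int, np.ndarray]:
    """Per-clone haplotype populations after epimutation drift.

    Returns ``{clone: (cells_per_clone, n_cpgs) uint8 array}``.  The
    clone-founding bottleneck is explicit: the root clone is founded by a
    single transformed cell in state ``founder_state`` (default
    all-unmethylated), and every other clone by a single cell drawn from
    its parent's population.  The founder cell drifts for the branch's
    division count and the clone then expands into ``cells_per_clone``
    independent lineages over ``expansion_divisions`` further divisions
    (within-clone epiallele diversity).
    """
    if not (0 <= mu_gain <= 1 and 0 <= mu_loss <= 1):
        raise ValueError("epimutation rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if founder_state is None:
        founder_state = np.zeros(n_cpgs, dtype=np.uint8)
    founder_state = np.asarray(founder_state, dtype=np.uint8)
    pops: dict[int, np.ndarray] = {}
    order = [tree.root]
    while len(order) < tree.n_clones:
        for c in list(order):
            for k in tree.children(c):
                if k not in order:
                    order.append(k)
    for c in order:
        if tree.parents[c] is None:
            founder = founder_state
        else:
            parent_pop = pops[tree.parents[c]]
            founder = parent_pop[rng.integers(parent_pop.shape[0])]
        founder = _drift(founder[None, :], tree.divisions[c],
                         mu_gain, mu_loss, rng)[0]
        base = np.tile(founder, (cells_per_clone, 1))
        pops[c] = _drift(base, expansion_divisions, mu_gain, mu_loss, rng)
    return pops


# ---------------------------------------------------------------------------
# sample synthesis

def _default_locus(n_cpgs: int) -> ClockLocus:
    return ClockLocus("simclock", "chrS",
                      tuple(100 + 2 * i for i in range(n_cpgs)))


def synthesize_samples(tree: CloneTree, pops: dict[int, np.ndarray],
                       samples: list[SimulatedSample], seed: int = 0,
                       locus: ClockLocus | None = None
                       ) -> list[HaplotypeTable]:
    """Sequence each sample: multinomial reads over the clone mixture.

    Each read picks a component (clone, weighted by its fraction, or
    normal contamination, modelled as a fully unmethylated molecule) and
    then a random cell of that clone.  Returns one complete-read
    :class:`HaplotypeTable` per sample.
    """
    rng = np.random.default_rng(seed)
    n_cpgs = next(iter(pops.values())).shape[1]
    locus = locus or _default_locus(n_cpgs)
    tables = []
    for s in samples:
        if s.purity > 1 + 1e-9:
            raise ValueError("clone fractions must sum to <= 1")
        clones = sorted(s.clone_fractions)
        probs = np.array([s.clone_fractions[c] for c in clones]
                         + [s.normal_fraction])
        probs = probs / probs.sum()
        comp = rng.choice(len(probs), size=s.depth, p=probs)
        counts: dict[str, int] = {}
        for ci in comp:
            if ci == len(clones):  # normal contamination
                bits = "0" * n_cpgs
            else:
                pop = pops[clones[ci]]
                cell = pop[rng.integers(pop.shape[0])]
                bits = "".join("1" if b else "0" for b in cell)
            counts[bits] = counts.get(bits, 0) + 1
        tables.append(HaplotypeTable(
            sample_id=s.sample_id, locus=locus, counts=counts,
            site_positions=locus.cpg_positions,
            filters=("coverage", "complete"),
            stats={"n_input": s.depth, "n_complete": s.depth,
                   "n_dropped_missing": 0}))
    return tables


def write_sample_read_calls(table: HaplotypeTable, path) -> None:
    """Emit a per-read simple-calls TSV for a synthesized table (for
    parser round-trips)."""
    with open(path, "wt", encoding="utf-8") as fh:
        i = 0
        for bits in sorted(table.counts):
            for _ in range(table.counts[bits]):
                rid = f"{table.sample_id}.r{i}"
                i += 1
                for pos, b in zip(table.site_positions, bits):
                    call = "M" if b == "1" else "U"
                    fh.write(f"{rid}\t{table.sample_id}\t{table.locus.name}"
                             f"\t{pos}\t{call}\n")


def synthesize_snv_ccfs(tree: CloneTree, samples: list[SimulatedSample],
                        depth: int = 60, seed: int = 0, noise: bool = True,
                        normal_id: str = "normal"
                        ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Variant records with binomial read noise plus the true CCF matrix.

    The true CCF of an SNV in a sample is the summed fraction of clones
    carrying it divided by the tumour content; on a diploid genome with
    one mutated allele the implied VAF is ``CCF * purity / 2``.  With
    ``noise=False`` alt counts are the exact expectations (rounded), so
    CCFs recompute to the truth at the read-count resolution.

    Returns ``(records, truth)`` with ``truth`` indexed by the records'
    mutation keys.
    """
    rng = np.random.default_rng(seed)
    snvs = tree.all_snvs()
    profiles = {c: tree.snv_profile(c) for c in range(tree.n_clones)}
    records = []
    truth_rows = {}
    for j, snv in enumerate(snvs):
        key_chrom, key_pos = "chr1", 10_000 + j
        calls = {normal_id: SampleCall(depth=depth, alt_count=0,
                                       genotype="0/0")}
        row = {}
        for s in samples:
            carried = sum(f for c, f in s.clone_fractions.items()
                          if snv in profiles[c])
            ccf = carried / s.purity if s.purity > 0 else 0.0
            row[s.sample_id] = ccf
            vaf = ccf * s.purity / 2.0
            if noise:
                alt = int(rng.binomial(depth, vaf))
            else:
                alt = vaf * depth
            gt = "0/1" if (alt if noise else round(alt)) > 0 else "0/0"
            calls[s.sample_id] = SampleCall(
                depth=depth, alt_count=alt, genotype=gt)
        rec = VariantRecord(chromosome=key_chrom, position=key_pos,
                            ref="A", alt="T", samples=calls,
                            mappability=1.0, in_repeat=False,
                            cn_total=2.0, cn_clonal=True,
                            info={"snv_id": snv})
        records.append(rec)
        truth_rows[rec.key] = row
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth = truth[[s.sample_id for s in samples]]
    return records, truth


#: default drift-study genealogy: root, two ancestral lineages, four extant
#: clones (two sisters under each ancestor); ancestors are not sampled.
DRIFT_STUDY_PARENTS: tuple[int | None, ...] = (None, 0, 0, 1, 1, 2, 2)

#: default per-branch divisions for the drift study: a longer shared history
#: within the primary (root 10, ancestral branches 15) and brief recent
#: metastatic expansions (leaf branches 5).
DRIFT_STUDY_DIVISIONS: tuple[int, ...] = (10, 15, 15, 5, 5, 5, 5)


def simulate_drift_study(seed: int, n_cpgs: int = 16, mu_gain: float = 0.02,
                         mu_loss: float = 0.002, depth: int = 1000,
                         purity: float = 0.95, cells_per_clone: int = 50,
                         expansion_divisions: int = 3) -> dict:
    """One replicate of the default epimutation-drift study.

    Four extant clones related as ((c3,c4),(c5,c6)) through two unsampled
    ancestral lineages are sequenced at the given depth; the ground-truth
    sister pairs are returned alongside the haplotype tables so a caller
    can ask whether a reconstructed genealogy groups them correctly.
    """
    tree = CloneTree(parents=DRIFT_STUDY_PARENTS,
                     divisions=DRIFT_STUDY_DIVISIONS)
    pops = evolve_methylation(tree, n_cpgs=n_cpgs, mu_gain=mu_gain,
                              mu_loss=mu_loss,
                              cells_per_clone=cells_per_clone,
                              expansion_divisions=expansion_divisions,
                              seed=seed)
    leaf_clones = [3, 4, 5, 6]
    samples = [SimulatedSample(f"c{i}", {i: purity}, depth=depth)
               for i in leaf_clones]
    tables = synthesize_samples(tree, pops, samples, seed=seed)
    return {"tree": tree, "pops": pops, "tables": tables,
            "sample_ids": [s.sample_id for s in samples],
            "sister_pairs": [("c3", "c4"), ("c5", "c6")]}


def simulate_deconvolution_study(seed: int,
                                 weights=(0.6, 0.3, 0.1, 0.0, 0.0),
                                 snvs_per_branch: int = 40,
                                 depth: int = 1000, purity: float = 0.95
                                 ) -> dict:
    """One replicate of the default ctDNA-deconvolution study.

    Five tissue lesions are seeded independently from the primary (star
    clone tree), so each carries private mutations and a distinct
    methylation-haplotype population; ctDNA is a known weighted mixture
    of the tissue profiles with read noise at the given depth.  Returns
    the noisy tissue records, the true CCF matrix, the noisy ctDNA CCF
    vector, the tissue haplotype tables and the noisy ctDNA haplotype
    frequencies.
    """
    n_tissues = len(weights)
    star = (None,) + (0,) * n_tissues
    tree = simulate_clone_tree(n_tissues + 1, divisions_per_branch=15,
                               snvs_per_branch=snvs_per_branch, seed=seed,
                               parents=star)
    tissues = [SimulatedSample(f"t{i}", {i + 1: purity}, depth=depth)
               for i in range(n_tissues)]
    records, truth = synthesize_snv_ccfs(tree, tissues, depth=depth,
                                         seed=seed)
    y_ccf, clean_ccf = synthesize_ctdna(truth, weights, depth=depth,
                                        seed=seed + 1, mode="ccf")
    pops = evolve_methylation(tree, n_cpgs=16, mu_gain=0.02, mu_loss=0.002,
                              cells_per_clone=50, expansion_divisions=3,
                              seed=seed)
    tables = synthesize_samples(tree, pops, tissues, seed=seed + 2)
    return {"tree": tree, "tissues": tissues, "records": records,
            "truth": truth, "y_ccf": y_ccf, "clean_ccf": clean_ccf,
            "tables": tables, "weights": np.asarray(weights, dtype=float)}


def synthesize_ctdna(tissue_profiles: pd.DataFrame, weights, depth: int =
                     1000, seed: int = 0, mode: str = "fraction"
                     ) -> tuple[pd.Series, pd.Series]:
    """ctDNA feature vector as a known mixture of tissue profiles.

    ``tissue_profiles`` is features × tissue samples; ``weights`` (same
    order as the columns, non-negative, summing to 1) define the mixture
    ``clean = profiles @ w``.  Read noise at the given depth is binomial
    per feature for ``mode="fraction"``/``"ccf"`` (CCF values are mapped
    through the implied allele fraction, i.e. halved, before drawing) and
    multinomial across features for ``mode="haplotype"`` (frequencies
    summing to 1).

    Returns ``(noisy, clean)``.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    if w.size != tissue_profiles.shape[1]:
        raise ValueError("one weight per tissue column required")
    rng = np.random.default_rng(seed)
    clean = pd.Series(tissue_profiles.to_numpy(dtype=float) @ w,
                      index=tissue_profiles.index)
    if mode in ("fraction", "ccf"):
        scale = 0.5 if mode == "ccf" else 1.0
        p = np.clip(clean.to_numpy() * scale, 0.0, 1.0)
        noisy = rng.binomial(depth, p) / (depth * scale)
    elif mode == "haplotype":
        p = clean.to_numpy()
        total = p.sum()
        if total <= 0:
            raise ValueError("haplotype mode needs positive frequencies")
        draws = rng.multinomial(depth, p / total)
        noisy = draws / depth * total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(noisy, index=tissue_profiles.index), clean
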