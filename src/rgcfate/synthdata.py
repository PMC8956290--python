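"""Synthetic time-course scRNA-seq with a planted fate tree.

The generator emulates the structure of a developing neuronal class sampled
at 5-6 ages: terminal types organized into subclasses on a binary fate tree,
progressive and asynchronous fate restriction (each internal node has a
"decouple time" after which its two descendant branches separate), counts
drawn from a Poisson model with Gamma-distributed library-size factors, batch
structure within each age, and an optional ipsilateral/contralateral gene
signature expressed in mutually exclusive early subsets.

Because the fate vector of every simulated cell is known exactly, the
downstream estimators (transport-based fate vectors, potential, couplings,
specification times, laterality propagation) can be validated against a
planted ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


# ---------------------------------------------------------------------------
# fate tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of the fate tree.

    Internal nodes carry a ``decouple_time``: before it the two child
    branches are statistically interchangeable, after it fate mass
    concentrates on one branch per cell.
    """

    node_id: int
    children: tuple[int, int] | None  # None for leaves
    leaves: tuple[int, ...]  # terminal type indices under this node
    decouple_time: float  # for leaves: time their parent decoupled


@dataclass
class FateTree:
    """Binary fate tree over terminal types, with subclasses as clades."""

    n_types: int
    nodes: dict[int, TreeNode]
    root: int
    subclass_labels: np.ndarray  # per terminal type, subclass index
    age_grid: tuple[float, ...]
    seed: int

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.children is not None]

    def leaf_node_id(self, type_idx: int) -> int:
        return self._leaf_ids[type_idx]

    def __post_init__(self) -> None:
        self._leaf_ids = {
            n.leaves[0]: n.node_id
            for n in self.nodes.values()
            if n.children is None
        }
        # parent map for clade queries
        self.parent = {}
        for n in self.nodes.values():
            if n.children is not None:
                for c in n.children:
                    self.parent[c] = n.node_id

    def decouple_time_of_type(self, type_idx: int) -> float:
        """Age at which a terminal type separates from its sibling branch."""
        return self.nodes[self.leaf_node_id(type_idx)].decouple_time

    def clades(self, min_size: int = 1) -> list[tuple[int, ...]]:
        """All leaf sets of tree nodes with at least ``min_size`` leaves."""
        return [n.leaves for n in self.nodes.values() if len(n.leaves) >= min_size]


def make_fate_tree(
    n_types: int,
    n_subclasses: int,
    age_grid,
    decouple_spread: float = 0.1,
    root_lead: float = 2.0,
    seed: int = 0,
) -> FateTree:
    """Build a random binary fate tree whose decouple times span the age grid.

    Subclasses are clades: a binary tree is first built over subclasses (these
    nodes decouple earliest), then within each subclass. Internal nodes take
    decouple times in a randomized topological order, evenly spread (with
    Gaussian jitter of sd ``decouple_spread`` times the grid span) from
    ``root_lead`` days *before* the first sampled age - so restriction is
    already under way at the first snapshot, as in the real time course -
    to the second-to-last age, by when nearly all pairs have separated;
    times never decrease from root to leaf.
    """
    age_grid = tuple(float(a) for a in age_grid)
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if not all(b > a for a, b in zip(age_grid, age_grid[1:])):
        raise ValueError("age_grid must be strictly increasing")
    if n_subclasses > n_types:
        raise ValueError("n_subclasses cannot exceed n_types")
    if n_subclasses < 1:
        raise ValueError("n_subclasses must be >= 1")

    rng = np.random.default_rng(seed)

    # contiguous partition of type indices into subclasses
    sizes = np.full(n_subclasses, n_types // n_subclasses)
    sizes[: n_types % n_subclasses] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    subclass_labels = np.zeros(n_types, dtype=int)
    groups = []
    for s in range(n_subclasses):
        members = tuple(range(bounds[s], bounds[s + 1]))
        subclass_labels[list(members)] = s
        groups.append(members)

    nodes: dict[int, TreeNode] = {}
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0] - 1

    def build_over(blocks: list[tuple[int, ...]]) -> int:
        """Random binary tree whose leaves are the given blocks (returned ids)."""
        if len(blocks) == 1:
            block = blocks[0]
            if len(block) == 1:
                nid = new_id()
                nodes[nid] = TreeNode(nid, None, block, np.nan)
                return nid
            # split the block itself
            cut = int(rng.integers(1, len(block)))
            left = build_over([block[:cut]])
            right = build_over([block[cut:]])
        else:
            cut = int(rng.integers(1, len(blocks)))
            left = build_over(blocks[:cut])
            right = build_over(blocks[cut:])
        nid = new_id()
        leaves = tuple(sorted(nodes[left].leaves + nodes[right].leaves))
        nodes[nid] = TreeNode(nid, (left, right), leaves, np.nan)
        return nid

    root = build_over(groups)

    # depth of every internal node
    depth: dict[int, int] = {root: 0}
    order: list[int] = [root]
    stack = [root]
    while stack:
        nid = stack.pop()
        node = nodes[nid]
        if node.children is None:
            continue
        for c in node.children:
            depth[c] = depth[nid] + 1
            order.append(c)
            stack.append(c)
    max_depth = max(
        (depth[n.node_id] for n in nodes.values() if n.children is not None),
        default=0,
    )

    lo, hi = age_grid[0], age_grid[-1]
    span = hi - lo
    last_decouple = age_grid[-2] if len(age_grid) > 2 else hi
    # decouple times: evenly spread in breadth-first order from just before
    # the first age to the second-to-last age (by when nearly all pairs have
    # separated), jittered, and non-decreasing from root to leaves
    n_internal = sum(1 for n in nodes.values() if n.children is not None)
    slots = np.linspace(lo - root_lead, last_decouple, max(n_internal, 2))
    # randomized topological order: any node whose parent is timed may take
    # the next slot, so sibling subtrees decouple asynchronously
    nodes[root].decouple_time = lo - root_lead
    ready = [c for c in nodes[root].children if nodes[c].children is not None]
    slot_i = 1
    while ready:
        nid = ready.pop(int(rng.integers(len(ready))))
        node = nodes[nid]
        t = slots[min(slot_i, len(slots) - 1)] + rng.normal(0.0, decouple_spread * span)
        slot_i += 1
        parent_t = nodes[_parent_of(nodes, nid)].decouple_time
        node.decouple_time = float(np.clip(t, max(parent_t, lo - root_lead), last_decouple))
        ready.extend(c for c in node.children if nodes[c].children is not None)
    # leaves inherit the parent's decouple time (the age the type separates)
    for node in nodes.values():
        if node.children is None:
            node.decouple_time = nodes[_parent_of(nodes, node.node_id)].decouple_time \
                if _parent_of(nodes, node.node_id) is not None else lo

    return FateTree(
        n_types=n_types,
        nodes=nodes,
        root=root,
        subclass_labels=subclass_labels,
        age_grid=age_grid,
        seed=seed,
    )


def _parent_of(nodes: dict[int, TreeNode], nid: int) -> int | None:
    for n in nodes.values():
        if n.children is not None and nid in n.children:
            return n.node_id
    return None


# ---------------------------------------------------------------------------
# ground-truth fates
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-cell planted truth: age, batch, fate vector, state, laterality."""

    cells: pd.DataFrame  # age, batch, true_type, true_cluster, clump, laterality, lib_factor
    fates: np.ndarray  # n_cells x n_types, rows sum to 1
    tree: FateTree
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def fate_frame(self) -> pd.DataFrame:
        cols = [f"type{j}" for j in range(self.tree.n_types)]
        return pd.DataFrame(self.fates, index=self.cells.index, columns=cols)

    def planted_partition(self, commit_threshold: float = 1.5) -> np.ndarray:
        """Planted cluster label per cell, mirroring what clustering sees.

        Committed cells (planted potential below ``commit_threshold``) form
        type-aligned clusters; uncommitted cells cluster by lineage state
        crossed with their maturation micro-state (``clump``), because the
        fate-orthogonal continuum dominates their expression.
        """
        pot = 1.0 / (self.fates**2).sum(axis=1)
        committed = pot < commit_threshold
        state = self.cells["true_cluster"].to_numpy()
        clump = self.cells["clump"].to_numpy()
        destined = self.cells["true_type"].to_numpy()
        n_clumps = int(clump.max()) + 1
        labels = np.where(
            committed,
            destined,
            self.tree.n_types + state * n_clumps + clump,
        )
        return labels


def _branch_weight(t: float, decouple_time: float, sharpness: float, terminal: bool) -> float:
    """Commitment weight in [0, 1]: 0 before decoupling, -> 1 after."""
    if terminal:
        return 1.0
    return float(1.0 - np.exp(-sharpness * max(0.0, t - decouple_time)))


def _cell_fate_vector(
    tree: FateTree, destined: int, t: float, sharpness: float, terminal: bool
) -> np.ndarray:
    """Fate vector = product of per-node branch probabilities down the tree.

    At nodes on the destined path the destined branch gets
    ``base + w * (1 - base)`` where ``base`` is its leaf fraction and ``w``
    the commitment weight; off-path subtrees split mass by leaf fractions.
    """
    f = np.zeros(tree.n_types)
    # stack of (node_id, mass, on_destined_path)
    stack: list[tuple[int, float, bool]] = [(tree.root, 1.0, True)]
    while stack:
        nid, mass, on_path = stack.pop()
        node = tree.nodes[nid]
        if mass == 0.0:
            continue
        if node.children is None:
            f[node.leaves[0]] += mass
            continue
        left, right = node.children
        n_left = len(tree.nodes[left].leaves)
        n_tot = len(node.leaves)
        base_left = n_left / n_tot
        if on_path and destined in node.leaves:
            dest_left = destined in tree.nodes[left].leaves
            w = _branch_weight(t, node.decouple_time, sharpness, terminal)
            base_dest = base_left if dest_left else 1.0 - base_left
            p_dest = base_dest + w * (1.0 - base_dest)
            p_left = p_dest if dest_left else 1.0 - p_dest
            stack.append((left, mass * p_left, dest_left))
            stack.append((right, mass * (1.0 - p_left), not dest_left))
        else:
            stack.append((left, mass * base_left, False))
            stack.append((right, mass * (1.0 - base_left), False))
    return f


def _true_cluster(tree: FateTree, destined: int, t: float, terminal: bool) -> int:
    """Effective lineage state: deepest node on the destined path already decoupled."""
    if terminal:
        return tree.leaf_node_id(destined)
    nid = tree.root
    while True:
        node = tree.nodes[nid]
        # strict: a node splits the state only once its branches have begun
        # to diverge in expression (t past the decouple time)
        if node.children is None or node.decouple_time >= t:
            return nid
        left, right = node.children
        nid = left if destined in tree.nodes[left].leaves else right


def simulate_fates(
    tree: FateTree,
    n_cells_per_age: int,
    age_grid=None,
    sharpness: float = 0.5,
    n_batches: int = 2,
    n_clumps: int = 4,
    seed: int = 0,
) -> GroundTruth:
    """Simulate per-cell planted fate vectors across the age grid.

    Each cell carries a destined terminal type (sampled uniformly); its fate
    vector is the product of branch probabilities along the tree, with
    commitment accumulating after each node's decouple time at rate
    ``sharpness`` (per day). At the terminal age every fate vector is a point
    mass; in the ``sharpness -> 0`` limit fate vectors stay at the leaf-count
    baseline (uniform over types) at all pre-terminal ages.
    """
    if sharpness < 0:
        raise ValueError("sharpness must be > 0 (use a small value for weak restriction)")
    ages = tuple(float(a) for a in (age_grid if age_grid is not None else tree.age_grid))
    rng = np.random.default_rng(seed)

    records = []
    fate_rows = []
    terminal_age = ages[-1]
    for t in ages:
        terminal = t >= terminal_age
        destined_types = rng.integers(0, tree.n_types, size=n_cells_per_age)
        batches = rng.integers(0, n_batches, size=n_cells_per_age)
        clumps = rng.integers(0, n_clumps, size=n_cells_per_age)
        for i in range(n_cells_per_age):
            d = int(destined_types[i])
            fate_rows.append(_cell_fate_vector(tree, d, t, sharpness, terminal))
            records.append(
                {
                    "age": t,
                    "batch": int(batches[i]),
                    "true_type": d,
                    "true_cluster": _true_cluster(tree, d, t, terminal),
                    "clump": int(clumps[i]),
                    "laterality": "none",
                    "lib_factor": 1.0,
                }
            )
    cells = pd.DataFrame(records)
    cells.index = pd.Index([f"cell{i:06d}" for i in range(len(cells))], name="cell")
    fates = np.vstack(fate_rows)
    np.testing.assert_allclose(fates.sum(axis=1), 1.0, atol=1e-9)
    return GroundTruth(cells=cells, fates=fates, tree=tree, seed=seed)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    truth: GroundTruth,
    n_genes: int = 1000,
    programs_per_type: int = 8,
    program_strength: float = 12.0,
    batch_effect_sd: float = 0.0,
    batch_gene_frac: float = 0.1,
    libsize_shape: float = 10.0,
    mean_counts_per_cell: float = 2000.0,
    maturation_frac: float = 0.1,
    aux_dim: int = 3,
    aux_strength: float = 1.0,
    aux_gene_frac: float = 0.2,
    aux_fade_power: float = 1.0,
    aux_persistence: float = 0.0,
    seed: int = 0,
) -> CountMatrix:
    """Draw transcript counts from the planted truth.

    Each terminal type owns a disjoint sparse gene program; a cell's expected
    expression is the fate-weighted mixture of type programs plus a shared
    age-dependent maturation program over a common baseline. On top of the
    fate-aligned programs, ``aux_dim`` continuous fate-orthogonal axes
    (random per-cell scores loading a random gene subset) emulate the
    maturation/positional continuum that dominates early heterogeneity in
    real precursors; each cell's continuum amplitude fades with its own
    commitment (``clip(potential - 1, 0, 1) ** aux_fade_power``), so
    uncommitted cells form arbitrary cuts of a continuum while specified
    cells coalesce into type-aligned clusters. Counts are Poisson with a per-cell library
    factor drawn from a Gamma distribution of shape ``libsize_shape`` (mean
    1), matching the technical-noise null used for highly-variable-gene
    selection: without planted programs or batch shifts the counts are
    exactly Gamma-Poisson. Batch effects multiply a random
    ``batch_gene_frac`` subset of genes by a log-normal factor of log-sd
    ``batch_effect_sd`` per (age, batch).
    """
    tree = truth.tree
    n_prog = tree.n_types * programs_per_type
    n_mat = int(round(maturation_frac * n_genes))
    if n_prog + n_mat > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for {n_prog} program genes "
            f"+ {n_mat} maturation genes"
        )
    rng = np.random.default_rng(seed)
    n_cells = truth.n_cells

    # baseline rates: log-normal spread across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # disjoint programs
    gene_perm = rng.permutation(n_genes)
    prog_genes = gene_perm[:n_prog].reshape(tree.n_types, programs_per_type)
    mat_genes = gene_perm[n_prog : n_prog + n_mat]

    # boost matrix: genes x types, sparse
    boost = np.zeros((n_genes, tree.n_types))
    for b in range(tree.n_types):
        boost[prog_genes[b], b] = program_strength

    ages = truth.cells["age"].to_numpy()
    age_span = max(ages.max() - ages.min(), 1.0)
    age_frac = (ages - ages.min()) / age_span
    mat_slopes = rng.choice([-1.0, 1.0], size=n_mat) * rng.uniform(0.5, 1.5, size=n_mat)

    # expected rates: baseline * (1 + fate-weighted program boost)
    rates = np.tile(base[:, None], (1, n_cells))
    rates *= 1.0 + boost @ truth.fates.T
    rates[mat_genes, :] *= np.exp(np.outer(mat_slopes, age_frac))

    # fate-orthogonal continuum: fades as each cell commits (the immature
    # maturation/positional programs are shed asynchronously with
    # specification, not on a global clock)
    if aux_dim > 0 and aux_strength > 0:
        n_aux_genes = int(round(aux_gene_frac * n_genes))
        aux_genes = rng.choice(n_genes, size=n_aux_genes, replace=False)
        loadings = rng.normal(0.0, 1.0, size=(n_aux_genes, aux_dim))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        # clumpy continuum: micro-state centers (ids planted in the truth)
        # plus within-clump spread; centers drift between ages (persistence
        # aux_persistence) - the early maturation/positional axes are not
        # stable lineages, so their cross-age correspondence is only partial
        clump = truth.cells["clump"].to_numpy()
        n_clumps = int(clump.max()) + 1
        scores = np.empty((n_cells, aux_dim))
        centers = rng.normal(0.0, 1.5, size=(n_clumps, aux_dim))
        rho = aux_persistence
        for t in np.unique(ages):
            m = ages == t
            scores[m] = centers[clump[m]] + rng.normal(0.0, 0.5, size=(int(m.sum()), aux_dim))
            centers = rho * centers + np.sqrt(1.0 - rho**2) * rng.normal(
                0.0, 1.5, size=(n_clumps, aux_dim)
            )
        cell_potential = 1.0 / (truth.fates**2).sum(axis=1)
        fade = np.clip(cell_potential - 1.0, 0.0, 1.0) ** aux_fade_power
        rates[aux_genes, :] *= np.exp(aux_strength * fade[None, :] * (loadings @ scores.T))
        for d in range(aux_dim):
            truth.cells[f"aux{d}"] = scores[:, d]

    # batch effects on a random gene subset per (age, batch)
    if batch_effect_sd > 0:
        batches = truth.cells["batch"].to_numpy()
        for key in sorted(set(zip(ages.tolist(), batches.tolist()))):
            mask = (ages == key[0]) & (batches == key[1])
            n_shift = int(round(batch_gene_frac * n_genes))
            shift_genes = rng.choice(n_genes, size=n_shift, replace=False)
            factors = np.exp(rng.normal(0.0, batch_effect_sd, size=n_shift))
            rates[np.ix_(shift_genes, np.where(mask)[0])] *= factors[:, None]

    # normalize so each cell's expected total is mean_counts_per_cell
    rates *= mean_counts_per_cell / rates.sum(axis=0, keepdims=True)

    lib = rng.gamma(shape=libsize_shape, scale=1.0 / libsize_shape, size=n_cells)
    counts = rng.poisson(rates * lib[None, :])

    truth.cells["lib_factor"] = lib

    genes = pd.Index([f"g{m:05d}" for m in range(n_genes)], name="gene")
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        genes=genes,
        cells=truth.cells.index,
        obs=truth.cells.copy(),
    )
    cm.obs.attrs["seed"] = seed
    cm.program_genes = {b: [f"g{m:05d}" for m in prog_genes[b]] for b in range(tree.n_types)}
    return cm


# ---------------------------------------------------------------------------
# laterality planting
# ---------------------------------------------------------------------------

def plant_laterality(
    truth: GroundTruth,
    counts: CountMatrix,
    frac_ipsi: float = 0.05,
    ipsi_genes=("Zic2", "Zic1", "Igfbp5"),
    contra_genes=("Isl2", "Fgf12", "Igf1"),
    fade_age: float | None = None,
    signal_rate: float = 8.0,
    clade_size: int = 3,
    seed: int = 0,
) -> CountMatrix:
    """Plant mutually exclusive ipsi/contra signatures in early-age cells.

    A ``frac_ipsi`` subset of cells at ages ``<= fade_age`` is labeled ``I``
    and overexpresses ``ipsi_genes`` while suppressing ``contra_genes``; a
    matched disjoint subset is labeled ``C`` with the roles reversed. After
    ``fade_age`` the signature is absent (the ipsi program is developmentally
    transient). Labels are biased toward a small clade of terminal types so
    the planted ipsi lineage is fate-restricted and can be recovered by
    propagating calls through transport maps. Named signature genes absent
    from the matrix are appended as new rows.
    """
    ipsi_genes = list(ipsi_genes)
    contra_genes = list(contra_genes)
    if set(ipsi_genes) & set(contra_genes):
        raise ValueError("ipsi and contra gene sets must be disjoint")
    if not 0 < frac_ipsi < 0.5:
        raise ValueError("frac_ipsi must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    tree = truth.tree
    ages = np.asarray(sorted(truth.cells["age"].unique()))
    if fade_age is None:
        fade_age = float(ages[min(1, len(ages) - 1)])

    # add any missing signature genes as zero rows
    missing = [g for g in ipsi_genes + contra_genes if g not in counts.genes]
    X = sp.lil_matrix(
        (counts.shape[0] + len(missing), counts.shape[1]), dtype=counts.counts.dtype
    )
    X[: counts.shape[0]] = counts.counts
    genes = counts.genes.append(pd.Index(missing))

    # the ipsi lineage is an early-determined identity: among small clades,
    # pick the one whose destined early cells are already most fate-restricted
    age_arr = truth.cells["age"].to_numpy()
    early_mask = age_arr <= (fade_age if fade_age is not None else np.sort(np.unique(age_arr))[min(1, len(np.unique(age_arr)) - 1)])
    want = min(clade_size, max(1, tree.n_types // 3))
    candidates = [c for c in tree.clades() if want <= len(c) <= tree.n_types // 2]
    if not candidates:
        candidates = sorted(tree.clades(), key=len)[:1]

    def _restriction(clade) -> float:
        """Earliness score: ipsi identity belongs to early-specifying types."""
        sel = early_mask & np.isin(truth.cells["true_type"].to_numpy(), list(clade))
        if not sel.any():
            return -np.inf
        boundary = float(truth.fates[sel][:, list(clade)].sum(axis=1).mean())
        mean_decouple = float(np.mean([tree.decouple_time_of_type(b) for b in clade]))
        return boundary - mean_decouple / max(abs(tree.age_grid[-1]), 1.0)

    ipsi_clade = max(candidates, key=_restriction)
    contra_clade = max(
        (c for c in tree.clades() if not set(c) & set(ipsi_clade)),
        key=_restriction,
    )

    age_col = truth.cells["age"].to_numpy()
    destined = truth.cells["true_type"].to_numpy()
    early = age_col <= fade_age

    def _pick(clade) -> np.ndarray:
        chosen = []
        # per early age, label the most lineage-committed destined cells
        # (laterality-determined cells are committed to the lineage)
        for t in np.unique(age_col[early]):
            at_age = early & (age_col == t)
            pool = np.where(at_age & np.isin(destined, list(clade)))[0]
            n_want = int(round(frac_ipsi * at_age.sum()))
            if len(pool) < n_want:
                warnings.warn("fewer destined cells than requested; taking the whole clade pool")
                chosen.append(pool)
                continue
            in_clade_mass = truth.fates[pool][:, list(clade)].sum(axis=1)
            chosen.append(pool[np.argsort(-in_clade_mass, kind="stable")[:n_want]])
        return np.concatenate(chosen) if chosen else np.empty(0, dtype=int)

    i_cells = _pick(ipsi_clade)
    c_cells = _pick(contra_clade)

    gi = genes.get_indexer(ipsi_genes)
    gc = genes.get_indexer(contra_genes)
    lib = truth.cells["lib_factor"].to_numpy()

    # both modules are moderately expressed across early cells (the
    # contralateral markers are broad), so suppression is visible
    early_idx = np.where(early)[0]
    for g in np.concatenate([gi, gc]):
        X[g, early_idx] = rng.poisson(0.25 * signal_rate * lib[early_idx])
    for rows, cols_on, cols_off in ((i_cells, gi, gc), (c_cells, gc, gi)):
        for g in cols_on:
            X[g, rows] = rng.poisson(signal_rate * lib[rows])
        for g in cols_off:
            X[g, rows] = 0

    lat = truth.cells["laterality"].copy()
    lat.iloc[i_cells] = "I"
    lat.iloc[c_cells] = "C"
    truth.cells["laterality"] = lat
    truth.ipsi_types = tuple(ipsi_clade)
    truth.contra_types = tuple(contra_clade)

    out = CountMatrix(
        counts=sp.csr_matrix(X), genes=genes, cells=counts.cells,
        obs=truth.cells.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# convenience: full synthetic dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    n_types: int = 12,
    n_subclasses: int = 4,
    age_grid=(0.0, 1.0, 3.0, 6.0, 11.0, 20.0),
    n_cells_per_age: int = 400,
    n_genes: int = 1000,
    sharpness: float = 0.5,
    batch_effect_sd: float = 0.0,
    with_laterality: bool = False,
    seed: int = 0,
    **count_kwargs,
) -> tuple[GroundTruth, CountMatrix]:
    """One-call generator: tree -> fates -> counts (-> laterality).

    Sub-seeds for each stage are derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tree = make_fate_tree(n_types, n_subclasses, age_grid, seed=sub[0])
    truth = simulate_fates(tree, n_cells_per_age, age_grid, sharpness=sharpness, seed=sub[1])
    counts = simulate_counts(
        truth, n_genes=n_genes, batch_effect_sd=batch_effect_sd, seed=sub[2], **count_kwargs
    )
    if with_laterality:
        counts = plant_laterality(truth, counts, seed=sub[3])
    return truth, counts
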