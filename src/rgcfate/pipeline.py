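"""End-to-end orchestration of the analysis stages on one dataset.

The driver mirrors the published workflow: normalize the full time course
together, select HVGs once, cluster each age separately, relate consecutive
ages by supervised classification, solve consecutive entropic transport
maps, compose them to the terminal age, and derive fate vectors, potentials,
couplings, specification times, and (optionally) laterality calls. All
stages are also available individually; this module just wires them with
consistent bookkeeping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import cluster as cl
from . import diversity as dv
from . import fates as ft
from . import laterality as lat
from . import preprocess as pp
from . import transport as tp
from . import xmap
from .config import RunConfig
from .io import CountMatrix


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def preprocess_stage(counts: CountMatrix, config: RunConfig):
    """Filter, normalize, and select HVGs on the pooled time course."""
    filtered = pp.filter_cells_genes(
        counts, config.min_genes_per_cell, config.min_cells_per_gene
    )
    em = pp.normalize_log(filtered, target=config.normalize_target)
    hvg = pp.select_hvgs(filtered, z_factor=config.hvg_z_factor)
    return filtered, em, hvg


def cluster_stage(em, hvg, config: RunConfig, seed: int = 0, embed_mode: str = "pca"):
    """Per-age embedding + Louvain clustering on the HVG expression."""
    hvg_em = em.subset_genes(hvg.selected_genes)
    ages = sorted(em.obs["age"].unique())
    seeds = _subseeds(seed, 2 * len(ages))
    partitions: dict[float, cl.ClusterPartition] = {}
    embeddings: dict[float, cl.Embedding] = {}
    for i, age in enumerate(ages):
        mask = (em.obs["age"] == age).to_numpy()
        Xa = hvg_em.dense()[:, mask].T  # cells x genes
        batches = em.obs.loc[mask, "batch"].to_numpy() if "batch" in em.obs else None
        k = max(cl.choose_dim_rmt(Xa.T), 2)
        emb = cl.embed(
            Xa,
            batches=batches if embed_mode == "inmf" else None,
            k=min(k, 20),
            mode=embed_mode,
            seed=seeds[2 * i],
        )
        n_nb = min(config.n_neighbors, max(5, Xa.shape[0] // 10))
        part = cl.graph_cluster(
            emb,
            n_neighbors=n_nb,
            resolution=config.louvain_resolution,
            seed=seeds[2 * i + 1],
            age=age,
        )
        em_age = em.__class__(
            X=em.X[:, mask], genes=em.genes, cells=em.cells[mask],
            target=em.target, obs=em.obs.loc[mask],
        )
        part = cl.refine_partition(
            part, em_age, embedding=emb.H,
            min_de_genes=config.merge_min_de_genes,
            logfc_threshold=config.de_logfc_threshold,
            alpha=config.de_alpha,
        )
        embeddings[age] = emb
        partitions[age] = part
    return hvg_em, embeddings, partitions


def diversity_stage(hvg_em, embeddings, partitions, seed: int = 0) -> pd.DataFrame:
    rows = []
    ages = sorted(partitions)
    seeds = _subseeds(seed, len(ages))
    X = hvg_em.dense()
    for s, age in zip(seeds, ages):
        mask = (hvg_em.obs["age"] == age).to_numpy()
        rows.append(
            dv.diversity_report(
                X[:, mask], partitions[age].labels, embeddings[age].H, age=age, seed=s
            )
        )
    return pd.DataFrame(rows)


def xmap_stage(hvg_em, partitions, config: RunConfig, seed: int = 0) -> pd.DataFrame:
    """Consecutive-age correspondence: test age mapped to the next (reference) age."""
    ages = sorted(partitions)
    X = hvg_em.dense()
    rows = []
    seeds = _subseeds(seed, len(ages))
    for i, (young, old) in enumerate(zip(ages, ages[1:])):
        m_y = (hvg_em.obs["age"] == young).to_numpy()
        m_o = (hvg_em.obs["age"] == old).to_numpy()
        table = xmap.map_clusters(
            X[:, m_o].T,
            partitions[old].labels,
            X[:, m_y].T,
            partitions[young].labels,
            seed=seeds[i],
            train_frac=config.train_frac,
            max_cells=config.max_train_cells_per_cluster,
            err_thresh=config.max_cluster_error,
            n_top_features=config.n_top_features,
            min_common_features=min(50, X.shape[0]),
        )
        try:
            nce_val = xmap.nce(table)
        except ValueError:
            nce_val = np.nan  # single-cluster test partition
        entry = {
            "test_age": young,
            "ref_age": old,
            "ari": xmap.ari(table),
            "nce": nce_val,
        }
        entry["table"] = table
        rows.append(entry)
    return pd.DataFrame(rows)


def transport_stage(hvg_em, partitions, config: RunConfig, seed: int = 0):
    """Consecutive maps, compositions to the terminal age, fates + potential."""
    ages = sorted(hvg_em.obs["age"].unique())
    X = hvg_em.dense()
    snaps = {a: X[:, (hvg_em.obs["age"] == a).to_numpy()].T for a in ages}
    maps = {}
    for young, old in zip(ages, ages[1:]):
        maps[(young, old)] = tp.solve_coupling(
            snaps[young],
            snaps[old],
            eps=config.epsilon,
            lam1=config.lambda1,
            lam2=config.lambda2,
            days_gap=old - young,
        )
    terminal = ages[-1]
    terminal_labels = partitions[terminal].labels
    fates_by_age = {}
    potential_by_age = {}
    for i, age in enumerate(ages[:-1]):
        chain = [maps[(a, b)] for a, b in zip(ages[i:-1], ages[i + 1:])]
        composed = tp.compose(chain)
        fm = tp.fate_vectors(composed, terminal_labels, source_age=age, terminal_age=terminal)
        fates_by_age[age] = fm
        potential_by_age[age] = float(np.mean(tp.potential(fm.F)))
    potential_by_age[terminal] = 1.0  # point-mass by construction at the terminal age
    return maps, fates_by_age, potential_by_age


def fates_stage(fates_by_age, partitions, config: RunConfig, subclass_labels=None):
    """Couplings per age, network export, localization, specification times.

    The localization series of every type is anchored at the terminal age,
    where each cell's fate is a point mass on its own cluster, so the
    logistic fit is constrained on both ends.
    """
    ages = sorted(fates_by_age)
    couplings = {a: ft.coupling_matrix(fates_by_age[a]) for a in ages}
    networks = {
        a: ft.export_network(couplings[a], threshold=config.coupling_threshold) for a in ages
    }
    n_types = fates_by_age[ages[0]].n_types
    terminal = max(partitions)
    term_labels = partitions[terminal].labels
    term_ids = fates_by_age[ages[0]].cluster_ids
    fit_ages = ages + [terminal]
    loc = np.full((len(fit_ages), n_types), np.nan)
    N_series = []
    for i, a in enumerate(ages):
        labels = partitions[a].labels
        N_series.append(partitions[a].n_clusters)
        for b in range(n_types):
            loc[i, b] = ft.localization(fates_by_age[a], labels, b)
    # terminal anchor: point-mass fates on the terminal clusters themselves
    F_term = (term_labels[:, None] == np.asarray(term_ids)[None, :]).astype(float)
    N_series.append(partitions[terminal].n_clusters)
    for b in range(n_types):
        loc[len(ages), b] = ft.localization(F_term, term_labels, b)
    tau_rows = []
    for b in range(n_types):
        try:
            fit = ft.specification_time(
                loc[:, b], N_series, fit_ages,
                t_max=config.decay_terminal_t,
                threshold_factor=config.localization_factor,
            )
            tau_rows.append(
                {"type": b, "tau_sp": fit.tau_sp, "censored": fit.censored,
                 "gamma0": fit.gamma0, "gamma1": fit.gamma1}
            )
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"specification fit skipped for type {b}: {exc}")
    tau = pd.DataFrame(tau_rows, columns=["type", "tau_sp", "censored", "gamma0", "gamma1"])
    subclass = None
    if subclass_labels is not None:
        try:
            subclass = ft.subclass_coupling_test(couplings[ages[0]], subclass_labels)
        except ValueError as exc:
            warnings.warn(f"subclass coupling test skipped: {exc}")
    return {
        "couplings": couplings,
        "networks": networks,
        "localization": pd.DataFrame(loc, index=fit_ages),
        "tau_sp": tau,
        "subclass_test": subclass,
    }


def laterality_stage(
    em, maps, partitions, config: RunConfig,
    ipsi_genes=("Zic2", "Zic1", "Igfbp5"),
    contra_genes=("Isl2", "Fgf12", "Igf1"),
):
    """Score/call laterality at the earliest age and propagate to terminal types."""
    ages = sorted(em.obs["age"].unique())
    first = ages[0]
    mask = (em.obs["age"] == first).to_numpy()
    em_first = type(em)(
        X=em.X[:, mask], genes=em.genes, cells=em.cells[mask],
        target=em.target, obs=em.obs.loc[mask],
    )
    ipsi = lat.signature_score(em_first, ipsi_genes)
    contra = lat.signature_score(em_first, contra_genes)
    calls = lat.call_laterality(ipsi, contra, k_sd=config.laterality_k_sd)
    chain = [maps[(a, b)] for a, b in zip(ages[:-1], ages[1:])]
    fractions = lat.propagate_ipsi(calls, chain, partitions[ages[-1]].labels)
    de = lat.de_ipsi(
        em_first, calls.i_mask,
        fc_threshold=config.laterality_fc, alpha=config.laterality_alpha,
    ) if calls.i_mask.sum() > 0 else None
    return calls, fractions, de


def run_all(
    counts: CountMatrix,
    config: RunConfig | None = None,
    seed: int = 0,
    subclass_labels=None,
    with_laterality: bool = False,
) -> dict:
    """Run every stage on a count matrix; returns a dict of stage results."""
    config = config or RunConfig()
    s = _subseeds(seed, 6)
    filtered, em, hvg = preprocess_stage(counts, config)
    hvg_em, embeddings, partitions = cluster_stage(em, hvg, config, seed=s[0])
    div = diversity_stage(hvg_em, embeddings, partitions, seed=s[1])
    xm = xmap_stage(hvg_em, partitions, config, seed=s[2])
    maps, fates_by_age, pot = transport_stage(hvg_em, partitions, config, seed=s[3])
    fr = fates_stage(fates_by_age, partitions, config, subclass_labels=subclass_labels)
    results = {
        "filtered": filtered,
        "expression": em,
        "hvg": hvg,
        "partitions": partitions,
        "embeddings": embeddings,
        "diversity": div,
        "xmap": xm,
        "maps": maps,
        "fates": fates_by_age,
        "potential": pot,
        "fate_analysis": fr,
        "config": config,
        "seed": seed,
    }
    if with_laterality:
        calls, fractions, de = laterality_stage(em, maps, partitions, config)
        results["laterality"] = {"calls": calls, "fractions": fractions, "de": de}
    return results
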