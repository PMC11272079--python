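"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its arguments and seed: the same
call produces byte-identical output.  The generators emulate the four
input layers of the pipeline:

* codon alignments evolved under GY94 along a tree with branch-specific
  (optionally site-class-specific) omega;
* genome-wide rate tables with a controllable median M0 omega, per-branch
  positive-selection flags at given frequencies, and plantable "rapid"
  genes at known identities;
* RPKM-style expression matrices over a configurable number of conditions
  with controllable expression breadth per gene;
* tip phenotypes that are linear in a per-tip covariate plus Brownian
  motion residuals on the tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._codons import sense_codons
from .alignment import CodonAlignment
from .codonmodel import _Eig, _unscaled_rate_matrix, equal_codon_freqs
from .ratetable import GenomeRateTable, make_record
from .trees import PhyloTree

__all__ = [
    "melanogaster_tree",
    "simulate_codon_alignment",
    "simulate_expression",
    "simulate_genome_rates",
    "simulate_phenotype_on_tree",
]

SPECIES = ["Dsim", "Dsec", "Dmel", "Dyak", "Dere"]


def melanogaster_tree(scale: float = 1.0) -> PhyloTree:
    """Synthetic five-taxon tree with the melanogaster-subgroup topology.

    Branch lengths (substitutions per codon) are plausible stand-ins for
    this clade, not published estimates.
    """
    nwk = (
        "((Dsim:{a},Dsec:{a}):{b},Dmel:{c},(Dyak:{d},Dere:{d}):{b});"
    ).format(a=0.05 * scale, b=0.03 * scale, c=0.08 * scale, d=0.09 * scale)
    return PhyloTree.from_newick(nwk)


def _class_transition_matrices(
    tree: PhyloTree,
    kappa: float,
    class_props: np.ndarray,
    class_omegas: "list[dict[str, float]]",
    freqs: np.ndarray,
    code: str,
) -> "list[dict[str, np.ndarray]]":
    """Per-class, per-branch transition matrices.

    Branch lengths are expected substitutions per codon averaged over the
    site-class mixture: all classes on a branch share one scale (the
    mixture-average rate), so conserved classes evolve slower — matching
    the likelihood engine's convention.
    """
    lengths = tree.branch_lengths
    eigs: dict[float, tuple[_Eig, float]] = {}
    for om in class_omegas:
        for w in om.values():
            if w not in eigs:
                q = _unscaled_rate_matrix(kappa, w, freqs, code)
                rate = float(-(freqs * np.diag(q)).sum())
                eigs[w] = (_Eig(q, freqs), max(rate, 1e-300))
    out: list[dict[str, np.ndarray]] = [dict() for _ in class_omegas]
    props = np.asarray(class_props, dtype=float)
    for label, t in lengths.items():
        scale = sum(p * eigs[om[label]][1] for p, om in zip(props, class_omegas))
        scale = max(float(scale), 1e-300)
        for k, om in enumerate(class_omegas):
            p = eigs[om[label]][0].transition(t / scale)
            p /= p.sum(axis=1, keepdims=True)
            out[k][label] = p
    return out


def _evolve(states: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample child states given parent states and a transition matrix."""
    out = np.empty_like(states)
    for s in np.unique(states):
        mask = states == s
        out[mask] = rng.choice(p.shape[1], size=int(mask.sum()), p=p[s])
    return out


def simulate_codon_alignment(
    tree: PhyloTree,
    kappa: float = 2.0,
    omega: "float | dict[str, float]" = 0.2,
    n_codons: int = 500,
    codon_freqs: np.ndarray | None = None,
    seed: int = 0,
    code: str = "universal",
    site_class_props: np.ndarray | None = None,
    site_class_omegas: "list[dict[str, float]] | None" = None,
) -> CodonAlignment:
    """Evolve codons along a tree by exact transition-probability sampling.

    Root codons are drawn from ``codon_freqs``; each branch applies the
    matrix exponential of its scaled GY94 rate matrix.  With
    ``site_class_props``/``site_class_omegas`` a per-site mixture is drawn
    first (branch-site style simulation).
    """
    rng = np.random.default_rng(seed)
    freqs = equal_codon_freqs(code) if codon_freqs is None else np.asarray(codon_freqs)
    labels = tree.branch_labels
    if site_class_props is not None:
        props = np.asarray(site_class_props, dtype=float)
        classes = rng.choice(len(props), size=n_codons, p=props)
        omega_maps = site_class_omegas
    else:
        classes = np.zeros(n_codons, dtype=int)
        props = np.array([1.0])
        if isinstance(omega, dict):
            omega_maps = [dict(omega)]
        else:
            omega_maps = [dict.fromkeys(labels, float(omega))]
    per_class_p = _class_transition_matrices(tree, kappa, props, omega_maps, freqs, code)

    nodes = tree.postorder_structure()
    order = list(reversed(range(len(nodes))))  # preorder: root first
    states: dict[int, np.ndarray] = {}
    root = len(nodes) - 1
    states[root] = rng.choice(len(freqs), size=n_codons, p=freqs)
    for i in order:
        if i == root:
            continue
        node = nodes[i]
        parent_states = states[node["parent"]]
        child = np.empty(n_codons, dtype=np.int64)
        for c in np.unique(classes):
            mask = classes == c
            child[mask] = _evolve(
                parent_states[mask], per_class_p[c][node["label"]], rng
            )
        states[i] = child
    codons = sense_codons(code)
    taxa, seqs = [], []
    for i, node in enumerate(nodes):
        if node["is_tip"]:
            taxa.append(node["label"])
            seqs.append("".join(codons[s] for s in states[i]))
    return CodonAlignment(taxa, seqs, code=code)


def simulate_expression(
    n_genes: int = 200,
    n_conditions: int = 59,
    breadths: "np.ndarray | int | None" = None,
    log_mean: float = 3.0,
    log_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """RPKM-style genes x conditions matrix with controlled breadth.

    Each gene expresses in ``k`` conditions (its breadth); expressed
    conditions receive log-normal positive values with per-condition noise
    ``noise_sd`` (0 gives equal values, so tau hits the closed form
    (n - k) / (n - 1) exactly).  Breadths default to a uniform draw over
    1..n_conditions, mixing narrow and broad genes.
    """
    rng = np.random.default_rng(seed)
    if breadths is None:
        breadths = rng.integers(1, n_conditions + 1, size=n_genes)
    elif np.isscalar(breadths):
        breadths = np.full(n_genes, int(breadths))
    values = np.zeros((n_genes, n_conditions))
    for g in range(n_genes):
        k = int(breadths[g])
        cols = rng.choice(n_conditions, size=k, replace=False)
        base = np.exp(rng.normal(log_mean, log_sd))
        noise = rng.normal(0.0, noise_sd, size=k) if noise_sd > 0 else 0.0
        values[g, cols] = base * np.exp(noise)
    genes = [f"G{g:05d}" for g in range(n_genes)]
    conditions = [f"cond{c:02d}" for c in range(n_conditions)]
    return pd.DataFrame(values, index=genes, columns=conditions)


def simulate_genome_rates(
    n_genes: int = 2000,
    branches: "list[str] | None" = None,
    m0_median: float = 0.0909,
    gamma_shape: float = 1.2,
    possel_freq: "dict[str, float] | float" = 0.0,
    planted: "dict[str, float] | None" = None,
    ds_log_mean: float = np.log(0.15),
    ds_log_sd: float = 0.6,
    gt1_fraction: float = 0.002,
    lowdiv_fraction: float = 0.01,
    seed: int = 0,
) -> GenomeRateTable:
    """Genome-wide rate table with known generating quantities.

    M0 omega is gamma distributed with its *distribution* median fixed at
    ``m0_median`` (scale solved from the gamma quantile function).
    Per-branch dS is log-normal; dN = omega_branch * dS with branch omega
    jittered around the gene's M0 value.  ``gt1_fraction`` of branch
    records get dS forced to ~0 (GT1 sentinels) and ``lowdiv_fraction``
    get both rates forced below threshold (LOWDIV).  ``planted`` maps
    gene ids (e.g. ``"G00012"``) to fixed M0 omegas so screens can be
    checked against a constructed truth.
    """
    from scipy.stats import gamma as gamma_dist

    rng = np.random.default_rng(seed)
    branches = branches or SPECIES
    if np.isscalar(possel_freq):
        possel_freq = dict.fromkeys(branches, float(possel_freq))
    scale = m0_median / gamma_dist.ppf(0.5, gamma_shape)
    genes = [f"G{g:05d}" for g in range(n_genes)]
    m0 = dict(zip(genes, rng.gamma(gamma_shape, scale, size=n_genes)))
    if planted:
        for g, w in planted.items():
            if g not in m0:
                raise KeyError(f"planted gene {g!r} outside generated ids")
            m0[g] = float(w)
    records, pos_sel = [], {}
    for g in genes:
        for b in branches:
            ds = float(np.exp(rng.normal(ds_log_mean, ds_log_sd)))
            w = m0[g] * float(np.exp(rng.normal(0.0, 0.4)))
            dn = w * ds
            u = rng.random()
            if u < gt1_fraction:
                ds, dn = 1e-6, max(dn, 0.002)
            elif u < gt1_fraction + lowdiv_fraction:
                ds, dn = 1e-5, 1e-5
            records.append(make_record(g, b, dn, ds))
            pos_sel[(g, b)] = bool(rng.random() < possel_freq[b])
    return GenomeRateTable.from_records(records, m0, pos_sel)


def simulate_phenotype_on_tree(
    tree: PhyloTree,
    x: "dict[str, float]",
    intercept: float,
    slope: float,
    bm_sigma2: float,
    seed: int = 0,
) -> pd.Series:
    """y = intercept + slope * x + MVN(0, bm_sigma2 * V_BM(tree)) per tip."""
    from .pgls import bm_covariance

    rng = np.random.default_rng(seed)
    tips, vcv = bm_covariance(tree)
    xv = np.array([x[t] for t in tips])
    mean = intercept + slope * xv
    if bm_sigma2 > 0:
        chol = np.linalg.cholesky(bm_sigma2 * vcv + 1e-12 * np.eye(len(tips)))
        y = mean + chol @ rng.standard_normal(len(tips))
    else:
        y = mean
    return pd.Series(y, index=tips, name="phenotype")
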