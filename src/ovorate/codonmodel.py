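"""Goldman-Yang (GY94) codon substitution models and their ML fits.

The instantaneous rate from codon i to codon j is zero unless the codons
differ at exactly one nucleotide position, and otherwise proportional to
the target codon's equilibrium frequency pi_j, multiplied by kappa for a
transition and by omega for a nonsynonymous change.  The matrix is scaled
so one unit of branch length equals one expected substitution per codon.

Three model classes follow the Model/Results convention: construct from a
:class:`~ovorate.alignment.CodonAlignment` and a
:class:`~ovorate.trees.PhyloTree`, call ``fit()``, inspect the returned
Results object (``summary()`` prints an estimation table).

* :class:`M0` - a single omega shared by every branch and site.
* :class:`FreeRatio` - an independent omega per branch; its results carry
  per-branch (dN, dS) decompositions with sentinel classification.
* :class:`BranchSite` - model A: four site classes with a foreground
  branch whose class-2 omega2 >= 1 is tested against omega2 = 1 by a
  likelihood-ratio test on chi^2 with 1 df.

Likelihoods are computed with Felsenstein pruning over site patterns, with
transition probabilities from the spectral decomposition of the reversible
rate matrix and per-node rescaling against underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from ._codons import change_tables, sense_codons
from .alignment import CodonAlignment
from .ratetable import BranchRateRecord, make_record
from .trees import PhyloTree

logger = logging.getLogger("ovorate")

__all__ = [
    "CodonModelParams",
    "ConvergenceError",
    "build_rate_matrix",
    "transition_matrix",
    "decompose_branch_rates",
    "M0",
    "FreeRatio",
    "BranchSite",
    "fit_m0",
    "fit_free_ratio",
    "branch_site_test",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; ``best`` carries the best fit so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class CodonModelParams:
    """Parameters of a GY94 model on a tree.

    kappa > 0 is the transition/transversion rate ratio, ``omega_map`` maps
    each branch label to its dN/dS (a single shared value appears under
    every label for M0), ``codon_freqs`` is a distribution over the sense
    codons, ``branch_lengths`` are expected substitutions per codon.
    """

    kappa: float
    omega_map: dict[str, float]
    codon_freqs: np.ndarray
    branch_lengths: dict[str, float]
    code: str = "universal"

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon_freqs must sum to 1")
        if any(w < 0 for w in self.omega_map.values()):
            raise ValueError("omega must be >= 0")
        if any(t < 0 for t in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")


def equal_codon_freqs(code: str = "universal") -> np.ndarray:
    n = len(sense_codons(code))
    return np.full(n, 1.0 / n)


def f3x4_codon_freqs(aln: CodonAlignment) -> np.ndarray:
    """F3x4 frequencies: per-position nucleotide frequencies multiplied out
    over the sense codons and renormalized."""
    codons = sense_codons(aln.code)
    pos_freq = [dict.fromkeys("ACGT", 0.0) for _ in range(3)]
    for seq in aln.sequences:
        for k in range(0, len(seq), 3):
            for p in range(3):
                base = seq[k + p]
                if base in "ACGT":
                    pos_freq[p][base] += 1.0
    for p in range(3):
        total = sum(pos_freq[p].values())
        for b in "ACGT":
            pos_freq[p][b] = pos_freq[p][b] / total if total else 0.25
    freqs = np.array(
        [pos_freq[0][c[0]] * pos_freq[1][c[1]] * pos_freq[2][c[2]] for c in codons]
    )
    if freqs.sum() == 0:
        return equal_codon_freqs(aln.code)
    return freqs / freqs.sum()


def _unscaled_rate_matrix(kappa: float, omega: float, freqs: np.ndarray, code: str) -> np.ndarray:
    single, transition, synonymous = change_tables(code)
    rates = np.where(single, np.tile(freqs, (len(freqs), 1)), 0.0)
    rates = np.where(single & transition, rates * kappa, rates)
    rates = np.where(single & ~synonymous, rates * omega, rates)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return rates


def build_rate_matrix(params: CodonModelParams, branch: str) -> np.ndarray:
    """Scaled instantaneous rate matrix for one branch (rows sum to zero;
    expected substitutions per codon per unit time equal one)."""
    omega = params.omega_map[branch]
    q = _unscaled_rate_matrix(params.kappa, omega, params.codon_freqs, params.code)
    rate = -(params.codon_freqs * np.diag(q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / rate


class _Eig:
    """Spectral decomposition of a scaled reversible rate matrix."""

    __slots__ = ("A", "lam", "B")

    def __init__(self, q: np.ndarray, freqs: np.ndarray):
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
        self.A = vec / sqrt_pi[:, None]
        self.lam = lam
        self.B = vec.T * sqrt_pi[None, :]

    def transition(self, t: float) -> np.ndarray:
        p = (self.A * np.exp(self.lam * t)) @ self.B
        np.clip(p, 0.0, None, out=p)
        return p


def transition_matrix(params: CodonModelParams, branch: str, t: float | None = None) -> np.ndarray:
    """P(t) = exp(Q t) for a branch (t defaults to the branch length)."""
    q = build_rate_matrix(params, branch)
    if t is None:
        t = params.branch_lengths[branch]
    return _Eig(q, params.codon_freqs).transition(t)


def _syn_nonsyn_flux(kappa: float, freqs: np.ndarray, code: str) -> tuple[float, float]:
    """Unscaled (nonsynonymous, synonymous) substitution flux at omega = 1."""
    single, transition, synonymous = change_tables(code)
    base = np.where(single, np.tile(freqs, (len(freqs), 1)), 0.0)
    base = np.where(single & transition, base * kappa, base)
    flux = freqs[:, None] * base
    nonsyn = flux[single & ~synonymous].sum()
    syn = flux[single & synonymous].sum()
    return float(nonsyn), float(syn)


def decompose_branch_rates(params: CodonModelParams, branch: str) -> tuple[float, float]:
    """Per-branch (dN, dS) from the fitted model.

    Expected nonsynonymous/synonymous substitution flux on the branch
    divided by site proportions computed from the same model with omega
    set to 1 (codeml bookkeeping); satisfies dN/dS = omega(branch).
    """
    omega = params.omega_map[branch]
    t = params.branch_lengths[branch]
    n1, s1 = _syn_nonsyn_flux(params.kappa, params.codon_freqs, params.code)
    denom = omega * n1 + s1
    if denom == 0 or t == 0:
        return 0.0, 0.0
    dn = t * omega * (n1 + s1) / denom
    ds = t * (n1 + s1) / denom
    return float(dn), float(ds)


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------


class LabelError(KeyError):
    pass


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Built once per (alignment, tree) pair; each likelihood evaluation
    supplies kappa, per-branch omega and branch lengths.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, codon_freqs: np.ndarray):
        missing = set(tree.tip_labels) - set(aln.taxa)
        if missing:
            raise LabelError(f"tree tips not in alignment: {sorted(missing)}")
        self.code = aln.code
        self.freqs = np.asarray(codon_freqs, dtype=float)
        self.n_states = len(self.freqs)

        matrix = aln.codon_indices()
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        nodes = tree.postorder_structure()
        self.nodes = nodes
        self.children: list[list[int]] = [[] for _ in nodes]
        for i, node in enumerate(nodes):
            if node["parent"] is not None:
                self.children[node["parent"]].append(i)
        self.branch_labels = [n["label"] for n in nodes[:-1]]

        tip_rows = [taxon_row[n["label"]] for n in nodes if n["is_tip"]]
        sub = matrix[tip_rows, :]
        patterns, counts = np.unique(sub, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        # map -1 (missing) to a virtual state indexing a padded all-ones column
        patterns = np.where(patterns < 0, self.n_states, patterns)
        self.tip_states: dict[int, np.ndarray] = {}
        row = 0
        for i, node in enumerate(nodes):
            if node["is_tip"]:
                self.tip_states[i] = patterns[row]
                row += 1
        self.n_sites = int(counts.sum())

    def _unscaled_eigs(self, kappa: float, omegas) -> dict[float, tuple[_Eig, float]]:
        """Per distinct omega: eigensystem of the *unscaled* rate matrix and
        its total substitution rate under the engine's frequencies."""
        out: dict[float, tuple[_Eig, float]] = {}
        for w in set(omegas):
            q = _unscaled_rate_matrix(kappa, w, self.freqs, self.code)
            rate = float(-(self.freqs * np.diag(q)).sum())
            out[w] = (_Eig(q, self.freqs), max(rate, 1e-300))
        return out

    def _pattern_loglik_from_p(self, pmaps: "list[dict[str, np.ndarray]]") -> np.ndarray:
        """Per-class, per-pattern log-likelihood given per-branch transition
        matrices for each site class (classes share the pruning pass)."""
        n_class = len(pmaps)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((n_class, self.n_patterns))
        ones_col = np.ones((self.n_states, 1))
        for i, node in enumerate(self.nodes):
            if node["is_tip"]:
                continue
            prod = np.ones((n_class, self.n_states, self.n_patterns))
            for c in self.children[i]:
                label = self.nodes[c]["label"]
                for k in range(n_class):
                    p = pmaps[k][label]
                    if c in self.tip_states:
                        padded = np.hstack([p, ones_col])
                        prod[k] *= padded[:, self.tip_states[c]]
                    else:
                        prod[k] *= p @ partial[c][k]
                if c in partial:
                    del partial[c]
            mx = prod.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            prod /= mx[:, None, :]
            logscale += np.log(mx)
            partial[i] = prod
        root = len(self.nodes) - 1
        site = np.einsum("s,ksp->kp", self.freqs, partial[root])
        return np.log(np.clip(site, 1e-300, None)) + logscale

    def pattern_loglik(
        self, kappa: float, omegas: "dict[str, float]", lengths: "dict[str, float]"
    ) -> np.ndarray:
        """Per-pattern log-likelihood (length ``n_patterns``).

        Each branch's matrix is scaled to one expected substitution per
        codon per unit branch length under that branch's own omega.
        """
        eigs = self._unscaled_eigs(kappa, omegas.values())
        pmap = {}
        for label, t in lengths.items():
            eig, rate = eigs[omegas[label]]
            pmap[label] = eig.transition(t / rate)
        return self._pattern_loglik_from_p([pmap])[0]

    def loglik(self, kappa, omegas, lengths) -> float:
        return float(self.counts @ self.pattern_loglik(kappa, omegas, lengths))

    def mixture_loglik(
        self,
        kappa: float,
        class_props: np.ndarray,
        class_omegas: "list[dict[str, float]]",
        lengths: "dict[str, float]",
    ) -> float:
        """Log-likelihood of a site-class mixture with shared branch lengths.

        Branch lengths are expected substitutions per codon *averaged over
        the site classes*: per branch, every class's unscaled matrix is
        divided by the mixture-average substitution rate, so conserved
        classes genuinely evolve slower than selected classes (the codeml
        convention).  Scaling each class separately would silently give
        conserved sites the same substitution load, shifted onto synonymous
        changes.
        """
        props = np.asarray(class_props, dtype=float)
        all_omegas = {w for om in class_omegas for w in om.values()}
        eigs = self._unscaled_eigs(kappa, all_omegas)
        pmaps: list[dict[str, np.ndarray]] = [dict() for _ in class_omegas]
        for label, t in lengths.items():
            scale = sum(
                p * eigs[om[label]][1] for p, om in zip(props, class_omegas)
            )
            scale = max(scale, 1e-300)
            for k, om in enumerate(class_omegas):
                pmaps[k][label] = eigs[om[label]][0].transition(t / scale)
        per_class = self._pattern_loglik_from_p(pmaps)
        with np.errstate(divide="ignore"):
            logw = np.log(props)
        site = logsumexp(per_class + logw[:, None], axis=0)
        return float(self.counts @ site)


# ---------------------------------------------------------------------------
# branch length initialization
# ---------------------------------------------------------------------------


def _initial_branch_lengths(aln: CodonAlignment, tree: PhyloTree) -> dict[str, float]:
    """Corrected pairwise codon distances least-squares fitted to the tree."""
    matrix = aln.codon_indices()
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    tips = tree.tip_labels
    k = 61.0
    pairs, dists = [], []
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            x = matrix[taxon_row[tips[a]]]
            y = matrix[taxon_row[tips[b]]]
            ok = (x >= 0) & (y >= 0)
            p = float(np.mean(x[ok] != y[ok])) if ok.any() else 0.0
            p = min(p, (k - 1.0) / k * 0.999)
            d = -(k - 1.0) / k * np.log(1.0 - k / (k - 1.0) * p)
            pairs.append((tips[a], tips[b]))
            dists.append(d)
    labels = tree.branch_labels
    col = {lab: j for j, lab in enumerate(labels)}
    rows = np.zeros((len(pairs), len(labels)))
    nodes = tree.postorder_structure()
    # path indicator: branches on the tip-to-root path for each tip
    paths: dict[str, set[str]] = {}
    index_label = [n["label"] for n in nodes]
    parent = [n["parent"] for n in nodes]
    for i, node in enumerate(nodes):
        if node["is_tip"]:
            path = set()
            j = i
            while parent[j] is not None:
                path.add(index_label[j])
                j = parent[j]
            paths[node["label"]] = path
    for r, (a, b) in enumerate(pairs):
        for lab in paths[a] ^ paths[b]:
            rows[r, col[lab]] = 1.0
    sol, *_ = np.linalg.lstsq(rows, np.asarray(dists), rcond=None)
    return {lab: float(max(sol[col[lab]], 1e-4)) for lab in labels}


def _maximize(neg, x0, bounds, n_restarts, seed, ftol=1e-9, maxiter=500):
    rng = np.random.default_rng(seed)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.uniform(-0.4, 0.4, size=len(x0)))
    best = None
    ok = False
    for s in starts:
        s = np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            neg, s, method="L-BFGS-B", bounds=bounds, options={"ftol": ftol, "maxiter": maxiter}
        )
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or res.success
    if not ok:
        raise ConvergenceError(f"optimizer did not converge: {best.message}", best=best)
    return best


_LOG_T_BOUNDS = (np.log(1e-7), np.log(20.0))
_LOG_KAPPA_BOUNDS = (np.log(1e-2), np.log(1e2))
_LOG_OMEGA_BOUNDS = (np.log(1e-6), np.log(50.0))


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------


class _CodonModelBase:
    def __init__(self, alignment: CodonAlignment, tree: PhyloTree, codon_freqs="equal"):
        if len(alignment.taxa) < 3:
            raise ValueError("codon model fits require at least 3 taxa")
        self.alignment = alignment
        self.tree = tree
        if isinstance(codon_freqs, str):
            if codon_freqs == "equal":
                freqs = equal_codon_freqs(alignment.code)
            elif codon_freqs == "f3x4":
                freqs = f3x4_codon_freqs(alignment)
            else:
                raise ValueError(f"unknown codon frequency model {codon_freqs!r}")
        else:
            freqs = np.asarray(codon_freqs, dtype=float)
        self.codon_freqs = freqs
        self.engine = PruningEngine(alignment, tree, freqs)
        self.branch_labels = self.engine.branch_labels

    def _t0(self):
        init = _initial_branch_lengths(self.alignment, self.tree)
        return np.array([init[lab] for lab in self.branch_labels])


@dataclass
class M0Results:
    """Fitted single-omega model."""

    params: CodonModelParams
    loglik: float
    omega: float
    kappa: float
    n_sites: int
    converged: bool = True

    def summary(self) -> str:
        lines = [
            "GY94 M0 (single dN/dS)",
            "=" * 46,
            f"codons: {self.n_sites}    log-likelihood: {self.loglik:.4f}",
            f"kappa  = {self.kappa:.4f}",
            f"omega  = {self.omega:.4f}",
            "branch lengths (subst/codon):",
        ]
        for lab, t in self.params.branch_lengths.items():
            lines.append(f"  {lab:<12s} {t:.5f}")
        return "\n".join(lines)


class M0(_CodonModelBase):
    """Single shared dN/dS across branches and sites."""

    def loglike(self, kappa: float, omega: float, lengths: dict[str, float]) -> float:
        omegas = {lab: omega for lab in self.branch_labels}
        return self.engine.loglik(kappa, omegas, lengths)

    def fit(self, start=None, n_restarts: int = 2, seed: int = 0, ftol: float = 1e-9) -> M0Results:
        nb = len(self.branch_labels)
        t0 = self._t0() if start is None else np.asarray(
            [start.branch_lengths[lab] for lab in self.branch_labels]
        )
        kappa0 = 2.0 if start is None else start.kappa
        omega0 = 0.3 if start is None else next(iter(start.omega_map.values()))
        x0 = np.concatenate([[np.log(kappa0), np.log(max(omega0, 1e-5))], np.log(np.maximum(t0, 1e-6))])
        bounds = [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS] + [_LOG_T_BOUNDS] * nb

        def neg(x):
            kappa, omega = np.exp(x[0]), np.exp(x[1])
            lengths = dict(zip(self.branch_labels, np.exp(x[2:])))
            return -self.engine.loglik(
                kappa, dict.fromkeys(self.branch_labels, omega), lengths
            )

        res = _maximize(neg, x0, bounds, n_restarts, seed, ftol=ftol)
        kappa, omega = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
        lengths = dict(zip(self.branch_labels, map(float, np.exp(res.x[2:]))))
        params = CodonModelParams(
            kappa, dict.fromkeys(self.branch_labels, omega), self.codon_freqs, lengths,
            code=self.alignment.code,
        )
        logger.info("M0 fit: lnL=%.4f kappa=%.3f omega=%.4f", -res.fun, kappa, omega)
        return M0Results(params, -float(res.fun), omega, kappa, self.engine.n_sites)


@dataclass
class FreeRatioResults:
    """Fitted per-branch omega model with (dN, dS) decomposition."""

    params: CodonModelParams
    loglik: float
    kappa: float
    rate_records: list[BranchRateRecord]
    n_sites: int

    @property
    def omega_map(self) -> dict[str, float]:
        return dict(self.params.omega_map)

    def summary(self) -> str:
        lines = [
            "GY94 free-ratio (per-branch dN/dS)",
            "=" * 46,
            f"codons: {self.n_sites}    log-likelihood: {self.loglik:.4f}",
            f"kappa  = {self.kappa:.4f}",
            f"{'branch':<12s} {'t':>8s} {'dN':>8s} {'dS':>8s} {'omega':>8s}",
        ]
        for rec in self.rate_records:
            lines.append(
                f"{rec.branch:<12s} {self.params.branch_lengths[rec.branch]:8.5f} "
                f"{rec.dN:8.5f} {rec.dS:8.5f} {rec.omega_token:>8s}"
            )
        return "\n".join(lines)


class FreeRatio(_CodonModelBase):
    """Independent dN/dS on every branch."""

    def fit(
        self,
        start=None,
        n_restarts: int = 2,
        seed: int = 0,
        ftol: float = 1e-9,
        low_div_threshold: float = 0.001,
    ) -> FreeRatioResults:
        nb = len(self.branch_labels)
        t0 = self._t0()
        x0 = np.concatenate(
            [[np.log(2.0)], np.log(np.maximum(t0, 1e-6)), np.full(nb, np.log(0.3))]
        )
        bounds = [_LOG_KAPPA_BOUNDS] + [_LOG_T_BOUNDS] * nb + [_LOG_OMEGA_BOUNDS] * nb

        def neg(x):
            kappa = np.exp(x[0])
            lengths = dict(zip(self.branch_labels, np.exp(x[1 : 1 + nb])))
            omegas = dict(zip(self.branch_labels, np.exp(x[1 + nb :])))
            return -self.engine.loglik(kappa, omegas, lengths)

        res = _maximize(neg, x0, bounds, n_restarts, seed, ftol=ftol)
        kappa = float(np.exp(res.x[0]))
        lengths = dict(zip(self.branch_labels, map(float, np.exp(res.x[1 : 1 + nb]))))
        omegas = dict(zip(self.branch_labels, map(float, np.exp(res.x[1 + nb :]))))
        params = CodonModelParams(
            kappa, omegas, self.codon_freqs, lengths, code=self.alignment.code
        )
        records = []
        gene = "gene"
        for lab in self.branch_labels:
            dn, ds = decompose_branch_rates(params, lab)
            records.append(make_record(gene, lab, dn, ds, low_div_threshold))
        logger.info("free-ratio fit: lnL=%.4f kappa=%.3f", -res.fun, kappa)
        return FreeRatioResults(params, -float(res.fun), kappa, records, self.engine.n_sites)


@dataclass
class BranchSiteResults:
    """Model A likelihood-ratio test of positive selection on a foreground
    branch; P from the upper chi^2(1) tail of 2*(lnL_alt - lnL_null)."""

    foreground: str
    loglik_alt: float
    loglik_null: float
    site_class_props: np.ndarray
    omega0: float
    omega2: float
    kappa: float
    params_alt: CodonModelParams = field(repr=False)

    @property
    def statistic(self) -> float:
        return max(0.0, 2.0 * (self.loglik_alt - self.loglik_null))

    @property
    def p_value(self) -> float:
        return float(chi2.sf(self.statistic, df=1))

    @property
    def positive_selection(self) -> bool:
        return self.p_value < 0.05

    def summary(self) -> str:
        p = self.site_class_props
        return "\n".join(
            [
                f"Branch-site model A, foreground = {self.foreground}",
                "=" * 46,
                f"lnL (alt)  = {self.loglik_alt:.4f}",
                f"lnL (null) = {self.loglik_null:.4f}",
                f"2*dlnL     = {self.statistic:.4f}   P(chi2, 1 df) = {self.p_value:.4g}",
                f"omega0 = {self.omega0:.4f}  omega2 = {self.omega2:.4f}  kappa = {self.kappa:.4f}",
                f"class props: p0={p[0]:.3f} p1={p[1]:.3f} p2a={p[2]:.3f} p2b={p[3]:.3f}",
                f"positive selection (P < 0.05): {self.positive_selection}",
            ]
        )


def _class_props(x: float, y: float) -> np.ndarray:
    """(p0, p1, p2a, p2b) from unconstrained (x, y)."""
    a = 1.0 / (1.0 + np.exp(-x))  # p0 / (p0 + p1)
    b = 1.0 / (1.0 + np.exp(-y))  # p0 + p1
    return np.array([a * b, (1 - a) * b, a * (1 - b), (1 - a) * (1 - b)])


class BranchSite(_CodonModelBase):
    """Branch-site model A with a designated foreground branch."""

    def __init__(self, alignment, tree, foreground: str, codon_freqs="equal"):
        super().__init__(alignment, tree, codon_freqs)
        if foreground not in self.branch_labels:
            raise LabelError(f"foreground branch {foreground!r} not in tree")
        self.foreground = foreground

    def _class_omegas(self, omega0: float, omega2: float):
        bg = self.branch_labels
        fg = self.foreground

        def per_branch(back, fore):
            d = dict.fromkeys(bg, back)
            d[fg] = fore
            return d

        return [
            per_branch(omega0, omega0),  # class 0
            per_branch(1.0, 1.0),        # class 1
            per_branch(omega0, omega2),  # class 2a
            per_branch(1.0, omega2),     # class 2b
        ]

    def _neg(self, fix_omega2: bool, nb: int):
        labels = self.branch_labels

        def neg(x):
            kappa = np.exp(x[0])
            lengths = dict(zip(labels, np.exp(x[1 : 1 + nb])))
            props = _class_props(x[1 + nb], x[2 + nb])
            omega0 = 1.0 / (1.0 + np.exp(-x[3 + nb]))
            omega2 = 1.0 if fix_omega2 else 1.0 + np.exp(x[4 + nb])
            return -self.engine.mixture_loglik(
                kappa, props, self._class_omegas(omega0, omega2), lengths
            )

        return neg

    def fit(self, n_restarts: int = 1, seed: int = 0, ftol: float = 1e-9) -> BranchSiteResults:
        nb = len(self.branch_labels)
        t0 = np.log(np.maximum(self._t0(), 1e-6))
        # null: omega2 fixed at 1
        x0 = np.concatenate([[np.log(2.0)], t0, [1.0, 1.0, 0.0]])
        bounds = (
            [_LOG_KAPPA_BOUNDS] + [_LOG_T_BOUNDS] * nb + [(-12, 12), (-12, 12), (-12, 12)]
        )
        res_null = _maximize(self._neg(True, nb), x0, bounds, n_restarts, seed, ftol=ftol)
        # Alternative warm-started from the null solution with omega2 free
        # (>= 1).  Under the null the class-2 proportion is unidentified and
        # often collapses to ~0, which would park the alternative at a saddle
        # where the omega2 gradient vanishes; restart the mixing parameters
        # at interior values so class 2 carries weight initially.
        bounds_alt = bounds + [(np.log(1e-4), np.log(49.0))]
        neg_alt = self._neg(False, nb)
        x_interior = res_null.x.copy()
        x_interior[1 + nb : 3 + nb] = [1.0, 1.0]
        x0_alt = np.concatenate([x_interior, [np.log(2.0)]])
        res_alt = _maximize(neg_alt, x0_alt, bounds_alt, n_restarts, seed + 1, ftol=ftol)
        lnl_alt, lnl_null = -float(res_alt.fun), -float(res_null.fun)
        if lnl_alt < lnl_null:  # alt nests the null; clamp tiny numerical deficits
            lnl_alt = lnl_null
        x = res_alt.x
        kappa = float(np.exp(x[0]))
        lengths = dict(zip(self.branch_labels, map(float, np.exp(x[1 : 1 + nb]))))
        props = _class_props(x[1 + nb], x[2 + nb])
        omega0 = float(1.0 / (1.0 + np.exp(-x[3 + nb])))
        omega2 = float(1.0 + np.exp(x[4 + nb]))
        params = CodonModelParams(
            kappa,
            dict.fromkeys(self.branch_labels, omega0),
            self.codon_freqs,
            lengths,
            code=self.alignment.code,
        )
        return BranchSiteResults(
            self.foreground, lnl_alt, lnl_null, props, omega0, omega2, kappa, params
        )


# -- convenience wrappers ----------------------------------------------------


def fit_m0(aln, tree, **kw) -> M0Results:
    return M0(aln, tree).fit(**kw)


def fit_free_ratio(aln, tree, **kw) -> FreeRatioResults:
    return FreeRatio(aln, tree).fit(**kw)


def branch_site_test(aln, tree, foreground: str, **kw) -> BranchSiteResults:
    return BranchSite(aln, tree, foreground).fit(**kw)
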