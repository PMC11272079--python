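"""GY94 rate-matrix structure, pruning likelihood, model fits and the
branch-site likelihood-ratio test."""

import itertools

import numpy as np
import pytest

from ovorate import simulate as sim
from ovorate._codons import change_tables, sense_codons
from ovorate.alignment import CodonAlignment
from ovorate.codonmodel import (
    M0,
    BranchSite,
    CodonModelParams,
    FreeRatio,
    PruningEngine,
    build_rate_matrix,
    decompose_branch_rates,
    equal_codon_freqs,
    f3x4_codon_freqs,
    transition_matrix,
)
from ovorate.ratetable import OmegaCode, make_record
from ovorate.trees import PhyloTree, star_tree


def _params(kappa=2.0, omega=0.4, freqs=None, branches=("b",), t=0.1):
    freqs = equal_codon_freqs() if freqs is None else freqs
    return CodonModelParams(
        kappa, dict.fromkeys(branches, omega), freqs, dict.fromkeys(branches, t)
    )


def _random_freqs(rng):
    f = rng.dirichlet(np.full(61, 5.0))
    return f / f.sum()


# -- rate matrix -------------------------------------------------------------


@pytest.mark.parametrize("kappa,omega", [(2.0, 0.4), (0.5, 1.7), (8.0, 0.01)])
def test_rate_matrix_rows_sum_to_zero_and_scaling(kappa, omega):
    q = build_rate_matrix(_params(kappa, omega), "b")
    np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
    freqs = equal_codon_freqs()
    assert -(freqs * np.diag(q)).sum() == pytest.approx(1.0, abs=1e-12)


def test_rate_matrix_zero_for_multi_nucleotide_changes():
    q = build_rate_matrix(_params(), "b")
    single, _, _ = change_tables("universal")
    off = ~np.eye(61, dtype=bool)
    assert np.all(q[off & ~single] == 0.0)
    assert np.all(q[single] > 0.0)


def test_equal_rates_when_kappa_and_omega_are_one():
    q = build_rate_matrix(_params(kappa=1.0, omega=1.0), "b")
    single, _, _ = change_tables("universal")
    rates = q[single]
    np.testing.assert_allclose(rates, rates[0])


def test_detailed_balance_under_random_frequencies():
    rng = np.random.default_rng(7)
    freqs = _random_freqs(rng)
    q = build_rate_matrix(_params(kappa=3.1, omega=0.6, freqs=freqs), "b")
    flux = freqs[:, None] * q
    np.testing.assert_allclose(flux, flux.T, atol=1e-14)


@pytest.mark.parametrize("t", [0.0, 0.05, 1.0, 5.0])
def test_transition_matrices_are_stochastic(t):
    rng = np.random.default_rng(3)
    p = transition_matrix(_params(freqs=_random_freqs(rng)), "b", t=t)
    assert (p >= -1e-12).all()
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)


# -- pruning likelihood ------------------------------------------------------


def enumeration_loglik(aln, tree, kappa, omega, lengths, freqs):
    """Independent oracle: sum the column likelihood over every assignment
    of codon states to internal nodes."""
    params = CodonModelParams(
        kappa, dict.fromkeys(lengths, omega), freqs, dict(lengths)
    )
    nodes = tree.postorder_structure()
    p = {
        n["label"]: transition_matrix(params, n["label"], t=lengths[n["label"]])
        for n in nodes[:-1]
    }
    mat = aln.codon_indices()
    row = {t: i for i, t in enumerate(aln.taxa)}
    internal = [i for i, n in enumerate(nodes) if not n["is_tip"]]
    root = len(nodes) - 1
    total = 0.0
    for col in range(aln.n_codons):
        like = 0.0
        for assign in itertools.product(range(61), repeat=len(internal)):
            state = {i: s for i, s in zip(internal, assign)}
            for i, n in enumerate(nodes):
                if n["is_tip"]:
                    state[i] = mat[row[n["label"]], col]
            term = freqs[state[root]]
            for i, n in enumerate(nodes):
                if n["parent"] is not None:
                    term *= p[n["label"]][state[n["parent"]], state[i]]
            like += term
        total += np.log(like)
    return total


@pytest.mark.parametrize(
    "newick,n_codons",
    [
        ("(A:0.15,B:0.3);", 2),
        ("(A:0.1,B:0.2,C:0.35);", 3),
        ("((A:0.1,B:0.2):0.15,C:0.3);", 3),
    ],
)
def test_pruning_equals_exhaustive_enumeration(newick, n_codons):
    tree = PhyloTree.from_newick(newick)
    rng = np.random.default_rng(17)
    freqs = _random_freqs(rng)
    aln = sim.simulate_codon_alignment(
        tree, kappa=2.5, omega=0.5, n_codons=n_codons, codon_freqs=freqs, seed=23
    )
    eng = PruningEngine(aln, tree, freqs)
    lengths = tree.branch_lengths
    lnl = eng.loglik(2.5, dict.fromkeys(eng.branch_labels, 0.5), lengths)
    oracle = enumeration_loglik(aln, tree, 2.5, 0.5, lengths, freqs)
    assert lnl == pytest.approx(oracle, abs=1e-9)


def test_likelihood_invariant_to_rerooting():
    """Pulley principle: the same unrooted tree written with different
    roots gives identical likelihoods under the reversible model."""
    rng = np.random.default_rng(5)
    freqs = _random_freqs(rng)
    t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3,D:0.25);")
    aln = sim.simulate_codon_alignment(
        t1, kappa=1.8, omega=0.3, n_codons=40, codon_freqs=freqs, seed=31
    )
    # same unrooted topology, rerooted on the A-B stem
    t2 = PhyloTree.from_newick("(A:0.1,B:0.2,(C:0.3,D:0.25):0.15);")
    lnls = []
    for tree in (t1, t2):
        eng = PruningEngine(aln, tree, freqs)
        lnls.append(
            eng.loglik(1.8, dict.fromkeys(eng.branch_labels, 0.3), tree.branch_lengths)
        )
    assert lnls[0] == pytest.approx(lnls[1], abs=1e-9)


def test_zero_branch_lengths_identical_sequences_reduce_to_prior():
    seq = "ATGGCTGAT" * 4
    aln = CodonAlignment(["A", "B", "C"], [seq] * 3)
    tree = PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
    freqs = equal_codon_freqs()
    eng = PruningEngine(aln, tree, freqs)
    lnl = eng.loglik(2.0, dict.fromkeys(eng.branch_labels, 0.5), tree.branch_lengths)
    idx = aln.codon_indices()[0]
    assert lnl == pytest.approx(np.log(freqs[idx]).sum(), abs=1e-10)


# -- decomposition -----------------------------------------------------------


def test_dn_equals_ds_at_neutrality():
    dn, ds = decompose_branch_rates(_params(omega=1.0, t=0.37), "b")
    assert dn == pytest.approx(ds, abs=1e-9)
    assert dn == pytest.approx(0.37, abs=1e-9)


@pytest.mark.parametrize("omega", [0.05, 0.5, 2.7])
def test_dn_over_ds_reproduces_omega(omega):
    rng = np.random.default_rng(int(omega * 100))
    params = _params(kappa=rng.uniform(1, 5), omega=omega, freqs=_random_freqs(rng), t=0.2)
    dn, ds = decompose_branch_rates(params, "b")
    assert dn / ds == pytest.approx(omega, rel=1e-6)


def test_zero_length_branch_has_zero_rates():
    assert decompose_branch_rates(_params(t=0.0), "b") == (0.0, 0.0)


# -- model fits --------------------------------------------------------------


def test_m0_recovers_simulated_omega(five_star):
    aln = sim.simulate_codon_alignment(five_star, kappa=2.0, omega=0.2, n_codons=2000, seed=8)
    res = M0(aln, five_star).fit(n_restarts=0)
    assert res.omega == pytest.approx(0.2, rel=0.15)
    assert res.kappa == pytest.approx(2.0, rel=0.2)


def test_identical_sequences_collapse_branch_lengths():
    seq = "ATGGCTGATCCAGGA" * 10
    aln = CodonAlignment(["A", "B", "C"], [seq] * 3)
    tree = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
    res = M0(aln, tree).fit(n_restarts=0)
    assert all(t < 1e-3 for t in res.params.branch_lengths.values())


def test_free_ratio_loglik_dominates_m0(five_taxon_tree, small_alignment):
    m0 = M0(small_alignment, five_taxon_tree).fit(n_restarts=0)
    fr = FreeRatio(small_alignment, five_taxon_tree).fit(n_restarts=0)
    assert fr.loglik >= m0.loglik - 1e-6


def test_free_ratio_zero_divergence_branch_is_lowdiv(five_star):
    tree = PhyloTree.from_newick("(A:0.15,B:0.15,C:0.15,D:0.15,E:0.0000001);")
    aln = sim.simulate_codon_alignment(tree, omega=0.3, n_codons=400, seed=12)
    res = FreeRatio(aln, tree).fit(n_restarts=0)
    codes = {r.branch: r.code for r in res.rate_records}
    assert codes["E"] is OmegaCode.LOWDIV


def test_high_omega_short_branch_classifies_gt1():
    """A branch with essentially no synonymous flux but real nonsynonymous
    divergence gets the '>1' sentinel."""
    params = _params(kappa=2.0, omega=30.0, t=0.02)
    dn, ds = decompose_branch_rates(params, "b")
    rec = make_record("g", "b", dn, ds)
    assert ds < 0.001 < dn
    assert rec.code is OmegaCode.GT1


def test_branch_site_alt_never_below_null(five_star):
    tree = star_tree(["A", "B", "C"], 0.2)
    aln = sim.simulate_codon_alignment(tree, omega=0.25, n_codons=150, seed=21)
    res = BranchSite(aln, tree, "C").fit(n_restarts=0)
    assert res.statistic >= 0.0
    assert res.site_class_props.sum() == pytest.approx(1.0, abs=1e-9)
    assert 0 < res.omega0 < 1
    assert res.omega2 >= 1.0


def test_branch_site_detects_planted_selection():
    """Power check: omega2 = 4 on ~10% of foreground sites is detected in
    a majority of replicates."""
    tree = star_tree(["A", "B", "C"], 0.2)
    base = {"A": 0.2, "B": 0.2, "C": 0.2}
    fg4 = {"A": 0.2, "B": 0.2, "C": 4.0}
    neutral = {"A": 1.0, "B": 1.0, "C": 1.0}
    hits = 0
    n_reps = 20
    for rep in range(n_reps):
        aln = sim.simulate_codon_alignment(
            tree,
            n_codons=2000,
            seed=1000 + rep,
            site_class_props=[0.6, 0.3, 0.1],
            site_class_omegas=[base, neutral, fg4],
        )
        res = BranchSite(aln, tree, "C").fit(n_restarts=0)
        hits += res.p_value < 0.05
    assert hits / n_reps > 0.5


def test_unknown_foreground_branch_raises(five_star, small_alignment):
    aln = sim.simulate_codon_alignment(five_star, n_codons=30, seed=2)
    with pytest.raises(KeyError):
        BranchSite(aln, five_star, "nope")


def test_f3x4_frequencies_sum_to_one(small_alignment):
    f = f3x4_codon_freqs(small_alignment)
    assert f.sum() == pytest.approx(1.0, abs=1e-12)
    assert (f >= 0).all()
    assert len(f) == len(sense_codons())
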