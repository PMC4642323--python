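"""Codon site models: pruning likelihood, model fits, LRT, site posteriors."""

import numpy as np
import pytest

from nbsevol._codon import uniform_codon_frequencies
from nbsevol.phylo import Node, PhyloTree
from nbsevol.selection import (
    CodonModelParams,
    SiteModelFit,
    chi2_critical,
    fit_model,
    lrt_m7_m8,
    positive_sites,
    site_likelihood,
)
from nbsevol.simulate import calibrate_separation, evolve_codon_sequence

from oracles import brute_force_likelihood

PI = uniform_codon_frequencies()


def star_tree(lengths: dict[str, float]) -> PhyloTree:
    return PhyloTree(root=Node(children=[Node(label=k, length=v)
                                         for k, v in lengths.items()]))


def test_chi2_critical_values_match_published_thresholds():
    assert chi2_critical(0.05, 2) == pytest.approx(5.991, abs=5e-4)
    assert chi2_critical(0.01, 2) == pytest.approx(9.210, abs=5e-4)
    # df=2 closed form: -2 ln(alpha)
    assert chi2_critical(0.3, 2) == pytest.approx(-2 * np.log(0.3))
    for bad in (0.0, 1.0, -1):
        with pytest.raises(ValueError):
            chi2_critical(bad, 2)


def test_pruning_equals_ancestral_state_summation():
    rng = np.random.default_rng(0)
    from nbsevol._codon import SENSE_CODONS
    for n_taxa, n_codons in ((3, 2), (4, 3)):
        labels = [f"t{i}" for i in range(n_taxa)]
        lengths = {l: float(rng.uniform(0.05, 0.6)) for l in labels}
        rows = {l: "".join(rng.choice(SENSE_CODONS, size=n_codons)) for l in labels}
        kappa, omega = float(rng.uniform(1, 4)), float(rng.uniform(0.1, 1.5))
        params = CodonModelParams(model="M0", kappa=kappa, omega=omega, pi=PI)
        lnl, _ = site_likelihood((labels, [rows[l] for l in labels]),
                                 star_tree(lengths), params)
        oracle = brute_force_likelihood(
            {l: [rows[l][i:i + 3] for i in range(0, 3 * n_codons, 3)] for l in labels},
            lengths, kappa, omega, PI)
        assert lnl == pytest.approx(oracle, abs=1e-9)


def test_zero_branches_and_identical_sequences_give_log_pi():
    rows = {"a": "ATGGCT", "b": "ATGGCT", "c": "ATGGCT"}
    tree = star_tree({k: 0.0 for k in rows})
    params = CodonModelParams(model="M0", kappa=2.0, omega=0.5, pi=PI)
    lnl, site = site_likelihood((list(rows), list(rows.values())), tree, params)
    assert lnl == pytest.approx(2 * np.log(1 / 61))
    assert site == pytest.approx([np.log(1 / 61)] * 2)


def test_m8_with_empty_positive_class_reduces_to_m7():
    rng = np.random.default_rng(1)
    from nbsevol._codon import SENSE_CODONS
    rows = {l: "".join(rng.choice(SENSE_CODONS, size=5)) for l in "abc"}
    tree = star_tree({l: 0.2 for l in rows})
    aln = (list(rows), list(rows.values()))
    m7 = CodonModelParams(model="M7", kappa=2.0, pi=PI, p=0.4, q=1.2)
    m8 = CodonModelParams(model="M8", kappa=2.0, pi=PI, p=0.4, q=1.2,
                          p0=1.0, omega_s=3.0)
    lnl7, _ = site_likelihood(aln, tree, m7)
    lnl8, _ = site_likelihood(aln, tree, m8)
    assert lnl8 == pytest.approx(lnl7, abs=1e-9)


def _sim_family(seed: int, omega: float, n_codons: int = 150, ks: float = 0.3):
    rng = np.random.default_rng(seed)
    sep = calibrate_separation(ks, 1.5, omega, PI)
    root = rng.choice(61, size=n_codons, p=PI)
    rows = {f"t{i}": evolve_codon_sequence(root, sep / 2, 1.5, omega, PI, rng)
            for i in range(4)}
    return (list(rows), list(rows.values())), star_tree({k: sep / 2 for k in rows})


def test_m8_never_fits_worse_than_m7():
    aln, tree = _sim_family(seed=2, omega=0.25)
    fit0 = fit_model(aln, tree, "M0", seed=0, restarts=1)
    fit7 = fit_model(aln, tree, "M7", seed=0, restarts=1, m0_fit=fit0)
    fit8 = fit_model(aln, tree, "M8", seed=0, restarts=1, m0_fit=fit0,
                     init={"p": fit7.params.p, "q": fit7.params.q,
                           "p0": 1.0, "omega_s": 1.0})
    assert fit8.lnl >= fit7.lnl - 1e-4
    lrt = lrt_m7_m8(fit7, fit8)
    assert lrt.two_delta_lnl >= 0.0
    assert lrt.significance in ("ns", "*", "**")


def test_identical_family_is_flagged_unidentifiable():
    rows = {"a": "ATGGCTAAA", "b": "ATGGCTAAA", "c": "ATGGCTAAA"}
    tree = star_tree({k: 0.1 for k in rows})
    fit = fit_model((list(rows), list(rows.values())), tree, "M0", seed=0, restarts=1)
    assert not fit.converged


def _fake_fit(model, lnl, fingerprint="x"):
    params = CodonModelParams(model=model, kappa=2.0, pi=PI, p=0.5, q=1.5,
                              p0=0.9, omega_s=2.0)
    return SiteModelFit(model=model, params=params, lnl=lnl,
                        site_lnl=np.zeros(1), branch_lengths={},
                        converged=True, data_fingerprint=fingerprint)


def test_lrt_arithmetic_and_significance_stars():
    res = lrt_m7_m8(_fake_fit("M7", -1000.0), _fake_fit("M8", -996.0))
    assert res.two_delta_lnl == pytest.approx(8.0)
    assert res.significance == "*"          # between 5.991 and 9.210
    res = lrt_m7_m8(_fake_fit("M7", -500.0), _fake_fit("M8", -495.0))
    assert res.two_delta_lnl == pytest.approx(10.0)
    assert res.significance == "**"
    res = lrt_m7_m8(_fake_fit("M7", -500.0), _fake_fit("M8", -500.0))
    assert res.two_delta_lnl == 0.0 and res.significance == "ns"


def test_lrt_rejects_mismatched_data():
    with pytest.raises(ValueError, match="different data"):
        lrt_m7_m8(_fake_fit("M7", -10, "x"), _fake_fit("M8", -9, "y"))


def test_site_posteriors_normalize_and_vanish_without_positive_class():
    aln, tree = _sim_family(seed=3, omega=0.2, n_codons=60)
    fit0 = fit_model(aln, tree, "M0", seed=0, restarts=1)
    fit8 = fit_model(aln, tree, "M8", seed=0, restarts=1, m0_fit=fit0)
    post = positive_sites(fit8)
    assert np.allclose(post.class_posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert ((post.prob_positive >= 0) & (post.prob_positive <= 1)).all()
    # force p0 = 1: no positive class mass anywhere
    fit8.params.p0 = 1.0
    omegas, weights = fit8.params.site_classes()
    fit8.class_weights = weights
    post0 = positive_sites(fit8)
    assert post0.prob_positive == pytest.approx(np.zeros(len(post0.prob_positive)))
    assert all(f == "" for f in post0.flags)


def test_purifying_site_stays_below_confidence_cutoffs():
    # conserved alignment under strong purifying weights: no site should be
    # called positively selected
    aln, tree = _sim_family(seed=4, omega=0.05, n_codons=80)
    fit0 = fit_model(aln, tree, "M0", seed=0, restarts=1)
    fit8 = fit_model(aln, tree, "M8", seed=0, restarts=1, m0_fit=fit0)
    post = positive_sites(fit8)
    assert post.prob_positive.max() < 0.95
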