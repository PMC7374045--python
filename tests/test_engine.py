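"""Coupled simulation loop, ensemble readouts and parameter resolution."""

import numpy as np
import pytest

from tmesim.boolnet import exact_stationary_distribution, parse_rules
from tmesim.diffusion import CytokineParams
from tmesim.model import (CellClamp, MutationRule, ReceptorRule, SecretionRule,
                          TMEModel, plateau_onset)
from tmesim.tissue import TissueConfig


def isolated_model(rules_text, q=0.05, phenotype=("P",)):
    """Single-cell-type model with no cytokine coupling."""
    net = parse_rules(rules_text, name="C", phenotype_nodes=list(phenotype))
    tissue = TissueConfig(L=6.0, rho=0.3, r_C=1.0, s=0.2, R_ex=0.0,
                          cancer_type="C", stromal_fractions={}, fixed_n=True)
    return TMEModel(networks={"C": net}, cytokines=[], secretion=[],
                    receptors=[], tissue=tissue, q=q)


def coupled_two_type_model(rate=5.0, threshold=0.2, q=0.0, L=4.0):
    """Type A secretes cytokine m gated by a clampable node; type B senses it."""
    net_a = parse_rules("targets, factors\nS, S\nP, S\n", name="A",
                        phenotype_nodes=["P"], secretion_nodes={"m": "S"})
    net_b = parse_rules("targets, factors\nOut, R\n", name="B",
                        receptors=["R"], phenotype_nodes=["Out"])
    tissue = TissueConfig(L=L, rho=0.5, r_C=0.5, s=0.5, R_ex=0.0,
                          cancer_type="A", stromal_fractions={"B": 1.0},
                          fixed_n=True)
    return TMEModel(
        networks={"A": net_a, "B": net_b},
        cytokines=[CytokineParams.from_length("m", lambda_=50.0)],
        secretion=[SecretionRule("A", "m", rate=rate)],
        receptors=[ReceptorRule("B", "m", "R", threshold=threshold)],
        tissue=tissue, q=q)


# ---------------------------------------------------------------------------
# construction / validation
# ---------------------------------------------------------------------------

def test_unwired_receptor_is_configuration_error():
    net = parse_rules("targets, factors\nP, R\n", name="A", receptors=["R"])
    tissue = TissueConfig(cancer_type="A", stromal_fractions={})
    with pytest.raises(ValueError, match="not a receptor node|unknown cytokine"):
        TMEModel(networks={"A": net}, cytokines=[],
                 secretion=[], receptors=[ReceptorRule("A", "m", "R")],
                 tissue=tissue)


def test_inert_cytokine_flagged(demo):
    assert demo.inert_cytokines == {"VEGF"}
    assert set(demo.active_cytokines) == {"EGF", "bFGF", "TGFb"}


def test_resolve_applies_theta(demo):
    theta = {"R:PCC:EGF": 8.0, "K:PSC:TGFb": 0.9, "alpha:KRAS": 0.4,
             "s": 0.3, "r_PSC": 0.25}
    secretion, receptors, mutations, tissue = demo.resolve(theta)
    assert {(r.cell_type, r.cytokine): r.rate for r in secretion}[("PCC", "EGF")] == 8.0
    assert {(r.cell_type, r.cytokine): r.threshold
            for r in receptors}[("PSC", "TGFb")] == 0.9
    assert {m.gene: m.alpha for m in mutations}["KRAS"] == 0.4
    assert tissue.s == 0.3
    assert tissue.r_C == pytest.approx(0.75)
    # the model's own defaults are untouched (pure derivation)
    assert demo.tissue.s == 0.07


def test_resolve_rejects_unknown_keys(demo):
    with pytest.raises(KeyError):
        demo.resolve({"R:PCC:IL6": 3.0})
    with pytest.raises(KeyError):
        demo.resolve({"nonsense": 1.0})


# ---------------------------------------------------------------------------
# step semantics
# ---------------------------------------------------------------------------

def test_constant_rules_reach_all_on_immediately():
    model = isolated_model("targets, factors\nP, 1\nQ, 1\n", q=0.0)
    res = model.simulate(M=2, T=3, K=2, seed=0)
    assert np.all(res.phenotype_trajectory("P")[:, 1:] == 1.0)
    assert res.expression_profile().loc["P"] == 1.0


def test_paracrine_receptor_reads_one_from_step_one():
    """With the secretion node clamped ON and lambda >> L the field is
    uniform, eta_total/(gamma_D L^3); a threshold below that value turns the
    receiver's receptor ON from the first update onward."""
    model = coupled_two_type_model(rate=5.0, threshold=0.2)
    V = model.tissue.L ** 3
    n_a = round(0.5 * 0.5 * V)
    c_uniform = (5.0 * n_a + 1.0 * 0) / V  # all A-cells clamped ON
    assert c_uniform > 0.2
    res = model.simulate(M=1, T=5, K=5, seed=1,
                         clamps=[CellClamp("A", "S", 1, 1.0)])
    out = res.phenotype_trajectory("Out", cell_type="B")
    # Out = R takes one extra step to propagate: receptor set at step 1,
    # Out reflects it from step 2
    assert np.all(out[:, 2:] == 1.0)


def test_below_threshold_receptor_stays_off():
    model = coupled_two_type_model(rate=5.0, threshold=1e3)
    res = model.simulate(M=1, T=4, K=4, seed=1,
                         clamps=[CellClamp("A", "S", 1, 1.0)])
    assert np.all(res.phenotype_trajectory("Out", cell_type="B")[:, 1:] == 0.0)


def test_same_seed_identical_trajectories(demo):
    r1 = demo.simulate(M=2, T=10, K=5, seed=42)
    r2 = demo.simulate(M=2, T=10, K=5, seed=42)
    assert np.array_equal(r1.genes, r2.genes)
    for k in r1.pheno:
        assert np.array_equal(r1.pheno[k], r2.pheno[k])


def test_different_seeds_differ(demo):
    r1 = demo.simulate(M=1, T=10, K=5, seed=1)
    r2 = demo.simulate(M=1, T=10, K=5, seed=2)
    assert not np.array_equal(r1.genes, r2.genes)


# ---------------------------------------------------------------------------
# ensemble readouts
# ---------------------------------------------------------------------------

def test_isolated_dynamics_match_stationary_oracle():
    """With no coupling, the ensemble per-gene ON fraction converges to the
    exact stationary marginal of the single-cell chain."""
    rules = "targets, factors\nA, B\nB, !A\n"
    q = 0.1
    model = isolated_model(rules, q=q, phenotype=("A",))
    net = model.networks["C"]
    pi = exact_stationary_distribution(net, q=q)
    # marginal P(A=1): states with bit 0 set
    marg_a = pi[[1, 3]].sum()
    res = model.simulate(M=10, T=300, K=200, seed=5)
    f_hat = res.expression_profile().loc["A"]
    n_cells = sum(c["C"] for c in res.cell_counts)
    se = 3 * np.sqrt(marg_a * (1 - marg_a) / (n_cells * 200 / 10))
    assert abs(f_hat - marg_a) < max(se, 0.01)


def test_mutation_fraction_matches_alpha(demo):
    theta = {"alpha:KRAS": 0.35}
    counts, totals = 0, 0
    for seed in range(6):
        res = demo.simulate(theta, M=2, T=2, K=1, seed=seed)
        for audit, n in zip(res.clamp_audit, res.cell_counts):
            counts += audit["PCC"].get("KRAS", 0)
            totals += n["PCC"]
    frac = counts / totals
    se = np.sqrt(0.35 * 0.65 / totals)
    assert abs(frac - 0.35) < 4 * se


def test_k_longer_than_t_rejected(demo):
    with pytest.raises(ValueError, match="tail steps exceed"):
        demo.simulate(M=1, T=10, K=20, seed=0)


def test_phenotype_score_recomputable_from_tidy_table(demo):
    res = demo.simulate(M=3, T=30, K=15, seed=9)
    df = res.to_frame()
    window = 10
    sub = df[(df.cell_type == "PCC") & (df.node == "Proliferation")
             & (df.step > 30 - window)]
    assert res.phenotype_score("Proliferation", window=window) == \
        pytest.approx(sub["fraction"].mean())


def test_phenotype_score_edge_cases(demo):
    res = demo.simulate(M=1, T=5, K=5, seed=0)
    with pytest.raises(KeyError, match="available"):
        res.phenotype_trajectory("NotANode")
    with pytest.raises(ValueError, match="window"):
        res.phenotype_score("Proliferation", window=99)


def test_plateau_onset_synthetic():
    steps = np.arange(201.)
    flat = np.full(201, 0.8) + 0.001 * np.sin(steps)
    assert plateau_onset(flat) == 10
    ramp = np.concatenate([np.linspace(0, 0.8, 61), np.full(140, 0.8)])
    onset = plateau_onset(ramp)
    assert 50 <= onset <= 80
    diverging = np.linspace(0, 1, 60)
    with pytest.raises(ValueError):
        plateau_onset(diverging, plateau_window=100)


def test_summary_mentions_phenotypes(demo):
    res = demo.simulate(M=2, T=10, K=5, seed=3)
    text = res.summary()
    assert "PCC.Proliferation" in text and "PSC.Activation" in text
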