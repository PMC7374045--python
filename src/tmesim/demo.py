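"""Built-in demonstration model and synthetic data generators.

The two-cell demo model is a compact, hand-written stand-in for the
published pancreatic cancer-cell (PCC) / stellate-cell (PSC) network pair.
It reproduces the wiring motifs that drive the system's qualitative
behavior rather than any particular published rule set:

* cancer cells secrete EGF, bFGF and TGFb; EGF and bFGF are autocrine
  (EGFR/FGFR feed the KRAS-PI3K growth axis, which in turn drives
  secretion);
* TGFb activates stellate cells, and *activated* stellate cells secrete
  bFGF — the cancer -> stellate -> cancer paracrine relay;
* stellate cells also secrete VEGF, which no modeled cell senses (an
  intentionally inert output, mirroring the weak VEGF-perturbation response
  of the full model);
* growth-axis activity suppresses the p53 arm, so proliferation and
  apoptosis are mutually exclusive readouts, and the four recurrent PDAC
  mutations (KRAS activating; TP53/CDKN2A/SMAD4 inactivating) enter as
  permanent node clamps on a fraction alpha of cancer cells.

Everything here is synthetic and regenerable from a single seed; the
transcribed published networks, when available, slot into the same rule-file
format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boolnet import BooleanNetwork, parse_rules, rule_to_str
from .cohort import MUTATION_PREVALENCE
from .diffusion import CytokineParams
from .model import MutationRule, ReceptorRule, SecretionRule, TMEModel
from .params import Param, ParameterSpace
from .tissue import TissueConfig

__all__ = ["pcc_network", "psc_network", "demo_model", "demo_parameter_space",
           "make_toy_network", "make_synthetic_cohort", "table_protocol_space", "TABLE_PROTOCOLS"]

PCC_RULES = """\
targets, factors
KRAS, EGFR | FGFR
PI3K, KRAS
TP53, !PI3K
CDKN2A, TP53
SMAD4, TGFBR
EGF, KRAS
bFGF, KRAS
TGFb, KRAS
Proliferation, KRAS & !TP53 & !CDKN2A
Apoptosis, TP53 & !KRAS
Autophagy, SMAD4 & !PI3K
"""

PSC_RULES = """\
targets, factors
Activation, TGFBR | Activation
bFGF, Activation
VEGF, Activation
Proliferation, Activation
"""


def pcc_network() -> BooleanNetwork:
    """Demo pancreatic cancer cell network (3 receptors, 11 regulatory nodes)."""
    return parse_rules(
        PCC_RULES, name="PCC",
        receptors=["EGFR", "FGFR", "TGFBR"],
        phenotype_nodes=["Proliferation", "Apoptosis", "Autophagy"],
        secretion_nodes={"EGF": "EGF", "bFGF": "bFGF", "TGFb": "TGFb"},
    )


def psc_network() -> BooleanNetwork:
    """Demo pancreatic stellate cell network (1 receptor, 4 regulatory nodes)."""
    return parse_rules(
        PSC_RULES, name="PSC",
        receptors=["TGFBR"],
        phenotype_nodes=["Activation", "Proliferation"],
        secretion_nodes={"bFGF": "bFGF", "VEGF": "VEGF"},
    )


#: default cytokine transport: interaction distance lambda = 2.5 cell
#: diameters, unit degradation rate (all quantities nondimensional).
DEFAULT_LAMBDA = 2.5


def demo_model(R: float = 5.0, K_pcc: float = 0.6, K_psc: float = 0.4,
               L: float = 10.0, rho: float = 0.25, r_C: float = 0.6,
               s: float = 0.07, q: float = 0.01, lambda_: float = DEFAULT_LAMBDA,
               alphas: dict[str, float] | None = None,
               fixed_n: bool = True) -> TMEModel:
    """Build the two-cell-type demo model.

    Defaults give ~250 cells in a 10^3 box (one-diameter voxels), secretion
    rates R=5, thresholds above the all-basal background field (~rho) but
    below actively sourced fields, clustering s=0.07 and flip probability
    q=0.01.
    """
    alphas = alphas or {}
    tissue = TissueConfig(L=L, rho=rho, r_C=r_C, s=s, R_ex=1.5,
                          cancer_type="PCC",
                          stromal_fractions={"PSC": 1.0}, fixed_n=fixed_n)
    cytokines = [CytokineParams.from_length(m, lambda_)
                 for m in ("EGF", "bFGF", "TGFb", "VEGF")]
    secretion = [
        SecretionRule("PCC", "EGF", rate=R),
        SecretionRule("PCC", "bFGF", rate=R),
        SecretionRule("PCC", "TGFb", rate=R),
        SecretionRule("PSC", "bFGF", rate=R),
        SecretionRule("PSC", "VEGF", rate=R),
    ]
    receptors = [
        ReceptorRule("PCC", "EGF", "EGFR", threshold=K_pcc),
        ReceptorRule("PCC", "bFGF", "FGFR", threshold=K_pcc),
        ReceptorRule("PCC", "TGFb", "TGFBR", threshold=K_pcc),
        ReceptorRule("PSC", "TGFb", "TGFBR", threshold=K_psc),
    ]
    # activating KRAS clamps ON; the tumor suppressors clamp OFF
    mutations = [MutationRule("KRAS", 1, alpha=alphas.get("KRAS", 0.0))]
    mutations += [MutationRule(g, 0, alpha=alphas.get(g, 0.0))
                  for g in ("TP53", "CDKN2A", "SMAD4")]
    return TMEModel(networks={"PCC": pcc_network(), "PSC": psc_network()},
                    cytokines=cytokines, secretion=secretion,
                    receptors=receptors, tissue=tissue, mutations=mutations,
                    q=q, h=1.0, name="demo")


def demo_parameter_space(include_mutations: bool = False) -> ParameterSpace:
    """Default bounded parameter space for sensitivity and calibration.

    Secretion rates span [1, 10] (basal to strongly active), thresholds a
    log-scaled band straddling the transition between the all-basal
    background field (~rho) and actively sourced fields, the stellate
    fraction [0.1, 0.9] and the clustering parameter [0.01, 1] (clustered to
    homogeneous).
    """
    params = [
        Param("R:PCC:EGF", 1.0, 10.0),
        Param("R:PCC:bFGF", 1.0, 10.0),
        Param("R:PCC:TGFb", 1.0, 10.0),
        Param("R:PSC:bFGF", 1.0, 10.0),
        Param("K:PCC:EGF", 0.3, 3.0, scale="log"),
        Param("K:PCC:bFGF", 0.3, 3.0, scale="log"),
        Param("K:PCC:TGFb", 0.3, 3.0, scale="log"),
        Param("K:PSC:TGFb", 0.1, 1.5, scale="log"),
        Param("r_PSC", 0.1, 0.9),
        Param("s", 0.01, 1.0, scale="log"),
    ]
    if include_mutations:
        params += [Param(f"alpha:{g}", 0.0, 1.0)
                   for g in ("KRAS", "TP53", "CDKN2A", "SMAD4")]
    return ParameterSpace(params)


#: secretion-rate freezing protocols probing the stellate-cancer interplay:
#: "sym"  — all secretion rates equal (5), all loops equally weighted;
#: "asym" — cancer rates frozen low (2), stellate bFGF rate sampled in
#:          [2, 10] (stellate-to-cancer signaling dominant);
#: "egf"/"bfgf"/"tgfb" — one cancer autocrine loop sampled in [2, 10] with
#:          the other cancer rates frozen at 2 and the stellate rate at 5.
#: In every protocol the stellate fraction r_PSC, the clustering s and the
#: KRAS-mutant fraction are sampled; the readout is PRCC(r_PSC, phenotype).
TABLE_PROTOCOLS = ("sym", "asym", "egf", "bfgf", "tgfb")


def table_protocol_space(protocol: str) -> ParameterSpace:
    """Parameter space for one secretion-rate freezing protocol.

    These express the cancer/stellate interplay experiments purely as
    ParameterSpace configurations (frozen vs sampled secretion rates); no
    special-case simulation code is involved.
    """
    if protocol not in TABLE_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {TABLE_PROTOCOLS}")
    params = [Param("r_PSC", 0.1, 0.9),
              Param("s", 0.01, 1.0, scale="log"),
              Param("alpha:KRAS", 0.0, 1.0)]
    frozen = {
        "sym": {"R:PCC:EGF": 5.0, "R:PCC:bFGF": 5.0, "R:PCC:TGFb": 5.0,
                "R:PSC:bFGF": 5.0},
        "asym": {"R:PCC:EGF": 2.0, "R:PCC:bFGF": 2.0, "R:PCC:TGFb": 2.0},
        "egf": {"R:PCC:bFGF": 2.0, "R:PCC:TGFb": 2.0, "R:PSC:bFGF": 5.0},
        "bfgf": {"R:PCC:EGF": 2.0, "R:PCC:TGFb": 2.0, "R:PSC:bFGF": 5.0},
        "tgfb": {"R:PCC:EGF": 2.0, "R:PCC:bFGF": 2.0, "R:PSC:bFGF": 5.0},
    }[protocol]
    sampled = {"sym": None, "asym": "R:PSC:bFGF", "egf": "R:PCC:EGF",
               "bfgf": "R:PCC:bFGF", "tgfb": "R:PCC:TGFb"}[protocol]
    params += [Param(name, value, value + 1.0, frozen=value)
               for name, value in frozen.items()]
    if sampled:
        params.append(Param(sampled, 2.0, 10.0))
    return ParameterSpace(params)


# ---------------------------------------------------------------------------
# Toy random networks (oracle-sized)
# ---------------------------------------------------------------------------

def make_toy_network(n: int, k: int = 2, seed=None, name: str = "toy") -> BooleanNetwork:
    """Random n-node Boolean network with at most k inputs per rule.

    Rules are random and/or/not compositions over randomly chosen inputs;
    the last node is annotated as the phenotype readout.  Limited to n <= 12
    so the exact stationary oracle stays applicable.
    """
    if n < 1 or n > 12:
        raise ValueError("toy networks support 1..12 nodes")
    rng = np.random.default_rng(seed)
    names = [f"g{i}" for i in range(n)]
    rules = {}
    for i, target in enumerate(names):
        n_in = int(rng.integers(1, min(k, n) + 1))
        inputs = rng.choice(names, size=n_in, replace=False)
        ast = None
        for node in inputs:
            lit = ("var", str(node))
            if rng.random() < 0.5:
                lit = ("not", lit)
            ast = lit if ast is None else (
                ("and", ast, lit) if rng.random() < 0.5 else ("or", ast, lit))
        rules[target] = ast
    text = "targets, factors\n" + "\n".join(
        f"{t}, {rule_to_str(a)}" for t, a in rules.items())
    return parse_rules(text, name=name, phenotype_nodes=[names[-1]])


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

def make_synthetic_cohort(n_samples: int, theta_true: dict[str, float],
                          out_dir, noise_level: float = 0.05, seed=None,
                          theta_spread: float = 0.1,
                          space: ParameterSpace | None = None,
                          M: int = 6, T: int = 80, K: int = 40,
                          model: TMEModel | None = None):
    """Write a synthetic cohort (fractions/mutations/expression CSVs + truth).

    Per sample: cell fractions from a Dirichlet draw, mutation bits from the
    cohort Bernoulli prevalences (KRAS 0.93, TP53 0.73, CDKN2A 0.30, SMAD4
    0.32), and target expression equal to the demo model's simulated cancer
    expression profile at a per-sample theta jittered around ``theta_true``
    (relative spread ``theta_spread`` of each parameter's range), plus
    additive uniform noise of amplitude ``noise_level`` — small enough to
    preserve the rank structure the calibration cost sees.

    Returns (records as DataFrames, truth dict); files are written to
    ``out_dir`` (fractions.csv, mutations.csv, expression.csv, truth.json).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = model if model is not None else demo_model()
    space = space or demo_parameter_space()

    barcodes = [f"SYN-{i:04d}" for i in range(n_samples)]
    fractions = pd.DataFrame({
        "barcode": barcodes,
        **dict(zip(["PCC", "PSC"],
                   (rng.dirichlet([6.0, 4.0], size=n_samples) * 1.0).T)),
    })
    mutations = pd.DataFrame(
        {"barcode": barcodes,
         **{g: (rng.random(n_samples) < p).astype(int)
            for g, p in MUTATION_PREVALENCE.items()}})

    expr_cols = {}
    truth: dict[str, dict] = {}
    sim_seeds = np.random.SeedSequence(
        rng.integers(0, 2 ** 31)).generate_state(n_samples)
    for i, bc in enumerate(barcodes):
        theta = dict(theta_true)
        for p in space.sampled:
            if p.name in theta:
                jitter = rng.normal(0.0, theta_spread * (p.high - p.low))
                theta[p.name] = float(min(max(theta[p.name] + jitter, p.low), p.high))
        # sample-level mutation alphas: 0 when the bit is absent
        for gene in MUTATION_PREVALENCE:
            key = f"alpha:{gene}"
            if key in theta and not mutations.loc[i, gene]:
                theta[key] = 0.0
        row = fractions.iloc[i]
        theta["r_PSC"] = float(row["PSC"] / (row["PCC"] + row["PSC"]))
        res = base.simulate(theta, M=M, T=T, K=K, seed=int(sim_seeds[i]))
        profile = res.expression_profile()
        noisy = profile + rng.uniform(-noise_level, noise_level, size=len(profile))
        expr_cols[bc] = noisy.clip(0.0, 1.0)
        truth[bc] = {"theta": theta}

    expression = pd.DataFrame(expr_cols)
    expression.insert(0, "gene", profile.index)

    fractions.to_csv(out_dir / "fractions.csv", index=False)
    mutations.to_csv(out_dir / "mutations.csv", index=False)
    expression.to_csv(out_dir / "expression.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({"theta_true": theta_true, "samples": truth}, fh, indent=1)
    return {"fractions": fractions, "mutations": mutations,
            "expression": expression}, truth
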