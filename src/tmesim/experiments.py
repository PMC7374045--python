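"""Canned study protocols on the built-in demo model.

These functions bundle the package's headline experiments at desk scale:
steady-state onset of the phenotype trajectories, the secretion-rate
freezing PRCC protocols probing the cancer/stellate interplay, the
calibration-beats-random benchmark on a synthetic cohort, and the
stellate-node perturbation screens.  They are plain library code — the
test suite and the reproduction script both call them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import SAConfig, spearman_cost
from .cohort import instantiate_sample, read_cohort
from .demo import (demo_model, demo_parameter_space, make_synthetic_cohort,
                   table_protocol_space, TABLE_PROTOCOLS)
from .model import plateau_onset
from .perturb import PerturbationSpec, response_stats, sweep
from .sensitivity import run_sensitivity

__all__ = ["run_plateau_experiment", "run_interplay_prcc",
           "run_calibration_benchmark", "run_perturbation_screen",
           "CalibrationBenchmark"]


def run_plateau_experiment(seed=0, runs: int = 10, steps: int = 100):
    """Run the demo model and locate the steady-state onset of the cancer
    proliferation trajectory (run-averaged, 10-step blocks, 2-SD plateau
    criterion).  Returns (onset step, SimulationResult)."""
    model = demo_model()
    res = model.simulate(M=runs, T=steps, K=steps // 2, seed=seed)
    onset = plateau_onset(res.phenotype_trajectory("Proliferation"))
    return onset, res


def run_interplay_prcc(protocols=TABLE_PROTOCOLS, n_sets: int = 200,
                       runs_per_set: int = 5, T: int = 100, seed=0) -> pd.DataFrame:
    """PRCC(r_PSC, cancer phenotype) for each secretion-rate freezing
    protocol; returns a protocol x phenotype table."""
    model = demo_model()
    ss = np.random.SeedSequence(seed).generate_state(len(TABLE_PROTOCOLS))
    seeds = dict(zip(TABLE_PROTOCOLS, ss))
    rows = {}
    for proto in protocols:
        res = run_sensitivity(model, table_protocol_space(proto),
                              n_sets=n_sets, runs_per_set=runs_per_set,
                              T=T, K=T // 2, window=50, seed=int(seeds[proto]))
        rows[proto] = res.prcc.loc["r_PSC"]
    return pd.DataFrame(rows).T


@dataclass
class CalibrationBenchmark:
    per_sample: pd.DataFrame      # barcode, sa_spearman, random_best_spearman, win
    mean_spearman: float
    mean_random_best: float
    wins: int
    n_samples: int


def run_calibration_benchmark(n_samples: int = 10, seed=0, tmp_dir=None,
                              n_random: int = 20, t_min: float = 0.01,
                              m_cal: int = 3, t_cal: int = 50,
                              noise_level: float = 0.03,
                              theta_spread: float = 0.6) -> CalibrationBenchmark:
    """Simulated-annealing calibration versus a random-parameter baseline.

    A synthetic cohort is generated from the demo model at per-sample true
    parameters jittered around a central theta; each sample is then
    calibrated by SA (T0=0.5, cooling 0.8, W=60, reduced M_cal ensemble per
    cost evaluation) and compared against the best of ``n_random`` uniform
    random parameter draws.  Both champions are re-evaluated with the same
    larger ensemble, so the comparison is not biased by which side saw more
    evaluation noise.
    """
    import tempfile
    rng = np.random.default_rng(seed)
    base = demo_model()
    space_full = demo_parameter_space(include_mutations=True).drop("r_PSC")
    theta_true = space_full.random(rng)
    if tmp_dir is None:
        tmp_dir = tempfile.mkdtemp(prefix="tmesim_cohort_")
    make_synthetic_cohort(n_samples, theta_true, tmp_dir,
                          noise_level=noise_level, theta_spread=theta_spread,
                          space=space_full,
                          seed=int(rng.integers(0, 2 ** 31)))
    records = read_cohort(f"{tmp_dir}/fractions.csv", f"{tmp_dir}/mutations.csv",
                          f"{tmp_dir}/expression.csv")

    rows = []
    sample_seeds = np.random.SeedSequence(
        int(rng.integers(0, 2 ** 31))).generate_state(2 * len(records))
    for i, rec in enumerate(sorted(records, key=lambda r: r.barcode)):
        model, space = instantiate_sample(rec, base, space_full)
        fit = model.fit(rec.expression, space,
                        sa_config=SAConfig(T_min=t_min),
                        seed=int(sample_seeds[2 * i]), M_cal=m_cal,
                        T_cal=t_cal, K_cal=t_cal // 2, M_final=8 * m_cal)
        # random baseline: best of n_random draws scored with the same
        # reduced ensemble as the SA cost evaluations, then re-evaluated
        rrng = np.random.default_rng(int(sample_seeds[2 * i + 1]))
        best_theta, best_cost = None, np.inf
        for j in range(n_random):
            theta = space.random(rrng)
            res = model.simulate(theta, M=m_cal, T=t_cal, K=t_cal // 2,
                                 seed=int(rrng.integers(0, 2 ** 31)))
            cost = spearman_cost(res.expression_profile(), rec.expression)
            if cost < best_cost:
                best_cost, best_theta = cost, theta
        res = model.simulate(best_theta, M=8 * m_cal, T=2 * t_cal, K=t_cal,
                             seed=int(rrng.integers(0, 2 ** 31)))
        random_final = 1.0 - spearman_cost(res.expression_profile(),
                                           rec.expression)
        rows.append({"barcode": rec.barcode,
                     "sa_spearman": fit.final_spearman,
                     "random_best_spearman": random_final,
                     "win": fit.final_spearman > random_final})
    table = pd.DataFrame(rows)
    return CalibrationBenchmark(
        per_sample=table,
        mean_spearman=float(table["sa_spearman"].mean()),
        mean_random_best=float(table["random_best_spearman"].mean()),
        wins=int(table["win"].sum()),
        n_samples=len(table),
    )


def run_perturbation_screen(node: str = "bFGF", value: int = 0,
                            alphas=(0.0, 0.25, 0.5, 0.75, 1.0),
                            replicates: int = 15, seed=0,
                            theta=None) -> dict[str, float]:
    """Clamp a stellate node in a swept fraction of stellate cells and
    summarize the cancer-apoptosis response (Spearman correlation, OLS
    slope, p-value)."""
    model = demo_model()
    spec = PerturbationSpec(cell_type="PSC", node=node, value=value,
                            alphas=list(alphas), replicates=replicates,
                            readout_node="Apoptosis")
    table = sweep(model, spec, theta=theta, seed=seed, M=1, T=100, K=50)
    stats_ = response_stats(table)
    stats_["table"] = table
    return stats_
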