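"""Parameter calibration by simulated annealing.

The per-sample cost is the rank dissimilarity between the simulated cancer
expression profile and the sample's target expression,

    C_p(theta) = 1 - Spearman(G_model(theta), G_target(p)),

minimized over the bounded parameter space by simulated annealing: W
Metropolis steps per temperature with Gaussian proposals of scale
sigma(T) = sigma_0 * T (per-dimension, scaled by the parameter's range,
reflected into bounds), geometric cooling T_{k+1} = 0.8 T_k from T_0 = 0.5
down to T_min.  Downhill moves are always accepted; uphill moves with
probability exp(-dC / T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import ParameterSpace

__all__ = ["SAConfig", "spearman_cost", "metropolis_step", "propose",
           "simulated_annealing", "CalibrationResult", "fit_model"]

#: cost assigned when the correlation is undefined (a constant vector);
#: equals the worst possible 1 - rho.
WORST_COST = 2.0


@dataclass
class SAConfig:
    T0: float = 0.5
    cooling: float = 0.8
    sigma0: float = 1.0
    W: int = 60
    T_min: float = 0.01
    reevaluate_incumbent: bool = False
    #: with a stochastic cost, refresh the cached incumbent cost at every
    #: temperature change so a single lucky evaluation cannot stall the chain
    refresh_each_stage: bool = True

    def __post_init__(self):
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.W < 1:
            raise ValueError("W must be >= 1")
        if not self.T_min < self.T0:
            raise ValueError("T_min must be below T0")

    @property
    def n_temperatures(self) -> int:
        k = int(np.ceil(np.log(self.T_min / self.T0) / np.log(self.cooling)))
        return max(k, 1)


def spearman_cost(model_expr: pd.Series, target_expr: pd.Series,
                  gene_map: dict[str, str] | None = None) -> float:
    """1 - Spearman rank correlation over mapped genes (ties -> average ranks).

    ``gene_map`` maps model node names to target gene names; by default
    genes are matched by identical names.  A constant vector makes the
    correlation undefined; the cost is then the worst value 2.
    """
    model_expr = pd.Series(model_expr)
    target_expr = pd.Series(target_expr)
    if gene_map:
        model_expr = model_expr.rename(index=gene_map)
    common = model_expr.index.intersection(target_expr.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} genes shared between model and target; "
                         "need at least 3")
    x = model_expr.loc[common].to_numpy(float)
    y = target_expr.loc[common].to_numpy(float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return WORST_COST
    rho = stats.spearmanr(x, y).statistic
    return float(1.0 - rho)


def propose(theta: dict[str, float], T: float, space: ParameterSpace,
            sigma0: float, rng: np.random.Generator) -> dict[str, float]:
    """Gaussian proposal centered on theta with per-dimension scale
    sigma0 * T * (high - low), reflected into the bounds."""
    out = dict(theta)
    for p in space.sampled:
        width = p.high - p.low
        x = theta[p.name] + rng.normal(0.0, sigma0 * T * width)
        # reflect into [low, high]
        span = 2.0 * width
        x = (x - p.low) % span
        if x > width:
            x = span - x
        out[p.name] = float(p.low + x)
    out.update(space.frozen)
    return out


def metropolis_step(theta, cost, T, cost_fn, space, config: SAConfig,
                    rng: np.random.Generator):
    """One Metropolis move; returns (theta, cost, accepted)."""
    theta_new = propose(theta, T, space, config.sigma0, rng)
    try:
        cost_new = cost_fn(theta_new)
    except Exception as exc:  # cost evaluation failed -> reject the proposal
        warnings.warn(f"cost evaluation failed ({exc}); proposal rejected",
                      stacklevel=2)
        return theta, cost, False
    if config.reevaluate_incumbent:
        cost = cost_fn(theta)
    dC = cost_new - cost
    if dC <= 0.0 or rng.random() < np.exp(-dC / T):
        return theta_new, cost_new, True
    return theta, cost, False


def simulated_annealing(cost_fn, space: ParameterSpace,
                        config: SAConfig | None = None, seed=None,
                        theta0: dict[str, float] | None = None,
                        keep_top: int = 5):
    """Minimize ``cost_fn(theta)`` over ``space``.

    Returns (best theta, best cost, trace DataFrame, top candidates).  theta
    is initialized uniformly at random in the space unless ``theta0`` is
    given.  The trace records every evaluation (stage, step, temperature,
    cost, accepted, best-so-far); ``top`` holds the ``keep_top``
    lowest-cost (cost, theta) pairs seen, useful for re-screening when the
    cost is stochastic.
    """
    config = config or SAConfig()
    rng = np.random.default_rng(seed)
    theta = space.clip(theta0) if theta0 is not None else space.random(rng)
    cost = cost_fn(theta)
    best_theta, best_cost = dict(theta), cost
    top: list[tuple[float, dict]] = [(cost, dict(theta))]

    rows = []
    T = config.T0
    stage = 0
    while T >= config.T_min:
        if stage > 0 and config.refresh_each_stage:
            cost = cost_fn(theta)
        for w in range(config.W):
            theta, cost, accepted = metropolis_step(
                theta, cost, T, cost_fn, space, config, rng)
            if accepted and (len(top) < keep_top or cost < top[-1][0]):
                top.append((cost, dict(theta)))
                top.sort(key=lambda t: t[0])
                del top[keep_top:]
            if cost < best_cost:
                best_theta, best_cost = dict(theta), cost
            rows.append((stage, w, T, cost, accepted, best_cost))
        T *= config.cooling
        stage += 1
    trace = pd.DataFrame(rows, columns=["stage", "step", "temperature", "cost",
                                        "accepted", "best_cost"])
    return best_theta, best_cost, trace, top


class CalibrationResult:
    """Result of fitting a TMEModel to a target expression vector."""

    def __init__(self, model, params, cost, trace, target, space, sa_config,
                 final_cost=None, final_spearman=None, seed=None):
        self.model = model
        self.params = dict(params)
        self.cost = float(cost)
        self.trace = trace
        self.target = target
        self.space = space
        self.sa_config = sa_config
        self.final_cost = final_cost
        self.final_spearman = final_spearman
        self.seed = seed

    @property
    def spearman(self) -> float:
        """Rank correlation achieved during the search (1 - cost)."""
        return 1.0 - self.cost

    def summary(self) -> str:
        lines = [f"CalibrationResult ({len(self.space.sampled)} free parameters, "
                 f"{len(self.trace)} cost evaluations)"]
        lines.append(f"  search-best cost {self.cost:.4f} "
                     f"(Spearman {self.spearman:.4f})")
        if self.final_cost is not None:
            lines.append(f"  full-ensemble cost {self.final_cost:.4f} "
                         f"(Spearman {self.final_spearman:.4f})")
        for p in self.space.sampled:
            lines.append(f"  {p.name:>24s} = {self.params[p.name]:.4f} "
                         f"in [{p.low}, {p.high}]")
        for name, val in self.space.frozen.items():
            lines.append(f"  {name:>24s} = {val} (frozen)")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["cost"].to_numpy(), alpha=0.5, label="cost")
        ax.plot(self.trace["best_cost"].to_numpy(), label="best so far")
        ax.set_xlabel("Metropolis step")
        ax.set_ylabel("1 - Spearman")
        ax.legend()
        return ax


def fit_model(model, target, space: ParameterSpace, sa_config=None, seed=None,
              gene_map=None, M_cal: int = 3, T_cal: int = 60, K_cal: int = 30,
              M_final: int | None = None) -> CalibrationResult:
    """Simulated-annealing calibration of a TMEModel (see TMEModel.fit).

    Cost evaluations use a reduced ensemble (M_cal runs of T_cal steps) to
    keep the ~1000-evaluation search tractable; the returned result also
    reports the cost re-evaluated at M_final runs (default 4x M_cal).
    """
    sa_config = sa_config or SAConfig()
    target = pd.Series(target, dtype=float)
    ss = np.random.SeedSequence(seed)
    sa_seed, eval_ss, final_seed = ss.spawn(3)
    eval_seeds = iter(eval_ss.generate_state(10 ** 6))

    def cost_fn(theta):
        res = model.simulate(theta, M=M_cal, T=T_cal, K=K_cal,
                             seed=int(next(eval_seeds)))
        return spearman_cost(res.expression_profile(), target, gene_map)

    best_theta, best_cost, trace, top = simulated_annealing(
        cost_fn, space, sa_config, seed=sa_seed)

    # the search cost is stochastic, so the lowest *recorded* cost may be a
    # lucky evaluation: re-screen the top candidates with a larger ensemble
    final_seeds = iter(final_seed.generate_state(2 * len(top) + 2))
    M_final = M_final or 4 * M_cal
    if len(top) > 1:
        rescored = []
        for cand_cost, cand_theta in top:
            res = model.simulate(cand_theta, M=2 * M_cal, T=2 * T_cal, K=T_cal,
                                 seed=int(next(final_seeds)))
            rescored.append((spearman_cost(res.expression_profile(), target,
                                           gene_map), cand_theta))
        best_cost, best_theta = min(rescored, key=lambda t: t[0])

    res = model.simulate(best_theta, M=M_final, T=2 * T_cal, K=T_cal,
                         seed=int(next(final_seeds)))
    final_cost = spearman_cost(res.expression_profile(), target, gene_map)
    return CalibrationResult(model, best_theta, best_cost, trace, target, space,
                             sa_config, final_cost=final_cost,
                             final_spearman=1.0 - final_cost, seed=seed)
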