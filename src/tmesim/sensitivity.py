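"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

Parameter sets are drawn by Latin hypercube sampling (one jittered point per
equal-probability stratum per dimension); each set is simulated with a small
ensemble and the outputs (phenotype scores, gene ON fractions) averaged.
The partial rank correlation coefficient (PRCC) between a parameter and an
output is the Pearson correlation of the residuals left after rank-
transforming every column and regressing both the target parameter's ranks
and the output's ranks on the ranks of all other sampled parameters;
significance comes from the usual t transform with n - 2 - (d - 1) degrees
of freedom, d being the number of sampled dimensions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .params import ParameterSpace

__all__ = ["lhs_sample", "prcc", "prcc_matrix", "run_sensitivity",
           "SensitivityResult"]


def lhs_sample(space: ParameterSpace, n: int, seed=None) -> pd.DataFrame:
    """Draw n Latin-hypercube parameter sets over the sampled dimensions.

    Each dimension's n values occupy distinct equal-probability strata with
    uniform jitter inside each stratum; log-scaled parameters are stratified
    in log10 space.  Frozen parameters appear as constant columns.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    sampled = space.sampled
    if sampled:
        unit = qmc.LatinHypercube(d=len(sampled), seed=seed).random(n)
    else:
        unit = np.empty((n, 0))
    data = {}
    for j, p in enumerate(sampled):
        if p.scale == "log":
            lo, hi = np.log10(p.low), np.log10(p.high)
            data[p.name] = 10 ** (lo + unit[:, j] * (hi - lo))
        else:
            data[p.name] = p.low + unit[:, j] * (p.high - p.low)
    for name, value in space.frozen.items():
        data[name] = np.full(n, value)
    return pd.DataFrame(data, columns=space.names)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average", axis=0)


def _residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y after least-squares projection on [1, Z]."""
    X = np.column_stack([np.ones(len(y)), Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def prcc(samples: pd.DataFrame, output: np.ndarray, target: str):
    """PRCC between one parameter column and an output vector.

    Returns (coefficient, p-value).  Constant outputs make the PRCC
    undefined: (nan, nan) is returned with a warning.
    """
    if target not in samples.columns:
        raise KeyError(f"unknown parameter {target!r}")
    y = np.asarray(output, dtype=float)
    n = len(y)
    if len(samples) != n:
        raise ValueError("samples and output lengths differ")
    others = [c for c in samples.columns if c != target
              and np.ptp(samples[c].to_numpy(float)) > 0]
    d = len(others) + 1
    if n <= d + 2:
        raise ValueError(f"need n > dims + 2 (n={n}, dims={d})")
    x = samples[target].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"parameter {target!r} is constant; PRCC undefined")
    if np.ptp(y) == 0:
        warnings.warn(f"constant output; PRCC vs {target!r} undefined", stacklevel=2)
        return float("nan"), float("nan")

    rx = _rank(x)
    ry = _rank(y)
    Z = _rank(samples[others].to_numpy(float)) if others else np.empty((n, 0))
    ex = _residuals(rx, Z)
    ey = _residuals(ry, Z)
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float((ex * ey).sum() / denom)
    r = min(max(r, -1.0), 1.0)
    dof = n - 2 - (d - 1)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def prcc_matrix(samples: pd.DataFrame, outputs: pd.DataFrame):
    """PRCC and p-values for every (sampled parameter, output) pair."""
    varying = [c for c in samples.columns if np.ptp(samples[c].to_numpy(float)) > 0]
    coef = pd.DataFrame(index=varying, columns=outputs.columns, dtype=float)
    pval = pd.DataFrame(index=varying, columns=outputs.columns, dtype=float)
    for out_name in outputs.columns:
        y = outputs[out_name].to_numpy(float)
        for param in varying:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coef.loc[param, out_name], pval.loc[param, out_name] = \
                    prcc(samples[varying], y, param)
    return coef, pval


class SensitivityResult:
    """LHS samples, per-set ensemble outputs, and the PRCC/p-value matrices."""

    def __init__(self, samples: pd.DataFrame, outputs: pd.DataFrame,
                 prcc_: pd.DataFrame, pvalues: pd.DataFrame, failed=None):
        self.samples = samples
        self.outputs = outputs
        self.prcc = prcc_
        self.pvalues = pvalues
        self.failed = failed or []

    def summary(self) -> str:
        lines = [f"SensitivityResult: {len(self.samples)} parameter sets, "
                 f"{self.prcc.shape[0]} parameters x {self.prcc.shape[1]} outputs"]
        if self.failed:
            lines.append(f"  {len(self.failed)} parameter sets failed and were excluded")
        with pd.option_context("display.width", 120, "display.precision", 3):
            lines.append(str(self.prcc))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.prcc.to_csv(path)

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.prcc.to_numpy(float), cmap="RdYlGn_r", vmin=-1, vmax=1)
        ax.set_xticks(range(self.prcc.shape[1]), self.prcc.columns, rotation=90)
        ax.set_yticks(range(self.prcc.shape[0]), self.prcc.index)
        ax.figure.colorbar(im, ax=ax, label="PRCC")
        return ax


def run_sensitivity(model, space: ParameterSpace, n_sets: int,
                    runs_per_set: int = 100, outputs=None, T: int = 400,
                    K: int = 200, window: int = 50, seed=None,
                    progress: bool = False) -> SensitivityResult:
    """LHS-sample the space, simulate each parameter set, compute PRCCs.

    ``outputs`` is a list of (cell_type, phenotype node) pairs; default is
    every phenotype node of the cancer network.  Each output is the ensemble
    phenotype score (trailing-window mean over runs_per_set simulations).
    Parameter sets whose simulation fails are excluded with a warning.
    """
    ss = np.random.SeedSequence(seed)
    lhs_seed, sim_ss = ss.spawn(2)
    samples = lhs_sample(space, n_sets, seed=np.random.default_rng(lhs_seed))
    if outputs is None:
        ct = model.cancer_type
        outputs = [(ct, node) for node in model.networks[ct].phenotype_nodes]

    rows, failed = [], []
    child_seeds = sim_ss.generate_state(n_sets)
    iterator = range(n_sets)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="sensitivity")
        except ImportError:
            pass
    for i in iterator:
        theta = samples.iloc[i].to_dict()
        try:
            res = model.simulate(theta, M=runs_per_set, T=T, K=K,
                                 seed=int(child_seeds[i]))
            rows.append({f"{ct}.{node}": res.phenotype_score(node, window=window,
                                                             cell_type=ct)
                         for ct, node in outputs})
        except Exception as exc:
            warnings.warn(f"parameter set {i} failed ({exc}); excluded", stacklevel=2)
            failed.append(i)
            rows.append(None)

    keep = [i for i, r in enumerate(rows) if r is not None]
    out_df = pd.DataFrame([rows[i] for i in keep], index=keep)
    kept_samples = samples.iloc[keep].reset_index(drop=True)
    out_df = out_df.reset_index(drop=True)
    coef, pval = prcc_matrix(kept_samples, out_df)
    return SensitivityResult(kept_samples, out_df, coef, pval, failed=failed)
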