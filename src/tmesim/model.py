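"""The coupled multicellular model and its simulation results.

``TMEModel`` couples one Boolean network per cell type with steady-state
cytokine fields on a periodic grid.  Each simulation step (1) assembles the
per-voxel secretion sources from the current secretion-node states,
(2) solves the steady diffusion-degradation equation per cytokine,
(3) writes receptor bits from local concentrations versus thresholds, and
(4) updates every cell's Boolean state synchronously with random
perturbation and permanent clamps (mutations, in silico interventions).

Ensemble readouts follow the ergodic-averaging scheme: the per-gene ON
fraction of cancer cells, averaged over the last K steps of M independent
runs (fresh random initial states and fresh tissue draw per run), estimates
the stationary expression profile G(theta) used for calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boolnet import BooleanNetwork, update_states
from .diffusion import (CytokineGrid, CytokineParams, assemble_source,
                        solve_steady_state_batch)
from .params import ParameterSpace
from .tissue import CellPopulation, TissueConfig, generate_tissue

__all__ = ["SecretionRule", "ReceptorRule", "MutationRule", "CellClamp",
           "TMEModel", "SimulationResult", "plateau_onset"]


@dataclass(frozen=True)
class SecretionRule:
    """A cell type secretes a cytokine at basal rate 1 (node OFF) or active
    rate R > 1 (node ON); ``node`` defaults to the network's annotated
    secretion node for that cytokine."""
    cell_type: str
    cytokine: str
    rate: float = 5.0
    node: str | None = None


@dataclass(frozen=True)
class ReceptorRule:
    """A cell type's receptor node reads 1 iff the local concentration of the
    cytokine strictly exceeds the threshold K (shared by all cells of the
    type)."""
    cell_type: str
    cytokine: str
    node: str
    threshold: float = 0.5


@dataclass(frozen=True)
class MutationRule:
    """A somatic mutation: clamp ``gene`` to ``value`` (1 activating, e.g.
    KRAS; 0 inactivating, e.g. TP53/CDKN2A/SMAD4) in a random fraction alpha
    of cancer cells."""
    gene: str
    value: int
    alpha: float = 0.0
    cell_type: str = "PCC"


@dataclass(frozen=True)
class CellClamp:
    """An in silico perturbation: force ``node`` to ``value`` in a Bernoulli
    (fraction)-selected subset of cells of one type.  Applied after mutation
    clamps, so on overlap the perturbation wins within its selected cells."""
    cell_type: str
    node: str
    value: int
    fraction: float = 1.0


def _bernoulli_mask(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    if fraction >= 1.0:
        return np.ones(n, dtype=bool)
    if fraction <= 0.0:
        return np.zeros(n, dtype=bool)
    return rng.random(n) < fraction


class TMEModel:
    """Multiscale tumor-microenvironment model.

    Parameters
    ----------
    networks : dict
        cell-type label -> BooleanNetwork.
    cytokines : list of CytokineParams
        Transport parameters per signaling molecule.
    secretion, receptors : lists of rules
        Wiring between secretion nodes, cytokine fields and receptor nodes.
    tissue : TissueConfig
        Spatial point-process configuration.
    mutations : list of MutationRule, optional
    q : float
        Per-node per-step flip probability (same for all genes and types).
    h : float
        Grid spacing; default one cell diameter (contact-like limit when
        lambda <~ h).
    """

    def __init__(self, networks: dict[str, BooleanNetwork],
                 cytokines: list[CytokineParams],
                 secretion: list[SecretionRule],
                 receptors: list[ReceptorRule],
                 tissue: TissueConfig,
                 mutations: list[MutationRule] | None = None,
                 q: float = 0.01, h: float = 1.0,
                 cancer_type: str | None = None,
                 name: str = "tme"):
        self.networks = dict(networks)
        self.cytokines = {c.name: c for c in cytokines}
        self.tissue = tissue
        self.mutations = list(mutations or [])
        self.q = float(q)
        self.h = float(h)
        self.name = name
        self.cancer_type = cancer_type or tissue.cancer_type

        if self.cancer_type not in self.networks:
            raise ValueError(f"cancer type {self.cancer_type!r} has no network")

        self.secretion: list[SecretionRule] = []
        for r in secretion:
            net = self._net(r.cell_type)
            node = r.node or net.secretion_nodes.get(r.cytokine)
            if node is None:
                raise ValueError(
                    f"{r.cell_type}: no secretion node annotated for {r.cytokine!r}")
            if node not in net.rules:
                raise ValueError(f"{r.cell_type}: secretion node {node!r} is not a "
                                 "regulatory node")
            if r.cytokine not in self.cytokines:
                raise ValueError(f"unknown cytokine {r.cytokine!r} in secretion rule")
            self.secretion.append(replace(r, node=node))

        self.receptors: list[ReceptorRule] = []
        for r in receptors:
            net = self._net(r.cell_type)
            if r.node not in net.receptors:
                raise ValueError(f"{r.cell_type}: {r.node!r} is not a receptor node")
            if r.cytokine not in self.cytokines:
                raise ValueError(f"unknown cytokine {r.cytokine!r} in receptor rule")
            if any(o.cell_type == r.cell_type and o.cytokine == r.cytokine
                   for o in self.receptors):
                raise ValueError(f"duplicate receptor rule ({r.cell_type}, {r.cytokine})")
            self.receptors.append(r)

        wired_receiving = {r.cytokine for r in self.receptors}
        wired_secreting = {r.cytokine for r in self.secretion}
        #: cytokines that are secreted but never sensed (no field is solved)
        self.inert_cytokines = set(self.cytokines) - wired_receiving
        self.active_cytokines = sorted(wired_receiving & wired_secreting)
        for m in wired_receiving - wired_secreting:
            warnings.warn(f"cytokine {m!r} has receptors but no secretor; its field "
                          "is identically zero", stacklevel=2)

        for mut in self.mutations:
            net = self._net(mut.cell_type)
            if mut.gene not in net.rules:
                raise ValueError(f"mutation gene {mut.gene!r} is not a regulatory node "
                                 f"of {mut.cell_type!r}")

    def _net(self, cell_type: str) -> BooleanNetwork:
        try:
            return self.networks[cell_type]
        except KeyError:
            raise ValueError(f"unknown cell type {cell_type!r}; have "
                             f"{sorted(self.networks)}") from None

    # ------------------------------------------------------------------
    # theta -> concrete per-run settings
    # ------------------------------------------------------------------

    def resolve(self, theta: dict[str, float] | None):
        """Apply a flat parameter dict (see :mod:`tmesim.params`) on top of
        the model's defaults; returns (secretion rules, receptor rules,
        alpha-by-mutation, tissue config). The model itself is not mutated."""
        theta = dict(theta or {})
        secretion = {(r.cell_type, r.cytokine): r for r in self.secretion}
        receptors = {(r.cell_type, r.cytokine): r for r in self.receptors}
        alphas = {m.gene: m.alpha for m in self.mutations}
        tissue = self.tissue

        for key, value in theta.items():
            if key.startswith("R:") or key.startswith("K:"):
                kind, cell_type, cytokine = key.split(":")
                table = secretion if kind == "R" else receptors
                rule = table.get((cell_type, cytokine))
                if rule is None:
                    raise KeyError(f"no {'secretion' if kind == 'R' else 'receptor'} "
                                   f"rule for ({cell_type}, {cytokine})")
                table[(cell_type, cytokine)] = replace(
                    rule, **({"rate": float(value)} if kind == "R"
                             else {"threshold": float(value)}))
            elif key.startswith("alpha:"):
                gene = key.split(":", 1)[1]
                if gene not in alphas:
                    raise KeyError(f"no mutation rule declared for gene {gene!r}")
                alphas[gene] = float(value)
            elif key == "s":
                tissue = tissue.replace(s=float(value))
            elif key == "r_C":
                tissue = tissue.replace(r_C=float(value))
            elif key == "r_PSC":
                tissue = tissue.replace(r_C=1.0 - float(value))
            else:
                raise KeyError(f"unrecognized parameter {key!r}")
        mutations = [replace(m, alpha=alphas[m.gene]) for m in self.mutations]
        return list(secretion.values()), list(receptors.values()), mutations, tissue

    # ------------------------------------------------------------------
    # Simulation
    # ------------------------------------------------------------------

    def simulate(self, theta: dict[str, float] | None = None, M: int = 20,
                 T: int = 400, K: int = 200, seed=None,
                 population: CellPopulation | None = None,
                 clamps: list[CellClamp] | None = None) -> "SimulationResult":
        """Run an ensemble of M independent simulations of T steps.

        Each run draws fresh random initial Boolean states and (unless a
        fixed ``population`` is supplied) a fresh tissue realization.  The
        expression profile averages the last K steps of every run.
        """
        if K > T:
            raise ValueError(f"K={K} tail steps exceed T={T} total steps")
        secretion, receptors, mutations, tissue = self.resolve(theta)
        ss = np.random.SeedSequence(seed)
        runs = [self._run_once(np.random.default_rng(child), secretion, receptors,
                               mutations, tissue, T, population, clamps or [])
                for child in ss.spawn(M)]
        return SimulationResult._from_runs(self, runs, M=M, T=T, K=K, theta=theta,
                                           seed=seed)

    def _run_once(self, rng, secretion, receptors, mutations, tissue, T,
                  population, clamps):
        pop = population if population is not None else generate_tissue(tissue, rng=rng)
        grid = CytokineGrid(tissue.L, self.h)

        cells: dict[str, dict] = {}
        for cell_type, net in self.networks.items():
            idx = pop.indices_of(cell_type)
            if idx.size == 0:
                continue
            X = rng.random((idx.size, net.n)) < 0.5
            if net.receptor_idx.size:
                X[:, net.receptor_idx] = False
            cells[cell_type] = {
                "net": net,
                "X": X,
                "voxel": grid.voxel_index(pop.positions[idx]),
                "clamps": [],
            }

        # permanent clamps: mutations first, explicit perturbations last (they win)
        for mut in mutations:
            entry = cells.get(mut.cell_type)
            if entry is None or mut.alpha <= 0.0:
                continue
            mask = _bernoulli_mask(rng, len(entry["X"]), mut.alpha)
            entry["clamps"].append((mut.gene, bool(mut.value), mask))
        for cl in clamps:
            entry = cells.get(cl.cell_type)
            if entry is None:
                continue
            if cl.node not in entry["net"].index:
                raise ValueError(f"{cl.cell_type}: unknown node {cl.node!r}")
            mask = _bernoulli_mask(rng, len(entry["X"]), cl.fraction)
            entry["clamps"].append((cl.node, bool(cl.value), mask))
        # clamps hold from the initial state on
        for entry in cells.values():
            for node, val, mask in entry["clamps"]:
                entry["X"][mask, entry["net"].index[node]] = val

        by_cytokine: dict[str, list] = {m: [] for m in self.active_cytokines}
        for r in secretion:
            if r.cytokine in by_cytokine and r.cell_type in cells:
                by_cytokine[r.cytokine].append(r)
        receptor_rules = [r for r in receptors if r.cell_type in cells]

        pheno = {(ct, node): np.empty(T + 1)
                 for ct, e in cells.items() for node in e["net"].phenotype_nodes}
        cancer = cells.get(self.cancer_type)
        genes = np.empty((T + 1, cancer["net"].n)) if cancer is not None else None

        def record(t):
            for (ct, node), arr in pheno.items():
                e = cells[ct]
                arr[t] = e["X"][:, e["net"].index[node]].mean()
            if genes is not None:
                genes[t] = cancer["X"].mean(axis=0)

        solved = [m for m in self.active_cytokines if by_cytokine[m]]
        solved_params = [self.cytokines[m] for m in solved]
        h3 = grid.h ** 3

        record(0)
        for t in range(1, T + 1):
            fields = {}
            if solved:
                sources = np.zeros((len(solved), grid.n_voxels))
                for k, m in enumerate(solved):
                    for r in by_cytokine[m]:
                        e = cells[r.cell_type]
                        state = e["X"][:, e["net"].index[r.node]]
                        eta = 1.0 + (r.rate - 1.0) * state
                        sources[k] += np.bincount(e["voxel"], weights=eta,
                                                  minlength=grid.n_voxels)
                conc = solve_steady_state_batch(
                    sources.reshape(len(solved), *grid.shape) / h3,
                    solved_params, grid)
                fields = {m: conc[k].ravel() for k, m in enumerate(solved)}

            receptor_values: dict[str, dict] = {ct: {} for ct in cells}
            for r in receptor_rules:
                field_ = fields.get(r.cytokine)
                e = cells[r.cell_type]
                if field_ is None:
                    bits = np.zeros(len(e["X"]), dtype=bool)
                else:
                    bits = field_[e["voxel"]] > r.threshold
                receptor_values[r.cell_type][r.node] = bits

            for ct, e in cells.items():
                e["X"] = update_states(e["net"], e["X"],
                                       receptor_values=receptor_values[ct],
                                       q=self.q, rng=rng, clamps=e["clamps"])
            record(t)

        counts = {ct: len(e["X"]) for ct, e in cells.items()}
        clamp_audit = {ct: {node: int(mask.sum()) for node, _v, mask in e["clamps"]}
                       for ct, e in cells.items()}
        return {"pheno": pheno, "genes": genes, "counts": counts,
                "clamp_audit": clamp_audit}

    # ------------------------------------------------------------------
    # Calibration front-end (statsmodels-style fit)
    # ------------------------------------------------------------------

    def fit(self, target, space: ParameterSpace, sa_config=None, seed=None,
            gene_map=None, M_cal: int = 3, T_cal: int = 60, K_cal: int = 30,
            M_final: int | None = None):
        """Calibrate free parameters to a target expression vector by
        simulated annealing on the cost 1 - Spearman(G_model, target).

        Returns a :class:`tmesim.calibrate.CalibrationResult`.
        """
        from .calibrate import fit_model
        return fit_model(self, target, space, sa_config=sa_config, seed=seed,
                         gene_map=gene_map, M_cal=M_cal, T_cal=T_cal, K_cal=K_cal,
                         M_final=M_final)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class SimulationResult:
    """Ensemble simulation output.

    Attributes
    ----------
    pheno : dict
        (cell_type, phenotype node) -> (M, T+1) array of per-step ON
        fractions (step 0 is the initial state).
    genes : (M, T+1, n) array or None
        Per-step ON fraction of every cancer-network node.
    """

    def __init__(self, model, pheno, genes, counts, clamp_audit, M, T, K,
                 theta, seed):
        self.model = model
        self.pheno = pheno
        self.genes = genes
        self.cell_counts = counts
        self.clamp_audit = clamp_audit
        self.M, self.T, self.K = M, T, K
        self.theta = dict(theta or {})
        self.seed = seed

    @classmethod
    def _from_runs(cls, model, runs, M, T, K, theta, seed):
        keys = sorted({k for r in runs for k in r["pheno"]})
        pheno = {k: np.full((M, T + 1), np.nan) for k in keys}
        for i, r in enumerate(runs):
            for k, arr in r["pheno"].items():
                pheno[k][i] = arr
        genes = None
        if runs and runs[0]["genes"] is not None:
            genes = np.stack([r["genes"] for r in runs])
        counts = [r["counts"] for r in runs]
        audit = [r["clamp_audit"] for r in runs]
        return cls(model, pheno, genes, counts, audit, M, T, K, theta, seed)

    # -- readouts -------------------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return self.model.networks[self.model.cancer_type].nodes

    def expression_profile(self, K: int | None = None,
                           regulatory_only: bool = False) -> pd.Series:
        """G(theta): per-gene ON fraction of cancer cells averaged over the
        last K steps of all M runs (Monte-Carlo estimate of the stationary
        expectation)."""
        if self.genes is None:
            raise ValueError("no cancer cells were present in the simulation")
        K = self.K if K is None else K
        prof = self.genes[:, -K:, :].mean(axis=(0, 1))
        series = pd.Series(prof, index=self.gene_names, name="f_hat")
        if regulatory_only:
            net = self.model.networks[self.model.cancer_type]
            series = series[net.regulatory_nodes]
        return series

    def phenotype_trajectory(self, node: str, cell_type: str | None = None) -> np.ndarray:
        key = (cell_type or self.model.cancer_type, node)
        if key not in self.pheno:
            raise KeyError(f"no phenotype {key}; available: {sorted(self.pheno)}")
        return self.pheno[key]

    def phenotype_score(self, node: str, window: int = 50,
                        cell_type: str | None = None) -> float:
        """Mean ON fraction over the trailing ``window`` steps, averaged over
        runs — the tissue-level phenotype readout."""
        traj = self.phenotype_trajectory(node, cell_type)
        if window > traj.shape[1]:
            raise ValueError(f"window {window} exceeds recorded steps {traj.shape[1]}")
        return float(traj[:, -window:].mean())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: run, step, cell_type, node, fraction."""
        rows = []
        for (ct, node), arr in self.pheno.items():
            M, S = arr.shape
            rows.append(pd.DataFrame({
                "run": np.repeat(np.arange(M), S),
                "step": np.tile(np.arange(S), M),
                "cell_type": ct, "node": node,
                "fraction": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        lines = [f"SimulationResult: {self.M} runs x {self.T} steps "
                 f"(tail K={self.K}), q={self.model.q}"]
        mean_counts = {ct: float(np.mean([c.get(ct, 0) for c in self.cell_counts]))
                       for ct in self.model.networks}
        lines.append("mean cells per type: " +
                     ", ".join(f"{ct}={v:.1f}" for ct, v in mean_counts.items()))
        for (ct, node), arr in sorted(self.pheno.items()):
            tail = arr[:, -min(self.K, arr.shape[1]):]
            lines.append(f"  {ct}.{node}: {tail.mean():.3f} "
                         f"(SD over runs {tail.mean(axis=1).std(ddof=1) if self.M > 1 else 0:.3f})")
        return "\n".join(lines)

    def plot_trajectories(self, nodes=None, cell_type=None, ax=None):
        """Phenotype ON-fraction trajectories (mean +/- SD over runs)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ct = cell_type or self.model.cancer_type
        nodes = nodes or self.model.networks[ct].phenotype_nodes
        steps = np.arange(self.T + 1)
        for node in nodes:
            traj = self.phenotype_trajectory(node, ct)
            mean, sd = traj.mean(axis=0), traj.std(axis=0, ddof=1 if self.M > 1 else 0)
            ax.plot(steps, mean, label=f"{ct}.{node}")
            ax.fill_between(steps, mean - sd, mean + sd, alpha=0.2)
        ax.set_xlabel("time step")
        ax.set_ylabel("fraction of cells ON")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax


def plateau_onset(trajectory: np.ndarray, window: int = 10,
                  plateau_window: int = 50) -> int | None:
    """First step at which the run-averaged trajectory has plateaued.

    The trajectory (runs x steps, or steps,) is averaged over runs; the
    plateau SD is taken over the trailing ``plateau_window`` steps.  The
    onset is the end of the first ``window``-step block whose mean differs
    from the next block's mean by less than 2 plateau SDs (and stays so).
    Returns None if no plateau is reached.
    """
    traj = np.asarray(trajectory, dtype=float)
    mean = traj.mean(axis=0) if traj.ndim == 2 else traj
    if mean.size < max(2 * window + 1, plateau_window):
        raise ValueError("trajectory too short for the requested windows")
    sd = mean[-plateau_window:].std(ddof=1)
    tol = 2.0 * sd
    n_blocks = mean.size // window
    blocks = mean[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    stable = np.abs(np.diff(blocks)) < tol
    for b in range(len(stable)):
        if stable[b:].all():
            return (b + 1) * window
    return None
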