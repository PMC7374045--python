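"""Lattice-free 3D tissue generation.

Cancer cells are placed by a Thomas cluster process: Poisson parent centers
of intensity ``rho_cc = s * rho_C`` with Poisson(1/s) offspring per center,
scattered isotropically with a Gaussian kernel.  The kernel width sigma is
fixed so that the expected cell density inside the sigma-sphere of a cluster
equals ``rho_max`` (default 8 * rho), preventing unrealistically dense
clusters.  Stromal and immune cells follow a void process: uniform Poisson
candidates thinned by a hard exclusion radius ``R_ex`` around the *same*
cluster centers, with the candidate intensity compensated so that the
expected retained density is ``rho_S = (1 - r_C) * rho``.  All geometry is
periodic (minimum-image distances, positions wrapped into [0, L)^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = ["TissueConfig", "CellPopulation", "derive_sigma", "generate_tissue"]

#: P(||Z|| <= 1) for a standard 3D normal Z — mass of a Gaussian cluster
#: within one sigma of its center.
P_WITHIN_SIGMA = float(stats.chi.cdf(1.0, df=3))


@dataclass
class TissueConfig:
    """Geometry and composition of a simulated tissue block.

    Lengths are in cell diameters, densities in cells per unit volume.
    """

    L: float = 10.0                      # domain edge length
    rho: float = 0.25                    # total cell density
    r_C: float = 0.6                     # cancer-cell fraction
    s: float = 0.07                      # clustering (rho_cc = s * rho_C)
    R_ex: float = 1.5                    # stromal exclusion radius
    rho_max_multiplier: float = 8.0      # rho_max = multiplier * rho
    cancer_type: str = "PCC"
    stromal_fractions: dict[str, float] = field(default_factory=lambda: {"PSC": 1.0})
    fixed_n: bool = False                # realize exactly round(rho * L^3) cells

    def __post_init__(self):
        if self.L <= 0 or self.rho <= 0 or self.s <= 0 or self.R_ex < 0:
            raise ValueError("L, rho, s must be positive and R_ex nonnegative")
        if not 0.0 <= self.r_C <= 1.0:
            raise ValueError("r_C must lie in [0, 1]")
        if self.stromal_fractions and any(v < 0 for v in self.stromal_fractions.values()):
            raise ValueError("stromal fractions must be nonnegative")

    @property
    def rho_C(self) -> float:
        return self.r_C * self.rho

    @property
    def rho_S(self) -> float:
        return (1.0 - self.r_C) * self.rho

    @property
    def rho_cc(self) -> float:
        return self.s * self.rho_C

    @property
    def rho_max(self) -> float:
        return self.rho_max_multiplier * self.rho

    @property
    def mu(self) -> float:
        """Expected offspring per cluster center (rho_C / rho_cc = 1/s)."""
        return 1.0 / self.s

    def replace(self, **kw) -> "TissueConfig":
        from dataclasses import replace
        return replace(self, **kw)


@dataclass
class CellPopulation:
    positions: np.ndarray          # (N, 3) in [0, L)^3
    types: np.ndarray              # (N,) str labels
    L: float
    cluster_centers: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def indices_of(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.types == cell_type)

    def type_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.types, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(len(self)),
            "type": self.types,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, L: float) -> "CellPopulation":
        df = pd.read_csv(path)
        required = {"type", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cell table missing column(s) {sorted(missing)}")
        pos = df[["x", "y", "z"]].to_numpy(float) % L
        return cls(positions=pos, types=df["type"].to_numpy(str), L=L)


def derive_sigma(cfg: TissueConfig) -> float:
    """Gaussian cluster spread sigma capping within-sigma density at rho_max.

    A cluster holds mu = 1/s expected points, a fraction ``P_WITHIN_SIGMA``
    of which fall inside the sigma-sphere of volume (4/3) pi sigma^3.
    Setting that expected density equal to rho_max gives

        sigma = (3 mu P1 / (4 pi rho_max))^(1/3).
    """
    return float((3.0 * cfg.mu * P_WITHIN_SIGMA / (4.0 * np.pi * cfg.rho_max)) ** (1.0 / 3.0))


def _min_image_sq_dist(points: np.ndarray, centers: np.ndarray, L: float) -> np.ndarray:
    d = np.abs(points[:, None, :] - centers[None, :, :])
    d = np.minimum(d, L - d)
    return (d ** 2).sum(axis=2)


def generate_tissue(cfg: TissueConfig, seed=None,
                    rng: np.random.Generator | None = None) -> CellPopulation:
    """Draw one tissue realization.

    With ``cfg.fixed_n`` the total count is fixed at round(rho * L^3)
    (composition multinomial in the type fractions) for reproducible tests;
    otherwise counts are Poisson as dictated by the point processes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    V = cfg.L ** 3
    sigma = derive_sigma(cfg)

    # --- cluster centers (shared by cancer and void processes) -------------
    n_centers = 0
    if cfg.r_C > 0:
        n_centers = rng.poisson(cfg.rho_cc * V)
        if n_centers == 0:
            warnings.warn("no cluster centers realized; resampling to avoid an "
                          "empty cancer compartment", stacklevel=2)
            while n_centers == 0:
                n_centers = rng.poisson(max(cfg.rho_cc * V, 1.0))
    centers = rng.uniform(0.0, cfg.L, size=(n_centers, 3)) if n_centers else \
        np.empty((0, 3))

    positions, labels = [], []

    # --- cancer cells: Thomas process ---------------------------------------
    if cfg.r_C > 0:
        if cfg.fixed_n:
            n_cancer = int(round(cfg.rho_C * V))
            parent = rng.integers(0, n_centers, size=n_cancer)
        else:
            offspring = rng.poisson(cfg.mu, size=n_centers)
            parent = np.repeat(np.arange(n_centers), offspring)
            n_cancer = parent.size
        pts = centers[parent] + rng.normal(0.0, sigma, size=(n_cancer, 3))
        positions.append(pts % cfg.L)
        labels.extend([cfg.cancer_type] * n_cancer)

    # --- stromal cells: void process ----------------------------------------
    if cfg.r_C < 1.0 and cfg.stromal_fractions:
        total = sum(cfg.stromal_fractions.values())
        names = list(cfg.stromal_fractions)
        probs = np.array([cfg.stromal_fractions[t] / total for t in names])
        v_ex = 4.0 / 3.0 * np.pi * cfg.R_ex ** 3
        p_keep = float(np.exp(-cfg.rho_cc * v_ex))  # Boolean-model void probability
        target = int(round(cfg.rho_S * V)) if cfg.fixed_n else None
        kept_list = []
        kept_total = 0
        tree = cKDTree(centers % cfg.L, boxsize=cfg.L) if n_centers else None
        for _ in range(200):
            if cfg.fixed_n:
                n_cand = max(int(np.ceil((target - kept_total) / p_keep * 1.2)), 16)
            else:
                n_cand = rng.poisson(cfg.rho_S * V / p_keep)
            if n_cand == 0:
                break
            cand = rng.uniform(0.0, cfg.L, size=(n_cand, 3))
            if tree is not None and cfg.R_ex > 0:
                near = tree.query_ball_point(cand, cfg.R_ex, return_length=True)
                cand = cand[near == 0]
            kept_list.append(cand)
            kept_total += len(cand)
            if not cfg.fixed_n or kept_total >= target:
                break
        kept = np.concatenate(kept_list) if kept_list else np.empty((0, 3))
        if cfg.fixed_n and target is not None:
            kept = kept[:target]
        if len(kept):
            positions.append(kept)
            labels.extend(rng.choice(names, size=len(kept), p=probs).tolist())

    if positions:
        pos = np.concatenate(positions)
    else:
        pos = np.empty((0, 3))
    return CellPopulation(positions=pos, types=np.array(labels, dtype=object),
                          L=cfg.L, cluster_centers=centers % cfg.L if n_centers else None)
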