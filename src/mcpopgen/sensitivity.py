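"""Morris elementary-effects screening of the sparse approximation quality.

The four model/algorithm parameters — population size N, mutation rate mu,
clonality rate c and approximation threshold s — are each restricted to a
grid; random one-step-at-a-time trajectories through the normalized grid
hypercube yield elementary effects EE = (y_after - y_before) / delta for
every output statistic.  The mean absolute effect mu* screens parameter
importance and the standard deviation sigma of the effects flags
non-linearity and interactions.

Default grids: N in {10, 20, ..., 100}; mu in {1e-12, ..., 1e-3} by decade
(uniform on the exponent, i.e. log scale); c in {0.1, ..., 1.0} step 0.1;
s in {0.80, 0.82, ..., 0.98}.  The default of 30 trajectories over the
4 parameters gives 150 model evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popgen
from .approx import approximate_matrix
from .model import ModelParams, build_transition_matrix
from .spectral import dominant_eigenvector
from .statespace import StateSpace

__all__ = ["default_grids", "MorrisDesign", "MorrisResult", "morris_design",
           "elementary_effects", "GsaConfig", "run_gsa"]


def default_grids() -> dict[str, np.ndarray]:
    return {
        "N": np.arange(10, 101, 10, dtype=float),
        "mu": 10.0 ** np.arange(-12, -2),
        "c": np.round(np.arange(0.1, 1.01, 0.1), 10),
        "s": np.round(np.arange(0.80, 0.99, 0.02), 10),
    }


@dataclass
class MorrisDesign:
    """One-step-at-a-time trajectories over the parameter grids.

    ``levels[t]`` is the (k+1) x k integer array of grid indices of
    trajectory t; ``steps[t]`` lists, per move, the changed parameter index
    and the signed normalized step delta = +-1/(L_p - 1).
    """

    grids: dict[str, np.ndarray]
    levels: list[np.ndarray]
    steps: list[list[tuple[int, float]]]
    seed: int | None = None

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def n_points(self) -> int:
        return sum(lv.shape[0] for lv in self.levels)

    def points(self) -> pd.DataFrame:
        """All evaluation points in order, in actual parameter values."""
        rows = []
        for lv in self.levels:
            for idx in lv:
                rows.append(
                    {n: self.grids[n][i] for n, i in zip(self.names, idx)}
                )
        return pd.DataFrame(rows)


def morris_design(grids: dict, trajectories: int, seed: int | None = None) -> MorrisDesign:
    """Sample ``trajectories`` random one-step trajectories over the grids.

    Each trajectory starts at a random grid point and changes every
    parameter exactly once, in random order, by one grid step in a random
    direction (reflected at the grid boundary).  Reproducible under
    ``seed``; ``trajectories * (k + 1)`` evaluation points in total.
    """
    grids = {k: np.asarray(v, dtype=float) for k, v in grids.items()}
    for name, g in grids.items():
        if g.size < 2:
            raise ValueError(f"grid for {name!r} needs >= 2 levels, got {g.size}")
    rng = np.random.default_rng(seed)
    names = list(grids)
    sizes = np.array([grids[n].size for n in names])
    levels, steps = [], []
    for _ in range(trajectories):
        idx = np.array([rng.integers(0, s) for s in sizes])
        order = rng.permutation(len(names))
        traj = [idx.copy()]
        moves = []
        for p in order:
            d = 1 if rng.random() < 0.5 else -1
            if not 0 <= idx[p] + d < sizes[p]:
                d = -d
            idx[p] += d
            traj.append(idx.copy())
            moves.append((int(p), d / (sizes[p] - 1.0)))
        levels.append(np.array(traj))
        steps.append(moves)
    return MorrisDesign(grids=grids, levels=levels, steps=steps, seed=seed)


@dataclass
class MorrisResult:
    """mu* and sigma of the elementary effects, per output and parameter."""

    table: pd.DataFrame  # columns: output, parameter, mu_star, sigma, n_effects

    def for_output(self, output: str) -> pd.DataFrame:
        sub = self.table[self.table["output"] == output]
        if sub.empty:
            raise KeyError(f"unknown output {output!r}")
        return sub.set_index("parameter")[["mu_star", "sigma", "n_effects"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def elementary_effects(design: MorrisDesign, outputs) -> MorrisResult:
    """Compute mu* (mean |EE|) and sigma (sd of EE) from evaluated outputs.

    ``outputs``: one value per design point — a 1-D array/Series for a
    single statistic, or a DataFrame with one column per statistic.
    Non-finite outputs void the elementary effects they touch; those are
    omitted from the aggregation.  A parameter with no finite effect at all
    raises.
    """
    if isinstance(outputs, pd.DataFrame):
        out_df = outputs
    else:
        out_df = pd.DataFrame({"y": np.asarray(outputs, dtype=float)})
    if len(out_df) != design.n_points:
        raise ValueError(
            f"{len(out_df)} outputs for {design.n_points} design points"
        )
    names = design.names
    rows = []
    for col in out_df.columns:
        y = out_df[col].to_numpy(dtype=float)
        effects: dict[int, list[float]] = {p: [] for p in range(len(names))}
        pos = 0
        for lv, moves in zip(design.levels, design.steps):
            for k, (p, delta) in enumerate(moves):
                y0, y1 = y[pos + k], y[pos + k + 1]
                if np.isfinite(y0) and np.isfinite(y1):
                    effects[p].append((y1 - y0) / delta)
            pos += lv.shape[0]
        for p, name in enumerate(names):
            ee = np.array(effects[p])
            if ee.size == 0:
                raise ValueError(
                    f"no finite elementary effects for parameter {name!r} "
                    f"and output {col!r}"
                )
            rows.append(
                {
                    "output": col,
                    "parameter": name,
                    "mu_star": float(np.abs(ee).mean()),
                    "sigma": float(ee.std(ddof=1)) if ee.size > 1 else 0.0,
                    "n_effects": int(ee.size),
                }
            )
    return MorrisResult(table=pd.DataFrame(rows))


@dataclass
class GsaConfig:
    """Configuration of the full screening experiment."""

    grids: dict = field(default_factory=default_grids)
    trajectories: int = 30
    n_eff: float = 1000.0
    power_lambda: float = 2.0 / 3.0
    clonal_mutation: bool = True
    max_dense_states: int = 8000

    @classmethod
    def from_dict(cls, d: dict) -> "GsaConfig":
        cfg = cls()
        if "grids" in d:
            cfg.grids = {k: np.asarray(v, dtype=float) for k, v in d["grids"].items()}
        for key in ("trajectories", "n_eff", "power_lambda", "clonal_mutation",
                    "max_dense_states"):
            if key in d:
                setattr(cfg, key, type(getattr(cfg, key))(d[key]))
        return cfg


def _evaluate_point(N: int, mu: float, c: float, s: float,
                    cfg: GsaConfig, cache: dict) -> dict:
    """Build, approximate, and compare limiting F_IS distributions."""
    key = (N, mu, c, s)
    if key in cache:
        return cache[key]
    space = StateSpace(N)
    params = ModelParams(N=N, mu=mu, c=c, clonal_mutation=cfg.clonal_mutation)
    dense = build_transition_matrix(params, space, max_states=cfg.max_dense_states)
    sparse, report = approximate_matrix(dense, s)
    f_orig = popgen.fis_distribution(dominant_eigenvector(dense))
    f_appr = popgen.fis_distribution(dominant_eigenvector(sparse))
    out = {"density": report.density}
    for meth in popgen.DIVERGENCE_METHODS:
        out[meth] = popgen.divergence(f_orig, f_appr, method=meth,
                                      lam=cfg.power_lambda)
    gt = popgen.g_test(f_orig, f_appr, n_eff=cfg.n_eff)
    out["g_statistic"] = gt.statistic
    out["g_pvalue"] = gt.pvalue
    cache[key] = out
    return out


def run_gsa(config: GsaConfig | None = None, seed: int | None = None,
            design: MorrisDesign | None = None) -> tuple[pd.DataFrame, MorrisResult]:
    """Full screening pipeline: design, per-point evaluation, effects.

    Returns the per-point table (parameters plus all output statistics;
    failed points carry NaN outputs and failed=True) and the MorrisResult
    over every output.  Identical seeds give identical tables.
    """
    cfg = config if config is not None else GsaConfig()
    if design is None:
        design = morris_design(cfg.grids, cfg.trajectories, seed)
    pts = design.points()
    cache: dict = {}
    records = []
    for _, row in pts.iterrows():
        rec = dict(row)
        try:
            rec.update(
                _evaluate_point(int(row["N"]), float(row["mu"]), float(row["c"]),
                                float(row["s"]), cfg, cache)
            )
            rec["failed"] = False
        except Exception as exc:  # noqa: BLE001 - per-point failures are data
            rec["failed"] = True
            rec["error"] = str(exc)
        records.append(rec)
    table = pd.DataFrame(records)
    out_cols = [c for c in table.columns
                if c not in design.names and c not in ("failed", "error")]
    result = elementary_effects(design, table[out_cols])
    return table, result
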