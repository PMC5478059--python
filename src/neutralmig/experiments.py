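"""The three computational experiments, as reproducible pipeline stages.

``recovery_experiment``
    Sanity check: simulate spatially implicit communities across a grid of
    known migration rates and measure each estimator's mean absolute
    recovery error (given vs estimated m).

``additivity_experiment``
    Robustness check: simulate lattice communities whose migration splits
    into an adjacent-plot and a metacommunity share, and ask whether the
    spatially implicit estimators recover the joint probability
    ``m_adj + m_meta`` — they do when the metacommunity share dominates,
    and underestimate it when the adjacent share dominates.

``field_emulation``
    Emulate a field inventory: run the implicit model at a migration rate
    previously estimated from real data and summarize pooled species,
    singletons, Fisher's alpha and the rank-abundance distribution.  This
    doubles as the synthetic field-data generator: the returned community
    matrix has the plot x species shape of the inventories it emulates
    (e.g. 67 one-hectare plots of 625 stems for Guyana/Suriname).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (
    MigrationEstimate,
    etienne_onestage_matrix,
    etienne_twostage,
    gst_migration,
    inference_migration,
)
from .logseries import LogseriesMetacommunity, solve_fisher_alpha
from .simulate import (
    DEFAULT_GENERATIONS,
    CommunityMatrix,
    LatticeConfig,
    run_implicit_batch,
    run_lattice,
)

__all__ = [
    "ESTIMATORS",
    "RecoveryResult",
    "AdditivityResult",
    "EmulationResult",
    "recovery_experiment",
    "additivity_experiment",
    "field_emulation",
    "rad_summary",
]

ESTIMATORS = {
    "gst": gst_migration,
    "inference": inference_migration,
    "etienne1": etienne_onestage_matrix,
    "etienne2": etienne_twostage,
}

#: datasets emulated by the synthetic generator: (plots, pooled trees,
#: morphospecies) of the three Amazonian inventories, and which
#: metacommunity the corresponding simulations draw from.
FIELD_SHAPES = {
    "GS": {"plots": 67, "trees": 37_446, "species": 1_042, "meta": "MC-low"},
    "FG": {"plots": 63, "trees": 35_075, "species": 1_204, "meta": "MC-low"},
    "EC": {"plots": 72, "trees": 34_544, "species": 2_021, "meta": "MC-high"},
}

#: (N, S) of the three logseries metacommunities.
METACOMMUNITIES = {
    "MC-low": (20_191_600_511, 4_582),
    "MC-high": (5_611_001_426, 6_834),
    "MC-spatial": (5_500_000, 2_697),
}


@dataclass
class RecoveryResult:
    """Given-vs-estimated migration across a grid of rates."""

    table: pd.DataFrame          # one row per (m_given, estimator, replicate)
    summary: pd.DataFrame        # mean |m_hat - m| per estimator

    def delta_m(self, method: str) -> float:
        return float(self.summary.loc[method, "delta_m"])


@dataclass
class AdditivityResult:
    """Joint-migration estimates on lattice scenarios."""

    table: pd.DataFrame          # one row per (scenario, estimator)
    matrices: list[CommunityMatrix] = field(default_factory=list)


@dataclass
class EmulationResult:
    """Summary of one emulated field inventory."""

    matrix: CommunityMatrix
    species: int
    singletons: int
    pooled_alpha: float
    mean_plot_alpha: float
    rad: np.ndarray
    estimates: dict[str, MigrationEstimate] = field(default_factory=dict)


def _matrix_from_rows(rows: np.ndarray, S: int) -> CommunityMatrix:
    counts = np.zeros((rows.shape[0], S), dtype=np.int64)
    for p in range(rows.shape[0]):
        counts[p] = np.bincount(rows[p], minlength=S)
    frame = pd.DataFrame(
        counts,
        index=[f"plot{p + 1:03d}" for p in range(rows.shape[0])],
        columns=[f"sp{r:06d}" for r in range(1, S + 1)],
    )
    return CommunityMatrix(frame.loc[:, frame.sum(axis=0) > 0])


def recovery_experiment(
    meta: LogseriesMetacommunity,
    m_grid: list[float],
    estimators: list[str] = ("gst", "inference"),
    n_plots: int = 20,
    J: int = 625,
    replicates: int = 3,
    generations: float = DEFAULT_GENERATIONS,
    seed: int | None = None,
) -> RecoveryResult:
    """Simulate the implicit model over ``m_grid`` and score each estimator.

    All grid points and replicates advance in one batched simulation (plots
    are independent in the implicit model), then each (m, replicate) block
    of ``n_plots`` plots is handed to each estimator.
    """
    for m in m_grid:
        if not 0 < m <= 1:
            raise ValueError(f"grid migration rates must be in (0, 1], got {m}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    m_arr = np.repeat(np.asarray(m_grid, dtype=float), replicates * n_plots)
    comm = run_implicit_batch(meta, m_arr, J, generations, seed)
    records = []
    for i, m in enumerate(m_grid):
        block = comm[i * replicates * n_plots: (i + 1) * replicates * n_plots]
        for rep in range(replicates):
            mat = _matrix_from_rows(
                block[rep * n_plots: (rep + 1) * n_plots], meta.S
            )
            for name in estimators:
                try:
                    est = ESTIMATORS[name](mat)
                    records.append(
                        {
                            "m_given": m, "estimator": name, "replicate": rep,
                            "m_hat": est.mean, "sd": est.sd,
                            "failed": False,
                        }
                    )
                except Exception as exc:  # per-cell failure flag
                    records.append(
                        {
                            "m_given": m, "estimator": name, "replicate": rep,
                            "m_hat": np.nan, "sd": np.nan,
                            "failed": True, "error": str(exc),
                        }
                    )
    table = pd.DataFrame.from_records(records)
    ok = table[~table["failed"]]
    summary = (
        ok.assign(abs_err=(ok["m_hat"] - ok["m_given"]).abs())
        .groupby("estimator")["abs_err"].mean()
        .rename("delta_m").to_frame()
    )
    return RecoveryResult(table=table, summary=summary)


def additivity_experiment(
    meta: LogseriesMetacommunity,
    scenarios: list[tuple[float, float]],
    estimators: list[str] = ("gst", "inference"),
    rows: int = 20,
    cols: int = 20,
    J: int = 500,
    generations: float = DEFAULT_GENERATIONS,
    seed: int | None = None,
    keep_matrices: bool = False,
) -> AdditivityResult:
    """One lattice run per ``(m_adj, m_meta)`` scenario, each estimated.

    The output table carries the scenario parameters, pooled species and
    singleton counts, and per-estimator mean/sd of the joint migration
    estimate (plus the unclamped raw mean as a diagnostic).
    """
    rng = np.random.default_rng(seed)
    records = []
    matrices = []
    for m_adj, m_meta in scenarios:
        cfg = LatticeConfig(
            rows=rows, cols=cols, J=J, m_adj=m_adj, m_meta=m_meta,
            generations=generations, seed=int(rng.integers(2**31 - 1)),
        )
        mat = run_lattice(meta, cfg)
        if keep_matrices:
            matrices.append(mat)
        base = {
            "m_adj": m_adj, "m_meta": m_meta,
            "m_local": 1.0 - m_adj - m_meta,
            "m_joint": m_adj + m_meta,
            "species": mat.pooled_species(),
            "singletons": mat.pooled_singletons(),
            "meta_dominated": m_meta >= m_adj,
        }
        for name in estimators:
            est = ESTIMATORS[name](mat)
            records.append(
                base | {
                    "estimator": name, "m_hat": est.mean, "sd": est.sd,
                    "m_hat_raw": est.mean_raw,
                }
            )
    return AdditivityResult(
        table=pd.DataFrame.from_records(records), matrices=matrices
    )


def field_emulation(
    meta: LogseriesMetacommunity,
    n_plots: int,
    J: int,
    m: float,
    generations: float = DEFAULT_GENERATIONS,
    seed: int | None = None,
    estimators: list[str] = (),
) -> EmulationResult:
    """Emulate a field inventory with the implicit model at migration ``m``.

    Reports the pooled species and singleton counts, Fisher's alpha both
    from the pooled sample and averaged over per-plot fits, and the pooled
    rank-abundance distribution; optionally re-estimates migration from the
    emulated matrix with the named estimators.
    """
    if not 0 < m <= 1:
        raise ValueError("migration must be in (0, 1]")
    m_arr = np.full(n_plots, m)
    comm = run_implicit_batch(meta, m_arr, J, generations, seed)
    mat = _matrix_from_rows(comm, meta.S)
    rad, plot_alphas, pooled_alpha = rad_summary(mat)
    result = EmulationResult(
        matrix=mat,
        species=mat.pooled_species(),
        singletons=mat.pooled_singletons(),
        pooled_alpha=pooled_alpha,
        mean_plot_alpha=float(np.nanmean(plot_alphas)),
        rad=rad,
    )
    for name in estimators:
        result.estimates[name] = ESTIMATORS[name](mat)
    return result


def rad_summary(mat: CommunityMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Rank-abundance distribution and Fisher's alpha summaries.

    Returns ``(rad, plot_alphas, pooled_alpha)``: the pooled relative
    abundances sorted descending, the per-plot alphas solved from each
    plot's (J, S) — NaN for degenerate plots with S = 1 or S = J, which a
    logseries fit cannot represent — and the alpha of the pooled sample.
    """
    pooled = mat.pooled()
    pooled = pooled[pooled > 0]
    if pooled.sum() == 0:
        raise ValueError("empty community matrix")
    order = np.argsort(pooled)[::-1]
    rad = pooled[order] / pooled.sum()
    plot_alphas = []
    for row in mat.counts.to_numpy():
        J = int(row.sum())
        S = int((row > 0).sum())
        if S <= 1 or S >= J:
            plot_alphas.append(np.nan)
        else:
            plot_alphas.append(solve_fisher_alpha(J, S))
    pooled_alpha = solve_fisher_alpha(int(pooled.sum()), int((pooled > 0).sum()))
    return rad, np.asarray(plot_alphas), pooled_alpha
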