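"""Scoring the estimator against simulator ground truth, and parameter sweeps.

Accuracy is the mean absolute error (MAE) of the estimated center against the
unit's true mean innervation x, over the recordings where an estimate was
produced; robustness is the count ``N_ne`` of recordings with no estimate.
The two are combined into the error score

    ES(alpha) = 0.5 * ( alpha * MAE / (IED/2) + (1 - alpha) * N_ne / N_total ),

with the weight ``alpha`` trading accuracy (high alpha) against robustness
(low alpha).  The sweep evaluates ES over a (wavelet-width, cluster-radius)
grid at several SNR levels and reports the arg-min cell per (SNR, alpha).

The sweep exploits the pipeline's structure: the band-pass depends on neither
swept parameter, the delay/line/intersection stage depends only on the
wavelet width, and only the clustering stage sees the DBSCAN radius — so each
stage runs once per recording at the coarsest level that covers the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .izc_estimator import (
    EstimatorParams,
    bandpass,
    cluster_and_center,
    delay_profile,
    intersections,
    normalize_points,
    pair_lines,
)
from .virtual_experiment import Recording, add_noise

__all__ = [
    "EvalRecord",
    "SweepResult",
    "mae",
    "error_score",
    "sweep",
    "robustness_profile",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_EPS_GRID",
]

#: Default sweep grids, chosen to bracket the physics: motor-unit-potential
#: lobes span roughly 1-5 ms at 2 cm electrode depth, and cluster radii from a
#: fraction of an electrode pitch to several pitches.
DEFAULT_LAMBDA_GRID = np.geomspace(0.5e-3, 10e-3, 13)
DEFAULT_EPS_GRID = np.geomspace(0.1, 10.0, 13)


@dataclass(frozen=True)
class EvalRecord:
    mu_id: int
    geometry_set_id: int
    array_offset: float
    snr_db: float | None
    lam: float
    eps: float
    success: bool
    true_center_x: float
    est_center_x: float | None
    abs_error: float | None  # m, defined iff success


@dataclass
class SweepResult:
    """Grid of per-(lam, eps, snr) scores plus the flat evaluation records."""

    table: pd.DataFrame  # columns: lam, eps, snr_db, n_total, n_ne, mae, es_<alpha>...
    alphas: tuple[float, ...]
    records: list[EvalRecord] = field(default_factory=list)

    def optimal(self, snr_db: float | None, alpha: float) -> pd.Series:
        """Arg-min ES cell on one SNR slice; ties break to smaller lam, then eps."""
        col = _es_col(alpha)
        key = np.inf if snr_db is None else float(snr_db)
        sl = self.table[(self.table.snr_db == key) & self.table[col].notna()]
        if sl.empty:
            raise ValueError(f"no defined score at snr={snr_db}, alpha={alpha}")
        sl = sl.sort_values(["lam", "eps"], kind="stable")
        return sl.loc[sl[col].idxmin()]


def mae(records: list[EvalRecord]) -> float | None:
    """Mean absolute error (m) over successful records; None if none succeeded."""
    errs = [r.abs_error for r in records if r.success]
    return float(np.mean(errs)) if errs else None


def error_score(
    mae_val: float | None, n_ne: int, n_total: int, alpha: float, ied: float
) -> float | None:
    """The combined accuracy/robustness score; None where MAE is undefined.

    With alpha = 0 the MAE term drops out and the score is defined even when
    nothing was estimated.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    robustness = (1.0 - alpha) * n_ne / n_total
    if alpha == 0:
        return 0.5 * robustness
    if mae_val is None:
        return None
    return 0.5 * (alpha * mae_val / (ied * 0.5) + robustness)


def _es_col(alpha: float) -> str:
    return f"es_{alpha:g}"


def sweep(
    dataset: list[Recording],
    lambdas=DEFAULT_LAMBDA_GRID,
    epsilons=DEFAULT_EPS_GRID,
    snr_list=(None,),
    alphas=(0.25, 0.5, 0.75),
    base_params: EstimatorParams | None = None,
    seed: int = 0,
    keep_records: bool = False,
) -> SweepResult:
    """Full-factorial (lam, eps) x SNR evaluation of the estimator.

    ``dataset`` holds noiseless recordings with ground truth in their
    metadata.  For each SNR level (``None`` = noiseless) a noisy copy of every
    recording is drawn from a counter-based stream of ``seed``, so cells are
    reproducible and independent of evaluation order.
    """
    lambdas = np.asarray(list(lambdas), dtype=float)
    epsilons = np.asarray(list(epsilons), dtype=float)
    base = base_params or EstimatorParams(ied=dataset[0].ied)
    cells: dict[tuple[int, int, float | None], list[EvalRecord]] = {
        (i, j, s): [] for i in range(len(lambdas)) for j in range(len(epsilons)) for s in snr_list
    }
    ss = np.random.SeedSequence(seed)
    for r_idx, rec in enumerate(dataset):
        for s_idx, snr in enumerate(snr_list):
            if snr is None:
                noisy = rec
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=ss.entropy, spawn_key=(r_idx, s_idx))
                )
                noisy = add_noise(rec, snr, rng)
            filtered = bandpass(noisy.dd, noisy.fs, base)
            for i, lam in enumerate(lambdas):
                profile = delay_profile(filtered, noisy.fs, lam)
                pts = intersections(pair_lines(profile))
                for j, eps in enumerate(epsilons):
                    params = EstimatorParams(
                        wavelet_width=lam,
                        cluster_eps=float(eps),
                        min_cluster_size=base.min_cluster_size,
                        expected_cv=base.expected_cv,
                        band=base.band,
                        ied=base.ied,
                    )
                    if len(pts) == 0:
                        res_success, est_x = False, None
                    else:
                        res = cluster_and_center(
                            normalize_points(pts, params), params, noisy.dd_positions
                        )
                        res_success, est_x = res.success, res.center_x
                    true_x = rec.meta["true_center_x"]
                    cells[(i, j, snr)].append(
                        EvalRecord(
                            mu_id=rec.meta.get("mu_id", -1),
                            geometry_set_id=rec.meta.get("geometry_set", -1),
                            array_offset=rec.meta.get("array_offset", 0.0),
                            snr_db=np.inf if snr is None else float(snr),
                            lam=float(lam),
                            eps=float(eps),
                            success=res_success,
                            true_center_x=true_x,
                            est_center_x=est_x,
                            abs_error=abs(est_x - true_x) if res_success else None,
                        )
                    )
    rows = []
    all_records: list[EvalRecord] = []
    for (i, j, snr), recs in cells.items():
        n_total = len(recs)
        n_ne = sum(not r.success for r in recs)
        m = mae(recs)
        row = {
            "lam": float(lambdas[i]),
            "eps": float(epsilons[j]),
            "snr_db": np.inf if snr is None else float(snr),
            "n_total": n_total,
            "n_ne": n_ne,
            "mae": m,
        }
        for alpha in alphas:
            row[_es_col(alpha)] = error_score(m, n_ne, n_total, alpha, base.ied)
        rows.append(row)
        if keep_records:
            all_records.extend(recs)
    table = pd.DataFrame(rows)
    return SweepResult(table=table, alphas=tuple(alphas), records=all_records)


def robustness_profile(
    dataset: list[Recording],
    parameter_sets: list[tuple[float, float]],
    snr_range=(-10, -5, 0, 5, 10, 15, 20),
    base_params: EstimatorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Absolute-error distribution and N_ne per SNR for chosen (lam, eps) sets.

    Returns one row per (parameter set, SNR) with quantiles 0.25/0.5/0.75,
    mean and s.d. of the absolute error plus the untracked count; an SNR of
    ``None`` evaluates the noiseless limit.
    """
    rows = []
    for lam, eps in parameter_sets:
        res = sweep(
            dataset,
            lambdas=[lam],
            epsilons=[eps],
            snr_list=tuple(snr_range),
            alphas=(0.5,),
            base_params=base_params,
            seed=seed,
            keep_records=True,
        )
        for snr in snr_range:
            key = np.inf if snr is None else float(snr)
            recs = [r for r in res.records if r.snr_db == key]
            errs = np.array([r.abs_error for r in recs if r.success])
            rows.append(
                {
                    "lam": lam,
                    "eps": eps,
                    "snr_db": key,
                    "n_total": len(recs),
                    "n_ne": sum(not r.success for r in recs),
                    "ae_mean": errs.mean() if errs.size else np.nan,
                    "ae_sd": errs.std() if errs.size else np.nan,
                    "ae_q25": np.quantile(errs, 0.25) if errs.size else np.nan,
                    "ae_q50": np.quantile(errs, 0.50) if errs.size else np.nan,
                    "ae_q75": np.quantile(errs, 0.75) if errs.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_report(result: SweepResult, outdir) -> None:
    """CSV table plus one ES heatmap image per (SNR, alpha) slice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "sweep.csv", index=False)
    lams = np.sort(result.table.lam.unique())
    epss = np.sort(result.table.eps.unique())
    for snr in result.table.snr_db.unique():
        for alpha in result.alphas:
            col = _es_col(alpha)
            grid = (
                result.table[result.table.snr_db == snr]
                .pivot(index="eps", columns="lam", values=col)
                .reindex(index=epss, columns=lams)
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            mesh = ax.pcolormesh(lams * 1e3, epss, grid.values, shading="nearest")
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_xlabel("wavelet width (ms)")
            ax.set_ylabel("cluster radius (pitch units)")
            ax.set_title(f"ES(alpha={alpha:g}), SNR={snr}")
            fig.colorbar(mesh, ax=ax, label="error score")
            fig.tight_layout()
            fig.savefig(outdir / f"es_snr{snr}_alpha{alpha:g}.png", dpi=120)
            plt.close(fig)
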