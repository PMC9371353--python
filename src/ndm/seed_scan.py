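"""Repeated-seeding engine: rank candidate epicentres of atrophy spread.

Diffusion is initiated from every bilateral homologue pair in turn; the
diffused pattern at each model time is correlated (Pearson) with the
measured atrophy map over all *non-seed* regions, giving one
correlation-time trace per seed.  Seeds are ranked by the maximum of
their trace, with family-wise correction across the seed family.

On the default 82-region parcellation with unit time steps 0..50 this
yields 41 seed conditions, 51 time points and 80-region correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .atrophy import AtrophyMap
from .connectome import Connectome, RegionTable
from .diffusion import DiffusionTrajectory, LaplacianDecomposition, build_laplacian, propagate

logger = logging.getLogger(__name__)

__all__ = [
    "SeedScanResult",
    "default_times",
    "bilateral_seed_vector",
    "correlation_trace",
    "repeated_seed_scan",
    "fwe_correct",
]


def default_times(tmax: int = 50) -> np.ndarray:
    """Unit-step model-time grid 0, 1, ..., tmax (51 points by default)."""
    return np.arange(tmax + 1, dtype=float)


@dataclass(frozen=True)
class SeedScanResult:
    """Correlation-time surface plus per-seed summary statistics.

    ``corr_matrix`` is seeds x times with NaN marking times where the
    correlation is undefined (zero variance, e.g. every seed's t = 0
    column).  Per-seed arrays are aligned with ``seed_labels``.
    """

    seed_labels: list[str]
    seed_groups: list[tuple[int, ...]]
    times: np.ndarray
    corr_matrix: np.ndarray
    max_r: np.ndarray
    t_star: np.ndarray
    p_values: np.ndarray
    p_fwe: np.ndarray
    n_regions_used: int
    correction: str = "bonferroni"

    @property
    def n_seeds(self) -> int:
        return len(self.seed_labels)

    def ranking(self) -> np.ndarray:
        """Seed indices sorted by max_r descending (stable for ties)."""
        return np.argsort(-self.max_r, kind="stable")

    def top_seed(self) -> str:
        return self.seed_labels[int(self.ranking()[0])]

    def to_frame(self) -> pd.DataFrame:
        order = self.ranking()
        return pd.DataFrame(
            {
                "seed_label": np.asarray(self.seed_labels)[order],
                "max_r": self.max_r[order],
                "t_star": self.t_star[order],
                "p": self.p_values[order],
                "p_fwe": self.p_fwe[order],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def surface_to_tsv(self, path) -> None:
        """Full correlation surface in long format: seed, time, r."""
        s = np.repeat(self.seed_labels, len(self.times))
        t = np.tile(self.times, self.n_seeds)
        pd.DataFrame({"seed_label": s, "time": t, "r": self.corr_matrix.ravel()}).to_csv(
            path, sep="\t", index=False, na_rep="NA"
        )


def bilateral_seed_vector(regions: RegionTable, seed_group) -> np.ndarray:
    """Indicator vector with 1 at each member of a homologue pair.

    ``seed_group`` may be a tuple of region indices, a single index, or a
    region label (whose homologue, if any, is included automatically).
    A single-region (midline) seed is accepted and logged.
    """
    if isinstance(seed_group, str):
        i = regions.index_of(seed_group)
        h = regions.table["homologue_id"].iloc[i]
        seed_group = (i,) if pd.isna(h) else (i, int(h))
    elif np.isscalar(seed_group):
        seed_group = (int(seed_group),)
    idx = [int(i) for i in seed_group]
    for i in idx:
        if not (0 <= i < regions.n):
            raise ValueError(f"unknown region index {i}")
    if len(idx) == 1:
        logger.info("seeding single (midline) region %s", regions.labels[idx[0]])
    f0 = np.zeros(regions.n)
    f0[idx] = 1.0
    return f0


def correlation_trace(
    traj: DiffusionTrajectory,
    atrophy: AtrophyMap,
    exclude,
) -> np.ndarray:
    """Pearson r between f(t) and measured atrophy at each time, seed excluded.

    Returns one r per time point; NaN where either vector has zero
    variance over the retained regions (undefined, never reported as 0).
    """
    n = traj.values.shape[1]
    if atrophy.n != n:
        raise ValueError("trajectory and atrophy map cover different region counts")
    mask = np.ones(n, dtype=bool)
    mask[list(exclude)] = False
    x = traj.values[:, mask]
    y = atrophy.t_values[mask]
    return _pearson_rows(x, y)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of matrix x against vector y; NaN on zero variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.linalg.norm(xc, axis=1)
    ynorm = np.linalg.norm(yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (xnorm * ynorm)
    r[(xnorm == 0)] = np.nan
    if ynorm == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def _corr_p_two_sided(r: float, n_used: int) -> float:
    """Two-sided p for a Pearson r via its t transform, df = n_used - 2."""
    df = n_used - 2
    if df <= 0:
        return 1.0
    denom = 1.0 - r * r
    if denom <= 0:
        return float(np.finfo(float).tiny)
    t = abs(r) * np.sqrt(df / denom)
    p = 2.0 * scipy.stats.t.sf(t, df)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def repeated_seed_scan(
    c: Connectome,
    atrophy: AtrophyMap,
    dec: LaplacianDecomposition | None = None,
    times: np.ndarray | None = None,
    alpha: float = 1.0,
    correction: str = "bonferroni",
) -> SeedScanResult:
    """Scan every bilateral seed over the model-time grid and rank seeds.

    For each seed the maximum is taken over times with a defined
    correlation (the all-zero prediction at t = 0 is always excluded);
    argmax ties resolve to the smallest time.
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    if not np.array_equal(atrophy.labels, c.regions.labels):
        raise ValueError("atrophy map and connectome regions are misaligned")
    if dec is None:
        dec = build_laplacian(c)
    groups = c.regions.seed_groups()
    n_seeds = len(groups)
    corr = np.full((n_seeds, len(times)), np.nan)
    for s, group in enumerate(groups):
        f0 = bilateral_seed_vector(c.regions, group)
        traj = propagate(dec, f0, times, alpha=alpha)
        corr[s] = correlation_trace(traj, atrophy, exclude=group)
    if np.all(np.isnan(corr)):
        raise ValueError("degenerate atrophy map: correlation undefined at every seed/time")

    max_r = np.empty(n_seeds)
    t_star = np.empty(n_seeds)
    pvals = np.empty(n_seeds)
    n_used = c.n - len(groups[0])
    for s in range(n_seeds):
        row = corr[s]
        valid = ~np.isnan(row)
        if not valid.any():
            max_r[s] = np.nan
            t_star[s] = np.nan
            pvals[s] = 1.0
            continue
        best = np.nanmax(row)
        max_r[s] = best
        t_star[s] = times[valid & (row == best)][0]  # smallest time on ties
        pvals[s] = _corr_p_two_sided(best, c.n - len(groups[s]))
    labels = [c.regions.seed_label(g) for g in groups]
    result = SeedScanResult(
        seed_labels=labels,
        seed_groups=groups,
        times=times,
        corr_matrix=corr,
        max_r=max_r,
        t_star=t_star,
        p_values=pvals,
        p_fwe=np.minimum(pvals * n_seeds, 1.0),
        n_regions_used=n_used,
        correction="bonferroni",
    )
    if correction != "bonferroni":
        result = fwe_correct(result, method=correction)
    return result


def fwe_correct(result: SeedScanResult, method: str = "bonferroni") -> SeedScanResult:
    """Family-wise correction of per-seed p-values across the seed family."""
    if method == "bonferroni":
        p_fwe = np.minimum(result.p_values * result.n_seeds, 1.0)
    elif method == "holm":
        p_fwe = multipletests(result.p_values, method="holm")[1]
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return replace(result, p_fwe=p_fwe, correction=method)
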