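"""Measured-atrophy maps: regional t-statistics from volume tables.

Volumes are first normalized by each subject's total intracranial volume
(ICV) to remove head-size differences; regional group contrasts are then
summarised as t-statistics.  Sign convention throughout: positive t means
volume loss in the patient / later group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "VolumeTable",
    "AtrophyMap",
    "load_volume_tables",
    "normalize_icv",
    "t_map_two_sample",
    "t_map_paired",
]


@dataclass(frozen=True)
class VolumeTable:
    """Per-subject regional volumes for one group or timepoint.

    ``volumes`` is indexed by subject_id with one column per region label
    (mm^3, or dimensionless fractions once normalized); ``icv`` is the
    matching per-subject total intracranial volume.
    """

    volumes: pd.DataFrame
    icv: pd.Series
    group: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.volumes.index.equals(self.icv.index):
            raise ValueError("volume table and ICV have mismatched subjects")
        if (self.volumes.to_numpy() <= 0).any():
            raise ValueError("regional volumes must be strictly positive")
        if (self.icv.to_numpy() <= 0).any():
            raise ValueError("ICV must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    @property
    def region_labels(self) -> np.ndarray:
        return self.volumes.columns.to_numpy()


@dataclass(frozen=True)
class AtrophyMap:
    """Regional atrophy effect sizes (t) with uncorrected p-values."""

    labels: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    design: str = "precomputed"
    contrast: str = ""
    group_sizes: tuple = ()

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.t_values) == len(self.p_values)):
            raise ValueError("labels, t and p must have equal length")
        if not np.all(np.isfinite(self.t_values)):
            raise ValueError("t-values must be finite")
        p = np.asarray(self.p_values, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"region_label": self.labels, "t": self.t_values, "p": self.p_values}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AtrophyMap":
        t = pd.read_csv(path, sep="\t")
        return cls(
            labels=t["region_label"].to_numpy(),
            t_values=t["t"].to_numpy(dtype=float),
            p_values=t["p"].to_numpy(dtype=float),
        )


def load_volume_tables(path) -> dict[str, VolumeTable]:
    """Read a subject x region TSV, split into one VolumeTable per group.

    Expected columns: ``subject_id``, ``group``, ``ICV``, then one column
    per region label (any order of the metadata columns is accepted).
    """
    t = pd.read_csv(path, sep="\t")
    meta = {"subject_id", "group", "ICV"}
    missing = meta - set(t.columns)
    if missing:
        raise ValueError(f"volume table is missing columns {sorted(missing)}")
    region_cols = [c for c in t.columns if c not in meta]
    out = {}
    for grp, sub in t.groupby("group", sort=False):
        sub = sub.set_index("subject_id")
        out[str(grp)] = VolumeTable(
            volumes=sub[region_cols].astype(float),
            icv=sub["ICV"].astype(float),
            group=str(grp),
        )
    return out


def normalize_icv(v: VolumeTable) -> VolumeTable:
    """Divide each subject's regional volumes by their ICV."""
    if v.normalized:
        return v
    return replace(v, volumes=v.volumes.div(v.icv, axis=0), normalized=True)


def _check_aligned(a: VolumeTable, b: VolumeTable) -> None:
    if list(a.volumes.columns) != list(b.volumes.columns):
        raise ValueError("volume tables have mismatched region columns")


def t_map_two_sample(
    patients: VolumeTable,
    controls: VolumeTable,
    welch: bool = False,
) -> AtrophyMap:
    """Per-region two-sample t-map, oriented so patient volume loss is positive.

    Pooled-variance t by default (``df = n1 + n2 - 2``); set ``welch`` for
    the unequal-variance variant.
    """
    _check_aligned(patients, controls)
    p = patients.volumes.to_numpy(dtype=float)
    c = controls.volumes.to_numpy(dtype=float)
    n1, n2 = p.shape[0], c.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    diff = c.mean(axis=0) - p.mean(axis=0)  # loss in patients -> positive
    vp = p.var(axis=0, ddof=1)
    vc = c.var(axis=0, ddof=1)
    if welch:
        se2 = vp / n1 + vc / n2
        df = se2**2 / (
            (vp / n1) ** 2 / (n1 - 1) + (vc / n2) ** 2 / (n2 - 1)
        )
    else:
        pooled = ((n1 - 1) * vp + (n2 - 1) * vc) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    degenerate = se2 == 0
    if np.any(degenerate & (diff != 0)):
        bad = patients.region_labels[degenerate & (diff != 0)].tolist()
        raise ValueError(f"zero within-group variance with nonzero effect in {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(se2))
    pvals = _two_sided_p(t, df)
    return AtrophyMap(
        labels=patients.region_labels,
        t_values=t,
        p_values=pvals,
        design="two_sample",
        contrast=f"{controls.group or 'controls'} minus {patients.group or 'patients'}",
        group_sizes=(n1, n2),
    )


def t_map_paired(earlier: VolumeTable, later: VolumeTable) -> AtrophyMap:
    """Per-region paired t-map on within-subject change (earlier minus later)."""
    _check_aligned(earlier, later)
    missing_later = earlier.volumes.index.difference(later.volumes.index)
    missing_earlier = later.volumes.index.difference(earlier.volumes.index)
    if len(missing_later) or len(missing_earlier):
        raise ValueError(
            "unmatched subjects between timepoints: "
            f"only earlier={missing_later.tolist()}, only later={missing_earlier.tolist()}"
        )
    order = earlier.volumes.index
    d = earlier.volumes.to_numpy(dtype=float) - later.volumes.loc[order].to_numpy(dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 matched subjects")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    if np.any(degenerate & (mean != 0)):
        bad = earlier.region_labels[degenerate & (mean != 0)].tolist()
        raise ValueError(f"zero variance of paired differences in {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, mean / (sd / np.sqrt(n)))
    df = np.full(d.shape[1], float(n - 1))
    return AtrophyMap(
        labels=earlier.region_labels,
        t_values=t,
        p_values=_two_sided_p(t, df),
        design="paired",
        contrast=f"{earlier.group or 'earlier'} minus {later.group or 'later'}",
        group_sizes=(n,),
    )


def _two_sided_p(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    return np.clip(p, np.finfo(float).tiny, 1.0)
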