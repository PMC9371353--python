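"""Loading and validation of weighted structural connectomes.

A connectome is a symmetric nonnegative matrix of connection strengths
(e.g. tractography streamline counts) over a labelled bilateral brain
parcellation.  The region table carries, for each region, its hemisphere
and the index of its contralateral homologue; bilateral homologue pairs
drive the seeding stage downstream.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Relative tolerance for accepting (and symmetrizing) float-noisy
#: asymmetry in nominally symmetric tractography matrices.
SYMMETRY_RTOL = 1e-8

_HEMISPHERES = frozenset({"left", "right", "midline"})

_LEFT_PREFIXES = ("lh_", "lh.", "Left-", "ctx-lh-")
_RIGHT_PREFIXES = ("rh_", "rh.", "Right-", "ctx-rh-")


class ConnectomeError(ValueError):
    """Raised when a connectome or region table fails validation."""


@dataclass(frozen=True)
class RegionTable:
    """Bilateral region labelling of a parcellation.

    Parameters
    ----------
    table
        DataFrame with columns ``region_id`` (consecutive 0-based ints),
        ``label`` (unique strings), ``hemisphere`` (``left`` / ``right`` /
        ``midline``) and nullable-integer ``homologue_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["region_id", "label", "hemisphere", "homologue_id"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ConnectomeError(f"region table is missing columns {missing}")
        n = len(t)
        ids = t["region_id"].to_numpy()
        if not np.array_equal(ids, np.arange(n)):
            raise ConnectomeError("region_ids must be consecutive 0-based integers")
        if t["label"].duplicated().any():
            dupes = t.loc[t["label"].duplicated(), "label"].tolist()
            raise ConnectomeError(f"duplicate region labels: {dupes}")
        bad_hemi = set(t["hemisphere"]) - _HEMISPHERES
        if bad_hemi:
            raise ConnectomeError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        hom = t["homologue_id"]
        for i, h in hom.items():
            if pd.isna(h):
                if t.loc[i, "hemisphere"] != "midline":
                    raise ConnectomeError(
                        f"non-midline region {t.loc[i, 'label']!r} has no homologue"
                    )
                continue
            h = int(h)
            if h == i:
                raise ConnectomeError(f"region {i} is its own homologue")
            if not (0 <= h < n):
                raise ConnectomeError(f"homologue_id {h} out of range for region {i}")
            back = hom.iloc[h]
            if pd.isna(back) or int(back) != i:
                raise ConnectomeError(
                    f"homologue relation not symmetric between regions {i} and {h}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def index_of(self, label: str) -> int:
        hits = np.flatnonzero(self.labels == label)
        if hits.size == 0:
            raise KeyError(f"unknown region label {label!r}")
        return int(hits[0])

    def homologue_pairs(self) -> list[tuple[int, int]]:
        """All bilateral pairs ``(i, j)`` with ``i < j``, in table order."""
        pairs = []
        hom = self.table["homologue_id"]
        for i, h in hom.items():
            if pd.isna(h):
                continue
            h = int(h)
            if i < h:
                pairs.append((i, h))
        return pairs

    def seed_groups(self) -> list[tuple[int, ...]]:
        """Seeding units: one per homologue pair, plus midline singletons."""
        groups: list[tuple[int, ...]] = [tuple(p) for p in self.homologue_pairs()]
        for i, h in self.table["homologue_id"].items():
            if pd.isna(h):
                groups.append((int(i),))
        groups.sort(key=lambda g: g[0])
        return groups

    def seed_label(self, group: tuple[int, ...]) -> str:
        """Bilateral base name for a seed group (hemisphere prefix stripped)."""
        lab = str(self.labels[group[0]])
        for p in _LEFT_PREFIXES + _RIGHT_PREFIXES:
            if lab.startswith(p):
                return lab[len(p):]
        return lab

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        t = pd.read_csv(path, sep="\t", dtype={"label": str, "hemisphere": str})
        t["homologue_id"] = pd.array(t.get("homologue_id"), dtype="Int64")
        t["region_id"] = t["region_id"].astype(int)
        return cls(t.reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_labels(cls, labels) -> "RegionTable":
        """Infer hemispheres and homologues from label prefixes.

        Labels carrying a recognised left/right prefix (``lh_``, ``rh_``,
        ``Left-``, ``Right-``, ...) are paired by their shared stem; any
        label without a recognised prefix becomes a midline region.
        """
        labels = [str(x) for x in labels]
        hemi, stem = [], []
        for lab in labels:
            for p in _LEFT_PREFIXES:
                if lab.startswith(p):
                    hemi.append("left")
                    stem.append(lab[len(p):])
                    break
            else:
                for p in _RIGHT_PREFIXES:
                    if lab.startswith(p):
                        hemi.append("right")
                        stem.append(lab[len(p):])
                        break
                else:
                    hemi.append("midline")
                    stem.append(lab)
        hom: list = [pd.NA] * len(labels)
        by_stem: dict[tuple[str, str], int] = {}
        for i, (h, s) in enumerate(zip(hemi, stem)):
            by_stem[(h, s)] = i
        for i, (h, s) in enumerate(zip(hemi, stem)):
            other = {"left": "right", "right": "left"}.get(h)
            if other is not None and (other, s) in by_stem:
                hom[i] = by_stem[(other, s)]
        t = pd.DataFrame(
            {
                "region_id": np.arange(len(labels)),
                "label": labels,
                "hemisphere": hemi,
                "homologue_id": pd.array(hom, dtype="Int64"),
            }
        )
        return cls(t)


def default_region_table() -> RegionTable:
    """The 82-region bilateral Desikan-Killiany table shipped with the package."""
    ref = importlib.resources.files("ndm") / "data" / "dk82_regions.tsv"
    with importlib.resources.as_file(ref) as path:
        return RegionTable.from_tsv(path)


@dataclass(frozen=True)
class Connectome:
    """A validated weighted undirected brain network.

    ``weights`` is symmetric, nonnegative, zero-diagonal and describes a
    single connected component; ``regions`` labels its nodes.
    """

    weights: np.ndarray
    regions: RegionTable

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != self.regions.n:
            raise ConnectomeError(
                f"matrix has {w.shape[0]} nodes but region table has {self.regions.n}"
            )
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("weight matrix contains NaN or infinite entries")
        if np.any(w < 0):
            raise ConnectomeError("weight matrix contains negative entries")
        scale = np.abs(w).max() or 1.0
        asym = np.abs(w - w.T).max()
        if asym > SYMMETRY_RTOL * scale:
            raise ConnectomeError(
                f"weight matrix asymmetry {asym:.3g} exceeds tolerance "
                f"{SYMMETRY_RTOL * scale:.3g}"
            )
        if asym > 0:
            logger.warning("symmetrizing weight matrix (max asymmetry %.3g)", asym)
            w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0):
            logger.warning("zeroing nonzero diagonal of weight matrix")
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        ncomp, comp = connected_components(csr_matrix(w > 0), directed=False)
        if ncomp != 1:
            sizes = np.bincount(comp)
            small = int(np.argmin(sizes))
            members = self.regions.labels[comp == small].tolist()
            raise ConnectomeError(
                f"disconnected graph: component of size {sizes[small]} "
                f"containing {members}"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def save(self, matrix_path, regions_path) -> None:
        """Write the canonical text representation (round-trips exactly)."""
        np.savetxt(matrix_path, self.weights, fmt="%.17g", delimiter=" ")
        self.regions.to_tsv(regions_path)


def load_connectome(matrix_path, regions_path=None) -> Connectome:
    """Load a delimited square weight matrix plus region table.

    The matrix file may be whitespace- or comma-delimited, with no header.
    If ``regions_path`` is omitted the default 82-region table is used
    (and must match the matrix dimension).
    """
    with open(matrix_path) as fh:
        first = fh.readline()
    delimiter = "," if ("," in first and not re.search(r"\d\s+\d", first.strip())) else None
    w = np.loadtxt(matrix_path, delimiter=delimiter, dtype=float)
    if w.ndim == 0:
        w = w.reshape(1, 1)
    regions = (
        default_region_table() if regions_path is None else RegionTable.from_tsv(regions_path)
    )
    return Connectome(w, regions)


def node_degrees(c: Connectome) -> np.ndarray:
    """Weighted degree (strength) of each node: row sums of the weight matrix."""
    return c.weights.sum(axis=1)
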