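"""Synthetic connectomes and study-like datasets with a planted seed.

Generates bilateral modular weighted graphs (denser within hemisphere,
boosted homotopic edges, log-normal weights mimicking streamline counts)
and atrophy data whose group difference is proportional to a diffusion
profile initiated from a chosen homologue pair at a chosen model time.
The planted ground truth is returned separately so analyses cannot leak it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .atrophy import AtrophyMap, VolumeTable
from .connectome import Connectome, ConnectomeError, RegionTable, default_region_table
from .diffusion import build_laplacian, propagate

__all__ = [
    "SyntheticSpec",
    "synth_connectome",
    "synth_atrophy",
    "synth_volume_tables",
]

_REDRAW_LIMIT = 50


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study generator.

    ``seed_pair`` indexes the homologue-pair list (None = drawn at
    random); ``t_star`` is the planted model time; ``noise_sigma`` scales
    additive atrophy noise as a fraction of the peak diffused value;
    ``effect`` is the fractional volume loss at the peak region.

    Topology: each hemisphere is a sparse near-regular random graph of
    binary degree ``within_degree`` (mirrored across hemispheres); the
    hemispheres are joined by one homotopic edge per region pair, boosted
    by ``homotopic_boost``, plus optional extra cross-hemisphere edges
    with ``cross_density``.  Low uniform degree keeps mixing slow, so
    different planted seeds remain distinguishable over the whole
    default time grid.  Per-region log-normal size factors
    (``region_size_sigma``) scale edge weights multiplicatively, giving
    realistic nodal-strength heterogeneity without altering the
    normalized diffusion operator (factorizable scalings cancel in the
    degree normalization).
    """

    n_regions: int = 82
    within_degree: int = 3
    cross_density: float = 0.0
    homotopic_boost: float = 10.0
    weight_mu: float = 4.0
    weight_sigma: float = 0.1
    region_size_sigma: float = 0.2
    seed_pair: int | None = None
    t_star: float = 10.0
    alpha: float = 1.0
    noise_sigma: float = 0.05
    atrophy_scale: float = 3.0
    n_patients: int = 14
    n_controls: int = 12
    effect: float = 0.05
    subject_cv: float = 0.02
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be an even integer >= 4")
        if not (1 <= self.within_degree < self.n_regions // 2):
            raise ValueError("within_degree must be in [1, n_regions/2)")
        if not (0 <= self.cross_density <= 1):
            raise ValueError("cross_density must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.t_star < 0:
            raise ValueError("t_star must be nonnegative")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("group sizes must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _synthetic_regions(n: int) -> RegionTable:
    """Default table for n = 82, generic bilateral labels otherwise."""
    if n == 82:
        return default_region_table()
    half = n // 2
    rows = []
    for i in range(half):
        rows.append((i, f"lh_region{i:03d}", "left", i + half))
    for i in range(half):
        rows.append((i + half, f"rh_region{i:03d}", "right", i))
    t = pd.DataFrame(rows, columns=["region_id", "label", "hemisphere", "homologue_id"])
    t["homologue_id"] = pd.array(t["homologue_id"], dtype="Int64")
    return RegionTable(t)


def _near_regular_adjacency(half: int, degree: int, rng: np.random.Generator) -> np.ndarray:
    """Simple random graph with (near-)uniform binary degree via stub pairing.

    If ``half * degree`` is odd, one extra stub is added to a random node.
    Draws with self-loops or multi-edges are rejected and resampled.
    """
    for _ in range(_REDRAW_LIMIT * 10):
        stubs = np.repeat(np.arange(half), degree)
        if len(stubs) % 2:
            stubs = np.append(stubs, rng.integers(half))
        rng.shuffle(stubs)
        adj = np.zeros((half, half), dtype=bool)
        ok = True
        for a, b in stubs.reshape(-1, 2):
            if a == b or adj[a, b]:
                ok = False
                break
            adj[a, b] = adj[b, a] = True
        if ok:
            return adj
    raise RuntimeError("could not draw a simple near-regular graph")


def synth_connectome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> Connectome:
    """Draw a connected bilateral weighted graph with labelled homologues.

    Each hemisphere gets an independent weight realisation on a shared
    near-regular topology; homotopic edges join every pair, with their
    log-normal weight multiplied by ``homotopic_boost``.  Redraws
    (bounded) if a draw comes out disconnected.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    regions = _synthetic_regions(spec.n_regions)
    n = spec.n_regions
    half = n // 2
    mu, sig = spec.weight_mu, spec.weight_sigma
    for _ in range(_REDRAW_LIMIT):
        w = np.zeros((n, n))
        # mirrored topology: both hemispheres share one adjacency draw,
        # with independent weight realisations
        adj = _near_regular_adjacency(half, spec.within_degree, rng)
        for off in (0, half):
            wt = np.triu(adj * rng.lognormal(mu, sig, (half, half)), k=1)
            w[off:off + half, off:off + half] = wt + wt.T
        if spec.cross_density > 0:
            cross = rng.random((half, half)) < spec.cross_density
            cw = cross * rng.lognormal(mu, sig, (half, half))
            w[:half, half:] += cw
            w[half:, :half] += cw.T
        for i, j in regions.homologue_pairs():
            w[i, j] = w[j, i] = rng.lognormal(mu, sig) * spec.homotopic_boost
        size = rng.lognormal(0.0, spec.region_size_sigma, n)
        w *= np.outer(size, size)
        np.fill_diagonal(w, 0.0)
        w = (w + w.T) / 2.0
        try:
            return Connectome(w, regions)
        except ConnectomeError:
            continue
    raise RuntimeError(f"no connected draw in {_REDRAW_LIMIT} attempts")


def _planted_profile(spec: SyntheticSpec, c: Connectome, rng: np.random.Generator):
    """Diffusion profile of the planted seed pair at the planted time."""
    pairs = c.regions.homologue_pairs()
    k = spec.seed_pair if spec.seed_pair is not None else int(rng.integers(len(pairs)))
    if not (0 <= k < len(pairs)):
        raise ValueError(f"seed_pair {k} out of range (have {len(pairs)} pairs)")
    pair = pairs[k]
    f0 = np.zeros(c.n)
    f0[list(pair)] = 1.0
    dec = build_laplacian(c)
    f = propagate(dec, f0, np.array([spec.t_star]), alpha=spec.alpha).values[0]
    truth = {
        "seed_pair_index": k,
        "seed_regions": [str(c.regions.labels[i]) for i in pair],
        "seed_label": c.regions.seed_label(pair),
        "t_star": float(spec.t_star),
        "alpha": float(spec.alpha),
    }
    return f, truth


def synth_atrophy(
    spec: SyntheticSpec,
    c: Connectome,
    rng: np.random.Generator | None = None,
) -> tuple[AtrophyMap, dict]:
    """Planted t-like atrophy map: scale * f_k(t*) + Gaussian noise.

    Noise standard deviation is ``noise_sigma * max(f)``, applied before
    scaling so ``noise_sigma`` is a fraction of the profile peak.
    Returns the map and a separate ground-truth record.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    f, truth = _planted_profile(spec, c, rng)
    noisy = f + rng.normal(0.0, spec.noise_sigma * f.max(), size=c.n)
    t_like = spec.atrophy_scale * noisy
    # nominal p against a t reference with the default study's df
    df = spec.n_patients + spec.n_controls - 2
    p = np.clip(2 * scipy.stats.t.sf(np.abs(t_like), df), np.finfo(float).tiny, 1.0)
    amap = AtrophyMap(
        labels=c.regions.labels,
        t_values=t_like,
        p_values=p,
        design="synthetic",
        contrast="planted diffusion profile",
    )
    truth = dict(truth, noise_sigma=float(spec.noise_sigma), scale=float(spec.atrophy_scale))
    return amap, truth


def synth_volume_tables(
    spec: SyntheticSpec,
    c: Connectome,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeTable, VolumeTable, dict]:
    """Per-subject volume tables whose group contrast follows the planted profile.

    Controls get baseline regional means; patients lose volume in
    proportion to the planted diffusion profile, calibrated so the
    most-affected *non-seed* region loses fraction ``effect`` (the seed
    regions themselves lose more, as the origin of the spread).  Volumes
    scale with a per-subject ICV (so ICV normalization is meaningful) and
    carry multiplicative log-normal subject noise with coefficient of
    variation ``subject_cv``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    f, truth = _planted_profile(spec, c, rng)
    seed_idx = [c.regions.index_of(lab) for lab in truth["seed_regions"]]
    nonseed = np.ones(c.n, dtype=bool)
    nonseed[seed_idx] = False
    peak = f[nonseed].max()
    rel = f / peak if peak > 0 else f
    n = c.n
    base_means = rng.lognormal(np.log(4000.0), 0.5, size=n)  # mm^3 scale
    icv_ref = 1.5e6

    def _group(n_subj: int, loss: np.ndarray, prefix: str, group: str) -> VolumeTable:
        icv = icv_ref * rng.normal(1.0, 0.05, size=n_subj).clip(0.8, 1.2)
        noise = rng.lognormal(0.0, spec.subject_cv, size=(n_subj, n))
        vols = base_means[None, :] * (1.0 - loss)[None, :] * noise * (icv / icv_ref)[:, None]
        ids = [f"{prefix}{i:03d}" for i in range(n_subj)]
        return VolumeTable(
            volumes=pd.DataFrame(vols, index=pd.Index(ids, name="subject_id"),
                                 columns=c.regions.labels),
            icv=pd.Series(icv, index=pd.Index(ids, name="subject_id"), name="ICV"),
            group=group,
        )

    # seed regions may exceed the calibrated peak; cap so volumes stay positive
    patients = _group(spec.n_patients, np.clip(spec.effect * rel, 0.0, 0.9), "pat", "patients")
    controls = _group(spec.n_controls, np.zeros(n), "con", "controls")
    truth = dict(truth, effect=float(spec.effect), subject_cv=float(spec.subject_cv))
    return patients, controls, truth


def write_volume_tables(path, *tables: VolumeTable) -> None:
    """Concatenate VolumeTables into one subject x region TSV with metadata."""
    frames = []
    for v in tables:
        t = v.volumes.copy()
        t.insert(0, "ICV", v.icv)
        t.insert(0, "group", v.group)
        frames.append(t.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
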