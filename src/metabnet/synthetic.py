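"""Synthetic multi-group ROI-uptake cohorts with planted network structure.

Real FDG-PET cohorts are rarely shareable, so every downstream stage is
exercised against simulated subject×ROI tables whose statistical structure is
known exactly.  Signals are multivariate normal under a latent factor model
(covariance Σ = ΛΛᵀ + diag(ψ), positive definite by construction, unit
variances), whose factors encode:

* **segments** — three blocks of 15 regions per hemisphere sharing a segment
  factor, giving uniform within-segment covariance (clustered, segregated
  local communities); part of each segment factor is shared between the
  hemispheres, producing homotopic left–right coupling;
* **bridges** — mirrored inter-segment region pairs, each with a private
  factor.  The hemispheric gain multiplies one side's bridge loadings: at
  gain 1 bridge correlations rank below the segment tier and the thresholded
  hemispheric network stays segregated; a raised gain promotes that side's
  bridges above the segment tier, integrating its network and raising its
  global efficiency — the planted ground truth for the asymmetry analyses;
* **hubs** — two regions per hemisphere that load on *two* segment factors
  each (segments 0+1 and 1+2), making them the dominant inter-segment
  connectors and hence high-betweenness hub nodes in the whole-brain
  network.

With equal gains the two hemisphere blocks are mirror images, so any
hemispheric statistic is exchangeable under left↔right relabelling.  Age and
sex act as linear confounds on every region, to be removed by the
partial-correlation stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .roi_io import AtlasDefinition, RoiSignalTable, default_atlas, write_roi_table

__all__ = [
    "PlantedStructure",
    "CovariateModel",
    "CohortConfig",
    "CohortResult",
    "default_structure",
    "plant_asymmetry",
    "default_cohort_config",
    "generate_cohort",
    "population_correlation",
    "write_cohort",
]

# baseline uptake level and signal scale, in normalized-uptake units
BASELINE_UPTAKE = 1.0
SIGNAL_SCALE = 0.1
# minimum idiosyncratic variance: also a lower bound on covariance eigenvalues
MIN_NOISE_VAR = 0.005


@dataclass(frozen=True)
class PlantedStructure:
    """Ground-truth covariance structure over ROIs (atlas order).

    The implied covariance is ``loadings @ loadings.T + diag(noise_var)``
    with unit diagonal — a correlation matrix, positive definite whenever
    every ``noise_var`` entry is positive.  ``bridge_cols`` maps hemisphere →
    loading-column indices of that side's bridge factors, the handle used by
    :func:`plant_asymmetry`.
    """

    loadings: np.ndarray
    noise_var: np.ndarray
    hemisphere: tuple[str, ...]
    hub_nodes: tuple[int, ...] = ()
    bridge_pairs: Mapping[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    bridge_cols: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    gains: Mapping[str, float] = field(default_factory=lambda: {"L": 1.0, "R": 1.0})

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        psi = np.asarray(self.noise_var, dtype=float)
        if lam.ndim != 2 or lam.shape[0] != psi.shape[0]:
            raise ValueError("loadings and noise_var must agree on n_rois")
        if lam.shape[0] % 2:
            raise ValueError("n_rois must be even for a hemisphere split")
        if len(self.hemisphere) != lam.shape[0]:
            raise ValueError("hemisphere labels must cover every ROI")
        if psi.min() <= 0:
            i = int(np.argmin(psi))
            raise ValueError(
                f"implied covariance not positive definite: ROI {i} has "
                f"communality {1 - psi[i]:.4f} >= 1 "
                f"(smallest eigenvalue <= {psi.min():.4g})"
            )
        diag = (lam**2).sum(axis=1) + psi
        if not np.allclose(diag, 1.0):
            raise ValueError("loadings and noise_var must give unit variances")
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "noise_var", psi)

    @property
    def n_rois(self) -> int:
        return self.loadings.shape[0]

    def covariance(self) -> np.ndarray:
        """Implied correlation matrix of the latent (noise-free) signals."""
        cov = self.loadings @ self.loadings.T + np.diag(self.noise_var)
        np.fill_diagonal(cov, 1.0)
        return (cov + cov.T) / 2

    def precision(self) -> np.ndarray:
        """Inverse of the implied correlation matrix (partial-correlation view)."""
        return np.linalg.inv(self.covariance())

    @classmethod
    def from_precision(
        cls, theta: np.ndarray, hemisphere: tuple[str, ...] | None = None
    ) -> "PlantedStructure":
        """Build a structure from an explicit precision (inverse covariance).

        Off-diagonal precision entry (i, j) ≠ 0 plants a direct partial
        correlation of opposite sign between regions i and j.  The implied
        covariance is normalized to unit variances.  Intended for small
        hand-crafted patterns in tests; such structures carry no bridge
        metadata, so hemispheric gains cannot be planted on them.
        """
        theta = np.asarray(theta, dtype=float)
        if not np.allclose(theta, theta.T):
            raise ValueError("precision must be symmetric")
        eigmin = float(np.linalg.eigvalsh(theta)[0])
        if eigmin <= 0:
            raise ValueError(
                f"implied covariance not positive definite: smallest "
                f"precision eigenvalue = {eigmin:.6g}"
            )
        cov = np.linalg.inv(theta)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        # split a small idiosyncratic floor out of the diagonal so the
        # loadings/noise representation stays positive definite
        psi = np.full(len(corr), MIN_NOISE_VAR)
        lam = np.linalg.cholesky(corr - np.diag(psi))
        n = len(corr)
        if hemisphere is None:
            hemisphere = tuple("L" if i % 2 == 0 else "R" for i in range(n))
        return cls(loadings=lam, noise_var=psi, hemisphere=hemisphere)


def default_structure(
    n_rois: int = 90,
    seed: int = 12345,
    segment_var: float = 0.38,
    shared_var: float = 0.22,
    bridge_var: float = 0.12,
    n_bridges: int = 20,
    hub_var: float = 0.33,
    hub_positions: tuple[int, ...] = (5, 37),
    n_segments: int = 3,
) -> PlantedStructure:
    """Build the default mirrored two-hemisphere planted structure.

    ROIs follow the bundled atlas order (left/right interleaved: even
    positional indices are left, odd are right); within-hemisphere ring
    position ``k`` maps to atlas indices ``2k`` (left) and ``2k+1`` (right).
    Ring positions split into ``n_segments`` contiguous segments.  The same
    pattern is planted on both sides, so the hemispheres are exchangeable
    until :func:`plant_asymmetry` raises one side's bridge gain.

    Variances are communality shares per ROI: ``segment_var`` the segment
    factor (of which ``shared_var`` is shared across hemispheres),
    ``bridge_var`` a bridge endpoint's base loading share, ``hub_var`` a
    hub's share per joined segment.
    """
    if n_rois % 2:
        raise ValueError("n_rois must be even")
    m = n_rois // 2
    if m % n_segments:
        raise ValueError(f"{m} ROIs per hemisphere not divisible into {n_segments} segments")
    seg_size = m // n_segments
    seg_of = lambda k: k // seg_size  # noqa: E731
    rng = np.random.default_rng(seed)
    atlas_idx = {"L": [2 * k for k in range(m)], "R": [2 * k + 1 for k in range(m)]}
    for p in hub_positions:
        if not 0 <= p < m:
            raise ValueError(f"hub position {p} outside hemisphere ring")

    # mirrored inter-segment bridge pairs, one bridge per node, hubs excluded
    bridges: list[tuple[int, int]] = []
    busy = set(hub_positions)
    tries = 0
    while len(bridges) < n_bridges and tries < 100_000:
        tries += 1
        a, b = sorted(rng.integers(0, m, size=2).tolist())
        if seg_of(a) == seg_of(b) or a in busy or b in busy:
            continue
        bridges.append((a, b))
        busy.update((a, b))
    if len(bridges) < n_bridges:
        raise ValueError(f"could only place {len(bridges)} of {n_bridges} bridges")

    n_factors = 2 * n_segments + n_segments + 2 * n_bridges
    lam = np.zeros((n_rois, n_factors))
    own_var = segment_var - shared_var
    own_col = {"L": lambda s: s, "R": lambda s: n_segments + s}
    shared_col = lambda s: 2 * n_segments + s  # noqa: E731

    for side in ("L", "R"):
        for k in range(m):
            if k in hub_positions:
                continue
            i = atlas_idx[side][k]
            s = seg_of(k)
            lam[i, own_col[side](s)] = np.sqrt(own_var)
            lam[i, shared_col(s)] = np.sqrt(shared_var)

    # hubs: members of two adjacent segments at hub_var communality each
    hub_scale = np.sqrt(hub_var / segment_var)
    hubs: list[int] = []
    for side in ("L", "R"):
        for p in hub_positions:
            h = atlas_idx[side][p]
            hubs.append(h)
            s = seg_of(p)
            joined = (s, s + 1) if s < n_segments - 1 else (s - 1, s)
            for s_ in joined:
                lam[h, own_col[side](s_)] = hub_scale * np.sqrt(own_var)
                lam[h, shared_col(s_)] = hub_scale * np.sqrt(shared_var)

    bridge_pairs: dict[str, tuple[tuple[int, int], ...]] = {}
    bridge_cols: dict[str, tuple[int, ...]] = {}
    col = 3 * n_segments
    for side in ("L", "R"):
        pairs, cols = [], []
        for a, b in bridges:
            i, j = atlas_idx[side][a], atlas_idx[side][b]
            lam[i, col] = np.sqrt(bridge_var)
            lam[j, col] = np.sqrt(bridge_var)
            pairs.append((min(i, j), max(i, j)))
            cols.append(col)
            col += 1
        bridge_pairs[side] = tuple(pairs)
        bridge_cols[side] = tuple(cols)

    psi = 1.0 - (lam**2).sum(axis=1)
    return PlantedStructure(
        loadings=lam,
        noise_var=psi,
        hemisphere=tuple("L" if i % 2 == 0 else "R" for i in range(n_rois)),
        hub_nodes=tuple(sorted(hubs)),
        bridge_pairs=bridge_pairs,
        bridge_cols=bridge_cols,
    )


def plant_asymmetry(
    structure: PlantedStructure, gain: float, side: str = "R"
) -> PlantedStructure:
    """Scale one hemisphere's bridge loadings by ``gain``.

    Bridge *correlations* scale as gain²: gain 1 leaves the structure
    unchanged; a raised gain promotes that side's inter-segment bridges above
    the segment correlation tier, so the thresholded hemispheric network
    integrates and its global efficiency exceeds the other side's.  Applying
    gain g then 1/g restores the original exactly.  A gain that drives any
    region's communality to 1 (breaking positive definiteness) is rejected.
    """
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    if gain == 1.0:
        return structure
    cols = structure.bridge_cols.get(side, ())
    if not cols:
        raise ValueError("structure carries no bridge factors for gain planting")
    lam = structure.loadings.copy()
    lam[:, list(cols)] *= gain
    psi = 1.0 - (lam**2).sum(axis=1)
    if psi.min() <= MIN_NOISE_VAR:
        i = int(np.argmin(psi))
        raise ValueError(
            f"gain {gain} breaks positive definiteness: ROI {i} communality "
            f"{1 - psi[i]:.4f} (noise variance floor {MIN_NOISE_VAR})"
        )
    gains = dict(structure.gains)
    gains[side] = gains.get(side, 1.0) * gain
    return replace(structure, loadings=lam, noise_var=psi, gains=gains)


@dataclass(frozen=True)
class CovariateModel:
    """Linear age/sex confounding of ROI signals.

    ``age_coef`` is uptake units per year (applied to age − ``age_center``);
    ``sex_coef`` the uptake offset for sex = 1.  Scalars apply uniformly to
    every region.
    """

    age_range: tuple[float, float] = (55.0, 75.0)
    sex_p: float = 0.5
    age_coef: float = -0.003
    sex_coef: float = 0.02
    age_center: float = 65.0


@dataclass(frozen=True)
class CohortConfig:
    group_specs: tuple[tuple[str, int], ...]
    network_spec: Mapping[str, PlantedStructure]
    seed: int = 0
    n_rois: int = 90
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for label, n in self.group_specs:
            if n < 5:
                raise ValueError(f"group {label!r} has n={n} < 5 subjects")
        if self.n_rois % 2:
            raise ValueError("n_rois must be even")
        for label, _ in self.group_specs:
            if label not in self.network_spec:
                raise ValueError(f"no planted structure for group {label!r}")
            if self.network_spec[label].n_rois != self.n_rois:
                raise ValueError(f"structure for {label!r} has wrong n_rois")


@dataclass
class CohortResult:
    """Generated tables plus the ground truth they were drawn from."""

    tables: dict[str, RoiSignalTable]
    truth: dict[str, PlantedStructure]
    config: CohortConfig


def default_cohort_config(
    seed: int = 0, n_per_group: Mapping[str, int] | None = None
) -> CohortConfig:
    """The four-group study layout: HC/AD/PDD/DLB with n = 22/22/18/22.

    Disease groups carry planted hemispheric imbalance of inter-segment
    bridge connectivity: rightward in AD (gain 1.6) and DLB (gain 2.0),
    leftward in PDD (gain 1.6); HC is symmetric.
    """
    sizes = {"HC": 22, "AD": 22, "PDD": 18, "DLB": 22}
    if n_per_group:
        sizes.update(n_per_group)
    base = default_structure()
    spec = {
        "HC": base,
        "AD": plant_asymmetry(base, 1.6, "R"),
        "PDD": plant_asymmetry(base, 1.6, "L"),
        "DLB": plant_asymmetry(base, 2.0, "R"),
    }
    groups = tuple((g, sizes[g]) for g in ("HC", "AD", "PDD", "DLB"))
    return CohortConfig(group_specs=groups, network_spec=spec, seed=seed)


def population_correlation(
    structure: PlantedStructure,
    noise_sd: float = 0.0,
    signal_scale: float = SIGNAL_SCALE,
) -> np.ndarray:
    """Population correlation of the generated signals, measurement noise included."""
    total = signal_scale**2 * structure.covariance()
    total += noise_sd**2 * np.eye(structure.n_rois)
    d = np.sqrt(np.diag(total))
    out = total / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def generate_cohort(
    config: CohortConfig, atlas: AtlasDefinition | None = None
) -> CohortResult:
    """Draw the cohort: one subject×ROI table per group, ground truth alongside.

    Signals are ``baseline + scale·(z_f Λᵀ + √ψ ε) + covariate effects +
    measurement noise`` with Λ, ψ the group's planted factor loadings and
    idiosyncratic variances.  Output is byte-identical under a fixed config
    seed.
    """
    if atlas is None:
        atlas = default_atlas()
    if atlas.n_rois != config.n_rois:
        raise ValueError(
            f"atlas has {atlas.n_rois} ROIs but config expects {config.n_rois}"
        )
    roi_names = atlas.abbreviations
    cm = config.covariate_model
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.group_specs))
    tables: dict[str, RoiSignalTable] = {}
    for (label, n), ss in zip(config.group_specs, seeds):
        rng = np.random.default_rng(ss)
        structure = config.network_spec[label]
        lam, psi = structure.loadings, structure.noise_var
        age = rng.uniform(*cm.age_range, size=n)
        sex = (rng.random(n) < cm.sex_p).astype(int)
        z_f = rng.standard_normal((n, lam.shape[1]))
        z_i = rng.standard_normal((n, config.n_rois))
        latent = z_f @ lam.T + np.sqrt(psi) * z_i
        signals = BASELINE_UPTAKE + SIGNAL_SCALE * latent
        signals += np.outer(cm.age_coef * (age - cm.age_center), np.ones(config.n_rois))
        signals += np.outer(cm.sex_coef * sex, np.ones(config.n_rois))
        signals += config.noise_sd * rng.standard_normal((n, config.n_rois))
        df = pd.DataFrame(signals, columns=roi_names)
        df.insert(0, "sex", sex)
        df.insert(0, "age", np.round(age, 6))
        df.insert(0, "group", label)
        df.insert(0, "subject_id", [f"{label}_{i:03d}" for i in range(n)])
        tables[label] = RoiSignalTable(df, roi_names=list(roi_names))
    return CohortResult(tables=tables, truth=dict(config.network_spec), config=config)


def write_cohort(result: CohortResult, out_dir: str | Path) -> list[Path]:
    """Write each group's table plus ground-truth sidecars; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for label, table in result.tables.items():
        p = out / f"cohort_{label}.csv"
        write_roi_table(table, p)
        written.append(p)
        structure = result.truth[label]
        mp = out / f"truth_{label}_covariance.txt"
        np.savetxt(mp, structure.covariance(), fmt="%.8g")
        meta = {
            "group": label,
            "hub_nodes": list(structure.hub_nodes),
            "gains": dict(structure.gains),
            "bridge_pairs": {
                s: [list(p_) for p_ in prs]
                for s, prs in structure.bridge_pairs.items()
            },
        }
        jp = out / f"truth_{label}.json"
        jp.write_text(json.dumps(meta, indent=1))
        written.extend([mp, jp])
    return written
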