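"""Seed-based correlation analysis with Fisher r-to-z group comparison.

For a chosen seed region, the Pearson correlation of the seed's uptake with
every other region is computed per group across subjects, variance-stabilized
with Fisher's r-to-z transform

    z = ½ · ln((1 + r)/(1 − r)),

and two groups are compared per target with the standard two-sample statistic

    Z = (z₁ − z₂) / sqrt(1/(n₁ − 3) + 1/(n₂ − 3)),

referred to the standard normal (two-tailed).  Benjamini–Hochberg FDR
controls the 89 simultaneous target comparisons.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import _residualize
from .roi_io import RoiSignalTable

__all__ = ["fisher_z", "seed_map", "compare_groups", "fdr_correct", "seed_comparison_table"]

DEFAULT_SEED_ROI = "MTG.R"


def fisher_z(r):
    """Fisher r-to-z transform, natural log; requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = 0.5 * np.log((1 + r) / (1 - r))
    return float(out) if out.ndim == 0 else out


def seed_map(
    table: RoiSignalTable,
    seed_roi: str = DEFAULT_SEED_ROI,
    covariates: Sequence[str] | None = None,
) -> pd.Series:
    """Correlation of the seed region with every other region across subjects.

    Plain Pearson by default; passing covariate names residualizes both seed
    and targets first.  Returns a Series indexed by target ROI.  Targets that
    duplicate the seed (|r| = 1) are kept in the map but flagged by the
    caller before the z-transform.
    """
    if seed_roi not in table.roi_names:
        raise ValueError(f"seed ROI {seed_roi!r} not in table")
    if table.n_subjects < 5:
        raise ValueError("need at least 5 subjects for a seed map")
    sig = table.signals
    if covariates:
        sig = _residualize(sig, table.covariate_matrix(list(covariates)))
    k = table.roi_names.index(seed_roi)
    seed_sig = sig[:, k]
    if seed_sig.std() == 0:
        raise ValueError(f"seed ROI {seed_roi!r} has zero variance")
    sd = sig.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zs = (sig - sig.mean(axis=0)) / sd
    zseed = (seed_sig - seed_sig.mean()) / seed_sig.std()
    r = zs.T @ zseed / table.n_subjects
    r = np.clip(r, -1.0, 1.0)
    targets = [n for n in table.roi_names if n != seed_roi]
    idx = [i for i, n in enumerate(table.roi_names) if n != seed_roi]
    return pd.Series(r[idx], index=targets, name=f"r({seed_roi})")


def compare_groups(
    z_map1: pd.Series, n1: int, z_map2: pd.Series, n2: int
) -> pd.DataFrame:
    """Two-sample Fisher-z comparison per target: Z statistic and two-tailed p.

    Z is antisymmetric under swapping the groups; p is unchanged.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need n > 3")
    if list(z_map1.index) != list(z_map2.index):
        raise ValueError("z maps must share identical targets")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z_map1.to_numpy() - z_map2.to_numpy()) / se
    p = 2 * stats.norm.sf(np.abs(z_stat))
    return pd.DataFrame({"Z": z_stat, "p": p}, index=z_map1.index)


def fdr_correct(pvalues, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (discovery flags, adjusted q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return flags, q


def seed_comparison_table(
    table1: RoiSignalTable,
    table2: RoiSignalTable,
    seed_roi: str = DEFAULT_SEED_ROI,
    covariates: Sequence[str] | None = None,
    q_level: float = 0.05,
    group_labels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full seed analysis for a group pair: r, z per group; Z, p, q, direction.

    Targets with a degenerate |r| = 1 in either group are excluded from the
    z comparison (reported with NaN statistics).
    """
    r1, r2 = seed_map(table1, seed_roi, covariates), seed_map(table2, seed_roi, covariates)
    ok = (np.abs(r1) < 1) & (np.abs(r2) < 1)
    z1 = pd.Series(np.where(ok, 0.5 * np.log((1 + r1) / (1 - r1)), np.nan), index=r1.index)
    z2 = pd.Series(np.where(ok, 0.5 * np.log((1 + r2) / (1 - r2)), np.nan), index=r2.index)
    cmp = compare_groups(z1[ok], table1.n_subjects, z2[ok], table2.n_subjects)
    flags, q = fdr_correct(cmp["p"].to_numpy(), q_level)
    out = pd.DataFrame(
        {"r1": r1, "r2": r2, "z1": z1, "z2": z2, "Z": np.nan, "p": np.nan, "q": np.nan}
    )
    out.loc[cmp.index, "Z"] = cmp["Z"]
    out.loc[cmp.index, "p"] = cmp["p"]
    out.loc[cmp.index, "q"] = q
    out["significant"] = False
    out.loc[cmp.index, "significant"] = flags
    out["direction"] = np.where(
        out["significant"] & (out["Z"] > 0), "strengthened",
        np.where(out["significant"] & (out["Z"] < 0), "weakened", "none"),
    )
    if group_labels:
        out.insert(0, "group_pair", f"{group_labels[0]}_vs_{group_labels[1]}")
    out.index.name = "target_roi"
    return out
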