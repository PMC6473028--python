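"""Hemispheric network asymmetry of global and local efficiency.

Each hemisphere's 45-region network is built independently (partial
correlation, binarized at a common sparsity) and its global and local
efficiencies M_L and M_R compared.  The asymmetry index

    AI = 200 · |M_R − M_L| / (M_R + M_L)

is a percent-scaled imbalance: non-negative, zero iff the hemispheres match,
and invariant to a common rescaling of both efficiencies.

Two resampling schemes back the within-group inference:

* a **hemisphere-swap permutation test** (default) — each subject's left and
  right homologous ROI vectors are independently swapped with probability ½,
  which leaves the data distribution invariant under the null hypothesis
  that the hemispheres are exchangeable; the two-tailed p-value for
  M_R − M_L is exact up to Monte-Carlo error;
* **bootstrap resampling** of subjects (with replacement), which yields
  sampling distributions of M_L, M_R and AI — these feed the between-group
  Welch t-test on AI — and, optionally, a crossing-based within-group
  p-value (conservative for threshold-network statistics, hence not the
  default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import _pcorr
from .metrics import efficiencies
from .network import binarize_at_sparsity
from .roi_io import AtlasDefinition, RoiSignalTable, default_atlas

__all__ = [
    "AsymmetryResult",
    "split_hemispheres",
    "hemispheric_efficiencies",
    "asymmetry_index",
    "within_group_test",
    "compare_ai_between_groups",
]

DEFAULT_SPARSITY = 0.28


def split_hemispheres(
    table: RoiSignalTable, atlas: AtlasDefinition | None = None
) -> tuple[RoiSignalTable, RoiSignalTable]:
    """Split a whole-brain table into (left, right) hemisphere tables.

    Subjects are unchanged; each output carries that hemisphere's ROI columns
    in atlas order.  Requires a balanced hemisphere split.
    """
    if atlas is None:
        atlas = default_atlas()
    unknown = [n for n in table.roi_names if n not in atlas.abbreviations]
    if unknown:
        raise ValueError(f"ROIs without atlas hemisphere labels: {unknown}")
    side_of = dict(zip(atlas.entries["abbreviation"], atlas.entries["hemisphere"]))
    left = [n for n in table.roi_names if side_of[n] == "L"]
    right = [n for n in table.roi_names if side_of[n] == "R"]
    if len(left) != len(right):
        raise ValueError(f"unbalanced hemispheres: {len(left)} L vs {len(right)} R")
    return table.subset_rois(left), table.subset_rois(right)


def _hemi_efficiencies(
    signals: np.ndarray, design: np.ndarray, sparsity: float
) -> tuple[float, float]:
    corr = _pcorr(signals, design)
    adj = binarize_at_sparsity(corr, sparsity)
    return efficiencies(adj)


def hemispheric_efficiencies(
    left: RoiSignalTable,
    right: RoiSignalTable,
    covariates: Sequence[str] = ("age", "sex"),
    sparsity: float = DEFAULT_SPARSITY,
) -> dict[str, tuple[float, float]]:
    """Efficiencies per hemisphere: {'Eglob': (M_L, M_R), 'Eloc': (M_L, M_R)}.

    Each hemisphere's partial-correlation network is built independently and
    binarized at the same sparsity.  Disconnected hemispheric networks are
    allowed (disconnected pairs contribute 0 to efficiency); an edgeless one
    triggers a warning.
    """
    if left.n_subjects != right.n_subjects:
        raise ValueError("hemisphere tables must come from the same subjects")
    covariates = list(covariates)
    eg_l, el_l = _hemi_efficiencies(left.signals, left.covariate_matrix(covariates), sparsity)
    eg_r, el_r = _hemi_efficiencies(right.signals, right.covariate_matrix(covariates), sparsity)
    if eg_l == 0 or eg_r == 0:
        warnings.warn("a hemispheric network is edgeless; efficiencies are zero")
    return {"Eglob": (eg_l, eg_r), "Eloc": (el_l, el_r)}


def asymmetry_index(m_r: float, m_l: float) -> float:
    """AI = 200·|M_R − M_L|/(M_R + M_L); requires non-negative inputs, not both zero."""
    if m_r < 0 or m_l < 0:
        raise ValueError("efficiencies must be non-negative")
    if m_r + m_l == 0:
        raise ValueError("both efficiencies are zero; AI undefined")
    return 200.0 * abs(m_r - m_l) / (m_r + m_l)


@dataclass
class AsymmetryResult:
    """Hemispheric efficiencies, AI, and resampling results for one group."""

    group_label: str
    sparsity: float
    m_l: dict[str, float]  # metric -> left-hemisphere efficiency
    m_r: dict[str, float]
    ai: dict[str, float]
    p_within: dict[str, float]
    direction: dict[str, str]  # leftward / rightward / none
    distributions: dict[str, pd.DataFrame]  # metric -> bootstrap M_L, M_R, AI
    n_rep: int
    seed: int
    alpha: float
    method: str = "swap"
    n_redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.m_l:
            rows.append({
                "group": self.group_label, "metric": metric,
                "M_L": self.m_l[metric], "M_R": self.m_r[metric],
                "AI": self.ai[metric], "p_within": self.p_within[metric],
                "direction": self.direction[metric],
            })
        return pd.DataFrame(rows)


def within_group_test(
    table: RoiSignalTable,
    atlas: AtlasDefinition | None = None,
    covariates: Sequence[str] = ("age", "sex"),
    sparsity: float = DEFAULT_SPARSITY,
    n_rep: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "swap",
    with_bootstrap: bool = True,
    max_redraws: int = 100,
) -> AsymmetryResult:
    """Resampling test of left-vs-right network efficiency within one group.

    With ``method='swap'`` (default) the p-value comes from ``n_rep``
    hemisphere-swap permutations: each permutation independently relabels
    every subject's homologous left/right ROI pairs with probability ½ and
    recomputes M_R − M_L, giving an exact test of hemispheric
    exchangeability (two-tailed, add-one smoothed).  With
    ``method='bootstrap'`` the p-value is the two-tailed crossing fraction
    of the bootstrap distribution of M_R − M_L.

    Bootstrap resamples of subjects (with replacement, original n) are drawn
    either way when ``with_bootstrap`` is set, yielding the M_L/M_R/AI
    distributions used by :func:`compare_ai_between_groups`.  A resample
    producing a zero-variance ROI is redrawn (count recorded).
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    if method not in ("swap", "bootstrap"):
        raise ValueError("method must be 'swap' or 'bootstrap'")
    left, right = split_hemispheres(table, atlas)
    covariates = list(covariates)
    sig_l, sig_r = left.signals, right.signals
    design = left.covariate_matrix(covariates)
    n = table.n_subjects

    point = hemispheric_efficiencies(left, right, covariates, sparsity)
    rng = np.random.default_rng(seed)

    need_boot = with_bootstrap or method == "bootstrap"
    boot_rows: dict[str, list[tuple[float, float]]] = {"Eglob": [], "Eloc": []}
    redraws = 0
    if need_boot:
        for _ in range(n_rep):
            for _attempt in range(max_redraws):
                idx = rng.integers(0, n, size=n)
                sl, sr, d = sig_l[idx], sig_r[idx], design[idx]
                degenerate = (sl.std(axis=0) == 0).any() or (sr.std(axis=0) == 0).any()
                # a resample may also make a covariate constant (e.g. all one sex)
                degenerate = degenerate or (d.size and (d.std(axis=0) == 0).any())
                if degenerate:
                    redraws += 1
                    continue
                break
            else:
                raise RuntimeError("could not draw a resample without zero-variance ROIs")
            boot_rows["Eglob"].append(
                (_hemi_efficiencies(sl, d, sparsity)[0], _hemi_efficiencies(sr, d, sparsity)[0])
            )
            boot_rows["Eloc"].append(
                (_hemi_efficiencies(sl, d, sparsity)[1], _hemi_efficiencies(sr, d, sparsity)[1])
            )

    p_within: dict[str, float] = {}
    if method == "swap":
        obs = {m: point[m][1] - point[m][0] for m in ("Eglob", "Eloc")}
        exceed = {m: 0 for m in obs}
        for _ in range(n_rep):
            flip = rng.random(n) < 0.5
            sl = np.where(flip[:, None], sig_r, sig_l)
            sr = np.where(flip[:, None], sig_l, sig_r)
            eg_l, el_l = _hemi_efficiencies(sl, design, sparsity)
            eg_r, el_r = _hemi_efficiencies(sr, design, sparsity)
            if abs(eg_r - eg_l) >= abs(obs["Eglob"]):
                exceed["Eglob"] += 1
            if abs(el_r - el_l) >= abs(obs["Eloc"]):
                exceed["Eloc"] += 1
        for m in obs:
            p_within[m] = (1 + exceed[m]) / (1 + n_rep)
    else:
        for m in ("Eglob", "Eloc"):
            arr = np.asarray(boot_rows[m])
            diff = arr[:, 1] - arr[:, 0]
            p = 2.0 * (min((diff <= 0).sum(), (diff >= 0).sum()) + 1) / (n_rep + 1)
            p_within[m] = min(p, 1.0)

    m_l, m_r, ai, direction, dists = {}, {}, {}, {}, {}
    for metric in ("Eglob", "Eloc"):
        ml, mr = point[metric]
        m_l[metric], m_r[metric] = ml, mr
        ai[metric] = asymmetry_index(mr, ml)
        if p_within[metric] < alpha:
            direction[metric] = "rightward" if mr > ml else "leftward"
        else:
            direction[metric] = "none"
        if need_boot:
            arr = np.asarray(boot_rows[metric])
            dists[metric] = pd.DataFrame({
                "M_L": arr[:, 0], "M_R": arr[:, 1],
                "AI": 200.0 * np.abs(arr[:, 1] - arr[:, 0]) / (arr[:, 0] + arr[:, 1]),
            })
    return AsymmetryResult(
        group_label=_label(table), sparsity=sparsity, m_l=m_l, m_r=m_r, ai=ai,
        p_within=p_within, direction=direction, distributions=dists,
        n_rep=n_rep, seed=seed, alpha=alpha, method=method, n_redraws=redraws,
    )


def _label(table: RoiSignalTable) -> str:
    g = table.data["group"].unique()
    return str(g[0]) if len(g) == 1 else "?"


def compare_ai_between_groups(
    result_a: AsymmetryResult, result_b: AsymmetryResult, metric: str = "Eglob"
) -> tuple[float, float]:
    """Welch two-sample t-test on the two groups' AI bootstrap distributions.

    Returns (t, two-tailed p); t is antisymmetric under swapping the groups.
    """
    if metric not in result_a.distributions or metric not in result_b.distributions:
        raise ValueError("both results need bootstrap distributions (with_bootstrap=True)")
    a = result_a.distributions[metric]["AI"].to_numpy()
    b = result_b.distributions[metric]["AI"].to_numpy()
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("both AI distributions are degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
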