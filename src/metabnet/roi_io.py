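"""Atlas definitions, ROI signal tables, and ROI mean extraction from label volumes.

The atlas follows the Automated Anatomical Labeling (AAL) convention with the
cerebellum excluded: 90 cerebral regions, 45 per hemisphere, with side encoded
by an ``.L``/``.R`` abbreviation suffix.  Subject data are held as a
:class:`RoiSignalTable` — one row per subject, one column of mean tracer
uptake per region, plus ``subject_id``, ``group``, ``age`` and ``sex``
covariate columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtlasDefinition",
    "RoiSignalTable",
    "ZeroVarianceWarning",
    "default_atlas",
    "load_atlas",
    "extract_roi_means",
    "read_roi_table",
    "write_roi_table",
]

COVARIATE_COLUMNS = ("subject_id", "group", "age", "sex")


class ZeroVarianceWarning(UserWarning):
    """A region has zero variance within a group; correlations involving it are undefined."""


@dataclass(frozen=True)
class AtlasDefinition:
    """A parcellation: ROI integer labels, abbreviations, names and hemispheres."""

    entries: pd.DataFrame  # columns: roi_id, abbreviation, name, hemisphere

    def __post_init__(self) -> None:
        df = self.entries
        required = {"roi_id", "abbreviation", "name", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        dup = df["roi_id"][df["roi_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate roi_id values: {sorted(set(dup))}")
        dup_abbr = df["abbreviation"][df["abbreviation"].duplicated()]
        if len(dup_abbr):
            raise ValueError(f"duplicate abbreviations: {sorted(set(dup_abbr))}")
        bad = set(df["hemisphere"]) - {"L", "R"}
        if bad:
            rows = df.index[df["hemisphere"].isin(bad)].tolist()
            raise ValueError(f"unknown hemisphere codes {sorted(bad)} at rows {rows}")

    @property
    def n_rois(self) -> int:
        return len(self.entries)

    @property
    def abbreviations(self) -> list[str]:
        return self.entries["abbreviation"].tolist()

    @property
    def roi_ids(self) -> np.ndarray:
        return self.entries["roi_id"].to_numpy()

    def hemisphere_indices(self, side: str) -> np.ndarray:
        """Positional indices (atlas order) of the ROIs on one side, 'L' or 'R'."""
        if side not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {side!r}")
        return np.flatnonzero((self.entries["hemisphere"] == side).to_numpy())

    def split_hemispheres(self) -> tuple["AtlasDefinition", "AtlasDefinition"]:
        """Return (left, right) sub-atlases; requires an even split."""
        left = self.entries[self.entries["hemisphere"] == "L"].reset_index(drop=True)
        right = self.entries[self.entries["hemisphere"] == "R"].reset_index(drop=True)
        if len(left) != len(right):
            raise ValueError(
                f"unbalanced hemispheres: {len(left)} left vs {len(right)} right ROIs"
            )
        return AtlasDefinition(left), AtlasDefinition(right)


def default_atlas() -> AtlasDefinition:
    """The bundled 90-region AAL-style atlas (cerebellum excluded)."""
    with resources.files("metabnet.data").joinpath("aal90.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return AtlasDefinition(df)


def load_atlas(path: str | Path) -> AtlasDefinition:
    """Read an atlas definition from delimited text (comma or tab, sniffed).

    Requires ``roi_id`` and ``abbreviation`` columns.  When no explicit
    ``hemisphere`` column is present the side is parsed from a trailing
    ``.L``/``.R`` on the abbreviation.  A missing ``name`` column is filled
    from the abbreviation.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "roi_id" not in df.columns or "abbreviation" not in df.columns:
        raise ValueError(f"{path}: atlas file needs 'roi_id' and 'abbreviation' columns")
    if "hemisphere" not in df.columns:
        suffix = df["abbreviation"].str.rsplit(".", n=1).str[-1]
        bad = ~suffix.isin(["L", "R"])
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValueError(
                f"{path}: cannot infer hemisphere from abbreviation at rows {rows}"
            )
        df = df.assign(hemisphere=suffix)
    if "name" not in df.columns:
        df = df.assign(name=df["abbreviation"])
    return AtlasDefinition(df[["roi_id", "abbreviation", "name", "hemisphere"]].copy())


@dataclass
class RoiSignalTable:
    """Per-subject mean uptake per ROI with subject covariates.

    ``data`` holds one row per subject: the covariate columns of
    :data:`COVARIATE_COLUMNS` followed by one numeric column per ROI, in
    atlas order.
    """

    data: pd.DataFrame
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roi_names:
            self.roi_names = [c for c in self.data.columns if c not in COVARIATE_COLUMNS]
        missing = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"table missing covariate columns: {missing}")
        sig = self.data[self.roi_names]
        non_numeric = [c for c in self.roi_names if not np.issubdtype(sig[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric signal columns: {non_numeric}")
        if sig.isna().any().any():
            bad = [c for c in self.roi_names if sig[c].isna().any()]
            raise ValueError(f"missing signal values in columns: {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def signals(self) -> np.ndarray:
        """Subjects × ROIs signal matrix (float64)."""
        return self.data[self.roi_names].to_numpy(dtype=float)

    def covariate_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        """Numeric design columns for the named covariates (no intercept)."""
        cols = []
        for name in covariates:
            if name not in self.data.columns:
                raise ValueError(f"unknown covariate {name!r}")
            cols.append(pd.to_numeric(self.data[name]).to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((self.n_subjects, 0))

    def subset_rois(self, names: Sequence[str]) -> "RoiSignalTable":
        keep = list(COVARIATE_COLUMNS) + list(names)
        return RoiSignalTable(self.data[keep].copy(), roi_names=list(names))

    def flag_zero_variance(self) -> list[str]:
        """Names of ROIs with zero variance; emits a :class:`ZeroVarianceWarning`."""
        sig = self.signals
        flat = [n for n, v in zip(self.roi_names, sig.var(axis=0)) if v == 0]
        if flat:
            warnings.warn(
                f"zero-variance ROIs: {flat}", ZeroVarianceWarning, stacklevel=2
            )
        return flat


def read_roi_table(path: str | Path, atlas: AtlasDefinition) -> RoiSignalTable:
    """Read a subject×ROI table and validate it against an atlas.

    Signal columns may appear in any order; they are reordered to atlas order.
    Group labels are preserved verbatim.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing_cov = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing_cov:
        raise ValueError(f"{path}: missing covariate columns {missing_cov}")
    missing_roi = [a for a in atlas.abbreviations if a not in df.columns]
    if missing_roi:
        raise ValueError(f"{path}: missing ROI columns {missing_roi}")
    ordered = df[list(COVARIATE_COLUMNS) + atlas.abbreviations].copy()
    table = RoiSignalTable(ordered, roi_names=atlas.abbreviations)
    table.flag_zero_variance()
    return table


def write_roi_table(table: RoiSignalTable, path: str | Path) -> None:
    """Write a table as comma-delimited UTF-8 text."""
    table.data.to_csv(path, index=False)


def extract_roi_means(
    image: np.ndarray,
    labels: np.ndarray,
    atlas: AtlasDefinition,
    normalize: str | None = None,
) -> np.ndarray:
    """Mean image intensity per atlas ROI from an integer label volume.

    ``image`` and ``labels`` must share shape; voxels labelled 0 are ignored.
    Returns one mean per atlas entry, in atlas order.  Accepts arrays or
    nibabel images (anything with ``get_fdata``).  ``normalize='global-mean'``
    divides by the mean intensity over all labelled voxels (per-subject
    intensity scaling); default is no normalization.
    """
    if hasattr(image, "get_fdata"):
        image = image.get_fdata()
    if hasattr(labels, "get_fdata"):
        labels = np.rint(labels.get_fdata()).astype(np.int64)
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label volume must be integer-valued")
    if image.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs labels {labels.shape}"
        )
    flat_labels = labels.ravel()
    flat_image = image.ravel()
    n = int(flat_labels.max()) + 1
    counts = np.bincount(flat_labels, minlength=n)
    sums = np.bincount(flat_labels, weights=flat_image, minlength=n)
    means = np.empty(atlas.n_rois)
    for k, roi_id in enumerate(atlas.roi_ids):
        if roi_id >= n or counts[roi_id] == 0:
            raise ValueError(f"roi_id {roi_id} absent from label volume")
        means[k] = sums[roi_id] / counts[roi_id]
    if normalize is not None:
        if normalize != "global-mean":
            raise ValueError(f"unknown normalization {normalize!r}")
        labelled = flat_labels > 0
        means = means / (flat_image[labelled].mean())
    return means
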