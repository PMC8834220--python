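"""Spectra containers, CSV I/O and wavenumber/wavelength conversion.

The instrument grid convention is FT-NIR style: wavenumbers in cm^-1 stored
in *descending* order (12,000 -> 4000 cm^-1).  Readers accept either
orientation as long as the grid is strictly monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "wn_to_nm",
    "nm_to_wn",
    "average_replicates",
]


@dataclass
class SpectraSet:
    """A set of spectra sharing one wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly monotone (either direction).
    absorbance
        Matrix of shape ``(n_samples, len(grid))``.
    sample_ids
        Unique sample identifiers, one per row.
    meta
        Per-sample metadata indexed like ``sample_ids`` (block, bag,
        face index, berry_id, ...).  May be empty.
    """

    grid: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.grid.ndim != 1:
            raise ValueError("grid must be one-dimensional")
        d = np.diff(self.grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be strictly monotone")
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} spectra rows"
            )
        if p != self.grid.size:
            raise ValueError(
                f"absorbance has {p} columns but grid has {self.grid.size} points"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")
        if self.meta is None or len(self.meta) == 0:
            self.meta = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = pd.Index(self.sample_ids, name="sample_id")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def copy_with(self, absorbance: np.ndarray | None = None) -> "SpectraSet":
        return SpectraSet(
            grid=self.grid.copy(),
            absorbance=(self.absorbance if absorbance is None else absorbance).copy(),
            sample_ids=list(self.sample_ids),
            meta=self.meta.copy(),
        )

    def select_rows(self, index: np.ndarray) -> "SpectraSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            grid=self.grid.copy(),
            absorbance=self.absorbance[index],
            sample_ids=[self.sample_ids[i] for i in index],
            meta=self.meta.iloc[index],
        )


def _meta_path(path: str) -> str:
    return str(path) + ".meta.csv" if not str(path).endswith(".csv") else str(path)[:-4] + ".meta.csv"


def write_spectra(spectra: SpectraSet, path: str) -> None:
    """Write a wide CSV: first column ``sample_id``, then one column per
    wavenumber.  Non-trivial metadata goes to a ``<stem>.meta.csv`` sidecar.
    """
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[repr(float(w)) for w in spectra.grid],
    )
    df.to_csv(path)  # default repr: shortest exact round-trip form
    if spectra.meta.shape[1] > 0:
        spectra.meta.to_csv(_meta_path(path))


def read_spectra(path: str) -> SpectraSet:
    """Read a wide spectra CSV written by :func:`write_spectra`.

    Raises
    ------
    ValueError
        On duplicate sample ids, a duplicated or non-numeric wavenumber
        header, or ragged/non-finite rows.
    """
    # validate the raw header first: pandas silently renames duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    grid = []
    for col in header:
        try:
            grid.append(float(col))
        except ValueError as exc:
            raise ValueError(f"non-numeric wavenumber header {col!r}") from exc
    grid = np.asarray(grid)
    if len(np.unique(grid)) != grid.size:
        dup = grid[pd.Index(grid).duplicated()][0]
        raise ValueError(f"duplicated wavenumber header {dup!r}")
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        raise ValueError("ragged or missing values in spectra table")
    meta = pd.DataFrame()
    import os

    mp = _meta_path(path)
    if os.path.exists(mp):
        meta = pd.read_csv(mp, index_col=0)
    return SpectraSet(
        grid=grid,
        absorbance=df.to_numpy(dtype=float),
        sample_ids=[str(i) for i in df.index],
        meta=meta,
    )


def wn_to_nm(wavenumber):
    """Convert wavenumber (cm^-1) to wavelength (nm): lambda = 1e7 / nu."""
    wavenumber = np.asarray(wavenumber, dtype=float)
    if np.any(wavenumber <= 0):
        raise ValueError("wavenumber must be positive")
    out = 1e7 / wavenumber
    return float(out) if out.ndim == 0 else out


def nm_to_wn(wavelength):
    """Convert wavelength (nm) to wavenumber (cm^-1): nu = 1e7 / lambda."""
    wavelength = np.asarray(wavelength, dtype=float)
    if np.any(wavelength <= 0):
        raise ValueError("wavelength must be positive")
    out = 1e7 / wavelength
    return float(out) if out.ndim == 0 else out


def average_replicates(spectra: SpectraSet, group_key: str) -> SpectraSet:
    """Average replicate spectra (e.g. the three berry faces) by a metadata key.

    Returns one row per group, the arithmetic mean of the member rows, in
    first-occurrence order.  Metadata is reduced to the columns constant
    within every group.
    """
    if group_key not in spectra.meta.columns:
        raise ValueError(f"metadata has no column {group_key!r}")
    groups = spectra.meta[group_key].astype(str)
    if groups.isna().any() or (groups == "").any():
        raise ValueError(f"empty {group_key!r} value in metadata")
    order = list(dict.fromkeys(groups))
    rows = []
    meta_rows = []
    keep_cols = [
        c
        for c in spectra.meta.columns
        if c != group_key
        and all(spectra.meta.loc[(groups == g).to_numpy(), c].nunique() == 1 for g in order)
    ]
    for g in order:
        mask = (groups == g).to_numpy()
        rows.append(spectra.absorbance[mask].mean(axis=0))
        first = spectra.meta.loc[mask, keep_cols].iloc[0]
        meta_rows.append(first)
    meta = pd.DataFrame(meta_rows)
    meta.index = pd.Index(order, name="sample_id")
    return SpectraSet(
        grid=spectra.grid.copy(),
        absorbance=np.vstack(rows),
        sample_ids=order,
        meta=meta,
    )
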