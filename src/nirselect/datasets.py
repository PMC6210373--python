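"""Containers and file I/O for wide-format NIR spectral tables.

A spectral dataset is stored on disk as one wide delimited table: first
column ``sample_id``, second column ``label``, remaining columns named by
wavenumber (cm^-1) and holding absorbance values.  In memory the same data
live in a :class:`SpectraSet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "SpectraParseError", "read_spectra", "write_spectra"]


class SpectraParseError(ValueError):
    """Raised when a spectral table cannot be parsed; names the offending cell."""


@dataclass
class SpectraSet:
    """An absorbance matrix with per-sample labels.

    Parameters
    ----------
    wavenumbers : (P,) array
        Strictly monotonic wavenumber grid in cm^-1 (instrument convention
        here is descending, e.g. 12000 -> 3499).
    absorbance : (N, P) array
        Unitless absorbance, all values finite.
    labels : (N,) array
        Categorical class identifiers (stored as strings).
    sample_ids : (N,) array
        Per-sample identifier strings.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=str)
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"s{i:04d}" for i in range(self.absorbance.shape[0])]
            )
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        n, p = self.absorbance.shape
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size != p:
            raise ValueError(
                f"wavenumbers has length {self.wavenumbers.size}, expected {p}"
            )
        if self.labels.shape != (n,):
            raise ValueError(f"labels has shape {self.labels.shape}, expected ({n},)")
        if self.sample_ids.shape != (n,):
            raise ValueError(
                f"sample_ids has shape {self.sample_ids.shape}, expected ({n},)"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        diffs = np.diff(self.wavenumbers)
        if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("wavenumbers must be strictly monotonic")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def select(self, indices) -> "SpectraSet":
        """Row subset (order of `indices` preserved)."""
        idx = np.asarray(indices)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same metadata, new absorbance matrix of identical shape."""
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
        )

    def equals(self, other: "SpectraSet", rtol: float = 1e-7, atol: float = 1e-9) -> bool:
        return (
            self.absorbance.shape == other.absorbance.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, rtol=rtol, atol=atol)
            and np.allclose(self.absorbance, other.absorbance, rtol=rtol, atol=atol)
            and bool(np.all(self.labels == other.labels))
            and bool(np.all(self.sample_ids == other.sample_ids))
        )


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_spectra(
    path,
    delimiter: str | None = None,
    id_column: str = "sample_id",
    label_column: str = "label",
) -> SpectraSet:
    """Read a wide spectral table into a :class:`SpectraSet`.

    The header row must carry `id_column`, `label_column` and then numeric
    wavenumber names.  Raises :class:`SpectraParseError` naming the row and
    column for malformed headers or non-numeric absorbance cells.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise SpectraParseError(f"missing required column {col!r} in {path}")
    wn_cols = [c for c in df.columns if c not in (id_column, label_column)]
    if not wn_cols:
        raise SpectraParseError(f"no wavenumber columns found in {path}")
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError:
        bad = next(c for c in wn_cols if not _is_number(c))
        raise SpectraParseError(
            f"malformed header: column {bad!r} is not a numeric wavenumber"
        ) from None

    raw = df[wn_cols]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad_mask = np.isnan(values) & ~raw.isna().to_numpy()
    if bad_mask.any():
        r, c = np.argwhere(bad_mask)[0]
        raise SpectraParseError(
            f"non-numeric absorbance cell at data row {r + 1}, "
            f"column {wn_cols[c]!r}: {raw.iat[r, c]!r}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise SpectraParseError(
            f"empty absorbance cell at data row {r + 1}, column {wn_cols[c]!r}"
        )
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=values,
        labels=df[label_column].to_numpy(dtype=str),
        sample_ids=df[id_column].to_numpy(dtype=str),
    )


def write_spectra(
    ds: SpectraSet,
    path,
    delimiter: str | None = None,
    id_column: str = "sample_id",
    label_column: str = "label",
) -> None:
    """Write a :class:`SpectraSet` to a wide delimited table.

    Refuses empty datasets; duplicated sample ids produce a warning but the
    file is still written.  ``read_spectra(write_spectra(ds))`` reproduces
    `ds` up to floating-point representation.
    """
    if ds.n_samples == 0:
        raise ValueError("refusing to write a dataset with 0 samples")
    ids, counts = np.unique(ds.sample_ids, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(
            f"duplicated sample_ids: {list(ids[counts > 1][:5])}", stacklevel=2
        )
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    cols = {id_column: ds.sample_ids, label_column: ds.labels}
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(
        ds.absorbance, columns=[f"{w:.10g}" for w in ds.wavenumbers], index=df.index
    )
    pd.concat([df, spec], axis=1).to_csv(
        path, sep=sep, index=False, float_format="%.10g"
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
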