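"""Domain types and preprocessing for NIR absorbance spectra.

A :class:`SpectraSet` holds an ``n_samples x n_points`` absorbance matrix on a
shared wavenumber axis (cm^-1, stored high-to-low as acquired), together with
per-sample brand labels and unique sample ids.  The only preprocessing offered
is the standard normal variate (SNV) transform, which autoscales each spectrum
to zero mean and unit standard deviation and thereby removes additive baseline
offsets and multiplicative particle-size (scatter) effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "DegenerateSpectrumError",
    "SpectraParseError",
    "snv_transform",
    "read_spectra_csv",
    "write_spectra_csv",
]


class DegenerateSpectrumError(ValueError):
    """A spectrum with zero standard deviation cannot be SNV-scaled."""


class SpectraParseError(ValueError):
    """A spectra CSV file violates the expected layout."""


@dataclass
class SpectraSet:
    """Labelled absorbance matrix on a common wavenumber axis.

    Parameters
    ----------
    absorbance : ndarray, shape (n_samples, n_points)
        Absorbance values (arbitrary absorbance units); must be finite.
    wavenumbers : ndarray, shape (n_points,)
        Strictly monotonic axis in cm^-1.  Ascending input is accepted and
        normalized to the stored descending convention (10,000 -> 4,000);
        the original direction is recorded in ``metadata['original_order']``.
    labels : sequence of str, shape (n_samples,)
        Brand identifier per sample (e.g. "A"/"B"/"C").
    sample_ids : sequence of str, shape (n_samples,), optional
        Unique per-sample identifiers; generated as ``s0001...`` if omitted.
    """

    absorbance: np.ndarray
    wavenumbers: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=str).ravel()
        n, p = self.absorbance.shape
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i + 1:04d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=str).ravel()
        if self.wavenumbers.size != p:
            raise ValueError(
                f"wavenumbers length {self.wavenumbers.size} != n_points {p}"
            )
        if self.labels.size != n:
            raise ValueError(f"labels length {self.labels.size} != n_samples {n}")
        if self.sample_ids.size != n:
            raise ValueError("sample_ids length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        dw = np.diff(self.wavenumbers)
        if self.wavenumbers.size >= 2 and np.all(dw > 0):
            # normalize ascending input to the stored descending convention
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
            self.metadata.setdefault("original_order", "ascending")
        elif self.wavenumbers.size >= 2 and np.all(dw < 0):
            self.metadata.setdefault("original_order", "descending")
        elif self.wavenumbers.size >= 2:
            raise ValueError("wavenumbers must be strictly monotonic")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def subset(self, indices: np.ndarray) -> "SpectraSet":
        idx = np.asarray(indices)
        return SpectraSet(
            absorbance=self.absorbance[idx],
            wavenumbers=self.wavenumbers.copy(),
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            metadata=dict(self.metadata),
        )


def snv_transform(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: autoscale each spectrum to mean 0, sd 1.

    The sample standard deviation (divisor ``n - 1``) is used, following the
    dominant chemometrics convention.  Additive offsets and positive
    multiplicative factors per spectrum cancel exactly:
    ``snv(a * x + b) == snv(x)`` for ``a > 0``.

    Raises
    ------
    DegenerateSpectrumError
        If any spectrum is constant (zero standard deviation), naming the
        offending sample id.
    """
    X = spectra.absorbance
    if X.shape[1] < 2:
        raise ValueError("SNV requires spectra with at least 2 points")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        ids = ", ".join(spectra.sample_ids[bad[:5]])
        raise DegenerateSpectrumError(
            f"zero-variance spectrum cannot be SNV-scaled: sample_id(s) {ids}"
        )
    return SpectraSet(
        absorbance=(X - mu) / sd,
        wavenumbers=spectra.wavenumbers.copy(),
        labels=spectra.labels.copy(),
        sample_ids=spectra.sample_ids.copy(),
        metadata=dict(spectra.metadata),
    )


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV: header ``sample_id,label,<w1>,...,<wp>``."""
    df = pd.DataFrame(
        spectra.absorbance, columns=[repr(float(w)) for w in spectra.wavenumbers]
    )
    df.insert(0, "label", spectra.labels)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra_csv`.

    The wavenumber axis is taken from the header and must be strictly
    monotonic (either direction; ascending input is normalized).  Ragged rows
    or non-numeric cells raise :class:`SpectraParseError` with the offending
    row number.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SpectraParseError(f"{path}: no samples (empty file)") from None
    except pd.errors.ParserError as exc:
        raise SpectraParseError(f"{path}: {exc}") from None
    if df.shape[0] == 0:
        raise SpectraParseError(f"{path}: no samples")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "label":
        raise SpectraParseError(
            f"{path}: header must start with 'sample_id,label' followed by wavenumbers"
        )
    try:
        wavenumbers = np.array([float(c) for c in cols[2:]])
    except ValueError:
        raise SpectraParseError(f"{path}: non-numeric wavenumber in header") from None
    dw = np.diff(wavenumbers)
    if wavenumbers.size >= 2 and not (np.all(dw > 0) or np.all(dw < 0)):
        raise SpectraParseError(f"{path}: wavenumber header is not strictly monotonic")
    raw = df[cols[2:]].to_numpy()
    absorbance = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        row = raw[i]
        if pd.isna(row).any():
            raise SpectraParseError(f"{path}: row {i + 2}: ragged or missing cells")
        try:
            absorbance[i] = row.astype(float)
        except ValueError:
            raise SpectraParseError(f"{path}: row {i + 2}: non-numeric absorbance cell") from None
    return SpectraSet(
        absorbance=absorbance,
        wavenumbers=wavenumbers,
        labels=df["label"].to_numpy(dtype=str),
        sample_ids=df["sample_id"].to_numpy(dtype=str),
    )
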