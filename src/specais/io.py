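"""Trial-ensemble container and file I/O.

A :class:`TrialEnsemble` is the package's core in-memory object: a
(trials x samples) real matrix of repeated observations of one univariate
process, plus its sampling rate.  Trials are treated as interchangeable
realizations of the same process (cyclostationarity), which is what
licenses pooling samples across trials during estimation.

Supported on-disk formats: delimited text matrices (CSV/TSV, one trial
per row by default), HDF5 (one dataset per condition, sampling rate as a
dataset attribute), and JSON for analysis results.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import h5py

__all__ = [
    "TrialEnsemble",
    "load_ensemble",
    "save_ensemble",
    "save_result",
    "load_result",
]


@dataclass
class TrialEnsemble:
    """Multi-trial univariate signal with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_samples)
        Signal values (arbitrary units).  A 1-D vector is promoted to a
        single trial.
    fs : float
        Sampling rate in Hz; must be positive.
    label : str
        Free-text condition tag (e.g. an anesthetic level).
    meta : dict
        Provenance information (source path, generator parameters, ...).
    """

    data: np.ndarray
    fs: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (trials, samples) matrix")
        if self.data.shape[1] < 2:
            raise ValueError("each trial needs at least 2 samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at trial {r}, sample {c}: {self.data[r, c]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


def load_ensemble(
    path: str,
    fs: float | None = None,
    layout: str = "trials_as_rows",
    dataset: str | None = None,
) -> TrialEnsemble:
    """Read a trial ensemble from delimited text or HDF5.

    Parameters
    ----------
    path : str
        CSV/TSV file of equal-length numeric rows, or an HDF5 file.
    fs : float, optional
        Sampling rate in Hz.  Required for text input; for HDF5 it
        defaults to the dataset's ``fs`` attribute.
    layout : {"trials_as_rows", "trials_as_cols"}
        Orientation of text matrices.
    dataset : str, optional
        HDF5 dataset name; defaults to the first dataset in the file.

    Raises
    ------
    ValueError
        On ragged rows, non-numeric content, non-finite values, or a
        missing sampling rate.
    """
    if layout not in ("trials_as_rows", "trials_as_cols"):
        raise ValueError(f"unknown layout {layout!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if dataset is None:
                keys = [k for k in f if isinstance(f[k], h5py.Dataset)]
                if not keys:
                    raise ValueError(f"no datasets in {path}")
                dataset = keys[0]
            dset = f[dataset]
            data = np.asarray(dset)
            if fs is None:
                if "fs" not in dset.attrs:
                    raise ValueError("fs not given and no 'fs' attribute in HDF5")
                fs = float(dset.attrs["fs"])
            label = str(dset.attrs.get("label", dataset))
    else:
        if fs is None:
            raise ValueError("fs is required for text input")
        delim = "\t" if path.endswith((".tsv", ".tab")) else ","
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append([float(v) for v in line.replace(delim, " ").split()])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: non-numeric entry ({e})")
        if not rows:
            raise ValueError(f"{path}: empty file")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
        data = np.asarray(rows, dtype=float)
        label = os.path.splitext(os.path.basename(path))[0]
    if layout == "trials_as_cols":
        data = data.T
    ens = TrialEnsemble(data=data, fs=float(fs), label=label)
    ens.meta["source"] = os.path.abspath(path)
    return ens


def save_ensemble(ens: TrialEnsemble, path: str, dataset: str | None = None) -> None:
    """Write an ensemble as CSV (trials as rows) or HDF5 by extension."""
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "a") as f:
            name = dataset or (ens.label or "signal")
            if name in f:
                del f[name]
            d = f.create_dataset(name, data=ens.data)
            d.attrs["fs"] = ens.fs
            d.attrs["label"] = ens.label
    else:
        delim = "\t" if path.endswith((".tsv", ".tab")) else ","
        np.savetxt(path, ens.data, delimiter=delim)


def save_result(result, path: str) -> None:
    """Serialize a spectral analysis result to JSON (round-trippable)."""
    if os.path.isdir(path):
        raise IsADirectoryError(path)
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def load_result(path: str):
    """Load a result written by :func:`save_result`."""
    from .spectral import SpectralAISResult

    with open(path) as fh:
        return SpectralAISResult.from_dict(json.load(fh))
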