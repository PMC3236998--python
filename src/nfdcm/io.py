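"""Readers and writers for spectra, posteriors and comparison tables.

Spectra travel as CSV with columns ``frequency_hz, channel_i, channel_j,
real, imag`` (one row per frequency and channel pair); posteriors as JSON;
comparison tables as CSV.  Floats are written with full precision so that
a write/read round trip is value-identical.  Every file carries a small
provenance block (package version plus whatever the caller supplies).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import ComparisonTable
from .inversion import PosteriorDensity
from .spectral_features import SpectralData

_FLOAT_FMT = "%.17g"


class ResultFormatError(ValueError):
    """File does not parse as the expected result type."""


def write_spectra(path: str | Path, data: SpectralData) -> None:
    path = Path(path)
    n_f, n_c, _ = data.values.shape
    rows = []
    for i in range(n_c):
        for j in range(n_c):
            block = pd.DataFrame({
                "frequency_hz": data.freqs_hz,
                "channel_i": i, "channel_j": j,
                "real": data.values[:, i, j].real,
                "imag": data.values[:, i, j].imag})
            rows.append(block)
    df = pd.concat(rows, ignore_index=True)
    meta = {"version": __version__, **data.meta}
    with path.open("w") as fh:
        fh.write("# nfdcm-spectra " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_spectra(path: str | Path) -> SpectralData:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# nfdcm-spectra"):
            meta = json.loads(first.split(None, 2)[2])
            _check_version(meta, path)
            body_start = 1
        else:
            body_start = 0
    try:
        df = pd.read_csv(path, skiprows=body_start,
                         float_precision="round_trip")
        required = {"frequency_hz", "channel_i", "channel_j", "real", "imag"}
        if not required <= set(df.columns):
            raise ResultFormatError(
                f"{path}: missing columns {required - set(df.columns)}")
        freqs = np.sort(df["frequency_hz"].unique())
        n_c = int(df["channel_i"].max()) + 1
        values = np.zeros((freqs.size, n_c, n_c), dtype=complex)
        for (i, j), grp in df.groupby(["channel_i", "channel_j"]):
            grp = grp.sort_values("frequency_hz")
            if grp.shape[0] != freqs.size:
                raise ResultFormatError(
                    f"{path}: incomplete grid for channel pair ({i}, {j})")
            values[:, int(i), int(j)] = (grp["real"].to_numpy()
                                         + 1j * grp["imag"].to_numpy())
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        if isinstance(e, ResultFormatError):
            raise
        raise ResultFormatError(f"{path}: cannot parse spectra CSV: {e}")
    return SpectralData(freqs, values, meta=meta)


def write_posterior(path: str | Path, post: PosteriorDensity) -> None:
    payload = {
        "provenance": {"version": __version__, "format": "nfdcm-posterior"},
        "names": list(post.names),
        "mu": {n: float(v) for n, v in zip(post.names, post.mu)},
        "C": np.asarray(post.C).tolist(),
        "F": float(post.F),
        "lambda": float(post.lam),
        "trace": [float(v) for v in post.trace],
        "data_hash": post.data_hash,
        "settings": post.settings,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_posterior(path: str | Path) -> PosteriorDensity:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        prov = payload.get("provenance", {})
        if prov.get("format") != "nfdcm-posterior":
            raise ResultFormatError(f"{path}: not a posterior file")
        _check_version(prov, path)
        names = tuple(payload["names"])
        mu = np.array([payload["mu"][n] for n in names], dtype=float)
        return PosteriorDensity(
            mu=mu, C=np.array(payload["C"], dtype=float),
            F=float(payload["F"]), lam=float(payload["lambda"]),
            names=names, trace=list(payload["trace"]),
            data_hash=payload.get("data_hash", ""),
            settings=payload.get("settings", {}))
    except (json.JSONDecodeError, KeyError, TypeError) as e:
        raise ResultFormatError(f"{path}: cannot parse posterior JSON: {e}")


def write_comparison(path: str | Path, table: ComparisonTable) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# nfdcm-comparison "
                 + json.dumps({"version": __version__, "best": table.best,
                               "strong": table.strong}) + "\n")
        table.table.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_comparison(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("# nfdcm-comparison"):
            _check_version(json.loads(first.split(None, 2)[2]), path)
            skip = 1
    try:
        df = pd.read_csv(path, skiprows=skip)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise ResultFormatError(f"{path}: cannot parse comparison CSV: {e}")
    if not {"model", "F"} <= set(df.columns):
        raise ResultFormatError(f"{path}: missing model/F columns")
    return df


def _check_version(meta: dict, path: Path) -> None:
    version = meta.get("version")
    if version is not None and version != __version__:
        warnings.warn(
            f"{path} was written by nfdcm {version}, reading with "
            f"{__version__}", stacklevel=3)
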