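"""Reading and writing ROI time series, module tables and ModeSets.

Time series are delimited text (comma or tab), one column per ROI with a
header row of ROI labels and one row per time point. Module tables are
two-column delimited text (roi_label, module_name). ModeSets serialise
to a per-participant directory of TSV tables plus a JSON meta file,
round-tripping at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ModuleOrdering
from .datatypes import ModeSet, MultivariateSignal, MVMDParams, ValidationError

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_modules",
    "save_modeset",
    "load_modeset",
]

_FLOAT_FMT = "%.17g"  # lossless for float64


def _read_delimited(path: str | Path, header: bool) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: ragged or malformed row ({exc})") from exc
    return df


def read_timeseries(
    path: str | Path, dt: float, header: bool = True
) -> MultivariateSignal:
    """Load a ROI-by-time matrix; columns become channels, mean-centred.

    A missing header shows up as non-numeric first-row values; pass
    ``header=False`` (CLI: ``--no-header``) for label-less files.
    """
    path = Path(path)
    df = _read_delimited(path, header)
    if header:
        labels = [str(c) for c in df.columns]
        if any(_is_number(l) for l in labels):
            raise ValidationError(
                f"{path}: header row looks numeric - missing header? "
                "use --no-header / header=False"
            )
    else:
        labels = [f"roi_{i}" for i in range(df.shape[1])]
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        bad = [
            (i, labels[j], df.iat[i, j])
            for i in range(df.shape[0]) for j in range(df.shape[1])
            if not _is_number(df.iat[i, j])
        ][:10]
        raise ValidationError(f"{path}: non-numeric cells at (row, roi): {bad}")
    if np.isnan(arr).any():
        rows, cols = np.nonzero(np.isnan(arr))
        locs = [(int(r), labels[c]) for r, c in zip(rows[:10], cols[:10])]
        raise ValidationError(f"{path}: NaN cells at (row, roi): {locs}")
    sig = MultivariateSignal(
        arr.T.astype(float), dt=dt, channel_labels=labels,
        participant_id=path.stem,
    )
    return sig.demeaned()


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_timeseries(sig: MultivariateSignal, path: str | Path) -> None:
    """Write channels as columns with a label header (tab-separated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sig.data.T, columns=sig.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_modules(path: str | Path, roi_labels: list[str] | None = None
                 ) -> ModuleOrdering:
    """Load a (roi_label, module_name) table into a module ordering.

    Modules are ordered by first appearance in the file. If
    ``roi_labels`` is given (the time-series header), mismatches between
    the two label sets are reported.
    """
    path = Path(path)
    df = _read_delimited(path, header=True)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected exactly 2 columns")
    rois = [str(v) for v in df.iloc[:, 0]]
    mods = [str(v) for v in df.iloc[:, 1]]
    dupes = {r for r in rois if rois.count(r) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate ROI labels {sorted(dupes)}")
    module_of = dict(zip(rois, mods))
    if roi_labels is not None:
        missing = sorted(set(roi_labels) - set(rois))
        extra = sorted(set(rois) - set(roi_labels))
        if missing or extra:
            raise ValidationError(
                f"{path}: module table does not match time-series labels; "
                f"missing={missing} extra={extra}"
            )
        labels = list(roi_labels)
    else:
        labels = rois
    return ModuleOrdering(roi_labels=labels, module_of=module_of)


def save_modeset(ms: ModeSet, directory: str | Path) -> Path:
    """Serialise a ModeSet to one directory per participant.

    Layout: ``omega.tsv`` (mode index, central frequency Hz),
    ``mode_<k>.tsv`` (T rows x C columns, header = channel labels),
    ``residual.tsv``, ``meta.json`` (params, dt, convergence).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "omega.tsv").open("w") as fh:
        fh.write("mode\tomega_hz\n")
        for k in range(ms.K):
            fh.write(f"{k}\t{ms.omega[k]:.17g}\n")
    header = "\t".join(ms.channel_labels)
    for k in range(ms.K):
        np.savetxt(directory / f"mode_{k}.tsv", ms.modes[k].T,
                   fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")
    np.savetxt(directory / "residual.tsv", ms.residual.T,
               fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")
    meta = {
        "participant_id": ms.participant_id,
        "dt": ms.dt,
        "iterations": ms.iterations,
        "converged": ms.converged,
        "params": ms.params.to_dict(),
        "channel_labels": ms.channel_labels,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_modeset(directory: str | Path) -> ModeSet:
    """Inverse of :func:`save_modeset` (lossless round-trip)."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    omega_tab = np.loadtxt(directory / "omega.tsv", skiprows=1, ndmin=2)
    K = omega_tab.shape[0]
    omega = omega_tab[:, 1]
    modes = np.stack([
        np.loadtxt(directory / f"mode_{k}.tsv", skiprows=1, ndmin=2).T
        for k in range(K)
    ])
    residual = np.loadtxt(directory / "residual.tsv", skiprows=1, ndmin=2).T
    return ModeSet(
        modes=modes,
        omega=omega,
        iterations=int(meta["iterations"]),
        converged=bool(meta["converged"]),
        residual=residual,
        params=MVMDParams(**meta["params"]),
        dt=float(meta["dt"]),
        channel_labels=list(meta["channel_labels"]),
        participant_id=meta["participant_id"],
    )
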