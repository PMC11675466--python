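"""Reading and writing of stacks, label maps, curves and fit results.

Stacks travel as multipage float32 TIFFs (one page per echo) with a JSON
sidecar carrying the echo-time grid, TR and noise sigma; label maps as
single-page integer TIFFs with a JSON name table; decay curves as CSV with
columns te_ms, signal and optionally sigma.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import LabelMap, MultiEchoStack
from .relaxometry import DecayCurve, FitResult

__all__ = [
    "save_stack",
    "load_stack",
    "save_labelmap",
    "load_labelmap",
    "save_curve",
    "load_curve",
    "save_fit",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(stack: MultiEchoStack, path: str | Path, tr: float | None = None) -> Path:
    """Write a stack as a multipage float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.data.astype(np.float32), 2, 0)  # echo-first pages
    tifffile.imwrite(path, pages)
    meta = {
        "te_grid_ms": [float(v) for v in stack.te_grid],
        "sigma": None if stack.sigma is None else float(stack.sigma),
    }
    if tr is not None:
        meta["tr_ms"] = float(tr)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_stack(path: str | Path) -> MultiEchoStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    meta = json.loads(_sidecar(path).read_text())
    data = np.moveaxis(pages.astype(float), 0, 2)
    return MultiEchoStack(
        data=data,
        te_grid=np.asarray(meta["te_grid_ms"], dtype=float),
        sigma=meta.get("sigma"),
    )


def save_labelmap(labelmap: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labelmap.labels.astype(np.int32))
    _sidecar(path).write_text(
        json.dumps({str(k): v for k, v in labelmap.names.items()}, indent=2)
    )
    return path


def load_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = np.asarray(tifffile.imread(path))
    names: dict[int, str] = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelMap(labels, names)


def save_curve(curve: DecayCurve, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"te_ms": curve.te, "signal": curve.y})
    if curve.sigma != 1.0:
        df["sigma"] = curve.sigma
    df.to_csv(path, index=False)
    return path


def load_curve(path: str | Path) -> DecayCurve:
    df = pd.read_csv(path)
    sigma = float(df["sigma"].iloc[0]) if "sigma" in df.columns else 1.0
    return DecayCurve(df["te_ms"].to_numpy(float), df["signal"].to_numpy(float), sigma=sigma)


def save_fit(fit: FitResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fit.to_dict(), indent=2))
    return path
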