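"""File I/O: TIFF image pairs, CSV vector fields, HDF5 chains, manifests.

Conventions: images are 16-bit single-channel TIFFs with intensities on
the 0-1000 a.u. scale; vector fields and metrics are CSV with pixel and
micrometer coordinates; MCMC chains go to HDF5; every artifact gets a
JSON sidecar or manifest recording the configuration and seeds so runs
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .piv import DeformationField
from .pivuq import PIVUncertainty
from .bayes import TractionPosterior

__all__ = [
    "write_image_pair",
    "read_image_pair",
    "write_deformation_csv",
    "read_deformation_csv",
    "write_traction_csv",
    "write_chains_h5",
    "write_bootstrap_draws_h5",
    "write_manifest",
]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if f.name not in ("islands",)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return repr(obj)
    return obj


def write_image_pair(
    directory: str | Path,
    ref: np.ndarray,
    session: np.ndarray,
    pixel_size: float,
    meta: dict | None = None,
    stem: str = "pair",
) -> tuple[Path, Path]:
    """Write ref/session as 16-bit TIFFs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in (("ref", ref), ("session", session)):
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(p, np.clip(img, 0, 65535).astype(np.uint16))
        paths.append(p)
    sidecar = {"pixel_size_um": pixel_size, "saturation_au": 1000.0}
    sidecar.update(_jsonable(meta or {}))
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return paths[0], paths[1]


def read_image_pair(
    ref_path: str | Path, session_path: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    ref = tifffile.imread(ref_path).astype(float)
    session = tifffile.imread(session_path).astype(float)
    if ref.shape != session.shape:
        raise ValueError(
            f"image shapes differ: {ref.shape} vs {session.shape}"
        )
    return ref, session


def write_deformation_csv(
    path: str | Path,
    field: DeformationField,
    unc: PIVUncertainty | None = None,
    pixel_size: float | None = None,
) -> Path:
    """Deformation (and optional uncertainty) as tidy CSV."""
    path = Path(path)
    ny, nx = field.grid_shape
    X, Y = np.meshgrid(field.x_px, field.y_px)
    data = {
        "x_px": X.ravel(),
        "y_px": Y.ravel(),
        "ux_px": field.u[..., 0].ravel(),
        "uy_px": field.u[..., 1].ravel(),
        "valid": field.valid.ravel().astype(int),
    }
    if unc is not None:
        data["sigma_ux_px"] = unc.sigma_u[..., 0].ravel()
        data["sigma_uy_px"] = unc.sigma_u[..., 1].ravel()
        data["angular_std_rad"] = unc.angular_std.ravel()
    df = pd.DataFrame(data)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    header = {"WL": field.WL, "WS": field.WS}
    if pixel_size is not None:
        header["pixel_size_um"] = pixel_size
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def read_deformation_csv(path: str | Path) -> DeformationField:
    path = Path(path)
    df = pd.read_csv(path)
    header = json.loads(path.with_suffix(".json").read_text())
    x = np.unique(df["x_px"].to_numpy())
    y = np.unique(df["y_px"].to_numpy())
    ny, nx = len(y), len(x)
    u = np.stack(
        [
            df["ux_px"].to_numpy().reshape(ny, nx),
            df["uy_px"].to_numpy().reshape(ny, nx),
        ],
        axis=-1,
    )
    valid = df["valid"].to_numpy().reshape(ny, nx).astype(bool)
    return DeformationField(
        x_px=x, y_px=y, u=u, WL=header["WL"], WS=header["WS"], valid=valid
    )


def write_traction_csv(
    path: str | Path,
    x_um: np.ndarray,
    y_um: np.ndarray,
    posterior: TractionPosterior,
) -> Path:
    """Posterior traction summary as CSV (one row per window)."""
    path = Path(path)
    nw = posterior.n_windows
    X, Y = np.meshgrid(x_um, y_um)
    tx, ty = posterior.component_maps()
    mag = posterior.magnitude_map().ravel()
    sig = posterior.sigma_t
    with np.errstate(divide="ignore"):
        snr = np.where(sig > 0, mag / sig, np.inf)
    df = pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "tx_hat_Pa": tx.ravel(),
            "ty_hat_Pa": ty.ravel(),
            "sigma_tx_Pa": posterior.sigma_tx,
            "sigma_ty_Pa": posterior.sigma_ty,
            "sigma_t_Pa": sig,
            "angular_std_rad": posterior.angular_std,
            "snr_t": snr,
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_chains_h5(
    path: str | Path,
    posterior: TractionPosterior,
    store_t_draws: bool = False,
) -> Path:
    """Persist MCMC chains (alpha/beta always, t draws on request)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("alpha_chain", data=posterior.alpha_chain)
        f.create_dataset("beta_chain", data=posterior.beta_chain)
        f.create_dataset("t_hat", data=posterior.t_hat)
        f.create_dataset("sigma_t", data=posterior.sigma_t)
        f.attrs["grid_shape"] = posterior.grid_shape
        if store_t_draws and posterior.draws is not None:
            f.create_dataset("t_draws", data=posterior.draws)
    return path


def write_bootstrap_draws_h5(
    path: str | Path, unc: "PIVUncertainty"
) -> Path:
    """Persist raw bootstrap displacement draws for audit (requires a
    run with ``keep_draws=True``)."""
    import h5py

    if unc.draws is None:
        raise ValueError("uncertainty object carries no retained draws")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("draws_px", data=unc.draws)
        f.create_dataset("valid", data=unc.valid)
        f.create_dataset("sigma_u_px", data=unc.sigma_u)
    return path


def write_manifest(path: str | Path, **entries: Any) -> Path:
    """JSON run manifest (seeds, configs, package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {"tfmuq_version": __version__}
    manifest.update({k: _jsonable(v) for k, v in entries.items()})
    path.write_text(json.dumps(manifest, indent=2))
    return path
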