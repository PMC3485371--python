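"""HDF5 persistence for spectral tensors and PLS results, with provenance.

Every artifact embeds a ``config_hash`` attribute; loaders verify it when an
expected hash is supplied, so artifacts produced under different pipeline
configurations cannot be silently mixed.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import xarray as xr

from .pls import PLSResult

__all__ = ["save_tensor", "load_tensor", "save_pls_result", "load_pls_result"]


def _check_hash(found: str | None, expected: str | None, path) -> None:
    if expected is not None and found != expected:
        raise ValueError(
            f"{path}: artifact config hash {found!r} does not match the "
            f"current configuration {expected!r}; refusing to mix artifacts"
        )


def save_tensor(tensor: xr.DataArray, path: str | Path, config_hash: str = "") -> None:
    """Write a labelled 4-D spectral tensor to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["name"] = tensor.name or "tensor"
        f.attrs["dims"] = list(tensor.dims)
        for k, v in tensor.attrs.items():
            f.attrs[f"meta_{k}"] = v
        f.create_dataset("values", data=tensor.values)
        for name in tensor.coords:
            vals = np.asarray(tensor[name].values)
            if vals.dtype.kind in ("U", "O"):
                vals = vals.astype("S")
            grp = f.create_dataset(f"coords/{name}", data=vals)
            grp.attrs["dim"] = tensor[name].dims[0]


def load_tensor(path: str | Path, expect_hash: str | None = None) -> xr.DataArray:
    with h5py.File(path, "r") as f:
        _check_hash(f.attrs.get("config_hash"), expect_hash, path)
        dims = [str(d) for d in f.attrs["dims"]]
        coords = {}
        for name, ds in f["coords"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            dim = ds.attrs["dim"]
            coords[name] = (dim, vals) if name != dim else vals
        attrs = {
            k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")
        }
        return xr.DataArray(
            f["values"][()],
            dims=dims,
            coords=coords,
            name=str(f.attrs["name"]),
            attrs=attrs,
        )


def save_pls_result(res: PLSResult, path: str | Path, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["kind"] = res.kind
        f.attrs["n_perm"] = res.n_perm
        f.attrs["n_boot"] = res.n_boot
        f.attrs["seed"] = -1 if res.seed is None else res.seed
        f.attrs["n_channels"] = res.n_channels
        f.attrs["conditions"] = [str(c) for c in res.conditions]
        f.create_dataset("singular_values", data=res.singular_values)
        f.create_dataset("contrasts", data=res.contrasts)
        f.create_dataset("saliences", data=res.saliences)
        f.create_dataset("freqs", data=res.freqs)
        if res.perm_p is not None:
            f.create_dataset("perm_p", data=res.perm_p)
        if res.bsr is not None:
            f.create_dataset("bsr", data=res.bsr)
        meta = f.create_group("feature_meta")
        for col in res.feature_meta.columns:
            vals = res.feature_meta[col].to_numpy()
            if vals.dtype.kind in ("U", "O"):
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals)


def load_pls_result(path: str | Path, expect_hash: str | None = None) -> PLSResult:
    with h5py.File(path, "r") as f:
        _check_hash(f.attrs.get("config_hash"), expect_hash, path)
        meta = {}
        for col, ds in f["feature_meta"].items():
            vals = ds[()]
            meta[col] = vals.astype(str) if vals.dtype.kind == "S" else vals
        seed = int(f.attrs["seed"])
        return PLSResult(
            singular_values=f["singular_values"][()],
            contrasts=f["contrasts"][()],
            saliences=f["saliences"][()],
            perm_p=f["perm_p"][()] if "perm_p" in f else None,
            bsr=f["bsr"][()] if "bsr" in f else None,
            conditions=[str(c) for c in f.attrs["conditions"]],
            feature_meta=pd.DataFrame(meta),
            freqs=f["freqs"][()],
            n_channels=int(f.attrs["n_channels"]),
            kind=str(f.attrs["kind"]),
            n_perm=int(f.attrs["n_perm"]),
            n_boot=int(f.attrs["n_boot"]),
            seed=None if seed == -1 else seed,
        )
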