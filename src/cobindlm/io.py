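"""Readers and writers for the package's on-disk formats.

BED is 0-based half-open; matrices and embeddings go to HDF5 with id maps
and the producing config hash stored as attributes; configs and provenance
are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .encoding import BinnedSignalMatrix, CistromeCatalog, TokenMatrix, VOCABULARY

BED_COLUMNS = ["chrom", "start", "end"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int | None = None):
    import cobindlm
    payload = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": getattr(cobindlm, "__version__", "unknown"),
        "numpy_version": np.__version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
    return payload


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] > 3:
        df = df.rename(columns={"col3": "name"})
    return df


def write_bed(df: pd.DataFrame, path):
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def write_token_matrix(tokens: TokenMatrix, path, config: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("tokens", data=tokens.tokens, compression="gzip")
        f.create_dataset("position_ids", data=tokens.position_ids)
        f.attrs["cistrome_ids"] = json.dumps(list(tokens.cistrome_ids))
        f.attrs["vocabulary"] = json.dumps(list(tokens.vocabulary))
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)


def read_token_matrix(path) -> TokenMatrix:
    with h5py.File(path, "r") as f:
        return TokenMatrix(
            tokens=f["tokens"][...],
            cistrome_ids=json.loads(f.attrs["cistrome_ids"]),
            position_ids=f["position_ids"][...],
            vocabulary=tuple(json.loads(f.attrs["vocabulary"])),
        )


def write_signal_matrix(matrix: BinnedSignalMatrix, path, config: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values, compression="gzip")
        f.create_dataset("starts", data=np.asarray(matrix.starts))
        f.create_dataset("ends", data=np.asarray(matrix.ends))
        f.create_dataset("chroms", data=np.asarray(matrix.chroms, dtype="S"))
        if matrix.peak_mask is not None:
            f.create_dataset("peak_mask", data=matrix.peak_mask, compression="gzip")
        f.attrs["cistrome_ids"] = json.dumps(list(matrix.cistrome_ids))
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)


def read_signal_matrix(path) -> BinnedSignalMatrix:
    with h5py.File(path, "r") as f:
        return BinnedSignalMatrix(
            values=f["values"][...],
            chroms=f["chroms"][...].astype(str),
            starts=f["starts"][...],
            ends=f["ends"][...],
            cistrome_ids=json.loads(f.attrs["cistrome_ids"]),
            peak_mask=f["peak_mask"][...] if "peak_mask" in f else None,
        )


def write_embeddings(path, embeddings: np.ndarray, region_ids: np.ndarray,
                     regulator_ids: list[str], config: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("embeddings", data=embeddings, compression="gzip")
        f.create_dataset("region_ids", data=np.asarray(region_ids))
        f.attrs["regulator_ids"] = json.dumps(list(regulator_ids))
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)


def read_embeddings(path):
    with h5py.File(path, "r") as f:
        return (f["embeddings"][...], f["region_ids"][...],
                json.loads(f.attrs["regulator_ids"]))


def write_contact_matrix(matrix: np.ndarray, path):
    np.savetxt(path, np.asarray(matrix), delimiter="\t")


def read_contact_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact archive must hold a square matrix")
    return m


def write_truth(truth, path):
    payload = {
        "module_of_regulator": truth.module_of_regulator,
        "driver_set": sorted(truth.driver_set),
        "region_module_activity": truth.region_module_activity.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path):
    from .synthetic import PlantedTruth
    d = json.loads(Path(path).read_text())
    return PlantedTruth(
        module_of_regulator=d["module_of_regulator"],
        driver_set=set(d["driver_set"]),
        region_module_activity=np.asarray(d["region_module_activity"], dtype=bool),
    )
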