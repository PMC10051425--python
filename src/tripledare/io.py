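"""Dataset serialization: HDF5 canonical container with CSV sidecars.

Layout: ``/raw [N,3,3,T]``, ``/aux [N,A]``, ``/labels [N,L]``,
``/meta/subject_ids [N]`` plus root attributes ``domain`` and
``label_names``.  ``write_dataset(..., csv_sidecar=True)`` additionally
writes ``<stem>.labels.csv`` and ``<stem>.aux.csv`` for quick inspection; a
file missing ``/labels`` falls back to the labels sidecar when present.
Reading with ``hide_labels=True`` returns a dataset whose label accessor
raises, the contract that keeps target labels out of training.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import DomainDataset


class DatasetFormatError(ValueError):
    pass


def write_dataset(dataset: DomainDataset, path: str | Path,
                  csv_sidecar: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("raw", data=dataset.raw)
        fh.create_dataset("aux", data=dataset.aux)
        if dataset._labels is not None and not dataset.labels_hidden:
            fh.create_dataset("labels", data=dataset._labels.astype(np.int8))
        meta = fh.create_group("meta")
        meta.create_dataset("subject_ids", data=np.asarray(dataset.subject_ids))
        fh.attrs["domain"] = dataset.domain
        fh.attrs["label_names"] = list(dataset.label_names)
        if dataset.features is not None:
            fh.create_dataset("features", data=dataset.features)
            fh["features"].attrs["feature_names"] = list(dataset.feature_names)
    if csv_sidecar:
        if dataset._labels is not None and not dataset.labels_hidden:
            pd.DataFrame(dataset._labels, columns=dataset.label_names).to_csv(
                path.with_suffix(".labels.csv"), index=False)
        pd.DataFrame(dataset.aux).to_csv(path.with_suffix(".aux.csv"), index=False)
    return path


def read_dataset(path: str | Path, hide_labels: bool = False) -> DomainDataset:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        for group in ("raw", "aux", "meta"):
            if group not in fh:
                raise DatasetFormatError(f"{path}: missing required group '/{group}'")
        if "subject_ids" not in fh["meta"]:
            raise DatasetFormatError(f"{path}: missing '/meta/subject_ids'")
        raw = fh["raw"][...]
        aux = fh["aux"][...]
        subject_ids = fh["meta/subject_ids"][...]
        domain = str(fh.attrs.get("domain", "source"))
        label_names = [str(l) for l in fh.attrs["label_names"]]
        labels = fh["labels"][...] if "labels" in fh else None
        features = fh["features"][...] if "features" in fh else None
        feature_names = ([str(n) for n in fh["features"].attrs["feature_names"]]
                         if features is not None else [])
    if labels is None:
        sidecar = path.with_suffix(".labels.csv")
        if sidecar.exists():
            df = pd.read_csv(sidecar)
            if list(df.columns) != label_names:
                raise DatasetFormatError(
                    f"{sidecar}: label columns do not match dataset label_names")
            labels = df.to_numpy(dtype=np.int8)
    if raw.ndim != 4 or raw.shape[1:3] != (3, 3):
        raise DatasetFormatError(f"{path}: '/raw' must have shape [N,3,3,T]")
    if aux.shape[0] != raw.shape[0]:
        raise DatasetFormatError(f"{path}: '/aux' and '/raw' lengths differ")
    if labels is not None and labels.shape[1] != len(label_names):
        raise DatasetFormatError(f"{path}: label matrix width does not match label_names")
    ds = DomainDataset(raw=raw, aux=aux, subject_ids=subject_ids, domain=domain,
                       label_names=label_names, _labels=labels,
                       features=features, feature_names=feature_names)
    return ds.without_labels() if hide_labels else ds
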