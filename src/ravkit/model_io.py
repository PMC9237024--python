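"""Lossless persistence of fitted RAV models.

Layout of a model directory::

    index.h5         matrices (RAV index, pooled loadings, normalisation
                     stats) as float64 HDF5 datasets with name vectors
    metadata.json    build parameters, cluster info, provenance, study
                     metadata, format version
    enrichment.tsv   stored GSEA table (may be absent if unannotated)
    mesh.tsv         stored MeSH table (may be absent)
    manifest.json    sha256 of every component file + format version

Loading verifies the manifest hashes and refuses models written by a
newer major format version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ClusterAssignment, NormalizationStats, PooledLoadings, RAVIndex
from .model import RAVModel

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = "1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_str_array(group, name, values) -> None:
    group.create_dataset(name, data=np.asarray([str(v) for v in values], dtype=object),
                         dtype=h5py.string_dtype("utf-8"))


def _read_str_array(group, name) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def save_model(model: RAVModel, path) -> dict:
    """Write a fitted model to ``path`` (a directory); returns the manifest."""
    model._check_fitted()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    index = model.rav_index_
    with h5py.File(path / "index.h5", "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("ravs", data=index.ravs.to_numpy(), dtype="f8")
        _write_str_array(f, "gene_ids", index.gene_ids)
        _write_str_array(f, "rav_ids", index.ravs.columns)
        f.create_dataset("pooled_loadings", data=model.pooled_.loadings.to_numpy(), dtype="f8")
        f.create_dataset("labels", data=model.assignment_.labels, dtype="i8")
        g = f.create_group("stats")
        g.create_dataset("mean", data=model.stats_.mean, dtype="f8")
        g.create_dataset("sd", data=model.stats_.sd, dtype="f8")
        _write_str_array(g, "gene_ids", model.stats_.gene_ids)

    meta = {
        "format_version": FORMAT_VERSION,
        "params": model.get_params(),
        "n_pooled": int(model.n_pooled_),
        "gsea_collection_size": getattr(model, "gsea_collection_size_", None),
        "dropped_genes": list(model.dropped_genes_),
        "cluster_info": json.loads(
            index.cluster_info.reset_index().to_json(orient="split", index=False)
        ),
        "provenance": json.loads(
            model.pooled_.provenance.assign(rav=index.provenance["rav"])
            .to_json(orient="split", index=False)
        ),
        "study_meta": None
        if model.study_meta_ is None
        else json.loads(model.study_meta_.reset_index().to_json(orient="split")),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    files = ["index.h5", "metadata.json"]
    gsea = getattr(model, "gsea_", None)
    if gsea is not None:
        gsea.to_csv(path / "enrichment.tsv", sep="\t", index=False)
        files.append("enrichment.tsv")
    mesh = getattr(model, "mesh_", None)
    if mesh is not None:
        mesh.to_csv(path / "mesh.tsv", sep="\t", index=False)
        files.append("mesh.tsv")

    manifest = {
        "format_version": FORMAT_VERSION,
        "files": {name: _sha256(path / name) for name in files},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_model(path) -> RAVModel:
    """Reload a model directory written by :func:`save_model`.

    Refuses to load when a component is missing, a content hash does not
    match the manifest, or the format major version is newer than this
    code understands.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing component: manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())

    major = int(str(manifest.get("format_version", "0")).split(".")[0])
    if major > int(FORMAT_VERSION.split(".")[0]):
        raise ValueError(
            f"model format version {manifest['format_version']} is newer than "
            f"supported {FORMAT_VERSION}"
        )
    for name, digest in manifest["files"].items():
        fp = path / name
        if not fp.exists():
            raise FileNotFoundError(f"missing component: {name}")
        if _sha256(fp) != digest:
            raise ValueError(f"content hash mismatch for component: {name}")

    meta = json.loads((path / "metadata.json").read_text())
    with h5py.File(path / "index.h5", "r") as f:
        gene_ids = pd.Index(_read_str_array(f, "gene_ids"), name="gene")
        rav_ids = _read_str_array(f, "rav_ids")
        ravs = pd.DataFrame(f["ravs"][()], index=gene_ids, columns=rav_ids)
        pooled_arr = f["pooled_loadings"][()]
        labels = f["labels"][()]
        stats = NormalizationStats(
            pd.Index(_read_str_array(f["stats"], "gene_ids"), name="gene"),
            f["stats"]["mean"][()],
            f["stats"]["sd"][()],
        )

    def _from_split(obj):
        return pd.DataFrame(obj["data"], columns=obj["columns"])

    prov = _from_split(meta["provenance"])
    cluster_info = _from_split(meta["cluster_info"]).set_index("rav")

    model = RAVModel(**meta["params"])
    model.rav_index_ = RAVIndex(ravs, cluster_info, prov)
    model.stats_ = stats
    model.genes_ = gene_ids
    model.assignment_ = ClusterAssignment(np.asarray(labels), len(rav_ids))
    model.pooled_ = PooledLoadings(
        pd.DataFrame(pooled_arr, index=gene_ids),
        prov[["study_id", "pc", "variance_explained", "is_control"]],
    )
    model.dropped_genes_ = list(meta["dropped_genes"])
    model.n_pooled_ = int(meta["n_pooled"])
    if meta["study_meta"] is None:
        model.study_meta_ = None
    else:
        sm = meta["study_meta"]
        df = pd.DataFrame(sm["data"], columns=sm["columns"])
        model.study_meta_ = df.set_index(df.columns[0])

    if meta.get("gsea_collection_size") is not None:
        model.gsea_collection_size_ = int(meta["gsea_collection_size"])
    if (path / "enrichment.tsv").exists():
        gsea = pd.read_csv(path / "enrichment.tsv", sep="\t")
        if "description" in gsea.columns:
            gsea["description"] = gsea["description"].fillna("")
        model.gsea_ = gsea
    if (path / "mesh.tsv").exists():
        model.mesh_ = pd.read_csv(path / "mesh.tsv", sep="\t")
    return model
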