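"""Readers, writers and persistence for cohorts, models and results.

On-disk layout of a cohort directory:

* ``embeddings.npz`` (key ``embeddings``, float32) or ``embeddings.h5``
  (dataset ``embeddings``) — the tile feature matrix;
* ``manifest.tsv`` — one row per tile with columns ``tile_id, slide_id,
  patient_id, weak_label, source_cluster, is_ood, sex, race``.

Manifests can be streamed in chunks without touching the embeddings; models
are stored as a single ``.npz`` of arrays plus JSON metadata; configs
round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trustwsi._nn import MLP
from trustwsi.sngp import RFFHead, SNGPConfig, SNGPModel
from trustwsi.synthetic import CohortConfig, TileTable

__all__ = [
    "MalformedManifestError",
    "cohort_config_from_yaml",
    "cohort_config_to_yaml",
    "load_model",
    "read_cohort",
    "read_manifest",
    "run_manifest",
    "save_model",
    "write_cohort",
]

MANIFEST_COLUMNS = [
    "tile_id",
    "slide_id",
    "patient_id",
    "weak_label",
    "source_cluster",
    "is_ood",
    "sex",
    "race",
]


class MalformedManifestError(ValueError):
    """Raised with the offending line number for unusable manifest rows."""


def write_cohort(tiles: TileTable, outdir: str | Path, fmt: str = "npz") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "npz":
        np.savez_compressed(
            outdir / "embeddings.npz", embeddings=tiles.embeddings.astype(np.float32)
        )
    elif fmt == "h5":
        import h5py

        with h5py.File(outdir / "embeddings.h5", "w") as f:
            f.create_dataset("embeddings", data=tiles.embeddings.astype(np.float32))
    else:
        raise ValueError(f"unknown embeddings format {fmt!r}")
    tiles.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir


def read_manifest(path: str | Path, chunksize: int | None = None):
    """Read a manifest TSV; with ``chunksize`` returns an iterator of
    DataFrame chunks so huge manifests stream without eager embedding I/O."""
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in MANIFEST_COLUMNS if c not in head.columns]
    if missing:
        raise MalformedManifestError(f"manifest {path} lacks column(s): {', '.join(missing)}")
    kwargs = dict(sep="\t", dtype={"weak_label": int})
    try:
        if chunksize:
            return pd.read_csv(path, chunksize=chunksize, **kwargs)
        return pd.read_csv(path, **kwargs)
    except (ValueError, pd.errors.ParserError) as e:
        raise MalformedManifestError(f"malformed manifest {path}: {e}") from e


def read_cohort(indir: str | Path) -> TileTable:
    indir = Path(indir)
    manifest = read_manifest(indir / "manifest.tsv")
    npz, h5 = indir / "embeddings.npz", indir / "embeddings.h5"
    if npz.exists():
        emb = np.load(npz)["embeddings"]
    elif h5.exists():
        import h5py

        with h5py.File(h5, "r") as f:
            emb = f["embeddings"][...]
    else:
        raise FileNotFoundError(f"no embeddings.npz or embeddings.h5 in {indir}")
    if len(emb) != len(manifest):
        raise MalformedManifestError(
            f"manifest has {len(manifest)} rows but embeddings {len(emb)}"
        )
    return TileTable(embeddings=emb, manifest=manifest)


def cohort_config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    d = asdict(config)
    if d.get("cluster_means") is not None:
        d["cluster_means"] = np.asarray(d["cluster_means"]).tolist()
    Path(path).write_text(yaml.safe_dump(d))


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("slides_per_patient", "tiles_per_slide", "cluster_scales"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("cluster_means") is not None:
        d["cluster_means"] = np.asarray(d["cluster_means"], dtype=float)
    return CohortConfig(**d)


def save_model(model: SNGPModel, path: str | Path) -> None:
    """Persist an SNGP model as arrays + JSON metadata in one ``.npz``."""
    arrays = {}
    for i, layer in enumerate(model.extractor.layers):
        arrays[f"layer{i}_W"] = layer.W
        arrays[f"layer{i}_b"] = layer.b
    arrays["W_L"] = np.asarray(model.head.W_L)
    arrays["b_L"] = np.asarray(model.head.b_L)
    arrays["beta"] = model.head.beta
    arrays["precision"] = model.head.precision
    meta = {
        "config": asdict(model.config),
        "n_layers": len(model.extractor.layers),
        "residual": model.extractor.residual,
        "feature_dim": model.head.feature_dim,
        "K": model.head.K,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> SNGPModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg_d = meta["config"]
    for key in ("hidden_sizes", "abmil_hidden"):
        cfg_d[key] = tuple(cfg_d[key])
    config = SNGPConfig(**cfg_d)
    n_in = data["layer0_W"].shape[1]
    mlp = MLP(
        n_in,
        config.hidden_sizes,
        np.random.default_rng(0),
        dropout=config.dropout,
        residual=meta["residual"],
    )
    for i, layer in enumerate(mlp.layers):
        layer.W = data[f"layer{i}_W"]
        layer.b = data[f"layer{i}_b"]
    head = RFFHead(
        meta["feature_dim"], D_L=config.D_L, K=meta["K"], tau=config.tau,
        rng=np.random.default_rng(0),
    )
    W_L = data["W_L"].copy()
    b_L = data["b_L"].copy()
    W_L.flags.writeable = False
    b_L.flags.writeable = False
    head.W_L, head.b_L = W_L, b_L
    head.set_posterior(data["beta"], data["precision"])
    return SNGPModel(extractor=mlp, head=head, config=config)


def run_manifest(config_obj, seed: int, path: str | Path) -> dict:
    """Write a reproducibility manifest: config hash, seed and versions."""
    cfg = config_obj if isinstance(config_obj, dict) else asdict(config_obj)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    info = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(info, indent=2, default=str))
    return info
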