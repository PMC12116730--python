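"""File formats: corpus manifests, image files, checkpoints, score tables.

Images travel as 16-bit grayscale PNG, 8/16-bit TIFF, or raw ``.npy`` arrays
beside a manifest CSV (columns: image_id, path, domain, score,
distortion_kinds, severity_levels, split, seed).  Checkpoints are single
``.npz`` archives holding every parameter array under a flattened key path
plus a JSON metadata blob (format version, phase, config echo, seed, corpus
hash); loading a checkpoint into a matching architecture reproduces forward
outputs bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import CorpusManifest, CT_IQA_RANGE, ImageRecord, ScoreRange

__all__ = [
    "CHECKPOINT_VERSION",
    "Checkpoint",
    "write_corpus",
    "read_images",
    "read_manifest",
    "save_checkpoint",
    "load_checkpoint",
    "write_scores",
    "read_scores",
]

CHECKPOINT_VERSION = 1
_MANIFEST_COLUMNS = [
    "image_id", "path", "domain", "score",
    "distortion_kinds", "severity_levels", "split", "seed",
]


# ---------------------------------------------------------------------------
# corpus files


def write_corpus(
    manifest: CorpusManifest, out_dir, image_format: str = "png"
) -> Path:
    """Write images plus a manifest CSV; returns the manifest path.

    ``png`` stores 16-bit grayscale (quantized to 1/65535); ``npy`` stores
    the float64 arrays exactly.
    """
    import pandas as pd

    if image_format not in ("png", "npy"):
        raise ValueError("image_format must be 'png' or 'npy'")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in manifest.records:
        rel = f"images/{r.image_id}.{image_format}"
        fp = out_dir / rel
        if image_format == "npy":
            np.save(fp, r.pixels)
        else:
            from PIL import Image

            arr = np.clip(np.round(r.pixels * 65535.0), 0, 65535).astype(np.uint16)
            Image.fromarray(arr).save(fp)
        rows.append(
            {
                "image_id": r.image_id,
                "path": rel,
                "domain": r.domain,
                "score": r.score,
                "distortion_kinds": "|".join(d.kind for d in r.distortions),
                "severity_levels": "|".join(f"{d.level:g}" for d in r.distortions),
                "split": r.split,
                "seed": r.distortions[0].seed if r.distortions else 0,
            }
        )
    path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)
    with open(out_dir / "generator_config.json", "w") as fh:
        json.dump(manifest.generator_config, fh, indent=2, default=str)
    return path


def _load_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    if arr.ndim != 2:
        raise ValueError(f"non-grayscale image (ndim={arr.ndim}): {path.name}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype in (np.uint16, np.int32):  # PIL I;16 loads as int32
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def read_images(manifest_path, skip_bad: bool = False) -> list[ImageRecord]:
    """Load every manifest row into an :class:`ImageRecord`, in row order.

    Per-record failures abort the run with a collected error report unless
    ``skip_bad`` is set, in which case offending rows are dropped.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in ("image_id", "path", "score") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    records, errors = [], []
    for _, row in df.iterrows():
        try:
            pixels = _load_image(manifest_path.parent / row["path"])
            records.append(
                ImageRecord(
                    image_id=str(row["image_id"]),
                    pixels=pixels,
                    score=float(row["score"]),
                    domain=str(row.get("domain", "target")),
                    split=str(row.get("split", "train")),
                )
            )
        except Exception as exc:  # noqa: BLE001 - aggregated into the report
            errors.append(f"{row['image_id']}: {exc}")
    if errors and not skip_bad:
        raise IOError(
            "failed to load {} record(s):\n  {}".format(len(errors), "\n  ".join(errors))
        )
    return records


def read_manifest(
    manifest_path, score_range: ScoreRange = CT_IQA_RANGE, skip_bad: bool = False
) -> CorpusManifest:
    """Full corpus read-back: records plus domain/score-range packaging."""
    records = read_images(manifest_path, skip_bad=skip_bad)
    if not records:
        raise ValueError(f"no readable records in {manifest_path}")
    domain = records[0].domain
    return CorpusManifest(records, domain, score_range,
                          {"loaded_from": str(manifest_path)})


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class Checkpoint:
    params: dict
    phase: str
    config: dict
    seed: int
    manifest_hash: str
    version: int


def _flatten_tree(tree, prefix=""):
    out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            if "/" in str(k):
                raise ValueError(f"parameter key may not contain '/': {k!r}")
            out.update(_flatten_tree(v, f"{prefix}{k}/"))
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            out.update(_flatten_tree(v, f"{prefix}#{i}/"))
    else:
        out[prefix[:-1]] = np.asarray(tree)
    return out


def _unflatten_tree(flat: dict):
    root: dict = {}
    for key, value in flat.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        leaf = value
        node[parts[-1]] = float(leaf) if leaf.ndim == 0 else leaf
    return _listify(root)


def _listify(node):
    if not isinstance(node, dict):
        return node
    if node and all(k.startswith("#") for k in node):
        return [
            _listify(node[f"#{i}"]) for i in range(len(node))
        ]
    return {k: _listify(v) for k, v in node.items()}


def save_checkpoint(
    path,
    params: dict,
    phase: str,
    config: dict | None = None,
    seed: int = 0,
    manifest_hash: str = "",
) -> None:
    """Single-file archive of all parameters plus JSON metadata."""
    flat = _flatten_tree(params)
    meta = json.dumps(
        {
            "version": CHECKPOINT_VERSION,
            "phase": phase,
            "config": config or {},
            "seed": seed,
            "manifest_hash": manifest_hash,
        },
        default=str,
    )
    np.savez(path, __meta__=np.bytes_(meta.encode()), **flat)


def load_checkpoint(path) -> Checkpoint:
    """Read a checkpoint back; rejects unknown format versions."""
    try:
        with np.load(path, allow_pickle=False) as z:
            if "__meta__" not in z:
                raise ValueError("not a checkpoint: metadata block missing")
            meta = json.loads(bytes(z["__meta__"].item()).decode())
            flat = {k: z[k] for k in z.files if k != "__meta__"}
    except (OSError, ValueError) as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint format version {meta.get('version')} incompatible with "
            f"supported version {CHECKPOINT_VERSION}"
        )
    return Checkpoint(
        params=_unflatten_tree(flat),
        phase=meta["phase"],
        config=meta["config"],
        seed=meta["seed"],
        manifest_hash=meta["manifest_hash"],
        version=meta["version"],
    )


# ---------------------------------------------------------------------------
# score tables


def write_scores(path, image_ids, predicted, reference=None) -> None:
    import pandas as pd

    data = {"image_id": list(image_ids), "predicted_score": list(predicted)}
    if reference is not None:
        data["reference_score"] = list(reference)
    pd.DataFrame(data).to_csv(path, index=False)


def read_scores(path):
    import pandas as pd

    df = pd.read_csv(path)
    if "predicted_score" not in df.columns:
        raise ValueError("scores CSV must contain a predicted_score column")
    return df
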