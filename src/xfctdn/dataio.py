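"""Dataset persistence: TIFF images + a JSON manifest.

Normalized (noisy, clean) pairs are written as 32-bit float TIFFs; the
manifest records pair paths, metadata (noise level, bin width,
augmentation tag, phantom id), split membership and the normalization
constants, so a dataset on disk is self-describing and byte-reproducible
for a fixed seed (keys are sorted and no timestamps are stored).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .phantom import DatasetSplit, ImagePair, PairMeta

__all__ = ["save_dataset", "load_dataset", "write_run_manifest"]


def save_dataset(pairs: Sequence[ImagePair], split: DatasetSplit, out_dir,
                 extra_meta: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        noisy_rel = f"images/pair{i:05d}_noisy.tif"
        clean_rel = f"images/pair{i:05d}_clean.tif"
        tifffile.imwrite(out_dir / noisy_rel,
                         pair.noisy.astype(np.float32))
        tifffile.imwrite(out_dir / clean_rel,
                         pair.clean.astype(np.float32))
        entries.append({"id": i, "noisy": noisy_rel, "clean": clean_rel,
                        "meta": asdict(pair.meta)})
    manifest = {
        "pairs": entries,
        "split": {"train_ids": list(split.train_ids),
                  "test_ids": list(split.test_ids),
                  "test_fraction": split.test_fraction},
        "extra": extra_meta or {},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_dataset(manifest_path) -> tuple[list[ImagePair], DatasetSplit, dict]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    pairs = []
    for e in manifest["pairs"]:
        meta = PairMeta(**e["meta"])
        pairs.append(ImagePair(
            noisy=tifffile.imread(root / e["noisy"]).astype(np.float64),
            clean=tifffile.imread(root / e["clean"]).astype(np.float64),
            meta=meta))
    sp = manifest["split"]
    split = DatasetSplit(train_ids=tuple(sp["train_ids"]),
                         test_ids=tuple(sp["test_ids"]),
                         test_fraction=sp["test_fraction"])
    return pairs, split, manifest.get("extra", {})


def write_run_manifest(out_dir, command: str, params: dict) -> Path:
    """Record the exact configuration of a CLI run (no timestamps)."""
    import xfctdn
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"command": command, "params": params,
               "version": xfctdn.__version__,
               "numpy": np.__version__}
    path = out_dir / f"run_{command}.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
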