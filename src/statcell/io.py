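"""Image, table, config and checkpoint I/O.

Images travel as OME-TIFF with named channels (MEMB/NUC/STRUCT); channel
semantics are resolved from the OME metadata by name, not by order, with
the canonical (MEMB, NUC[, STRUCT]) order restored on read.  Checkpoints
are .npz archives carrying the network spec, every trainable array and the
normalization buffers, so a restored model reproduces embeddings
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .architecture import NetworkSpec, VAEModel
from .image import MEMB, NUC, STRUCT, CellImage
from .nn.layers import collect_state, restore_state
from .phantom import PhantomDataset, StructureKind
from .preprocessing import PreprocessConfig
from .training import TrainConfig

logger = logging.getLogger(__name__)

_CANONICAL = (MEMB, NUC, STRUCT)


def write_image(image: CellImage, path) -> None:
    """One cell per file; axes CYX or CZYX; channels named in OME metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    axes = "CZYX" if image.is_3d else "CYX"
    tifffile.imwrite(
        path,
        image.data,
        ome=True,
        metadata={
            "axes": axes,
            "Channel": {"Name": list(image.channel_names)},
            "PhysicalSizeX": image.pixel_size,
            "PhysicalSizeY": image.pixel_size,
        },
    )


def _channel_names_from_ome(ome_xml: str, n: int) -> tuple:
    names = re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome_xml or "")
    if len(names) == n:
        return tuple(names)
    return tuple(_CANONICAL[:n]) if n <= 3 else tuple(f"C{i}" for i in range(n))


def read_image(path, channel_names=None) -> CellImage:
    """Load an OME-TIFF cell image, resolving channels by OME name.

    Channels are reordered to canonical (MEMB, NUC[, STRUCT]) when the
    names allow it; a ``channel_names`` override acts as a sidecar mapping
    for plain TIFFs.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome = tf.ome_metadata
    except (FileNotFoundError, tifffile.TiffFileError, ValueError) as e:
        raise IOError(f"cannot read image {path}: {e}") from e
    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise IOError(f"{path}: unsupported array rank {data.ndim}")
    n = data.shape[0]
    if n < 2:
        raise IOError(f"{path}: expected >= 2 channels, found {n}")
    names = tuple(channel_names) if channel_names else _channel_names_from_ome(ome, n)
    if set(_CANONICAL[:n]) == set(names) and names != _CANONICAL[:n]:
        order = [names.index(c) for c in _CANONICAL[:n]]
        data = data[order]
        names = _CANONICAL[:n]
    return CellImage(np.asarray(data, dtype=np.float32), names)


def save_population(dataset: PhantomDataset, out_dir) -> Path:
    """Write one OME-TIFF per cell plus the metadata CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, im in enumerate(dataset.images):
        write_image(im, out_dir / f"cell_{i:05d}.ome.tiff")
    dataset.metadata.to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def load_population(in_dir) -> PhantomDataset:
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.csv")
    images = [
        read_image(in_dir / f"cell_{int(i):05d}.ome.tiff")
        for i in meta["cell_id"]
    ]
    kinds = tuple(
        sorted({StructureKind(v) for v in meta["label"]}, key=lambda k: k.value)
    )
    return PhantomDataset(images=images, metadata=meta, kinds=kinds)


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model: VAEModel, path, out_channels: int | None = None, **extra):
    """Spec + weights + buffers + run metadata in one .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = collect_state(model)
    meta = {
        "spec": dataclasses.asdict(model.spec),
        "out_channels": out_channels
        or model.decoder.blocks[-1].conv3._cout,
        "extra": extra,
    }
    np.savez_compressed(path, __meta__=np.bytes_(json.dumps(meta)), **state)


def load_checkpoint(path) -> VAEModel:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    spec_dict = meta["spec"]
    for key in ("input_shape", "channels"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = NetworkSpec(**spec_dict)
    model = VAEModel(spec, out_channels=meta["out_channels"])
    restore_state(model, state)
    return model


# -- run configuration ------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved configuration written next to every run's outputs."""

    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    network: NetworkSpec = dataclasses.field(default_factory=NetworkSpec)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    analysis: dict = dataclasses.field(default_factory=dict)

    def to_yaml(self, path=None) -> str:
        doc = {
            "data_dir": self.data_dir,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "network": dataclasses.asdict(self.network),
            "training": dataclasses.asdict(self.training),
            "preprocess": dataclasses.asdict(self.preprocess),
            "analysis": self.analysis,
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        net = doc.get("network", {})
        for key in ("input_shape", "channels"):
            if key in net:
                net[key] = tuple(net[key])
        tr = doc.get("training", {})
        for key in ("adam_betas", "split_fractions"):
            if key in tr:
                tr[key] = tuple(tr[key])
        pp = doc.get("preprocess", {})
        if "target_shape" in pp:
            pp["target_shape"] = tuple(pp["target_shape"])
        return cls(
            data_dir=doc.get("data_dir", "data"),
            out_dir=doc.get("out_dir", "out"),
            seed=doc.get("seed", 0),
            network=NetworkSpec(**net),
            training=TrainConfig(**tr),
            preprocess=PreprocessConfig(**pp),
            analysis=doc.get("analysis", {}),
        )


def write_run_outputs(out_dir, config: RunConfig, tables: dict | None = None,
                      images: dict | None = None) -> Path:
    """CSV tables, OME-TIFF images, config snapshot and a seed-stamped log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    for name, df in (tables or {}).items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    for name, im in (images or {}).items():
        write_image(im, out_dir / f"{name}.ome.tiff")
    (out_dir / "run.log").write_text(
        f"master_seed={config.seed}\nnumpy={np.__version__}\n"
    )
    return out_dir
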