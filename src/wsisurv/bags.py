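"""Per-slide feature bags: encoding, HDF5 serialization, patient merging.

A bag is the unit the MIL model consumes: one row of features per kept tile
plus the tile's level-0 pixel coordinates. Files use HDF5 with datasets
``feats`` (float32, n x d) and ``coords`` (int32, n x 2) and identifying
attributes, one file per slide.

Tile encoders are pluggable. The built-in "mock" encoder is a seeded linear
projection of the flattened image followed by tanh — deterministic, fast and
injective enough for pipeline testing. Adapters for external pretrained
encoders (e.g. a histology foundation model producing 1024-d vectors) plug in
through the same interface; requesting one that is not installed raises
immediately rather than silently falling back.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = ["FeatureBag", "EncoderSpec", "MockEncoder", "get_encoder",
           "encode_tiles", "write_bag", "read_bag", "merge_patient_bags"]


@dataclass
class FeatureBag:
    slide_id: str
    patient_id: str
    feats: np.ndarray          # (n_tiles, d) float32
    coords: np.ndarray         # (n_tiles, 2) int32, level-0 (x, y)
    slide_index: np.ndarray | None = None   # per-row slide provenance after merging

    def __post_init__(self):
        self.feats = np.asarray(self.feats, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.feats.ndim != 2 or self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("feats must be (n, d), coords must be (n, 2)")
        if self.feats.shape[0] != self.coords.shape[0]:
            raise ValueError("feats and coords row counts differ")
        if self.feats.shape[0] < 1:
            raise ValueError("bag must contain at least one tile")
        if not np.all(np.isfinite(self.feats)):
            raise ValueError("non-finite feature values")

    @property
    def n_tiles(self) -> int:
        return self.feats.shape[0]

    @property
    def dim(self) -> int:
        return self.feats.shape[1]


@dataclass(frozen=True)
class EncoderSpec:
    name: str
    output_dim: int
    deterministic: bool = True

    def __post_init__(self):
        if self.output_dim <= 0:
            raise ValueError("output_dim must be positive")


class MockEncoder:
    """Seeded random linear projection + tanh of the [0,1]-scaled image.

    Deterministic given (seed, image); distinct images map to distinct
    feature rows with probability 1 over the projection draw.
    """

    name = "mock"

    def __init__(self, output_dim: int = 1024, seed: int = 0, input_side: int = 224):
        rng = np.random.default_rng(seed)
        n_in = input_side * input_side * 3
        self.input_side = input_side
        self.output_dim = output_dim
        # scale keeps pre-tanh activations O(1)
        self.weight = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, output_dim))

    def spec(self) -> EncoderSpec:
        return EncoderSpec(name=self.name, output_dim=self.output_dim, deterministic=True)

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        s = self.input_side
        if tiles.shape[1:] != (s, s, 3):
            raise ValueError(f"expected tiles of shape ({s}, {s}, 3), got {tiles.shape[1:]}")
        flat = tiles.reshape(tiles.shape[0], -1).astype(np.float64) / 255.0
        return np.tanh(flat @ self.weight).astype(np.float32)


def get_encoder(name: str, output_dim: int = 1024, seed: int = 0, input_side: int = 224):
    """Resolve an encoder by name; `adapter:<pkg>` names require the package."""
    if name == "mock":
        return MockEncoder(output_dim=output_dim, seed=seed, input_side=input_side)
    if name.startswith("adapter:"):
        raise RuntimeError(
            f"encoder not installed: {name!r}; install the backing package or use 'mock'")
    raise ValueError(f"unknown encoder {name!r}")


def encode_tiles(tiles, encoder) -> np.ndarray:
    """Encode an ordered stack of 224x224 RGB tiles to a feature matrix."""
    tiles = np.asarray(tiles)
    feats = encoder(tiles)
    if feats.shape != (tiles.shape[0] if tiles.ndim == 4 else 1, encoder.output_dim):
        raise RuntimeError("encoder returned a matrix of unexpected shape")
    return feats


def write_bag(bag: FeatureBag, path, *, encoder_name: str = "", tile_um: float = 256.0,
              overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("feats", data=bag.feats.astype(np.float32))
        fh.create_dataset("coords", data=bag.coords.astype(np.int32))
        if bag.slide_index is not None:
            fh.create_dataset("slide_index", data=np.asarray(bag.slide_index, dtype=np.int32))
        fh.attrs["slide_id"] = bag.slide_id
        fh.attrs["patient_id"] = bag.patient_id
        fh.attrs["encoder_name"] = encoder_name
        fh.attrs["tile_um"] = float(tile_um)


def read_bag(path) -> FeatureBag:
    with h5py.File(path, "r") as fh:
        bag = FeatureBag(
            slide_id=fh.attrs["slide_id"],
            patient_id=fh.attrs["patient_id"],
            feats=fh["feats"][...],
            coords=fh["coords"][...],
            slide_index=fh["slide_index"][...] if "slide_index" in fh else None,
        )
    return bag


def merge_patient_bags(bags: list[FeatureBag]) -> FeatureBag:
    """Concatenate all slides of one patient, keeping per-row slide provenance."""
    if not bags:
        raise ValueError("no bags to merge")
    pid = bags[0].patient_id
    if any(b.patient_id != pid for b in bags):
        raise ValueError("bags belong to different patients")
    dims = {b.dim for b in bags}
    if len(dims) != 1:
        raise ValueError(f"mixed feature dimensions {sorted(dims)}")
    if len(bags) == 1:
        return bags[0]
    feats = np.concatenate([b.feats for b in bags], axis=0)
    coords = np.concatenate([b.coords for b in bags], axis=0)
    slide_index = np.concatenate(
        [np.full(b.n_tiles, i, dtype=np.int32) for i, b in enumerate(bags)])
    return FeatureBag(slide_id="+".join(b.slide_id for b in bags), patient_id=pid,
                      feats=feats, coords=coords, slide_index=slide_index)
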