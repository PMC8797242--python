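"""Synthetic cell phantoms with known geometry and known structure coupling.

A phantom is an ellipsoidal (ellipse in 2D) cell containing an ellipsoidal
nucleus.  The two reference channels emulate a membrane dye (cell interior
fill plus a bright cortical rim) and a DNA dye (filled nucleus).  The
structure channel is produced by a stated, tunable localization rule so
that coupling statistics and feature extraction can be validated against
ground truth:

* ``envelope`` — a shell hugging the nucleus boundary (nuclear-envelope-like);
* ``cortex`` — a band just inside the cell boundary (membrane-associated);
* ``cytoplasmic_puncta`` — random blobs in the cytoplasm (organelle-like);
* five control kinds — a blank channel, duplicates of the DNA and membrane
  channels, Gaussian noise masked to the dye support, and a random swap of
  another cell's structure channel (resolved at population level).

Intensity profiles are smooth ramps of the implicit ellipse coordinate, so
every channel's support is exactly its analytic mask — the invariant the
tests integrate against.  All randomness flows from one master seed through
a counter-based per-cell seed scheme, making populations bit-reproducible
and stable under subsetting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import MEMB, NUC, STRUCT, CellImage

__all__ = [
    "StructureKind",
    "PhantomParams",
    "PhantomDataset",
    "generate_reference",
    "generate_structure",
    "generate_population",
    "cell_seed",
]


class StructureKind(str, enum.Enum):
    ENVELOPE = "envelope"
    CORTEX = "cortex"
    CYTOPLASMIC_PUNCTA = "cytoplasmic_puncta"
    CONTROL_BLANK = "control_blank"
    CONTROL_DNA_DUP = "control_dna_dup"
    CONTROL_MEMB_DUP = "control_memb_dup"
    CONTROL_NOISE = "control_noise"
    CONTROL_RANDOM_SWAP = "control_random_swap"


CONTROL_KINDS = frozenset(
    {
        StructureKind.CONTROL_BLANK,
        StructureKind.CONTROL_DNA_DUP,
        StructureKind.CONTROL_MEMB_DUP,
        StructureKind.CONTROL_NOISE,
        StructureKind.CONTROL_RANDOM_SWAP,
    }
)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one phantom cell."""

    image_shape: tuple = (64, 64)  # (y, x) or (z, y, x)
    cell_semiaxes: tuple = (24.0, 18.0)
    nucleus_semiaxes: tuple = (11.0, 8.0)
    orientation: float = 0.0  # in-plane rotation, radians
    center_offset: tuple | None = None  # of the cell, pixels from image center
    nucleus_offset: tuple | None = None  # of the nucleus, pixels from cell center
    baseline: float = 0.0  # added inside each channel's support
    amplitude: tuple | float = 0.9  # peak intensity, scalar or per channel (memb, nuc, struct)
    noise_scale: float = 0.0  # additive Gaussian noise sd
    edge_width: float = 0.25  # boundary softness, in units of the ellipse coord
    structure_kind: StructureKind = StructureKind.CYTOPLASMIC_PUNCTA
    seed: int = 0

    def __post_init__(self):
        d = len(self.image_shape)
        if d not in (2, 3):
            raise ValueError("image_shape must be 2D or 3D")
        for name in ("cell_semiaxes", "nucleus_semiaxes"):
            if len(getattr(self, name)) != d:
                raise ValueError(f"{name} rank must match image_shape")
        for ax, (cn, cc) in enumerate(zip(self.nucleus_semiaxes, self.cell_semiaxes)):
            if cn >= cc:
                raise ValueError(
                    f"nucleus semi-axis {cn} on axis {ax} must be strictly "
                    f"smaller than the cell semi-axis {cc}"
                )
        for ax, (a, s) in enumerate(zip(self.cell_semiaxes, self.image_shape)):
            if 2 * a > s - 4:
                raise ValueError(
                    f"cell semi-axis {a} on axis {ax} does not fit into image "
                    f"extent {s} with a 2-pixel margin"
                )

    @property
    def dimensionality(self) -> int:
        return len(self.image_shape)

    def channel_amplitude(self, channel: int) -> float:
        """Per-channel peak intensity: 0=membrane, 1=nucleus, 2=structure."""
        if np.isscalar(self.amplitude):
            return float(self.amplitude)
        return float(self.amplitude[channel])


def _rotated_coords(shape, orientation, center):
    """Coordinate grids rotated by -orientation in the last two axes."""
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"
    )
    rel = [g - c for g, c in zip(grids, center)]
    c, s = np.cos(orientation), np.sin(orientation)
    # rotate in the (row, col) plane of the last two axes
    y, x = rel[-2], rel[-1]
    rel[-2] = c * y - s * x
    rel[-1] = s * y + c * x
    return rel


def _ellipse_field(shape, semiaxes, orientation, center):
    """Implicit coordinate f(p) = sum((p_i/a_i)^2); mask is f <= 1."""
    rel = _rotated_coords(shape, orientation, center)
    f = np.zeros(shape, dtype=np.float64)
    for r, a in zip(rel, semiaxes):
        f += (r / a) ** 2
    return f


def _fields(params: PhantomParams):
    shape = params.image_shape
    center = np.array(shape, dtype=np.float64) / 2.0 - 0.5
    if params.center_offset is not None:
        center = center + np.asarray(params.center_offset, dtype=np.float64)
    ncenter = center.copy()
    if params.nucleus_offset is not None:
        ncenter = ncenter + np.asarray(params.nucleus_offset, dtype=np.float64)
    f_cell = _ellipse_field(shape, params.cell_semiaxes, params.orientation, center)
    f_nuc = _ellipse_field(shape, params.nucleus_semiaxes, params.orientation, ncenter)
    return f_cell, f_nuc


def _ramp(f: np.ndarray, width: float) -> np.ndarray:
    """Smooth fill: 1 deep inside (f=0), 0 at and outside the boundary f=1."""
    return np.clip((1.0 - f) / width, 0.0, 1.0)


def _shell(f: np.ndarray, loc: float, width: float) -> np.ndarray:
    """Smooth bump of the implicit coordinate centred at f = loc."""
    return np.exp(-(((f - loc) / width) ** 2))


def generate_reference(params: PhantomParams) -> CellImage:
    """Two-channel reference phantom: membrane-like and nucleus-like dyes.

    Deterministic given ``params`` (including its seed).  Channel supports
    are exactly the analytic cell and nucleus masks when ``noise_scale=0``.
    """
    f_cell, f_nuc = _fields(params)
    base, w = params.baseline, params.edge_width
    amp_m = params.channel_amplitude(0)
    amp_n = params.channel_amplitude(1)
    cell_fill = _ramp(f_cell, w)
    rim = _shell(f_cell, 0.82, 0.10) * (f_cell <= 1.0)
    memb = np.clip(
        (base + 0.4 * amp_m) * (cell_fill > 0) * cell_fill + amp_m * rim, 0, 1
    )
    nuc = np.clip((base + amp_n) * _ramp(f_nuc, w), 0, 1)
    rng = np.random.default_rng(params.seed)
    if params.noise_scale > 0:
        memb = np.clip(memb + params.noise_scale * rng.standard_normal(memb.shape), 0, 1)
        nuc = np.clip(nuc + params.noise_scale * rng.standard_normal(nuc.shape), 0, 1)
    data = np.stack([memb, nuc]).astype(np.float32)
    return CellImage(data, (MEMB, NUC), meta={"phantom_params": params})


def generate_structure(
    reference: CellImage, kind: StructureKind | str, seed: int = 0
) -> np.ndarray:
    """Structure channel coupled to the reference by the stated rule.

    ``control_random_swap`` has no single-cell meaning and is resolved by
    :func:`generate_population`; requesting it here raises.
    """
    kind = StructureKind(kind)
    if reference.n_channels != 2:
        raise ValueError("reference must have exactly the 2 dye channels")
    if kind is StructureKind.CONTROL_BLANK:
        return np.zeros(reference.spatial_shape, dtype=np.float32)
    if kind is StructureKind.CONTROL_DNA_DUP:
        return reference.channel(NUC).copy()
    if kind is StructureKind.CONTROL_MEMB_DUP:
        return reference.channel(MEMB).copy()
    params: PhantomParams | None = reference.meta.get("phantom_params")
    if params is None:
        raise ValueError(
            f"{kind.value} requires phantom geometry metadata on the reference"
        )
    f_cell, f_nuc = _fields(params)
    amp = params.channel_amplitude(2)
    rng = np.random.default_rng(seed)
    if kind is StructureKind.CONTROL_NOISE:
        support = (f_cell <= 1.0) | (f_nuc <= 1.0)
        return np.clip(rng.standard_normal(f_cell.shape) * support, 0, 1).astype(
            np.float32
        )
    if kind is StructureKind.ENVELOPE:
        ch = amp * _shell(f_nuc, 1.0, 0.12)
    elif kind is StructureKind.CORTEX:
        ch = amp * _shell(f_cell, 0.90, 0.07) * (f_cell <= 1.0)
    elif kind is StructureKind.CYTOPLASMIC_PUNCTA:
        cyto = (f_cell < 0.8) & (f_nuc > 1.3)
        idx = np.argwhere(cyto)
        ch = np.zeros(f_cell.shape, dtype=np.float64)
        if len(idx):
            n_puncta = 12 if params.dimensionality == 2 else 20
            centers = idx[rng.integers(0, len(idx), size=n_puncta)]
            grids = np.meshgrid(
                *[np.arange(s, dtype=np.float64) for s in f_cell.shape], indexing="ij"
            )
            for c in centers:
                r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
                ch += amp * np.exp(-r2 / (2 * 1.6**2))
        ch *= f_cell <= 1.0
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"population-level kind {kind.value} at single-cell scope")
    return np.clip(ch, 0, 1).astype(np.float32)


def cell_seed(master_seed: int, index: int) -> int:
    """Counter-scheme per-cell seed: stable under population subsetting."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PhantomDataset:
    images: list
    metadata: pd.DataFrame
    kinds: tuple  # label_index -> StructureKind, sorted by enum value

    def __len__(self) -> int:
        return len(self.images)

    def arrays(self) -> np.ndarray:
        return np.stack([im.data for im in self.images])


def _allocate_counts(n: int, fractions: dict) -> dict:
    """Largest-remainder rounding of n * fraction to integers summing to n."""
    kinds = sorted(fractions, key=lambda k: StructureKind(k).value)
    raw = {k: n * fractions[k] for k in kinds}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(kinds, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def generate_population(
    n: int,
    kind_mix: dict,
    base_params: PhantomParams = PhantomParams(),
    seed: int = 0,
    geometry_jitter: float = 0.12,
    orientation_jitter: float = 0.35,
    center_jitter: float = 2.0,
    intensity_jitter: float = 0.15,
    mitosis_fraction: float = 0.1,
) -> PhantomDataset:
    """Population of three-channel phantoms with per-cell metadata.

    Geometry is jittered around ``base_params``; a ``mitosis_fraction`` of
    cells get the rounder "mitotic" geometry (near-equal semi-axes, taller
    in 3D), the rest are tagged interphase.  ``control_random_swap`` cells
    receive another randomly chosen cell's pre-swap structure channel.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not kind_mix:
        raise ValueError("kind_mix must contain at least one structure kind")
    fractions = {StructureKind(k): float(v) for k, v in kind_mix.items()}
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError(f"kind fractions sum to {sum(fractions.values())}, not 1")
    counts = _allocate_counts(n, fractions)
    kinds_sorted = tuple(sorted(fractions, key=lambda k: k.value))
    kind_index = {k: i for i, k in enumerate(kinds_sorted)}

    master = np.random.default_rng(seed)
    assignment = np.repeat(
        [k.value for k in kinds_sorted], [counts[k] for k in kinds_sorted]
    )
    master.shuffle(assignment)
    phase_draw = master.random(n)

    images, rows, provisional = [], [], []
    d = base_params.dimensionality
    for i in range(n):
        s_i = cell_seed(seed, i)
        rng = np.random.default_rng(s_i)
        kind = StructureKind(assignment[i])
        mitotic = phase_draw[i] < mitosis_fraction
        cell_ax = np.array(base_params.cell_semiaxes, dtype=np.float64)
        nuc_ax = np.array(base_params.nucleus_semiaxes, dtype=np.float64)
        cell_ax *= 1.0 + geometry_jitter * rng.uniform(-1, 1, size=d)
        nuc_ax *= 1.0 + geometry_jitter * rng.uniform(-1, 1, size=d)
        if mitotic:
            # rounder cell; taller along the first (z / y) axis
            r = cell_ax.mean()
            cell_ax = 0.35 * cell_ax + 0.65 * r
            cell_ax[0] *= 1.15
            rn = nuc_ax.mean()
            nuc_ax = 0.35 * nuc_ax + 0.65 * rn
        # keep the jittered/mitotic geometry inside the stated image margin
        max_ax = (np.array(base_params.image_shape, dtype=np.float64) - 4.0) / 2.0
        cell_ax = np.minimum(cell_ax, 0.98 * max_ax)
        nuc_ax = np.minimum(nuc_ax, 0.85 * cell_ax)
        theta = float(base_params.orientation + orientation_jitter * rng.uniform(-1, 1))
        off = rng.uniform(-center_jitter, center_jitter, size=d)
        noff = rng.uniform(-3.0, 3.0, size=d)
        # cell-to-cell dye brightness variability, independent per channel
        base_amp = np.array(
            [base_params.channel_amplitude(c) for c in range(3)], dtype=np.float64
        )
        amp = tuple(
            np.clip(
                base_amp * (1.0 + intensity_jitter * rng.uniform(-1, 1, size=3)),
                0.05,
                1.0,
            )
        )
        p = replace(
            base_params,
            cell_semiaxes=tuple(cell_ax),
            nucleus_semiaxes=tuple(nuc_ax),
            orientation=theta,
            center_offset=tuple(off),
            nucleus_offset=tuple(noff),
            amplitude=amp,
            structure_kind=kind,
            seed=s_i,
        )
        ref = generate_reference(p)
        pre_kind = (
            StructureKind.CYTOPLASMIC_PUNCTA
            if kind is StructureKind.CONTROL_RANDOM_SWAP
            else kind
        )
        struct = generate_structure(ref, pre_kind, seed=s_i)
        provisional.append(struct)
        images.append(ref)
        rows.append(
            {
                "cell_id": i,
                "label": kind.value,
                "label_index": kind_index[kind],
                "phase": "mitosis" if mitotic else "interphase",
                "seed": s_i,
                "cell_semiaxes": ";".join(f"{a:.3f}" for a in cell_ax),
                "nucleus_semiaxes": ";".join(f"{a:.3f}" for a in nuc_ax),
                "orientation": theta,
            }
        )

    swap_rng = np.random.default_rng(cell_seed(seed, n))  # one past the last cell
    final = []
    for i, (ref, row) in enumerate(zip(images, rows)):
        ch = provisional[i]
        if row["label"] == StructureKind.CONTROL_RANDOM_SWAP.value and n > 1:
            j = int(swap_rng.integers(0, n - 1))
            j = j if j < i else j + 1  # uniform over all other cells
            ch = provisional[j]
            row["swap_source"] = j
        final.append(ref.with_channel(STRUCT, ch))
    meta = pd.DataFrame(rows)
    return PhantomDataset(images=final, metadata=meta, kinds=kinds_sorted)
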