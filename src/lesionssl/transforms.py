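"""Exactly invertible spatial transforms for consistency regularization.

The teacher branch of the mean-teacher scheme sees a spatially transformed
copy of each volume; its output is mapped back through the inverse transform
before being compared with the student output.  For that comparison to be
meaningful the transform must have an *exact* voxel-level inverse — no
interpolation.  The family implemented here is therefore restricted to

* axis flips,
* rotations by multiples of 90 degrees in an axis-aligned plane,
* integer-voxel translations (zero padding on the way in, with the voxels
  lost at the border tracked by :meth:`ReversibleTransform.valid_mask`).

Transforms act on the trailing three axes, so the same object can be applied
to a ``(z, y, x)`` volume, a ``(c, z, y, x)`` multi-channel image or a
probability map without modification (permutation equivariance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

AXES = ("z", "y", "x")
PRIMITIVES = ("flip", "rot90", "translate")

# planes for 90-degree rotations, as pairs of trailing-axis indices
PLANES = ((0, 1), (0, 2), (1, 2))


def _shift(volume: np.ndarray, offsets: Sequence[int], fill: float = 0.0) -> np.ndarray:
    """Translate by integer voxels along the trailing three axes, filling with `fill`."""
    out = np.full_like(volume, fill)
    src = [slice(None)] * volume.ndim
    dst = [slice(None)] * volume.ndim
    for i, off in enumerate(offsets):
        ax = volume.ndim - 3 + i
        n = volume.shape[ax]
        if abs(off) >= n:
            return out
        if off >= 0:
            src[ax] = slice(0, n - off)
            dst[ax] = slice(off, n)
        else:
            src[ax] = slice(-off, n)
            dst[ax] = slice(0, n + off)
    out[tuple(dst)] = volume[tuple(src)]
    return out


@dataclass(frozen=True)
class ReversibleTransform:
    """An ordered composite of flip / right-angle rotation / integer translation.

    Parameters
    ----------
    ops
        Sequence of primitives, each one of ``("flip", axis)``,
        ``("rot90", (ax_a, ax_b), k)`` or ``("translate", (dz, dy, dx))``
        with axes given as trailing-axis indices (0 = z, 1 = y, 2 = x).
    grid_shape
        Optional shape of the trailing three axes, used for validation.
    """

    ops: tuple = ()
    grid_shape: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "ops", tuple(tuple(_freeze(p)) for p in self.ops))
        for op in self.ops:
            kind = op[0]
            if kind == "flip":
                if op[1] not in (0, 1, 2):
                    raise ValueError(f"flip axis must be 0, 1 or 2, got {op[1]}")
            elif kind == "rot90":
                plane, k = op[1], op[2]
                if tuple(plane) not in PLANES:
                    raise ValueError(f"rotation plane must be one of {PLANES}, got {plane}")
                if k not in (0, 1, 2, 3):
                    raise ValueError(f"rotation count k must be in 0..3, got {k}")
            elif kind == "translate":
                if len(op[1]) != 3:
                    raise ValueError("translation needs one integer offset per axis")
            else:
                raise ValueError(f"unknown primitive {kind!r}")

    # -- application ------------------------------------------------------

    def _check(self, volume: np.ndarray) -> None:
        if volume.ndim < 3:
            raise ValueError("volume must have at least 3 dimensions")
        shape = volume.shape[-3:]
        if self.grid_shape is not None and tuple(shape) != tuple(self.grid_shape):
            raise ValueError(
                f"volume grid {shape} does not match transform grid {self.grid_shape}"
            )
        for op in self.ops:
            if op[0] == "rot90" and op[2] % 2 == 1:
                a, b = op[1]
                if shape[a] != shape[b]:
                    raise ValueError(
                        f"odd rotation in plane {op[1]} requires equal extents, "
                        f"got {shape[a]} x {shape[b]}"
                    )
            if op[0] == "translate" and any(
                abs(o) >= shape[i] for i, o in enumerate(op[1])
            ):
                raise ValueError("translation offset exceeds grid extent")

    def apply(self, volume: np.ndarray) -> np.ndarray:
        """Apply the composite transform (voxel permutation + zero fill)."""
        self._check(volume)
        v = volume
        nd = volume.ndim
        for op in self.ops:
            if op[0] == "flip":
                v = np.flip(v, axis=nd - 3 + op[1])
            elif op[0] == "rot90":
                a, b = op[1]
                v = np.rot90(v, k=op[2], axes=(nd - 3 + a, nd - 3 + b))
            else:
                v = _shift(v, op[1])
        return np.ascontiguousarray(v)

    def apply_inverse(self, volume: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Apply the exact inverse.

        Flips and rotations invert bit-exactly on the full grid.  For
        translations the voxels shifted out of the grid by :meth:`apply`
        cannot be recovered; they are refilled with ``fill`` and flagged by
        :meth:`valid_mask` so downstream losses can exclude them.
        """
        self._check(volume)
        v = volume
        nd = volume.ndim
        for op in reversed(self.ops):
            if op[0] == "flip":
                v = np.flip(v, axis=nd - 3 + op[1])
            elif op[0] == "rot90":
                a, b = op[1]
                v = np.rot90(v, k=(4 - op[2]) % 4, axes=(nd - 3 + a, nd - 3 + b))
            else:
                v = _shift(v, tuple(-o for o in op[1]), fill=fill)
        return np.ascontiguousarray(v)

    def valid_mask(self, grid_shape: Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask of voxels that survive ``apply_inverse(apply(.))``.

        Everything is valid for flip/rotation-only composites; translations
        erode a border of width equal to the absolute offset.
        """
        shape = tuple(grid_shape) if grid_shape is not None else self.grid_shape
        if shape is None:
            raise ValueError("grid_shape required when transform has none recorded")
        ones = np.ones(shape, dtype=np.float32)
        return self.apply_inverse(self.apply(ones)) > 0.5

    @property
    def is_identity(self) -> bool:
        return all(
            (op[0] == "rot90" and op[2] == 0)
            or (op[0] == "translate" and all(o == 0 for o in op[1]))
            for op in self.ops
        )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"ops": [list(op) for op in self.ops],
             "grid_shape": list(self.grid_shape) if self.grid_shape else None}
        )

    @classmethod
    def from_json(cls, text: str) -> "ReversibleTransform":
        d = json.loads(text)
        gs = tuple(d["grid_shape"]) if d.get("grid_shape") else None
        return cls(ops=tuple(tuple(op) for op in d["ops"]), grid_shape=gs)


def _freeze(op):
    kind = op[0]
    if kind == "flip":
        return (kind, int(op[1]))
    if kind == "rot90":
        return (kind, tuple(int(a) for a in op[1]), int(op[2]))
    if kind == "translate":
        return (kind, tuple(int(o) for o in op[1]))
    return tuple(op)


def identity_transform(grid_shape=None) -> ReversibleTransform:
    return ReversibleTransform(ops=(), grid_shape=grid_shape)


def sample_transform(
    rng: np.random.Generator,
    allowed: Iterable[str] = PRIMITIVES,
    max_translation: int = 2,
    grid_shape: Sequence[int] | None = None,
) -> ReversibleTransform:
    """Draw a random composite transform.

    Each primitive family is drawn independently: a Bernoulli(1/2) flip per
    axis, one rotation with uniformly random plane and ``k`` in 0..3 (odd
    ``k`` only in planes with equal extents), and per-axis integer
    translation offsets uniform in ``[-max_translation, max_translation]``.
    The draw is deterministic given the generator state; ``allowed = ()``
    yields the identity.
    """
    allowed = set(allowed)
    unknown = allowed - set(PRIMITIVES)
    if unknown:
        raise ValueError(f"unknown primitives {sorted(unknown)}")
    if grid_shape is not None and "translate" in allowed and max_translation >= min(grid_shape):
        raise ValueError(
            f"max_translation={max_translation} must be smaller than the "
            f"smallest grid extent {min(grid_shape)}"
        )
    ops = []
    if "flip" in allowed:
        for ax in range(3):
            if rng.integers(0, 2) == 1:
                ops.append(("flip", ax))
    if "rot90" in allowed:
        plane = PLANES[rng.integers(0, len(PLANES))]
        k = int(rng.integers(0, 4))
        if grid_shape is not None and grid_shape[plane[0]] != grid_shape[plane[1]] and k % 2 == 1:
            k = (k + 1) % 4  # keep the draw but stay shape-preserving
        if k:
            ops.append(("rot90", plane, k))
    if "translate" in allowed and max_translation > 0:
        offs = tuple(int(rng.integers(-max_translation, max_translation + 1)) for _ in range(3))
        if any(offs):
            ops.append(("translate", offs))
    gs = tuple(grid_shape) if grid_shape is not None else None
    return ReversibleTransform(ops=tuple(ops), grid_shape=gs)
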