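"""Depth-slab space-separation of the reconstruction task.

The grid is split along z into contiguous near-equal slabs, one per
configured device/worker.  Each worker receives the full signal matrix and
detector array (partitioning detectors instead would multiply peak memory)
but computes only its slab's voxels; slab volumes are concatenated in slab
order.  Because every voxel's arithmetic is independent of slab membership,
the partitioned result is bit-identical to the monolithic one for any
worker count.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from .config import Config
from .geometry import DetectorArray, ReconGrid
from .recon import ReconVolume, backproject


class PartitionError(RuntimeError):
    """Raised when a reconstruction worker fails; names the slab."""


@dataclass
class SlabPlan:
    """Ordered contiguous depth slabs covering [0, nz) exactly."""

    slabs: list[tuple[int, int]]  # (z_start_index, z_count) per worker
    num_workers: int


def plan_slabs(nz: int, num_workers: int) -> SlabPlan:
    """Split nz depth planes into num_workers contiguous near-equal slabs.

    Slab thicknesses differ by at most one plane; remainder planes go to
    the earliest slabs.
    """
    if nz < 1:
        raise ValueError(f"nz must be >= 1, got {nz}")
    if not (1 <= num_workers <= nz):
        raise ValueError(
            f"num_workers must be in [1, nz = {nz}], got {num_workers}"
        )
    base, rem = divmod(nz, num_workers)
    slabs = []
    start = 0
    for w in range(num_workers):
        count = base + (1 if w < rem else 0)
        slabs.append((start, count))
        start += count
    return SlabPlan(slabs=slabs, num_workers=num_workers)


def _slab_task(args):
    S, array, grid, cfg, z0, count, slab_idx = args
    try:
        vol = backproject(S, array, grid, cfg, z_range=(z0, z0 + count))
        return slab_idx, vol.values
    except Exception as exc:  # re-raised with slab context by the caller
        raise PartitionError(f"worker for slab {slab_idx} (z {z0}..{z0 + count}) failed: {exc}") from exc


def reconstruct_partitioned(
    S: np.ndarray,
    array: DetectorArray,
    grid: ReconGrid,
    cfg: Config,
) -> ReconVolume:
    """Reconstruct the volume with ``cfg.num_devices`` slab workers.

    One worker → a plain monolithic ``backproject`` call.  Otherwise the
    slabs are dispatched to a process pool, gathered by slab index
    (deterministic irrespective of completion order), and concatenated
    along z.
    """
    plan = plan_slabs(grid.dims[2], cfg.num_devices)
    if plan.num_workers == 1:
        return backproject(S, array, grid, cfg)

    tasks = [
        (S, array, grid, cfg, z0, count, idx)
        for idx, (z0, count) in enumerate(plan.slabs)
    ]
    results: dict[int, np.ndarray] = {}
    with ProcessPoolExecutor(max_workers=plan.num_workers) as pool:
        try:
            for slab_idx, values in pool.map(_slab_task, tasks):
                results[slab_idx] = values
        except PartitionError:
            raise
        except Exception as exc:
            raise PartitionError(f"slab reconstruction failed: {exc}") from exc

    values = np.concatenate([results[i] for i in range(len(plan.slabs))], axis=2)
    return ReconVolume(values, grid)
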