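"""Read WE run stores back from HDF5.

The writer lives on :meth:`wepath.we_engine.WeRun.to_hdf5`; this module
reconstructs a :class:`WeRun` sufficient for analysis: genealogy (including
split-archive intermediates), weights, progress coordinates, and
conformations.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .structures import Conformation
from .we_engine import IterationRecord, Walker, WeRun, WeRunConfig

__all__ = ["read_run_hdf5"]


def _load_walkers(group, labels, iteration):
    ids = group["ids"][...]
    parents = group["parent_ids"][...]
    weights = group["weights"][...]
    pcoords = group["pcoords"][...]
    flags = group["flags"][...]
    coords = group["coords"][...]
    walkers = []
    for k in range(len(ids)):
        pc = pcoords[k]
        pc = float(pc[0]) if pc.shape[0] == 1 else tuple(float(x) for x in pc)
        walkers.append(
            Walker(
                id=int(ids[k]), parent_id=int(parents[k]),
                conformation=Conformation(labels, coords[k]),
                weight=float(weights[k]), pcoord=pc,
                iteration=iteration, flagged=bool(flags[k]),
            )
        )
    return walkers


def read_run_hdf5(path) -> WeRun:
    """Load a persisted WE run store."""
    with h5py.File(path, "r") as fh:
        config = WeRunConfig(**json.loads(fh.attrs["config"]))
        labels = tuple(json.loads(fh.attrs["residue_labels"]))
        initial = _load_walkers(fh["initial"], labels, 0)
        run = WeRun(config=config, initial_walkers=initial)
        if "iterations" in fh:
            for key in sorted(fh["iterations"]):
                g = fh[f"iterations/{key}"]
                it = int(key)
                walkers = _load_walkers(g["propagated"], labels, it)
                resampled = _load_walkers(g["resampled"], labels, it)
                archive = (_load_walkers(g["split_archive"], labels, it)
                           if "split_archive" in g else [])
                run.iterations.append(
                    IterationRecord(
                        iteration=it, walkers=walkers,
                        bin_labels=g["propagated"]["bins"][...],
                        resampled=resampled, flux=float(g.attrs["flux"]),
                        split_archive=archive,
                    )
                )
    return run
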