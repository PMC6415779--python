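"""Multicolor alignment by reference-channel transform transfer.

One channel (chosen by the user, typically the one with the higher
resolution) is aligned with the single-color 2D or 3D algorithm; each
structure's recovered alignment parameters are then applied verbatim to the
structure's other channels, which therefore keep their geometric
relationship to the reference channel.  The scheme generalizes to any
number of channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .molecules import MoleculeList, apply_transform, rotz3
from .pipeline import Align2DResult, align_structures_2d, align_structures_3d
from .register3d import Align3DRun, TiltSearchSpec

logger = logging.getLogger(__name__)

__all__ = ["MulticolorResult", "align_multicolor"]


@dataclass
class MulticolorResult:
    aligned: list  # per structure: dict channel -> MoleculeList
    reference_channel: int
    mode: str
    run: object  # Align2DResult (2D) or Align3DRun (3D)

    def channel_lists(self, channel: int) -> list:
        return [s[channel] for s in self.aligned]


def _check_structures(structures, reference_channel: int) -> None:
    for i, chans in enumerate(structures):
        if reference_channel not in chans:
            raise ValueError(
                f"structure {i} is missing reference channel {reference_channel}"
            )
        dims = {ml.xyz.shape[1] for ml in chans.values()}
        if len(dims) > 1:
            raise ValueError(
                f"structure {i} mixes 2D and 3D channels; one coordinate "
                "frame per structure is required"
            )


def align_multicolor(
    structures,
    reference_channel: int,
    mode: str = "3d",
    spec: TiltSearchSpec | None = None,
    deform: bool = True,
    **params,
) -> MulticolorResult:
    """Align multi-channel structures on the reference channel only.

    ``structures`` is a sequence of ``{channel_id: MoleculeList}`` maps, all
    channels of one structure sharing one coordinate frame.  In ``2d`` mode
    the reference channel is ellipse-fitted and circularized (unless
    ``deform=False``) and the same deformation scales are applied to the
    other channels; in ``3d`` mode no deformation is applied and the
    recovered rotation (tilt + in-plane) and shift are transferred.
    """
    structures = [dict(s) for s in structures]
    _check_structures(structures, reference_channel)
    ref_lists = [s[reference_channel] for s in structures]

    if mode == "2d":
        run: Align2DResult = align_structures_2d(ref_lists, deform=deform, **params)
        if run.failures:
            surviving = {ml.structure_id for ml in run.aligned}
            structures = [
                s for s in structures
                if s[reference_channel].structure_id in surviving
            ]
        aligned = []
        for s, t in zip(structures, run.transforms):
            aligned.append({
                cid: apply_transform(ml, t) for cid, ml in s.items()
            })
        return MulticolorResult(
            aligned=aligned, reference_channel=reference_channel,
            mode=mode, run=run,
        )

    if mode != "3d":
        raise ValueError(f"unknown mode {mode!r}")
    run3: Align3DRun = align_structures_3d(ref_lists, spec=spec, **params)
    aligned = []
    for s, rot, centroid, ref_aligned in zip(
        structures, run3.rotations, run3.centroids, run3.aligned
    ):
        ref_in = s[reference_channel]
        # net translation of the iterated alignment, recovered from the
        # reference channel: aligned = rot @ (p - centroid) + shift
        shift = ref_aligned.xyz.mean(axis=0) - (
            (ref_in.xyz - centroid).mean(axis=0) @ rot.T
        )
        out = {}
        for cid, ml in s.items():
            if cid == reference_channel:
                out[cid] = ref_aligned
            else:
                out[cid] = ml.with_coords(
                    (ml.xyz - centroid) @ rot.T + shift
                )
        aligned.append(out)
    return MulticolorResult(
        aligned=aligned, reference_channel=reference_channel, mode=mode, run=run3,
    )
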