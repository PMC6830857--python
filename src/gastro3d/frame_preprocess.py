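"""Endoscope frame pre-processing: channel separation and duplicated-frame removal.

Raw endoscope captures contain runs of frames that are (nearly) bit-identical —
an artifact of the capture hardware — which add cost and drift to downstream
structure-from-motion without adding information.  The dedup rule is a
reference-advance scan: keep the current reference frame, drop every successive
frame whose changed-pixel ratio against the reference falls below a threshold
``phi``, and promote the first sufficiently different frame to be the new
reference.

Frames are numpy ``uint8`` arrays, ``(H, W)`` single-channel or ``(H, W, 3)``
RGB.  Comparisons run on raw integer intensities; no normalisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrameSequence",
    "DedupConfig",
    "DedupReport",
    "split_channels",
    "difference_ratio",
    "remove_duplicates",
]

_CHANNELS = ("RGB", "R", "G", "B")


@dataclass
class FrameSequence:
    """An ordered sequence of same-sized frames with a channel tag.

    ``indices`` are the identities of the frames (original positions in the
    source video or frame ids of a sparse reconstruction); they survive
    deduplication so downstream stages can refer back to source frames.
    """

    frames: list[np.ndarray]
    channel: str = "RGB"
    source_id: str = ""
    indices: list[int] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}, got {self.channel!r}")
        if not self.indices:
            self.indices = list(range(len(self.frames)))
        if len(self.indices) != len(self.frames):
            raise ValueError("indices and frames must have equal length")
        expect_ndim = 3 if self.channel == "RGB" else 2
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        for f in self.frames:
            if f.ndim != expect_ndim:
                raise ValueError(
                    f"channel {self.channel!r} expects {expect_ndim}-d frames, got shape {f.shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple | None:
        return self.frames[0].shape if self.frames else None

    def subset(self, positions: list[int]) -> "FrameSequence":
        return FrameSequence(
            frames=[self.frames[i] for i in positions],
            channel=self.channel,
            source_id=self.source_id,
            indices=[self.indices[i] for i in positions],
            names=[self.names[i] for i in positions] if self.names else [],
        )


@dataclass(frozen=True)
class DedupConfig:
    """Parameters of duplicated-frame removal.

    phi
        Changed-pixel ratio threshold in [0, 1]; a successor frame with ratio
        strictly below ``phi`` is dropped as a duplicate.  Published operating
        value: 0.6.
    zero_tolerance
        Absolute intensity difference (integer levels) up to which a pixel
        still counts as unchanged.  Default 0: strictly non-zero differences
        count, matching exact-duplicate detection.  Real sensors add noise, so
        a small positive value is exposed for captures that are duplicated up
        to noise.
    """

    phi: float = 0.6
    zero_tolerance: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be >= 0")


@dataclass
class DedupReport:
    """Outcome of one deduplication pass.

    ``kept_indices``/``removed_indices`` partition the input sequence's
    ``indices``.  ``ratios`` holds one changed-pixel ratio per comparison made
    (in scan order), ``comparisons`` the compared (reference, candidate) index
    pairs.
    """

    kept_indices: list[int]
    removed_indices: list[int]
    ratios: list[float]
    comparisons: list[tuple[int, int]] = field(default_factory=list)
    phi: float = 0.6

    def to_dict(self) -> dict:
        return {
            "phi": self.phi,
            "kept_indices": list(self.kept_indices),
            "removed_indices": list(self.removed_indices),
            "ratios": [float(x) for x in self.ratios],
            "comparisons": [list(c) for c in self.comparisons],
        }


def split_channels(seq: FrameSequence) -> tuple[FrameSequence, FrameSequence, FrameSequence]:
    """Split an RGB sequence into three single-channel sequences (R, G, B).

    Pixel planes are views of the source data, bit-identical to the
    corresponding channel of each input frame.
    """
    if seq.channel != "RGB":
        raise ValueError(f"split_channels requires an RGB sequence, got {seq.channel!r}")
    out = []
    for ci, tag in enumerate("RGB"):
        out.append(
            FrameSequence(
                frames=[np.ascontiguousarray(f[..., ci]) for f in seq.frames],
                channel=tag,
                source_id=seq.source_id,
                indices=list(seq.indices),
                names=list(seq.names),
            )
        )
    return tuple(out)


def difference_ratio(a: np.ndarray, b: np.ndarray, zero_tolerance: int = 0) -> float:
    """Fraction of pixels whose intensity differs between two frames.

    A pixel differs when ``|a - b| > zero_tolerance`` in any channel.  Returns
    a value in [0, 1]; symmetric in its arguments.
    """
    if a.shape != b.shape:
        raise ValueError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a.astype(np.int16) - b.astype(np.int16))
    changed = diff > zero_tolerance
    if changed.ndim == 3:  # a pixel differs if ANY channel differs
        changed = changed.any(axis=-1)
    return float(changed.sum()) / changed.size


def remove_duplicates(
    seq: FrameSequence, cfg: DedupConfig | None = None
) -> tuple[FrameSequence, DedupReport]:
    """Drop near-duplicate successor frames by the reference-advance rule.

    The first frame is always kept and becomes the reference I_t.  Each
    successive frame I_{t+k} is compared against the reference; while the
    changed-pixel ratio is < phi the candidate is removed, and the first
    candidate with ratio >= phi is kept and becomes the new reference.
    """
    cfg = cfg or DedupConfig()
    n = len(seq)
    if n == 0:
        return seq, DedupReport([], [], [], [], cfg.phi)

    kept_pos = [0]
    removed_pos: list[int] = []
    ratios: list[float] = []
    comparisons: list[tuple[int, int]] = []
    ref = 0
    for cand in range(1, n):
        ratio = difference_ratio(seq.frames[ref], seq.frames[cand], cfg.zero_tolerance)
        ratios.append(ratio)
        comparisons.append((seq.indices[ref], seq.indices[cand]))
        if ratio < cfg.phi:
            removed_pos.append(cand)
        else:
            kept_pos.append(cand)
            ref = cand
    report = DedupReport(
        kept_indices=[seq.indices[i] for i in kept_pos],
        removed_indices=[seq.indices[i] for i in removed_pos],
        ratios=ratios,
        comparisons=comparisons,
        phi=cfg.phi,
    )
    return seq.subset(kept_pos), report
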