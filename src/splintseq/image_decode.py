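"""Decode multi-round, 4-channel in situ sequencing image stacks.

A field of view is imaged over R sequencing rounds; in each round every
rolling-circle amplicon fluoresces in the channel of the barcode base read
out that round. The pipeline is:

1. translational registration of every round to the reference round
   (normalized cross-correlation on channel-summed volumes);
2. background subtraction: a morphological opening of size 5 is subtracted
   from each channel and negatives are clamped to zero;
3. a composite volume (sum over rounds and channels) is upsampled in Z by a
   shape-preserving piecewise-cubic interpolation, filtered with a
   difference of Gaussians, binarized by Otsu's threshold and split into
   amplicons by a seeded watershed; labels are then downsampled back to the
   original Z grid;
4. per round, the 4 channels are quantile-normalized to a common reference
   distribution and each amplicon's base is called as the channel with the
   highest mean over its top-30 brightest voxels;
5. the R per-round calls are concatenated into a barcode and decoded with
   the error-correcting reference code.

Axis order is (z, y, x) with 0-based voxel indices throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .barcodes import BarcodeCode, DecodeResult, decode

__all__ = [
    "RoundStack",
    "Amplicon",
    "DEFAULT_CHANNEL_BASES",
    "register_rounds",
    "subtract_background",
    "make_composite",
    "segment_amplicons",
    "quantile_normalize",
    "basecall_round",
    "basecall_all",
    "amplicons_from_labels",
    "amplicon_table",
    "decode_experiment",
]

#: Channel index -> called base. The physical channel order (fluorophore /
#: laser line) is instrument configuration; remap via RoundStack.channel_bases.
DEFAULT_CHANNEL_BASES = ("A", "C", "G", "T")

#: Default voxel size (z, y, x) in nm: 500-nm z steps, 250-nm pixels.
DEFAULT_VOXEL_SIZE = (500.0, 250.0, 250.0)


@dataclass
class RoundStack:
    """One sequencing round: a (4, z, y, x) intensity volume.

    ``shift`` (z, y, x) records the measured displacement of this round
    relative to the reference round after registration.
    """

    round_index: int
    volume: np.ndarray
    channel_bases: tuple[str, ...] = DEFAULT_CHANNEL_BASES
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    low_confidence: bool = False

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float32)
        if self.volume.ndim != 4 or self.volume.shape[0] != len(self.channel_bases):
            raise ValueError(
                f"volume must be (n_channels, z, y, x); got {self.volume.shape}"
            )


@dataclass
class Amplicon:
    """A segmented amplicon with per-round calls and its decoded identity."""

    label: int
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (z, y, x) index arrays
    centroid: tuple[float, float, float]
    calls: list[str] = field(default_factory=list)
    intensities: list[np.ndarray] = field(default_factory=list)
    tie_rounds: list[int] = field(default_factory=list)
    barcode: str = ""
    decode: DecodeResult | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_rounds(
    stacks: Sequence[RoundStack],
    reference_round: int = 1,
    max_shift: float | None = 10.0,
    upsample_factor: int = 1,
) -> tuple[list[RoundStack], dict[int, tuple[float, float, float]]]:
    """Translate every round onto the reference round's coordinate frame.

    The shift of each round is estimated by phase correlation (normalized
    cross-correlation maximum) between channel-summed volumes, then applied
    to all channels. Reported shifts are the displacement of the round
    relative to the reference (a round whose content sits at +s reports +s
    and is translated by -s). Shifts with magnitude above ``max_shift`` in
    any axis, and all-zero volumes, are flagged low-confidence; degenerate
    volumes get zero shift.
    """
    if len(stacks) < 2:
        raise ValueError("need at least 2 rounds to register")
    by_index = {s.round_index: s for s in stacks}
    ref = by_index[reference_round]
    ref_sum = ref.volume.sum(axis=0)
    out: list[RoundStack] = []
    shifts: dict[int, tuple[float, float, float]] = {}
    for s in stacks:
        if s.round_index == reference_round:
            s.shift = (0.0, 0.0, 0.0)
            shifts[s.round_index] = s.shift
            out.append(s)
            continue
        mov_sum = s.volume.sum(axis=0)
        if not np.any(mov_sum) or not np.any(ref_sum):
            warnings.warn(
                f"round {s.round_index}: degenerate (all-zero) volume; "
                "assuming zero shift"
            )
            s.shift, s.low_confidence = (0.0, 0.0, 0.0), True
            shifts[s.round_index] = s.shift
            out.append(s)
            continue
        correction, error, _ = phase_cross_correlation(
            ref_sum, mov_sum, upsample_factor=upsample_factor,
            normalization="phase",
        )
        correction = np.asarray(correction, dtype=float)
        displacement = -correction
        if max_shift is not None and np.abs(displacement).max() > max_shift:
            s.low_confidence = True
            displacement = np.clip(displacement, -max_shift, max_shift)
            correction = -displacement
        registered = np.empty_like(s.volume)
        for c in range(s.volume.shape[0]):
            registered[c] = ndimage.shift(
                s.volume[c], correction, order=1, mode="constant", cval=0.0
            )
        s.volume = registered
        s.shift = tuple(displacement)
        shifts[s.round_index] = s.shift
        out.append(s)
    return out, shifts


# ---------------------------------------------------------------------------
# background subtraction and composite
# ---------------------------------------------------------------------------

def subtract_background(volume: np.ndarray, opening_size: int = 5) -> np.ndarray:
    """Subtract a morphological opening (slice-wise, size 5) and clamp at 0.

    The opening estimates the smooth non-uniform background of each plane;
    punctate amplicons are narrower than the structuring element and survive
    the subtraction untouched. Works on (z, y, x) or (c, z, y, x) arrays,
    opening over the trailing (y, x) axes.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.min() < 0:
        raise ValueError("input volume must be non-negative")
    size = (1,) * (volume.ndim - 2) + (opening_size, opening_size)
    opened = ndimage.grey_opening(volume, size=size, mode="nearest")
    return np.maximum(volume - opened, 0.0)


def make_composite(stacks: Sequence[RoundStack]) -> np.ndarray:
    """Voxelwise sum over all rounds and channels (registered, bg-subtracted)."""
    shapes = {s.volume.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"round volumes differ in shape: {shapes}")
    composite = np.zeros(stacks[0].volume.shape[1:], dtype=np.float64)
    for s in stacks:
        composite += s.volume.sum(axis=0)
    return composite


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_amplicons(
    composite: np.ndarray,
    z_interp_factor: int | None = None,
    dog_sigmas: tuple[float, float] = (1.0, 3.0),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    min_seed_distance: int | None = None,
) -> np.ndarray:
    """Label amplicons in the composite volume via DoG + Otsu + watershed.

    The volume is upsampled along Z by monotone piecewise-cubic (PCHIP)
    interpolation — by default to make voxels approximately isotropic given
    ``voxel_size`` — filtered with a difference of Gaussians
    ``dog_sigmas=(low, high)`` in the interpolated space, thresholded with
    Otsu's method and split by a watershed seeded at local maxima of the
    filtered volume. Labels are downsampled back to the original Z grid and
    relabeled contiguously 1..N.
    """
    composite = np.asarray(composite, dtype=np.float64)
    if z_interp_factor is None:
        z_interp_factor = max(1, int(round(voxel_size[0] / voxel_size[1])))
    nz = composite.shape[0]
    if z_interp_factor > 1 and nz > 1:
        z = np.arange(nz)
        z_new = np.arange(nz * z_interp_factor) / z_interp_factor
        z_new = np.clip(z_new, 0, nz - 1)
        interp = PchipInterpolator(z, composite, axis=0)(z_new)
    else:
        z_interp_factor = 1
        interp = composite
    filtered = difference_of_gaussians(interp, dog_sigmas[0], dog_sigmas[1])
    if not np.any(filtered > 0):
        warnings.warn("empty foreground; no amplicons segmented")
        return np.zeros_like(composite, dtype=np.int32)
    thresh = threshold_otsu(filtered)
    mask = filtered > thresh
    if not mask.any():
        warnings.warn("empty foreground after Otsu; no amplicons segmented")
        return np.zeros_like(composite, dtype=np.int32)
    if min_seed_distance is None:
        min_seed_distance = max(1, int(np.ceil(dog_sigmas[0])))
    peaks = peak_local_max(
        filtered, min_distance=min_seed_distance, labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(filtered.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    labels = watershed(-filtered, markers=markers, mask=mask)
    labels = labels[::z_interp_factor]
    # contiguous relabeling in order of first appearance
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]


def amplicons_from_labels(labels: np.ndarray) -> list[Amplicon]:
    """Extract voxel sets and centroids from a labeled volume."""
    out: list[Amplicon] = []
    ids = np.unique(labels)
    ids = ids[ids > 0]
    centroids = ndimage.center_of_mass(labels > 0, labels, ids) if len(ids) else []
    for lab, cen in zip(ids, centroids):
        voxels = np.nonzero(labels == lab)
        out.append(Amplicon(int(lab), voxels, tuple(float(c) for c in cen)))
    return out


# ---------------------------------------------------------------------------
# basecalling
# ---------------------------------------------------------------------------

def quantile_normalize(volume: np.ndarray) -> np.ndarray:
    """Quantile-normalize the 4 channels of one round to common order stats.

    Each channel's voxel intensities are mapped onto the mean of the four
    channels' sorted intensity vectors, so after normalization every channel
    holds exactly the same intensity multiset and basecalling is invariant
    to monotone per-channel rescaling. Ties are broken by voxel order
    (stable sort), which matters only for flat background.
    """
    volume = np.asarray(volume, dtype=np.float64)
    n_ch = volume.shape[0]
    flat = volume.reshape(n_ch, -1)
    order = np.argsort(flat, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(flat, order, axis=1)
    reference = sorted_vals.mean(axis=0)
    normalized = np.empty_like(flat)
    for c in range(n_ch):
        normalized[c, order[c]] = reference
    return normalized.reshape(volume.shape)


def basecall_round(
    amplicon: Amplicon,
    round_stack: RoundStack,
    top_k: int = 30,
    normalized_volume: np.ndarray | None = None,
) -> tuple[str, np.ndarray, bool]:
    """Call one round's base for one amplicon.

    For each channel, the quantile-normalized intensities within the
    amplicon's voxels are sorted and the top ``min(top_k, n_voxels)`` values
    averaged; the called base is the channel with the highest average. Exact
    ties keep the first channel in configuration order and set the tie flag.
    """
    if amplicon.n_voxels == 0:
        raise ValueError(f"amplicon {amplicon.label} has no voxels")
    vol = normalized_volume
    if vol is None:
        vol = quantile_normalize(round_stack.volume)
    k = min(top_k, amplicon.n_voxels)
    means = np.empty(vol.shape[0])
    for c in range(vol.shape[0]):
        vals = vol[c][amplicon.voxels]
        idx = np.argpartition(vals, -k)[-k:] if k < vals.size else slice(None)
        means[c] = vals[idx].mean()
    best = int(np.argmax(means))
    tie = bool(np.sum(means == means[best]) > 1)
    return round_stack.channel_bases[best], means, tie


def basecall_all(
    amplicons: Sequence[Amplicon],
    stacks: Sequence[RoundStack],
    code: BarcodeCode,
    top_k: int = 30,
) -> list[Amplicon]:
    """Basecall every amplicon over all rounds and decode the barcodes.

    Rounds are taken in ``round_index`` order; round r reads barcode
    position r. The concatenated word is decoded with the error-correcting
    reference code and the result attached to each amplicon.
    """
    ordered = sorted(stacks, key=lambda s: s.round_index)
    if len(ordered) != code.length:
        raise ValueError(
            f"{len(ordered)} rounds cannot read a {code.length}-base barcode"
        )
    normalized = [quantile_normalize(s.volume) for s in ordered]
    for amp in amplicons:
        amp.calls, amp.intensities, amp.tie_rounds = [], [], []
        for s, vol in zip(ordered, normalized):
            base, means, tie = basecall_round(amp, s, top_k, normalized_volume=vol)
            amp.calls.append(base)
            amp.intensities.append(means)
            if tie:
                amp.tie_rounds.append(s.round_index)
        amp.barcode = "".join(amp.calls)
        amp.decode = decode(amp.barcode, code)
    return list(amplicons)


# ---------------------------------------------------------------------------
# tables and orchestration
# ---------------------------------------------------------------------------

def amplicon_table(
    amplicons: Sequence[Amplicon],
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> pd.DataFrame:
    """Tabulate decoded amplicons (centroids in voxels and nm)."""
    rows = []
    for a in amplicons:
        dec = a.decode
        rows.append(
            {
                "label": a.label,
                "n_voxels": a.n_voxels,
                "z": a.centroid[0],
                "y": a.centroid[1],
                "x": a.centroid[2],
                "z_nm": a.centroid[0] * voxel_size[0],
                "y_nm": a.centroid[1] * voxel_size[1],
                "x_nm": a.centroid[2] * voxel_size[2],
                "barcode": a.barcode,
                "status": dec.status if dec else "",
                "gene": dec.assigned_gene if dec else None,
                "distance": dec.distance if dec else None,
                "n_tie_rounds": len(a.tie_rounds),
            }
        )
    return pd.DataFrame(rows)


def decode_experiment(
    stacks: Sequence[RoundStack],
    code: BarcodeCode,
    reference_round: int = 1,
    opening_size: int = 5,
    dog_sigmas: tuple[float, float] = (1.0, 3.0),
    top_k: int = 30,
    max_shift: float | None = 10.0,
) -> tuple[list[Amplicon], pd.DataFrame]:
    """Run the full decode pipeline on raw round stacks.

    Registration -> background subtraction -> composite -> segmentation ->
    per-round basecalling -> barcode decode. Returns the amplicon objects
    and the summary table.
    """
    stacks, _ = register_rounds(stacks, reference_round, max_shift=max_shift)
    for s in stacks:
        s.volume = subtract_background(s.volume, opening_size)
    composite = make_composite(stacks)
    labels = segment_amplicons(
        composite, dog_sigmas=dog_sigmas, voxel_size=stacks[0].voxel_size
    )
    amplicons = amplicons_from_labels(labels)
    basecall_all(amplicons, stacks, code, top_k=top_k)
    return amplicons, amplicon_table(amplicons, stacks[0].voxel_size)
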