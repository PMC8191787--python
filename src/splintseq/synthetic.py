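"""Synthetic data generator: every input the other modules need.

Emulates a multiplexed in situ sequencing experiment end to end so the
whole pipeline is testable without microscopy data:

- random transcriptomes with planted near-homolog windows at a controlled
  mismatch count (for off-target screening);
- a ground-truth amplicon field: nuclei placed with minimum separation,
  per-cell amplicon clouds with per-gene abundances, per-round planted
  basecall errors;
- rendered image stacks: per round, each amplicon contributes a 3D Gaussian
  spot in the channel of its barcode base for that round, with optional
  per-round global shifts and additive Gaussian noise; nuclei are rendered
  as smooth disks in a DAPI image.

All randomness flows from an integer seed through ``numpy``'s default
generator, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .barcodes import BarcodeCode, generate_code
from .image_decode import DEFAULT_CHANNEL_BASES, DEFAULT_VOXEL_SIZE, RoundStack
from .probe_design import TranscriptRecord

__all__ = [
    "GroundTruth",
    "make_transcriptome",
    "make_field",
    "render_rounds",
    "simulate_96plex_mini",
    "match_to_truth",
]

_BASES = "ACGT"


@dataclass
class GroundTruth:
    """Planted truth for one simulated field of view."""

    field_shape: tuple[int, int, int]  # (z, y, x)
    code: BarcodeCode
    abundances: pd.Series  # gene -> planted relative abundance
    nuclei: pd.DataFrame  # columns: cell, y, x, radius
    amplicons: pd.DataFrame  # gene, barcode, read_barcode, z, y, x, cell, intensity
    errors: pd.DataFrame  # amplicon, round, true_base, planted_base
    shifts: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return self.code.length


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def make_transcriptome(
    n_genes: int = 60,
    length_range: tuple[int, int] = (400, 2000),
    n_homolog_pairs: int = 0,
    homolog_mismatches: int = 6,
    seed: int = 0,
    k: int = 25,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Random transcripts with optional planted near-homolog windows.

    For each homolog pair a k-nt window of the donor transcript is copied
    into the acceptor with exactly ``homolog_mismatches`` substitutions.
    The returned truth table lists the planted windows, so a probe designed
    over a donor window has a known off-target at a known distance.
    """
    if homolog_mismatches < 0 or homolog_mismatches > k:
        raise ValueError("homolog_mismatches must be in [0, k]")
    if 2 * n_homolog_pairs > n_genes:
        raise ValueError("not enough genes for the requested homolog pairs")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < k:
        raise ValueError(f"minimum transcript length must be >= {k}")
    seqs = [_random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_genes)]

    planted = []
    for p in range(n_homolog_pairs):
        donor, acceptor = 2 * p, 2 * p + 1
        # donor window must survive the homotetramer filter to be a candidate
        for _ in range(200):
            dstart = int(rng.integers(0, len(seqs[donor]) - k + 1))
            window = seqs[donor][dstart : dstart + k]
            if "GGGG" not in window and "CCCC" not in window:
                break
        else:
            raise RuntimeError("could not find a clean donor window")
        mutated = list(window)
        pos = rng.choice(k, size=homolog_mismatches, replace=False)
        for i in pos:
            mutated[i] = rng.choice([b for b in _BASES if b != window[i]])
        mutated = "".join(mutated)
        astart = int(rng.integers(0, len(seqs[acceptor]) - k + 1))
        seqs[acceptor] = (
            seqs[acceptor][:astart] + mutated + seqs[acceptor][astart + k :]
        )
        planted.append(
            {
                "donor_gene": f"g{donor:03d}",
                "donor_start": dstart,
                "acceptor_gene": f"g{acceptor:03d}",
                "acceptor_start": astart,
                "mismatches": homolog_mismatches,
                "window": window,
            }
        )
    records = [
        TranscriptRecord(f"t{i:03d}", f"g{i:03d}", s) for i, s in enumerate(seqs)
    ]
    return records, pd.DataFrame(planted)


# ---------------------------------------------------------------------------
# amplicon field
# ---------------------------------------------------------------------------

def make_field(
    code: BarcodeCode,
    n_cells: int = 4,
    amplicons_per_cell: int = 60,
    field_shape: tuple[int, int, int] = (32, 256, 256),
    error_rate: float = 0.0,
    errors_per_amplicon: int | None = None,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    abundances: pd.Series | None = None,
    nucleus_radius: float = 20.0,
    min_separation: float = 7.0,
    margin: int = 10,
) -> GroundTruth:
    """Plant a ground-truth amplicon field around randomly placed nuclei.

    Nucleus centers keep at least 4 radii of separation; each cell gets
    ``amplicons_per_cell`` amplicons scattered around its nucleus with a
    minimum inter-amplicon separation (so rendered spots stay resolvable —
    a simplification relative to real spatial crowding). Genes are drawn
    per amplicon from the planted abundances; per-round basecall errors are
    planted either at ``error_rate`` per base or as exactly
    ``errors_per_amplicon`` per amplicon.
    """
    if not code.assignment:
        raise ValueError("code must carry a gene -> barcode assignment")
    rng = np.random.default_rng(seed)
    nz, ny, nx = field_shape
    if genes is None:
        genes = list(code.assignment)
    missing = set(genes) - set(code.assignment)
    if missing:
        raise ValueError(f"genes without barcodes: {sorted(missing)[:5]}")
    if abundances is None:
        abundances = pd.Series(
            rng.lognormal(mean=0.0, sigma=1.0, size=len(genes)), index=list(genes)
        )
    abundances = abundances / abundances.sum()

    # nuclei: rejection-sample xy centers with minimum separation
    sep = 4.0 * nucleus_radius
    lo_y, hi_y = margin + nucleus_radius, ny - margin - nucleus_radius
    lo_x, hi_x = margin + nucleus_radius, nx - margin - nucleus_radius
    if hi_y <= lo_y or hi_x <= lo_x:
        raise ValueError("field too small for the requested nuclei")
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == n_cells:
            break
        c = (float(rng.uniform(lo_y, hi_y)), float(rng.uniform(lo_x, hi_x)))
        if all(np.hypot(c[0] - y, c[1] - x) >= sep for y, x in centers):
            centers.append(c)
    if len(centers) < n_cells:
        raise ValueError("field too small for the requested number of cells")
    nuclei = pd.DataFrame(
        {
            "cell": np.arange(1, n_cells + 1),
            "y": [c[0] for c in centers],
            "x": [c[1] for c in centers],
            "radius": nucleus_radius,
        }
    )

    # amplicons: clouds around nuclei, min separation, inside the margin
    positions: list[tuple[float, float, float]] = []
    cells: list[int] = []
    tree_pts: list[tuple[float, float, float]] = []
    for cell_idx, (cy, cx) in enumerate(centers, start=1):
        placed = 0
        attempts = 0
        while placed < amplicons_per_cell and attempts < 50000:
            attempts += 1
            y = rng.normal(cy, nucleus_radius * 1.3)
            x = rng.normal(cx, nucleus_radius * 1.3)
            z = rng.uniform(4, nz - 4)
            if not (margin <= y < ny - margin and margin <= x < nx - margin):
                continue
            if tree_pts:
                d = np.min(
                    np.linalg.norm(
                        np.asarray(tree_pts) - np.array([z, y, x]), axis=1
                    )
                )
                if d < min_separation:
                    continue
            tree_pts.append((z, y, x))
            positions.append((z, y, x))
            cells.append(cell_idx)
            placed += 1
        if placed < amplicons_per_cell:
            raise ValueError("field too crowded for the requested amplicons")

    n_amp = len(positions)
    gene_draw = rng.choice(list(genes), size=n_amp, p=abundances.values)
    intensities = rng.lognormal(mean=np.log(150.0), sigma=0.25, size=n_amp)

    # planted per-round errors
    n_rounds = code.length
    read_barcodes = []
    error_rows = []
    for i in range(n_amp):
        true_bc = code.assignment[gene_draw[i]]
        bc = list(true_bc)
        if errors_per_amplicon is not None:
            rounds = rng.choice(n_rounds, size=errors_per_amplicon, replace=False)
        else:
            rounds = np.nonzero(rng.random(n_rounds) < error_rate)[0]
        for r in rounds:
            new = rng.choice([b for b in _BASES if b != bc[r]])
            error_rows.append(
                {
                    "amplicon": i,
                    "round": int(r) + 1,
                    "true_base": bc[r],
                    "planted_base": new,
                }
            )
            bc[r] = new
        read_barcodes.append("".join(bc))

    amplicons = pd.DataFrame(
        {
            "gene": gene_draw,
            "barcode": [code.assignment[g] for g in gene_draw],
            "read_barcode": read_barcodes,
            "z": [p[0] for p in positions],
            "y": [p[1] for p in positions],
            "x": [p[2] for p in positions],
            "cell": cells,
            "intensity": intensities,
        }
    )
    return GroundTruth(
        field_shape=field_shape,
        code=code,
        abundances=abundances,
        nuclei=nuclei,
        amplicons=amplicons,
        errors=pd.DataFrame(error_rows),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_gaussian(volume: np.ndarray, center, sigma, amplitude: float) -> None:
    """Add a 3D Gaussian blob to a volume in place (local 4-sigma patch)."""
    nz, ny, nx = volume.shape
    cz, cy, cx = center
    sz, sy, sx = sigma
    z0, z1 = max(0, int(cz - 4 * sz)), min(nz, int(cz + 4 * sz) + 2)
    y0, y1 = max(0, int(cy - 4 * sy)), min(ny, int(cy + 4 * sy) + 2)
    x0, x1 = max(0, int(cx - 4 * sx)), min(nx, int(cx + 4 * sx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    blob = amplitude * np.exp(
        -(
            (zz - cz) ** 2 / (2 * sz**2)
            + (yy - cy) ** 2 / (2 * sy**2)
            + (xx - cx) ** 2 / (2 * sx**2)
        )
    )
    volume[z0:z1, y0:y1, x0:x1] += blob


def render_rounds(
    truth: GroundTruth,
    psf_sigma: tuple[float, float, float] = (1.0, 1.5, 1.5),
    noise_sd: float = 0.0,
    shifts: Sequence[tuple[int, int, int]] | None = None,
    channel_bases: tuple[str, ...] = DEFAULT_CHANNEL_BASES,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
) -> tuple[list[RoundStack], np.ndarray]:
    """Render the planted field as per-round 4-channel stacks plus DAPI.

    In round r every amplicon contributes a 3D Gaussian spot (the point
    spread function, sigma in voxels) in the channel of its possibly
    error-planted barcode base at position r. Each round's whole volume is
    translated by that round's global integer shift; Gaussian read noise is
    added and clamped at zero. Nuclei are rendered as smooth bright disks
    in a 2D DAPI image.
    """
    if min(psf_sigma) <= 0:
        raise ValueError("psf_sigma must be positive")
    n_rounds = truth.n_rounds
    if shifts is None:
        shifts = [(0, 0, 0)] * n_rounds
    if len(shifts) != n_rounds:
        raise ValueError(f"need {n_rounds} shifts, got {len(shifts)}")
    truth.shifts = [tuple(int(v) for v in s) for s in shifts]
    channel_of = {b: i for i, b in enumerate(channel_bases)}
    rng = np.random.default_rng(seed)
    nz, ny, nx = truth.field_shape
    stacks: list[RoundStack] = []
    amp = truth.amplicons
    for r in range(n_rounds):
        volume = np.zeros((len(channel_bases), nz, ny, nx), dtype=np.float64)
        dz, dy, dx = truth.shifts[r]
        for row in amp.itertuples():
            base = row.read_barcode[r]
            _add_gaussian(
                volume[channel_of[base]],
                (row.z + dz, row.y + dy, row.x + dx),
                psf_sigma,
                row.intensity,
            )
        if noise_sd > 0:
            volume += rng.normal(0.0, noise_sd, size=volume.shape)
            np.maximum(volume, 0.0, out=volume)
        stacks.append(
            RoundStack(
                round_index=r + 1,
                volume=volume.astype(np.float32),
                channel_bases=channel_bases,
                voxel_size=voxel_size,
            )
        )

    dapi = np.zeros((ny, nx), dtype=np.float64)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for row in truth.nuclei.itertuples():
        d2 = (yy - row.y) ** 2 + (xx - row.x) ** 2
        sigma = row.radius / 1.5
        dapi += 1000.0 * np.exp(-d2 / (2 * sigma**2))
    if noise_sd > 0:
        dapi += rng.normal(0.0, noise_sd, size=dapi.shape)
        np.maximum(dapi, 0.0, out=dapi)
    return stacks, dapi


# ---------------------------------------------------------------------------
# preset and truth matching
# ---------------------------------------------------------------------------

#: Default per-round global shifts of the mini preset (integer voxels).
MINI_SHIFTS = [
    (0, 0, 0), (0, 1, -1), (0, 2, 1), (-1, 1, 0),
    (0, -2, 2), (1, 1, 1), (0, 0, -2), (0, -1, 0),
]


def simulate_96plex_mini(
    seed: int = 7,
    noise_sd: float = 0.0,
    error_rate: float = 0.0,
    errors_per_amplicon: int | None = None,
    n_cells: int = 4,
    amplicons_per_cell: int = 60,
    shifts: Sequence[tuple[int, int, int]] | None = MINI_SHIFTS,
) -> tuple[GroundTruth, list[RoundStack], np.ndarray]:
    """Desk-scale stand-in for a 96-gene multiplexed experiment.

    96 genes with an 8-base distance-3 barcode each, 4 cells with ~60
    amplicons each in a 32 x 256 x 256 volume, 8 rounds x 4 channels, with
    small per-round global shifts — sized so the full decode pipeline runs
    in about a minute on one CPU.
    """
    genes = [f"gene{i:02d}" for i in range(96)]
    code = generate_code(8, 3, genes=genes)
    truth = make_field(
        code,
        n_cells=n_cells,
        amplicons_per_cell=amplicons_per_cell,
        error_rate=error_rate,
        errors_per_amplicon=errors_per_amplicon,
        seed=seed,
    )
    stacks, dapi = render_rounds(
        truth, noise_sd=noise_sd, shifts=shifts, seed=seed + 1
    )
    return truth, stacks, dapi


def match_to_truth(
    amplicon_df: pd.DataFrame, truth: GroundTruth, max_dist: float = 4.0
) -> pd.DataFrame:
    """Match decoded amplicons to planted ones by nearest centroid.

    Adds ``true_gene``, ``true_barcode``, ``true_cell`` and ``match_dist``
    columns to a copy of the decoded table; unmatched rows get NaN.
    """
    out = amplicon_df.copy()
    truth_pos = truth.amplicons[["z", "y", "x"]].to_numpy()
    tree = cKDTree(truth_pos)
    dist, idx = tree.query(out[["z", "y", "x"]].to_numpy())
    matched = dist <= max_dist
    out["match_dist"] = dist
    out["true_gene"] = np.where(
        matched, truth.amplicons["gene"].to_numpy()[idx], None
    )
    out["true_barcode"] = np.where(
        matched, truth.amplicons["barcode"].to_numpy()[idx], None
    )
    out["true_cell"] = np.where(
        matched, truth.amplicons["cell"].to_numpy()[idx], -1
    )
    return out
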