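"""Error-robust DNA barcodes with guaranteed minimum Hamming distance.

Amplicon identities are encoded in 8-base barcodes read out over 8 rounds of
in situ sequencing. A minimum pairwise Hamming distance of 3 guarantees that
every single-base readout error decodes uniquely to the true barcode, and
that double errors are either corrected (when the minimum distance to the
reference set is still unique) or safely discarded.

Generation uses a deterministic greedy lexicode: iterate all 4^L words in
lexicographic order (A < C < G < T) and keep a word iff its distance to
every previously kept word is at least the design distance. The resulting
set is a deterministic function of (length, distance, filters), so a
reference table serialized once is reproducible forever.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeCode",
    "DecodeResult",
    "hamming",
    "code_space_size",
    "generate_code",
    "verify_code",
    "decode",
    "decode_table",
    "write_code",
    "read_code",
]

_BASES = "ACGT"
_ENCODE = {b: i for i, b in enumerate(_BASES)}


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def code_space_size(length: int) -> int:
    """Number of distinct DNA words of the given length (4**length)."""
    return 4 ** length


@dataclass
class BarcodeCode:
    """An ordered barcode set with a guaranteed minimum pairwise distance."""

    length: int
    min_distance: int
    barcodes: list[str]
    assignment: dict[str, str] = field(default_factory=dict)  # gene -> barcode

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")
        genes = list(self.assignment)
        if len(set(self.assignment.values())) != len(genes):
            raise ValueError("gene->barcode assignment must be injective")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def gene_of(self) -> dict[str, str]:
        """Inverse assignment: barcode -> gene."""
        return {bc: g for g, bc in self.assignment.items()}

    def as_array(self) -> np.ndarray:
        return np.array(
            [[_ENCODE[b] for b in bc] for bc in self.barcodes], dtype=np.uint8
        )


def generate_code(
    length: int = 8,
    min_dist: int = 3,
    n_needed: int | None = None,
    seed: int | None = None,
    genes: Sequence[str] | None = None,
    no_homotetramer: bool = False,
    gc_bounds: tuple[float, float] | None = None,
) -> BarcodeCode:
    """Greedy lexicode over all 4**length DNA words.

    Optional composition filters (homotetramer exclusion, GC-content bounds)
    are applied before the distance test; both are off by default. When
    ``genes`` is given, barcodes are assigned to genes in order; ``seed``
    only shuffles that assignment (generation itself is deterministic).
    """
    if n_needed is not None and n_needed > code_space_size(length):
        raise ValueError("n_needed exceeds the barcode space")
    kept_str: list[str] = []
    kept = np.empty((0, length), dtype=np.uint8)
    n_genes = len(genes) if genes is not None else None
    target = n_needed if n_needed is not None else None
    if target is None and n_genes is not None:
        target = n_genes
    for word in itertools.product(_BASES, repeat=length):
        bc = "".join(word)
        if no_homotetramer and any(b * 4 in bc for b in _BASES):
            continue
        if gc_bounds is not None:
            gc = (bc.count("G") + bc.count("C")) / length
            if not gc_bounds[0] <= gc <= gc_bounds[1]:
                continue
        enc = np.array([_ENCODE[b] for b in bc], dtype=np.uint8)
        if kept.size and int((kept != enc).sum(axis=1).min()) < min_dist:
            continue
        kept_str.append(bc)
        kept = np.vstack([kept, enc])
        if target is not None and len(kept_str) >= target:
            break
    if target is not None and len(kept_str) < target:
        raise ValueError(
            f"requested {target} barcodes but only {len(kept_str)} achievable "
            f"at length {length}, distance {min_dist}"
        )
    assignment: dict[str, str] = {}
    if genes is not None:
        order = list(range(n_genes))
        if seed is not None:
            np.random.default_rng(seed).shuffle(order)
        assignment = {genes[i]: kept_str[j] for j, i in enumerate(order)}
    return BarcodeCode(length, min_dist, kept_str, assignment)


def verify_code(code: BarcodeCode | Sequence[str]) -> int:
    """Exact minimum pairwise Hamming distance over all barcode pairs."""
    barcodes = code.barcodes if isinstance(code, BarcodeCode) else list(code)
    if len(barcodes) < 2:
        raise ValueError("need at least 2 barcodes")
    arr = np.array(
        [[_ENCODE[b] for b in bc] for bc in barcodes], dtype=np.uint8
    )
    dists = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    np.fill_diagonal(dists, arr.shape[1] + 1)
    return int(dists.min())


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of matching one observed barcode against the reference set."""

    observed: str
    status: str  # perfect | corrected | discarded_distance | discarded_ambiguous
    assigned_gene: str | None
    assigned_barcode: str | None
    distance: int | None


def decode(observed: str, code: BarcodeCode) -> DecodeResult:
    """Error-correcting decode of one observed barcode.

    A perfect match keeps its identity; otherwise the Hamming distance to
    every reference barcode is computed. A minimum distance > 2 discards the
    read; a non-unique minimum distance discards it as ambiguous; a unique
    minimum of 1 or 2 corrects the read to that reference barcode.
    """
    if len(observed) != code.length or set(observed) - set(_BASES):
        raise ValueError(f"malformed observed barcode {observed!r}")
    gene_of = code.gene_of
    if observed in gene_of:
        return DecodeResult(observed, "perfect", gene_of[observed], observed, 0)
    dists = [hamming(observed, bc) for bc in code.barcodes]
    dmin = min(dists)
    if dmin > 2:
        return DecodeResult(observed, "discarded_distance", None, None, None)
    hits = [i for i, d in enumerate(dists) if d == dmin]
    if len(hits) > 1:
        return DecodeResult(observed, "discarded_ambiguous", None, None, None)
    bc = code.barcodes[hits[0]]
    return DecodeResult(observed, "corrected", gene_of.get(bc), bc, dmin)


def decode_table(observed_list: Iterable[str], code: BarcodeCode) -> dict:
    """Decode a list of observed barcodes and summarize the outcome.

    Returns a dict with the per-status ``counts`` and ``fractions``, the
    per-gene amplicon counts (perfect + corrected), and the full list of
    :class:`DecodeResult`.
    """
    results = [decode(obs, code) for obs in observed_list]
    statuses = ["perfect", "corrected", "discarded_distance", "discarded_ambiguous"]
    counts = {s: 0 for s in statuses}
    per_gene: dict[str, int] = {}
    for r in results:
        counts[r.status] += 1
        if r.assigned_gene is not None:
            per_gene[r.assigned_gene] = per_gene.get(r.assigned_gene, 0) + 1
    total = len(results)
    fractions = {s: (c / total if total else 0.0) for s, c in counts.items()}
    return {
        "counts": counts,
        "fractions": fractions,
        "per_gene": pd.Series(per_gene, dtype=int).sort_index(),
        "results": results,
        "total": total,
    }


def write_code(code: BarcodeCode, path) -> None:
    """Serialize a code as TSV (columns gene_id, barcode)."""
    if code.assignment:
        rows = [{"gene_id": g, "barcode": bc} for g, bc in code.assignment.items()]
    else:
        rows = [{"gene_id": f"bc{i:04d}", "barcode": bc}
                for i, bc in enumerate(code.barcodes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_code(path, min_distance: int | None = None) -> BarcodeCode:
    """Read a gene/barcode TSV back into a :class:`BarcodeCode`.

    The stated ``min_distance`` (default: measured) is verified against the
    actual set; an inconsistent claim raises.
    """
    df = pd.read_csv(path, sep="\t")
    barcodes = list(df["barcode"])
    length = len(barcodes[0])
    measured = verify_code(barcodes) if len(barcodes) > 1 else length
    if min_distance is None:
        min_distance = measured
    elif measured < min_distance:
        raise ValueError(
            f"code claims distance {min_distance} but measured {measured}"
        )
    assignment = dict(zip(df["gene_id"], df["barcode"]))
    return BarcodeCode(length, min_distance, barcodes, assignment)
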