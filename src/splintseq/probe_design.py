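"""Padlock probe design for direct RNA-splinted ligation.

Probes carry two hybridization arms covering a contiguous 25-nt footprint on
the target mRNA (default split: 18-nt 5' arm, 7-nt 3' arm). After adjacent
hybridization the two probe termini are joined by an RNA-splinted DNA ligase
and the circle is amplified by rolling-circle amplification. Design proceeds
in stages:

1. enumerate all 25-nt target windows, discarding windows containing
   homotetramers of G or C;
2. drop candidates whose ligation junction is disfavored by the ligase;
3. screen each window against a reference transcriptome (genes with
   baseMean >= 10 in a matched RNA-seq experiment), requiring at least six
   mismatches to every window of every non-target transcript;
4. score the assembled 60-nt oligo for secondary structure and keep the ten
   least-structured probes per target.
"""

from __future__ import annotations

import math
import string
import subprocess
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TranscriptRecord",
    "ProbeCandidate",
    "ParseError",
    "revcomp",
    "read_transcripts",
    "read_expression_table",
    "filter_reference",
    "enumerate_candidates",
    "split_arms",
    "DEFAULT_JUNCTION_TABLE",
    "junction_quality",
    "OfftargetIndex",
    "offtarget_screen",
    "structure_score",
    "rank_and_select",
    "assemble_probe",
    "assemble_singleplex_probe",
    "design_probes",
    "write_order_sheet",
    "read_order_sheet",
]

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Target footprint length (nt) shared by the two hybridization arms.
FOOTPRINT = 25
#: Default 5' hybridization arm length (nt).
DEFAULT_ARM5_LEN = 18
#: Length of the universal sequencing anchor (nt).
ANCHOR_LEN = 23
#: Assembled multiplex probe length (nt): 18 + 4 + 23 + 8 + 7.
PROBE_LEN = 60


class ParseError(ValueError):
    """Raised when an input record violates the sequence contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """A target transcript (mRNA sense strand, stored as DNA)."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeCandidate:
    """One 25-nt target window and, once assembled, its 60-nt probe.

    ``start`` is the 0-based half-open window start on the transcript.
    ``junction`` holds the two probe bases joined at the ligation nick
    (3'-arm terminal base followed by 5'-arm terminal base).
    """

    transcript_id: str
    gene_id: str
    start: int
    target_25mer: str
    arm5: str = ""
    arm3: str = ""
    junction: str = ""
    structure_dG: float = math.nan
    offtarget_min_mm: float = math.nan
    probe_seq: str = ""
    rank: int = 0


# ---------------------------------------------------------------------------
# input parsing
# ---------------------------------------------------------------------------

def read_transcripts(fasta_path, gene_delimiter: str = "|") -> list[TranscriptRecord]:
    """Read target transcripts from FASTA.

    Headers of the form ``transcript_id<delimiter>gene_id`` populate both
    identifiers; otherwise the gene id defaults to the transcript id.
    Sequences are uppercased and U is converted to T. Any other character
    (including IUPAC ambiguity codes) raises :class:`ParseError` naming the
    offending record.
    """
    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ParseError(f"empty sequence for record {rec.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {rec.id!r} contains non-ACGTU characters: {sorted(bad)}"
            )
        if gene_delimiter and gene_delimiter in rec.id:
            transcript_id, gene_id = rec.id.split(gene_delimiter)[:2]
        else:
            transcript_id = gene_id = rec.id
        records.append(TranscriptRecord(transcript_id, gene_id, seq))
    if not records:
        raise ParseError(f"no FASTA records found in {fasta_path}")
    return records


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene-level expression table (TSV with gene_id and baseMean)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id", df.columns[0])
    bm_col = cols.get("basemean") or cols.get("base_mean") or df.columns[1]
    out = df[[gene_col, bm_col]].rename(
        columns={gene_col: "gene_id", bm_col: "base_mean"}
    )
    if out["gene_id"].duplicated().any():
        raise ParseError("expression table has duplicate gene_id rows")
    return out


def filter_reference(
    transcripts: Sequence[TranscriptRecord],
    expression_table: pd.DataFrame,
    min_base_mean: float = 10.0,
    missing: str = "drop",
) -> list[TranscriptRecord]:
    """Restrict a transcriptome to expressed genes (baseMean >= threshold).

    Removal is strict ``<``: a gene exactly at the threshold is kept. Genes
    absent from the table are treated per ``missing``: ``"drop"`` (default;
    treated as baseMean 0, with a warning) or ``"keep"``.
    """
    if missing not in {"drop", "keep"}:
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    base_mean = dict(
        zip(expression_table["gene_id"], expression_table["base_mean"])
    )
    kept: list[TranscriptRecord] = []
    n_missing = 0
    for t in transcripts:
        if t.gene_id not in base_mean:
            n_missing += 1
            if missing == "keep":
                kept.append(t)
            continue
        if base_mean[t.gene_id] >= min_base_mean:
            kept.append(t)
    if n_missing and missing == "drop":
        warnings.warn(
            f"{n_missing} transcript(s) had no expression entry and were dropped"
        )
    return kept


# ---------------------------------------------------------------------------
# candidate enumeration and arms
# ---------------------------------------------------------------------------

def enumerate_candidates(
    transcript: TranscriptRecord,
    k: int = FOOTPRINT,
    arm5_len: int = DEFAULT_ARM5_LEN,
    legacy_g_filter: bool = False,
) -> list[ProbeCandidate]:
    """All k-mer target windows of a transcript, minus homotetramer windows.

    Windows containing GGGG or CCCC are excluded (``legacy_g_filter=True``
    restores the original G-only rule). Arms and junction are filled in;
    structure and off-target fields are left for the later stages.
    """
    seq = transcript.sequence
    if len(seq) < k:
        warnings.warn(
            f"transcript {transcript.transcript_id!r} shorter than {k} nt; "
            "no candidates"
        )
        return []
    banned = ("GGGG",) if legacy_g_filter else ("GGGG", "CCCC")
    out: list[ProbeCandidate] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b in window for b in banned):
            continue
        arm5, arm3, junction = split_arms(window, min(arm5_len, k - 1))
        out.append(
            ProbeCandidate(
                transcript_id=transcript.transcript_id,
                gene_id=transcript.gene_id,
                start=i,
                target_25mer=window,
                arm5=arm5,
                arm3=arm3,
                junction=junction,
            )
        )
    return out


def split_arms(target_25mer: str, arm5_len: int = DEFAULT_ARM5_LEN):
    """Split a target window into the probe's two hybridization arms.

    The probe anneals antiparallel to the target, so the probe's 5' arm is
    the reverse complement of the 5' portion of the target window and the 3'
    arm the reverse complement of the remainder. The ligation nick sits
    between the probe's two termini; the returned ``junction`` is the ordered
    pair (probe 3'-arm terminal base, probe 5'-arm terminal base).
    """
    n = len(target_25mer)
    if not 0 < arm5_len < n:
        raise ValueError(f"arm5_len must be in (0, {n}), got {arm5_len}")
    arm5 = revcomp(target_25mer[:arm5_len])
    arm3 = revcomp(target_25mer[arm5_len:])
    junction = arm3[-1] + arm5[0]
    return arm5, arm3, junction


def _default_junction_table() -> dict[str, str]:
    # Ligase-activity classes observed for SplintR on ordered junction pairs:
    # junctions containing G ligate poorly; TC/CC/AC are the most reliable.
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            j = a + b
            if j in {"TC", "CC", "AC"}:
                table[j] = "favored"
            elif "G" in j:
                table[j] = "disfavored"
            else:
                table[j] = "neutral"
    return table


DEFAULT_JUNCTION_TABLE: Mapping[str, str] = _default_junction_table()


def junction_quality(junction: str, table: Mapping[str, str] | None = None) -> str:
    """Quality class of a ligation junction: favored / neutral / disfavored."""
    if table is None:
        table = DEFAULT_JUNCTION_TABLE
    if len(junction) != 2 or set(junction) - DNA_ALPHABET:
        raise ValueError(f"junction must be an ordered ACGT pair, got {junction!r}")
    return table[junction]


# ---------------------------------------------------------------------------
# off-target screening (exact Hamming window scan)
# ---------------------------------------------------------------------------

_ENCODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class OfftargetIndex:
    """Sliding-window view over a reference transcriptome for Hamming scans.

    Ungapped Hamming distance over every k-nt window of every reference
    transcript (sense strand by default; ``scan_reverse`` adds the reverse
    complement). Exact and deterministic, in place of a heuristic gapped
    aligner.
    """

    def __init__(
        self,
        reference: Sequence[TranscriptRecord],
        k: int = FOOTPRINT,
        scan_reverse: bool = False,
    ):
        self.k = k
        self._windows: list[tuple[str, np.ndarray]] = []
        for t in reference:
            seqs = [t.sequence]
            if scan_reverse:
                seqs.append(revcomp(t.sequence))
            for s in seqs:
                if len(s) < k:
                    continue
                enc = _encode(s)
                self._windows.append((t.gene_id, sliding_window_view(enc, k)))

    def min_mismatches(self, kmer: str, exclude_gene: str) -> float:
        """Minimum Hamming distance of kmer to any window of any other gene."""
        q = _encode(kmer)
        best = math.inf
        for gene_id, win in self._windows:
            if gene_id == exclude_gene:
                continue
            d = int((win != q).sum(axis=1).min())
            if d < best:
                best = d
                if best == 0:
                    break
        return best


def offtarget_screen(
    candidate: ProbeCandidate,
    reference: Sequence[TranscriptRecord] | OfftargetIndex,
    min_mismatches: int = 6,
    scan_reverse: bool = False,
) -> tuple[bool, float]:
    """Screen a candidate window against the reference transcriptome.

    Returns ``(passed, offtarget_min_mm)`` where the distance is the minimum
    Hamming distance to any window of any non-target transcript (``inf`` if
    the reference is empty). A candidate passes iff the minimum distance is
    at least ``min_mismatches``.
    """
    if isinstance(reference, OfftargetIndex):
        index = reference
    else:
        index = OfftargetIndex(reference, k=len(candidate.target_25mer),
                               scan_reverse=scan_reverse)
    mm = index.min_mismatches(candidate.target_25mer, candidate.gene_id)
    candidate.offtarget_min_mm = mm
    return mm >= min_mismatches, mm


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

_PAIR_ENERGY = {
    ("A", "T"): -1.0, ("T", "A"): -1.0,
    ("G", "C"): -2.0, ("C", "G"): -2.0,
}
_STACK_BONUS = -1.0
_MIN_LOOP = 3


def _nussinov_energy(seq: str) -> float:
    """Minimum free energy of a max base-pairing dynamic program.

    Watson-Crick pairs only (AT -1, GC -2 kcal/mol-like units), an extra
    -1 per stacked pair, minimum hairpin loop of 3 unpaired bases. This is a
    coarse but fully deterministic and dependency-free folding model; scores
    are only comparable within one backend.
    """
    n = len(seq)
    INF = math.inf
    W = [[0.0] * n for _ in range(n)]
    V = [[INF] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            e = _PAIR_ENERGY.get((seq[i], seq[j]))
            if e is not None:
                inner = W[i + 1][j - 1]
                if V[i + 1][j - 1] + _STACK_BONUS < inner:
                    inner = V[i + 1][j - 1] + _STACK_BONUS
                V[i][j] = e + inner
            best = min(W[i + 1][j], W[i][j - 1], V[i][j])
            for k in range(i + 1, j):
                s = W[i][k] + W[k + 1][j]
                if s < best:
                    best = s
            W[i][j] = min(best, 0.0)
    return W[0][n - 1] if n else 0.0


def _rnafold_energy(seq: str) -> float:
    """MFE from the external ``RNAfold`` executable (optional backend)."""
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:
        raise RuntimeError("RNAfold backend unavailable") from exc
    line = proc.stdout.strip().splitlines()[-1]
    return float(line[line.rfind("(") + 1 : line.rfind(")")])


_STRUCTURE_BACKENDS = {
    "nussinov": _nussinov_energy,
    "rnafold": _rnafold_energy,
}


def structure_score(probe_seq: str, backend: str = "nussinov") -> float:
    """Predicted secondary-structure score of a probe (lower = more folded)."""
    try:
        fn = _STRUCTURE_BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown structure backend {backend!r}; "
            f"choose from {sorted(_STRUCTURE_BACKENDS)}"
        ) from None
    return fn(probe_seq)


# ---------------------------------------------------------------------------
# ranking and assembly
# ---------------------------------------------------------------------------

def rank_and_select(
    candidates: Sequence[ProbeCandidate], n: int = 10
) -> list[ProbeCandidate]:
    """Keep the n candidates with the least predicted structure.

    Sorted by structure score descending (least structure first), ties broken
    by transcript coordinate ascending. Ranks are assigned 1..n.
    """
    ordered = sorted(candidates, key=lambda c: (-c.structure_dG, c.start))
    chosen = ordered[: min(n, len(ordered))]
    for r, c in enumerate(chosen, start=1):
        c.rank = r
    return chosen


def assemble_probe(arm5: str, arm3: str, anchor_23nt: str, barcode8: str) -> str:
    """Assemble a multiplex probe: arm5 + barcode[5-8] + anchor + barcode + arm3.

    The 4-base element upstream of the anchor is a copy of positions 5-8 of
    the 8-base barcode (readout chemistry is most reliable within 4 bases of
    the anchor from either direction). With the default 18/7 arms the total
    is 18 + 4 + 23 + 8 + 7 = 60 nt.
    """
    if len(anchor_23nt) != ANCHOR_LEN:
        raise ValueError(f"anchor must be {ANCHOR_LEN} nt, got {len(anchor_23nt)}")
    if len(barcode8) != 8:
        raise ValueError(f"barcode must be 8 nt, got {len(barcode8)}")
    return arm5 + barcode8[4:8] + anchor_23nt + barcode8 + arm3


def assemble_singleplex_probe(
    arm5: str, arm3: str, anchor_23nt: str,
    filler_up: str = "TTATTA", filler_down: str = "ATTATT",
) -> str:
    """Assemble a singleplex probe with a 35-nt linker (6 + 23 + 6)."""
    if len(anchor_23nt) != ANCHOR_LEN:
        raise ValueError(f"anchor must be {ANCHOR_LEN} nt, got {len(anchor_23nt)}")
    if len(filler_up) != 6 or len(filler_down) != 6:
        raise ValueError("filler sequences must be 6 nt each")
    return arm5 + filler_up + anchor_23nt + filler_down + arm3


# Default universal sequencing anchor (configurable; any 23-nt sequence the
# readout chemistry primes on works).
DEFAULT_ANCHOR = "TCGTCGGCAGCGTCAGATGTGTA"


def design_probes(
    transcripts: Sequence[TranscriptRecord],
    reference: Sequence[TranscriptRecord],
    barcode_assignment: Mapping[str, str],
    n_per_gene: int = 10,
    arm5_len: int = DEFAULT_ARM5_LEN,
    min_offtarget_mm: int = 6,
    anchor: str = DEFAULT_ANCHOR,
    junction_table: Mapping[str, str] | None = None,
    structure_backend: str = "nussinov",
    scan_reverse: bool = False,
    legacy_g_filter: bool = False,
) -> list[ProbeCandidate]:
    """Full design pipeline: enumerate, filter, screen, score, rank, assemble."""
    index = OfftargetIndex(reference, scan_reverse=scan_reverse)
    probes: list[ProbeCandidate] = []
    for t in transcripts:
        barcode = barcode_assignment.get(t.gene_id)
        if barcode is None:
            warnings.warn(f"no barcode assigned to gene {t.gene_id!r}; skipped")
            continue
        survivors = []
        for c in enumerate_candidates(t, arm5_len=arm5_len,
                                      legacy_g_filter=legacy_g_filter):
            if junction_quality(c.junction, junction_table) == "disfavored":
                continue
            ok, _ = offtarget_screen(c, index, min_mismatches=min_offtarget_mm)
            if not ok:
                continue
            c.probe_seq = assemble_probe(c.arm5, c.arm3, anchor, barcode)
            c.structure_dG = structure_score(c.probe_seq, structure_backend)
            survivors.append(c)
        probes.extend(rank_and_select(survivors, n=n_per_gene))
    return probes


# ---------------------------------------------------------------------------
# order sheet
# ---------------------------------------------------------------------------

def _well_name(i: int) -> str:
    """Row-major 96-well plate position A1..H12, wrapping to further plates."""
    i = i % 96
    return f"{string.ascii_uppercase[i // 12]}{i % 12 + 1}"


def write_order_sheet(probes: Sequence[ProbeCandidate], path,
                      fasta_path=None) -> pd.DataFrame:
    """Write probes as a synthesis order sheet (TSV; optional FASTA copy).

    Columns: probe name, sequence, 5'-phosphate flag (required for ligation)
    and a row-major 96-well plate position.
    """
    if not probes:
        raise ValueError("no probes to write")
    rows = []
    for i, p in enumerate(probes):
        rows.append(
            {
                "name": f"{p.gene_id}_{p.transcript_id}_{p.start}",
                "gene_id": p.gene_id,
                "transcript_id": p.transcript_id,
                "start": p.start,
                "sequence": p.probe_seq,
                "phosphate_5p": True,
                "plate": i // 96 + 1,
                "well": _well_name(i),
                "structure_score": p.structure_dG,
                "offtarget_min_mm": p.offtarget_min_mm,
                "rank": p.rank,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for row in rows:
                fh.write(f">{row['name']}\n{row['sequence']}\n")
    return df


def read_order_sheet(path) -> pd.DataFrame:
    """Read back an order sheet written by :func:`write_order_sheet`."""
    return pd.read_csv(path, sep="\t")
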