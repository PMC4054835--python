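"""Sequence-level QC: adaptor-contamination scanning, GC/length profiling
of detected vs undetected isoforms, and transcript coverage breadth.

The adaptor scan answers "what fraction of reads carry whole-transcript-
amplification adaptor sequence?". A read is a hit if any ungapped placement
of the adaptor (or its reverse complement) against the read — at any offset,
including end overhangs of at least ``min_overlap`` bases — reaches
``min_identity`` over the overlapping region. IUPAC ambiguity codes in the
adaptor match their base sets; an N in a read always counts as a mismatch.
Gapped alignment is deliberately not offered: adaptor carry-over is an
ungapped phenomenon, and the ungapped scan is deterministic and fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iohub import ReadRecord

#: IUPAC nucleotide codes as 4-bit masks (A=1, C=2, G=4, T=8).
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_READ_BITS = np.zeros(256, dtype=np.uint8)
for _b, _code in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _READ_BITS[ord(_b)] = _code
    _READ_BITS[ord(_b.lower())] = _code
# N (and anything unknown) stays 0 in reads: always a mismatch.

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _adaptor_bits(adaptor: str) -> np.ndarray:
    bad = [c for c in adaptor.upper() if c not in _IUPAC_BITS]
    if bad:
        raise ValueError(f"adaptor contains non-IUPAC characters: {sorted(set(bad))}")
    return np.array([_IUPAC_BITS[c] for c in adaptor.upper()], dtype=np.uint8)


def reverse_complement(adaptor: str) -> str:
    return adaptor.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AdaptorScanResult:
    n_reads: int
    n_hits: int
    parameters: dict

    @property
    def fraction_hits(self) -> float:
        return self.n_hits / self.n_reads if self.n_reads else 0.0


def _scan_block(
    block: np.ndarray, adaptor_bits: np.ndarray, min_identity: float, min_overlap: int
) -> np.ndarray:
    """Hit mask for a (n_reads x read_length) bit-encoded block, one strand."""
    n, read_len = block.shape
    a_len = len(adaptor_bits)
    hits = np.zeros(n, dtype=bool)
    # offset = position of adaptor base 0 relative to read base 0
    for offset in range(-(a_len - min_overlap), read_len - min_overlap + 1):
        r_start = max(0, offset)
        r_end = min(read_len, offset + a_len)
        overlap = r_end - r_start
        if overlap < min_overlap:
            continue
        a_start = r_start - offset
        need = int(np.ceil(min_identity * overlap))
        sub = block[~hits, r_start:r_end]
        if sub.size == 0:
            break
        matches = (
            (sub & adaptor_bits[a_start : a_start + overlap]) != 0
        ).sum(axis=1)
        new_hits = matches >= need
        if new_hits.any():
            idx = np.flatnonzero(~hits)
            hits[idx[new_hits]] = True
    return hits


def _read_hits_adaptor(
    bases: str, adaptor: str, min_identity: float = 0.8, min_overlap: int = 16
) -> bool:
    """Single-read scan (both strands); used by the read simulator's
    background rejection step."""
    block = _READ_BITS[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)][None, :]
    for strand in (adaptor, reverse_complement(adaptor)):
        if _scan_block(block, _adaptor_bits(strand), min_identity, min_overlap)[0]:
            return True
    return False


def adaptor_scan(
    reads: Iterable[ReadRecord],
    adaptor: str,
    min_identity: float = 0.8,
    min_overlap: int = 16,
    both_strands: bool = True,
    chunk_size: int = 8192,
) -> AdaptorScanResult:
    """Count reads carrying the adaptor by ungapped similarity.

    Streams the input in chunks (constant memory in read count); the result
    is independent of read order. Lowering ``min_identity`` can only add
    hits.
    """
    if len(adaptor) < min_overlap:
        raise ValueError(
            f"adaptor length {len(adaptor)} shorter than min_overlap {min_overlap}"
        )
    strands = [_adaptor_bits(adaptor)]
    if both_strands:
        strands.append(_adaptor_bits(reverse_complement(adaptor)))

    n_reads = 0
    n_hits = 0
    # group by read length within a chunk so each block is rectangular
    buffer: dict[int, list[np.ndarray]] = {}
    buffered = 0

    def flush() -> int:
        nonlocal buffer, buffered
        hits = 0
        for length, rows in buffer.items():
            block = np.vstack(rows)
            mask = np.zeros(block.shape[0], dtype=bool)
            for strand_bits in strands:
                mask |= _scan_block(block, strand_bits, min_identity, min_overlap)
            hits += int(mask.sum())
        buffer = {}
        buffered = 0
        return hits

    for read in reads:
        n_reads += 1
        row = _READ_BITS[np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)]
        buffer.setdefault(len(row), []).append(row)
        buffered += 1
        if buffered >= chunk_size:
            n_hits += flush()
    n_hits += flush()

    return AdaptorScanResult(
        n_reads=n_reads,
        n_hits=n_hits,
        parameters={
            "adaptor": adaptor.upper(),
            "min_identity": min_identity,
            "min_overlap": min_overlap,
            "strands": "both" if both_strands else "forward",
        },
    )


# ---------------------------------------------------------------------------
# GC / length profiling


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_length_profile(
    gene_meta: pd.DataFrame,
    detected_flags: Sequence[bool],
) -> dict:
    """Compare GC content and transcript length between detected and
    undetected isoforms.

    ``gene_meta`` needs columns ``transcript_length`` (bp, >= 1) and
    ``gc_fraction`` (in [0, 1]). Returns per-group means and a two-sided
    rank-based (Mann-Whitney) location-test p-value for each attribute;
    an empty group yields absent summaries and no test.
    """
    lengths = gene_meta["transcript_length"].to_numpy(dtype=float)
    gc = gene_meta["gc_fraction"].to_numpy(dtype=float)
    if (lengths < 1).any():
        raise ValueError("transcript_length must be >= 1")
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc_fraction must lie in [0, 1]")
    flags = np.asarray(detected_flags, dtype=bool)
    if flags.size != len(gene_meta):
        raise ValueError("detected_flags length must match gene_meta")

    out: dict = {"n_detected": int(flags.sum()), "n_undetected": int((~flags).sum())}
    for group, mask in (("detected", flags), ("undetected", ~flags)):
        if mask.any():
            out[f"mean_gc_{group}"] = float(gc[mask].mean())
            out[f"mean_length_{group}"] = float(lengths[mask].mean())
    if flags.any() and (~flags).any():
        out["p_gc"] = float(
            stats.mannwhitneyu(gc[flags], gc[~flags], alternative="two-sided").pvalue
        )
        out["p_length"] = float(
            stats.mannwhitneyu(lengths[flags], lengths[~flags], alternative="two-sided").pvalue
        )
    return out


# ---------------------------------------------------------------------------
# Coverage breadth


def coverage_breadth(
    coverage_table: pd.DataFrame,
    expression: pd.Series,
    min_expr: float = 10.0,
) -> tuple[pd.Series, float | None]:
    """Per-transcript coverage breadth and its median over expressed
    transcripts.

    ``coverage_table`` needs columns ``length`` and ``covered_bases``
    (0 <= covered <= length), indexed by transcript id. Breadth =
    covered_bases / length; the median is taken over transcripts whose
    expression is >= ``min_expr`` (inclusive). Returns (breadth series,
    median or None when no transcript is expressed).
    """
    lengths = coverage_table["length"].to_numpy(dtype=float)
    covered = coverage_table["covered_bases"].to_numpy(dtype=float)
    if (covered > lengths).any():
        bad = coverage_table.index[covered > lengths][0]
        raise ValueError(f"covered_bases exceeds length for transcript {bad!r}")
    if (covered < 0).any() or (lengths < 1).any():
        raise ValueError("lengths must be >= 1 and covered_bases >= 0")
    breadth = pd.Series(covered / lengths, index=coverage_table.index, name="breadth")
    expr = expression.reindex(coverage_table.index)
    expressed = breadth[expr >= min_expr]
    if expressed.empty:
        warnings.warn("no transcript passes the expression threshold; median undefined")
        return breadth, None
    return breadth, float(expressed.median())
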