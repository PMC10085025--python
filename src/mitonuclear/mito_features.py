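"""Mitochondrial genome features: GC content and GC-cluster motif counts.

Yeast mtDNA is long, AT-rich and interrupted by short (~30-40 bp) mobile
GC-rich palindromic elements ("GC-clusters") that fall into homology
classes. This module counts cluster instances per class by motif scanning,
computes GC%, and correlates mtDNA features with petite frequencies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "ClusterMotifLibrary",
    "example_motif_library",
    "gc_percent",
    "detect_gc_clusters",
    "correlate_features",
    "build_feature_table",
    "read_motif_library",
]

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass
class ClusterMotifLibrary:
    """GC-cluster class motifs used for counting.

    Parameters
    ----------
    motifs :
        Mapping from class label (e.g. ``"M1"`` ... ``"M9"``) to one or more
        uppercase ACGT motif sequences.
    max_mismatch :
        Hamming-distance tolerance per motif match.
    """

    motifs: dict[str, list[str]] = field(default_factory=dict)
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        for label, seqs in self.motifs.items():
            if not seqs:
                raise ValueError(f"class {label!r} has no motifs")
            for s in seqs:
                if not _VALID_MOTIF.match(s):
                    raise ValueError(
                        f"motif for class {label!r} must be nonempty uppercase ACGT: {s!r}"
                    )

    @property
    def classes(self) -> list[str]:
        return sorted(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


def example_motif_library(max_mismatch: int = 2) -> ClusterMotifLibrary:
    """A synthetic 9-class GC-cluster motif library for testing and demos.

    Real cluster class definitions come from curated homology alignments;
    this bundled stand-in is synthetic: nine deterministic 32-bp palindromic
    GC-rich motifs (classes ``M1``-``M9``), mutually separated by well over
    twice the default mismatch tolerance so class counts are unambiguous.
    """
    rng = np.random.default_rng(20240917)
    bases = np.array(list("GCAT"))
    probs = np.array([0.4, 0.4, 0.1, 0.1])
    motifs: dict[str, list[str]] = {}
    half_len = 16
    min_dist = 2 * max(max_mismatch, 2) + 3
    halves: list[str] = []
    while len(halves) < 9:
        half = "".join(rng.choice(bases, size=half_len, p=probs))
        full = half + str(Seq(half).reverse_complement())
        if all(_hamming(full, h + str(Seq(h).reverse_complement())) >= min_dist for h in halves):
            halves.append(half)
            motifs[f"M{len(halves)}"] = [full]
    return ClusterMotifLibrary(motifs=motifs, max_mismatch=max_mismatch)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def gc_percent(sequence: str) -> float:
    """GC content in percent: ``100 * (G+C) / (A+C+G+T)``.

    Ambiguity codes are excluded from both numerator and denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    return 100.0 * gc / (gc + at)


def _scan_one_motif(seq_arr: np.ndarray, motif: str, tol: int) -> list[tuple[int, int]]:
    """All (start0, mismatches) windows where `motif` matches within `tol`."""
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    L = m.size
    if L > seq_arr.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, L)
    mism = (windows != m).sum(axis=1)
    hits = np.nonzero(mism <= tol)[0]
    return [(int(i), int(mism[i])) for i in hits]


def detect_gc_clusters(
    sequence: str, library: ClusterMotifLibrary
) -> tuple[dict[str, int], pd.DataFrame]:
    """Count GC-cluster instances per class by motif scanning.

    Both strands are scanned within the library's mismatch tolerance; a
    forward match and its reverse-complement at the same locus count once
    (the motifs are palindromic or near-palindromic). Overlapping candidate
    matches are resolved greedily left-to-right (ties broken by fewer
    mismatches, then class label), so the assignment is deterministic.

    Returns
    -------
    counts :
        Per-class match counts (every library class present, possibly 0).
    matches :
        DataFrame with columns ``cls``, ``start``, ``end`` (1-based
        inclusive), ``strand``, ``mismatches``.
    """
    if len(library) == 0:
        raise ValueError("empty motif library")
    seq = sequence.upper()
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: dict[tuple[int, str, str], tuple[int, str]] = {}
    for label in library.classes:
        for motif in library.motifs[label]:
            rc = str(Seq(motif).reverse_complement())
            for strand, pat in (("+", motif), ("-", rc)):
                for start, mism in _scan_one_motif(seq_arr, pat, library.max_mismatch):
                    key = (start, label, motif)
                    prev = candidates.get(key)
                    # same locus matched on both strands: count once,
                    # keep the better strand
                    if prev is None or mism < prev[0]:
                        candidates[key] = (mism, strand)
    rows = sorted(
        (start, mism, label, strand, len(motif))
        for (start, label, motif), (mism, strand) in candidates.items()
    )
    accepted = []
    last_end = -1  # 0-based inclusive end of last accepted match
    for start, mism, label, strand, length in rows:
        if start > last_end:
            accepted.append(
                {
                    "cls": label,
                    "start": start + 1,
                    "end": start + length,
                    "strand": strand,
                    "mismatches": mism,
                }
            )
            last_end = start + length - 1
    matches = pd.DataFrame(
        accepted, columns=["cls", "start", "end", "strand", "mismatches"]
    )
    counts = {label: 0 for label in library.classes}
    for label in matches["cls"]:
        counts[label] += 1
    return counts, matches


def build_feature_table(
    sequences: dict[str, str],
    library: ClusterMotifLibrary,
    intron_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-mtDNA feature table: length, GC%, per-class and total cluster counts.

    ``intron_lengths`` are optional user-supplied values (bp); features are
    indexed by sequence name.
    """
    records = []
    for name, seq in sequences.items():
        counts, _ = detect_gc_clusters(seq, library)
        row = {"mtdna": name, "length_bp": len(seq), "gc_pct": gc_percent(seq)}
        row.update({f"clusters_{c}": counts[c] for c in library.classes})
        row["clusters_total"] = sum(counts.values())
        if intron_lengths is not None:
            row["intron_bp"] = intron_lengths.get(name, np.nan)
        records.append(row)
    return pd.DataFrame(records).set_index("mtdna")


def correlate_features(
    feature_table: pd.DataFrame, petite_means: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each mtDNA feature with petite frequency.

    For each numeric feature column, returns Pearson r, R² = r², the
    two-sided p-value from the t-transform ``t = r * sqrt(n-2) / sqrt(1-r²)``
    with n−2 degrees of freedom, and the number of paired observations.
    Zero-variance features are flagged (``status = "undefined"``) with NaN
    statistics.
    """
    common = feature_table.index.intersection(petite_means.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    y = petite_means.loc[common].astype(float)
    rows = []
    for col in feature_table.columns:
        x = feature_table.loc[common, col].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or np.ptp(x[ok].to_numpy()) == 0 or np.ptp(y[ok].to_numpy()) == 0:
            rows.append(
                {"feature": col, "n": n, "r": np.nan, "r2": np.nan,
                 "p": np.nan, "status": "undefined"}
            )
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append(
            {"feature": col, "n": n, "r": float(r), "r2": float(r) ** 2,
             "p": float(p), "status": "ok"}
        )
    return pd.DataFrame(rows).set_index("feature")


def read_motif_library(path: str | Path, max_mismatch: int = 2) -> ClusterMotifLibrary:
    """Read a motif library from FASTA (class = first header token) or
    two-column TSV (``class<TAB>motif``)."""
    path = Path(path)
    motifs: dict[str, list[str]] = {}
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        for rec in SeqIO.parse(str(path), "fasta"):
            label = rec.id.split("|")[0]
            motifs.setdefault(label, []).append(str(rec.seq).upper())
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["cls", "motif"], comment="#")
        for label, motif in zip(df["cls"], df["motif"]):
            motifs.setdefault(str(label), []).append(str(motif).upper())
    return ClusterMotifLibrary(motifs=motifs, max_mismatch=max_mismatch)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read mtDNA sequences from a FASTA file into a name -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
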