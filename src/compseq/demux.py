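"""Paired-FASTQ -> per-subject, per-assay NT/IS read counts.

Stages: read joining, dual-barcode demultiplexing, primer-based locus
assignment, approximate-string (edit distance) allele classification.
Every input read pair lands in exactly one category, so counts are
conserved; reads failing a stage are tallied, not dropped.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import revcomp

NT, IS, AMBIGUOUS = "NT", "IS", "ambiguous"


@dataclass
class Tolerances:
    """Mismatch budgets for each assignment stage.

    Six diagnostic NT/IS positions give a clean-read margin of 6, so these
    defaults reject chimeric or low-quality reads without losing real ones.
    """

    barcode_max_mismatch: int = 1
    primer_max_mismatch: int = 2
    allele_max_distance: int = 2
    allele_min_margin: int = 1


@dataclass
class ReadCountTable:
    """Per subject x assay read tallies plus global unassigned buckets."""

    counts: pd.DataFrame  # columns: subject_id, assay_id, nt_reads, is_reads,
    #                       ambiguous_reads, unassigned_reads
    summary: dict = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        c = self.counts
        cell = int(c[["nt_reads", "is_reads", "ambiguous_reads",
                      "unassigned_reads"]].to_numpy().sum())
        glob = sum(self.summary.get(k, 0) for k in
                   ("join_failed", "no_subject", "no_locus"))
        return cell + glob

    def write(self, counts_path, summary_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary, indent=2))

    @classmethod
    def read(cls, counts_path, summary_path=None) -> "ReadCountTable":
        counts = pd.read_csv(counts_path, sep="\t",
                             dtype={"subject_id": str, "assay_id": str})
        summary = {}
        if summary_path is not None and Path(summary_path).exists():
            summary = json.loads(Path(summary_path).read_text())
        return cls(counts, summary)


# ---------------------------------------------------------------------------
# string primitives
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str, cap: Optional[int] = None) -> int:
    """Edit distance with an optional early-exit cap.

    If the true distance exceeds ``cap``, any value > cap may be returned.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    if la == 0 or lb == 0:
        return max(la, lb)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        best = cur[0]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if cur[j] < best:
                best = cur[j]
        if cap is not None and best > cap:
            return cap + 1
        prev = cur
    return prev[lb]


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def join_reads(read1: str, read2: str, min_length: int = 1) -> Optional[str]:
    """Concatenate read 1 with the reverse complement of read 2.

    The simulated layout is a non-overlapping split of the joined amplicon,
    so joining is plain concatenation in the documented orientation.
    Returns None (unassigned) when the joined product is shorter than
    ``min_length``.
    """
    if not read1 or not read2:
        return None
    joined = read1 + revcomp(read2)
    if len(joined) < min_length:
        return None
    return joined


class BarcodeIndex:
    """Dual-barcode lookup with bounded-mismatch fallback."""

    def __init__(self, subjects: pd.DataFrame):
        pairs = list(zip(subjects["barcode_f"], subjects["barcode_r"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate barcode pair in sample sheet")
        lengths_f = {len(b) for b in subjects["barcode_f"]}
        lengths_r = {len(b) for b in subjects["barcode_r"]}
        if len(lengths_f) != 1 or len(lengths_r) != 1:
            raise ValueError("barcodes must have uniform length")
        self.len_f = lengths_f.pop()
        self.len_r = lengths_r.pop()
        self.exact = {p: s for p, s in zip(pairs, subjects["subject_id"])}
        self.entries = [(s, f, r) for s, (f, r) in
                        zip(subjects["subject_id"], pairs)]


def demultiplex(joined: str, index: BarcodeIndex,
                max_mismatch: int = 1) -> Optional[str]:
    """Subject whose barcodes both match within ``max_mismatch``.

    Nearest total distance wins; ties and no-matches are unassigned.
    """
    if len(joined) < index.len_f + index.len_r:
        return None
    bf = joined[: index.len_f]
    br = revcomp(joined[-index.len_r:])
    hit = index.exact.get((bf, br))
    if hit is not None:
        return hit
    best, best_subject, tie = None, None, False
    for subject, f, r in index.entries:
        df = hamming(bf, f)
        if df > max_mismatch:
            continue
        dr = hamming(br, r)
        if dr > max_mismatch:
            continue
        d = df + dr
        if best is None or d < best:
            best, best_subject, tie = d, subject, False
        elif d == best:
            tie = True
    return None if tie else best_subject


class LocusIndex:
    """Primer lookup at fixed offsets after the barcodes."""

    def __init__(self, design: pd.DataFrame, barcode_len_f: int,
                 barcode_len_r: int):
        self.bf = barcode_len_f
        self.br = barcode_len_r
        self.entries = [
            (row.assay_id, row.primer_f, revcomp(row.primer_r))
            for row in design.itertuples(index=False)
        ]
        self.exact = {(pf, prc): aid for aid, pf, prc in self.entries}


def assign_locus(joined: str, index: LocusIndex,
                 max_mismatch: int = 2) -> Optional[str]:
    """Assay whose two primers match at the expected offsets.

    Both primers must be within ``max_mismatch``; ambiguity (tied nearest
    total distance) is unassigned.
    """
    if index.entries:
        _, pf0, prc0 = index.entries[0]
        lo, hi = index.bf, len(joined) - index.br
        key = (joined[lo: lo + len(pf0)], joined[hi - len(prc0): hi])
        hit = index.exact.get(key)
        if hit is not None:
            return hit
    best, best_assay, tie = None, None, False
    for assay_id, pf, prc in index.entries:
        lo = index.bf
        hi = len(joined) - index.br
        if hi - lo < len(pf) + len(prc):
            continue
        obs_f = joined[lo: lo + len(pf)]
        obs_r = joined[hi - len(prc): hi]
        df = hamming(obs_f, pf)
        if df > max_mismatch:
            continue
        dr = hamming(obs_r, prc)
        if dr > max_mismatch:
            continue
        d = df + dr
        if best is None or d < best:
            best, best_assay, tie = d, assay_id, False
        elif d == best:
            tie = True
    return None if tie else best_assay


def classify_allele(captured: str, nt_captured: str, is_captured: str,
                    max_distance: int = 2, min_margin: int = 1) -> str:
    """NT/IS call by edit distance to the two reference alleles.

    Returns the nearer allele iff min(d) <= max_distance and the distance
    gap is >= min_margin; otherwise "ambiguous".
    """
    if not captured:
        return AMBIGUOUS
    if captured == nt_captured:
        return NT if nt_captured != is_captured else AMBIGUOUS
    if captured == is_captured:
        return IS
    cap = max_distance + min_margin + 1
    d_nt = levenshtein(captured, nt_captured, cap=cap)
    d_is = levenshtein(captured, is_captured, cap=cap)
    if min(d_nt, d_is) > max_distance:
        return AMBIGUOUS
    if abs(d_nt - d_is) < min_margin:
        return AMBIGUOUS
    return NT if d_nt < d_is else IS


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(fastq1, fastq2) -> Iterator[tuple[str, str]]:
    with _open_maybe_gzip(fastq1) as f1, _open_maybe_gzip(fastq2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, _), (t2, s2, _) in zip(it1, it2):
            yield s1, s2


def count_reads(fastq1, fastq2, subjects: pd.DataFrame, design: pd.DataFrame,
                tolerances: Optional[Tolerances] = None) -> ReadCountTable:
    """Run join -> demultiplex -> locus -> allele over a paired FASTQ file.

    Produces a dense subject x assay table (zero-filled) plus a summary of
    globally unassigned reads; the conservation invariant

        n_pairs == sum(cell categories) + join_failed + no_subject + no_locus

    always holds.
    """
    tol = tolerances or Tolerances()
    try:
        bindex = BarcodeIndex(subjects)
    except ValueError:
        raise
    lindex = LocusIndex(design, bindex.len_f, bindex.len_r)
    refs = {row.assay_id: (row.nt_captured, row.is_captured,
                           len(row.primer_f), len(row.primer_r))
            for row in design.itertuples(index=False)}

    min_len = bindex.len_f + bindex.len_r + min(
        len(pf) + len(prc) for _, pf, prc in lindex.entries) + 1

    cells: dict[tuple[str, str], list[int]] = {}
    summary = {"total_pairs": 0, "join_failed": 0, "no_subject": 0,
               "no_locus": 0}
    try:
        pair_iter = iter_read_pairs(fastq1, fastq2)
        for n_pair, (s1, s2) in enumerate(pair_iter, start=1):
            summary["total_pairs"] = n_pair
            joined = join_reads(s1, s2, min_length=min_len)
            if joined is None:
                summary["join_failed"] += 1
                continue
            subject = demultiplex(joined, bindex, tol.barcode_max_mismatch)
            if subject is None:
                summary["no_subject"] += 1
                continue
            assay = assign_locus(joined, lindex, tol.primer_max_mismatch)
            if assay is None:
                summary["no_locus"] += 1
                continue
            nt_ref, is_ref, lpf, lpr = refs[assay]
            captured = joined[bindex.len_f + lpf: len(joined) - bindex.len_r - lpr]
            call = classify_allele(captured, nt_ref, is_ref,
                                   tol.allele_max_distance,
                                   tol.allele_min_margin)
            cell = cells.setdefault((subject, assay), [0, 0, 0, 0])
            if call == NT:
                cell[0] += 1
            elif call == IS:
                cell[1] += 1
            else:
                cell[2] += 1
    except OSError as exc:
        raise IOError(f"failed reading FASTQ pair {fastq1}/{fastq2}: {exc}") from exc

    rows = []
    for subject in subjects["subject_id"]:
        for assay in design["assay_id"]:
            c = cells.get((subject, assay), [0, 0, 0, 0])
            rows.append({"subject_id": subject, "assay_id": assay,
                         "nt_reads": c[0], "is_reads": c[1],
                         "ambiguous_reads": c[2], "unassigned_reads": c[3]})
    counts = pd.DataFrame(rows)
    summary["assigned_pairs"] = int(
        counts[["nt_reads", "is_reads", "ambiguous_reads"]].to_numpy().sum())
    return ReadCountTable(counts, summary)


def tally_to_counts(tally: pd.DataFrame) -> ReadCountTable:
    """Adapt a simulator molecule/read tally to the demux output schema.

    Lets downstream stages run without FASTQ emission (error-free
    equivalence is exercised in tests).
    """
    counts = tally[["subject_id", "assay_id", "nt_reads", "is_reads"]].copy()
    counts["ambiguous_reads"] = 0
    counts["unassigned_reads"] = 0
    summary = {"total_pairs": int(counts[["nt_reads", "is_reads"]].to_numpy().sum()),
               "join_failed": 0, "no_subject": 0, "no_locus": 0,
               "source": "tally"}
    summary["assigned_pairs"] = summary["total_pairs"]
    return ReadCountTable(counts, summary)
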