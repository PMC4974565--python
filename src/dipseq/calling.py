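"""Read-level insertion-site calling.

For every read the caller (1) detects the inserted cassette by exact k-mer
scanning against both cassette strands and verifies the hit by mismatch
counting, (2) strips the cassette to recover the host (LBD) flank, (3) aligns
the flank to the plasmid coding strand (exact k-mer anchors + mismatch-counted
full-flank verification) and (4) converts the junction into the insertion
coordinate ``p`` — the last LBD basepair, in the direction of transcription,
after which the cassette is found.

Because transposition duplicates ``duplication_len`` target bases on both
sides of the insert, a downstream (C-side) junction read reports the first
aligned base minus one **plus** the duplication length, so both ends of one
insertion event agree on ``p``.  The two ends are therefore independent
observations of the same event (internal technical replicates downstream).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import (
    ConstructReference,
    InsertionEvent,
    TransposonCassette,
    classify_insertion,
    revcomp,
)

Status = Literal["called", "filtered_no_insert", "filtered_no_lbd", "ambiguous", "non_orf"]


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the junction caller.

    min_kmer: exact k-mer size for cassette detection.
    min_flank: minimum aligned LBD flank supporting a call.
    max_mismatch: mismatches tolerated over the full flank alignment.
    cassette_max_mismatch: mismatches tolerated when verifying the cassette hit.
    anchor_k / anchor_step: exact-seed size and stride for flank anchoring.
    """

    min_kmer: int = 18
    min_flank: int = 20
    max_mismatch: int = 2
    cassette_max_mismatch: int = 4
    anchor_k: int = 14
    anchor_step: int = 7


@dataclass(frozen=True)
class ReadObservation:
    """One read's verdict."""

    read_id: str
    status: Status
    end: Literal["N", "C", "none"] = "none"
    orientation: Optional[str] = None
    dna_position: Optional[int] = None
    event: Optional[InsertionEvent] = None
    flank_len: int = 0

    def __post_init__(self) -> None:
        if self.status == "called" and self.event is None:
            raise ValueError("called observations must carry an event")
        if self.status != "called" and self.event is not None:
            raise ValueError("non-called observations must not carry an event")


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, early exit past limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


class _KmerIndex:
    """Exact k-mer -> positions lookup over one sequence."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        idx: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i : i + k], []).append(i)
        self.idx = idx

    def hits(self, kmer: str) -> list[int]:
        return self.idx.get(kmer, [])


@dataclass
class CassetteDetection:
    """Where the cassette sits in a read: 0-based start (may be negative when
    the cassette is clipped at the read's 5' side) and its strand in the read."""

    cassette_start: int
    strand: Literal["+", "-"]
    left_flank: str
    right_flank: str


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def _kmer_codes(seqs: Sequence[str], k: int, width: int) -> np.ndarray:
    """2-bit packed k-mer codes for a batch of reads (exact, no collisions).

    Returns an (n_reads, width - k + 1) int64 array; windows containing
    non-ACGT bases or padding are -1.
    """
    n = len(seqs)
    enc = np.full((n, width), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        b = np.frombuffer(s.encode(), dtype=np.uint8)[:width]
        enc[i, : len(b)] = _BASE_CODE[b]
    w = width - k + 1
    codes = np.zeros((n, w), dtype=np.int64)
    bad = np.zeros((n, w), dtype=bool)
    for j in range(k):
        col = enc[:, j : j + w]
        codes = codes * 4 + (col & 3)
        bad |= col > 3
    codes[bad] = -1
    return codes


def _encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = _BASE_CODE[ord(ch)]
        if v > 3:
            return -1
        code = code * 4 + int(v)
    return code


class JunctionCaller:
    """Stateful caller holding the reference/cassette indexes."""

    def __init__(
        self,
        ref: ConstructReference,
        cassette: TransposonCassette,
        params: CallerParams = CallerParams(),
    ):
        self.ref = ref
        self.cassette = cassette
        self.params = params
        k = params.min_kmer
        ins = cassette.insert_seq
        if len(ins) < k:
            raise ValueError("cassette shorter than min_kmer")
        self._cass_fwd = _KmerIndex(ins, k)
        self._cass_rev = _KmerIndex(revcomp(ins), k)
        self._plasmid_idx = _KmerIndex(ref.plasmid_seq, params.anchor_k)
        # packed-code lookup for the vectorized batch prefilter
        self._code_lookup: dict[int, list[tuple[str, int]]] = {}
        for strand, index in (("+", self._cass_fwd), ("-", self._cass_rev)):
            for kmer, offs in index.idx.items():
                code = _encode_kmer(kmer)
                if code >= 0:
                    entry = self._code_lookup.setdefault(code, [])
                    entry.extend((strand, off) for off in offs)
        self._codes_sorted = np.array(sorted(self._code_lookup), dtype=np.int64)

    # -- cassette detection -------------------------------------------------

    def detect_insert_junction(self, read_seq: str) -> Optional[CassetteDetection]:
        """Locate the cassette within a read, or None when absent.

        Scans every read k-mer against both cassette strands; the first hit
        whose implied cassette placement verifies (mismatches over the overlap
        within tolerance) wins.  The read portions outside the cassette are
        returned as candidate LBD flanks.
        """
        read_seq = read_seq.upper()
        k = self.params.min_kmer
        n = len(read_seq)
        if n < k:
            return None
        for i in range(n - k + 1):
            kmer = read_seq[i : i + k]
            for strand, index in (("+", self._cass_fwd), ("-", self._cass_rev)):
                for off in index.hits(kmer):
                    det = self._verify_placement(read_seq, i - off, strand)
                    if det is not None:
                        return det
        return None

    def _verify_placement(
        self, read_seq: str, cstart: int, strand: str
    ) -> Optional[CassetteDetection]:
        """Check a proposed cassette placement by mismatch counting over the
        full cassette/read overlap."""
        index = self._cass_fwd if strand == "+" else self._cass_rev
        L = len(self.cassette.insert_seq)
        n = len(read_seq)
        a, b = max(0, cstart), min(n, cstart + L)
        cass_read = read_seq[a:b]
        cass_ref = index.seq[a - cstart : b - cstart]
        limit = self.params.cassette_max_mismatch
        if _mismatches(cass_read, cass_ref, limit) <= limit:
            return CassetteDetection(
                cassette_start=cstart,
                strand=strand,
                left_flank=read_seq[:a],
                right_flank=read_seq[b:],
            )
        return None

    def detect_batch(self, read_seqs: Sequence[str]) -> list[Optional[CassetteDetection]]:
        """Vectorized cassette detection for many reads at once.

        A 2-bit packed k-mer prefilter finds candidate hit positions for the
        whole batch; only candidate placements are verified per read.  Result
        order matches the input; entries are None for cassette-free reads.
        """
        k = self.params.min_kmer
        out: list[Optional[CassetteDetection]] = [None] * len(read_seqs)
        if not read_seqs:
            return out
        upper = [s.upper() for s in read_seqs]
        width = max(len(s) for s in upper)
        if width < k:
            return out
        codes = _kmer_codes(upper, k, width)
        hit = np.isin(codes, self._codes_sorted)
        for r in np.flatnonzero(hit.any(axis=1)):
            seq = upper[r]
            for i in np.flatnonzero(hit[r]):
                if i + k > len(seq):
                    continue
                for strand, off in self._code_lookup[int(codes[r, i])]:
                    det = self._verify_placement(seq, int(i) - off, strand)
                    if det is not None:
                        out[int(r)] = det
                        break
                if out[int(r)] is not None:
                    break
        return out

    # -- flank alignment ----------------------------------------------------

    def _align_flank(self, flank: str) -> list[int]:
        """All plasmid offsets (0-based) where the full flank aligns with at
        most ``max_mismatch`` mismatches; anchored by exact k-mers."""
        p = self.params
        k = p.anchor_k
        if len(flank) < k:
            return []
        starts = list(range(0, len(flank) - k + 1, p.anchor_step))
        if starts[-1] != len(flank) - k:
            starts.append(len(flank) - k)
        candidates: set[int] = set()
        for s in starts:
            for pos in self._plasmid_idx.hits(flank[s : s + k]):
                candidates.add(pos - s)
        good = []
        plasmid = self.ref.plasmid_seq
        for off in sorted(candidates):
            if off < 0 or off + len(flank) > len(plasmid):
                continue
            if _mismatches(flank, plasmid[off : off + len(flank)], p.max_mismatch) <= p.max_mismatch:
                good.append(off)
        return good

    def locate_insertion_site(
        self, flank: str, junction_side: Literal["upstream", "downstream"]
    ) -> tuple[Optional[int], str]:
        """Map a flank (already on the plasmid coding strand) to ``p``.

        Returns ``(p_orf, status)`` where status is 'ok', 'ambiguous' or
        'no_alignment'.  ``p_orf`` may fall outside the ORF (backbone
        insertions); the caller classifies that separately.
        """
        offs = self._align_flank(flank)
        if len(offs) == 0:
            return None, "no_alignment"
        if len(offs) > 1:
            return None, "ambiguous"
        off = offs[0]
        if junction_side == "upstream":
            p_plasmid = off + len(flank)  # 1-based coord of last aligned base
        else:
            # first aligned base is the start of the duplicated target bases
            p_plasmid = off + self.cassette.duplication_len
        return p_plasmid - (self.ref.orf_start - 1), "ok"

    # -- per-read calling ---------------------------------------------------

    def call_read(
        self,
        read_id: str,
        read_seq: str,
        det: Optional[CassetteDetection] | str = "auto",
    ) -> list[ReadObservation]:
        """Resolve one read into observations (usually one; two when a short
        cassette lies fully inside the read, giving both junction ends).

        ``det`` may carry a precomputed cassette detection (from
        ``detect_batch``); the default recomputes it here.
        """
        if det == "auto":
            det = self.detect_insert_junction(read_seq)
        if det is None:
            return [ReadObservation(read_id, "filtered_no_insert")]
        read_seq = read_seq.upper()

        p = self.params
        results = []
        saw_ambiguous = False
        # flank role in plasmid space depends on the read's strand; resolve by
        # trying the flank as-is (plus-strand read) then reverse-complemented.
        for flank, read_side in ((det.left_flank, "left"), (det.right_flank, "right")):
            if len(flank) < p.min_flank:
                continue
            for read_strand, fseq in (("+", flank), ("-", revcomp(flank))):
                side = (
                    "upstream"
                    if (read_side == "left") == (read_strand == "+")
                    else "downstream"
                )
                p_orf, status = self.locate_insertion_site(fseq, side)
                if status == "ambiguous":
                    saw_ambiguous = True
                    continue
                if status != "ok":
                    continue
                # orientation: cassette strand in read combined with read strand
                orientation = "forward" if det.strand == read_strand else "reverse"
                end = {
                    ("upstream", "forward"): "N",
                    ("downstream", "forward"): "C",
                    ("upstream", "reverse"): "C",
                    ("downstream", "reverse"): "N",
                }[(side, orientation)]
                results.append((p_orf, orientation, end, len(flank)))
                break  # a flank aligns on one strand only

        if not results:
            if saw_ambiguous:
                return [ReadObservation(read_id, "ambiguous")]
            return [ReadObservation(read_id, "filtered_no_lbd")]

        obs = []
        for p_orf, orientation, end, flank_len in results:
            if not 0 <= p_orf <= self.ref.orf_len:
                obs.append(ReadObservation(read_id, "non_orf"))
                continue
            event = classify_insertion(self.ref, self.cassette, p_orf, orientation)
            obs.append(
                ReadObservation(
                    read_id,
                    "called",
                    end=end,
                    orientation=orientation,
                    dna_position=p_orf,
                    event=event,
                    flank_len=flank_len,
                )
            )
        return obs


def _take(iterator, n: int) -> list:
    out = []
    for item in iterator:
        out.append(item)
        if len(out) >= n:
            break
    return out


def _open_maybe_gzip(path: Path | str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def call_reads(
    fastq_paths: Sequence[Path | str] | Path | str,
    ref: ConstructReference,
    cassette: TransposonCassette,
    params: CallerParams = CallerParams(),
) -> tuple[list[ReadObservation], dict]:
    """Call every read in the given FASTQ file(s).

    Paired-end mates are processed independently; pass both files.  Returns
    the observations plus a summary dict (read counts per status, called
    counts per orientation and frame class).  Every read receives exactly one
    status; a read exposing both cassette ends contributes one observation
    per end but is counted once in the summary.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    caller = JunctionCaller(ref, cassette, params)
    observations: list[ReadObservation] = []
    status_counts = {
        s: 0
        for s in ("called", "filtered_no_insert", "filtered_no_lbd", "ambiguous", "non_orf")
    }
    orient_counts = {"forward": 0, "reverse": 0}
    frame_counts = {"productive": 0, "out_of_frame": 0, "reverse": 0}
    n_reads = 0
    chunk = 20000
    for path in fastq_paths:
        with _open_maybe_gzip(path) as fh:
            it = FastqGeneralIterator(fh)
            while True:
                batch = [(rid.split()[0], seq) for rid, seq, _q in _take(it, chunk)]
                if not batch:
                    break
                dets = caller.detect_batch([seq for _rid, seq in batch])
                for (rid, seq), det in zip(batch, dets):
                    n_reads += 1
                    obs = caller.call_read(rid, seq, det=det)
                    observations.extend(obs)
                    status_counts[obs[0].status] += 1
                    for o in obs:
                        if o.status == "called":
                            orient_counts[o.orientation] += 1
                            if o.event.productive:
                                frame_counts["productive"] += 1
                            elif o.orientation == "reverse":
                                frame_counts["reverse"] += 1
                            else:
                                frame_counts["out_of_frame"] += 1
    summary = {
        "n_reads": n_reads,
        "status_counts": status_counts,
        "orientation_counts": orient_counts,
        "frame_counts": frame_counts,
    }
    return observations, summary


def observations_to_frame(observations: Iterable[ReadObservation]) -> pd.DataFrame:
    """Tabular per-read calls (TSV-ready)."""
    rows = []
    for o in observations:
        rows.append(
            {
                "read_id": o.read_id,
                "status": o.status,
                "end": o.end,
                "orientation": o.orientation or "",
                "p": o.dna_position if o.dna_position is not None else "",
                "codon_site": o.event.codon_site if o.event and o.event.codon_site else "",
                "productive": o.event.productive if o.event else "",
                "flank_len": o.flank_len,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "status", "end", "orientation",
            "p", "codon_site", "productive", "flank_len",
        ],
    )
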