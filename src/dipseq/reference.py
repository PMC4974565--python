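"""Construct geometry: the LBD ORF, the inserted cassette, and all coordinate conventions.

Every other module leans on the conventions fixed here:

* DNA coordinates are 1-based and inclusive on the ORF coding strand.
* The DNA insertion position ``p`` of a variant is the last basepair of the
  ligand-binding domain (LBD), in the direction of transcription, after which
  the inserted cassette is found.  ``p = 0`` means the insert sits immediately
  5' of the ORF (a non-ORF event, excluded from residue profiles).
* The codon "in which the DNA insertion occurred" is ``ceil(p / 3)``: an
  insertion after base 1 or 2 of a codon belongs to that codon.  This is the
  only reading under which a 370-codon ORF offers exactly 370 productive sites.
* A forward-oriented insertion with ``p mod 3 == inframe_phase`` translates as
  a fusion protein and is *productive*; reverse or out-of-frame insertions are
  unproductive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

Orientation = Literal["forward", "reverse"]

_STOPS = {"TAA", "TAG", "TGA"}

# Deterministic stuffer used to fabricate a plasmid context when none is given.
_STUFFER_5 = "GCTAGCCTGCAGGTCGACTCTAGAGGATCCCCGGGTACCGAGCTCGAATTC"
_STUFFER_3 = "AAGCTTGGCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACCCTGG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ConstructReference:
    """The LBD ORF in its (circular) plasmid context, with codon numbering.

    ``numbering_offset`` is added to the raw codon index when reporting residue
    numbers, so constructs numbered by a published convention (e.g. a fusion
    numbered consecutively 1-410) can be represented directly.
    """

    name: str
    orf_seq: str
    plasmid_seq: str
    orf_start: int  # 1-based position of orf_seq within plasmid_seq
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        orf = self.orf_seq.upper()
        plasmid = self.plasmid_seq.upper()
        object.__setattr__(self, "orf_seq", orf)
        object.__setattr__(self, "plasmid_seq", plasmid)
        if len(orf) == 0 or len(orf) % 3 != 0:
            raise ValueError(
                f"ORF length {len(orf)} is not a positive multiple of 3"
            )
        if plasmid.count(orf) != 1:
            raise ValueError("ORF must occur exactly once in the plasmid sequence")
        if plasmid.find(orf) != self.orf_start - 1:
            raise ValueError(
                f"orf_start={self.orf_start} does not match the ORF location "
                f"in the plasmid (found at {plasmid.find(orf) + 1})"
            )

    @property
    def codon_count(self) -> int:
        return len(self.orf_seq) // 3

    @property
    def orf_len(self) -> int:
        return len(self.orf_seq)

    def codon_numbers(self) -> range:
        """Reported residue numbers, 1 + offset .. codon_count + offset."""
        return range(1 + self.numbering_offset, self.codon_count + self.numbering_offset + 1)


@dataclass(frozen=True)
class TransposonCassette:
    """The inserted-domain cassette and its transposition scar model.

    ``insert_seq`` is the cassette on its forward (coding) strand, including
    any fixed linker scar.  Transposition duplicates ``duplication_len`` bases
    of the target site on both sides of the insert, so the two junction ends
    of one event map to ORF coordinates that differ by ``duplication_len``
    until corrected.  ``inframe_phase`` is the value of ``p mod 3`` that
    yields an in-frame (productive) fusion; it depends on the scar design.
    """

    insert_seq: str
    duplication_len: int = 5
    inframe_phase: int = 0
    name: str = "cassette"

    def __post_init__(self) -> None:
        object.__setattr__(self, "insert_seq", self.insert_seq.upper())
        if not self.insert_seq:
            raise ValueError("insert_seq must be non-empty")
        if self.duplication_len < 0:
            raise ValueError("duplication_len must be >= 0")
        if self.inframe_phase not in (0, 1, 2):
            raise ValueError("inframe_phase must be 0, 1 or 2")

    @property
    def frame_preserving(self) -> bool:
        """True when insert + duplication keeps the downstream ORF in frame."""
        return (len(self.insert_seq) + self.duplication_len) % 3 == 0


@dataclass(frozen=True)
class InsertionEvent:
    """One insertion variant, fully classified.

    ``dna_position`` is the coordinate ``p`` described in the module
    docstring.  ``frame_phase`` is ``p mod 3`` for forward insertions and
    ``None`` for reverse ones (a reverse insert has no reading frame in the
    host ORF).  ``codon_site`` is set only for productive events.
    """

    dna_position: int
    orientation: Orientation
    frame_phase: Optional[int]
    productive: bool
    codon_site: Optional[int]

    def __post_init__(self) -> None:
        if self.dna_position < 0:
            raise ValueError("dna_position must be >= 0")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.productive and self.codon_site is None:
            raise ValueError("productive events must carry a codon_site")
        if not self.productive and self.codon_site is not None:
            raise ValueError("codon_site is defined only for productive events")


def _read_single_fasta(path: Path | str) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def load_reference(
    orf_fasta: Path | str,
    plasmid_fasta: Path | str | None = None,
    numbering_offset: int = 0,
) -> ConstructReference:
    """Load the LBD construct from FASTA.

    When no plasmid context is supplied, a minimal synthetic one (the ORF
    flanked by fixed stuffer sequence) is fabricated so that flank alignment
    near the ORF termini still has context to land on.  Internal stop codons
    trigger a warning but not an error: some constructs are numbered over a
    fusion whose source fragments carry vector-derived codons.
    """
    name, orf = _read_single_fasta(orf_fasta)
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    internal = [i for i in range(0, len(orf) - 3, 3) if orf[i : i + 3] in _STOPS]
    if internal:
        warnings.warn(
            f"{name}: internal stop codon(s) at codon(s) {[i // 3 + 1 for i in internal]}",
            stacklevel=2,
        )
    if plasmid_fasta is None:
        plasmid = _STUFFER_5 + orf + _STUFFER_3
        orf_start = len(_STUFFER_5) + 1
    else:
        _, plasmid = _read_single_fasta(plasmid_fasta)
        idx = plasmid.find(orf)
        if idx < 0 or plasmid.count(orf) != 1:
            raise ValueError("ORF not found exactly once in plasmid FASTA")
        orf_start = idx + 1
    return ConstructReference(
        name=name,
        orf_seq=orf,
        plasmid_seq=plasmid,
        orf_start=orf_start,
        numbering_offset=numbering_offset,
    )


def dna_to_codon(ref: ConstructReference, p: int) -> int:
    """Codon index of DNA insertion position ``p`` (with numbering offset)."""
    if not 1 <= p <= ref.orf_len:
        raise ValueError(f"p={p} outside ORF 1..{ref.orf_len}")
    return math.ceil(p / 3) + ref.numbering_offset


def classify_insertion(
    ref: ConstructReference,
    cassette: TransposonCassette,
    p: int,
    orientation: Orientation,
) -> InsertionEvent:
    """Classify an insertion at ``p`` into the six orientation x frame classes.

    Only forward insertions with ``p mod 3 == inframe_phase`` are productive;
    those get a codon site.  ``p = 0`` (insert 5' of the ORF) and reverse
    insertions are never productive.
    """
    if not 0 <= p <= ref.orf_len:
        raise ValueError(f"p={p} outside 0..{ref.orf_len}")
    if orientation == "reverse":
        return InsertionEvent(p, "reverse", None, False, None)
    phase = p % 3
    productive = p >= 1 and phase == cassette.inframe_phase
    codon = dna_to_codon(ref, p) if productive else None
    return InsertionEvent(p, "forward", phase, productive, codon)


def enumerate_candidate_sites(
    ref: ConstructReference, cassette: TransposonCassette
) -> list[int]:
    """All codon sites a productive insertion could occupy: one per codon."""
    sites = sorted(
        {
            dna_to_codon(ref, p)
            for p in range(1, ref.orf_len + 1)
            if p % 3 == cassette.inframe_phase
        }
    )
    assert len(sites) == ref.codon_count
    return sites


def candidate_site_table(
    ref: ConstructReference, cassette: TransposonCassette
):
    """Per-codon candidate table: codon_site, productive DNA position(s), phase.

    Returned as a pandas DataFrame; write with ``df.to_csv(path, sep='\\t')``.
    """
    import pandas as pd

    rows = []
    for p in range(1, ref.orf_len + 1):
        if p % 3 == cassette.inframe_phase:
            rows.append(
                {
                    "codon_site": dna_to_codon(ref, p),
                    "dna_position": p,
                    "phase": p % 3,
                }
            )
    return pd.DataFrame(rows).groupby("codon_site", as_index=False).agg(
        dna_positions=("dna_position", lambda s: ",".join(map(str, s))),
        phase=("phase", "first"),
    )
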