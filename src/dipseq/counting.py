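"""Aggregation of read observations into per-site count tables.

Rows are insertion-site keys, columns are ``(sample, end)`` pairs.  The N- and
C-terminal junction ends of one insertion event sample the same fragment pool
and are kept as separate columns so that downstream enrichment can treat them
as internal technical replicates; a summed view is available too.

Row keys are 4-tuples ``(kind, pos, orientation, phase)``: ``kind`` is
``"dna"`` for raw DNA-position rows (pos = the insertion coordinate p, phase =
p mod 3 or -1 for reverse) and ``"codon"`` after productive rows have been
collapsed to codon sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calling import ReadObservation
from .reference import ConstructReference, TransposonCassette, dna_to_codon

ROW_NAMES = ["kind", "pos", "orientation", "phase"]


@dataclass
class CountTable:
    """Per-site read counts across samples and junction ends.

    ``df`` has a 4-level row MultiIndex (see module docstring) and 2-level
    columns ``(sample, end)``.  ``round_labels`` maps sample -> sorting round.
    """

    df: pd.DataFrame
    round_labels: dict[str, str] = field(default_factory=dict)
    inframe_phase: int = 0

    def __post_init__(self) -> None:
        if not self.df.empty:
            if (self.df.values < 0).any():
                raise ValueError("counts must be non-negative")
            if self.df.index.duplicated().any():
                raise ValueError("duplicate row keys")

    @property
    def total(self) -> int:
        return int(self.df.values.sum())

    def is_productive_row(self) -> pd.Series:
        """Boolean mask over rows: forward, in-frame (or already codon-keyed)."""
        idx = self.df.index
        kind = idx.get_level_values("kind")
        orient = idx.get_level_values("orientation")
        phase = idx.get_level_values("phase")
        return pd.Series(
            (kind == "codon")
            | ((orient == "forward") & (phase == self.inframe_phase)),
            index=idx,
        )

    def to_tsv(self, path: Path | str) -> None:
        out = self.df.copy()
        out.columns = [f"{s}:{e}" for s, e in out.columns]
        out.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path: Path | str, round_labels: Optional[dict] = None, inframe_phase: int = 0) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2, 3])
        df.index.names = ROW_NAMES
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in df.columns], names=["sample", "end"]
        )
        return CountTable(df, round_labels or {}, inframe_phase)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        index=pd.MultiIndex.from_arrays([[], [], [], []], names=ROW_NAMES),
        columns=pd.MultiIndex.from_arrays([[], []], names=["sample", "end"]),
        dtype=int,
    )


def tally_observations(
    observations: Iterable[ReadObservation],
    sample_label: str,
    round_label: str = "",
    inframe_phase: int = 0,
) -> CountTable:
    """Count called observations into one sample's (N, C) columns.

    Only ``status == "called"`` observations contribute; the DNA insertion
    site designation is used for the count regardless of which cassette end
    the read detected, but N and C are tallied into separate columns.
    """
    counts: dict[tuple, dict[str, int]] = {}
    for o in observations:
        if o.status != "called":
            continue
        ev = o.event
        phase = ev.frame_phase if ev.frame_phase is not None else -1
        key = ("dna", ev.dna_position, ev.orientation, phase)
        counts.setdefault(key, {"N": 0, "C": 0})[o.end] += 1
    if not counts:
        return CountTable(_empty_frame(), {sample_label: round_label}, inframe_phase)
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=ROW_NAMES)
    df = pd.DataFrame(
        [[counts[k]["N"], counts[k]["C"]] for k in sorted(counts)],
        index=idx,
        columns=pd.MultiIndex.from_tuples(
            [(sample_label, "N"), (sample_label, "C")], names=["sample", "end"]
        ),
        dtype=int,
    )
    return CountTable(df, {sample_label: round_label}, inframe_phase)


def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Outer-join tables on row keys; missing cells become zero.

    Column order follows the input order (the sample sheet order).  Duplicate
    ``(sample, end)`` columns across tables are an error.
    """
    if not tables:
        return CountTable(_empty_frame())
    cols: list[tuple] = []
    for t in tables:
        for c in t.df.columns:
            if c in cols:
                raise ValueError(f"duplicate sample column {c}")
            cols.append(c)
    frames = [t.df for t in tables if not t.df.empty]
    if not frames:
        return CountTable(_empty_frame(), {}, tables[0].inframe_phase)
    merged = pd.concat(frames, axis=1).fillna(0).astype(int)
    merged = merged.loc[:, [c for c in cols if c in merged.columns]]
    merged = merged.sort_index()
    labels: dict[str, str] = {}
    for t in tables:
        labels.update(t.round_labels)
    phases = {t.inframe_phase for t in tables}
    if len(phases) > 1:
        raise ValueError("tables disagree on inframe_phase")
    return CountTable(merged, labels, phases.pop())


def filter_productive(table: CountTable) -> CountTable:
    """Keep only productive rows (forward, in-frame), before any normalization."""
    mask = table.is_productive_row()
    return CountTable(table.df.loc[mask.values], dict(table.round_labels), table.inframe_phase)


def collapse_by_codon(table: CountTable, ref: ConstructReference) -> CountTable:
    """Re-key productive rows by codon site (counts summed); unproductive rows
    keep their DNA-position keys unchanged."""
    if table.df.empty:
        return CountTable(table.df.copy(), dict(table.round_labels), table.inframe_phase)
    mask = table.is_productive_row().values
    prod = table.df.loc[mask]
    unprod = table.df.loc[~mask]
    pieces = []
    if not prod.empty:
        codons = [
            pos if kind == "codon" else dna_to_codon(ref, pos)
            for kind, pos, _o, _ph in prod.index
        ]
        new_idx = pd.MultiIndex.from_arrays(
            [["codon"] * len(codons), codons, ["forward"] * len(codons),
             [table.inframe_phase] * len(codons)],
            names=ROW_NAMES,
        )
        collapsed = prod.set_axis(new_idx).groupby(level=ROW_NAMES).sum()
        pieces.append(collapsed)
    if not unprod.empty:
        pieces.append(unprod)
    out = pd.concat(pieces).sort_index()
    return CountTable(out, dict(table.round_labels), table.inframe_phase)


def sum_ends(table: CountTable) -> CountTable:
    """Collapse the (N, C) junction-end columns of each sample into one."""
    if table.df.empty:
        return CountTable(table.df.copy(), dict(table.round_labels), table.inframe_phase)
    summed = table.df.T.groupby(level="sample", sort=False).sum().T
    summed.columns = pd.MultiIndex.from_tuples(
        [(s, "NC") for s in summed.columns], names=["sample", "end"]
    )
    return CountTable(summed, dict(table.round_labels), table.inframe_phase)
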