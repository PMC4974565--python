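"""Synthetic domain-insertion libraries, FACS-style sorting, and read generation.

This module makes the whole pipeline testable with no external data.  It
emulates the experimental workflow end to end:

* random transposon insertion, uniform over the ORF, in both orientations and
  all three frame phases ("all six reading frames");
* a strongly skewed initial abundance distribution (the observed ~1,000-fold
  construct-abundance bias is the default);
* ligand-switchable fluorescence for productive variants and background-only
  fluorescence for unproductive ones;
* fluorescence-gated sorting rounds with lognormal cell-to-cell noise and a
  small impurity (leak) rate;
* junction-spanning short reads from sheared fragments, with per-base
  substitution errors and a ground-truth table for every read.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import (
    ConstructReference,
    InsertionEvent,
    TransposonCassette,
    classify_insertion,
    revcomp,
)

RoundLabel = Literal["naive", "sort1", "sort2", "sort3"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODONS = {"TAA", "TAG", "TGA"}

# Variant-level fluorescence defaults (arbitrary fluorescence units).
BACKGROUND_AFU = 30.0     # unproductive / untranslated constructs
DIM_FOLDED_AFU = 120.0    # productive but not in the activity map


@dataclass
class InsertionVariant:
    """One library member: an insertion event with abundance and phenotype."""

    variant_id: str
    event: InsertionEvent
    abundance: float
    fluorescence: float = float("nan")  # mean AFU; set by assign_fluorescence

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass
class LibraryState:
    """A library pool at one point of the sorting schedule."""

    variants: list[InsertionVariant]
    round_label: str = "naive"
    rng_seed: int = 0

    def abundances(self) -> np.ndarray:
        return np.array([v.abundance for v in self.variants], dtype=float)

    def frequencies(self) -> np.ndarray:
        a = self.abundances()
        total = a.sum()
        if total <= 0:
            raise ValueError("library has zero total abundance")
        return a / total

    def productive_fraction(self) -> float:
        n = len(self.variants)
        return sum(v.event.productive for v in self.variants) / n if n else float("nan")


@dataclass(frozen=True)
class SelectionModel:
    """One FACS gate: keep cells whose fluorescence falls inside the window.

    A positive sort keeps a bright window (``gate_high`` typically infinite);
    a negative sort keeps a low window to discard constitutively bright
    constructs.  ``leak_rate`` is the probability a cell outside the gate
    nevertheless survives (sorter impurity).
    """

    gate_low: float
    gate_high: float = float("inf")
    sort_mode: Literal["positive", "negative"] = "positive"
    ligand_present: bool = True
    leak_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in [0, 1]")
        if self.gate_low > self.gate_high:
            raise ValueError("gate_low must be <= gate_high")


# ---------------------------------------------------------------------------
# Synthetic references (demo constructs; sequences are synthetic stand-ins
# with the real constructs' lengths and frame geometry).


def make_demo_reference(
    n_codons: int = 370, seed: int = 7, name: str = "demoLBD"
) -> ConstructReference:
    """A synthetic LBD construct: random stop-free ORF of ``n_codons`` codons
    in a synthetic plasmid context."""
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    codons[0] = "ATG"
    orf = "".join(codons)
    # random plasmid context; for tiny ORFs a random context may contain the
    # ORF by chance, so fall back to low-complexity stuffers that cannot
    for attempt in range(5):
        r = np.random.default_rng(seed + 1 + attempt)
        up = "".join(r.choice(list("ACGT"), size=400))
        down = "".join(r.choice(list("ACGT"), size=400))
        plasmid = up + orf + down
        if plasmid.count(orf) == 1:
            return ConstructReference(
                name=name, orf_seq=orf, plasmid_seq=plasmid, orf_start=len(up) + 1
            )
    for unit in ("GGCC", "AATT"):
        up = down = unit * 100
        plasmid = up + orf + down
        if plasmid.count(orf) == 1:
            return ConstructReference(
                name=name, orf_seq=orf, plasmid_seq=plasmid, orf_start=len(up) + 1
            )
    raise RuntimeError(f"could not build a unique plasmid context for {name}")


def make_demo_cassette(
    length: int = 799, duplication_len: int = 5, inframe_phase: int = 0, seed: int = 11
) -> TransposonCassette:
    """A synthetic fluorescent-domain cassette (cpGFP-sized stand-in).

    Length is chosen so the cassette plus target-site duplication preserves
    the downstream reading frame: (length + duplication_len) % 3 == 0.
    """
    if (length + duplication_len) % 3 != 0:
        raise ValueError("length + duplication_len must be divisible by 3")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return TransposonCassette(
        insert_seq=seq,
        duplication_len=duplication_len,
        inframe_phase=inframe_phase,
        name="demo-cassette",
    )


# ---------------------------------------------------------------------------
# Library construction and sorting


def simulate_naive_library(
    ref: ConstructReference,
    cassette: TransposonCassette,
    n_variants: int,
    abundance_fold_range: float = 1000.0,
    seed: int = 0,
) -> LibraryState:
    """Simulate random transposition into the ORF.

    ``n_variants`` insertion events are drawn with positions uniform over
    1..len(orf) and orientation Bernoulli(0.5); duplicate (position,
    orientation) draws collapse to one variant.  Abundances are lognormal,
    rescaled so the max/min ratio equals ``abundance_fold_range`` exactly.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if abundance_fold_range < 1:
        raise ValueError("abundance_fold_range must be >= 1")
    rng = np.random.default_rng(seed)
    positions = rng.integers(1, ref.orf_len + 1, size=n_variants)
    orients = rng.integers(0, 2, size=n_variants)
    seen: dict[tuple[int, str], None] = {}
    for p, o in zip(positions, orients):
        seen.setdefault((int(p), "forward" if o == 0 else "reverse"), None)
    keys = sorted(seen)
    z = rng.standard_normal(len(keys))
    if len(keys) > 1 and z.max() > z.min():
        z = (z - z.min()) / (z.max() - z.min()) * math.log(abundance_fold_range)
    else:
        z = np.zeros(len(keys))
    variants = [
        InsertionVariant(
            variant_id=f"v{p:05d}{'F' if o == 'forward' else 'R'}",
            event=classify_insertion(ref, cassette, p, o),
            abundance=float(np.exp(zi)),
        )
        for (p, o), zi in zip(keys, z)
    ]
    return LibraryState(variants=variants, round_label="naive", rng_seed=seed)


def assign_fluorescence(
    lib: LibraryState,
    activity_map: Mapping[int, tuple[float, float]],
    ligand_present: bool,
    f0_default: float = DIM_FOLDED_AFU,
    background: float = BACKGROUND_AFU,
) -> LibraryState:
    """Give each variant its mean fluorescence under the current condition.

    ``activity_map`` maps a productive codon site to ``(F0, dF/F)``.  A
    variant in the map fluoresces ``F0 * (1 + dF/F)`` with ligand and ``F0``
    without; other productive variants sit at a dim-but-folded default;
    unproductive variants show only background.
    """
    new = []
    for v in lib.variants:
        if not v.event.productive:
            f = background
        elif v.event.codon_site in activity_map:
            f0, dff = activity_map[v.event.codon_site]
            f = f0 * (1.0 + dff) if ligand_present else f0
        else:
            f = f0_default
        new.append(replace(v, fluorescence=float(f)))
    return LibraryState(variants=new, round_label=lib.round_label, rng_seed=lib.rng_seed)


def simulate_sort(
    lib: LibraryState,
    model: SelectionModel,
    n_cells_sorted: int,
    seed: int = 0,
    noise_cv: float = 0.35,
    round_label: Optional[str] = None,
) -> LibraryState:
    """One FACS round: multinomial sampling of cells, gated survival.

    Cells of a variant fluoresce around the variant mean with lognormal
    cell-to-cell noise (coefficient of variation ``noise_cv``); a cell
    survives if its fluorescence falls inside the gate, otherwise with
    probability ``leak_rate``.  The surviving cell counts become the new
    abundances.
    """
    if not lib.variants:
        raise ValueError("empty library")
    fluor = np.array([v.fluorescence for v in lib.variants])
    if np.isnan(fluor).any():
        raise ValueError("fluorescence not assigned; call assign_fluorescence first")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells_sorted, lib.frequencies())
    if noise_cv > 0:
        s = math.sqrt(math.log(1.0 + noise_cv**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.where(
                np.isfinite(model.gate_high),
                norm.cdf(np.log(np.maximum(model.gate_high, 1e-300) / np.maximum(fluor, 1e-300)) / s),
                1.0,
            )
            lo = np.where(
                model.gate_low > 0,
                norm.cdf(np.log(np.maximum(model.gate_low, 1e-300) / np.maximum(fluor, 1e-300)) / s),
                0.0,
            )
        q = np.clip(hi - lo, 0.0, 1.0)
        q = np.where(fluor <= 0, float(model.gate_low <= 0), q)
    else:
        q = ((fluor >= model.gate_low) & (fluor <= model.gate_high)).astype(float)
    p_surv = q + (1.0 - q) * model.leak_rate
    survivors = rng.binomial(counts, p_surv)
    if survivors.sum() == 0:
        raise RuntimeError(
            f"zero survivors: gate [{model.gate_low}, {model.gate_high}] AFU excluded "
            f"all {n_cells_sorted} cells (fluorescence range "
            f"{fluor.min():.1f}-{fluor.max():.1f}, leak_rate={model.leak_rate})"
        )
    new = [replace(v, abundance=float(c)) for v, c in zip(lib.variants, survivors)]
    label = round_label or _next_round(lib.round_label)
    return LibraryState(variants=new, round_label=label, rng_seed=seed)


def _next_round(label: str) -> str:
    order = ["naive", "sort1", "sort2", "sort3"]
    try:
        return order[order.index(label) + 1]
    except (ValueError, IndexError):
        return label + "+1"


def simulate_sort_series(
    lib: LibraryState,
    activity_map: Mapping[int, tuple[float, float]],
    models: Sequence[SelectionModel],
    n_cells_sorted: int,
    seed: int = 0,
    noise_cv: float = 0.35,
) -> list[LibraryState]:
    """Run a schedule of sorts (e.g. positive / negative / positive),
    reassigning fluorescence for each round's ligand condition.

    Returns the library after every round (not including the input library).
    """
    out = []
    current = lib
    for i, model in enumerate(models):
        current = assign_fluorescence(current, activity_map, model.ligand_present)
        current = simulate_sort(
            current, model, n_cells_sorted, seed=seed + 1000 + i, noise_cv=noise_cv
        )
        out.append(current)
    return out


# ---------------------------------------------------------------------------
# Read generation


def variant_construct(
    ref: ConstructReference, cassette: TransposonCassette, event: InsertionEvent
) -> tuple[str, int]:
    """Full plasmid sequence of one insertion variant.

    Returns ``(sequence, boundary)`` where ``boundary`` is the 0-based offset
    of the first cassette base: the transposon cassette (oriented), then the
    ``duplication_len`` duplicated target bases, are spliced in after plasmid
    position ``orf_start - 1 + p``.
    """
    p_plasmid = ref.orf_start - 1 + event.dna_position  # bases before the insert
    ins = (
        cassette.insert_seq
        if event.orientation == "forward"
        else revcomp(cassette.insert_seq)
    )
    dup = ref.plasmid_seq[p_plasmid - cassette.duplication_len : p_plasmid]
    seq = ref.plasmid_seq[:p_plasmid] + ins + dup + ref.plasmid_seq[p_plasmid:]
    return seq, p_plasmid


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    if hits.size:
        # substitute with a uniformly random different base
        shifts = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shifts) % 4]
    return arr.tobytes().decode()


def generate_reads(
    lib: LibraryState,
    ref: ConstructReference,
    cassette: TransposonCassette,
    depth: int,
    out_prefix: Path | str,
    read_len: int = 150,
    error_rate: float = 0.0,
    paired: bool = False,
    seed: int = 0,
    fragment_mean: float = 250.0,
    fragment_sd: float = 60.0,
    gzip_out: bool = False,
) -> tuple[list[Path], pd.DataFrame]:
    """Emit ``depth`` sheared fragments as FASTQ reads plus a ground-truth table.

    Fragments are drawn from variant constructs in proportion to abundance,
    with Normal(fragment_mean, fragment_sd) lengths truncated at ``read_len``.
    Single-end mode emits one read per fragment from a random strand; paired
    mode emits both fragment ends (R2 reverse-complemented).  The truth table
    records, per read, the originating variant, the true insertion position,
    which cassette end (N/C) the read spans (if any) and the supporting
    host-flank / cassette-overlap lengths.

    Returns the FASTQ path(s) and the truth DataFrame (also written to
    ``<out_prefix>.truth.tsv``).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    out_prefix = Path(out_prefix)
    rng = np.random.default_rng(seed)
    qual = "I" * read_len

    active = [v for v in lib.variants if v.abundance > 0]
    records: list[dict] = []
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []

    if depth > 0 and not active:
        raise ValueError("library has no variants with positive abundance")

    constructs = {}
    for v in active:
        constructs[v.variant_id] = variant_construct(ref, cassette, v.event)

    if depth > 0:
        weights = np.array([v.abundance for v in active], dtype=float)
        weights /= weights.sum()
        choice = rng.choice(len(active), size=depth, p=weights)
        frag_lens = rng.normal(fragment_mean, fragment_sd, size=depth)
        strands = rng.integers(0, 2, size=depth)
        u_start = rng.random(depth)
    else:
        choice = np.array([], dtype=int)

    ins_len = len(cassette.insert_seq)
    for i in range(depth):
        v = active[choice[i]]
        cseq, boundary = constructs[v.variant_id]
        clen = len(cseq)
        flen = int(np.clip(round(frag_lens[i]), read_len, clen))
        start = int(u_start[i] * (clen - flen + 1))
        end = start + flen
        frag = cseq[start:end]
        minus = bool(strands[i])

        def _truth(rs: int, re_: int, read_id: str) -> dict:
            up_flank = max(0, min(re_, boundary) - rs)
            cass = max(0, min(re_, boundary + ins_len) - max(rs, boundary))
            down_flank = max(0, re_ - max(rs, boundary + ins_len))
            spans_up = up_flank > 0 and cass > 0
            spans_down = down_flank > 0 and cass > 0
            fwd = v.event.orientation == "forward"
            if spans_up and spans_down:
                end_lbl, host_flank = "both", max(up_flank, down_flank)
            elif spans_up:
                end_lbl, host_flank = ("N" if fwd else "C"), up_flank
            elif spans_down:
                end_lbl, host_flank = ("C" if fwd else "N"), down_flank
            else:
                end_lbl, host_flank = "none", 0
            return {
                "read_id": read_id,
                "variant_id": v.variant_id,
                "true_p": v.event.dna_position,
                "orientation": v.event.orientation,
                "end": end_lbl,
                "host_flank": host_flank,
                "cassette_overlap": cass,
                "productive": v.event.productive,
            }

        if paired:
            rid = f"frag{i:07d}"
            r1 = frag[:read_len]
            r2 = revcomp(frag)[:read_len]
            reads1.append((rid + "/1", _apply_errors(r1, error_rate, rng)))
            reads2.append((rid + "/2", _apply_errors(r2, error_rate, rng)))
            records.append(_truth(start, start + read_len, rid + "/1"))
            records.append(_truth(end - read_len, end, rid + "/2"))
        else:
            rid = f"read{i:07d}"
            if minus:
                rseq = revcomp(frag)[:read_len]
                rs, re_ = end - read_len, end
            else:
                rseq = frag[:read_len]
                rs, re_ = start, start + read_len
            reads1.append((rid, _apply_errors(rseq, error_rate, rng)))
            records.append(_truth(rs, re_, rid))

    suffix = ".fastq.gz" if gzip_out else ".fastq"
    opener = (lambda p: gzip.open(p, "wt")) if gzip_out else (lambda p: open(p, "w"))

    def _write(path: Path, reads: list[tuple[str, str]]) -> None:
        with opener(path) as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual[: len(seq)]}\n")

    truth = pd.DataFrame(
        records,
        columns=[
            "read_id", "variant_id", "true_p", "orientation",
            "end", "host_flank", "cassette_overlap", "productive",
        ],
    )
    if paired:
        p1 = out_prefix.with_name(out_prefix.name + "_R1" + suffix)
        p2 = out_prefix.with_name(out_prefix.name + "_R2" + suffix)
        _write(p1, reads1)
        _write(p2, reads2)
        paths = [p1, p2]
    else:
        p1 = out_prefix.with_name(out_prefix.name + suffix)
        _write(p1, reads1)
        paths = [p1]
    truth.to_csv(out_prefix.with_name(out_prefix.name + ".truth.tsv"), sep="\t", index=False)
    return paths, truth
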