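"""Per-residue enrichment profiles and plate-reader biosensor activity.

Activity of an individual biosensor construct is the fractional fluorescence
change on ligand addition, dF/F = (F_ligand - F0) / F0, computed on
growth-normalized fluorescence (fluorescence divided by OD600 at the same
timepoint): F0 is the normalized value immediately before ligand addition and
F_ligand the mean of post-addition timepoints 2-6.  A control construct's
dF/F can be subtracted to remove plate-wide artifacts.

The profile view emits exactly one row per codon of the host protein, with
sentinel-capped values for cleared sites and an ordinal enrichment bin for
plotting, mirroring primary-sequence hotspot maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .enrichment import EnrichmentResult
from .reference import ConstructReference

DEFAULT_BIN_EDGES = (0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ActivityRecord:
    """Measured biosensor activity at one insertion site."""

    codon_site: int
    dff_mean: float
    dff_sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dff_sd < 0:
            raise ValueError("dff_sd must be >= 0")


@dataclass(frozen=True)
class RegressionReport:
    """OLS of activity on an enrichment predictor."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    pvalue: float  # two-sided test of slope == 0
    n: int


def compute_activity(
    od: pd.DataFrame,
    fluorescence: pd.DataFrame,
    ligand_add_index: int,
    control_well: Optional[str] = None,
) -> pd.Series:
    """Per-well dF/F from plate-reader timeseries.

    ``od`` and ``fluorescence`` are timepoint x well tables with identical
    shape; ``ligand_add_index`` is the row index of the first measurement
    after ligand addition.  Requires at least six post-addition timepoints.
    When ``control_well`` is given, its dF/F is subtracted from every well
    (additive control normalization).
    """
    if od.shape != fluorescence.shape or not od.columns.equals(fluorescence.columns):
        raise ValueError("od and fluorescence tables must be aligned")
    if (od.to_numpy() <= 0).any():
        raise ValueError("OD must be positive at every timepoint")
    n_post = len(od) - ligand_add_index
    if ligand_add_index < 1 or n_post < 6:
        raise ValueError(
            f"need >=6 post-addition timepoints and >=1 pre-addition; got "
            f"{n_post} post at ligand_add_index={ligand_add_index}"
        )
    norm = fluorescence / od
    f0 = norm.iloc[ligand_add_index - 1]
    f_ligand = norm.iloc[ligand_add_index + 1 : ligand_add_index + 6].mean()
    dff = (f_ligand - f0) / f0
    if control_well is not None:
        if control_well not in dff.index:
            raise ValueError(f"control well {control_well!r} not in table")
        dff = dff - dff[control_well]
    dff.name = "dff"
    return dff


def load_activity_table(path: Path | str) -> list[ActivityRecord]:
    """Read an activity TSV with columns site, dff_mean, dff_sd, n."""
    df = pd.read_csv(path, sep="\t")
    required = {"site", "dff_mean", "dff_sd", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"activity table needs columns {sorted(required)}")
    return [
        ActivityRecord(int(r.site), float(r.dff_mean), float(r.dff_sd), int(r.n))
        for r in df.itertuples()
    ]


def correlate_activity(
    results: Sequence[EnrichmentResult],
    activities: Sequence[ActivityRecord],
    predictor: Literal["log2fc", "fold_change", "read_count"] = "fold_change",
    include_capped: bool = False,
) -> RegressionReport:
    """Ordinary least squares of dF/F on a per-site enrichment predictor.

    Sites are matched on codon number (results must be codon-collapsed).
    Capped (appeared/cleared) sites carry sentinels rather than estimates and
    are excluded unless ``include_capped``.  ``read_count`` uses the mean
    normalized count (base_mean) as the abundance predictor.
    """
    by_site = {
        r.site[1]: r
        for r in results
        if r.site[0] == "codon" and (include_capped or r.cap == "none")
    }
    xs, ys = [], []
    for a in activities:
        r = by_site.get(a.codon_site)
        if r is None:
            continue
        if predictor == "log2fc":
            x = r.log2fc
        elif predictor == "fold_change":
            x = 2.0**r.log2fc
        elif predictor == "read_count":
            x = r.base_mean
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        xs.append(x)
        ys.append(a.dff_mean)
    if len(xs) < 3:
        raise ValueError(f"need >=3 matched sites, got {len(xs)}")
    x = np.asarray(xs)
    if np.allclose(x, x[0]):
        raise ValueError("predictor has zero variance")
    fit = linregress(x, np.asarray(ys))
    return RegressionReport(
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
        n=len(xs),
    )


def make_profile(
    results: Sequence[EnrichmentResult],
    ref: ConstructReference,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    cleared_value: Optional[float] = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-residue enrichment profile: exactly one row per codon.

    Input must be enrichment computed on a codon-collapsed productive table.
    Undetected codons are flagged with ``detected=False``; cleared sites carry
    ``cleared_value`` when given (e.g. -5 for display) instead of the
    enrichment run's own cap.  ``enrichment_bin`` is the ordinal bin of the
    log2 fold change over ``bin_edges`` (-1 for undetected or non-significant
    sites, matching white/absent coloring).
    """
    by_site = {}
    for r in results:
        if r.site[0] != "codon":
            raise ValueError("make_profile expects codon-collapsed results")
        by_site[r.site[1]] = r
    rows = []
    for codon in ref.codon_numbers():
        r = by_site.get(codon)
        if r is None:
            rows.append(
                {
                    "codon_site": codon, "log2fc": np.nan, "padj": np.nan,
                    "cap": "none", "significant": False,
                    "enrichment_bin": -1, "detected": False,
                }
            )
            continue
        val = r.log2fc
        if r.cap == "cleared" and cleared_value is not None:
            val = -abs(cleared_value)
        sig = r.significant
        rows.append(
            {
                "codon_site": codon, "log2fc": val, "padj": r.padj,
                "cap": r.cap, "significant": sig,
                "enrichment_bin": int(np.digitize(val, bin_edges)) if sig else -1,
                "detected": True,
            }
        )
    return pd.DataFrame(rows)


def write_profile_bed(profile: pd.DataFrame, ref: ConstructReference, path: Path | str) -> None:
    """BED export of the per-residue profile (0-based half-open residue
    intervals; TSV views stay 1-based)."""
    with open(path, "w") as fh:
        for r in profile.itertuples():
            score = 0.0 if not r.detected or np.isnan(r.log2fc) else r.log2fc
            fh.write(
                f"{ref.name}\t{r.codon_site - 1}\t{r.codon_site}\t"
                f"site_{r.codon_site}\t{score:.4f}\t+\n"
            )
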