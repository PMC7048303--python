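"""Y-chromosome region classification and X-Y divergence decay.

Pooled male and female read depth over a Y-linked contig separates three
region classes: male-specific sequence (near-zero female coverage at normal
male coverage), hyper-repetitive sequence (combined coverage far above the
single-copy expectation), and pseudoautosomal-like (PAR-like) sequence where
both sexes still map (female read fraction > 0.30) over a run longer than
3 kb.  Genes in the PAR-like regions retain distinguishable X and Y alleles
whose synonymous divergence is expected to decay with distance from the
sex-determining anchor locus, and to exceed interspecific X-allele baselines
wherever recombination arrest predates speciation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .codon_evolution import CodonAlignment, DivergenceEstimate, pairwise_divergence
from .io_formats import DepthTrack, RegionCall

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSummary",
    "XYGene",
    "DecayReport",
    "windowed_ratio",
    "classify_regions",
    "xy_divergence_table",
    "divergence_decay",
]

EXPECTED_SINGLE_COPY_DEPTH = 20.0
PAR_MIN_LENGTH_BP = 3000
FEMALE_FRACTION_PAR = 0.30
FEMALE_FRACTION_MALE_SPECIFIC = 0.05
REPETITIVE_DEPTH_FACTOR = 2.0
DEFAULT_WINDOW_BP = 500


@dataclass(frozen=True)
class WindowSummary:
    """Depth summary of one non-overlapping window."""

    contig: str
    start: int
    end: int
    mean_male: float
    mean_female: float
    female_fraction: float  # NaN when both depths are zero
    repetitive: bool


@dataclass(frozen=True)
class XYGene:
    """One PAR-like gene with X-Y divergence and interspecific baselines."""

    gene_id: str
    distance_to_anchor: float
    ds_xy: float
    divergence: DivergenceEstimate
    baselines: dict  # species label -> interspecific dS
    predates_speciation: bool  # ds_xy above every interspecific baseline


@dataclass(frozen=True)
class DecayReport:
    """Spearman summary of the ds_xy-vs-distance relationship."""

    n_genes: int
    rho: float
    p_value: float
    insufficient: bool
    constant_input: bool


def windowed_ratio(
    track: DepthTrack,
    window_bp: int = DEFAULT_WINDOW_BP,
    expected_single_copy_depth: float = EXPECTED_SINGLE_COPY_DEPTH,
) -> list[WindowSummary]:
    """Mean depths and female read fraction per non-overlapping window.

    The female fraction is F/(M+F) of the window means, NaN (undetermined)
    when both are zero.  A window is flagged repetitive when its combined
    mean depth (M+F)/2 exceeds ``REPETITIVE_DEPTH_FACTOR`` times the
    expected single-copy depth.  A trailing partial window is kept.
    """
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    if track.length == 0:
        raise ValueError("empty depth track")
    out = []
    for start in range(0, track.length, window_bp):
        end = min(start + window_bp, track.length)
        m = float(track.male_depth[start:end].mean())
        f = float(track.female_depth[start:end].mean())
        frac = f / (m + f) if (m + f) > 0 else math.nan
        rep = (m + f) / 2.0 > REPETITIVE_DEPTH_FACTOR * expected_single_copy_depth
        out.append(WindowSummary(track.contig, start, end, m, f, frac, rep))
    return out


def _window_class(
    w: WindowSummary,
    expected_depth: float,
    male_specific_fraction: float,
    par_fraction: float,
) -> str:
    if w.repetitive:
        return "repetitive"
    if (
        math.isfinite(w.female_fraction)
        and w.female_fraction < male_specific_fraction
        and w.mean_male >= 0.5 * expected_depth
    ):
        return "male-specific"
    if math.isfinite(w.female_fraction) and w.female_fraction > par_fraction:
        return "PAR-candidate"
    return "undetermined"


def classify_regions(
    windows: Sequence[WindowSummary],
    expected_single_copy_depth: float = EXPECTED_SINGLE_COPY_DEPTH,
    par_min_length_bp: int = PAR_MIN_LENGTH_BP,
    par_female_fraction: float = FEMALE_FRACTION_PAR,
    male_specific_fraction: float = FEMALE_FRACTION_MALE_SPECIFIC,
) -> list[RegionCall]:
    """Merge per-window classes into region calls.

    Window rule: repetitive if flagged; else male-specific when the female
    fraction is below ``male_specific_fraction`` at at least half the
    expected male depth; else a PAR candidate when the female fraction
    exceeds ``par_female_fraction``; otherwise undetermined.  Consecutive
    same-class windows merge; PAR candidate runs become PAR-like only when
    strictly longer than ``par_min_length_bp``, and are undetermined
    otherwise.  The procedure is deterministic and idempotent.
    """
    if not windows:
        return []
    runs: list[list] = []  # [class, start, end, sum_m*len, sum_f*len]
    for w in sorted(windows, key=lambda w: (w.contig, w.start)):
        cls = _window_class(
            w, expected_single_copy_depth, male_specific_fraction, par_fraction=par_female_fraction
        )
        if runs and runs[-1][0] == cls and runs[-1][1] == w.contig and runs[-1][3] == w.start:
            runs[-1][3] = w.end
            runs[-1][4] += w.mean_male * (w.end - w.start)
            runs[-1][5] += w.mean_female * (w.end - w.start)
        else:
            runs.append(
                [cls, w.contig, w.start, w.end,
                 w.mean_male * (w.end - w.start), w.mean_female * (w.end - w.start)]
            )
    # demote PAR-candidate runs that fail the length rule, then re-merge
    # adjacent undetermined runs so the output is idempotent
    for run in runs:
        if run[0] == "PAR-candidate":
            run[0] = "PAR-like" if run[3] - run[2] > par_min_length_bp else "undetermined"
    merged: list[list] = []
    for run in runs:
        if merged and merged[-1][0] == run[0] and merged[-1][1] == run[1] and merged[-1][3] == run[2]:
            merged[-1][3] = run[3]
            merged[-1][4] += run[4]
            merged[-1][5] += run[5]
        else:
            merged.append(run)
    calls = []
    for cls, contig, start, end, msum, fsum in merged:
        length = end - start
        m, f = msum / length, fsum / length
        frac = f / (m + f) if (m + f) > 0 else math.nan
        calls.append(RegionCall(contig, start, end, cls, m, f, frac))
    return calls


def xy_divergence_table(
    xy_alignments: Mapping[str, CodonAlignment],
    gene_midpoints: Mapping[str, float],
    anchor_position: float,
    ortholog_alignments: Mapping[str, Mapping[str, CodonAlignment]] | None = None,
    signed_distance: bool = False,
) -> list[XYGene]:
    """Per-gene X-Y dS, distance to the anchor, and interspecific baselines.

    ``xy_alignments`` maps gene id -> X/Y allele codon alignment;
    ``ortholog_alignments`` maps gene id -> {species -> X-allele ortholog
    alignment}, each measured with the same NG86+JC estimator.  Genes whose
    X-Y alignment is missing a usable column are skipped with a warning.
    """
    rows = []
    for gene_id, aln in xy_alignments.items():
        try:
            est = pairwise_divergence(aln)
        except ValueError as exc:
            logger.warning("skipping %s: %s", gene_id, exc)
            continue
        midpoint = gene_midpoints[gene_id]
        dist = midpoint - anchor_position
        if not signed_distance:
            dist = abs(dist)
        baselines = {}
        for species, ortho in (ortholog_alignments or {}).get(gene_id, {}).items():
            try:
                baselines[species] = pairwise_divergence(ortho).ds
            except ValueError as exc:
                logger.warning("skipping baseline %s/%s: %s", gene_id, species, exc)
        finite = [v for v in baselines.values() if math.isfinite(v)]
        predates = bool(finite) and math.isfinite(est.ds) and est.ds > max(finite)
        rows.append(
            XYGene(
                gene_id=gene_id,
                distance_to_anchor=float(dist),
                ds_xy=est.ds,
                divergence=est,
                baselines=baselines,
                predates_speciation=predates,
            )
        )
    return rows


def divergence_decay(xy_table: Sequence[XYGene]) -> DecayReport:
    """Spearman rank correlation between anchor distance and X-Y dS.

    Average ranks on ties; rho is undefined (NaN, flagged) when either
    variable is constant; fewer than 4 usable genes marks the report
    insufficient.
    """
    usable = [g for g in xy_table if math.isfinite(g.ds_xy)]
    if len(usable) < 4:
        return DecayReport(len(usable), math.nan, math.nan, True, False)
    dist = np.array([g.distance_to_anchor for g in usable])
    ds = np.array([g.ds_xy for g in usable])
    if np.ptp(dist) == 0 or np.ptp(ds) == 0:
        return DecayReport(len(usable), math.nan, math.nan, False, True)
    res = spearmanr(dist, ds)
    return DecayReport(len(usable), float(res.statistic), float(res.pvalue), False, False)


def xy_table_to_frame(xy_table: Sequence[XYGene]) -> pd.DataFrame:
    rows = []
    for g in xy_table:
        row = {
            "gene_id": g.gene_id,
            "distance_to_anchor": g.distance_to_anchor,
            "ds_xy": g.ds_xy,
            "predates_speciation": g.predates_speciation,
        }
        for species, ds in g.baselines.items():
            row[f"ds_{species}"] = ds
        rows.append(row)
    return pd.DataFrame(rows)
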