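"""Codon-level divergence estimation.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction: per-codon synonymous/nonsynonymous site counts,
pathway-averaged difference counts, dS, dN and their ratio ω = dN/dS;
the fourfold-degenerate-site transversion statistic (4DTv); sliding-window
dN/dS profiles along a codon alignment; outgroup-anchored assignment of
substitutions to the two paralog branches; and a counts-based exact
binomial screen for departure from neutrality (ω = 1).

All estimators operate on :class:`CodonAlignment` objects: gap-free paired
(or triple) codon columns.  Columns containing a gap, an ambiguous base or a
stop codon in any sequence are excluded when the alignment is built and are
carried along as a dropped-column tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from . import genetics
from .genetics import (
    CODON_INDEX,
    FOURFOLD_PREFIXES,
    ND_MATRIX,
    N_SITES,
    SD_MATRIX,
    S_SITES,
    is_transversion,
)

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "FourDTvResult",
    "WindowProfile",
    "BranchDivergence",
    "build_codon_alignment",
    "jukes_cantor",
    "pairwise_divergence",
    "fourdtv",
    "sliding_window_dnds",
    "branch_divergence",
    "sliding_window_branch",
    "neutrality_screen",
]

#: raw difference proportion at/above which an estimate is flagged saturated
SATURATION_P = 0.74


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free codon columns for 2 or 3 sequences.

    ``columns[k]`` is a tuple with one codon per sequence; ``column_origin[k]``
    gives, for each sequence, the 0-based codon index of that codon in its
    ungapped source CDS.  ``n_dropped`` counts alignment columns excluded at
    construction (gap, non-ACGT base, or stop codon in any sequence).
    """

    seq_labels: tuple[str, ...]
    columns: tuple[tuple[str, ...], ...]
    column_origin: tuple[tuple[int, ...], ...]
    n_dropped: int = 0

    def __post_init__(self):
        if len(self.seq_labels) not in (2, 3):
            raise ValueError("CodonAlignment holds 2 or 3 sequences")

    @property
    def n_seqs(self) -> int:
        return len(self.seq_labels)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def length_bp(self) -> int:
        """Alignment length in nucleotides (retained columns only)."""
        return 3 * len(self.columns)

    def sequence(self, label: str) -> list[str]:
        i = self.seq_labels.index(label)
        return [col[i] for col in self.columns]

    def indices(self) -> np.ndarray:
        """(n_seqs, n_columns) array of sense-codon indices."""
        return np.array(
            [[CODON_INDEX[col[i]] for col in self.columns] for i in range(self.n_seqs)],
            dtype=np.intp,
        )

    def slice_codons(self, start: int, stop: int) -> "CodonAlignment":
        return CodonAlignment(
            self.seq_labels,
            self.columns[start:stop],
            self.column_origin[start:stop],
            0,
        )

    @classmethod
    def from_ungapped(
        cls, cds_list: Sequence[str], labels: Sequence[str] | None = None
    ) -> "CodonAlignment":
        """Build from equal-length, already-in-register CDS (no gaps)."""
        lengths = {len(c) for c in cds_list}
        if len(lengths) != 1:
            raise ValueError("ungapped CDS must have equal lengths")
        if labels is None:
            labels = [f"seq{i + 1}" for i in range(len(cds_list))]
        codon_rows = [genetics.codons_of(c) for c in cds_list]
        columns, origins = [], []
        dropped = 0
        for k, col in enumerate(zip(*codon_rows)):
            if all(genetics.is_valid_codon(c) and not genetics.is_stop(c) for c in col):
                columns.append(tuple(col))
                origins.append(tuple([k] * len(col)))
            else:
                dropped += 1
        return cls(tuple(labels), tuple(columns), tuple(origins), dropped)


def build_codon_alignment(
    cds_list: Sequence[str],
    protein_alignment: Sequence[str],
    labels: Sequence[str] | None = None,
) -> CodonAlignment:
    """Back-translate a protein alignment onto its source CDS.

    Each aligned amino-acid column is replaced by the corresponding codon of
    each source CDS (the classic protein-guided codon alignment).  Rows of
    ``protein_alignment`` must be the aligned translations of ``cds_list``,
    checked codon by codon; a trailing stop codon on a CDS is tolerated.
    Columns containing a gap, an N-containing codon or an in-frame stop in
    any sequence are dropped and tallied.
    """
    if len(cds_list) != len(protein_alignment):
        raise ValueError("one protein row per CDS required")
    if len(cds_list) not in (2, 3):
        raise ValueError("2 or 3 sequences required")
    if labels is None:
        labels = [f"seq{i + 1}" for i in range(len(cds_list))]
    ncol = {len(r) for r in protein_alignment}
    if len(ncol) != 1:
        raise ValueError("protein alignment rows have unequal lengths")

    per_seq_codons: list[list[str]] = []
    per_seq_origin: list[list[int]] = []
    for row_i, (cds, prot) in enumerate(zip(cds_list, protein_alignment)):
        codons = genetics.codons_of(cds)
        # tolerate one trailing stop codon not represented in the protein row
        if codons and genetics.is_stop(codons[-1]):
            codons = codons[:-1]
        aa_positions = [i for i, aa in enumerate(prot) if aa != "-"]
        if len(aa_positions) != len(codons):
            raise ValueError(
                f"sequence {labels[row_i]!r}: protein row has "
                f"{len(aa_positions)} residues but CDS has {len(codons)} codons"
            )
        aligned_codons = ["-"] * len(prot)
        origin = [-1] * len(prot)
        for codon_i, col_i in enumerate(aa_positions):
            codon = codons[codon_i]
            aa = prot[col_i]
            if genetics.is_valid_codon(codon) and not genetics.is_stop(codon):
                expected = genetics.AMINO_ACID[codon]
                if aa not in (expected, "X"):
                    raise ValueError(
                        f"sequence {labels[row_i]!r}: codon {codon_i} "
                        f"({codon}={expected}) does not match protein "
                        f"residue {aa!r} at alignment column {col_i}"
                    )
            aligned_codons[col_i] = codon
            origin[col_i] = codon_i
        per_seq_codons.append(aligned_codons)
        per_seq_origin.append(origin)

    columns, origins = [], []
    dropped = 0
    for col_i in range(len(protein_alignment[0])):
        col = tuple(row[col_i] for row in per_seq_codons)
        ok = all(
            c != "-" and genetics.is_valid_codon(c) and not genetics.is_stop(c)
            for c in col
        )
        if ok:
            columns.append(col)
            origins.append(tuple(row[col_i] for row in per_seq_origin))
        else:
            dropped += 1
    return CodonAlignment(tuple(labels), tuple(columns), tuple(origins), dropped)


@dataclass(frozen=True)
class DivergenceEstimate:
    """NG86 + Jukes–Cantor summary of one pairwise codon alignment.

    ``ds``/``dn`` are NaN when the corresponding raw proportion reaches the
    Jukes–Cantor domain boundary (p >= 3/4); ``omega`` is NaN unless ds > 0
    and neither rate is saturated.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float
    saturated: bool
    n_columns_used: int
    n_columns_dropped: int


@dataclass(frozen=True)
class FourDTvResult:
    n_fourfold_sites: int
    n_transversions: float
    rate: float  # NaN when no fourfold sites


@dataclass(frozen=True)
class WindowProfile:
    """Sliding-window divergence profile in alignment bp coordinates."""

    windows: tuple[tuple[int, int, DivergenceEstimate], ...]
    truncated: bool = False  # alignment shorter than one full window


@dataclass(frozen=True)
class BranchDivergence:
    """Outgroup-polarized per-branch divergence for a paralog pair."""

    branch_labels: tuple[str, str]
    estimates: tuple[DivergenceEstimate, DivergenceEstimate]
    n_ambiguous: int


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN (the saturation marker) for p >= 3/4, where the corrected
    distance is undefined.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _estimate_from_counts(
    s_sites: float,
    n_sites: float,
    sd: float,
    nd: float,
    n_used: int,
    n_dropped: int,
) -> DivergenceEstimate:
    if n_used < 1:
        raise ValueError("no retained codon columns")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    saturated = ps >= SATURATION_P or pn >= SATURATION_P
    if saturated or math.isnan(ds) or math.isnan(dn) or ds <= 0:
        omega = math.nan
    else:
        omega = dn / ds
    return DivergenceEstimate(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        omega=omega,
        saturated=saturated,
        n_columns_used=n_used,
        n_columns_dropped=n_dropped,
    )


def pairwise_divergence(aln: CodonAlignment) -> DivergenceEstimate:
    """NG86 dS/dN/ω for a 2-sequence codon alignment.

    Site counts are averaged over the two sequences; difference counts are
    pathway-averaged per column; both proportions are Jukes–Cantor corrected.
    """
    if aln.n_seqs != 2:
        raise ValueError("pairwise_divergence requires a 2-sequence alignment")
    if aln.n_columns < 1:
        raise ValueError("alignment has no retained codon columns")
    idx = aln.indices()
    ia, ib = idx[0], idx[1]
    s_sites = 0.5 * (S_SITES[ia].sum() + S_SITES[ib].sum())
    n_sites = 0.5 * (N_SITES[ia].sum() + N_SITES[ib].sum())
    sd = SD_MATRIX[ia, ib].sum()
    nd = ND_MATRIX[ia, ib].sum()
    return _estimate_from_counts(
        s_sites, n_sites, float(sd), float(nd), aln.n_columns, aln.n_dropped
    )


def fourdtv(aln: CodonAlignment) -> FourDTvResult:
    """Transversion rate at fourfold-degenerate third codon positions.

    A column contributes one fourfold site iff the two codons share an
    identical 2-base prefix and that prefix encodes the same amino acid for
    all four third bases; the site counts one transversion when the third
    bases differ purine vs. pyrimidine.  The rate is left uncorrected for
    multiple hits.
    """
    if aln.n_seqs != 2:
        raise ValueError("fourdtv requires a 2-sequence alignment")
    sites = 0
    tv = 0
    for ca, cb in aln.columns:
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites += 1
            if is_transversion(ca[2], cb[2]):
                tv += 1
    rate = tv / sites if sites else math.nan
    return FourDTvResult(n_fourfold_sites=sites, n_transversions=float(tv), rate=rate)


def sliding_window_dnds(
    aln: CodonAlignment, window_bp: int = 150, step_bp: int = 30
) -> WindowProfile:
    """Windowed NG86 estimates over alignment coordinates from the start codon.

    Windows are [0, window), [step, window+step), ... in nucleotides of the
    retained alignment; the last window ends at or before the alignment end.
    An alignment shorter than one window yields a single truncated window.
    """
    if window_bp % 3 or step_bp % 3:
        raise ValueError("window_bp and step_bp must be multiples of 3")
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    length = aln.length_bp
    if length == 0:
        raise ValueError("alignment has no retained codon columns")
    if length < window_bp:
        est = pairwise_divergence(aln)
        return WindowProfile(windows=((0, length, est),), truncated=True)
    windows = []
    for start in range(0, length - window_bp + 1, step_bp):
        sub = aln.slice_codons(start // 3, (start + window_bp) // 3)
        windows.append((start, start + window_bp, pairwise_divergence(sub)))
    return WindowProfile(windows=tuple(windows), truncated=False)


def _branch_counts(aln: CodonAlignment, outgroup_label: str):
    """Per-branch pathway-averaged counts under the 3-taxon parsimony rule."""
    if aln.n_seqs != 3:
        raise ValueError("branch analysis requires a 3-sequence alignment")
    if outgroup_label not in aln.seq_labels:
        raise ValueError(f"outgroup label {outgroup_label!r} not in alignment")
    out_i = aln.seq_labels.index(outgroup_label)
    in_i = [i for i in range(3) if i != out_i]
    labels = tuple(aln.seq_labels[i] for i in in_i)
    sd = [0.0, 0.0]
    nd = [0.0, 0.0]
    ambiguous = 0
    for col in aln.columns:
        o = col[out_i]
        p = [col[in_i[0]], col[in_i[1]]]
        if p[0] == p[1]:
            continue
        if p[1] == o:  # change on ingroup-1's branch, ancestor state = o
            s, n = genetics.codon_pair_differences(o, p[0])
            sd[0] += s
            nd[0] += n
        elif p[0] == o:
            s, n = genetics.codon_pair_differences(o, p[1])
            sd[1] += s
            nd[1] += n
        else:
            ambiguous += 1
    return labels, in_i, sd, nd, ambiguous


def branch_divergence(aln: CodonAlignment, outgroup_label: str) -> BranchDivergence:
    """Assign substitutions to each paralog branch using the outgroup.

    A column with exactly one ingroup sequence differing while the other
    ingroup sequence matches the outgroup places the change (pathway-averaged
    if multi-base) on the differing sequence's branch.  Columns where all
    three codons differ, or where the outgroup matches neither ingroup state,
    are skipped and tallied as parsimony-ambiguous.  Each branch's rates use
    that sequence's own site counts over all retained columns.
    """
    labels, in_i, sd, nd, ambiguous = _branch_counts(aln, outgroup_label)
    idx = aln.indices()
    ests = []
    for k in range(2):
        rows = idx[in_i[k]]
        s_sites = float(S_SITES[rows].sum())
        n_sites = float(N_SITES[rows].sum())
        ests.append(
            _estimate_from_counts(
                s_sites, n_sites, sd[k], nd[k], aln.n_columns, aln.n_dropped
            )
        )
    return BranchDivergence(
        branch_labels=labels, estimates=(ests[0], ests[1]), n_ambiguous=ambiguous
    )


def sliding_window_branch(
    aln: CodonAlignment,
    outgroup_label: str,
    window_bp: int = 150,
    step_bp: int = 30,
) -> dict[str, WindowProfile]:
    """Per-branch sliding-window profiles (same windowing as pairwise)."""
    if window_bp % 3 or step_bp % 3:
        raise ValueError("window_bp and step_bp must be multiples of 3")
    length = aln.length_bp
    if length == 0:
        raise ValueError("alignment has no retained codon columns")
    starts = (
        [0]
        if length < window_bp
        else list(range(0, length - window_bp + 1, step_bp))
    )
    truncated = length < window_bp
    per_branch: dict[str, list] = {}
    for start in starts:
        end = min(start + window_bp, length)
        sub = aln.slice_codons(start // 3, end // 3)
        bd = branch_divergence(sub, outgroup_label)
        for label, est in zip(bd.branch_labels, bd.estimates):
            per_branch.setdefault(label, []).append((start, end, est))
    return {
        label: WindowProfile(windows=tuple(rows), truncated=truncated)
        for label, rows in per_branch.items()
    }


def neutrality_screen(est: DivergenceEstimate) -> float:
    """Exact binomial test of the hypothesis ω = 1 on substitution counts.

    Under neutrality the expected fraction of differences that are
    nonsynonymous equals the nonsynonymous site fraction N/(N+S).  The
    observed nd out of round(sd+nd) differences is tested two-sided against
    that null proportion using the small-p-summation (minimum-likelihood)
    definition.  Returns NaN when the alignment carries no differences.
    """
    total = est.sd + est.nd
    if total < 0.5:
        return math.nan
    n = int(round(total))
    k = min(int(round(est.nd)), n)
    p0 = est.n_sites / (est.n_sites + est.s_sites)
    return binomtest(k, n, p0, alternative="two-sided").pvalue
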