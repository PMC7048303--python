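"""Build the filtered paralog-pair catalog.

Genes annotated as transposable elements and "repetitive" genes with more
than five distinct within-genome homologs at the similarity threshold are
discarded; the surviving similarity hits become gene pairs, grouped into
families by single-linkage connected components of the hit graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .codon_evolution import DivergenceEstimate, FourDTvResult
from .io_formats import GeneRecord, SimilarityHit

__all__ = ["GenePair", "filter_genes", "make_pairs", "pairs_to_frame"]

#: a gene with more than this many distinct homologs is treated as repetitive
REPETITIVE_HOMOLOG_CUTOFF = 5


@dataclass
class GenePair:
    """Two retained genes joined by a significant similarity hit.

    ``gene_a`` < ``gene_b`` lexicographically; ``family_id`` indexes the
    single-linkage family both genes belong to.  Divergence annotations are
    attached downstream.
    """

    gene_a: str
    gene_b: str
    family_id: int
    divergence: DivergenceEstimate | None = None
    fourdtv: FourDTvResult | None = None
    wgd_flag: bool = False

    def __post_init__(self):
        if not self.gene_a < self.gene_b:
            raise ValueError("gene_a must sort before gene_b")

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}--{self.gene_b}"


def _homolog_counts(hits: Iterable[SimilarityHit]) -> dict[str, set[str]]:
    homologs: dict[str, set[str]] = {}
    for h in hits:
        homologs.setdefault(h.query_id, set()).add(h.subject_id)
        homologs.setdefault(h.subject_id, set()).add(h.query_id)
    return homologs


def filter_genes(
    genes: Sequence[GeneRecord],
    hits: Sequence[SimilarityHit],
    homolog_cutoff: int = REPETITIVE_HOMOLOG_CUTOFF,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the TE and repetitive-gene exclusions.

    ``hits`` must already be thresholded (self-hits removed, evalue
    filtered).  A gene is excluded when its ``is_te`` flag is set, or when it
    has strictly more than ``homolog_cutoff`` distinct non-self homologs.
    Returns the retained gene-id set and an exclusion report with one row per
    removed gene (columns: gene_id, reason, n_homologs).
    """
    homologs = _homolog_counts(hits)
    retained: set[str] = set()
    rows = []
    for g in genes:
        n_hom = len(homologs.get(g.gene_id, ()))
        if g.is_te:
            rows.append({"gene_id": g.gene_id, "reason": "TE", "n_homologs": n_hom})
        elif n_hom > homolog_cutoff:
            rows.append(
                {"gene_id": g.gene_id, "reason": "repetitive", "n_homologs": n_hom}
            )
        else:
            retained.add(g.gene_id)
    report = pd.DataFrame(rows, columns=["gene_id", "reason", "n_homologs"])
    return retained, report


def make_pairs(
    retained: set[str], hits: Sequence[SimilarityHit]
) -> list[GenePair]:
    """Turn surviving hits into GenePairs with single-linkage family ids.

    One pair per hit whose both genes were retained; families are the
    connected components of the retained-hit graph, numbered in order of
    their lexicographically smallest member; pairs are sorted (family,
    gene_a, gene_b).  The output is invariant to input row order.
    """
    kept = sorted(
        {
            tuple(sorted((h.query_id, h.subject_id)))
            for h in hits
            if h.query_id in retained and h.subject_id in retained
        }
    )
    graph = nx.Graph(kept)
    components = sorted(nx.connected_components(graph), key=min)
    family_of: dict[str, int] = {}
    for fam_id, comp in enumerate(components):
        for gene in comp:
            family_of[gene] = fam_id
    pairs = [GenePair(a, b, family_of[a]) for a, b in kept]
    pairs.sort(key=lambda p: (p.family_id, p.gene_a, p.gene_b))
    return pairs


def pairs_to_frame(pairs: Sequence[GenePair]) -> pd.DataFrame:
    """Flatten a pair catalog (with any annotations) to a DataFrame."""
    rows = []
    for p in pairs:
        row = {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "family_id": p.family_id,
            "wgd_flag": p.wgd_flag,
        }
        if p.divergence is not None:
            d = p.divergence
            row.update(
                S=d.s_sites, N=d.n_sites, sd=d.sd, nd=d.nd, ds=d.ds, dn=d.dn,
                omega=d.omega, saturated=d.saturated,
                columns_used=d.n_columns_used, columns_dropped=d.n_columns_dropped,
            )
        if p.fourdtv is not None:
            row.update(
                fourfold_sites=p.fourdtv.n_fourfold_sites,
                fourdtv=p.fourdtv.rate,
            )
        rows.append(row)
    return pd.DataFrame(rows)
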