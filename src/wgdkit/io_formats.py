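"""Readers and writers for every external format the pipeline touches.

Conventions enforced here, once, so the analysis modules never see them:

* all internal coordinates are 0-based half-open; BED output is 0-based
  half-open; depth input is accepted 1-based (samtools-depth dialect);
* CDS are uppercased, U mapped to T, ambiguity codes other than N mapped
  to N; a CDS whose length is not a multiple of 3 is trimmed at the 3' end
  to the nearest codon with a logged warning;
* similarity hits are the 12-column BLAST outfmt-6 tab dialect;
* expression matrices are TSV with a 2-row header carrying per-sample sex
  and stage labels;
* all writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENTARY_CLEANUP = str.maketrans(
    {c: "N" for c in "RYSWKMBDHV"} | {"U": "T"}
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


# ---------------------------------------------------------------------------
# gene records / FASTA


@dataclass
class GeneRecord:
    """One CDS with optional genomic coordinates and a TE annotation flag."""

    gene_id: str
    cds: str
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    is_te: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            self.end = self.start + max(len(self.cds), 1)


def _normalize_cds(gene_id: str, seq: str) -> str:
    seq = seq.upper().translate(_COMPLEMENTARY_CLEANUP)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParseError(f"{gene_id}: unexpected characters {sorted(bad)} in sequence")
    if len(seq) % 3:
        trimmed = len(seq) % 3
        logger.warning(
            "%s: CDS length %d not a multiple of 3; trimming %d base(s) at 3' end",
            gene_id,
            len(seq),
            trimmed,
        )
        seq = seq[: len(seq) - trimmed]
    return seq


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read CDS FASTA into GeneRecords, preserving input order.

    Sequences are uppercased, U->T, non-N ambiguity codes -> N, and frames
    trimmed to whole codons (with a warning).  Malformed headers or empty
    sequences raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has an empty sequence")
        records.append(GeneRecord(gene_id=header, cds=_normalize_cds(header, seq)))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.cds), width):
                fh.write(rec.cds[i : i + width] + "\n")


def read_gene_coords(path: str | Path, records: Sequence[GeneRecord] | None = None):
    """Read a minimal gene coordinate TSV and optionally annotate records.

    Columns: gene_id, contig, start (0-based), end, strand, is_te (0/1).
    Returns a DataFrame; when ``records`` is given, matching records are
    updated in place and the (same) list returned instead.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["gene_id", "contig", "start", "end", "strand", "is_te"],
        header=None,
        comment="#",
        dtype={"gene_id": str, "contig": str},
    )
    if records is None:
        return df
    by_id = {r["gene_id"]: r for r in df.to_dict("records")}
    for rec in records:
        row = by_id.get(rec.gene_id)
        if row is not None:
            rec.contig = row["contig"]
            rec.start = int(row["start"])
            rec.end = int(row["end"])
            rec.strand = str(row["strand"])
            rec.is_te = bool(int(row["is_te"]))
    return records


# ---------------------------------------------------------------------------
# similarity hits (BLAST outfmt-6 dialect)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


_OUTFMT6_COLS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path, max_evalue: float = 1e-20) -> list[SimilarityHit]:
    """Read a 12-column tabular hit file, filter and deduplicate.

    Self-hits and hits with evalue > ``max_evalue`` are removed; reciprocal
    duplicates (a,b)/(b,a) are collapsed keeping the best (max) bitscore,
    reported with the lexicographically smaller id first.
    """
    if max_evalue < 0:
        raise ValueError("max_evalue must be non-negative")
    try:
        df = pd.read_csv(path, sep="\t", names=_OUTFMT6_COLS, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: not a 12-column tab-separated hit table: {exc}")
    for col in ("evalue", "bitscore"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ParseError(f"{path}:{bad}: non-numeric {col} column")
        df[col] = vals
    if (df["evalue"] < 0).any():
        raise ParseError(f"{path}: negative evalue")
    df = df[df["query_id"].astype(str) != df["subject_id"].astype(str)]
    df = df[df["evalue"] <= max_evalue]
    best: dict[tuple[str, str], SimilarityHit] = {}
    for row in df.itertuples(index=False):
        a, b = sorted((str(row.query_id), str(row.subject_id)))
        key = (a, b)
        hit = SimilarityHit(a, b, float(row.evalue), float(row.bitscore))
        prev = best.get(key)
        if prev is None or hit.bitscore > prev.bitscore:
            best[key] = hit
    return [best[k] for k in sorted(best)]


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the same 12-column dialect (unused columns zeroed)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# depth tracks


@dataclass
class DepthTrack:
    """Per-position male and female pooled read depth on one contig."""

    contig: str
    male_depth: np.ndarray  # int, 0-based positions
    female_depth: np.ndarray

    def __post_init__(self):
        self.male_depth = np.asarray(self.male_depth, dtype=np.int64)
        self.female_depth = np.asarray(self.female_depth, dtype=np.int64)
        if self.male_depth.shape != self.female_depth.shape:
            raise ValueError("male and female depth arrays differ in length")
        if (self.male_depth < 0).any() or (self.female_depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return len(self.male_depth)


def read_depth(path: str | Path) -> dict[str, DepthTrack]:
    """Read a 4-column samtools-depth-like TSV into per-contig tracks.

    Input positions are 1-based; internally 0-based.  Positions missing from
    the file are filled with depth 0 up to the maximum reported position.
    """
    df = pd.read_csv(
        path, sep="\t", names=["contig", "pos", "male", "female"], header=None,
        comment="#", dtype={"contig": str},
    )
    for col in ("pos", "male", "female"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ParseError(f"{path}:{bad}: non-numeric {col} column")
        df[col] = vals.astype(np.int64)
    if (df[["male", "female"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative depth value")
    if (df["pos"] < 1).any():
        raise ParseError(f"{path}: positions are 1-based and must be >= 1")
    tracks: dict[str, DepthTrack] = {}
    for contig, grp in df.groupby("contig", sort=False):
        n = int(grp["pos"].max())
        male = np.zeros(n, dtype=np.int64)
        female = np.zeros(n, dtype=np.int64)
        idx = grp["pos"].to_numpy() - 1
        male[idx] = grp["male"].to_numpy()
        female[idx] = grp["female"].to_numpy()
        tracks[str(contig)] = DepthTrack(str(contig), male, female)
    return tracks


def write_depth(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write tracks back to the 1-based 4-column TSV (all positions)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tr in tracks:
            for i in range(tr.length):
                fh.write(
                    f"{tr.contig}\t{i + 1}\t{tr.male_depth[i]}\t{tr.female_depth[i]}\n"
                )


# ---------------------------------------------------------------------------
# region calls / BED


@dataclass(frozen=True)
class RegionCall:
    """Classified half-open interval on a contig with depth support."""

    contig: str
    start: int
    end: int
    call: str  # male-specific | PAR-like | repetitive | undetermined
    mean_male_depth: float = 0.0
    mean_female_depth: float = 0.0
    female_read_fraction: float = float("nan")

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("region must span at least 1 bp")


def merge_calls(calls: Sequence[RegionCall]) -> list[RegionCall]:
    """Merge overlapping or adjacent calls of the same class on a contig.

    Depth statistics of a merged call are length-weighted means.
    """
    out: list[RegionCall] = []
    keyed = sorted(calls, key=lambda c: (c.contig, c.call, c.start, c.end))
    for c in keyed:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.contig == c.contig
            and prev.call == c.call
            and c.start <= prev.end
        ):
            w1, w2 = prev.end - prev.start, c.end - c.start
            end = max(prev.end, c.end)
            frac = np.nansum(
                [prev.female_read_fraction * w1, c.female_read_fraction * w2]
            ) / (w1 + w2)
            out[-1] = RegionCall(
                prev.contig,
                prev.start,
                end,
                prev.call,
                (prev.mean_male_depth * w1 + c.mean_male_depth * w2) / (w1 + w2),
                (prev.mean_female_depth * w1 + c.mean_female_depth * w2) / (w1 + w2),
                float(frac),
            )
        else:
            out.append(c)
    return sorted(out, key=lambda c: (c.contig, c.start, c.end))


def write_bed(calls: Sequence[RegionCall], path: str | Path) -> None:
    """Write region calls as BED: contig, start, end, class, score.

    The score column is the female read fraction scaled to 0-1000 and
    rounded.  Overlapping calls of the same class are merged before writing.
    """
    merged = merge_calls(calls)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in merged:
            frac = c.female_read_fraction
            score = 0 if not np.isfinite(frac) else int(round(frac * 1000))
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.call}\t{score}\n")


def read_bed(path: str | Path) -> list[RegionCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, score = line.rstrip("\n").split("\t")
            calls.append(
                RegionCall(
                    contig,
                    int(start),
                    int(end),
                    name,
                    female_read_fraction=int(score) / 1000,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample sex and stage.

    ``values`` is a DataFrame indexed by gene_id with one column per sample;
    ``sex`` and ``stage`` are Series indexed by the sample ids.  ``unit``
    tags the values as raw ``counts`` or normalized ``rpkm``.
    """

    values: pd.DataFrame
    sex: pd.Series
    stage: pd.Series
    unit: str = "counts"

    def __post_init__(self):
        samples = list(self.values.columns)
        if list(self.sex.index) != samples or list(self.stage.index) != samples:
            raise ValueError("sex/stage metadata must cover exactly the sample columns")
        if not set(self.sex.unique()) <= {"M", "F"}:
            raise ValueError("sex labels must be M or F")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, sex: str | None = None, stages: set | None = None) -> list[str]:
        keep = pd.Series(True, index=self.values.columns)
        if sex is not None:
            keep &= self.sex == sex
        if stages is not None:
            keep &= self.stage.isin(list(stages))
        return list(keep.index[keep])


def read_expression(path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read a gene x sample TSV with a 2-row header (sex, stage).

    Row 1: ``sex`` then one of M/F per sample column; row 2: ``stage`` then a
    free-form stage label per column; remaining rows: gene_id then values.
    Sample ids are ``{stage}_{sex}``, suffixed for uniqueness when repeated.
    """
    with open(path, encoding="utf-8") as fh:
        sex_row = fh.readline().rstrip("\n").split("\t")
        stage_row = fh.readline().rstrip("\n").split("\t")
        if sex_row[0] != "sex" or stage_row[0] != "stage":
            raise ParseError(f"{path}: expected 'sex' and 'stage' header rows")
        sexes = sex_row[1:]
        stages = stage_row[1:]
        if len(sexes) != len(stages):
            raise ParseError(f"{path}: sex and stage header rows differ in length")
        samples: list[str] = []
        seen: dict[str, int] = {}
        for sx, st in zip(sexes, stages):
            base = f"{st}_{sx}"
            seen[base] = seen.get(base, 0) + 1
            samples.append(base if seen[base] == 1 else f"{base}.{seen[base]}")
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        df.columns = samples
        df.index.name = "gene_id"
    return ExpressionMatrix(
        values=df.astype(float),
        sex=pd.Series(sexes, index=samples),
        stage=pd.Series(stages, index=samples),
        unit=unit,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sex\t" + "\t".join(matrix.sex) + "\n")
        fh.write("stage\t" + "\t".join(matrix.stage) + "\n")
        for gene_id, row in matrix.values.iterrows():
            vals = "\t".join(f"{v:g}" for v in row.to_numpy())
            fh.write(f"{gene_id}\t{vals}\n")
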