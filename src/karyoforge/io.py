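"""Readers and writers for gene models, homology tables, TE intervals, blocks and paintings.

Coordinate conventions
----------------------
Input files follow their own standards (GFF3 is 1-based closed, BED is 0-based
half-open).  Internally everything is stored 0-based half-open in bp, and all
synteny work happens in *gene rank* space: within each chromosome genes are
sorted by start coordinate and numbered 0..n-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "rank"]

TE_CLASSES = ("Copia", "Gypsy", "LINE1", "Other")


class FormatError(ValueError):
    """A file violated its declared on-disk format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open bp span plus its order index on the chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class HomologyPair:
    """One retained query/subject hit from a protein similarity search."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class TEInterval:
    """A transposable-element annotation, class-normalised to Copia/Gypsy/LINE1/Other."""

    chromosome: str
    start: int
    end: int
    te_class: str


class GeneTable:
    """Ordered gene models of one genome, the coordinate system for all synteny work.

    Parameters
    ----------
    species_id : str
    frame : DataFrame with columns gene_id, chromosome, start, end, strand.
        Ranks are (re)assigned here by sorting on (chromosome, start, gene_id).
    chrom_lengths : optional mapping chromosome -> bp length.  Defaults to the
        max gene end per chromosome.
    """

    def __init__(self, species_id: str, frame: pd.DataFrame, chrom_lengths: dict | None = None):
        df = frame.copy()
        for col in ("gene_id", "chromosome", "start", "end", "strand"):
            if col not in df.columns:
                raise ValueError(f"gene frame missing column {col!r}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r} in {species_id}")
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise FormatError(f"gene {bad!r}: start >= end")
        df = df.sort_values(["chromosome", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
        df["rank"] = df.groupby("chromosome", sort=False).cumcount()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.species_id = species_id
        self.frame = df[GENE_COLUMNS]
        self._by_chrom = {c: g.reset_index(drop=True) for c, g in self.frame.groupby("chromosome", sort=True)}
        self._rank_of = dict(zip(df["gene_id"], df["rank"]))
        self._chrom_of = dict(zip(df["gene_id"], df["chromosome"]))
        if chrom_lengths is None:
            chrom_lengths = {c: int(g["end"].max()) for c, g in self._by_chrom.items()}
        self.chrom_lengths = dict(chrom_lengths)
        self.excluded_count = 0  # set by read_genes when a chromosome_list drops records

    # -- basic accessors ----------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    def genes_on(self, chromosome: str) -> pd.DataFrame:
        """Genes of one chromosome, ordered by rank."""
        return self._by_chrom[chromosome]

    def chrom_size(self, chromosome: str) -> int:
        return len(self._by_chrom[chromosome])

    def rank_of(self, gene_id: str) -> int:
        return self._rank_of[gene_id]

    def chrom_of(self, gene_id: str) -> str:
        return self._chrom_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank_of

    def gene_at(self, chromosome: str, rank: int) -> pd.Series:
        return self._by_chrom[chromosome].iloc[rank]

    def bp_span(self, chromosome: str, rank_lo: int, rank_hi: int) -> tuple[int, int]:
        """bp interval [start of first gene, end of last gene) for an inclusive rank range."""
        g = self._by_chrom[chromosome]
        return int(g["start"].iloc[rank_lo]), int(g["end"].iloc[rank_hi])

    def __eq__(self, other):
        return (
            isinstance(other, GeneTable)
            and self.species_id == other.species_id
            and self.frame.equals(other.frame)
        )

    def __repr__(self):
        return f"GeneTable({self.species_id}: {self.n_genes} genes on {len(self._by_chrom)} chromosomes)"


# ---------------------------------------------------------------------------
# gene model readers / writers
# ---------------------------------------------------------------------------


def _parse_gff3_genes(path, feature_type: str):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise FormatError(f"{path}: malformed GFF3 record at line {lineno}: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get("ID") or feat.attributes.get("Name")
            if not ids:
                raise FormatError(f"{path}: gene feature without ID at line {lineno}")
            # GFF3 1-based closed -> 0-based half-open
            records.append((ids[0], feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "+"))
    return records


def _parse_bed_genes(path):
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed BED record at line {lineno}: need >=4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed BED record at line {lineno}: {exc}") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            records.append((parts[3], parts[0], start, end, strand))
    return records


def read_genes(
    path,
    format: str = "gff3",
    chromosome_list: set | None = None,
    species_id: str = "genome",
    feature_type: str = "gene",
) -> GeneTable:
    """Read gene models, keep chromosome-scale sequences only, assign ranks.

    Genes on sequences absent from ``chromosome_list`` (scaffolds, typically) are
    dropped; the dropped count is logged and stored on the returned table as
    ``excluded_count``.
    """
    if format == "gff3":
        records = _parse_gff3_genes(path, feature_type)
    elif format == "bed":
        records = _parse_bed_genes(path)
    else:
        raise ValueError(f"unknown gene format {format!r}")
    excluded = 0
    if chromosome_list is not None:
        kept = [r for r in records if r[1] in chromosome_list]
        excluded = len(records) - len(kept)
        if excluded:
            logger.info("%s: excluded %d genes on sequences outside the chromosome list", path, excluded)
        records = kept
    if not records:
        warnings.warn(f"{path}: no gene records retained; empty gene table", stacklevel=2)
    frame = pd.DataFrame(records, columns=["gene_id", "chromosome", "start", "end", "strand"])
    table = GeneTable(species_id, frame)
    table.excluded_count = excluded
    return table


def write_genes(table: GeneTable, path, format: str = "gff3") -> None:
    """Write a GeneTable back out (GFF3 gene features or BED6)."""
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for row in table.frame.itertuples():
                fh.write(
                    f"{row.chromosome}\tkaryoforge\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )
        elif format == "bed":
            for row in table.frame.itertuples():
                fh.write(f"{row.chromosome}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n")
        else:
            raise ValueError(f"unknown gene format {format!r}")


# ---------------------------------------------------------------------------
# homology tables
# ---------------------------------------------------------------------------


def filter_homology(frame: pd.DataFrame, evalue_max: float = 1e-5, top_k: int = 5) -> list[HomologyPair]:
    """Apply the E-value cutoff and a per-query best-hit cap to an in-memory table.

    ``frame`` needs columns query_id, subject_id, evalue, bitscore.  Exact
    (query, subject) duplicates collapse to the best-scoring line.  Per query only
    the ``top_k`` hits by bitscore survive; ties at the boundary are all kept.
    """
    df = frame[["query_id", "subject_id", "evalue", "bitscore"]].copy()
    df["evalue"] = pd.to_numeric(df["evalue"], errors="raise")
    df["bitscore"] = pd.to_numeric(df["bitscore"], errors="raise")
    df = df[df["evalue"] <= evalue_max]
    df = (
        df.sort_values(["query_id", "bitscore", "evalue"], ascending=[True, False, True], kind="mergesort")
        .drop_duplicates(["query_id", "subject_id"], keep="first")
    )
    if top_k is not None and len(df):
        # keep everything tied with the k-th best bitscore per query
        df = df.sort_values(["query_id", "bitscore"], ascending=[True, False], kind="mergesort")
        nth = df.groupby("query_id", sort=False).cumcount()
        kth = df.loc[nth == top_k - 1, ["query_id", "bitscore"]].set_index("query_id")["bitscore"]
        thr = df["query_id"].map(kth)
        df = df[thr.isna() | (df["bitscore"] >= thr)]
    df = df.sort_values(["query_id", "subject_id"], kind="mergesort")
    return [
        HomologyPair(r.query_id, r.subject_id, float(r.evalue), float(r.bitscore))
        for r in df.itertuples()
    ]


def read_homology(path, evalue_max: float = 1e-5, top_k: int = 5) -> list[HomologyPair]:
    """Read an aligner tabular file (outfmt-6 style, >=12 columns) and filter it."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty homology table", stacklevel=2)
        return []
    if df.shape[1] < 12:
        raise FormatError(f"{path}: expected >=12 tab-separated columns, found {df.shape[1]}")
    sub = df.iloc[:, [0, 1, 10, 11]].copy()
    sub.columns = ["query_id", "subject_id", "evalue", "bitscore"]
    try:
        sub["evalue"] = pd.to_numeric(sub["evalue"], errors="raise")
        sub["bitscore"] = pd.to_numeric(sub["bitscore"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric evalue/bitscore column: {exc}") from exc
    return filter_homology(sub, evalue_max=evalue_max, top_k=top_k)


# ---------------------------------------------------------------------------
# TE intervals
# ---------------------------------------------------------------------------


def normalize_te_class(label: str) -> str:
    """Map an annotation label onto the four canonical classes."""
    s = label.lower()
    if "copia" in s:
        return "Copia"
    if "gypsy" in s:
        return "Gypsy"
    if "l1" in s or "line" in s:
        return "LINE1"
    return "Other"


def read_te_intervals(path, format: str = "bed") -> list[TEInterval]:
    """Read TE annotations (BED with the class in the name column, or GFF3 with a
    class attribute / feature type) and normalise class labels."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "bed":
                if len(parts) < 4:
                    raise FormatError(f"{path}: malformed BED record at line {lineno}")
                chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            elif format == "gff3":
                if len(parts) < 9:
                    raise FormatError(f"{path}: malformed GFF3 record at line {lineno}")
                chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                label = attrs.get("class") or attrs.get("Classification") or parts[2]
            else:
                raise ValueError(f"unknown TE format {format!r}")
            if start >= end:
                warnings.warn(f"{path}:{lineno}: TE interval with start >= end rejected", stacklevel=2)
                continue
            out.append(TEInterval(chrom, start, end, normalize_te_class(label)))
    return out


def write_te_intervals(intervals, path) -> None:
    with open(path, "w") as fh:
        for te in intervals:
            fh.write(f"{te.chromosome}\t{te.start}\t{te.end}\t{te.te_class}\n")


# ---------------------------------------------------------------------------
# block and painting files (bespoke tab-separated formats)
# ---------------------------------------------------------------------------

BLOCK_MAGIC = "# karyoforge blocks v1"


def write_blocks(blocks, path) -> None:
    """One header line per block, then one anchor pair per line.

    Format::

        # karyoforge blocks v1
        >block_id  species_a  species_b  chrom_a  chrom_b  orientation  n_pairs
        rank_a  rank_b  gene_a  gene_b
    """
    with open(path, "w") as fh:
        fh.write(BLOCK_MAGIC + "\n")
        for b in blocks:
            fh.write(
                f">{b.block_id}\t{b.species_a}\t{b.species_b}\t{b.chrom_a}\t{b.chrom_b}\t"
                f"{b.orientation}\t{b.n_pairs}\n"
            )
            for a in b.anchors:
                fh.write(f"{a.rank_a}\t{a.rank_b}\t{a.gene_a}\t{a.gene_b}\n")


def read_blocks(path):
    """Inverse of :func:`write_blocks`; hard error on header/anchor count mismatch."""
    from .synteny import Anchor, SyntenyBlock  # local import to avoid a cycle

    blocks = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != BLOCK_MAGIC:
            raise FormatError(f"{path}: not a karyoforge block file")
        header = None
        anchors = []

        def finish():
            if header is None:
                return
            bid, sa, sb, ca, cb, orient, npairs = header
            if len(anchors) != int(npairs):
                raise FormatError(
                    f"{path}: block {bid!r} declares {npairs} anchors but has {len(anchors)}"
                )
            blocks.append(
                SyntenyBlock(
                    block_id=bid, species_a=sa, species_b=sb, chrom_a=ca, chrom_b=cb,
                    orientation=orient, anchors=list(anchors),
                )
            )

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                finish()
                parts = line[1:].split("\t")
                if len(parts) != 7:
                    raise FormatError(f"{path}: malformed block header {line!r}")
                header = parts
                anchors = []
            else:
                parts = line.split("\t")
                if len(parts) != 4 or header is None:
                    raise FormatError(f"{path}: malformed anchor line {line!r}")
                ra, rb, ga, gb = parts
                anchors.append(
                    Anchor(rank_a=int(ra), rank_b=int(rb), chrom_a=header[3], chrom_b=header[4],
                           gene_a=ga, gene_b=gb)
                )
        finish()
    return blocks


def write_painting(painting, path) -> None:
    """One line per painted segment: species, chromosome, start rank, end rank
    (inclusive), proto id ("NA" for unpainted gaps), supporting gene count."""
    with open(path, "w") as fh:
        fh.write("#species\tchromosome\tstart_rank\tend_rank\tproto_id\tn_support\n")
        for seg in painting.segments:
            fh.write(
                f"{painting.species_id}\t{seg.chromosome}\t{seg.start_rank}\t{seg.end_rank}\t"
                f"{seg.proto_id if seg.proto_id is not None else 'NA'}\t{seg.n_support}\n"
            )


def read_painting(path):
    from .ancestor import Painting, PaintingSegment

    segs = []
    species = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sp, chrom, lo, hi, proto, nsup = line.rstrip("\n").split("\t")
            species = sp
            segs.append(
                PaintingSegment(chrom, int(lo), int(hi), None if proto == "NA" else proto, int(nsup))
            )
    return Painting.from_segments(species or "NA", segs)


# ---------------------------------------------------------------------------
# misc small tables / config
# ---------------------------------------------------------------------------


def read_centromeres(path) -> dict:
    """Tab-separated ``chromosome<TAB>centromere_rank`` table -> dict."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, rank = line.split()[:2]
            out[chrom] = int(rank)
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
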