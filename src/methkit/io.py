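"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* **Cytosine report** — the per-cytosine tab-separated dialect emitted by
  bisulfite aligners (one row per strand-specific cytosine):
  ``chrom  pos  strand  count_methylated  count_unmethylated  context  trinucleotide``
  with 1-based positions and context in {CpG, CHG, CHH}. Bismark CX reports
  write the CpG context as ``CG``; both spellings are accepted
  (case-insensitively) and normalised to ``CpG``.
* **FASTA** — reference sequences, wrapped at 60 columns on output, read
  through :mod:`pyfaidx`.
* **GFF3** — gene models with ``gene`` and ``exon`` features, parsed through
  :mod:`gffutils` and validated into :class:`GeneModel` records.
* **Sample sheet** — TSV mapping ``sample_id`` to genotype, condition,
  tissue-culture/drought stage, and the path of its cytosine report.
* **Generic tables** — TSV with a header, stable column order and fixed
  float precision, used for all derived outputs.

Coordinate convention: external formats are 1-based inclusive (cytosine
report positions, GFF3 intervals); *internal* interval arithmetic is 0-based
half-open. The conversion happens here, at the I/O boundary, and nowhere
else. Site positions keep their external 1-based value throughout because
they are point coordinates, not intervals.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, NamedTuple, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "CytosineSite",
    "GeneModel",
    "SampleSheet",
    "MethkitError",
    "ParseError",
    "ValidationError",
    "read_cytosine_report",
    "iter_cytosine_report",
    "write_cytosine_report",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_sample_sheet",
    "write_table",
    "read_table",
]

#: canonical context labels, in the order they are reported
CONTEXTS = ("CpG", "CHG", "CHH")

_CONTEXT_ALIASES = {
    "cpg": "CpG",
    "cg": "CpG",
    "chg": "CHG",
    "chh": "CHH",
}

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


class MethkitError(Exception):
    """Base class for errors raised by methkit."""


class ParseError(MethkitError):
    """A malformed row or token in an input file."""


class ValidationError(MethkitError):
    """Structurally valid input that violates a model invariant."""


class CytosineSite(NamedTuple):
    """One strand-specific cytosine with its read counts.

    ``pos`` is the 1-based genomic position of the cytosine; ``tri`` is the
    trinucleotide starting at the cytosine *on the site's own strand*, so
    ``tri[0]`` is always ``C`` (or ``N`` at contig edges).
    """

    chrom: str
    pos: int
    strand: str
    meth: int
    unmeth: int
    context: str
    tri: str

    @property
    def depth(self) -> int:
        return self.meth + self.unmeth

    @property
    def level(self) -> float:
        """Methylation level in [0, 1]; undefined (ValueError) at depth 0."""
        d = self.depth
        if d == 0:
            raise ValueError("methylation level undefined at zero depth")
        return self.meth / d


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its ordered exon intervals.

    Intervals are stored 0-based half-open (``start``, ``end``). Exons are
    sorted ascending and non-overlapping; introns are the gaps between
    consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at [{s}, {e})"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (0-based half-open); may be empty."""
        gaps = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        return tuple(gaps)


@dataclass
class SampleSheet:
    """Sample metadata: one row per sample with its factor levels and report path."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "genotype", "condition", "stage", "report_path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate sample_ids: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def rows(self) -> Iterator[pd.Series]:
        for _, row in self.frame.iterrows():
            yield row


def _open_text(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently (by suffix)."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def normalize_context(token: str) -> str:
    try:
        return _CONTEXT_ALIASES[token.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown methylation context token: {token!r}") from None


def _parse_report_row(line: str, lineno: int) -> CytosineSite:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 7:
        raise ParseError(f"line {lineno}: expected >=7 tab-separated columns, got {len(parts)}")
    chrom, pos_s, strand, meth_s, unmeth_s, ctx, tri = parts[:7]
    strand = strand.replace("−", "-")  # tolerate unicode minus
    if strand not in ("+", "-"):
        raise ParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
    try:
        pos = int(pos_s)
        meth = int(meth_s.replace("−", "-"))
        unmeth = int(unmeth_s.replace("−", "-"))
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer position or count") from None
    if pos < 1:
        raise ParseError(f"line {lineno}: position must be >=1, got {pos}")
    if meth < 0 or unmeth < 0:
        raise ParseError(f"line {lineno}: negative read count")
    try:
        context = normalize_context(ctx)
    except ParseError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    return CytosineSite(chrom, pos, strand, meth, unmeth, context, tri.upper())


def iter_cytosine_report(path) -> Iterator[CytosineSite]:
    """Stream a cytosine report row by row with bounded memory.

    Rows with zero depth are retained (the depth filter is a separate,
    explicit stage). Malformed rows raise :class:`ParseError` naming the
    1-based line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield _parse_report_row(line, lineno)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a whole cytosine report into a DataFrame (columns ``REPORT_COLUMNS``)."""
    records = list(iter_cytosine_report(path))
    if not records:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    df = pd.DataFrame(records, columns=REPORT_COLUMNS)
    return df.astype({"pos": "int64", "meth": "int64", "unmeth": "int64"})


def write_cytosine_report(sites: pd.DataFrame | Iterable[CytosineSite], path) -> None:
    """Write sites in the 7-column report dialect (no header, tab-separated)."""
    with _open_text(path, "wt") as fh:
        if isinstance(sites, pd.DataFrame):
            rows = sites[REPORT_COLUMNS].itertuples(index=False)
        else:
            rows = iter(sites)
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\t{r[5]}\t{r[6]}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into {name: uppercase sequence} via pyfaidx."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from a GFF3 with ``gene`` and ``exon`` features.

    Exon features are attached to their gene through the ``Parent``
    attribute (directly, or via an intermediate mRNA whose own ``Parent``
    is the gene). Validation errors — an exon outside its gene span,
    overlapping exons within one gene, an unresolvable Parent — raise
    :class:`ValidationError`.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = {
            "chrom": g.seqid,
            "strand": g.strand if g.strand in "+-" else "+",
            "start": g.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
            "end": g.end,
            "exons": [],
        }
    # map transcript-level features back to their gene
    parent_of: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for t in db.features_of_type(ftype):
            for p in t.attributes.get("Parent", []):
                parent_of[t.id] = p
    for ex in db.features_of_type("exon"):
        parents = ex.attributes.get("Parent", [])
        if not parents:
            raise ValidationError(f"exon at {ex.seqid}:{ex.start}-{ex.end} has no Parent")
        for p in parents:
            gene_id = p if p in genes else parent_of.get(p)
            if gene_id is None or gene_id not in genes:
                raise ValidationError(
                    f"exon Parent {p!r} does not resolve to a gene"
                )
            genes[gene_id]["exons"].append((ex.start - 1, ex.end))
    models = []
    for gene_id, info in genes.items():
        exons = sorted(set(info["exons"]))
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {gene_id}: overlapping exons")
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=info["chrom"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Serialise gene models as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda m: (m.chrom, m.start, m.gene_id)):
            fh.write(
                f"{g.chrom}\tmethkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tmethkit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_sample_sheet(path, check_paths: bool = True) -> SampleSheet:
    """Load a sample sheet TSV; report paths are resolved relative to the sheet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sheet = SampleSheet(df)
    base = os.path.dirname(os.path.abspath(str(path)))
    resolved = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["report_path"]
    ]
    sheet.frame = df.assign(report_path=resolved)
    if check_paths:
        missing = [p for p in resolved if not os.path.exists(p)]
        if missing:
            raise ValidationError(f"sample sheet references missing files: {missing}")
    return sheet


def write_table(records: pd.DataFrame, path, float_precision: int = 4) -> None:
    """Write a derived table as TSV: header, stable column order, fixed float format.

    String cells may not contain the delimiter; an embedded tab raises
    :class:`ValidationError` rather than silently corrupting the file.
    """
    obj_cols = records.select_dtypes(include=["object", "string"]).columns
    for c in obj_cols:
        col = records[c].dropna().astype(str)
        if col.str.contains("\t").any():
            raise ValidationError(f"column {c!r} contains a tab character")
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
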