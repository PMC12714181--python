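"""Readers and writers for the on-disk formats the pipeline touches.

All matrix text is tab-delimited, UTF-8, "." decimal separator, with a
mandatory header row. Expression matrices are genes x samples with HGNC-style
symbols in the first column. Promoters travel as FASTA with the record ID
equal to the gene symbol and the last base at TSS-relative position -1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .motif import PFM, MotifSite

VALUE_KINDS = ("counts", "continuous")
GROUPS_TUMOR = ("healthy", "tumor")
GROUPS_KNOCKDOWN = ("control", "perturbed")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression matrix.

    ``value_kind`` is "counts" (non-negative integers) or "continuous"
    (non-negative reals such as RPKM). Gene and sample identifiers are
    unique and order-preserving.
    """

    data: pd.DataFrame  # genes x samples
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )
        if self.value_kind == "counts" and not np.allclose(values, np.rint(values)):
            raise ValidationError("value_kind='counts' requires integral values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.value_kind)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.value_kind)


def make_metadata(rows: Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    """Build a sample metadata table from (sample_id, cohort, group) rows."""
    meta = pd.DataFrame(rows, columns=["sample_id", "cohort", "group"])
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    for col in ("sample_id", "cohort", "group"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"sample {dup!r} appears in more than one metadata row")


def read_expression_matrix(
    path: str | Path,
    value_kind: str,
    duplicate_policy: str | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited gene x sample matrix.

    Duplicate gene rows collapse by ``duplicate_policy``: "sum" (default for
    counts) or "mean" (default for continuous). Any non-numeric cell raises a
    :class:`ParseError` naming the gene row and sample column.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: header row must name at least one sample")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, header=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        g, s = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    if numeric.index.has_duplicates:
        policy = duplicate_policy or ("sum" if value_kind == "counts" else "mean")
        grouped = numeric.groupby(level=0, sort=False)
        if policy == "sum":
            numeric = grouped.sum()
        elif policy == "mean":
            numeric = grouped.mean()
        else:
            raise ValidationError(f"unknown duplicate_policy {policy!r}")
    numeric.index.name = raw.index.name
    return ExpressionMatrix(numeric, value_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with 6 significant digits."""
    matrix.data.to_csv(Path(path), sep="\t", float_format="%.6g", index_label="gene")


@dataclass(frozen=True)
class TFPrior:
    """Directed TF -> target edge list used as the network prior."""

    edges: frozenset  # of (tf, target) tuples

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}


def read_tf_prior(path: str | Path, allow_self_loops: bool = False) -> TFPrior:
    """Read a two-column (TF, target) tab-delimited edge list.

    An optional header line ("tf<TAB>target", any case, or a line starting
    with '#') is skipped. Duplicate pairs are collapsed.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and (
                line.startswith("#") or [f.lower() for f in fields] == ["tf", "target"]
            ):
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            tf, target = fields
            if tf == target and not allow_self_loops:
                raise ValidationError(f"{path}:{lineno}: self-loop {tf!r} (pass allow_self_loops=True to keep)")
            edges.add((tf, target))
    return TFPrior(edges=frozenset(edges))


def write_tf_prior(prior: TFPrior, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\n")
        for tf, target in sorted(prior.edges):
            fh.write(f"{tf}\t{target}\n")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets (the annotation substrate for enrichment)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate term_id in gene set collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term_id <TAB> description <TAB> member..."""
    path = Path(path)
    sets = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs term, description and >=1 member")
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def read_pfm(path: str | Path) -> PFM:
    """Read a JASPAR-style PFM: '>ID name' header then A/C/G/T count rows.

    Counts may be bracketed (``A [ 1 2 3 ]``) or plain.
    """
    path = Path(path)
    motif_id = "motif"
    rows: dict[str, list[float]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0] if line[1:].split() else "motif"
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise ParseError(f"{path}:{lineno}: expected a row labeled A, C, G or T")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count ({exc})") from None
            if base in rows:
                raise ParseError(f"{path}:{lineno}: duplicate {base} row")
            rows[base] = values
    missing = [b for b in "ACGT" if b not in rows]
    if missing:
        raise ParseError(f"{path}: missing count row(s) for {', '.join(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path}: count rows have unequal lengths {sorted(lengths)}")
    counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    if np.any(counts < 0):
        raise ValidationError(f"{path}: negative count in PFM")
    return PFM(counts=counts, motif_id=motif_id)


def write_pfm(pfm: PFM, path: str | Path, name: str = "") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f">{pfm.motif_id} {name}".rstrip() + "\n")
        for b, row in zip("ACGT", pfm.counts):
            fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


def write_sites_bed(
    sites: Sequence[MotifSite], path: str | Path, promoter_length: int = 2000
) -> None:
    """Write sites as BED6 in promoter-local coordinates (0 = position -L).

    chrom = gene symbol, name = strandless site label, score = rel_score
    scaled to 0-1000; a seventh column carries the TSS-relative start.
    """
    for s in sites:
        if s.tss_start >= s.tss_end:  # MotifSite enforces this, but be explicit
            raise ValidationError(f"site start {s.tss_start} >= end {s.tss_end}")
    ordered = sorted(sites, key=lambda s: (s.gene, s.tss_start, s.strand))
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in ordered:
            local_start = s.tss_start + promoter_length
            local_end = s.tss_end + promoter_length
            if local_start < 0:
                raise ValidationError(
                    f"site start {s.tss_start} precedes the promoter window -{promoter_length}"
                )
            score = int(round(max(0.0, min(1.0, s.rel_score)) * 1000))
            fh.write(
                f"{s.gene}\t{local_start}\t{local_end}\tsite\t{score}\t{s.strand}\t{s.tss_start}\n"
            )


def write_sites_table(sites: Sequence[MotifSite], path: str | Path) -> None:
    ordered = sorted(sites, key=lambda s: (s.gene, s.tss_start, s.strand))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\ttss_start\ttss_end\tstrand\tscore\trel_score\n")
        for s in ordered:
            fh.write(
                f"{s.gene}\t{s.tss_start}\t{s.tss_end}\t{s.strand}\t{s.score:.6g}\t{s.rel_score:.6g}\n"
            )


def read_promoters(path: str | Path) -> dict[str, str]:
    """Read promoter FASTA; record ID = gene symbol, last base at TSS -1."""
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in promoters:
            raise ValidationError(f"{path}: duplicate promoter record {record.id!r}")
        promoters[record.id] = str(record.seq).upper()
    if not promoters:
        raise ParseError(f"{path}: no FASTA records found")
    return promoters


def write_promoters(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read sample_id / time / event / expression TSV."""
    table = pd.read_csv(Path(path), sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if (table["time"] <= 0).any():
        raise ValidationError(f"{path}: survival times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event indicators must be 0 or 1")
    return table


def write_de_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a DE result table with the fixed downstream column contract."""
    cols = ["gene", "base_mean", "log2fc", "p", "padj"]
    results.loc[:, cols].to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_de_results(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), sep="\t")
    missing = {"gene", "log2fc", "p", "padj"} - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return table
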