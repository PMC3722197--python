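"""Readers, writers and the pipeline configuration.

All tabular formats are UTF-8 tab-separated with '#'-prefixed comment
lines ignored.  Expression matrices: first column = row id, header row =
sample ids.  Sample sheets: three columns (sample, group, replicate).
Every writer's output is parseable by the corresponding reader.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .boosting import PromoterSet
from .enrichment import AnnotationMap
from .expression import DeTable, DiscreteExpressionMatrix, IntensityMatrix

__all__ = [
    "PipelineConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "read_fasta_promoters",
    "read_gene_list",
    "write_gene_list",
    "read_annotation_tsv",
    "write_de_table",
    "read_discrete_tsv",
    "write_discrete_tsv",
    "write_venn",
]


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline in one round-trippable place."""

    fc_de: float = 1.2
    q_de: float = 0.05
    fc_discrete: float = 1.5
    overlap_fc: float = 1.5
    overlap_p: float = 1e-4
    k_list: tuple[int, ...] = (5, 6)
    rounds: int = 400
    epsilon: float | None = None
    subsample_rate: float = 0.5
    max_depth: int = 2
    runs: int = 5
    k_top: int = 20
    min_runs: int = 4
    edge_threshold: float = 1.0
    final_k: int = 10
    universe_size: int = 21_249
    seed: int = 0
    scoring_conditions: list[str] | None = None

    def __post_init__(self) -> None:
        if self.min_runs > self.runs:
            raise ValueError("min_runs cannot exceed runs")
        if self.fc_de < 1 or self.fc_discrete < 1 or self.overlap_fc < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if not (0 < self.subsample_rate <= 1):
            raise ValueError("subsample_rate must be in (0, 1]")
        self.k_list = tuple(self.k_list)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_list"] = list(d["k_list"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with row ids in the first column, file order kept."""
    path = Path(path)
    header = None
    for line in path.read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            header = line.rstrip("\n").split("\t")[1:]
            break
    if header and len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty data section")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row id(s) {dupes}")
    non_numeric = df.columns[
        ~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = df.index.get_indexer(df.index[bad][:1])[0] + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric cell in column {col!r} near line {line}")
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """3-column TSV (sample, group, replicate) -> (groups, replicates)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["sample", "group", "replicate"], header=None,
        dtype=str,
    )
    # tolerate an explicit header row
    if df.iloc[0].tolist() == ["sample", "group", "replicate"]:
        df = df.iloc[1:]
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample in sample sheet")
    df = df.set_index("sample")
    return df["group"], df["replicate"]


def read_intensity_matrix(matrix_path: str | Path, sheet_path: str | Path) -> IntensityMatrix:
    values = read_expression_tsv(matrix_path)
    groups, replicates = read_sample_sheet(sheet_path)
    return IntensityMatrix(values, groups, replicates)


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """FASTA -> PromoterSet; ids = header up to first whitespace, sequences
    case-folded to upper; duplicate ids and letters outside ACGTN rejected."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"header-only FASTA record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return PromoterSet(sequences)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for gene, seq in promoters.sequences.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_annotation_tsv(
    path: str | Path, universe: set[str] | None = None, universe_size: int | None = None
) -> AnnotationMap:
    """2-column TSV (gene_id, term_id), multiple rows per gene."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene", "term"], header=None, dtype=str)
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        terms.setdefault(term, set()).add(gene)
    return AnnotationMap(terms, universe=universe or set(), universe_size=universe_size)


def write_de_table(de: DeTable, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", comment="#")


def write_discrete_tsv(d: DiscreteExpressionMatrix, path: str | Path) -> None:
    d.calls.to_csv(path, sep="\t", index_label="gene")


def read_discrete_tsv(path: str | Path) -> DiscreteExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene", comment="#").astype(int)
    return DiscreteExpressionMatrix(df)


def write_venn(regions: dict[tuple[str, ...], set[str]], path: str | Path) -> None:
    """Region -> count -> comma-joined genes, one region per line."""
    with Path(path).open("w") as fh:
        fh.write("region\tcount\tgenes\n")
        for members in sorted(regions, key=lambda m: (len(m), m)):
            genes = sorted(regions[members])
            fh.write(f"{'&'.join(members)}\t{len(genes)}\t{','.join(genes)}\n")
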