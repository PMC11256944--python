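"""Readers and writers for the tabular formats the pipeline consumes.

Four external table kinds are handled here and normalised into light
domain containers:

* MAF-like somatic mutation tables (TSV) -> lists of :class:`MutationRecord`
* drug response tables (CSV/TSV with columns sample, drug, audrc)
  -> :class:`ResponseTable`
* variant-effect score tables (annotator-style TSV keyed by
  chrom/pos/ref/alt with one column per scoring algorithm)
  -> :class:`ScoreTable`
* plain-text gene panels (one symbol per line) -> :class:`GenePanel`

Variant keys are ``(chrom, pos, ref, alt)`` with 1-based MAF/VCF-style
coordinates.  Gene symbols are matched case-sensitively.  Score values
are stored normalised to ``[0, 1)``; CADD-class raw columns (range
``[0, 99]``) are rescaled on load via :func:`qmsdr.features.normalize_cadd`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: cell contents treated as missing scores in annotator outputs
NA_SENTINELS = ("", "NA", "NaN", "nan", ".")

VariantKey = tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant observed in one sample.

    ``pos`` is a 1-based coordinate; ``protein_change`` is HGVS-p-style
    text such as ``"p.V600E"`` or ``None`` when not reported.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) is not a variant")
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")

    @property
    def variant_key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ReadDiagnostics:
    """Row-level bookkeeping from a table read."""

    n_read: int = 0
    n_skipped: int = 0
    n_duplicates: int = 0
    skipped_rows: list[int] = field(default_factory=list)


@dataclass
class ResponseTable:
    """Measured drug responses: ``(sample, drug) -> AUDRC``.

    AUDRC semantics: 0 = total cell death, 1 = no drug effect, values
    above 1 indicate growth.  Replicate measurements are averaged at
    load time so the mapping holds one entry per pair.
    """

    entries: dict[tuple[str, str], float]

    def audrc(self, sample_id: str, drug_id: str) -> float:
        return self.entries[(sample_id, drug_id)]

    def drugs(self) -> list[str]:
        return sorted({d for (_, d) in self.entries})

    def samples(self) -> list[str]:
        return sorted({s for (s, _) in self.entries})

    def for_drug(self, drug_id: str) -> pd.Series:
        """Per-sample AUDRC for one drug, indexed by sample id."""
        data = {s: v for (s, d), v in self.entries.items() if d == drug_id}
        if not data:
            raise KeyError(f"no responses recorded for drug {drug_id!r}")
        return pd.Series(data, name=drug_id).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "drug": d, "audrc": v}
            for (s, d), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["sample", "drug", "audrc"])


@dataclass(frozen=True)
class GenePanel:
    """An ordered, duplicate-free list of gene symbols.

    The order is part of the trained-model contract: layer-1 blocks of
    the response network are laid out in panel order, so a panel is
    serialised together with any model trained on it.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene panel contains duplicate symbols")
        if not self.genes:
            raise ValidationError("gene panel is empty")

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index


@dataclass
class ScoreTable:
    """Per-variant scores from one or more effect-prediction algorithms.

    ``scores[key]`` is a float vector aligned with ``algorithms``; missing
    values are NaN.  Every present value lies in ``[0, 1)`` — raw CADD-class
    columns are rescaled on load.
    """

    algorithms: tuple[str, ...]
    scores: dict[VariantKey, np.ndarray]

    def get(self, key: VariantKey) -> np.ndarray | None:
        return self.scores.get(key)

    def algorithm_index(self, name: str) -> int:
        try:
            return self.algorithms.index(name)
        except ValueError:
            raise KeyError(f"unknown algorithm {name!r}; table has {self.algorithms}")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationDialect:
    """Column-name mapping for MAF-like mutation tables."""

    sample: str = "sample"
    gene: str = "gene"
    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    protein_change: str | None = "protein_change"
    sep: str = "\t"

    def required_columns(self) -> list[str]:
        return [self.sample, self.gene, self.chrom, self.pos, self.ref, self.alt]


def read_mutation_table(
    path: str | Path, dialect: MutationDialect = MutationDialect()
) -> tuple[list[MutationRecord], ReadDiagnostics]:
    """Read a MAF-like TSV into mutation records.

    Rows whose coordinate cannot be parsed as a positive integer, or that
    violate a record invariant, are skipped and counted in the returned
    diagnostics rather than aborting the load.  Exact-duplicate rows
    (same sample, gene and variant) collapse to one observation.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in dialect.required_columns():
        if col not in df.columns:
            raise FormatError(f"mutation table {path} lacks required column {col!r}")
    has_pc = dialect.protein_change is not None and dialect.protein_change in df.columns

    records: list[MutationRecord] = []
    diag = ReadDiagnostics()
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        diag.n_read += 1
        try:
            pos = int(row[dialect.pos])
        except (TypeError, ValueError):
            diag.n_skipped += 1
            diag.skipped_rows.append(idx)
            continue
        pc = row[dialect.protein_change] if has_pc else None
        if pc in NA_SENTINELS:
            pc = None
        try:
            records.append(
                MutationRecord(
                    sample_id=str(row[dialect.sample]),
                    gene=str(row[dialect.gene]),
                    chrom=str(row[dialect.chrom]),
                    pos=pos,
                    ref=str(row[dialect.ref]),
                    alt=str(row[dialect.alt]),
                    protein_change=pc,
                )
            )
        except ValidationError:
            diag.n_skipped += 1
            diag.skipped_rows.append(idx)
    deduped = dedupe_mutations(records)
    diag.n_duplicates = len(records) - len(deduped)
    return deduped, diag


def write_mutation_table(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: MutationDialect = MutationDialect(),
) -> None:
    cols = dialect.required_columns() + (
        [dialect.protein_change] if dialect.protein_change else []
    )
    rows = []
    for r in records:
        row = [r.sample_id, r.gene, r.chrom, r.pos, r.ref, r.alt]
        if dialect.protein_change:
            row.append(r.protein_change if r.protein_change is not None else "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=dialect.sep, index=False)


def dedupe_mutations(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Collapse exact-duplicate mutation rows to one observation each."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.sample_id, r.gene, r.variant_key)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# response tables
# ---------------------------------------------------------------------------


def read_response_table(path: str | Path, sep: str | None = None) -> ResponseTable:
    """Read a sample/drug/audrc table, averaging replicate measurements.

    The separator is sniffed from the extension (``.tsv`` -> tab) unless
    given.  AUDRC must be non-negative; values above 1 (cell growth) are
    allowed.
    """
    if sep is None:
        sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "drug", "audrc"):
        if col not in df.columns:
            raise FormatError(f"response table {path} lacks required column {col!r}")
    if (df["audrc"] < 0).any():
        bad = int(df.index[df["audrc"] < 0][0])
        raise ValidationError(f"negative AUDRC at row {bad}")
    grouped = df.groupby(["sample", "drug"], sort=False)["audrc"].mean()
    entries = {
        (str(s), str(d)): float(v) for (s, d), v in grouped.items()
    }
    return ResponseTable(entries=entries)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlgorithmColumn:
    """Declares where one algorithm's scores live and their raw scale.

    ``scale`` is ``"unit"`` for algorithms emitting values in ``[0, 1)``
    (CHASMplus, VEST4) or ``"cadd_raw"`` for CADD-class columns in
    ``[0, 99]``, which are divided by 100 on load.
    """

    name: str
    column: str
    scale: str = "unit"  # "unit" | "cadd_raw"


#: the three-algorithm layout of the default annotator export
DEFAULT_ALGORITHM_COLUMNS = (
    AlgorithmColumn("CHASMplus", "chasmplus", "unit"),
    AlgorithmColumn("VEST4", "vest4", "unit"),
    AlgorithmColumn("CADD", "cadd_raw", "cadd_raw"),
)


def read_score_table(
    path: str | Path,
    algorithm_columns: Sequence[AlgorithmColumn] = DEFAULT_ALGORITHM_COLUMNS,
) -> ScoreTable:
    """Read an annotator-style score TSV keyed by chrom/pos/ref/alt.

    Blank and ``NA`` cells become missing.  Variants with no score from
    any declared algorithm are omitted entirely.  Raw values outside the
    declared range raise a validation error naming the offending row.
    """
    from .features import normalize_cadd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"score table {path} lacks required column {col!r}")
    for spec in algorithm_columns:
        if spec.column not in df.columns:
            raise FormatError(f"score table {path} lacks algorithm column {spec.column!r}")

    names = tuple(spec.name for spec in algorithm_columns)
    scores: dict[VariantKey, np.ndarray] = {}
    for idx, row in df.iterrows():
        vec = np.full(len(algorithm_columns), np.nan)
        for j, spec in enumerate(algorithm_columns):
            cell = row[spec.column]
            if pd.isna(cell) or str(cell).strip() in NA_SENTINELS:
                continue
            raw = float(cell)
            if spec.scale == "cadd_raw":
                if not 0.0 <= raw <= 99.0:
                    raise ValidationError(
                        f"row {idx}: raw CADD value {raw} outside [0, 99]"
                    )
                vec[j] = normalize_cadd(raw)
            else:
                if not 0.0 <= raw < 1.0:
                    raise ValidationError(
                        f"row {idx}: {spec.name} value {raw} outside [0, 1)"
                    )
                vec[j] = raw
        if np.all(np.isnan(vec)):
            continue  # no information for this variant
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        scores[key] = vec
    return ScoreTable(algorithms=names, scores=scores)


def write_score_table(
    table: ScoreTable,
    path: str | Path,
    algorithm_columns: Sequence[AlgorithmColumn] = DEFAULT_ALGORITHM_COLUMNS,
) -> None:
    """Write scores back out in the raw annotator dialect (CADD rescaled x100)."""
    if tuple(s.name for s in algorithm_columns) != table.algorithms:
        raise ValidationError("algorithm_columns do not match table.algorithms")
    rows = []
    for (chrom, pos, ref, alt), vec in sorted(table.scores.items()):
        row: dict[str, object] = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for j, spec in enumerate(algorithm_columns):
            v = vec[j]
            if np.isnan(v):
                row[spec.column] = ""
            else:
                row[spec.column] = v * 100.0 if spec.scale == "cadd_raw" else v
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt"] + [s.column for s in algorithm_columns]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene panels
# ---------------------------------------------------------------------------


def read_gene_panel(paths: str | Path | Sequence[str | Path]) -> GenePanel:
    """Union one or more one-symbol-per-line files into a panel.

    The union is deduplicated and sorted lexicographically so that panel
    order — and hence the network's layer-1 block layout — is stable
    across runs regardless of file order.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    union: set[str] = set()
    for p in paths:
        symbols = [ln.strip() for ln in Path(p).read_text().splitlines() if ln.strip()]
        if len(set(symbols)) != len(symbols):
            logger.warning("gene panel %s contains duplicate symbols; deduplicated", p)
        union.update(symbols)
    if not union:
        raise ValidationError("gene panel union is empty")
    return GenePanel(genes=tuple(sorted(union)))


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.genes) + "\n")
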