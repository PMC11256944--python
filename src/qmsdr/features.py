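"""Gene-level feature encodings of somatic mutations.

A tumor sample is represented as a ``genes x channels`` block of values
in ``[0, 1]``:

* ``binary`` — one channel, 1 if the gene carries any somatic mutation;
* ``single_qms`` — one continuous channel holding the maximum score of
  the gene's mutations under one algorithm (optionally plus the
  "not scored" flag channel);
* ``multi_qms`` — one channel per algorithm (max rule applied per
  channel independently) plus a binary "not scored" channel that fires
  when a gene carries a mutation no configured algorithm scored;
* ``marker`` — a single-gene, single-residue binary feature (e.g. BRAF
  residue 600 substituted away from valine), the classical biomarker
  baseline.

Unmutated genes are all-zero in every mode.  When a gene carries several
mutations, each score channel takes the maximum over the mutations; a
mutation missing one algorithm's score contributes 0 to that channel
only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigError, ValidationError
from .io import GenePanel, MutationRecord, ScoreTable

#: canonical channel order of the three-algorithm encoding
DEFAULT_ALGORITHM_ORDER = ("CHASMplus", "VEST4", "CADD")
NOT_SCORED_CHANNEL = "not_scored"


def normalize_cadd(raw: float) -> float:
    """Rescale a raw CADD-class score from ``[0, 99]`` to ``[0, 0.99]``.

    The transform is the linear map ``raw / 100`` so that the maximum
    raw value 99 maps to 0.99, keeping CADD channels on the same unit
    scale as probability-like scorers.
    """
    if not 0.0 <= raw <= 99.0:
        raise ValidationError(f"raw CADD score {raw} outside [0, 99]")
    return raw / 100.0


@dataclass(frozen=True)
class MarkerSpec:
    """A single-residue biomarker: substitutions of ``ref_aa`` at ``residue``."""

    gene: str
    residue: int
    ref_aa: str


@dataclass(frozen=True)
class EncodingConfig:
    """How mutations are turned into per-gene channels.

    ``algorithms`` must be a subset of the score table's algorithms and
    fixes the channel order.  ``include_not_scored`` appends the binary
    flag channel in score modes.
    """

    mode: str  # binary | single_qms | multi_qms | marker
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHM_ORDER
    include_not_scored: bool = True
    marker_spec: MarkerSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "single_qms", "multi_qms", "marker"):
            raise ConfigError(f"unknown encoding mode {self.mode!r}")
        if self.mode == "single_qms" and len(self.algorithms) != 1:
            raise ConfigError("single_qms requires exactly one algorithm")
        if self.mode == "multi_qms" and len(self.algorithms) < 2:
            raise ConfigError("multi_qms requires at least two algorithms")
        if self.mode == "marker" and self.marker_spec is None:
            raise ConfigError("marker mode requires marker_spec")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.mode == "binary":
            return ("mutated",)
        if self.mode == "marker":
            assert self.marker_spec is not None
            return (f"{self.marker_spec.gene}_{self.marker_spec.residue}_marker",)
        channels = tuple(self.algorithms)
        if self.include_not_scored:
            channels = channels + (NOT_SCORED_CHANNEL,)
        return channels

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class FeatureMatrix:
    """The model input: ``samples x genes x channels`` values in [0, 1]."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    panel: GenePanel
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n, g, c = self.values.shape
        if n != len(self.sample_ids) or g != len(self.panel) or c != len(
            self.channel_names
        ):
            raise ValidationError("feature matrix axes do not match metadata")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def flat(self) -> np.ndarray:
        """Gene-major 2-D view ``(samples, genes*channels)`` for the network."""
        n = self.values.shape[0]
        return self.values.reshape(n, -1)

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return FeatureMatrix(
            values=self.values[rows],
            sample_ids=tuple(sample_ids),
            panel=self.panel,
            channel_names=self.channel_names,
        )

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            sample_ids=np.array(self.sample_ids, dtype=object),
            genes=np.array(self.panel.genes, dtype=object),
            channel_names=np.array(self.channel_names, dtype=object),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                values=z["values"],
                sample_ids=tuple(str(s) for s in z["sample_ids"]),
                panel=GenePanel(genes=tuple(str(g) for g in z["genes"])),
                channel_names=tuple(str(c) for c in z["channel_names"]),
            )


# ---------------------------------------------------------------------------
# per-gene channel rules
# ---------------------------------------------------------------------------


def gene_channel_value(
    mutations: Sequence[MutationRecord], score_table: ScoreTable, algorithm: str
) -> float:
    """Max of one algorithm's scores over a gene's mutations; 0 if none.

    A mutation absent from the score table, or missing this algorithm's
    score, contributes 0 to the maximum.
    """
    j = score_table.algorithm_index(algorithm)
    best = 0.0
    for m in mutations:
        vec = score_table.get(m.variant_key)
        if vec is None or np.isnan(vec[j]):
            continue
        best = max(best, float(vec[j]))
    return best


def not_scored_flag(
    mutations: Sequence[MutationRecord],
    score_table: ScoreTable,
    algorithms: Sequence[str] | None = None,
) -> int:
    """1 iff the gene carries a mutation no configured algorithm scored."""
    if not mutations:
        return 0
    idx = (
        range(len(score_table.algorithms))
        if algorithms is None
        else [score_table.algorithm_index(a) for a in algorithms]
    )
    for m in mutations:
        vec = score_table.get(m.variant_key)
        if vec is None or all(np.isnan(vec[j]) for j in idx):
            return 1
    return 0


_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z\*])(\d+)(.+)$")


def parse_protein_change(text: str) -> tuple[str, int, str] | None:
    """Parse ``p.V600E``/``V600E``-style notation to (ref_aa, residue, alt).

    Returns None when the text is not a parseable single-residue change.
    """
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if m is None:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


def build_marker_feature(
    mutations: Sequence[MutationRecord],
    marker_spec: MarkerSpec,
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, int], int]:
    """Binary per-sample single-residue marker, plus an unparseable count.

    A sample is positive iff it carries a mutation in the marker gene
    whose protein change substitutes the specified residue away from the
    reference amino acid (any alternate amino acid, including nonsense,
    counts).  Mutations in the marker gene whose protein change cannot
    be parsed are counted and treated as non-marker.
    """
    if sample_ids is None:
        sample_ids = sorted({m.sample_id for m in mutations})
    flags = {s: 0 for s in sample_ids}
    n_unparseable = 0
    for m in mutations:
        if m.gene != marker_spec.gene or m.sample_id not in flags:
            continue
        if m.protein_change is None:
            n_unparseable += 1
            continue
        parsed = parse_protein_change(m.protein_change)
        if parsed is None:
            n_unparseable += 1
            continue
        ref_aa, residue, alt = parsed
        if (
            residue == marker_spec.residue
            and ref_aa == marker_spec.ref_aa
            and alt != ref_aa
        ):
            flags[m.sample_id] = 1
    return flags, n_unparseable


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------


def _group_by_sample_gene(
    mutations: Iterable[MutationRecord], panel: GenePanel
) -> dict[tuple[str, str], list[MutationRecord]]:
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for m in mutations:
        if m.gene not in panel:
            continue  # off-panel mutations are silently ignored
        groups.setdefault((m.sample_id, m.gene), []).append(m)
    return groups


def build_feature_matrix(
    mutations: Sequence[MutationRecord],
    score_table: ScoreTable | None,
    panel: GenePanel,
    config: EncodingConfig,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the samples x genes x channels input tensor.

    ``sample_ids`` fixes the row order and includes samples with no
    on-panel mutations (all-zero rows); by default rows are the sorted
    distinct sample ids present in ``mutations``.
    """
    if config.mode in ("single_qms", "multi_qms"):
        if score_table is None:
            raise ConfigError(f"{config.mode} encoding requires a score table")
        for a in config.algorithms:
            score_table.algorithm_index(a)  # raises KeyError on unknown name
    if sample_ids is None:
        sample_ids = sorted({m.sample_id for m in mutations})
    sample_ids = tuple(str(s) for s in sample_ids)
    channels = config.channel_names
    values = np.zeros((len(sample_ids), len(panel), len(channels)))

    if config.mode == "marker":
        assert config.marker_spec is not None
        flags, _ = build_marker_feature(mutations, config.marker_spec, sample_ids)
        gi = panel.index.get(config.marker_spec.gene)
        if gi is None:
            raise ConfigError(f"marker gene {config.marker_spec.gene!r} not in panel")
        for si, s in enumerate(sample_ids):
            values[si, gi, 0] = flags[s]
        return FeatureMatrix(values, sample_ids, panel, channels)

    row_of = {s: i for i, s in enumerate(sample_ids)}
    gene_index = panel.index
    for (sample, gene), muts in _group_by_sample_gene(mutations, panel).items():
        if sample not in row_of:
            continue
        si, gi = row_of[sample], gene_index[gene]
        if config.mode == "binary":
            values[si, gi, 0] = 1.0
            continue
        assert score_table is not None
        for cj, alg in enumerate(config.algorithms):
            values[si, gi, cj] = gene_channel_value(muts, score_table, alg)
        if config.include_not_scored:
            values[si, gi, -1] = not_scored_flag(muts, score_table, config.algorithms)
    return FeatureMatrix(values, sample_ids, panel, channels)


# ---------------------------------------------------------------------------
# representation entropy
# ---------------------------------------------------------------------------


def representation_entropy(values: np.ndarray, bins: int = 20) -> float:
    """Shannon entropy (log2 bits) of an empirical feature distribution.

    1-D input is treated as a single channel; 2-D input ``(n, channels)``
    is scored by the joint distribution over per-channel equal-width bins
    on ``[0, 1]``, so richer encodings can only gain entropy as channels
    are appended.
    """
    if bins < 2:
        raise ConfigError("bins must be >= 2")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("entropy of an empty sample is undefined")
    if arr.ndim == 1:
        arr = arr[:, None]
    binned = np.clip(np.floor(arr * bins).astype(int), 0, bins - 1)
    _, counts = np.unique(binned, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())
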