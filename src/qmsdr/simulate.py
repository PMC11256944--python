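"""Synthetic cohorts with the structure the response models assume.

The generator emulates the five external inputs — mutation tables,
multi-algorithm score tables with missingness, drug responses, gene
panels and clinical cohorts — with a planted mechanism that mirrors the
classical single-residue biomarker situation: a driver gene whose
*high-impact* (hotspot) mutations confer drug sensitivity while its
low-impact mutations do not.  A binary mutated/unmutated encoding cannot
separate the two by construction; score encodings can.

Per sample, genes mutate independently.  Each mutation carries a latent
functional impact u in [0, 1): passengers draw from Beta(1, 5) (weak,
right-skewed toward 0) while driver/modifier mutations are an even
mixture of strong hotspot draws from Beta(8, 2) and the passenger
distribution, so a substantial share of driver-gene mutations are
sub-threshold and invisible to a mutated/unmutated flag.  Each scoring
algorithm
observes u through independent Gaussian noise with per-algorithm
missingness, and a fraction of mutations are scored by no algorithm at
all.  The noiseless response is

    y = 1 - a * 1[max u over driver mutations >= tau]
          - sum_m a_m * 1[max u over modifier-m mutations >= tau]

clipped at 0, with additive Gaussian measurement noise.  Hotspot driver
mutations are written with a fixed-residue protein change (e.g.
``p.V600E``) so the single-residue marker baseline can be built.

Randomness is split into named substreams (rates, mutations, impacts,
scores, responses, cohort) off one seed, so adding a downstream stage
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import ClinicalCohort
from .exceptions import ConfigError
from .io import GenePanel, MutationRecord, ResponseTable, ScoreTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DriverSpec:
    """A planted sensitivity driver (or modifier) gene.

    ``effect`` is the AUDRC drop conferred when the gene carries a
    mutation with latent impact >= the cohort threshold; ``hotspot_residue``
    receives the protein changes of hotspot draws so a single-residue
    marker can target it.
    """

    gene: str
    effect: float
    mutation_rate: float
    hotspot_residue: int = 600
    hotspot_ref_aa: str = "V"
    hotspot_weight: float = 0.5
    hotspot_beta: tuple[float, float] = (8.0, 2.0)

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ConfigError("driver effect must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation rate must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale analogue of a pan-cancer cell-line
    screen: 1200 samples, a 200-gene panel, a strong threshold driver
    plus three weaker modifiers, three correlated scoring algorithms
    with realistic missingness, and ~10% of mutations scored by nothing.
    """

    n_samples: int = 1200
    n_genes: int = 200
    mutation_rate_range: tuple[float, float] = (0.05, 0.15)
    driver: DriverSpec = DriverSpec("BRAF", effect=0.5, mutation_rate=0.35)
    second_driver: DriverSpec | None = None
    modifiers: tuple[DriverSpec, ...] = (
        DriverSpec("TP53", effect=0.08, mutation_rate=0.15, hotspot_residue=273, hotspot_ref_aa="R"),
        DriverSpec("PIK3CA", effect=0.06, mutation_rate=0.12, hotspot_residue=1047, hotspot_ref_aa="H"),
        DriverSpec("BCL2", effect=0.05, mutation_rate=0.10, hotspot_residue=101, hotspot_ref_aa="G"),
    )
    impact_threshold: float = 0.8
    algorithms: tuple[str, ...] = ("CHASMplus", "VEST4", "CADD")
    score_noise_sd: tuple[float, ...] = (0.05, 0.08, 0.12)
    missingness: tuple[float, ...] = (0.08, 0.05, 0.10)
    unscored_rate: float = 0.10
    extra_mutation_prob: float = 0.10
    response_noise_sd: float = 0.08
    drug_id: str = "DRUG1"
    # clinical-cohort settings
    n_patients: int = 120
    censoring_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            *self.mutation_rate_range,
            *self.missingness,
            self.unscored_rate,
            self.extra_mutation_prob,
            self.censoring_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        if not 0.0 < self.impact_threshold < 1.0:
            raise ConfigError("impact_threshold must be in (0, 1)")
        if len(self.score_noise_sd) != len(self.algorithms) or len(
            self.missingness
        ) != len(self.algorithms):
            raise ConfigError("per-algorithm settings must match algorithms")

    @property
    def special_genes(self) -> tuple[DriverSpec, ...]:
        extra = (self.second_driver,) if self.second_driver else ()
        return (self.driver, *extra, *self.modifiers)

    def panel(self) -> GenePanel:
        special = [d.gene for d in self.special_genes]
        n_passengers = self.n_genes - len(special)
        if n_passengers < 0:
            raise ConfigError("n_genes smaller than the number of special genes")
        passengers = [f"GENE{i:04d}" for i in range(n_passengers)]
        return GenePanel(genes=tuple(sorted(special + passengers)))


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    impacts: dict[tuple, float]  # (sample, gene, variant_key) -> latent u
    noiseless_response: pd.Series  # sample -> response before noise/clipping
    driver_genes: dict[str, float]  # gene -> planted effect size
    impact_threshold: float


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_impact(rng: np.random.Generator, spec: DriverSpec | None) -> tuple[float, bool]:
    """Latent impact u and whether the draw came from the hotspot component."""
    if spec is not None and rng.random() < spec.hotspot_weight:
        a, b = spec.hotspot_beta
        return float(rng.beta(a, b)), True
    return float(rng.beta(1, 5)), False


def _protein_change(
    rng: np.random.Generator, spec: DriverSpec | None, hotspot: bool
) -> str:
    if spec is not None and hotspot:
        alt = rng.choice([a for a in AMINO_ACIDS if a != spec.hotspot_ref_aa])
        return f"p.{spec.hotspot_ref_aa}{spec.hotspot_residue}{alt}"
    ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
    residue = int(rng.integers(1, 500))
    if spec is not None and residue == spec.hotspot_residue:
        residue += 1  # keep non-hotspot draws off the marker residue
    return f"p.{ref}{residue}{alt}"


def _generate_mutation_process(
    config: GeneratorConfig,
    sample_ids: Sequence[str],
    rngs: dict[str, np.random.Generator],
) -> tuple[list[MutationRecord], ScoreTable, SyntheticTruth]:
    """Shared mutation/score/response machinery for cell lines and patients."""
    panel = config.panel()
    special = {d.gene: d for d in config.special_genes}
    rate_rng = rngs["rates"]
    lo, hi = config.mutation_rate_range
    gene_rates = {
        g: (special[g].mutation_rate if g in special else float(rate_rng.uniform(lo, hi)))
        for g in panel.genes
    }

    mut_rng, imp_rng, score_rng = rngs["mutations"], rngs["impacts"], rngs["scores"]
    mutations: list[MutationRecord] = []
    impacts: dict[tuple, float] = {}
    scores: dict[tuple, np.ndarray] = {}
    pos_counter: dict[str, int] = {}

    gene_chrom = {g: f"chr{1 + i % 22}" for i, g in enumerate(panel.genes)}
    for sample in sample_ids:
        for gi, gene in enumerate(panel.genes):
            if mut_rng.random() >= gene_rates[gene]:
                continue
            n_muts = 1 + (1 if mut_rng.random() < config.extra_mutation_prob else 0)
            for _ in range(n_muts):
                spec = special.get(gene)
                u, hotspot = _draw_impact(imp_rng, spec)
                pos_counter[gene] = pos_counter.get(gene, 0) + 1
                pos = (gi + 1) * 1_000_000 + pos_counter[gene]
                ref, alt = "A", "T"
                record = MutationRecord(
                    sample_id=sample,
                    gene=gene,
                    chrom=gene_chrom[gene],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    protein_change=_protein_change(imp_rng, spec, hotspot),
                )
                mutations.append(record)
                impacts[(sample, gene, record.variant_key)] = u
                if score_rng.random() < config.unscored_rate:
                    continue  # no algorithm scores this mutation at all
                vec = np.full(len(config.algorithms), np.nan)
                for k, sd in enumerate(config.score_noise_sd):
                    if score_rng.random() < config.missingness[k]:
                        continue
                    vec[k] = float(np.clip(u + score_rng.normal(0.0, sd), 0.0, 0.989))
                if not np.all(np.isnan(vec)):
                    scores[record.variant_key] = vec

    score_table = ScoreTable(algorithms=tuple(config.algorithms), scores=scores)

    # noiseless response from latent impacts
    tau = config.impact_threshold
    max_u: dict[tuple[str, str], float] = {}
    for (sample, gene, _), u in impacts.items():
        key = (sample, gene)
        max_u[key] = max(max_u.get(key, 0.0), u)
    noiseless = {}
    for sample in sample_ids:
        y = 1.0
        for spec in config.special_genes:
            if max_u.get((sample, spec.gene), 0.0) >= tau:
                y -= spec.effect
        noiseless[sample] = y
    truth = SyntheticTruth(
        impacts=impacts,
        noiseless_response=pd.Series(noiseless).sort_index(),
        driver_genes={d.gene: d.effect for d in config.special_genes},
        impact_threshold=tau,
    )
    return mutations, score_table, truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[MutationRecord], ScoreTable, ResponseTable, SyntheticTruth]:
    """Generate a cell-line cohort: mutations, scores, responses, truth.

    Reproducible from the config (which carries the seed): the same
    config yields identical cohorts.
    """
    rngs = _substreams(config.seed, ["rates", "mutations", "impacts", "scores", "responses", "cohort"])
    sample_ids = [f"CL{i:04d}" for i in range(config.n_samples)]
    mutations, score_table, truth = _generate_mutation_process(config, sample_ids, rngs)

    resp_rng = rngs["responses"]
    entries = {}
    for sample in sample_ids:
        y = truth.noiseless_response[sample]
        if config.response_noise_sd > 0:
            y = y + float(resp_rng.normal(0.0, config.response_noise_sd))
        entries[(sample, config.drug_id)] = max(0.0, y)
    return mutations, score_table, ResponseTable(entries=entries), truth


def generate_clinical_cohort(
    config: GeneratorConfig,
    outcome: str = "recist",
) -> tuple[ClinicalCohort, SyntheticTruth]:
    """Generate a patient cohort with RECIST or survival outcomes.

    Patients are drawn from the same mutation/score process as cell
    lines (fresh substreams).  RECIST: true responders (noiseless
    response below 1 - effect/2) receive PR with probability 0.85,
    others with 0.10; non-PR patients split between SD and PD.
    Survival: months are exponential with mean 24 for true responders
    and 8 otherwise, with independent uniform censoring at the
    configured rate.
    """
    if outcome not in ("recist", "survival"):
        raise ConfigError(f"unknown outcome type {outcome!r}")
    rngs = _substreams(
        config.seed + 104729,  # distinct stream family from the cell-line cohort
        ["rates", "mutations", "impacts", "scores", "responses", "cohort"],
    )
    patient_ids = [f"PT{i:04d}" for i in range(config.n_patients)]
    mutations, score_table, truth = _generate_mutation_process(
        config, patient_ids, rngs
    )
    rng = rngs["cohort"]
    cut = 1.0 - config.driver.effect / 2.0
    is_responder = truth.noiseless_response < cut

    if outcome == "recist":
        classes = {}
        for pt in patient_ids:
            p_pr = 0.85 if is_responder[pt] else 0.10
            if rng.random() < p_pr:
                classes[pt] = "PR"
            else:
                classes[pt] = "SD" if rng.random() < 0.5 else "PD"
        cohort = ClinicalCohort(
            mutations=mutations,
            recist=pd.Series(classes).loc[patient_ids],
            score_table=score_table,
        )
    else:
        months, events = {}, {}
        for pt in patient_ids:
            mean = 24.0 if is_responder[pt] else 8.0
            t = float(rng.exponential(mean))
            if config.censoring_rate > 0 and rng.random() < config.censoring_rate:
                months[pt] = float(rng.uniform(0.0, t))
                events[pt] = False
            else:
                months[pt] = t
                events[pt] = True
        cohort = ClinicalCohort(
            mutations=mutations,
            survival=pd.DataFrame(
                {"months": pd.Series(months), "event": pd.Series(events)}
            ).loc[patient_ids],
            score_table=score_table,
        )
    return cohort, truth


def two_driver_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The two-driver benchmark cohort: a second, marker-invisible driver.

    The second driver acts through its own hotspot residue, so a
    single-residue marker on the first driver misses its sensitive
    samples while a score-based model can recover them.  Both drivers
    use a sharp hotspot impact distribution (Beta(25, 2), essentially
    always above the sensitivity threshold): activating-hotspot biology
    where the marker residue is a consistently strong biomarker, as for
    BRAF V600X.
    """
    sharp = (25.0, 2.0)
    defaults = dict(
        driver=DriverSpec(
            "BRAF", effect=0.5, mutation_rate=0.25, hotspot_weight=0.5,
            hotspot_beta=sharp,
        ),
        second_driver=DriverSpec(
            "MAP2K1", effect=0.45, mutation_rate=0.20, hotspot_residue=57,
            hotspot_ref_aa="Q", hotspot_weight=0.5, hotspot_beta=sharp,
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
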