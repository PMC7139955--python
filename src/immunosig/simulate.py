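"""Synthetic pan-cancer-like cohorts with known immune-module structure.

The generator emulates the features of multi-cancer-type bulk RNA-seq
cohorts that the downstream pipeline depends on, with ground truth kept
alongside:

* several cancer types, each with its own per-gene baseline shift;
* a latent immune-active / immune-silent sample dichotomy: active
  samples carry an additive log2 shift on immune-module genes;
* planted co-expression modules built from a latent-factor model — a
  module gene's log2 deviation is ``sqrt(rho) * factor + sqrt(1-rho) *
  noise`` so the expected pairwise within-module correlation is
  ``rho``;
* linear-scale counts obtained as ``round(2**log2)``, so the
  upper-quartile normalizer sees realistic input (the generating log2
  matrix is preserved in the truth record);
* right-censored survival times from a Weibull baseline hazard scaled
  by ``exp(sum_s beta_s * Z_s + covariate effects)``, censored
  administratively at a fixed horizon.

True raw and standardized signature scores are computed from the
generating log2 matrix with the same scoring code used downstream, so
parameter-recovery tests compare like with like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LINEAR, LOG2, ExpressionMatrix
from .scoring import SignatureDefinition, ratio_score, raw_score, standardize

#: Table-1-like stage distribution (stage <=2 / 3 / 4)
STAGE_LEVELS = ("<=2", "3", "4")
STAGE_PROBS = (0.06, 0.82, 0.12)

CYTO_LEVELS = ("Optimal", "Suboptimal", "Unknown")
CYTO_PROBS = (0.69, 0.06, 0.25)


@dataclass
class ModuleSpec:
    """One planted co-expression module ("immune subsystem").

    ``active_shift`` is the mean log2 increment applied to module genes
    in immune-active samples; each gene's own amplitude is drawn once as
    ``active_shift * Uniform(1 - shift_heterogeneity, 1 +
    shift_heterogeneity)``, mimicking the uneven per-gene response of
    real infiltration programs (and giving the activity signal
    across-gene variance, which correlation-based sample clustering
    needs).  ``within_corr`` is the target pairwise Pearson correlation
    among module genes (before the shift).
    """

    name: str
    n_genes: int
    active_shift: float = 2.0
    within_corr: float = 0.8
    shift_heterogeneity: float = 0.5
    genes: list[str] | None = None  # explicit member names; synthesized if None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"module {self.name}: n_genes must be >= 1")
        if not 0.0 <= self.within_corr < 1.0:
            raise ValueError(f"module {self.name}: within_corr must be in [0, 1)")
        if self.genes is not None and len(self.genes) != self.n_genes:
            raise ValueError(f"module {self.name}: |genes| != n_genes")

    def gene_names(self) -> list[str]:
        if self.genes is not None:
            return list(self.genes)
        return [f"{self.name}_g{i + 1}" for i in range(self.n_genes)]


def default_modules() -> list[ModuleSpec]:
    """Modules mirroring the packaged signatures: a 57-gene cytotoxic
    lymphocyte module, the 3-gene CXCR3-ligand module, and a 4-gene
    M2-macrophage module (which tracks immune activity only weakly)."""
    from .scoring import load_default_signatures

    sigs = load_default_signatures()
    return [
        ModuleSpec("CLIS", 57, active_shift=2.0, within_corr=0.8, genes=sigs["CLIS"].genes),
        ModuleSpec("TCT", 3, active_shift=2.0, within_corr=0.8, genes=sigs["TCT"].genes),
        ModuleSpec("M2TAM", 4, active_shift=1.0, within_corr=0.8, genes=sigs["M2TAM"].genes),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults give a 3-type, 300-sample cohort with the three standard
    modules, 40% immune-active samples, log2 residual SD 1.0, a Weibull
    baseline with median survival around 2 years, administrative
    censoring at 5 years, and a protective hazard of HR 0.6 per
    standardized unit on the TCT:M2TAM ratio signature.
    """

    n_types: int = 3
    samples_per_type: int | list[int] = 100
    n_background_genes: int = 60
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    active_fraction: float = 0.4
    noise_sd: float = 1.0
    type_sd: float = 0.5  # SD of per-type per-gene baseline offsets
    baseline_shape: float = 1.2
    baseline_scale: float = 3.0
    betas: dict[str, float] = field(
        default_factory=lambda: {"TCT:M2TAM": math.log(0.6)}
    )
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.015,  # per year, around the cohort mean
            "stage[3]": 0.3,
            "stage[4]": 0.6,
            "cytoreduction[Optimal]": 0.0,
            "cytoreduction[Unknown]": 0.0,
        }
    )
    censor_time: float = 5.0
    endpoint: str = "OS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.baseline_shape <= 0:
            raise ValueError("baseline_shape must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")

    def per_type_counts(self) -> list[int]:
        if isinstance(self.samples_per_type, int):
            return [self.samples_per_type] * self.n_types
        if len(self.samples_per_type) != self.n_types:
            raise ValueError("samples_per_type list must have n_types entries")
        return list(self.samples_per_type)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # linear-scale counts
    truth: dict
    clinical: pd.DataFrame | None = None
    config: SimulationConfig | None = None


def _signature_names(config: SimulationConfig) -> list[str]:
    """Module names plus any ratio signatures ("NUM:DEN") referenced in
    the true betas."""
    names = [m.name for m in config.modules]
    for s in config.betas:
        if ":" in s and s not in names:
            names.append(s)
    return names


def simulate_expression(config: SimulationConfig) -> SyntheticCohort:
    """Draw the expression matrix and the truth record (no survival yet).

    Raises if gene names collide across modules/background or the
    configuration violates its invariants.
    """
    rng = np.random.default_rng((config.seed, 0))
    counts = config.per_type_counts()
    type_names = [f"type_{i + 1}" for i in range(config.n_types)]
    sample_ids: list[str] = []
    sample_type: list[str] = []
    for tname, k in zip(type_names, counts):
        for j in range(k):
            sample_ids.append(f"{tname}_s{j + 1:04d}")
            sample_type.append(tname)
    n_samples = len(sample_ids)

    module_genes: list[str] = []
    membership: dict[str, str] = {}
    for mod in config.modules:
        for g in mod.gene_names():
            if g in membership:
                raise ValueError(f"gene name {g!r} appears in more than one module")
            membership[g] = mod.name
            module_genes.append(g)
    background = [f"BG_g{i + 1}" for i in range(config.n_background_genes)]
    overlap = set(background) & set(module_genes)
    if overlap:
        raise ValueError(f"background gene names collide with modules: {sorted(overlap)[:5]}")
    genes = module_genes + background
    n_genes = len(genes)

    active = rng.random(n_samples) < config.active_fraction

    # per-gene baseline on log2 scale, plus per-(type, gene) offsets
    base = rng.uniform(3.0, 9.0, size=n_genes)
    type_offsets = rng.normal(0.0, config.type_sd, size=(config.n_types, n_genes))
    type_index = np.array([type_names.index(t) for t in sample_type])

    log2 = np.empty((n_genes, n_samples))
    log2[:] = base[:, None] + type_offsets[type_index, :].T

    gi = {g: i for i, g in enumerate(genes)}
    for mod in config.modules:
        rho = mod.within_corr
        factor = rng.normal(0.0, 1.0, size=n_samples)
        h = mod.shift_heterogeneity
        for g in mod.gene_names():
            eps = rng.normal(0.0, 1.0, size=n_samples)
            dev = math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * eps
            gene_shift = mod.active_shift * rng.uniform(1.0 - h, 1.0 + h)
            log2[gi[g]] += config.noise_sd * dev + gene_shift * active
    for g in background:
        log2[gi[g]] += config.noise_sd * rng.normal(0.0, 1.0, size=n_samples)

    annotations = pd.DataFrame(
        {"cancer_type": sample_type, "cohort": "synthetic"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    log2_df = pd.DataFrame(log2, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    log2_matrix = ExpressionMatrix(log2_df, LOG2, annotations)
    counts_df = np.round(np.power(2.0, log2_df)).clip(lower=0.0)
    expression = ExpressionMatrix(counts_df, LINEAR, annotations)

    # true scores: uniform-weight signatures over the generating log2 values
    raw_scores: dict[str, pd.Series] = {}
    z_scores: dict[str, pd.Series] = {}
    for mod in config.modules:
        sig = SignatureDefinition(mod.name, mod.gene_names())
        s = raw_score(log2_matrix, sig)
        raw_scores[mod.name] = s
        z_scores[mod.name] = standardize(s, name=mod.name).z
    for name in _signature_names(config):
        if ":" in name:
            num, den = name.split(":", 1)
            if num not in raw_scores or den not in raw_scores:
                raise ValueError(f"ratio signature {name!r} references unknown module")
            sc = ratio_score(raw_scores[num], raw_scores[den], name=name)
            raw_scores[name] = sc.raw
            z_scores[name] = sc.z

    truth = {
        "log2": log2_matrix,
        "membership": membership,
        "background_genes": background,
        "active": pd.Series(active, index=sample_ids, name="immune_active"),
        "raw_scores": pd.DataFrame(raw_scores),
        "z_scores": pd.DataFrame(z_scores),
        "betas": dict(config.betas),
    }
    return SyntheticCohort(expression=expression, truth=truth, config=config)


def simulate_survival(
    cohort: SyntheticCohort, config: SimulationConfig | None = None
) -> SyntheticCohort:
    """Fill in the clinical table of a simulated cohort.

    Event times come from inverse-transform sampling of the Weibull
    baseline ``S0(t) = exp(-(t/scale)^shape)`` under the proportional
    hazards ``h(t) = h0(t) * exp(lp)``:

        T = scale * (-log(U) / exp(lp))**(1/shape)

    with the linear predictor summing true signature effects (on the
    standardized scale) and clinical-covariate effects.  Times are
    censored administratively at ``censor_time``.
    """
    config = config or cohort.config
    if config is None:
        raise ValueError("no configuration available")
    rng = np.random.default_rng((config.seed, 1))
    z = cohort.truth["z_scores"]
    unknown = [s for s in config.betas if s not in z.columns]
    if unknown:
        raise ValueError(f"betas reference unknown signature(s): {unknown}")
    sample_ids = list(z.index)
    n = len(sample_ids)

    age = np.clip(rng.normal(57.0, 11.0, size=n), 30.0, 90.0)
    stage = rng.choice(STAGE_LEVELS, size=n, p=STAGE_PROBS)
    cyto = rng.choice(CYTO_LEVELS, size=n, p=CYTO_PROBS)

    cb = config.covariate_betas
    lp = np.zeros(n)
    for sig, beta in config.betas.items():
        lp += beta * z[sig].to_numpy(dtype=float)
    lp += cb.get("age", 0.0) * (age - age.mean())
    lp += cb.get("stage[3]", 0.0) * (stage == "3")
    lp += cb.get("stage[4]", 0.0) * (stage == "4")
    lp += cb.get("cytoreduction[Optimal]", 0.0) * (cyto == "Optimal")
    lp += cb.get("cytoreduction[Unknown]", 0.0) * (cyto == "Unknown")

    u = rng.uniform(size=n)
    t_event = config.baseline_scale * np.power(
        -np.log(u) / np.exp(lp), 1.0 / config.baseline_shape
    )
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    # survival times must stay strictly positive
    time = np.maximum(time, min(1e-8, config.censor_time))

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "endpoint": config.endpoint,
            "age": age,
            "stage": stage,
            "cytoreduction": cyto,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for sig in z.columns:
        clinical[f"Z_{sig}"] = z[sig].to_numpy(dtype=float)
    return SyntheticCohort(
        expression=cohort.expression,
        truth={**cohort.truth, "event_times": pd.Series(t_event, index=sample_ids)},
        clinical=clinical,
        config=config,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Expression, truth and clinical table in one call."""
    return simulate_survival(simulate_expression(config), config)
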