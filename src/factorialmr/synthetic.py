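"""Synthetic survival-cohort generator with known ground truth.

Emulates the statistical structure a factorial Mendelian-randomization
analysis assumes: Hardy-Weinberg genotypes at independent (clumped)
variants, biomarkers equal to a weighted genetic score plus Gaussian noise
(with optional cross-trait pleiotropy), standard epidemiological covariates
(age, sex, assessment center, 10 genetic principal components), and
administratively censored survival outcomes from an exponential
proportional-hazards model whose linear predictor combines score, covariate
and optional score-product (interaction) effects.

Every generating parameter is recorded in a JSON ground-truth sidecar so
estimator-recovery experiments can compare estimates against truth without
hard-coding anything.

Seeding: one global seed; per-component substreams are spawned from it in a
fixed documented order (per-score genotypes, covariates, biomarkers,
per-outcome survival), so regenerating any cohort from its sidecar is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .scores import WeightTable, compute_score

__all__ = [
    "ScoreConfig",
    "BiomarkerConfig",
    "OutcomeConfig",
    "GeneratorConfig",
    "CohortTable",
    "GenerationError",
    "generate_genotypes",
    "generate_biomarkers",
    "generate_survival",
    "generate_cohort",
    "make_score_config",
    "default_weight_tables",
]

N_PCS = 10

_WEIGHTS_DIR = Path(__file__).parent / "data" / "weights"

#: score name -> unit for the shipped fixture weight tables
DEFAULT_SCORE_UNITS = {
    "lpa": "mg/dL",
    "hmgcr": "mg/dL",
    "npc1l1": "mg/dL",
    "pcsk9": "mg/dL",
    "ldlr": "mg/dL",
    "ldl": "mg/dL",
    "bmi": "kg/m2",
    "sbp": "mmHg",
    "smoking": "SD",
    "alcohol": "SD",
    "activity": "SD",
}


class GenerationError(RuntimeError):
    """Raised when a cohort cannot be generated from the given parameters."""


# --------------------------------------------------------------------------
# configuration dataclasses (all fields serialize to/from the JSON sidecar)
# --------------------------------------------------------------------------


@dataclass
class ScoreConfig:
    """One genetic score: variant frequencies and per-allele trait effects."""

    variant_ids: list
    freqs: np.ndarray
    betas: np.ndarray
    unit: str = "mg/dL"
    effect_alleles: list | None = None

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.effect_alleles is not None:
            self.effect_alleles = list(self.effect_alleles)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def score_mean(self) -> float:
        """E[S] = sum_j 2 p_j beta_j under Hardy-Weinberg."""
        return float(np.sum(2.0 * self.freqs * self.betas))

    def score_sd(self) -> float:
        """sd(S) = sqrt(sum_j 2 p_j (1-p_j) beta_j^2)."""
        return float(np.sqrt(np.sum(2.0 * self.freqs * (1.0 - self.freqs) * self.betas**2)))

    def weight_table(self, trait: str) -> WeightTable:
        alleles = self.effect_alleles or ["A"] * self.n_variants
        return WeightTable(
            variant_id=self.variant_ids,
            effect_allele=alleles,
            eaf=self.freqs,
            beta=self.betas,
            trait=trait,
            unit=self.unit,
        )


@dataclass
class BiomarkerConfig:
    """Measured biomarker = intercept + sum_s loading_s * score_s + N(0, noise_sd).

    Off-trait loadings encode cross-trait pleiotropy (e.g. an Lp(a) score
    with a negative loading on triglycerides).
    """

    intercept: float
    loadings: dict  # score name -> trait units per score unit
    noise_sd: float
    unit: str = "mg/dL"


@dataclass
class OutcomeConfig:
    """Exponential proportional-hazards outcome.

    ``baseline_hazard`` is events per person-year at the reference covariate
    pattern; ``log_hr_per_unit`` maps score names to the log hazard ratio
    per score unit; ``interaction_log_hr`` multiplies the product of the two
    standardized scores named by the generator's ``interaction_pair``.
    """

    baseline_hazard: float
    log_hr_per_unit: dict = field(default_factory=dict)
    interaction_log_hr: float = 0.0


@dataclass
class GeneratorConfig:
    """Complete ground truth for one synthetic cohort."""

    n_individuals: int
    scores: dict  # name -> ScoreConfig
    biomarkers: dict  # name -> BiomarkerConfig
    outcomes: dict  # name -> OutcomeConfig
    interaction_pair: tuple | None = None
    age_mean: float = 56.7
    age_sd: float = 8.0
    male_frac: float = 0.46
    n_centers: int = 10
    age_log_hr: float = 0.05
    sex_log_hr: float = 0.4
    center_log_hrs: list = None
    pc_log_hrs: list = None
    admin_censor_time: float = 12.25
    seed: int = 0

    def __post_init__(self):
        if self.center_log_hrs is None:
            self.center_log_hrs = [0.0] * self.n_centers
        if self.pc_log_hrs is None:
            self.pc_log_hrs = [0.0] * N_PCS
        if self.interaction_pair is not None:
            self.interaction_pair = tuple(self.interaction_pair)
        self.validate()

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not (0 < self.male_frac < 1):
            raise ValueError("male_frac must lie in (0,1)")
        if self.age_sd <= 0 or self.n_centers < 1:
            raise ValueError("age_sd must be > 0 and n_centers >= 1")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        if len(self.center_log_hrs) != self.n_centers:
            raise ValueError("center_log_hrs length must equal n_centers")
        if len(self.pc_log_hrs) != N_PCS:
            raise ValueError(f"pc_log_hrs must have length {N_PCS}")
        for name, sc in self.scores.items():
            if np.any(sc.freqs <= 0) or np.any(sc.freqs >= 1):
                raise ValueError(f"score {name!r}: allele frequencies must lie in (0,1)")
            if len(sc.freqs) != len(sc.betas) or len(sc.freqs) != sc.n_variants:
                raise ValueError(f"score {name!r}: inconsistent variant dimensions")
        for name, bm in self.biomarkers.items():
            if bm.noise_sd < 0:
                raise ValueError(f"biomarker {name!r}: noise_sd must be >= 0")
            unknown = set(bm.loadings) - set(self.scores)
            if unknown:
                raise ValueError(f"biomarker {name!r}: loadings on unknown scores {sorted(unknown)}")
        for name, oc in self.outcomes.items():
            if oc.baseline_hazard <= 0:
                raise ValueError(f"outcome {name!r}: baseline_hazard must be > 0")
            unknown = set(oc.log_hr_per_unit) - set(self.scores)
            if unknown:
                raise ValueError(f"outcome {name!r}: effects for unknown scores {sorted(unknown)}")
            if oc.interaction_log_hr != 0.0 and self.interaction_pair is None:
                raise ValueError(f"outcome {name!r}: interaction effect set but no interaction_pair")
        if self.interaction_pair is not None:
            missing = set(self.interaction_pair) - set(self.scores)
            if missing:
                raise ValueError(f"interaction_pair names unknown scores {sorted(missing)}")

    # -- sidecar (ground-truth) serialization ------------------------------
    def to_json_dict(self) -> dict:
        d = asdict(self)
        for name, sc in d["scores"].items():
            sc["freqs"] = list(map(float, sc["freqs"]))
            sc["betas"] = list(map(float, sc["betas"]))
        if d["interaction_pair"] is not None:
            d["interaction_pair"] = list(d["interaction_pair"])
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["scores"] = {k: ScoreConfig(**v) for k, v in d["scores"].items()}
        d["biomarkers"] = {k: BiomarkerConfig(**v) for k, v in d["biomarkers"].items()}
        d["outcomes"] = {k: OutcomeConfig(**v) for k, v in d["outcomes"].items()}
        if d.get("interaction_pair") is not None:
            d["interaction_pair"] = tuple(d["interaction_pair"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneratorConfig):
            return NotImplemented
        return self.to_json_dict() == other.to_json_dict()

    # -- factories ----------------------------------------------------------
    @classmethod
    def default(cls, n_individuals: int = 50_000, seed: int = 0) -> "GeneratorConfig":
        """Default cohort emulating the UK Biobank analysis population.

        Scores come from the shipped fixture weight tables; biomarker
        intercepts and noise are calibrated so the measured Lp(a), LDL-C and
        triglyceride columns match the published cohort means/SDs (17.6/19.7,
        138.0/33.6, 154.9/90.6 mg/dL) and so median-split group contrasts
        land at the published forest-plot magnitudes.
        """
        tables = default_weight_tables()
        scores = {
            name: ScoreConfig(
                variant_ids=list(wt.variant_id),
                freqs=wt.eaf,
                betas=wt.beta,
                unit=DEFAULT_SCORE_UNITS.get(name, "SD"),
                effect_alleles=list(wt.effect_allele),
            )
            for name, wt in tables.items()
        }
        s = {k: v.score_mean() for k, v in scores.items()}
        ldl_contributors = ["hmgcr", "npc1l1", "pcsk9", "ldlr", "ldl"]
        biomarkers = {
            "lpa": BiomarkerConfig(
                intercept=17.6 - s["lpa"], loadings={"lpa": 1.0}, noise_sd=15.4
            ),
            "ldl_c": BiomarkerConfig(
                intercept=138.0 - sum(s[k] for k in ldl_contributors) - 0.072 * s["lpa"],
                loadings={**{k: 1.0 for k in ldl_contributors}, "lpa": 0.072},
                noise_sd=32.9,
            ),
            "tg": BiomarkerConfig(
                intercept=154.9 + 0.165 * s["lpa"],
                loadings={"lpa": -0.165},
                noise_sd=90.6,
            ),
        }
        # per-unit log hazard ratios; the lpa entries are -log(HR50)/50 for
        # per-50-mg/dL-decrease hazard ratios spanning 0.73 (PAD) to 0.95 (VTE)
        def lpa_beta(hr50):
            return -float(np.log(hr50)) / 50.0

        ldl_beta = {"cad": 0.00713, "stroke": 0.004, "hf": 0.003, "pad": 0.005,
                    "vte": 0.0, "cv_death": 0.006}
        lifestyle = {
            "bmi": {"cad": 0.05, "stroke": 0.04, "hf": 0.07, "pad": 0.04, "vte": 0.05, "cv_death": 0.05},
            "sbp": {"cad": 0.02, "stroke": 0.025, "hf": 0.02, "pad": 0.015, "vte": 0.0, "cv_death": 0.02},
            "smoking": {"cad": 0.15, "stroke": 0.12, "hf": 0.10, "pad": 0.25, "vte": 0.05, "cv_death": 0.18},
            "alcohol": {"cad": 0.05, "stroke": 0.06, "hf": 0.05, "pad": 0.04, "vte": 0.02, "cv_death": 0.06},
            "activity": {"cad": -0.10, "stroke": -0.08, "hf": -0.12, "pad": -0.08, "vte": -0.04, "cv_death": -0.12},
        }
        hr50 = {"cad": 0.85, "stroke": 0.90, "hf": 0.90, "pad": 0.73, "vte": 0.95, "cv_death": 0.85}
        lam0 = {"cad": 0.012, "stroke": 0.008, "hf": 0.008, "pad": 0.006, "vte": 0.004, "cv_death": 0.006}
        outcomes = {}
        for oc in hr50:
            eff = {"lpa": lpa_beta(hr50[oc]), "ldl": ldl_beta[oc]}
            for t in ("hmgcr", "npc1l1", "pcsk9", "ldlr"):
                eff[t] = ldl_beta[oc]
            for arm, per in lifestyle.items():
                eff[arm] = per[oc]
            outcomes[oc] = OutcomeConfig(baseline_hazard=lam0[oc], log_hr_per_unit=eff)
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        n_centers = 10
        return cls(
            n_individuals=n_individuals,
            scores=scores,
            biomarkers=biomarkers,
            outcomes=outcomes,
            interaction_pair=("lpa", "ldlr"),
            n_centers=n_centers,
            center_log_hrs=list(rng.normal(0.0, 0.03, n_centers)),
            pc_log_hrs=[0.01] * N_PCS,
            seed=seed,
        )


def make_score_config(
    n_variants: int,
    target_sd: float,
    rng: np.random.Generator,
    unit: str = "mg/dL",
    prefix: str = "snp",
    freq_range: tuple = (0.05, 0.95),
) -> ScoreConfig:
    """Draw a synthetic score: uniform frequencies, normal betas rescaled so
    the theoretical Hardy-Weinberg score SD equals ``target_sd`` exactly."""
    freqs = rng.uniform(*freq_range, n_variants)
    betas = rng.normal(0.0, 1.0, n_variants)
    sd0 = float(np.sqrt(np.sum(2 * freqs * (1 - freqs) * betas**2)))
    betas = betas * (target_sd / sd0)
    ids = [f"{prefix}{i:04d}" for i in range(n_variants)]
    return ScoreConfig(variant_ids=ids, freqs=freqs, betas=betas, unit=unit)


def default_weight_tables() -> dict:
    """Load the shipped fixture weight tables (one per score arm).

    Variant counts mirror the published instrument sets (43 Lp(a), 26 HMGCR,
    6 NPC1L1, 42 PCSK9, 52 LDLR, 237 overall LDL-C, 62 BMI, 455 SBP,
    248 smoking, 98 alcohol, 16 physical activity); frequencies and weights
    are synthetic.
    """
    from .scores import read_weights

    tables = {}
    for path in sorted(_WEIGHTS_DIR.glob("*.tsv")):
        name = path.stem
        tables[name] = read_weights(path, unit=DEFAULT_SCORE_UNITS.get(name, "SD"))
    if not tables:
        raise FileNotFoundError(f"no weight tables found under {_WEIGHTS_DIR}")
    return tables


# --------------------------------------------------------------------------
# cohort container
# --------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Individuals x {dosages, covariates, biomarkers, survival outcomes}.

    ``data`` holds one row per individual: ``iid``, ``age``, ``sex`` (1 =
    male), ``center``, ``pc1..pc10``, one column per biomarker, ``time_<o>``
    / ``event_<o>`` per outcome, and one integer dosage column per variant.
    """

    data: pd.DataFrame
    variant_ids: list
    biomarkers: list
    outcomes: list

    def __len__(self) -> int:
        return len(self.data)

    def dosages(self) -> pd.DataFrame:
        return self.data[self.variant_ids]

    def survival(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        if outcome not in self.outcomes:
            raise KeyError(f"unknown outcome {outcome!r}; have {self.outcomes}")
        return (
            self.data[f"time_{outcome}"].to_numpy(float),
            self.data[f"event_{outcome}"].to_numpy(int),
        )

    def validate(self, admin_censor_time: float | None = None) -> None:
        df = self.data
        if df.isna().any().any():
            raise ValueError("cohort contains missing values")
        for oc in self.outcomes:
            t = df[f"time_{oc}"].to_numpy(float)
            e = df[f"event_{oc}"].to_numpy(int)
            if np.any(t <= 0):
                raise ValueError(f"outcome {oc!r}: non-positive follow-up time")
            if admin_censor_time is not None and np.any(t[e == 1] > admin_censor_time):
                raise ValueError(f"outcome {oc!r}: event after administrative censoring")
        dos = df[self.variant_ids].to_numpy()
        if not np.isin(dos, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_files(cls, cohort_tsv, sidecar_json) -> tuple["CohortTable", GeneratorConfig]:
        config = GeneratorConfig.from_json(sidecar_json)
        df = pd.read_csv(cohort_tsv, sep="\t")
        variant_ids = [v for sc in config.scores.values() for v in sc.variant_ids]
        table = cls(
            data=df,
            variant_ids=variant_ids,
            biomarkers=list(config.biomarkers),
            outcomes=list(config.outcomes),
        )
        return table, config


# --------------------------------------------------------------------------
# generation operations
# --------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genotypes(freqs, n: int, seed) -> np.ndarray:
    """Hardy-Weinberg dosages: entry (i,j) ~ Binomial(2, freqs[j]), independent."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValueError("allele frequencies must lie strictly in (0,1)")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(seed)
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)


def generate_biomarkers(score_values: dict, biomarkers: dict, seed) -> pd.DataFrame:
    """Biomarkers as linear combinations of true scores plus Gaussian noise."""
    rng = _as_rng(seed)
    n = len(next(iter(score_values.values()))) if score_values else 0
    cols = {}
    for name, bm in biomarkers.items():
        if bm.noise_sd < 0:
            raise ValueError(f"biomarker {name!r}: noise_sd must be >= 0")
        y = np.full(n, float(bm.intercept))
        for score_name, loading in bm.loadings.items():
            if score_name not in score_values:
                raise KeyError(f"biomarker {name!r} loads on unknown score {score_name!r}")
            y = y + loading * np.asarray(score_values[score_name], dtype=float)
        if bm.noise_sd > 0:
            y = y + rng.normal(0.0, bm.noise_sd, n)
        cols[name] = y
    return pd.DataFrame(cols)


def _standardized(sc: ScoreConfig, values: np.ndarray) -> np.ndarray:
    """Standardize a score by its theoretical Hardy-Weinberg mean and SD."""
    sd = sc.score_sd()
    if sd == 0:
        raise GenerationError("cannot standardize a zero-variance score")
    return (values - sc.score_mean()) / sd


def generate_survival(
    score_values: dict,
    covariates: pd.DataFrame,
    config: GeneratorConfig,
    seed,
) -> pd.DataFrame:
    """Draw (time, event) per outcome from the exponential PH model.

    The linear predictor is sum_s beta_s S_is + covariate effects (age
    centered at its generating mean) + the optional interaction term on the
    product of the two theoretically standardized scores.  Event times are
    exponential with rate lambda_0 exp(eta); administrative censoring at
    ``admin_censor_time``.
    """
    rng = _as_rng(seed)
    n = len(covariates)
    eta_cov = (
        config.age_log_hr * (covariates["age"].to_numpy(float) - config.age_mean)
        + config.sex_log_hr * covariates["sex"].to_numpy(float)
        + np.asarray(config.center_log_hrs)[covariates["center"].to_numpy(int)]
        + sum(
            config.pc_log_hrs[k - 1] * covariates[f"pc{k}"].to_numpy(float)
            for k in range(1, N_PCS + 1)
        )
    )
    prod = None
    if config.interaction_pair is not None:
        a, b = config.interaction_pair
        prod = _standardized(config.scores[a], score_values[a]) * _standardized(
            config.scores[b], score_values[b]
        )
    out = {}
    C = config.admin_censor_time
    for name, oc in config.outcomes.items():
        eta = eta_cov.copy()
        for score_name, beta in oc.log_hr_per_unit.items():
            eta = eta + beta * np.asarray(score_values[score_name], dtype=float)
        if oc.interaction_log_hr != 0.0:
            eta = eta + oc.interaction_log_hr * prod
        bad = np.flatnonzero(~np.isfinite(eta))
        if bad.size:
            raise GenerationError(
                f"outcome {name!r}: non-finite linear predictor for individual(s) "
                f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''}"
            )
        rate = oc.baseline_hazard * np.exp(eta)
        t_event = rng.exponential(1.0 / rate)
        event = (t_event <= C).astype(int)
        time = np.minimum(t_event, C)
        out[f"time_{name}"] = np.maximum(time, 1e-12)
        out[f"event_{name}"] = event
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a complete cohort from a validated :class:`GeneratorConfig`.

    Substream order: one genotype stream per score (config order), then
    covariates, biomarkers, and one survival stream per outcome.
    """
    config.validate()
    n = config.n_individuals
    n_streams = len(config.scores) + 2 + len(config.outcomes)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n_streams)]
    it = iter(streams)

    dosage_frames = []
    score_values = {}
    for name, sc in config.scores.items():
        G = generate_genotypes(sc.freqs, n, next(it))
        frame = pd.DataFrame(G, columns=sc.variant_ids)
        dosage_frames.append(frame)
        score_values[name] = compute_score(frame, sc.weight_table(name))

    rng_cov = next(it)
    covariates = pd.DataFrame(
        {
            "age": rng_cov.normal(config.age_mean, config.age_sd, n),
            "sex": rng_cov.binomial(1, config.male_frac, n),
            "center": rng_cov.integers(0, config.n_centers, n),
        }
    )
    pcs = rng_cov.normal(0.0, 1.0, (n, N_PCS))
    for k in range(N_PCS):
        covariates[f"pc{k + 1}"] = pcs[:, k]

    biomarker_df = generate_biomarkers(score_values, config.biomarkers, next(it))

    # one spawned stream per outcome, consumed inside generate_survival in order
    surv_parts = []
    for name, oc in config.outcomes.items():
        surv = generate_survival(
            score_values,
            covariates,
            _single_outcome_view(config, name),
            next(it),
        )
        surv_parts.append(surv)
    survival_df = pd.concat(surv_parts, axis=1)

    data = pd.concat(
        [pd.DataFrame({"iid": np.arange(n)}), covariates, biomarker_df, survival_df]
        + dosage_frames,
        axis=1,
    )
    cohort = CohortTable(
        data=data,
        variant_ids=[v for f in dosage_frames for v in f.columns],
        biomarkers=list(config.biomarkers),
        outcomes=list(config.outcomes),
    )
    cohort.validate(admin_censor_time=config.admin_censor_time)
    return cohort


def _single_outcome_view(config: GeneratorConfig, outcome: str) -> GeneratorConfig:
    """A shallow config restricted to one outcome (keeps per-outcome streams
    independent of how many outcomes precede it in the dict)."""
    view = GeneratorConfig.__new__(GeneratorConfig)
    view.__dict__.update(config.__dict__)
    view.outcomes = {outcome: config.outcomes[outcome]}
    return view
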