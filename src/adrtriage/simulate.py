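"""Synthetic ADR report generator.

Emulates the statistical structure the assessment pipeline assumes: eleven
independent Bernoulli Boolean predictors, a true causality category drawn
from a partial proportional-odds law on those predictors, reporter-side
assessments obtained by adding clamped ordinal noise to the true category,
a provincial expert assessment equal to the true category but masked as
missing for the (large) unreviewed fraction, and a serious-ADE flag equal to
the OR of the six severity items.

Defaults mirror the study conditions of a provincial spontaneous-reporting
corpus: 20,022 labeled reports, ~85% of reports without a provincial
assessment, most reports naming a suspect drug, and severity items that are
individually rare.  Covariates are generated independently; real SRS data
are correlated, which this generator deliberately does not model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelPartition, PPOParameters
from .schema import (
    CAUSALITY_COLUMNS,
    PREDICTOR_COLUMNS,
    SEVERITY_COLUMNS,
    ReportTable,
)

__all__ = [
    "SimulationConfig",
    "default_true_model",
    "default_config",
    "simulate_reports",
    "marginal_category_distribution",
    "make_fixture",
    "FIXTURE_NAMES",
]

def _read_maybe_path(source: str | Path) -> str:
    """Accept either a JSON string or a path to a JSON file."""
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    text = str(source)
    if text.lstrip().startswith("{"):
        return text
    return Path(text).read_text(encoding="utf-8")


#: Default predictor prevalences, in schema order: the five causality items
#: (time relationship, known type, dechallenge, rechallenge, alternative
#: explanation) are common to moderately rare; the six severity items
#: (death .. other significant event) are rare.
DEFAULT_PREVALENCE = (
    0.75, 0.65, 0.45, 0.08, 0.20,
    0.015, 0.005, 0.02, 0.02, 0.10, 0.06,
)

#: Reporter noise: symmetric distribution over offsets -2..+2 applied to the
#: true category and clamped to [1, 5].
DEFAULT_NOISE = {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}


def default_true_model(nonparallel_var: str = "casualty_assessment_5") -> PPOParameters:
    """The named default data-generating parameter set.

    Cut points are logit(j/5) (uniform marginal at x = 0); parallel slopes
    are a fixed-seed standard-normal draw scaled by 0.8; the chosen
    non-parallel variable carries the decreasing slope vector
    (1.2, 0.8, 0.4, 0.2), which keeps cumulative curves monotone for Boolean
    inputs while clearly violating the parallel assumption.
    """
    from scipy.special import logit

    theta = logit(np.arange(1, 5) / 5.0)
    parallel = tuple(v for v in PREDICTOR_COLUMNS if v != nonparallel_var)
    rng = np.random.default_rng(20190101)
    beta = rng.standard_normal(len(parallel)) * 0.8
    tau = np.array([[1.2], [0.8], [0.4], [0.2]])
    return PPOParameters(theta, beta, tau, ModelPartition(parallel, (nonparallel_var,)))


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic report table."""

    n: int = 20022
    prevalence: tuple[float, ...] = DEFAULT_PREVALENCE
    true_model: PPOParameters = field(default_factory=default_true_model)
    reporter_noise: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    missing_prov_rate: float = 0.85
    suspect_rate: float = 0.80
    new_ade_rate: float = 0.15
    gender_rate: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.prevalence) + [
            self.missing_prov_rate, self.suspect_rate, self.new_ade_rate, self.gender_rate,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.prevalence) != len(PREDICTOR_COLUMNS):
            raise ValueError("prevalence must have 11 entries")
        total = sum(self.reporter_noise.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reporter noise distribution sums to {total}, not 1")
        if any(o not in (-2, -1, 0, 1, 2) for o in self.reporter_noise):
            raise ValueError("noise offsets must lie in -2..2")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["true_model"] = {
            "theta": self.true_model.theta.tolist(),
            "beta": self.true_model.beta.tolist(),
            "tau": self.true_model.tau.tolist(),
            "parallel_vars": list(self.true_model.partition.parallel_vars),
            "nonparallel_vars": list(self.true_model.partition.nonparallel_vars),
        }
        doc["reporter_noise"] = {str(k): v for k, v in self.reporter_noise.items()}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        doc = json.loads(_read_maybe_path(source))
        tm = doc.pop("true_model")
        doc["true_model"] = PPOParameters(
            np.array(tm["theta"]), np.array(tm["beta"]), np.array(tm["tau"]),
            ModelPartition(tuple(tm["parallel_vars"]), tuple(tm["nonparallel_vars"])),
        )
        doc["reporter_noise"] = {int(k): v for k, v in doc["reporter_noise"].items()}
        doc["prevalence"] = tuple(doc["prevalence"])
        return cls(**doc)


def default_config(**overrides) -> SimulationConfig:
    """The shipped default configuration, with keyword overrides."""
    return SimulationConfig(**overrides)


def _category_probs(model: PPOParameters, X: np.ndarray) -> np.ndarray:
    """True category probabilities; errors on non-monotone patterns."""
    F = model.cumulative_probabilities(X)
    n = F.shape[0]
    probs = np.diff(np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))]), axis=1)
    if (probs < -1e-12).any():
        i = int(np.argmax((probs < -1e-12).any(axis=1)))
        raise ValueError(
            f"true model gives non-monotone cumulative probabilities at x = {X[i].tolist()}"
        )
    return np.clip(probs, 0.0, None)


def simulate_reports(config: SimulationConfig | None = None) -> ReportTable:
    """Draw one labeled report table; fully reproducible from ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n
    model = config.true_model

    X = (rng.random((n, 11)) < np.asarray(config.prevalence)[None, :]).astype(int)
    # reorder columns into the model's partition order for probability lookup
    order = [PREDICTOR_COLUMNS.index(v) for v in model.var_names]
    probs = _category_probs(model, X[:, order].astype(float))
    u = rng.random(n)
    truth = 1 + (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)

    offsets = np.array(sorted(config.reporter_noise))
    weights = np.array([config.reporter_noise[int(o)] for o in offsets])
    noisy = {}
    for col in ("r_assess", "ri_assess", "muni_assess"):
        off = rng.choice(offsets, size=n, p=weights)
        noisy[col] = np.clip(truth + off, 1, 5)

    prov = truth.copy()
    prov[rng.random(n) < config.missing_prov_rate] = -1

    df = pd.DataFrame(X, columns=list(PREDICTOR_COLUMNS))
    df["new_ade"] = (rng.random(n) < config.new_ade_rate).astype(int)
    df["serious_ade"] = (df[list(SEVERITY_COLUMNS)].to_numpy() == 1).any(axis=1).astype(int)
    df["gender"] = (rng.random(n) < config.gender_rate).astype(int)
    df["suspect"] = (rng.random(n) < config.suspect_rate).astype(int)
    for col in ("r_assess", "ri_assess", "muni_assess"):
        df[col] = noisy[col]
    df["prov_assess"] = prov
    df["label"] = truth
    return ReportTable(df, source=f"simulated(seed={config.seed})")


def marginal_category_distribution(config: SimulationConfig | None = None) -> np.ndarray:
    """Model-implied marginal P(Y = 1..5) under the covariate law.

    Computed by exhaustive summation over all 2^11 Boolean predictor
    patterns weighted by their Bernoulli probabilities — the analytic
    reference the Monte-Carlo generator is checked against.
    """
    config = config or SimulationConfig()
    model = config.true_model
    prev = np.asarray(config.prevalence)
    patterns = np.array(list(product((0, 1), repeat=11)), dtype=float)
    w = np.prod(np.where(patterns == 1, prev[None, :], 1 - prev[None, :]), axis=1)
    order = [PREDICTOR_COLUMNS.index(v) for v in model.var_names]
    probs = _category_probs(model, patterns[:, order])
    return w @ probs


# ---------------------------------------------------------------------------
# deterministic fixtures

FIXTURE_NAMES = ("table3_like", "planted_fig5", "all_branches")


def _blank_frame(n: int) -> pd.DataFrame:
    df = pd.DataFrame(0, index=range(n), columns=list(PREDICTOR_COLUMNS))
    for c in ("new_ade", "serious_ade", "gender", "suspect"):
        df[c] = 0
    for c in CAUSALITY_COLUMNS:
        df[c] = 3
    return df


def make_fixture(name: str) -> ReportTable:
    """Small deterministic tables used throughout the test-suite.

    ``table3_like``
        Nine rows reproducing the published reports-of-interest pattern:
        serious reports with model assessment 4 (one row: 5) against
        reporter-side assessments (1, 1, 3) and provincial assessment 4.
        The designated model assessment is stored in ``planted_auto``.
    ``planted_fig5``
        A 1,000-row table, already extended with ``auto_assess``/``risk_s``/
        ``risk_t``, in which exactly 7 planted rows satisfy the
        opposite-assessment triage query (suspect drug, risk_s < -8,
        provincial assessment > 3, reporter-side assessments <= 3).
    ``all_branches``
        25 rows covering every (Y, Y0) pair in {1..5}^2 (Y0 in
        ``ri_assess``, designated Y in ``planted_auto``).
    """
    if name == "table3_like":
        autos = [4, 4, 5, 4, 4, 4, 4, 4, 4]
        df = _blank_frame(len(autos))
        df["severity_assessment_4"] = 1          # life-threatening -> serious
        df["serious_ade"] = 1
        df["suspect"] = 1
        df["r_assess"] = 1
        df["ri_assess"] = 1
        df["muni_assess"] = 3
        df["prov_assess"] = 4
        df["planted_auto"] = autos
        return ReportTable(df, source="fixture:table3_like")

    if name == "all_branches":
        pairs = list(product(range(1, 6), range(1, 6)))
        df = _blank_frame(len(pairs))
        df["planted_auto"] = [y for y, _ in pairs]
        df["ri_assess"] = [y0 for _, y0 in pairs]
        return ReportTable(df, source="fixture:all_branches")

    if name == "planted_fig5":
        from .triage import extend_reports

        rng = np.random.default_rng(51)
        n = 1000
        df = _blank_frame(n)
        df["suspect"] = (rng.random(n) < 0.8).astype(int)
        df["severity_assessment_5"] = (rng.random(n) < 0.15).astype(int)
        df["serious_ade"] = df["severity_assessment_5"]
        for c in CAUSALITY_COLUMNS:
            df[c] = rng.integers(1, 6, size=n)
        autos = rng.integers(1, 6, size=n)
        # keep background rows off the target region: make serious rows agree
        serious = df["serious_ade"].to_numpy() == 1
        autos[serious] = df.loc[serious, "ri_assess"].to_numpy()
        planted = rng.choice(n, size=7, replace=False)
        df.loc[planted, "suspect"] = 1
        df.loc[planted, "severity_assessment_5"] = 1
        df.loc[planted, "serious_ade"] = 1
        df.loc[planted, "r_assess"] = 1
        df.loc[planted, "ri_assess"] = 1
        df.loc[planted, "muni_assess"] = 3
        df.loc[planted, "prov_assess"] = 4
        autos[planted] = 4                        # d = -3, serious -> s = -12
        df["planted"] = 0
        df.loc[planted, "planted"] = 1
        table = ReportTable(df, source="fixture:planted_fig5")
        return extend_reports(table, predictions=autos)

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
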