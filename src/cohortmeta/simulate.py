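"""Seeded generator of multi-cohort expression studies with known truth.

The generator emulates the statistical structure a multi-cohort biomarker
evaluation assumes: nine cohorts with the tumor/control group sizes of the
mRNA studies analysed (159/4, 58/17, 7/4, 3/3, 25/3, 3/3, 25/8, 18/18,
10/6), approximately normal per-gene log2 expression, a target gene planted
with a large positive standardized mean difference, blocks of up- and
down-regulated genes, a latent factor inducing co-expression with the
target, per-cohort batch shifts, IHC field scores whose expected specimen
IRS matches the in-house groups (~6.8 tumor, ~2.2 control; 110/47), and
exponential survival whose hazard depends on high target expression.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimulationSpec.seed``, so the same spec reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CONTROL, TUMOR, ExpressionCohort, IHCRecord

#: Tumor/control sample counts of the nine mRNA cohorts (merged platforms
#: counted once), in the order GPL11154, GPL570, then the single-study rows.
DEFAULT_COHORT_SIZES: tuple[tuple[int, int], ...] = (
    (159, 4),
    (58, 17),
    (7, 4),
    (3, 3),
    (25, 3),
    (3, 3),
    (25, 8),
    (18, 18),
    (10, 6),
)

DEFAULT_COHORT_IDS: tuple[str, ...] = (
    "COH01",
    "COH02",
    "COH03",
    "COH04",
    "COH05",
    "COH06",
    "COH07",
    "COH08",
    "COH09",
)

# Group-specific per-field multinomials calibrated so that the expected
# field IRS (intensity x proportion, independent draws) is ~6.8 for tumors
# and ~2.2 for controls, matching the in-house IHC group means.
DEFAULT_TUMOR_INTENSITY = (0.05, 0.15, 0.35, 0.45)  # E = 2.20
DEFAULT_TUMOR_PROPORTION = (0.02, 0.05, 0.18, 0.31, 0.44)  # E = 3.10
DEFAULT_CONTROL_INTENSITY = (0.30, 0.35, 0.30, 0.05)  # E = 1.10
DEFAULT_CONTROL_PROPORTION = (0.10, 0.25, 0.30, 0.25, 0.10)  # E = 2.00


@dataclass
class IHCSpec:
    n_tumor: int = 110
    n_control: int = 47
    n_fields: int = 10
    tumor_intensity: tuple[float, ...] = DEFAULT_TUMOR_INTENSITY
    tumor_proportion: tuple[float, ...] = DEFAULT_TUMOR_PROPORTION
    control_intensity: tuple[float, ...] = DEFAULT_CONTROL_INTENSITY
    control_proportion: tuple[float, ...] = DEFAULT_CONTROL_PROPORTION


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.02  # events per month in the low group
    hazard_ratio: float = 4.0  # multiplier for the high-expression group
    censor_rate: float = 0.005  # exponential censoring hazard per month

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be nonnegative")


@dataclass
class SimulationSpec:
    """Parameters of one simulated multi-cohort study."""

    seed: int = 0
    cohorts: Sequence[tuple[int, int]] = DEFAULT_COHORT_SIZES
    n_genes: int = 1000
    target_name: str = "TARGET"
    target_smd: float = 3.0
    target_loading: float = 0.7
    n_up: int = 50
    n_down: int = 50
    deg_delta: float = 2.0  # log2 units, applied +/- to planted DEGs
    coexpr_block: int = 50
    loading: float = 0.7
    batch_sd: float = 1.0  # SD of the per-cohort additive offset
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    stage_effect: float = 0.0  # extra target log2 shift in stage III/IV tumors
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    ihc: IHCSpec = field(default_factory=IHCSpec)

    def __post_init__(self) -> None:
        if any(n1 < 1 or n0 < 1 for n1, n0 in self.cohorts):
            raise ValueError("all cohort group sizes must be positive")
        if not abs(self.loading) < 1 or not abs(self.target_loading) < 1:
            raise ValueError("latent-factor loadings must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if 1 + self.n_up + self.n_down + self.coexpr_block > self.n_genes:
            raise ValueError(
                "infeasible spec: target + planted blocks exceed n_genes"
            )

    @property
    def target_sd(self) -> float:
        """Within-group SD of the target gene (latent loading + noise)."""
        return math.sqrt(self.target_loading**2 + self.noise_sd**2)

    @property
    def target_delta(self) -> float:
        """Tumor-control mean shift planting the requested SMD."""
        return self.target_smd * self.target_sd

    def gene_names(self) -> list[str]:
        names = [self.target_name]
        names += [f"UP{i:04d}" for i in range(1, self.n_up + 1)]
        names += [f"DN{i:04d}" for i in range(1, self.n_down + 1)]
        names += [f"CO{i:04d}" for i in range(1, self.coexpr_block + 1)]
        n_null = self.n_genes - len(names)
        names += [f"NULL{i:04d}" for i in range(1, n_null + 1)]
        return names

    def expected_coexpr_r(self, tumor_fraction: float = 0.0) -> float:
        """Closed-form Pearson r between a block gene and the target.

        cov = loading * target_loading (shared unit-variance latent);
        block-gene variance = loading^2 + noise^2; target variance adds the
        between-group spread p(1-p) delta^2 when groups are mixed with tumor
        fraction p.
        """
        lam_b, lam_t, s2 = self.loading, self.target_loading, self.noise_sd**2
        var_target = lam_t**2 + s2 + tumor_fraction * (1 - tumor_fraction) * self.target_delta**2
        return lam_b * lam_t / math.sqrt((lam_b**2 + s2) * var_target)


def _truth_table(spec: SimulationSpec) -> pd.DataFrame:
    names = spec.gene_names()
    role = (
        ["target"]
        + ["up"] * spec.n_up
        + ["down"] * spec.n_down
        + ["coexpr"] * spec.coexpr_block
        + ["null"] * (spec.n_genes - 1 - spec.n_up - spec.n_down - spec.coexpr_block)
    )
    true_lfc = np.zeros(spec.n_genes)
    true_lfc[0] = spec.target_delta
    true_lfc[1 : 1 + spec.n_up] = spec.deg_delta
    true_lfc[1 + spec.n_up : 1 + spec.n_up + spec.n_down] = -spec.deg_delta
    loading = np.zeros(spec.n_genes)
    loading[0] = spec.target_loading
    start = 1 + spec.n_up + spec.n_down
    loading[start : start + spec.coexpr_block] = spec.loading
    true_smd = true_lfc / np.where(loading != 0, np.sqrt(loading**2 + spec.noise_sd**2), spec.noise_sd)
    return pd.DataFrame(
        {"gene": names, "role": role, "true_log2fc": true_lfc, "loading": loading, "true_smd": true_smd}
    ).set_index("gene")


def simulate_cohorts(spec: SimulationSpec) -> tuple[list[ExpressionCohort], pd.DataFrame]:
    """Simulate the multi-cohort expression study described by ``spec``.

    Per gene g and sample s in cohort c:
    ``x = baseline_g + batch_c + delta_g * 1[tumor] + loading_g * f_s + eps``
    with latent factor f ~ N(0,1) per sample and eps ~ N(0, noise_sd^2).
    Returns the cohorts (log2 scale) plus a truth table of planted roles,
    log2 fold changes, loadings and true SMDs.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_table(spec)
    names = list(truth.index)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    delta = truth["true_log2fc"].to_numpy()
    loading = truth["loading"].to_numpy()

    cohorts = []
    for idx, (n1, n0) in enumerate(spec.cohorts):
        cohort_id = (
            DEFAULT_COHORT_IDS[idx] if idx < len(DEFAULT_COHORT_IDS) else f"COH{idx + 1:02d}"
        )
        n = n1 + n0
        is_tumor = np.array([True] * n1 + [False] * n0)
        batch_shift = rng.normal(0.0, spec.batch_sd)
        latent = rng.normal(0.0, 1.0, size=n)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

        matrix = (
            baseline[:, None]
            + batch_shift
            + np.outer(delta, is_tumor.astype(float))
            + np.outer(loading, latent)
            + noise
        )

        # clinical covariates: age, sex for everyone; stage for tumors only,
        # with the planted stage effect added to the target gene
        age = rng.integers(30, 80, size=n)
        sex = rng.choice(["male", "female"], size=n)
        stage = np.array(
            [rng.choice(["I", "II", "III", "IV"]) if t else "" for t in is_tumor]
        )
        late = np.isin(stage, ["III", "IV"])
        matrix[0, late] += spec.stage_effect

        samples = [f"{cohort_id}_S{j + 1:03d}" for j in range(n)]
        covariates = pd.DataFrame(
            {"age": age, "sex": sex, "stage": stage}, index=samples
        )
        cohorts.append(
            ExpressionCohort(
                cohort_id=cohort_id,
                platform_id=f"SIMPLAT{idx + 1:02d}",
                matrix=pd.DataFrame(matrix, index=names, columns=samples),
                group=pd.Series(np.where(is_tumor, TUMOR, CONTROL), index=samples),
                covariates=covariates,
                is_log_scale=True,
            )
        )
    return cohorts, truth


def simulate_ihc(spec: SimulationSpec) -> list[IHCRecord]:
    """Simulate per-specimen IHC field scores from group multinomials.

    Intensity and proportion categories are drawn independently per field,
    with group-specific distributions calibrated to the in-house group
    means (expected specimen IRS ~6.8 tumor, ~2.2 control).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    ihc = spec.ihc
    records = []
    for group, count, p_int, p_prop in (
        (TUMOR, ihc.n_tumor, ihc.tumor_intensity, ihc.tumor_proportion),
        (CONTROL, ihc.n_control, ihc.control_intensity, ihc.control_proportion),
    ):
        for i in range(count):
            intensities = rng.choice(4, size=ihc.n_fields, p=p_int)
            proportions = rng.choice(5, size=ihc.n_fields, p=p_prop)
            records.append(
                IHCRecord(
                    specimen_id=f"{group.upper()}{i + 1:03d}",
                    group=group,
                    fields=list(zip(intensities.tolist(), proportions.tolist())),
                    covariates={
                        "age": int(rng.integers(30, 80)),
                        "sex": str(rng.choice(["male", "female"])),
                    },
                )
            )
    return records


def simulate_survival(
    spec: SimulationSpec, expression: Sequence[float], seed_offset: int = 2
) -> pd.DataFrame:
    """Simulate (time, event) for samples given their target-gene expression.

    Event times are exponential with hazard ``baseline_hazard``, multiplied
    by ``hazard_ratio`` for samples at or above the median expression;
    censoring times are independent exponentials at ``censor_rate`` (a rate
    of 0 observes every event). Times are in months.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, seed_offset)))
    x = np.asarray(expression, dtype=float)
    high = x >= np.median(x)
    hazard = spec.survival.baseline_hazard * np.where(high, spec.survival.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if spec.survival.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.survival.censor_rate, size=len(x))
    else:
        censor_time = np.full(len(x), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event})
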