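"""Synthetic cohort generation.

Emulates a resting-state ageing cohort: per-subject parcellated BOLD-like
time series with a controllable within-/between-network correlation
structure, a 14-test cognitive battery with a planted two-factor structure,
and demographic confounds (age, sex, education, cognitive screening score)
whose correlations with latent cognition can be calibrated to target values.

The generative chain is

    confounds ──β──┐
                   ├─> latent cognition ──loadings──> battery scores
    segregation ─β─┘
        │
        └────────────────> per-subject correlation matrix ──> time series

so that every downstream stage (graph construction, strength features,
cognitive composites, ML benchmarking) has a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationSpec",
    "CohortSpec",
    "BatterySpec",
    "SyntheticCohort",
    "make_parcellation",
    "simulate_timeseries",
    "calibrate_confounds",
    "simulate_battery",
    "generate_cohort",
]


@dataclass(frozen=True)
class ParcellationSpec:
    """Assignment of P nodes to K functional networks.

    ``labels`` holds a 1-based network index per node, mirroring a
    400-node / 7-network (or 800-node) cortical parcellation.
    """

    node_count: int
    network_count: int
    labels: np.ndarray  # shape (P,), values in 1..K
    network_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.node_count,):
            raise ValueError("labels length must equal node_count")
        if labels.min(initial=1) < 1 or labels.max(initial=1) > self.network_count:
            raise ValueError("labels must lie in 1..network_count")
        counts = np.bincount(labels, minlength=self.network_count + 1)[1:]
        if (counts == 0).any():
            empty = int(np.where(counts == 0)[0][0] + 1)
            raise ValueError(f"network {empty} is empty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.network_count + 1)[1:]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    rho_within / rho_between set the baseline block correlations; each
    subject receives a segregation offset ``delta ~ N(0, segregation_sd)``
    applied antagonistically (+within, -between) so a single scalar controls
    how segregated that subject's connectome is.  ``effect_beta`` couples
    the standardized segregation offset into latent cognition;
    ``confound_betas`` are the (age, education, sex) correlations with
    latent cognition; ``age_segregation_beta`` optionally couples
    standardized age into the segregation offset so that connectivity
    features can be made confound-driven.
    """

    n_subjects: int
    timepoints: int = 296
    rho_within: float = 0.35
    rho_between: float = 0.18
    segregation_sd: float = 0.06
    effect_beta: float = 0.0
    confound_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    age_segregation_beta: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("require 0 <= rho_between <= rho_within < 1")
        if self.n_subjects < 1 or self.timepoints < 8:
            raise ValueError("need n_subjects >= 1 and timepoints >= 8")


def _default_loadings(n_tests: int = 14) -> np.ndarray:
    """Two-factor block loading pattern: tests 1-9 on the global/non-verbal
    factor, tests 10-14 on the verbal factor."""
    L = np.zeros((n_tests, 2))
    split = int(round(n_tests * 9 / 14))
    L[:split, 0] = 0.75
    L[split:, 1] = 0.75
    return L


@dataclass(frozen=True)
class BatterySpec:
    """Cognitive test battery structure (14 tests, two planted factors)."""

    n_tests: int = 14
    loadings: np.ndarray = field(default_factory=_default_loadings)
    unique_sd: float = 0.5
    invert_flags: np.ndarray = field(
        default_factory=lambda: np.zeros(14, dtype=bool)
    )
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        L = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        object.__setattr__(self, "loadings", L)
        object.__setattr__(
            self, "invert_flags", np.asarray(self.invert_flags, dtype=bool)
        )
        if L.shape[0] != self.n_tests:
            raise ValueError("loadings rows must equal n_tests")
        if not np.isfinite(L).all():
            raise ValueError("loadings must be finite")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if self.invert_flags.shape != (self.n_tests,):
            raise ValueError("invert_flags length must equal n_tests")


@dataclass
class SyntheticCohort:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    timeseries: list[np.ndarray]  # each (P, T)
    battery_raw: pd.DataFrame  # subjects x tests, NaN for missing
    confounds: pd.DataFrame  # age, sex, education, screening
    truth: pd.DataFrame  # latent_cognition, segregation
    parcellation: ParcellationSpec
    spec: CohortSpec

    def __post_init__(self) -> None:
        n = len(self.timeseries)
        for comp in (self.battery_raw, self.confounds, self.truth):
            if len(comp) != n:
                raise ValueError("inconsistent subject counts across components")


def make_parcellation(
    P: int,
    K: int,
    proportions: list[float] | None = None,
    network_names: list[str] | None = None,
) -> ParcellationSpec:
    """Contiguous block assignment of ``P`` nodes to ``K`` networks.

    With no ``proportions`` the split is as equal as possible (remainders go
    to the first networks).  Deterministic for fixed inputs.
    """
    if K < 1 or P < K:
        raise ValueError(f"P={P} nodes cannot fill K={K} non-empty networks")
    if proportions is not None:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (K,) or not np.isclose(props.sum(), 1.0):
            raise ValueError("proportions must have length K and sum to 1")
        sizes = np.maximum(1, np.floor(props * P).astype(int))
        # distribute the remainder deterministically by largest fraction
        while sizes.sum() < P:
            sizes[np.argmax(props * P - sizes)] += 1
        while sizes.sum() > P:
            big = np.where(sizes > 1)[0]
            sizes[big[np.argmin((props * P - sizes)[big])]] -= 1
    else:
        base, rem = divmod(P, K)
        sizes = np.full(K, base)
        sizes[:rem] += 1
    labels = np.repeat(np.arange(1, K + 1), sizes)
    names = tuple(network_names) if network_names else None
    return ParcellationSpec(P, K, labels, names)


def _clip_offsets(spec: CohortSpec, delta: np.ndarray) -> np.ndarray:
    """Clip per-subject offsets so block correlations stay feasible.

    The factor construction below requires
    0 <= rho_between - delta <= rho_within + delta < 1, which also keeps the
    implied block-exchangeable correlation matrix positive semi-definite.
    """
    lo = -(spec.rho_within - spec.rho_between) / 2.0
    hi_b = spec.rho_between  # rho_between - delta >= 0
    hi_w = 1.0 - spec.rho_within - 1e-6  # rho_within + delta < 1
    return np.clip(delta, lo, min(hi_b, hi_w))


def simulate_timeseries(
    parcellation: ParcellationSpec,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    offsets: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw per-subject node x time series with block-constant correlations.

    Subject s has target within-block correlation rho_within + delta_s and
    between-block correlation rho_between - delta_s.  The series are built
    from a shared global factor, one factor per network and white node
    noise, which guarantees the target matrix is positive semi-definite:

        x_i = sqrt(rho_b) g + sqrt(rho_w - rho_b) f_net(i) + sqrt(1 - rho_w) e_i

    Returns (timeseries, offsets_used).  Offsets outside the feasible range
    are clipped (and the clipped values reported).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    P, T = parcellation.node_count, spec.timepoints
    if offsets is None:
        offsets = rng.normal(0.0, spec.segregation_sd, size=spec.n_subjects)
    offsets = _clip_offsets(spec, np.asarray(offsets, dtype=float))
    labels0 = parcellation.labels - 1
    K = parcellation.network_count
    series: list[np.ndarray] = []
    for s in range(spec.n_subjects):
        rho_w = spec.rho_within + offsets[s]
        rho_b = spec.rho_between - offsets[s]
        if not (0 <= rho_b <= rho_w < 1):
            raise RuntimeError(
                f"subject {s}: infeasible block correlations after clipping "
                f"(within={rho_w:.3f}, between={rho_b:.3f})"
            )
        g = rng.standard_normal(T)
        f = rng.standard_normal((K, T))
        e = rng.standard_normal((P, T))
        x = (
            np.sqrt(rho_b) * g
            + np.sqrt(rho_w - rho_b) * f[labels0]
            + np.sqrt(1.0 - rho_w) * e
        )
        series.append(x)
    return series, offsets


def block_correlation_target(
    parcellation: ParcellationSpec, rho_within: float, rho_between: float
) -> np.ndarray:
    """The implied P x P target correlation matrix (unit diagonal)."""
    same = parcellation.labels[:, None] == parcellation.labels[None, :]
    C = np.where(same, rho_within, rho_between)
    np.fill_diagonal(C, 1.0)
    return C


def calibrate_confounds(
    targets: dict[str, float] | None = None,
    n: int = 500,
    rng: np.random.Generator | int | None = None,
    frac_low_screening: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the confound table and the betas that realize target
    cognition correlations.

    age ~ Uniform[55, 85]; sex ~ Bernoulli(0.5); education is a discretized
    normal on 1..10 with mean 6.5 and SD 1.9 (emulating the cohort's
    demographics); screening is an integer 0..18 score with an optional
    planted fraction <= 8 so the exclusion rule is exercisable.

    Because the confounds are generated (near-)independent, a latent
    cognition of the form ``c = b.z + sqrt(1 - |b|^2) eps`` has
    corr(c, confound_j) ~= b_j, so the returned betas are simply the target
    correlations (validated for feasibility).
    """
    targets = dict(targets or {})
    b = np.array(
        [targets.get("age", 0.0), targets.get("education", 0.0), targets.get("sex", 0.0)]
    )
    if np.any(np.abs(b) >= 1):
        raise ValueError("target correlations must satisfy |r| < 1")
    if b @ b >= 1:
        raise ValueError("joint correlation targets infeasible (sum of r^2 >= 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    age = rng.uniform(55.0, 85.0, size=n)
    sex = rng.integers(0, 2, size=n)
    education = np.clip(np.rint(rng.normal(6.5, 1.9, size=n)), 1, 10).astype(int)
    screening = np.full(n, 0)
    n_low = int(round(frac_low_screening * n))
    screening[:n_low] = rng.integers(0, 9, size=n_low)
    screening[n_low:] = rng.integers(9, 19, size=n - n_low)
    perm = rng.permutation(n)
    table = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "education": education,
            "screening": screening[perm],
        }
    )
    return table, b


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_battery(
    spec: BatterySpec,
    confounds: pd.DataFrame,
    latent_cognition: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Battery raw scores from latent cognition and unique noise.

    Both planted factors load on latent cognition (the global factor more
    strongly), plus factor-specific variance, so an eigenvalue>1 PCA on the
    z-scored battery recovers the two-factor structure while a forced
    one-component solution tracks global cognition.  Tests whose
    ``invert_flags`` entry is true are emitted on the inverted scale (higher
    raw value = worse performance).  Missing cells are injected completely
    at random at ``missing_rate``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(confounds)
    c = np.asarray(latent_cognition, dtype=float)
    if c.shape != (n,):
        raise ValueError("latent_cognition length must match confounds")
    n_factors = spec.loadings.shape[1]
    # factor f_j = w_j * c + sqrt(1-w_j^2) * specific_j
    w = np.full(n_factors, 0.75)
    if n_factors >= 1:
        w[0] = 0.85
    factors = w * c[:, None] + np.sqrt(1 - w**2) * rng.standard_normal((n, n_factors))
    scores = factors @ spec.loadings.T + spec.unique_sd * rng.standard_normal(
        (n, spec.n_tests)
    )
    scores[:, spec.invert_flags] *= -1.0
    if spec.missing_rate > 0:
        mask = rng.random((n, spec.n_tests)) < spec.missing_rate
        scores = np.where(mask, np.nan, scores)
    cols = [f"test_{i + 1:02d}" for i in range(spec.n_tests)]
    return pd.DataFrame(scores, columns=cols, index=confounds.index)


def generate_cohort(
    parcellation: ParcellationSpec,
    spec: CohortSpec,
    battery: BatterySpec | None = None,
    confound_targets: dict[str, float] | None = None,
    frac_low_screening: float = 0.0,
) -> SyntheticCohort:
    """Full cohort: confounds -> latent cognition -> battery + time series.

    ``spec.confound_betas`` is overridden by ``confound_targets`` when the
    latter is given (targets are correlations, which equal betas under the
    independence construction used here).  Determinism: the whole cohort is
    a function of ``spec.seed``.
    """
    battery = battery or BatterySpec()
    ss = np.random.SeedSequence(spec.seed)
    r_conf, r_seg, r_ts, r_bat = [np.random.default_rng(s) for s in ss.spawn(4)]

    confounds, b = calibrate_confounds(
        confound_targets, spec.n_subjects, r_conf, frac_low_screening
    )
    if confound_targets is None:
        b = np.asarray(spec.confound_betas, dtype=float)
    z_age = _standardize(confounds["age"].to_numpy())
    z_edu = _standardize(confounds["education"].to_numpy())
    z_sex = _standardize(confounds["sex"].to_numpy(dtype=float))

    delta_raw = r_seg.normal(0.0, spec.segregation_sd, size=spec.n_subjects)
    if spec.age_segregation_beta != 0.0 and spec.segregation_sd > 0:
        a = spec.age_segregation_beta
        delta_raw = spec.segregation_sd * (
            a * z_age + np.sqrt(max(0.0, 1 - a**2)) * delta_raw / spec.segregation_sd
        )
    series, delta = simulate_timeseries(parcellation, spec, rng=r_ts, offsets=delta_raw)

    seg_z = _standardize(delta) if spec.segregation_sd > 0 else np.zeros_like(delta)
    explained = float(b @ b) + spec.effect_beta**2
    resid = np.sqrt(max(0.0, 1.0 - min(explained, 1.0)))
    latent = (
        b[0] * z_age
        + b[1] * z_edu
        + b[2] * z_sex
        + spec.effect_beta * seg_z
        + resid * spec.noise_sd * r_bat.standard_normal(spec.n_subjects)
    )
    battery_raw = simulate_battery(battery, confounds, latent, r_bat)
    truth = pd.DataFrame(
        {"latent_cognition": latent, "segregation": delta},
        index=confounds.index,
    )
    return SyntheticCohort(series, battery_raw, confounds, truth, parcellation, spec)


def subject_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Assemble the subjects.tsv layout: id, confounds, test columns."""
    n = len(cohort.confounds)
    table = pd.concat(
        [
            pd.Series([f"sub-{i + 1:04d}" for i in range(n)], name="subject_id"),
            cohort.confounds.reset_index(drop=True),
            cohort.battery_raw.reset_index(drop=True),
        ],
        axis=1,
    )
    return table
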