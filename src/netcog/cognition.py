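"""Cognitive-target construction.

Screening-based exclusion, sex x age-band cell-median imputation,
inversion and z-scoring of the 14-test battery, KMO sampling adequacy,
PCA composites (eigenvalue>1 rule or a forced one-component global
solution) with varimax rotation, split-half stability, median-split /
extreme-group construction, and 1:1 propensity-score matching with balance
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from statsmodels.multivariate.factor_rotation import rotate_factors

TEST_COLS = [f"test_{i:02d}" for i in range(1, 15)]

__all__ = [
    "ComponentSolution",
    "GroupAssignment",
    "MatchedSample",
    "screen_subjects",
    "impute_by_cell",
    "invert_zscore",
    "kmo_index",
    "pca_components",
    "component_stability",
    "make_groups",
    "propensity_match",
    "CognitivePCA",
]


def _test_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("test_")]
    if not cols:
        raise ValueError("no test_* columns found")
    return cols


def screen_subjects(
    table: pd.DataFrame, min_screen: int = 9, max_missing: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects failing the cognitive screening or with too many
    missing tests.

    Excluded: screening score <= ``min_screen - 1`` (i.e. <= 8 by default),
    missing screening, or more than ``max_missing`` missing test values.
    Returns (retained table, exclusion log with one reason per subject).
    """
    cols = _test_columns(table)
    reasons = []
    keep = np.ones(len(table), dtype=bool)
    screening = table["screening"] if "screening" in table else pd.Series(
        np.nan, index=table.index
    )
    n_missing = table[cols].isna().sum(axis=1)
    for i, idx in enumerate(table.index):
        s = screening.loc[idx]
        if pd.isna(s):
            keep[i] = False
            reasons.append((idx, "missing screening score"))
        elif s < min_screen:
            keep[i] = False
            reasons.append((idx, f"screening score {s:g} below cutoff"))
        elif n_missing.loc[idx] > max_missing:
            keep[i] = False
            reasons.append((idx, f"{int(n_missing.loc[idx])} missing tests"))
    log = pd.DataFrame(reasons, columns=["subject", "reason"])
    return table.loc[keep].copy(), log


DEFAULT_AGE_BANDS = ((55, 64), (65, 74), (75, 85))


def _age_band(age: float, bands) -> int:
    for k, (lo, hi) in enumerate(bands):
        if lo <= age <= hi:
            return k
    # outside the stated range: nearest band
    return 0 if age < bands[0][0] else len(bands) - 1


def impute_by_cell(
    table: pd.DataFrame, age_bands=DEFAULT_AGE_BANDS
) -> pd.DataFrame:
    """Replace each missing test value by the median of that test within
    the subject's sex x age-band cell (closed bands [55,64], [65,74],
    [75,85] by default).  Non-missing cells are never altered."""
    cols = _test_columns(table)
    out = table.copy()
    band = table["age"].map(lambda a: _age_band(a, age_bands))
    for col in cols:
        if not out[col].isna().any():
            continue
        for (sex, b), idx in out.groupby([table["sex"], band]).groups.items():
            cell = out.loc[idx, col]
            if not cell.isna().any():
                continue
            med = cell.median(skipna=True)
            if pd.isna(med):
                raise ValueError(
                    f"cannot impute {col}: cell sex={sex}, age band {b} "
                    "has no observed values"
                )
            out.loc[idx, col] = cell.fillna(med)
    return out


def invert_zscore(
    table: pd.DataFrame,
    invert_flags: np.ndarray | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Negate invert-flagged tests (higher raw = worse) and z-score every
    test column (population SD by default; ``ddof=1`` for sample SD)."""
    cols = _test_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("battery must be complete before z-scoring")
    if invert_flags is not None:
        flags = np.asarray(invert_flags, dtype=bool)
        X = X * np.where(flags, -1.0, 1.0)
    sd = X.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = cols[int(np.where(sd == 0)[0][0])]
        raise ValueError(f"test {bad} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    return pd.DataFrame(Z, columns=cols, index=table.index)


def kmo_index(z: pd.DataFrame | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations obtained from the inverse
    correlation matrix.
    """
    X = np.asarray(z, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("KMO requires at least 3 tests")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


@dataclass
class ComponentSolution:
    """Retained (optionally varimax-rotated) PCA components."""

    loadings: pd.DataFrame  # tests x components
    eigenvalues: np.ndarray  # all eigenvalues, descending
    scores: pd.DataFrame  # subjects x components, zero mean, unit variance
    kmo: float
    rotation: str
    n_components_rule: str


def _fix_signs(L: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for k in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, k])), k] < 0:
            L[:, k] *= -1.0
            S[:, k] *= -1.0
    return L, S


def pca_components(
    z: pd.DataFrame,
    rule: str = "eigenvalue_gt_1",
    rotate: str = "varimax",
    forced_k: int = 1,
    tol: float = 1e-8,
) -> ComponentSolution:
    """PCA on the test correlation matrix with optional varimax rotation.

    ``rule='eigenvalue_gt_1'`` retains components with eigenvalue > 1;
    ``rule='forced_k'`` retains exactly ``forced_k`` (1 for the global
    cognition composite).  Loadings are eigenvectors scaled by sqrt of the
    eigenvalue; scores are unit-variance component scores; rotation is
    applied to loadings and scores jointly.  Component sign is fixed so the
    largest-magnitude loading is positive; rotated components are ordered
    by explained variance (sum of squared loadings).
    """
    cols = list(z.columns)
    X = z.to_numpy(dtype=float)
    n = X.shape[0]
    R = (X.T @ X) / n
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    if rule == "eigenvalue_gt_1":
        k = int((evals > 1.0 + tol).sum())
        if k == 0:
            raise ValueError("eigenvalue>1 rule retains no components")
    elif rule == "forced_k":
        k = forced_k
        if not 1 <= k <= len(evals):
            raise ValueError(f"forced_k={k} out of range")
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    lam = evals[:k]
    V = evecs[:, :k]
    L = V * np.sqrt(lam)
    # unit-variance unrotated scores: Z V / sqrt(lambda)
    S = X @ V / np.sqrt(lam)
    if rotate == "varimax" and k > 1:
        L, T = rotate_factors(L, "varimax")
        S = S @ T
    elif rotate not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotate!r}")
    # order rotated components by explained variance, fix signs
    idx = np.argsort(-(L**2).sum(axis=0))
    L, S = _fix_signs(L[:, idx].copy(), S[:, idx].copy())
    names = [f"PC{j + 1}" for j in range(k)]
    return ComponentSolution(
        loadings=pd.DataFrame(L, index=cols, columns=names),
        eigenvalues=evals,
        scores=pd.DataFrame(S, index=z.index, columns=names),
        kmo=kmo_index(X),
        rotation=rotate if k > 1 else "none",
        n_components_rule=rule,
    )


def match_components(
    La: pd.DataFrame | np.ndarray, Lb: pd.DataFrame | np.ndarray
) -> list[tuple[int, int, float]]:
    """Greedy matching of components; returns (index in a, index in b,
    sign-aligned Pearson loading correlation) triples.

    Matching runs on the uncentered cosine (Tucker congruence) matrix —
    centered correlation cannot disambiguate complementary block patterns,
    which are mutually (anti-)correlated near +/-1 — while the reported
    similarity is the conventional |Pearson r| of the matched loadings.
    """
    A = np.asarray(La, dtype=float)
    B = np.asarray(Lb, dtype=float)
    norm_a = np.linalg.norm(A, axis=0)
    norm_b = np.linalg.norm(B, axis=0)
    C = (A.T @ B) / np.outer(norm_a, norm_b)
    pearson = np.corrcoef(A.T, B.T)[: A.shape[1], A.shape[1] :]
    pairs = []
    used_a, used_b = set(), set()
    for _ in range(min(A.shape[1], B.shape[1])):
        best = None
        for i in range(A.shape[1]):
            if i in used_a:
                continue
            for j in range(B.shape[1]):
                if j in used_b:
                    continue
                if best is None or abs(C[i, j]) > abs(C[best[0], best[1]]):
                    best = (i, j)
        i, j = best
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, float(abs(pearson[i, j]))))
    return pairs


def component_stability(
    z: pd.DataFrame,
    mode: str = "split_half",
    rng: np.random.Generator | int | None = None,
    rule: str = "eigenvalue_gt_1",
    rotate: str = "varimax",
    complete_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Loading stability across data subsets.

    split_half: random halves, PCA per half, matched-component |Pearson r|
    of loadings.  drop_imputed: PCA on the complete-case subset
    (``complete_mask``) vs the full sample.  If the halves retain different
    component counts the matched subset is correlated and flagged.
    """
    if len(z) < 40:
        raise ValueError("need n >= 40 for a stability analysis")
    if mode == "split_half":
        rng = (
            np.random.default_rng(rng)
            if not isinstance(rng, np.random.Generator)
            else rng
        )
        perm = rng.permutation(len(z))
        half = len(z) // 2
        za, zb = z.iloc[perm[:half]], z.iloc[perm[half:]]
    elif mode == "drop_imputed":
        if complete_mask is None:
            raise ValueError("drop_imputed mode needs complete_mask")
        za, zb = z.loc[np.asarray(complete_mask)], z
    else:
        raise ValueError(f"unknown stability mode {mode!r}")
    sa = pca_components(za, rule=rule, rotate=rotate)
    sb = pca_components(zb, rule=rule, rotate=rotate)
    ka, kb = sa.loadings.shape[1], sb.loadings.shape[1]
    rows = [
        {"component_a": i + 1, "component_b": j + 1, "loading_r": r,
         "count_mismatch": ka != kb}
        for i, j, r in match_components(sa.loadings, sb.loadings)
    ]
    return pd.DataFrame(rows)


@dataclass
class GroupAssignment:
    labels: pd.Series  # 'high' | 'low' | 'excluded'
    scheme: str
    component_index: int = 0

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


def make_groups(
    scores: pd.Series | np.ndarray, scheme: str = "median", q: float = 0.25
) -> GroupAssignment:
    """High/low performance groups from a component score.

    median: score > median -> high, else low (exact ties -> low, a fixed
    convention for determinism).  extreme_quartiles: top q -> high, bottom
    q -> low, middle excluded.
    """
    s = pd.Series(scores).astype(float)
    if len(s) < 4:
        raise ValueError("need at least 4 subjects to form groups")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if scheme == "median":
        med = s.median()
        labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
        if (s == s.iloc[0]).all():
            warnings.warn("all scores equal: every subject labelled low")
    elif scheme == "extreme_quartiles":
        lo_cut, hi_cut = s.quantile(q), s.quantile(1 - q)
        labels = pd.Series("excluded", index=s.index)
        labels[s >= hi_cut] = "high"
        labels[s <= lo_cut] = "low"
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    return GroupAssignment(labels=labels, scheme=scheme)


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's-d style SMD with a pooled (average-variance) denominator."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    s = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / s) if s > 0 else 0.0


@dataclass
class MatchedSample:
    retained: pd.Index
    propensity: pd.Series
    balance: pd.DataFrame  # per covariate: smd/statistic/p, pre and post
    caliper: float = field(default=0.2)


def _balance_row(name, high, low, kind) -> dict:
    if kind == "continuous":
        t, p = stats.ttest_ind(high, low)
        stat = float(t)
    else:
        tab = pd.crosstab(
            np.concatenate([np.ones(len(high)), np.zeros(len(low))]),
            np.concatenate([high, low]),
        )
        if tab.shape == (2, 2):
            chi2, p, _, _ = stats.chi2_contingency(tab)
        else:  # degenerate: one sex only
            chi2, p = 0.0, 1.0
        stat = float(chi2)
    return {
        "covariate": name,
        "smd": standardized_mean_difference(high, low),
        "statistic": stat,
        "p": float(p),
    }


def propensity_match(
    groups: GroupAssignment,
    confounds: pd.DataFrame,
    caliper: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> MatchedSample:
    """1:1 greedy nearest-neighbour propensity matching without replacement.

    Logistic regression of group on (age, sex, education) gives the
    propensity; matching runs on the logit with a caliper of
    ``caliper`` x SD(logit).  Returns the retained ids plus a balance
    report (SMD and t-test for age/education, chi-square for sex) before
    and after matching.
    """
    covars = ["age", "sex", "education"]
    high, low = groups.high, groups.low
    if len(high) < 10 or len(low) < 10:
        raise ValueError("need at least 10 subjects per group for matching")
    ids = high.append(low)
    X = confounds.loc[ids, covars].to_numpy(dtype=float)
    y = np.concatenate([np.ones(len(high)), np.zeros(len(low))])
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    model = LogisticRegression(C=np.inf, max_iter=1000)
    model.fit(Xs, y)
    logit = Xs @ model.coef_.ravel() + model.intercept_[0]
    logit_s = pd.Series(logit, index=ids)
    cal = caliper * logit.std(ddof=1)

    # greedy without replacement, globally ordered by |logit distance|:
    # symmetric under swapping the group labels, deterministic
    lh = logit_s.loc[high].to_numpy()
    ll = logit_s.loc[low].to_numpy()
    dist = np.abs(lh[:, None] - ll[None, :])
    order = np.argsort(dist, axis=None, kind="stable")
    used_h = np.zeros(len(high), dtype=bool)
    used_l = np.zeros(len(low), dtype=bool)
    pairs: list[tuple] = []
    max_pairs = min(len(high), len(low))
    for flat in order:
        i, j = divmod(int(flat), len(low))
        if dist[i, j] > cal:
            break
        if used_h[i] or used_l[j]:
            continue
        used_h[i] = used_l[j] = True
        pairs.append((high[i], low[j]))
        if len(pairs) == max_pairs:
            break
    if not pairs:
        raise ValueError("no matches found within the caliper")
    retained = pd.Index([i for pair in pairs for i in pair])
    if len(pairs) < max_pairs:
        warnings.warn(
            f"caliper shrunk the matched sample to {len(pairs)} pairs "
            f"from {max_pairs} candidates"
        )

    rows = []
    for phase, (hi_idx, lo_idx) in {
        "pre": (high, low),
        "post": (retained.intersection(high), retained.intersection(low)),
    }.items():
        for name in covars:
            kind = "binary" if name == "sex" else "continuous"
            row = _balance_row(
                name,
                confounds.loc[hi_idx, name].to_numpy(dtype=float),
                confounds.loc[lo_idx, name].to_numpy(dtype=float),
                kind,
            )
            row["phase"] = phase
            rows.append(row)
    return MatchedSample(
        retained=retained,
        propensity=pd.Series(
            1.0 / (1.0 + np.exp(-logit)), index=ids, name="propensity"
        ),
        balance=pd.DataFrame(rows),
        caliper=caliper,
    )


class CognitivePCA(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: battery DataFrame -> component scores.

    fit learns the z-scoring statistics and rotated loadings on the
    training battery; transform projects (new) z-scored data onto them.
    """

    def __init__(
        self,
        rule: str = "eigenvalue_gt_1",
        rotate: str = "varimax",
        forced_k: int = 1,
        invert_flags=None,
    ):
        self.rule = rule
        self.rotate = rotate
        self.forced_k = forced_k
        self.invert_flags = invert_flags

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        cols = _test_columns(X)
        signs = (
            np.where(np.asarray(self.invert_flags, bool), -1.0, 1.0)
            if self.invert_flags is not None
            else np.ones(len(cols))
        )
        V = X[cols].to_numpy(dtype=float) * signs
        self.columns_ = cols
        self.signs_ = signs
        self.mean_ = V.mean(axis=0)
        self.scale_ = V.std(axis=0)
        z = pd.DataFrame((V - self.mean_) / self.scale_, columns=cols, index=X.index)
        sol = pca_components(
            z, rule=self.rule, rotate=self.rotate, forced_k=self.forced_k
        )
        self.solution_ = sol
        self.loadings_ = sol.loadings
        self.n_components_ = sol.loadings.shape[1]
        # projection weights: scores = Z V / sqrt(lam) (rotated)
        lam = sol.eigenvalues[: self.n_components_]
        self.projection_ = np.linalg.lstsq(
            z.to_numpy(), sol.scores.to_numpy(), rcond=None
        )[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        V = X[self.columns_].to_numpy(dtype=float) * self.signs_
        z = (V - self.mean_) / self.scale_
        S = z @ self.projection_
        return pd.DataFrame(
            S, index=X.index, columns=list(self.solution_.scores.columns)
        )
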