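"""Breed/sex ANOVA with a relationship random effect, and multiple comparisons.

The weekly weight model is a two-way ANOVA (breed, sex, breed x sex) with an
optional random effect whose covariance is proportional to a bird-by-bird
relationship matrix estimated from molecular markers (an animal-model-style
variance component).  The variance ratio is profiled by restricted maximum
likelihood on a one-dimensional grid; with the identity matrix (or no matrix)
the model reduces exactly to ordinary two-way ANOVA.

Multiple comparisons of group means use the Waller-Duncan k-ratio t-test,
a Bayes rule that adapts its critical value to the observed F statistic:
the larger the evidence for real differences, the more liberal the rule.
Letters are assigned so that means not separated by the rule share a letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "AnovaSpec",
    "AnovaResult",
    "lm1_anova",
    "backward_eliminate",
    "waller_duncan_t",
    "waller_duncan",
    "dimorphism_delta",
    "relationship_from_markers",
    "significance_code",
]


def significance_code(p: float) -> str:
    """The conventional legend: n.s. / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if np.isnan(p):
        return "n.s."
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class AnovaSpec:
    """Response with breed/sex factors and an optional relationship matrix."""

    response: np.ndarray
    breed: np.ndarray
    sex: np.ndarray
    relationship: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.breed = np.asarray(self.breed)
        self.sex = np.asarray(self.sex)
        n = self.response.size
        if self.breed.size != n or self.sex.size != n:
            raise ValueError("response, breed and sex must have the same length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")
        if self.relationship is not None:
            a = np.asarray(self.relationship, dtype=float)
            if a.shape != (n, n):
                raise ValueError("relationship must be n x n")
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError("relationship must be symmetric")
            if not np.allclose(np.diag(a), 1.0, atol=1e-8):
                raise ValueError("relationship must have unit diagonal")
            if np.linalg.eigvalsh(a).min() < -1e-8:
                raise ValueError("relationship must be positive semidefinite")
            self.relationship = a


@dataclass
class AnovaResult:
    """Per-term F tests with significance codes and the elimination trail."""

    table: pd.DataFrame  # index: term; columns: df, F, p, code
    df_resid: int
    retained: list[str]
    eliminated: list[str] = field(default_factory=list)
    variance_ratio: float = 0.0  # genetic-to-residual variance ratio used

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        lines = ["ANOVA (F tests)", "-" * 44]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append(f"residual df: {self.df_resid}")
        if self.relationship_used:
            lines.append(f"relationship variance ratio: {self.variance_ratio:.3g}")
        if self.eliminated:
            lines.append("eliminated: " + " -> ".join(self.eliminated))
        return "\n".join(lines)

    @property
    def relationship_used(self) -> bool:
        return self.variance_ratio > 0


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummies (drop first level, levels sorted)."""
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("factor needs at least 2 levels")
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _term_matrices(breed: np.ndarray, sex: np.ndarray) -> dict[str, np.ndarray]:
    db = _dummies(breed)
    ds = _dummies(sex)
    inter = np.einsum("ij,ik->ijk", db, ds).reshape(db.shape[0], -1)
    return {"breed": db, "sex": ds, "breed:sex": inter}


def _design(terms: Sequence[str], mats: dict[str, np.ndarray], n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    cols += [mats[t] for t in terms]
    return np.hstack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _reml_profile(
    y: np.ndarray, x_full: np.ndarray, eigvals: np.ndarray, eigvecs: np.ndarray
) -> float:
    """Profile the genetic:residual variance ratio over a fixed grid by REML."""
    n = y.size
    yt = eigvecs.T @ y
    xt = eigvecs.T @ x_full
    grid = np.concatenate([[0.0], np.logspace(-3, 3, 31)])
    best_ratio, best_crit = 0.0, np.inf
    for ratio in grid:
        w = 1.0 + ratio * eigvals
        sw = 1.0 / np.sqrt(w)
        yw = yt * sw
        xw = xt * sw[:, None]
        rss, rank = _rss(xw, yw)
        if n - rank <= 0 or rss <= 0:
            continue
        xtx = xw.T @ xw
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            continue
        crit = (n - rank) * np.log(rss / (n - rank)) + np.sum(np.log(w)) + logdet_xtx
        if crit < best_crit:
            best_crit, best_ratio = crit, ratio
    return best_ratio


def _anova_tables(
    y: np.ndarray,
    mats: dict[str, np.ndarray],
    terms: Sequence[str],
    intercept: np.ndarray,
) -> tuple[pd.DataFrame, int]:
    """Type-II F tests of ``terms`` against the full-model residual."""
    n = y.size

    def design(subset: Sequence[str]) -> np.ndarray:
        return np.hstack([intercept] + [mats[t] for t in subset])

    rss_full, rank_full = _rss(design(terms), y)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid
    if mse <= 1e-300:
        raise ValueError("zero residual variance; F undefined")
    rows = []
    for term in terms:
        if term == "breed:sex":
            reduced = [t for t in terms if t != term]
            base_rss, base_rank = _rss(design(reduced), y)
            ss = base_rss - rss_full
            term_rank = rank_full
        else:
            # Type II: main effect adjusted for the other main effect only
            others = [t for t in terms if t not in (term, "breed:sex")]
            with_rss, term_rank = _rss(design(others + [term]), y)
            base_rss, base_rank = _rss(design(others), y)
            ss = base_rss - with_rss
        df_term = term_rank - base_rank
        if df_term <= 0:
            raise ValueError(f"term {term!r} is aliased (singular design)")
        f = (ss / df_term) / mse
        p = float(stats.f.sf(f, df_term, df_resid))
        rows.append({"term": term, "df": df_term, "F": f, "p": p, "code": significance_code(p)})
    table = pd.DataFrame(rows).set_index("term")
    return table, df_resid


def lm1_anova(spec: AnovaSpec, terms: Sequence[str] | None = None) -> AnovaResult:
    """Fixed breed/sex/interaction F tests, relationship random effect optional.

    With no relationship matrix (or the identity) this is ordinary two-way
    ANOVA with Type-II sums of squares; otherwise the response and design are
    whitened at the REML-profiled variance ratio first.
    """
    if np.var(spec.response) == 0:
        raise ValueError("response has zero variance; F undefined")
    if terms is None:
        terms = ["breed", "sex", "breed:sex"]
    mats = _term_matrices(spec.breed, spec.sex)
    mats = {k: v for k, v in mats.items() if k in terms}
    n = spec.response.size
    if spec.relationship is None or np.allclose(spec.relationship, np.eye(n)):
        y, mats_w, ratio = spec.response, mats, 0.0
        intercept = np.ones((n, 1))
    else:
        eigvals, eigvecs = np.linalg.eigh(spec.relationship)
        eigvals = np.clip(eigvals, 0.0, None)
        x_full = np.hstack([np.ones((n, 1))] + list(mats.values()))
        ratio = _reml_profile(spec.response, x_full, eigvals, eigvecs)
        sw = 1.0 / np.sqrt(1.0 + ratio * eigvals)
        y = (eigvecs.T @ spec.response) * sw
        mats_w = {k: (eigvecs.T @ v) * sw[:, None] for k, v in mats.items()}
        intercept = (eigvecs.T @ np.ones(n))[:, None] * sw[:, None]
    table, df_resid = _anova_tables(y, mats_w, list(terms), intercept)
    return AnovaResult(
        table=table, df_resid=df_resid, retained=list(terms), variance_ratio=ratio
    )


def backward_eliminate(spec: AnovaSpec, alpha: float = 0.05) -> AnovaResult:
    """Backward elimination respecting marginality (interaction leaves first).

    Repeatedly drops the least significant removable term with p >= alpha and
    refits; returns the final model with the elimination trail.
    """
    terms = ["breed", "sex", "breed:sex"]
    eliminated: list[str] = []
    result = lm1_anova(spec, terms)
    while terms:
        removable = (
            ["breed:sex"]
            if "breed:sex" in terms
            else [t for t in terms]
        )
        cand = [(result.p(t), t) for t in removable]
        p_max, worst = max(cand)
        if p_max < alpha:
            break
        terms = [t for t in terms if t != worst]
        eliminated.append(worst)
        if not terms:
            # intercept-only model: nothing left to test
            result = AnovaResult(
                table=pd.DataFrame(columns=["df", "F", "p", "code"]),
                df_resid=spec.response.size - 1,
                retained=[],
                eliminated=eliminated,
                variance_ratio=result.variance_ratio,
            )
            return result
        result = lm1_anova(spec, terms)
    result.eliminated = eliminated
    result.retained = terms
    return result


# ---------------------------------------------------------------------------
# Waller-Duncan k-ratio t-test
# ---------------------------------------------------------------------------


def _expected_positive_part_t(m: float, s: float, df: float) -> float:
    """E[max(X, 0)] for X ~ m + s * t_df (df > 1)."""
    c = -m / s
    dens = stats.t.pdf(c, df)
    sf = stats.t.sf(c, df)
    return s * ((df + c * c) / (df - 1.0) * dens - c * sf)


def waller_duncan_t(k_ratio: float, f_stat: float, df_error: float) -> float:
    """Minimum-average-risk critical t of the Waller-Duncan rule.

    The between-mean F statistic estimates the prior variance ratio of the
    standardized mean differences (marginal variance F, so prior variance
    F - 1).  With linear losses in the true difference and loss ratio
    ``k_ratio`` for the two error kinds, the Bayes rule declares a
    difference when the standardized t exceeds the root of

        k_ratio * E[(-delta)+ | t] = E[(delta)+ | t]

    where the posterior of the standardized difference is centred at
    ``t * (1 - 1/F)`` with scale ``sqrt(1 - 1/F)``; Student-t tails at the
    error df absorb the uncertainty in the residual variance.  Returns
    ``inf`` when F <= 1 (no evidence of any real differences).
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if k_ratio <= 1:
        raise ValueError("k_ratio must exceed 1")
    if not np.isfinite(f_stat) or f_stat <= 1.0:
        return float("inf")
    shrink = 1.0 - 1.0 / f_stat
    s = float(np.sqrt(shrink))
    df = max(float(df_error), 1.5)

    def g(t: float) -> float:
        m = t * shrink
        e_pos = _expected_positive_part_t(m, s, df)
        e_neg = _expected_positive_part_t(-m, s, df)
        return k_ratio * e_neg - e_pos

    hi = 60.0
    if g(hi) > 0:  # even a huge t would not be declared
        return float("inf")
    return float(brentq(g, 1e-6, hi, xtol=1e-8))


def waller_duncan(
    group_means,
    group_ns,
    mse: float,
    df_error: float,
    f_stat: float,
    k_ratio: float = 100.0,
) -> dict:
    """Letter display: groups not separated by the k-ratio rule share a letter.

    ``group_means`` may be a mapping label -> mean or a sequence (labelled by
    position).  Letters are assigned from the largest mean downward; the
    assignment is invariant to the input ordering of groups.
    """
    if isinstance(group_means, dict):
        labels = list(group_means)
        means = np.array([group_means[g] for g in labels], dtype=float)
    else:
        means = np.asarray(group_means, dtype=float)
        labels = list(range(means.size))
    ns = np.asarray(
        [group_ns[g] for g in labels] if isinstance(group_ns, dict) else group_ns, dtype=float
    )
    if means.size < 2:
        raise ValueError("need at least 2 groups")
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")

    t_crit = waller_duncan_t(k_ratio, f_stat, df_error)
    order = np.lexsort((np.array([str(l) for l in labels], dtype=object), -means))

    def separated(i: int, j: int) -> bool:
        if not np.isfinite(t_crit):
            return False
        lsd = t_crit * np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
        return abs(means[i] - means[j]) >= lsd

    k = means.size
    letters: list[list[str]] = [[] for _ in range(k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_idx = 0
    start = 0
    while start < k:
        end = start
        while end + 1 < k and not any(
            separated(order[i], order[end + 1]) for i in range(start, end + 1)
        ):
            end += 1
        for i in range(start, end + 1):
            letters[order[i]].append(alphabet[letter_idx])
        letter_idx += 1
        if end == k - 1:
            break
        # next window starts at the first group separated from the current start
        nxt = start + 1
        while nxt <= end and not separated(order[start], order[nxt]):
            nxt += 1
        start = nxt
    # groups never reached (fully overlapping windows) cannot occur: every
    # group is covered because windows advance by at least one
    return {labels[i]: "".join(sorted(set(letters[i]))) for i in range(k)}


def dimorphism_delta(female_mean: float, male_mean: float) -> float:
    """Sexual-dimorphism statistic: (male - female) / female * 100 (percent)."""
    if female_mean <= 0:
        raise ValueError("female mean must be positive")
    return (male_mean - female_mean) / female_mean * 100.0


def relationship_from_markers(genotypes) -> np.ndarray:
    """Proportion-of-shared-alleles similarity from diploid marker genotypes.

    ``genotypes``: array-like of shape (n_birds, n_markers, 2); allele codes
    are integers (NaN/negative for missing).  Entry (i, j) is the mean over
    markers with both birds typed of (shared alleles)/2, counted as a
    multiset intersection.  The diagonal is 1.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("genotypes must have shape (n_birds, n_markers, 2)")
    n, m, _ = g.shape
    if m < 1:
        raise ValueError("need at least one marker")
    # sort the two alleles within each genotype so multiset logic is a
    # pair of comparisons
    g = np.sort(g, axis=2)
    missing = ~np.all(np.isfinite(g) & (g >= 0), axis=2)  # (n, m)

    sim_sum = np.zeros((n, n))
    sim_cnt = np.zeros((n, n))
    for j in range(m):
        a1 = g[:, j, 0]
        a2 = g[:, j, 1]
        ok = ~missing[:, j]
        eq = (a1[:, None] == a1[None, :]) & (a2[:, None] == a2[None, :])
        overlap = (
            (a1[:, None] == a1[None, :])
            | (a1[:, None] == a2[None, :])
            | (a2[:, None] == a1[None, :])
            | (a2[:, None] == a2[None, :])
        )
        shared = np.where(eq, 2.0, np.where(overlap, 1.0, 0.0))
        valid = ok[:, None] & ok[None, :]
        sim_sum += np.where(valid, shared / 2.0, 0.0)
        sim_cnt += valid
    if np.any(sim_cnt == 0):
        raise ValueError("some bird pair has no marker typed in common")
    sim = sim_sum / sim_cnt
    np.fill_diagonal(sim, 1.0)
    return sim
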