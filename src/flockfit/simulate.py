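"""Synthetic flock generator with known ground truth.

Emulates the longitudinal design of a two-breed slow-growing flock study:
four breed-sex groups followed with biweekly weighings from hatch to 32
weeks (17 records per bird), group-level Gompertz truth with log-normal
between-bird parameter variation, multiplicative measurement noise, an
optional mid-rearing biphasic growth slowdown, a biallelic minisatellite
genotype with an optional additive asymptote effect, and multi-locus marker
genotypes from which an allele-sharing relationship matrix is built.

Everything is driven by a :class:`FlockDesign` and a single seed, so every
downstream pipeline stage can be tested against retrievable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import Trajectory
from .gompertz import G1Params, predict_g1
from .groupstats import relationship_from_markers

__all__ = [
    "GroupDesign",
    "BiphasicPhase",
    "GenotypeEffectModel",
    "FlockDesign",
    "SyntheticDataset",
    "default_design",
    "simulate_flock",
    "apply_biphasic",
    "simulate_markers",
]

#: biweekly weighing schedule, hatch (day 0) to 32 weeks: 17 ages
DEFAULT_SCHEDULE = tuple(float(d) for d in range(0, 225, 14))


@dataclass(frozen=True)
class GroupDesign:
    """One breed-sex group: size, Gompertz truth, between-bird CVs."""

    breed: str
    sex: str
    n: int
    params: G1Params
    cv_bwa: float = 0.15
    cv_b: float = 0.11
    cv_k: float = 0.08

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name in ("cv_bwa", "cv_b", "cv_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BiphasicPhase:
    """Temporary growth slowdown: increments in [start, end] scaled."""

    start: float = 91.0  # 13 w
    end: float = 147.0  # 21 w
    multiplier: float = 0.6

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("multiplier must be non-negative")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass(frozen=True)
class GenotypeEffectModel:
    """Biallelic genotype with an optional additive asymptote effect.

    ``effect_per_allele`` grams are added to the asymptote per copy of the
    favourable allele from ``onset_day`` onward; ``groups`` restricts the
    effect to specific (breed, sex) pairs (None = all groups).
    """

    freqs: Mapping[str, float] = field(default_factory=lambda: {"F": 0.6, "G": 0.4})
    favourable_allele: str = "G"
    effect_per_allele: float = 0.0
    onset_day: float = 98.0  # 14 w
    groups: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("allele frequencies must be non-negative")
        if self.favourable_allele not in self.freqs:
            raise ValueError("favourable allele missing from frequency map")


@dataclass(frozen=True)
class FlockDesign:
    """Full specification of a synthetic flock."""

    groups: tuple[GroupDesign, ...]
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    noise_cv: float = 0.05
    biphasic: BiphasicPhase | None = None
    genotype_model: GenotypeEffectModel | None = None
    n_markers: int = 20
    marker_alleles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        sched = np.asarray(self.schedule, dtype=float)
        if sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must start at 0 and be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.biphasic is not None:
            if self.biphasic.start < sched[0] or self.biphasic.end > sched[-1]:
                raise ValueError("biphasic window must lie inside the schedule span")
        if self.n_markers <= 0 or self.marker_alleles <= 0:
            raise ValueError("marker counts must be positive")

    @property
    def n_birds(self) -> int:
        return sum(g.n for g in self.groups)


def default_design(seed: int = 0, **overrides) -> FlockDesign:
    """The study-design defaults: 4 groups (46/47/54/54), 17 biweekly ages.

    Group Gompertz truth is the published group-mean estimates for the two
    breeds; between-bird CVs are back-calculated from the reported standard
    errors (k's SEM prints as 0.000, so its CV is set to a typical 0.08).
    """
    groups = (
        GroupDesign("BS", "F", 46, G1Params(bwa=2184.0, b=3.32, k=0.014)),
        GroupDesign("BS", "M", 47, G1Params(bwa=3074.0, b=3.55, k=0.014)),
        GroupDesign("BP", "F", 54, G1Params(bwa=2012.0, b=2.99, k=0.016)),
        GroupDesign("BP", "M", 54, G1Params(bwa=2745.0, b=3.25, k=0.015)),
    )
    return FlockDesign(groups=groups, seed=seed, **overrides)


@dataclass
class SyntheticDataset:
    """Simulated flock with retrievable per-bird truth."""

    trajectories: list[Trajectory]
    weights: pd.DataFrame  # long format: bird_id, breed, sex, age_days, weight_g
    genotypes: pd.DataFrame | None  # bird_id, length1, length2, genotype
    marker_genotypes: np.ndarray  # (n_birds, n_markers, 2)
    relationship: np.ndarray
    truth: pd.DataFrame  # per-bird true parameters and effects
    design: FlockDesign

    @property
    def bird_ids(self) -> list[str]:
        return list(self.truth["bird_id"])


def apply_biphasic(times, weights, window: BiphasicPhase) -> np.ndarray:
    """Scale growth increments inside the slowdown window.

    Operates on increments, not levels, so trajectories stay non-decreasing
    for any non-negative multiplier; a multiplier of 1 is the identity.
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(weights, dtype=float)
    if window.start < t[0] or window.end > t[-1]:
        raise ValueError("biphasic window lies outside the schedule span")
    inc = np.diff(w, prepend=0.0)  # first "increment" is the hatch weight itself
    # an increment belongs to the window if its interval midpoint falls inside
    mid = t - np.diff(t, prepend=t[0]) / 2.0
    inside = (mid >= window.start) & (mid <= window.end)
    inc = np.where(inside, inc * window.multiplier, inc)
    return np.cumsum(inc)


def simulate_markers(
    n_birds: int,
    n_markers: int,
    alleles_per_marker: int,
    seed: int | np.random.Generator | None = None,
    family_size: int | None = None,
) -> np.ndarray:
    """Diploid multi-locus genotypes, shape (n_birds, n_markers, 2).

    By default alleles are drawn independently with uniform frequencies.
    With ``family_size`` set, birds are grouped into full-sib blocks: each
    block draws two parents and every sib inherits one allele per parent
    per locus, creating within-family allele sharing.
    """
    if n_birds <= 0 or n_markers <= 0 or alleles_per_marker <= 0:
        raise ValueError("all counts must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if family_size is None:
        return rng.integers(0, alleles_per_marker, size=(n_birds, n_markers, 2))
    out = np.empty((n_birds, n_markers, 2), dtype=np.int64)
    start = 0
    while start < n_birds:
        size = min(family_size, n_birds - start)
        sire = rng.integers(0, alleles_per_marker, size=(n_markers, 2))
        dam = rng.integers(0, alleles_per_marker, size=(n_markers, 2))
        for i in range(size):
            from_sire = sire[np.arange(n_markers), rng.integers(0, 2, n_markers)]
            from_dam = dam[np.arange(n_markers), rng.integers(0, 2, n_markers)]
            out[start + i, :, 0] = from_sire
            out[start + i, :, 1] = from_dam
        start += size
    return out


_GENO_LENGTHS = {"E": 588, "F": 557, "G": 525}


def simulate_flock(design: FlockDesign) -> SyntheticDataset:
    """Generate a flock per the design; fully deterministic given the seed."""
    rng = np.random.default_rng(design.seed)
    sched = np.asarray(design.schedule, dtype=float)
    gm = design.genotype_model

    traj: list[Trajectory] = []
    truth_rows = []
    geno_rows = []
    long_rows = []
    for group in design.groups:
        for i in range(group.n):
            bird_id = f"{group.breed}{group.sex}{i + 1:03d}"
            bwa = _lognormal_mean_preserving(rng, group.params.bwa, group.cv_bwa)
            b = _lognormal_mean_preserving(rng, group.params.b, group.cv_b)
            k = _lognormal_mean_preserving(rng, group.params.k, group.cv_k)
            params = G1Params(bwa=bwa, b=b, k=k)
            w = np.asarray(predict_g1(params, sched), dtype=float)

            n_fav = 0
            geno = None
            if gm is not None:
                alleles = rng.choice(
                    list(gm.freqs), size=2, p=list(gm.freqs.values())
                )
                geno = "".join(sorted(alleles))
                n_fav = int(np.sum(alleles == gm.favourable_allele))
                in_scope = gm.groups is None or (group.breed, group.sex) in gm.groups
                if in_scope and gm.effect_per_allele != 0.0 and n_fav > 0:
                    factor = (bwa + n_fav * gm.effect_per_allele) / bwa
                    w = np.where(sched >= gm.onset_day, w * factor, w)
                lengths = sorted({_GENO_LENGTHS[a] for a in geno}, reverse=True)
                geno_rows.append(
                    {
                        "bird_id": bird_id,
                        "length1": lengths[0],
                        "length2": lengths[1] if len(lengths) > 1 else lengths[0],
                        "genotype": geno,
                    }
                )

            if design.biphasic is not None:
                w = apply_biphasic(sched, w, design.biphasic)

            if design.noise_cv > 0:
                w = w * (1.0 + design.noise_cv * rng.standard_normal(sched.size))
                w = np.clip(w, 1e-3, None)

            traj.append(
                Trajectory(
                    bird_id=bird_id,
                    breed=group.breed,
                    sex=group.sex,
                    times=sched.copy(),
                    weights=w,
                )
            )
            truth_rows.append(
                {
                    "bird_id": bird_id,
                    "breed": group.breed,
                    "sex": group.sex,
                    "bwa": bwa,
                    "b": b,
                    "k": k,
                    "genotype": geno,
                    "n_favourable": n_fav,
                }
            )
            for t, wt in zip(sched, w):
                long_rows.append(
                    {
                        "bird_id": bird_id,
                        "breed": group.breed,
                        "sex": group.sex,
                        "age_days": t,
                        "weight_g": wt,
                    }
                )

    markers = simulate_markers(
        design.n_birds, design.n_markers, design.marker_alleles, seed=rng
    )
    relationship = relationship_from_markers(markers)
    return SyntheticDataset(
        trajectories=traj,
        weights=pd.DataFrame(long_rows),
        genotypes=pd.DataFrame(geno_rows) if geno_rows else None,
        marker_genotypes=markers,
        relationship=relationship,
        truth=pd.DataFrame(truth_rows),
        design=design,
    )


def _lognormal_mean_preserving(
    rng: np.random.Generator, mean: float, cv: float
) -> float:
    """Log-normal draw whose expectation equals ``mean`` at the given CV."""
    if cv == 0:
        return mean
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(mean * np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma))
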