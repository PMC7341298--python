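"""PAX7 minisatellite genotyping and association statistics.

The third intron of chicken *PAX7* carries a minisatellite with a 31-bp
repeat unit.  Amplicon length identifies the allele: E carries three units
(588 bp amplicon), F two units (557 bp) and G a single unit with an
additional one-nucleotide deletion (557 - 31 - 1 = 525 bp).  This module
calls alleles from fragment lengths, tests the genotype distribution against
random-mating (Hardy-Weinberg) proportions by allele randomization,
quantifies breed differentiation with the Weir-Cockerham fixation index,
and tests the weight-genotype association week by week with a one-way ANOVA
plus Waller-Duncan letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import significance_code, waller_duncan

__all__ = [
    "AlleleModel",
    "GenotypeRecord",
    "UnknownAlleleError",
    "call_alleles",
    "hwe_randomization_test",
    "fst_between",
    "lm2_assoc",
    "AssocResult",
    "assoc_by_age",
]


class UnknownAlleleError(ValueError):
    """A fragment length matches no reference allele within tolerance."""


@dataclass(frozen=True)
class AlleleModel:
    """Reference amplicon lengths of the minisatellite alleles.

    E = F + one 31-bp unit; G = F - one unit - one deleted nucleotide.
    Only F and G are observed in the two Piedmont breeds, but E is retained
    so the caller generalizes.
    """

    unit_length: int = 31
    f_length: int = 557
    tolerance: float = 3.0

    @property
    def e_length(self) -> int:
        return self.f_length + self.unit_length

    @property
    def g_length(self) -> int:
        return self.f_length - self.unit_length - 1

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {"E": self.e_length, "F": self.f_length, "G": self.g_length}


DEFAULT_ALLELE_MODEL = AlleleModel()


@dataclass(frozen=True)
class GenotypeRecord:
    """Called genotype for one bird."""

    bird_id: str
    fragment_lengths: tuple[float, ...]
    alleles: tuple[str, str]

    @property
    def genotype(self) -> str:
        return "".join(sorted(self.alleles))


def call_alleles(
    lengths: Sequence[float], model: AlleleModel = DEFAULT_ALLELE_MODEL
) -> tuple[str, str]:
    """Map 1 or 2 fragment lengths (bp) to an unordered allele pair.

    A single length is called as a homozygote.  Each length is matched to
    the nearest reference within ``model.tolerance`` bp; anything else
    raises :class:`UnknownAlleleError` naming the offending value.
    """
    if len(lengths) not in (1, 2):
        raise ValueError(f"expected 1 or 2 fragment lengths, got {len(lengths)}")
    refs = model.reference_lengths
    called = []
    for length in lengths:
        best = min(refs, key=lambda a: abs(refs[a] - length))
        if abs(refs[best] - length) > model.tolerance:
            raise UnknownAlleleError(
                f"fragment length {length} bp matches no allele within "
                f"{model.tolerance} bp of {refs}"
            )
        called.append(best)
    if len(called) == 1:
        called = called * 2
    return tuple(sorted(called))  # type: ignore[return-value]


def _genotypes_to_pairs(genotypes) -> list[tuple[str, str]]:
    """Accept a mapping genotype->count or an iterable of allele pairs."""
    if isinstance(genotypes, Mapping):
        pairs = []
        for geno, count in genotypes.items():
            pair = tuple(sorted(geno)) if not isinstance(geno, str) else tuple(sorted(geno))
            if len(pair) != 2:
                raise ValueError(f"genotype {geno!r} is not diploid")
            pairs.extend([pair] * int(count))
        return pairs
    return [tuple(sorted(g)) for g in genotypes]


def hwe_randomization_test(
    genotypes, n_rand: int = 2000, seed: int | np.random.Generator | None = None
) -> float:
    """Randomization test of Hardy-Weinberg proportions.

    Alleles are permuted among individuals ``n_rand`` times and re-paired;
    the deviation statistic is the difference between observed and expected
    (allele-frequency-based) heterozygosity.  The p-value is the fraction of
    randomized datasets at least as deviant (two-sided, add-one corrected).
    Returns NaN for a monomorphic sample (test undefined).
    """
    pairs = _genotypes_to_pairs(genotypes)
    n = len(pairs)
    if n < 5:
        raise ValueError(f"need at least 5 individuals, got {n}")
    alleles = np.array([a for pair in pairs for a in pair])
    uniq, codes = np.unique(alleles, return_inverse=True)
    if uniq.size < 2:
        return float("nan")
    freqs = np.bincount(codes) / codes.size
    h_exp = 1.0 - float(np.sum(freqs**2))
    codes = codes.reshape(n, 2)
    h_obs = float(np.mean(codes[:, 0] != codes[:, 1]))
    d_obs = abs(h_obs - h_exp)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = codes.ravel()
    keys = rng.random((n_rand, flat.size))
    order = np.argsort(keys, axis=1)
    shuffled = flat[order]
    h_perm = np.mean(shuffled[:, 0::2] != shuffled[:, 1::2], axis=1)
    d_perm = np.abs(h_perm - h_exp)
    n_extreme = int(np.sum(d_perm >= d_obs - 1e-12))
    return (1 + n_extreme) / (1 + n_rand)


def fst_between(pop_genotype_counts: Mapping[str, Mapping]) -> float:
    """Weir-Cockerham theta between populations at one locus.

    ``pop_genotype_counts`` maps population label -> genotype counts (mapping
    genotype -> count, genotype a 2-string like ``"FG"`` or a pair).  Uses
    the standard variance-component estimator (a, b, c summed over alleles).
    """
    pops = list(pop_genotype_counts)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    pairs_by_pop = {p: _genotypes_to_pairs(pop_genotype_counts[p]) for p in pops}
    sizes = np.array([len(pairs_by_pop[p]) for p in pops], dtype=float)
    if np.any(sizes == 0):
        raise ValueError("every population needs at least one genotyped bird")
    alleles = sorted({a for p in pops for pair in pairs_by_pop[p] for a in pair})
    if len(alleles) < 2:
        raise ValueError("need at least 2 alleles overall")

    r = float(len(pops))
    n_bar = sizes.mean()
    n_c = (r * n_bar - np.sum(sizes**2) / (r * n_bar)) / (r - 1.0)

    num = 0.0
    den = 0.0
    for allele in alleles:
        p_i = np.array(
            [
                np.mean([pair.count(allele) / 2.0 for pair in pairs_by_pop[p]])
                for p in pops
            ]
        )
        h_i = np.array(
            [
                np.mean([(allele in pair) and pair[0] != pair[1] for pair in pairs_by_pop[p]])
                for p in pops
            ],
            dtype=float,
        )
        p_bar = float(np.sum(sizes * p_i) / (r * n_bar))
        s2 = float(np.sum(sizes * (p_i - p_bar) ** 2) / ((r - 1.0) * n_bar))
        h_bar = float(np.sum(sizes * h_i) / (r * n_bar))
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        num += a
        den += a + b + c
    if den == 0:
        return float("nan")
    return num / den


@dataclass
class AssocResult:
    """One-way genotype-association ANOVA with a letter display."""

    f_stat: float
    p_value: float
    code: str
    df_between: int
    df_error: int
    group_means: dict[str, float]
    group_ns: dict[str, int]
    letters: dict[str, str]

    def summary(self) -> str:
        lines = [
            "Genotype association (one-way ANOVA)",
            "-" * 44,
            f"F({self.df_between}, {self.df_error}) = {self.f_stat:.3f}, "
            f"p = {self.p_value:.4g} {self.code}",
        ]
        for g in sorted(self.group_means):
            lines.append(
                f"  {g}: mean {self.group_means[g]:.1f} g  (n={self.group_ns[g]})  "
                f"{self.letters[g]}"
            )
        return "\n".join(lines)


def lm2_assoc(weights, genotypes, k_ratio: float = 100.0) -> AssocResult:
    """Weight-on-genotype ANOVA within one breed-sex group at one age.

    Requires at least two genotype classes with n >= 2 each.
    """
    w = np.asarray(weights, dtype=float)
    g = np.asarray(genotypes)
    if w.size != g.size:
        raise ValueError("weights and genotypes must have the same length")
    classes, counts = np.unique(g, return_counts=True)
    usable = classes[counts >= 2]
    if usable.size < 2:
        raise ValueError(
            "need at least 2 genotype classes with at least 2 birds each; "
            f"counts were {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    keep = np.isin(g, usable)
    w, g = w[keep], g[keep]
    groups = [w[g == c] for c in usable]

    f_stat, p = stats.f_oneway(*groups)
    df_between = usable.size - 1
    df_error = w.size - usable.size
    resid = np.concatenate([x - x.mean() for x in groups])
    mse = float(resid @ resid) / df_error
    means = {str(c): float(w[g == c].mean()) for c in usable}
    ns = {str(c): int((g == c).sum()) for c in usable}
    letters = waller_duncan(means, ns, mse, df_error, float(f_stat), k_ratio=k_ratio)
    return AssocResult(
        f_stat=float(f_stat),
        p_value=float(p),
        code=significance_code(float(p)),
        df_between=int(df_between),
        df_error=int(df_error),
        group_means=means,
        group_ns=ns,
        letters=letters,
    )


def assoc_by_age(
    weights_wide: pd.DataFrame, genotypes: Mapping[str, str], k_ratio: float = 100.0
) -> pd.DataFrame:
    """Per-age association trajectory.

    ``weights_wide``: birds x ages DataFrame (index bird_id, columns age in
    days); ``genotypes``: bird_id -> genotype label.  Returns a tidy frame
    with one row per age (F, p, code, letters).
    """
    geno = np.array([genotypes[b] for b in weights_wide.index])
    rows = []
    for age in weights_wide.columns:
        res = lm2_assoc(weights_wide[age].to_numpy(), geno, k_ratio=k_ratio)
        rows.append(
            {
                "age_days": age,
                "F": res.f_stat,
                "p": res.p_value,
                "code": res.code,
                "letters": ";".join(f"{g}={l}" for g, l in sorted(res.letters.items())),
            }
        )
    return pd.DataFrame(rows)
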