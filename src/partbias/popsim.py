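"""Target-population simulation: genotypes, sex, and liability-threshold binary traits.

The target population is the (unobserved) pool from which a study recruits.
Genotypes are unlinked autosomal variants in Hardy-Weinberg equilibrium coded
as minor-allele dosages in {0, 1, 2}; binary traits follow a standard
liability-threshold model with heritability defined on the liability scale.
Liabilities use mean-centered dosages (g - 2*maf) so that intercepts of the
downstream participation model map directly onto participation rates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "PopulationConfig",
    "Cohort",
    "TraitArchitecture",
    "simulate_genotypes",
    "simulate_cohort",
    "draw_trait_effects",
    "simulate_binary_trait",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Dimensions and allele-frequency law of the simulated target population.

    Parameters
    ----------
    n_individuals, n_variants
        Positive population and variant counts.
    maf
        Minor-allele frequency specification: a scalar in (0, 0.5], a
        ``(low, high)`` range sampled uniformly per variant, or an explicit
        per-variant array.
    male_fraction
        P(male) in (0, 1); sex is coded 0 = female, 1 = male.
    seed
        Seed for the population RNG.
    """

    n_individuals: int
    n_variants: int
    maf: object = (0.1, 0.5)
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0:
            raise ValueError("n_individuals and n_variants must be positive")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must lie in (0, 1)")
        arr = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if arr.size == 0 or np.any(arr <= 0.0) or np.any(arr > 0.5):
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        if arr.ndim > 1:
            raise ValueError("maf must be a scalar, a (low, high) pair, or a 1-D array")

    def resolve_mafs(self, rng: np.random.Generator) -> np.ndarray:
        """Materialize per-variant allele frequencies."""
        arr = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if arr.size == 1:
            return np.full(self.n_variants, arr[0])
        if arr.size == 2 and self.n_variants != 2:
            low, high = arr
            return rng.uniform(low, high, size=self.n_variants)
        if arr.size != self.n_variants:
            raise ValueError("per-variant maf array length must equal n_variants")
        return arr.copy()


@dataclass
class Cohort:
    """A simulated target population, later annotated with participation.

    ``genotypes`` is an ``n x m`` minor-allele dosage matrix (int8),
    ``sex`` codes 0 = female / 1 = male, ``traits`` maps trait names to binary
    vectors, and ``participation`` (if set) marks study participants.
    """

    genotypes: np.ndarray
    sex: np.ndarray
    mafs: np.ndarray
    traits: dict[str, np.ndarray] = field(default_factory=dict)
    participation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        g = self.genotypes
        valid = (
            np.issubdtype(g.dtype, np.integer) and g.min(initial=0) >= 0
            and g.max(initial=0) <= 2
        ) or np.isin(g, (0, 1, 2)).all()
        if not valid:
            raise ValueError("dosages must be 0, 1 or 2")
        self.sex = np.asarray(self.sex)
        if not np.isin(self.sex, (0, 1)).all():
            raise ValueError("sex must be coded 0 (female) / 1 (male)")
        if self.sex.shape[0] != self.genotypes.shape[0]:
            raise ValueError("sex and genotypes disagree on n_individuals")
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.mafs.shape[0] != self.genotypes.shape[1]:
            raise ValueError("mafs and genotypes disagree on n_variants")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def centered_genotypes(self) -> np.ndarray:
        """Dosages centered at their population expectation 2*maf (float64)."""
        return self.genotypes.astype(float) - 2.0 * self.mafs

    def participants(self) -> "Cohort":
        """Restrict the cohort to study participants."""
        if self.participation is None:
            raise ValueError("cohort has no participation indicator yet")
        keep = self.participation.astype(bool)
        return Cohort(
            genotypes=self.genotypes[keep],
            sex=self.sex[keep],
            mafs=self.mafs,
            traits={k: v[keep] for k, v in self.traits.items()},
            participation=np.ones(int(keep.sum()), dtype=np.int8),
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write one row per individual (variant dosages, sex, traits,
        participation) plus a ``#maf`` header line; exact round-trip."""
        cols = [f"v{j}" for j in range(self.n_variants)]
        header = cols + ["sex"] + list(self.traits) + (
            ["participation"] if self.participation is not None else []
        )
        buf = io.StringIO()
        buf.write("#maf\t" + "\t".join(repr(float(p)) for p in self.mafs) + "\n")
        buf.write("\t".join(header) + "\n")
        blocks = [self.genotypes, self.sex[:, None]]
        blocks += [v[:, None] for v in self.traits.values()]
        if self.participation is not None:
            blocks.append(np.asarray(self.participation)[:, None])
        mat = np.hstack([np.asarray(b, dtype=np.int64) for b in blocks])
        np.savetxt(buf, mat, fmt="%d", delimiter="\t")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "Cohort":
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#maf\t"):
                raise ValueError("missing #maf header line")
            mafs = np.array([float(x) for x in first.split("\t")[1:]])
            names = fh.readline().rstrip("\n").split("\t")
            mat = np.loadtxt(fh, dtype=np.int64, delimiter="\t", ndmin=2)
        m = mafs.size
        col = {name: i for i, name in enumerate(names)}
        trait_names = [c for c in names[m:] if c not in ("sex", "participation")]
        return cls(
            genotypes=mat[:, :m].astype(np.int8),
            sex=mat[:, col["sex"]].astype(np.int8),
            mafs=mafs,
            traits={t: mat[:, col[t]].astype(np.int8) for t in trait_names},
            participation=(
                mat[:, col["participation"]].astype(np.int8)
                if "participation" in col
                else None
            ),
        )


def simulate_genotypes(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the HWE dosage matrix; returns ``(genotypes, mafs)``.

    Column ``j`` is i.i.d. Binomial(2, maf_j) across individuals.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mafs = config.resolve_mafs(rng)
    geno = rng.binomial(2, mafs, size=(config.n_individuals, config.n_variants))
    return geno.astype(np.int8), mafs


def simulate_cohort(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> Cohort:
    """Simulate genotypes and sex for a target population."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geno, mafs = simulate_genotypes(config, rng)
    sex = (rng.random(config.n_individuals) < config.male_fraction).astype(np.int8)
    return Cohort(genotypes=geno, sex=sex, mafs=mafs)


@dataclass
class TraitArchitecture:
    """Genetic architecture of one liability-threshold binary trait.

    ``effects`` are per-allele liability effects on centered dosages; the
    analytic genetic variance ``sum_j 2 p_j (1-p_j) b_j^2`` equals
    ``h2_liability`` exactly by construction, and the environmental liability
    is Normal(0, 1 - h2).
    """

    h2_liability: float
    prevalence: float
    effects: np.ndarray
    causal_mask: np.ndarray
    mafs: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any(self.effects[~self.causal_mask] != 0.0):
            raise ValueError("non-causal variants must have effect exactly 0")

    def genetic_variance(self) -> float:
        """Analytic liability variance explained, from MAFs and effects."""
        return float(np.sum(2.0 * self.mafs * (1.0 - self.mafs) * self.effects**2))

    @property
    def threshold(self) -> float:
        return float(norm.ppf(1.0 - self.prevalence))


def scale_effects_to_variance(
    raw: np.ndarray, mafs: np.ndarray, target_variance: float
) -> np.ndarray:
    """Rescale raw per-allele effects so sum_j 2 p_j (1-p_j) b_j^2 hits the
    target exactly (not merely in expectation)."""
    if target_variance == 0.0:
        return np.zeros_like(raw, dtype=float)
    var = np.sum(2.0 * mafs * (1.0 - mafs) * raw**2)
    if var == 0.0:
        raise ValueError("cannot rescale all-zero effects to a nonzero variance")
    return raw * np.sqrt(target_variance / var)


def draw_trait_effects(
    mafs: np.ndarray,
    h2_liability: float,
    prevalence: float,
    causal_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TraitArchitecture:
    """Draw per-variant liability effects for a binary trait.

    Effects are i.i.d. normal per standardized genotype on the causal set and
    rescaled exactly to the liability-scale heritability.
    """
    mafs = np.asarray(mafs, dtype=float)
    if not 0.0 <= h2_liability < 1.0:
        raise ValueError("h2_liability must lie in [0, 1)")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if causal_mask is None:
        causal_mask = np.ones(mafs.size, dtype=bool)
    causal_mask = np.asarray(causal_mask, dtype=bool)
    if h2_liability > 0.0 and not causal_mask.any():
        raise ValueError("h2_liability > 0 requires a nonempty causal set")
    if rng is None:
        rng = np.random.default_rng(seed)
    effects = np.zeros(mafs.size)
    if h2_liability > 0.0:
        # per-standardized-genotype draws, converted to per-allele scale
        z = rng.standard_normal(int(causal_mask.sum()))
        sd = np.sqrt(2.0 * mafs[causal_mask] * (1.0 - mafs[causal_mask]))
        effects[causal_mask] = z / sd
        effects = scale_effects_to_variance(effects, mafs, h2_liability)
    return TraitArchitecture(
        h2_liability=h2_liability,
        prevalence=prevalence,
        effects=effects,
        causal_mask=causal_mask,
        mafs=mafs,
    )


def simulate_binary_trait(
    cohort: Cohort,
    arch: TraitArchitecture,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    name: str | None = None,
) -> np.ndarray:
    """Threshold the liability L = G_c b + e, e ~ N(0, 1 - h2), at
    Phi^{-1}(1 - K); optionally stores the trait on the cohort under ``name``."""
    if arch.effects.shape[0] != cohort.n_variants:
        raise ValueError("architecture and cohort disagree on the variant set")
    if rng is None:
        rng = np.random.default_rng(seed)
    liability = cohort.centered_genotypes() @ arch.effects
    liability += rng.normal(0.0, np.sqrt(1.0 - arch.h2_liability), cohort.n_individuals)
    trait = (liability > arch.threshold).astype(np.int8)
    if name is not None:
        cohort.traits[name] = trait
    return trait
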