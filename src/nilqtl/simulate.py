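"""Simulation of backcross-self (BCₙSₘ) near-isogenic line libraries.

The generator mimics how teosinte NIL libraries are built: an F1 between a
donor accession and the recurrent inbred is backcrossed to the recurrent
parent for ``n_backcross`` generations and then self-pollinated for
``n_self`` generations.  Meiosis follows the Haldane model (no crossover
interference): the number of crossovers on a chromosome of length L cM is
Poisson with mean L/100 and crossover positions are uniform, which yields
recombination fraction r = (1 - exp(-2d/100))/2 between loci d cM apart.

Genotypes are scored at the map's marker positions and coded

    ``B``  homozygous recurrent parent,
    ``H``  heterozygous,
    ``D``  homozygous donor.

Under this pedigree with neutral Mendelian transmission the per-locus
expectation for BC4S2 is about 96.1% B, 1.6% H and 2.3% D, i.e. roughly 4%
of each line's genome is donor-derived.  Lines are simulated as independent
descents (no shared early-generation parents, no selection among progeny).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, default_map

__all__ = [
    "PedigreeSpec",
    "EnvSpec",
    "QTLSpec",
    "NILGenotypes",
    "expected_genome_composition",
    "simulate_nil_population",
    "simulate_phenotypes",
    "default_family_sizes",
    "DEFAULT_TRAIT_INTERCEPTS",
    "DEFAULT_VARIANCE_COMPONENTS",
    "CALL_CODES",
]

CALL_CODES = ("B", "H", "D")

#: default trait intercepts (% dry matter) — typical kernel composition means
#: of a temperate maize inbred background
DEFAULT_TRAIT_INTERCEPTS = {"starch": 71.41, "protein": 10.77, "oil": 3.89}

#: default variance components (squared trait units) chosen so the entry-mean
#: heritability over 2 environments x 2 replicates lands near 0.70 (starch),
#: 0.76 (protein) and 0.94 (oil)
DEFAULT_VARIANCE_COMPONENTS = {
    "starch": {"sigma2_g": 1.4, "sigma2_ge": 0.6, "sigma2_e": 1.2},
    "protein": {"sigma2_g": 1.9, "sigma2_ge": 0.8, "sigma2_e": 0.8},
    "oil": {"sigma2_g": 0.20, "sigma2_ge": 0.017, "sigma2_e": 0.017},
}


@dataclass(frozen=True)
class PedigreeSpec:
    """Backcross-self pedigree: BCₙSₘ with n_backcross = n, n_self = m."""

    n_backcross: int = 4
    n_self: int = 2

    def __post_init__(self) -> None:
        if self.n_backcross < 0 or self.n_self < 0:
            raise ValueError("pedigree generation counts must be non-negative")


@dataclass(frozen=True)
class EnvSpec:
    """Trial structure and variance components for phenotype simulation.

    ``sigma2_g`` is the polygenic (background) genetic variance added on top
    of any planted QTL; ``sigma2_ge`` the genotype-by-environment variance;
    ``sigma2_e`` the plot residual variance.  All in squared trait units.
    """

    n_env: int = 2
    n_rep: int = 2
    env_effects: tuple[float, ...] | None = None
    sigma2_g: float = 1.0
    sigma2_ge: float = 0.25
    sigma2_e: float = 0.5

    def __post_init__(self) -> None:
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.env_effects is not None and len(self.env_effects) != self.n_env:
            raise ValueError("env_effects length must equal n_env")


@dataclass(frozen=True)
class QTLSpec:
    """A simulated additive QTL: marker, trait and per-family allele effects.

    ``effects`` maps family label -> additive effect in trait units per donor
    allele dose (dose 0 / 0.5 / 1 for B / H / D).  Families absent from the
    mapping carry a zero effect (their donor allele is equivalent to the
    recurrent allele at this locus).
    """

    marker: str
    trait: str
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class NILGenotypes:
    """Line x marker introgression calls plus per-line family labels.

    ``calls`` is a DataFrame indexed by line identifier with one column per
    marker, values in {"B", "H", "D"} or NaN for missing.
    """

    calls: pd.DataFrame
    family: pd.Series
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.family.index):
            raise ValueError("calls and family must be indexed by the same lines")
        if list(self.calls.columns) != list(self.gmap.markers):
            raise ValueError("call matrix columns must match the genetic map markers")
        values = self.calls.to_numpy(dtype=object)
        bad = ~(pd.isna(values) | np.isin(values, CALL_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype call {values[i, j]!r} for line "
                f"{self.calls.index[i]!r} at marker {self.calls.columns[j]!r}"
            )

    @property
    def lines(self) -> list[str]:
        return self.calls.index.tolist()

    @property
    def families(self) -> list[str]:
        return pd.unique(self.family).tolist()

    def donor_fraction(self) -> pd.Series:
        """Per-line fraction of scored markers carrying >= 1 donor allele."""
        v = self.calls.to_numpy(dtype=object)
        scored = ~pd.isna(v)
        donor = np.isin(v, ("H", "D"))
        return pd.Series(donor.sum(1) / scored.sum(1), index=self.calls.index)

    def composition(self) -> dict[str, float]:
        """Overall frequencies of B / H / D among scored calls."""
        v = self.calls.to_numpy(dtype=object)
        n = (~pd.isna(v)).sum()
        return {c: float(np.sum(v == c) / n) for c in CALL_CODES}


def expected_genome_composition(pedigree: PedigreeSpec) -> tuple[float, float, float]:
    """Neutral per-locus genotype probabilities (P_B, P_H, P_D) for a pedigree.

    The per-locus state follows a Markov chain started at H (the F1):
    each backcross sends H -> {B: 1/2, H: 1/2}; each selfing generation sends
    H -> {B: 1/4, H: 1/2, D: 1/4}.  B and D are absorbing.
    """
    p_b, p_h, p_d = 0.0, 1.0, 0.0
    for _ in range(pedigree.n_backcross):
        p_b, p_h = p_b + p_h / 2, p_h / 2
    for _ in range(pedigree.n_self):
        p_b, p_h, p_d = p_b + p_h / 4, p_h / 2, p_d + p_h / 4
    return (p_b, p_h, p_d)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, pos: np.ndarray,
             length: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized gamete formation for one chromosome across n individuals.

    ``hap_a``/``hap_b`` are (n, m) donor-allele indicators at the m marker
    positions ``pos`` (cM).  Crossovers: Poisson(length/100) per individual,
    uniform positions, no interference.
    """
    n = hap_a.shape[0]
    k = rng.poisson(max(length, 0.0) / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    kmax = int(k.max()) if n else 0
    if kmax == 0:
        choose_b = start.astype(bool)[:, None]
        return np.where(choose_b, hap_b, hap_a)
    xo = rng.uniform(0.0, max(length, 1e-12), size=(n, kmax))
    xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
    # number of crossovers left of each marker -> haplotype parity
    counts = (xo[:, :, None] <= pos[None, None, :]).sum(axis=1)
    choose_b = (start[:, None] + counts) % 2 == 1
    return np.where(choose_b, hap_b, hap_a)


def simulate_nil_population(
    gmap: GeneticMap | None = None,
    family_sizes: dict[str, int] | None = None,
    pedigree: PedigreeSpec = PedigreeSpec(),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> NILGenotypes:
    """Simulate a multi-family NIL library on a genetic map.

    Each line is an independent neutral descent through the pedigree; family
    labels record which donor accession a line derives from (donor genomes
    are interchangeable in the simulation — families differ only by label
    and, downstream, by the allele effects planted on them).

    Parameters
    ----------
    gmap : GeneticMap, optional
        Defaults to the bundled 728-marker, 10-chromosome map.
    family_sizes : mapping family label -> number of lines, optional
        Defaults to 10 families totalling 961 lines.
    pedigree : PedigreeSpec
        Defaults to BC4S2.
    seed : int
        Seed for the pseudo-random generator; fixed seed gives bit-identical
        output.
    missing_rate : float
        Fraction of calls masked to missing, uniformly at random.
    """
    if gmap is None:
        gmap = default_map()
    if family_sizes is None:
        family_sizes = default_family_sizes()
    if not family_sizes:
        raise ValueError("family_sizes is empty")
    for fam, size in family_sizes.items():
        if size <= 0:
            raise ValueError(f"family {fam!r} has non-positive size {size}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n_total = int(sum(family_sizes.values()))
    chroms = gmap.chromosomes

    # simulate all lines at once; family labels are assigned afterwards
    geno_blocks: list[np.ndarray] = []
    for chrom in chroms:
        pos = gmap.positions(chrom)
        length = gmap.chrom_length(chrom)
        m = pos.size
        hap_a = np.ones((n_total, m), dtype=np.int8)   # donor haplotype
        hap_b = np.zeros((n_total, m), dtype=np.int8)  # recurrent haplotype
        for _ in range(pedigree.n_backcross):
            gam = _meiosis(hap_a, hap_b, pos, length, rng)
            hap_a, hap_b = gam, np.zeros_like(gam)
        for _ in range(pedigree.n_self):
            g1 = _meiosis(hap_a, hap_b, pos, length, rng)
            g2 = _meiosis(hap_a, hap_b, pos, length, rng)
            hap_a, hap_b = g1, g2
        geno_blocks.append(hap_a + hap_b)  # donor allele count 0/1/2

    dose_count = np.concatenate(geno_blocks, axis=1)
    calls = np.array(CALL_CODES, dtype=object)[dose_count]
    if missing_rate > 0.0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.astype(object)
        calls[mask] = np.nan

    line_ids, fam_labels = [], []
    for fam, size in family_sizes.items():
        line_ids.extend(f"{fam}_L{i + 1:03d}" for i in range(size))
        fam_labels.extend([fam] * size)
    index = pd.Index(line_ids, name="line")
    return NILGenotypes(
        calls=pd.DataFrame(calls, index=index, columns=list(gmap.markers)),
        family=pd.Series(fam_labels, index=index, name="family"),
        gmap=gmap,
    )


def default_family_sizes() -> dict[str, int]:
    """Ten donor families, 58-185 lines each, 961 lines in total."""
    sizes = (185, 130, 110, 100, 95, 85, 75, 65, 58, 58)
    return {f"TIL{i + 1:02d}": s for i, s in enumerate(sizes)}


def _dose_of_calls(calls: pd.DataFrame, marker: str) -> np.ndarray:
    mapping = {"B": 0.0, "H": 0.5, "D": 1.0}
    col = calls[marker]
    return col.map(mapping).to_numpy(dtype=float)


def simulate_phenotypes(
    genos: NILGenotypes,
    qtl: list[QTLSpec],
    env: EnvSpec,
    seed: int = 0,
    intercepts: dict[str, float] | None = None,
    traits: list[str] | None = None,
    polygenic_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate a long-format plot table for a simulated trial.

    Each plot value is

        intercept + sum_q effect_{q, family(line)} * dose(line, marker_q)
        + polygenic(line) + env_effect + gxe(line, env) + residual(plot)

    with polygenic ~ N(0, sigma2_g), gxe ~ N(0, sigma2_ge) and residual
    ~ N(0, sigma2_e).  Missing genotype calls contribute the family-mean
    dose at that marker (so planted effects stay unbiased under masking).

    Returns a DataFrame with columns ``line, env, rep, trait, value``; one
    row per line x environment x replicate x trait.

    ``polygenic_corr``, if given, is a trait x trait correlation matrix for
    the polygenic deviates (traits in the order of ``traits``).
    """
    if intercepts is None:
        intercepts = DEFAULT_TRAIT_INTERCEPTS
    if traits is None:
        seen = list(dict.fromkeys([q.trait for q in qtl]))
        traits = seen if seen else list(intercepts)
    for q in qtl:
        if q.marker not in genos.calls.columns:
            raise KeyError(f"QTL marker {q.marker!r} not present in the genotypes")
        unknown = set(q.effects) - set(genos.families)
        if unknown:
            raise KeyError(f"QTL references unknown families: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(genos.lines)
    fam = genos.family.to_numpy()
    env_labels = [f"env{j + 1}" for j in range(env.n_env)]
    env_eff = (
        np.zeros(env.n_env)
        if env.env_effects is None
        else np.asarray(env.env_effects, dtype=float)
    )

    n_traits = len(traits)
    if polygenic_corr is None:
        chol = np.eye(n_traits)
    else:
        corr = np.asarray(polygenic_corr, dtype=float)
        if corr.shape != (n_traits, n_traits):
            raise ValueError("polygenic_corr must be traits x traits")
        chol = np.linalg.cholesky(corr)
    poly_z = rng.standard_normal((n, n_traits)) @ chol.T

    records = []
    for ti, trait in enumerate(traits):
        mu = float(intercepts.get(trait, 0.0))
        g = np.full(n, mu)
        for q in qtl:
            if q.trait != trait:
                continue
            dose = _dose_of_calls(genos.calls, q.marker)
            if np.isnan(dose).any():
                fam_series = pd.Series(dose, index=genos.calls.index)
                fam_mean = fam_series.groupby(genos.family).transform("mean")
                dose = np.where(np.isnan(dose), fam_mean.to_numpy(), dose)
                dose = np.nan_to_num(dose)
            eff = np.array([q.effects.get(f, 0.0) for f in fam])
            g = g + eff * dose
        g = g + np.sqrt(env.sigma2_g) * poly_z[:, ti]
        gxe = np.sqrt(env.sigma2_ge) * rng.standard_normal((n, env.n_env))
        for j, env_label in enumerate(env_labels):
            for r in range(env.n_rep):
                resid = np.sqrt(env.sigma2_e) * rng.standard_normal(n)
                values = g + env_eff[j] + gxe[:, j] + resid
                records.append(
                    pd.DataFrame(
                        {
                            "line": genos.lines,
                            "env": env_label,
                            "rep": f"rep{r + 1}",
                            "trait": trait,
                            "value": values,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)
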