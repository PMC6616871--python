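"""Synthetic genotype panels and the two phenotype simulation experiments.

Experiment 1 (scenario 1-3): an unlinked SNP panel carries six QTNs with
target heritabilities (0.10, 0.05, 0.05, 0.15, 0.05, 0.05) at allele
frequency 0.30; the phenotype is

    scenario 1:  y = 1 mu + sum_i z_i beta_i + e,            e ~ N(0, 10 I)
    scenario 2:  ... + phi,       phi ~ N(0, 2 K)  (panel's own kinship)
    scenario 3:  ... + sum_j (C_j # D_j) beta_jj   (3 epistatic pairs,
                  each contributing variance 1.25, i.e. h2 = 0.05)

Effects are calibrated from the heritabilities: with residual variance
sigma_e^2 and fixed background variances B, the total phenotypic variance
solves V (1 - sum_i h_i^2) = sigma_e^2 + B, and
beta_i = sqrt(h_i^2 V / (2 p (1 - p))).

Experiment 2: a five-generation pedigree (20 founders; four generations of
20 males + 1000 females each, every sire mated to 51 dams) over a genome of
5 chromosomes x 100 Mb x 2000 equally spaced SNPs, gene-dropped with
Haldane recombination at 1 cM/Mb.  Three correlated traits (heritabilities
0.35, 0.35, 0.50) arise from 50 pleiotropic QTLs placed at even SNP
indices; the association set is the 3000 females of generations G1-G3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerMap, PhenotypeVector, write_plink
from .kinship import KinshipFactor, build_kinship

__all__ = [
    "ScenarioConfig", "PedigreeDesign", "ScenarioTruth", "PedigreeResult",
    "simulate_genotypes", "calibrate_qtn_effects", "select_qtn_columns",
    "simulate_scenario", "simulate_pedigree", "export_experiment",
]


@dataclass
class ScenarioConfig:
    """Parameter bundle for the experiment-1 generators."""

    n_individuals: int = 199
    n_snps: int = 10_000
    qtn_count: int = 6
    qtn_allele_freq: float = 0.30
    qtn_h2: tuple[float, ...] = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
    grand_mean: float = 10.0
    residual_variance: float = 10.0
    polygenic_variance: float = 2.0      # scenario 2
    epi_pairs: int = 3                   # scenario 3
    epi_variance: float = 1.25           # per pair
    min_qtn_separation_bp: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.qtn_h2) != self.qtn_count:
            raise ValueError("qtn_h2 length must equal qtn_count")
        if not 0.0 < self.qtn_allele_freq <= 0.5:
            raise ValueError("qtn_allele_freq must lie in (0, 0.5]")
        if sum(self.qtn_h2) >= 1.0:
            raise ValueError("QTN heritabilities must sum to < 1")


@dataclass
class PedigreeDesign:
    """Five-generation mating design of the experiment-2 simulation."""

    generations: int = 5                 # G0..G4
    founders: int = 20
    males_per_gen: int = 20
    females_per_gen: int = 1000
    mates_per_male: int = 51
    chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    snps_per_chrom: int = 2000
    qtl_count: int = 50
    trait_h2: tuple[float, ...] = (0.35, 0.35, 0.50)
    genetic_correlation: np.ndarray | None = None
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.genetic_correlation is None:
            # not printed in the source design; traits 1-2 moderately
            # correlated, trait 3 independent
            self.genetic_correlation = np.array([[1.0, 0.5, 0.0],
                                                 [0.5, 1.0, 0.0],
                                                 [0.0, 0.0, 1.0]])
        self.genetic_correlation = np.asarray(self.genetic_correlation, dtype=float)
        t = len(self.trait_h2)
        if self.genetic_correlation.shape != (t, t):
            raise ValueError("genetic_correlation must be traits x traits")
        if np.linalg.eigvalsh(self.genetic_correlation).min() <= 0:
            raise ValueError("genetic_correlation must be positive definite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_h2)

    @property
    def total_individuals(self) -> int:
        return self.founders + (self.generations - 1) * (
            self.males_per_gen + self.females_per_gen)

    @property
    def total_snps(self) -> int:
        return self.chromosomes * self.snps_per_chrom


@dataclass
class ScenarioTruth:
    """Ground truth of one experiment-1 replicate."""

    scenario: int
    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    qtn_h2: tuple[float, ...]
    total_variance: float
    epi_pairs: list[tuple[int, int]] = field(default_factory=list)
    epi_effects: list[float] = field(default_factory=list)
    seed: int | None = None


@dataclass
class PedigreeResult:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    pedigree: pd.DataFrame
    phenotypes: list[PhenotypeVector]
    analysis_indices: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    residual_variances: np.ndarray
    seed: int | None = None


# ---------------------------------------------------------------------------
# Unlinked panels (experiment 1)
# ---------------------------------------------------------------------------

def _resolve_maf(maf_sampler, rng: np.random.Generator, m: int) -> np.ndarray:
    if maf_sampler is None:
        return rng.uniform(0.05, 0.5, size=m)
    if np.isscalar(maf_sampler):
        return np.full(m, float(maf_sampler))
    return np.asarray(maf_sampler(rng, m), dtype=float)


def simulate_genotypes(n: int, m: int, maf_sampler=None, seed=None, *,
                       n_chromosomes: int = 5, chrom_length_bp: int = 24_000_000,
                       spacing_bp: int | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Independent SNPs in Hardy-Weinberg proportions.

    Minor-allele frequencies come from ``maf_sampler`` (default
    Uniform(0.05, 0.5); a scalar fixes all SNPs, a callable receives
    ``(rng, m)``).  Codes count the major allele, so each column is
    Binomial(2, 1 - p).  Markers are equally spaced over a fixed synthetic
    genome (default 5 chromosomes of 24 Mb, a compact plant-genome scale);
    a smaller panel therefore means sparser markers, not a smaller genome.
    ``spacing_bp`` overrides the derived inter-marker distance.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    p = _resolve_maf(maf_sampler, rng, m)
    codes = rng.binomial(2, 1.0 - p, size=(n, m)).astype(np.int8)
    per = int(np.ceil(m / n_chromosomes))
    if spacing_bp is None:
        spacing_bp = max(1, chrom_length_bp // per)
    chrom = [str(1 + j // per) for j in range(m)]
    pos = [spacing_bp * (1 + j % per) for j in range(m)]
    marker_map = MarkerMap.from_arrays(
        [f"snp{j}" for j in range(m)], chrom, pos)
    g = GenotypeMatrix(codes, np.zeros((n, m), dtype=bool),
                       [f"ind{i}" for i in range(n)])
    return g, marker_map


def calibrate_qtn_effects(cfg: ScenarioConfig, scenario: int = 1
                          ) -> tuple[np.ndarray, float]:
    """QTN allele effects and the total phenotypic variance they imply.

    V (1 - sum h_i^2) = sigma_e^2 + fixed background variances, then
    beta_i = sqrt(h_i^2 V / (2 p (1 - p))).
    """
    if scenario not in (1, 2, 3):
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    h2 = np.asarray(cfg.qtn_h2, dtype=float)
    background = 0.0
    if scenario == 2:
        background += cfg.polygenic_variance
    elif scenario == 3:
        background += cfg.epi_pairs * cfg.epi_variance
    share_left = 1.0 - h2.sum()
    if share_left <= 0:
        raise ValueError("infeasible heritability shares (sum >= 1)")
    V = (cfg.residual_variance + background) / share_left
    p = cfg.qtn_allele_freq
    beta = np.sqrt(h2 * V / (2.0 * p * (1.0 - p)))
    return beta, float(V)


def select_qtn_columns(g: GenotypeMatrix, marker_map: MarkerMap,
                       cfg: ScenarioConfig) -> np.ndarray:
    """QTN columns with sample MAF nearest the target, mutually unlinked.

    Candidates are taken in order of |MAF - target|; a candidate is
    accepted only if it sits on a different chromosome than every chosen
    QTN or at least ``min_qtn_separation_bp`` away.
    """
    codes = np.asarray(g.codes, dtype=float)
    p_minor = 1.0 - codes.mean(axis=0) / 2.0
    maf = np.minimum(p_minor, 1.0 - p_minor)
    order = np.argsort(np.abs(maf - cfg.qtn_allele_freq), kind="stable")
    chrom = marker_map.chromosomes
    pos = marker_map.positions
    chosen: list[int] = []
    for j in order:
        if maf[j] <= 0:
            continue
        ok = all(chrom[j] != chrom[i]
                 or abs(int(pos[j]) - int(pos[i])) >= cfg.min_qtn_separation_bp
                 for i in chosen)
        if ok:
            chosen.append(int(j))
        if len(chosen) == cfg.qtn_count:
            return np.array(sorted(chosen))
    raise ValueError("panel too small to place unlinked QTNs")


def simulate_scenario(cfg: ScenarioConfig, g: GenotypeMatrix,
                      marker_map: MarkerMap, scenario: int = 1,
                      seed=None, *, kinship: KinshipFactor | None = None,
                      qtn_indices: np.ndarray | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[PhenotypeVector, ScenarioTruth]:
    """One phenotype replicate of the chosen scenario on a given panel."""
    rng = np.random.default_rng(seed) if rng is None else rng
    beta, V = calibrate_qtn_effects(cfg, scenario)
    if qtn_indices is None:
        qtn_indices = select_qtn_columns(g, marker_map, cfg)
    Z = np.asarray(g.codes, dtype=float)
    n = g.n
    y = np.full(n, cfg.grand_mean) + Z[:, qtn_indices] @ beta

    epi_pairs: list[tuple[int, int]] = []
    epi_effects: list[float] = []
    if scenario == 2:
        kf = kinship if kinship is not None else build_kinship(g)
        scale = np.sqrt(np.clip(kf.eigvals, 0.0, None) * cfg.polygenic_variance)
        y = y + kf.U @ (scale * rng.standard_normal(n))
    elif scenario == 3:
        non_qtn = np.setdiff1d(np.arange(g.m), qtn_indices)
        pool = rng.permutation(non_qtn)
        i = 0
        while len(epi_pairs) < cfg.epi_pairs:
            if i + 1 >= len(pool):
                raise ValueError("panel too small to place epistatic pairs")
            a, b = int(pool[i]), int(pool[i + 1])
            i += 2
            c = (Z[:, a] - Z[:, a].mean()) * (Z[:, b] - Z[:, b].mean())
            v = c.var()
            if v <= 0:
                continue
            b_jj = np.sqrt(cfg.epi_variance / v)
            y = y + c * b_jj
            epi_pairs.append((a, b))
            epi_effects.append(float(b_jj))

    y = y + rng.normal(0.0, np.sqrt(cfg.residual_variance), size=n)
    truth = ScenarioTruth(scenario=scenario, qtn_indices=qtn_indices,
                          qtn_effects=beta, qtn_h2=tuple(cfg.qtn_h2),
                          total_variance=V, epi_pairs=epi_pairs,
                          epi_effects=epi_effects, seed=seed)
    return PhenotypeVector(y, f"scenario{scenario}"), truth


# ---------------------------------------------------------------------------
# Pedigree simulation (experiment 2)
# ---------------------------------------------------------------------------

def _haldane_recomb_prob(distance_bp: np.ndarray) -> np.ndarray:
    """Recombination fraction at 1 cM/Mb: r = (1 - exp(-2 d_Morgan)) / 2."""
    d_morgan = np.asarray(distance_bp, dtype=float) * 1e-8
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def _drop_gametes(parent_haps: np.ndarray, parent_idx: np.ndarray,
                  recomb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gametes for one chromosome: Markov switching between the two
    parental haplotypes (Haldane, no interference)."""
    n_off = len(parent_idx)
    m_c = parent_haps.shape[2]
    start = rng.integers(0, 2, size=n_off)
    switches = rng.random((n_off, m_c - 1)) < recomb[None, :]
    which = (start[:, None] + np.concatenate(
        [np.zeros((n_off, 1), dtype=np.int64), np.cumsum(switches, axis=1)],
        axis=1)) % 2
    A = parent_haps[parent_idx]                      # n_off x 2 x m_c
    return np.take_along_axis(A, which[:, None, :], axis=1)[:, 0, :]


def simulate_pedigree(design: PedigreeDesign | None = None, seed=None
                      ) -> PedigreeResult:
    """Gene-drop the five-generation design and simulate three traits.

    Founder haplotypes are drawn with per-SNP allele frequencies uniform on
    the configured range; offspring receive recombinant gametes (Haldane
    map, 1 cM/Mb, so each 100 Mb chromosome spans 1 Morgan).  QTL effects
    are multivariate normal across traits with the configured correlation;
    per-trait residual variances are set so the realized heritabilities in
    the analysis set (females of G1..G(generations-2)) match ``trait_h2``.
    """
    design = design or PedigreeDesign()
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    N = design.total_individuals
    m_total = design.total_snps
    n_chrom = design.chromosomes
    m_c = design.snps_per_chrom
    spacing = design.chrom_length_bp // m_c
    positions = np.array([(j + 1) * spacing for j in range(m_c)] * n_chrom)
    chroms = np.repeat([str(c + 1) for c in range(n_chrom)], m_c)
    marker_map = MarkerMap.from_arrays(
        [f"snp{j}" for j in range(m_total)], chroms, positions)
    recomb = _haldane_recomb_prob(np.diff(positions[:m_c]))

    lo, hi = design.founder_freq_range
    freqs = rng.uniform(lo, hi, size=m_total)
    haps = np.zeros((N, 2, m_total), dtype=np.uint8)
    nf = design.founders
    haps[:nf] = (rng.random((nf, 2, m_total)) < freqs[None, None, :]).astype(np.uint8)

    sex = np.zeros(N, dtype="U1")
    generation = np.zeros(N, dtype=np.int64)
    sire = np.full(N, -1, dtype=np.int64)
    dam = np.full(N, -1, dtype=np.int64)
    n_f_males = nf // 2
    sex[:n_f_males] = "M"
    sex[n_f_males:nf] = "F"

    next_id = nf
    for gen in range(1, design.generations):
        prev = np.flatnonzero(generation == gen - 1) if gen > 1 else np.arange(nf)
        prev_males = prev[sex[prev] == "M"]
        prev_females = prev[sex[prev] == "F"]
        if len(prev_males) == 0 or len(prev_females) == 0:
            raise ValueError("previous generation lacks one sex; cannot mate")
        n_off = design.males_per_gen + design.females_per_gen
        # each sire serves an equal share of the matings (51 when 20 sires
        # produce 1020 offspring); dams sampled with replacement
        sires_g = np.repeat(prev_males, int(np.ceil(n_off / len(prev_males))))[:n_off]
        dams_g = rng.choice(prev_females, size=n_off, replace=True)
        ids = np.arange(next_id, next_id + n_off)
        generation[ids] = gen
        sire[ids] = sires_g
        dam[ids] = dams_g
        male_slots = rng.permutation(n_off)[:design.males_per_gen]
        sex[ids] = "F"
        sex[ids[male_slots]] = "M"
        for c in range(n_chrom):
            sl = slice(c * m_c, (c + 1) * m_c)
            haps[ids, 0, sl] = _drop_gametes(haps[:, :, sl], sires_g, recomb, rng)
            haps[ids, 1, sl] = _drop_gametes(haps[:, :, sl], dams_g, recomb, rng)
        next_id += n_off

    codes = haps.sum(axis=1, dtype=np.int8)
    genotypes = GenotypeMatrix(codes, np.zeros((N, m_total), dtype=bool),
                               [f"ind{i}" for i in range(N)])
    pedigree = pd.DataFrame({
        "id": [f"ind{i}" for i in range(N)], "sire": sire, "dam": dam,
        "sex": sex, "generation": generation})

    even = np.arange(0, m_total, 2)
    qtl_indices = np.sort(rng.choice(even, size=design.qtl_count, replace=False))
    chol = np.linalg.cholesky(design.genetic_correlation)
    qtl_effects = rng.standard_normal((design.qtl_count, design.n_traits)) @ chol.T
    G = codes[:, qtl_indices].astype(float) @ qtl_effects    # N x traits

    analysis = np.flatnonzero(
        (generation >= 1) & (generation <= design.generations - 2) & (sex == "F"))
    phenos: list[PhenotypeVector] = []
    resid_vars = np.zeros(design.n_traits)
    for t, h2 in enumerate(design.trait_h2):
        var_g = float(G[analysis, t].var())
        resid_vars[t] = var_g * (1.0 - h2) / h2 if var_g > 0 else 1.0
        y = G[:, t] + rng.normal(0.0, np.sqrt(resid_vars[t]), size=N)
        phenos.append(PhenotypeVector(y, f"trait{t + 1}"))

    return PedigreeResult(genotypes=genotypes, marker_map=marker_map,
                          pedigree=pedigree, phenotypes=phenos,
                          analysis_indices=analysis, qtl_indices=qtl_indices,
                          qtl_effects=qtl_effects, residual_variances=resid_vars,
                          seed=seed if seed is not None else design.seed)


def simulate_related_panel(n: int = 500, m: int = 2000, seed=None
                           ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Genotype panel of related individuals for variance-component work.

    Marker-based REML can only separate the polygenic variance from the
    residual when the kinship matrix varies across pairs: for a panel of
    unrelated individuals in Hardy-Weinberg equilibrium, K is close to a
    constant matrix plus noise and the variance ratio is unidentifiable.
    This generator therefore reduces the five-generation mating design to
    ``n`` individuals (20 founders, then four generations of 10 males and
    (n - 20)/4 - 10 females each), yielding a mixture of parent-offspring,
    full-sib and half-sib relationships like a livestock population.
    """
    if (n - 20) % 4 != 0 or n < 100:
        raise ValueError("n must be 20 + 4*g for a generation size g >= 20")
    per_gen = (n - 20) // 4
    design = PedigreeDesign(founders=20, males_per_gen=10,
                            females_per_gen=per_gen - 10, chromosomes=5,
                            snps_per_chrom=m // 5, qtl_count=2)
    res = simulate_pedigree(design, seed=seed)
    return res.genotypes, res.marker_map


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def export_experiment(g: GenotypeMatrix, marker_map: MarkerMap,
                      phenotypes: list[PhenotypeVector], truth,
                      directory, *, force: bool = False) -> None:
    """Write PLINK trio + phenotype TSV + truth JSON into ``directory``."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} exists and is not empty "
                              "(pass force=True to overwrite)")
    directory.mkdir(parents=True, exist_ok=True)
    write_plink(g, marker_map, directory / "genotypes")
    df = pd.DataFrame({"sample_id": g.sample_ids})
    for ph in phenotypes:
        df[ph.trait_name] = ph.values
    df.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1)
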