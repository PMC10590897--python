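"""Synthetic genotype/phenotype generator with planted QTL.

Generates inbred-line dosage matrices with block LD structure (a Gaussian
copula per block, thresholded to allele calls) and multi-environment ordinal
damage ratings from a liability model:

    liability = intercept + sum_q beta_q * dosage_q
                + env + GxE + rep(env) + residual

binned onto the half-point grid {1.0, 1.5, ..., 4.0} by fixed breakpoints.
Defaults emulate a multi-environment soybean screening trial: ~550 inbred
lines, chip-density SNPs with MAF >= 0.05, a handful of large- plus
small-effect QTL, and a three-replicate design across nine environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix

RATING_GRID = np.arange(1.0, 4.01, 0.5)

#: Liability step per half-rating-point.  Binning maps liability z to the
#: grid point nearest 2.5 + 0.5 * z / step, so a zero-liability line averages
#: a rating of 2.5 and the binning is unbiased and symmetric.  A genotype is
#: tolerant (adjusted mean <= 2) once its genetic value falls below -step;
#: with the default architecture (genetic SD ~0.84) step = 0.74 puts ~19% of
#: lines in each tail, matching a typical tolerant/moderate/susceptible mix.
LIABILITY_STEP = 0.74

#: Interior breakpoints: +-step/2, +-3*step/2, +-5*step/2.
DEFAULT_BREAKPOINTS = tuple(LIABILITY_STEP * b for b in
                            (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5))


@dataclass
class SimulationTruth:
    """Ground truth of a simulation: planted QTL and variance components."""

    qtl_snp_ids: list
    qtl_effects: np.ndarray
    variance_components: dict
    seed: int
    liability_breakpoints: tuple = DEFAULT_BREAKPOINTS
    intercept: float = 0.0  # latent-scale mean; 0 bins to the grid midpoint 2.5

    def __post_init__(self):
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if len(self.qtl_snp_ids) != len(self.qtl_effects):
            raise ValueError("qtl_snp_ids and qtl_effects length mismatch")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be >= 0")
        bp = np.asarray(self.liability_breakpoints, dtype=float)
        if len(bp) != 6 or not np.all(np.diff(bp) > 0):
            raise ValueError("need 6 strictly increasing liability breakpoints")


def default_variance_components() -> dict:
    """Environment / GxE / replicate / residual variances on the liability scale.

    With the default QTL variance shares summing to 0.70, these bring the
    total per-plot liability variance to ~1.0 so the default breakpoints
    (standard-normal quantiles) give the intended class mix, and the
    entry-mean repeatability is high, as in a well-replicated
    multi-environment screen of a visually scored trait.
    """
    return {"env": 0.12, "gxe": 0.05, "rep": 0.03, "residual": 0.10}


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    n_chromosomes: int = 10,
    block_size: int = 10,
    within_block_corr: float = 0.6,
    maf_range=(0.05, 0.5),
    seed: int = 0,
    het_rate: float = 0.0,
    max_retries: int = 200,
) -> GenotypeMatrix:
    """Simulate an inbred-line dosage matrix with block LD.

    Within a block, latent haplotype values are drawn from a compound-symmetric
    Gaussian copula with correlation ``within_block_corr`` and thresholded at
    the quantile of each SNP's target allele frequency; blocks are independent.
    Lines are fully inbred (one haplotype doubled) unless ``het_rate`` > 0, in
    which case that fraction of calls draws a second independent haplotype.
    Blocks are redrawn until every realized MAF clears the lower bound.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if n_lines < 2 or n_snps < 1:
        raise ValueError("need n_lines >= 2 and n_snps >= 1")
    if np.ceil(n_lines * lo) > n_lines:  # pragma: no cover - defensive
        raise ValueError("MAF lower bound unreachable at this n_lines")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E0]))
    # contiguous chromosome chunks; blocks never span a chromosome boundary
    chrom_sizes = np.full(n_chromosomes, n_snps // n_chromosomes)
    chrom_sizes[: n_snps % n_chromosomes] += 1

    cols, snp_ids, chroms, poss = [], [], [], []
    snp_idx = 0
    for c, csize in enumerate(chrom_sizes, start=1):
        pos = 0
        for start in range(0, int(csize), block_size):
            bsize = min(block_size, int(csize) - start)
            block = _draw_block(
                rng, n_lines, bsize, within_block_corr, lo, hi, het_rate,
                max_retries, chrom=c, start=snp_idx,
            )
            cols.append(block)
            for _ in range(bsize):
                snp_idx += 1
                pos += int(rng.integers(5_000, 100_000))
                snp_ids.append(f"snp{snp_idx:06d}")
                chroms.append(str(c))
                poss.append(pos)
    dosages = np.concatenate(cols, axis=1)
    # orient to minor-allele dosage (target freqs near 0.5 can land above it)
    flip = dosages.mean(axis=0) / 2.0 > 0.5
    dosages[:, flip] = 2 - dosages[:, flip]
    alleles = rng.choice(list("ACGT"), size=(n_snps, 2))
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": alleles[:, 0], "alt": alleles[:, 1]},
        index=snp_ids,
    )
    return GenotypeMatrix(
        line_ids=[f"line{i:04d}" for i in range(1, n_lines + 1)],
        snp_ids=snp_ids,
        dosages=dosages,
        snp_meta=meta,
    )


def _draw_block(rng, n_lines, bsize, rho, lo, hi, het_rate, max_retries, chrom, start):
    freqs = rng.uniform(lo, hi, size=bsize)
    thresh = stats.norm.ppf(freqs)
    for _ in range(max_retries):
        hap1 = _correlated_normals(rng, n_lines, bsize, rho)
        a1 = (hap1 < thresh).astype(np.int8)
        if het_rate > 0:
            hap2 = _correlated_normals(rng, n_lines, bsize, rho)
            a2 = (hap2 < thresh).astype(np.int8)
            use_het = rng.random((n_lines, bsize)) < het_rate
            d = np.where(use_het, a1 + a2, 2 * a1).astype(np.int8)
        else:
            d = (2 * a1).astype(np.int8)
        f = d.mean(axis=0) / 2.0
        maf = np.minimum(f, 1 - f)
        if np.all(maf >= lo):
            return d
    raise RuntimeError(
        f"could not realize MAF >= {lo} for block at chromosome {chrom}, "
        f"SNP index {start} (target freqs {np.round(freqs, 3)}) "
        f"after {max_retries} redraws; raise n_lines or the MAF lower bound"
    )


def _correlated_normals(rng, n, m, rho):
    # compound-symmetric correlation rho via a shared factor
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * own


def plant_qtl(
    genotypes: GenotypeMatrix,
    variance_shares=(0.30, 0.10, 0.10, 0.05, 0.05, 0.04, 0.03, 0.03),
    seed: int = 0,
    variance_components: dict = None,
) -> SimulationTruth:
    """Pick QTL SNPs and scale effects to hit target liability-variance shares.

    Each share is the fraction of total per-plot liability variance the QTL
    explains, computed against the realized dosage variance of the chosen SNP
    (so a share of 0.30 plants a major-effect locus).  QTL are spread across
    chromosomes where possible and signs alternate.
    """
    if variance_components is None:
        variance_components = default_variance_components()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x917]))
    shares = np.asarray(variance_shares, dtype=float)
    noise_var = sum(variance_components.values())
    total_var = noise_var / max(1e-12, 1.0 - shares.sum())

    meta = genotypes.snp_meta
    chrom_groups = list(meta.groupby("chrom", sort=False).groups.values())
    rng.shuffle(chrom_groups)
    chosen = []
    gi = 0
    while len(chosen) < len(shares):
        group = chrom_groups[gi % len(chrom_groups)]
        cand = [s for s in group if s not in chosen]
        if cand:
            chosen.append(cand[int(rng.integers(len(cand)))])
        gi += 1
    effects = []
    X = genotypes.imputed()
    for k, sid in enumerate(chosen):
        v = X[sid].to_numpy().var()
        beta = np.sqrt(shares[k] * total_var / max(v, 1e-9))
        effects.append(beta if k % 2 == 0 else -beta)
    return SimulationTruth(
        qtl_snp_ids=chosen,
        qtl_effects=np.array(effects),
        variance_components=dict(variance_components),
        seed=seed,
    )


def genetic_values(genotypes: GenotypeMatrix, truth: SimulationTruth) -> pd.Series:
    """Per-line genetic liability (centered QTL sum), indexed by line id."""
    X = genotypes.imputed()
    missing = [s for s in truth.qtl_snp_ids if s not in X.columns]
    if missing:
        raise ValueError(f"QTL SNPs absent from genotypes: {missing}")
    g = X[truth.qtl_snp_ids].to_numpy() @ truth.qtl_effects
    return pd.Series(g - g.mean(), index=genotypes.line_ids, name="genetic_value")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    n_envs: int = 9,
    n_reps: int = 3,
    return_liability: bool = False,
) -> pd.DataFrame:
    """Simulate plot ratings: one row per line x environment x replicate.

    Returns a long-format DataFrame (genotype, environment, replicate, score).
    With ``return_liability`` the continuous latent liability is included as a
    ``liability`` column (debug output for variance accounting).
    """
    if genotypes.n_lines == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    if n_envs < 1 or n_reps < 1:
        raise ValueError("need n_envs >= 1 and n_reps >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xBE7]))
    vc = truth.variance_components
    g = genetic_values(genotypes, truth).to_numpy()
    n = genotypes.n_lines

    env_eff = rng.normal(0, np.sqrt(vc.get("env", 0.0)), size=n_envs)
    rep_eff = rng.normal(0, np.sqrt(vc.get("rep", 0.0)), size=(n_envs, n_reps))
    gxe_eff = rng.normal(0, np.sqrt(vc.get("gxe", 0.0)), size=(n, n_envs))
    resid = rng.normal(0, np.sqrt(vc.get("residual", 0.0)), size=(n, n_envs, n_reps))

    liab = (
        truth.intercept
        + g[:, None, None]
        + env_eff[None, :, None]
        + gxe_eff[:, :, None]
        + rep_eff[None, :, :]
        + resid
    )
    score = bin_liability(liab, truth.liability_breakpoints)
    idx = pd.MultiIndex.from_product(
        [genotypes.line_ids, [f"env{e+1}" for e in range(n_envs)],
         [f"rep{r+1}" for r in range(n_reps)]],
        names=["genotype", "environment", "replicate"],
    )
    out = pd.DataFrame({"score": score.ravel()}, index=idx).reset_index()
    if return_liability:
        out["liability"] = liab.ravel()
    return out


def bin_liability(liability, breakpoints=DEFAULT_BREAKPOINTS) -> np.ndarray:
    """Map continuous liability onto the {1.0, 1.5, ..., 4.0} rating grid."""
    k = np.searchsorted(np.asarray(breakpoints, dtype=float), liability, side="left")
    return RATING_GRID[k]


def simulate_dataset(
    n_lines: int = 551,
    n_snps: int = 4970,
    n_chromosomes: int = 20,
    n_envs: int = 9,
    n_reps: int = 3,
    variance_shares=(0.30, 0.10, 0.10, 0.05, 0.05, 0.04, 0.03, 0.03),
    seed: int = 0,
    **genotype_kwargs,
):
    """One-call study emulation: genotypes, planted truth, and plot ratings.

    Defaults mirror a chip-genotyped advanced-breeding-line panel screened in
    a three-replicate design across nine environments, with one major and
    several minor QTL.  Genotype and phenotype RNG streams are derived
    independently from ``seed``, so re-simulating phenotypes does not perturb
    the genotypes.

    Returns ``(genotypes, truth, ratings)``.
    """
    g = simulate_genotypes(
        n_lines=n_lines, n_snps=n_snps, n_chromosomes=n_chromosomes,
        seed=seed, **genotype_kwargs,
    )
    truth = plant_qtl(g, variance_shares=variance_shares, seed=seed)
    ratings = simulate_phenotypes(g, truth, n_envs=n_envs, n_reps=n_reps)
    return g, truth, ratings


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the simulation ground truth as a YAML sidecar."""
    import yaml

    doc = {
        "qtl_snp_ids": list(truth.qtl_snp_ids),
        "qtl_effects": [float(b) for b in truth.qtl_effects],
        "variance_components": {k: float(v) for k, v in truth.variance_components.items()},
        "seed": int(truth.seed),
        "liability_breakpoints": [float(b) for b in truth.liability_breakpoints],
        "intercept": float(truth.intercept),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth(path) -> SimulationTruth:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimulationTruth(
        qtl_snp_ids=doc["qtl_snp_ids"],
        qtl_effects=np.asarray(doc["qtl_effects"], dtype=float),
        variance_components=doc["variance_components"],
        seed=doc["seed"],
        liability_breakpoints=tuple(doc["liability_breakpoints"]),
        intercept=doc.get("intercept", 0.0),
    )
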