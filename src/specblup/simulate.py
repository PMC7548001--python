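"""Synthetic multi-environment trial generator with known ground truth.

Emulates a hybrid-rye testcross study: recombinant inbred lines (RILs)
from a round-robin chain of biparental founder crosses, evaluated in
multi-environment alpha-lattice trials, with plot-level phenotypes
(fresh matter yield FMY, dry matter content DMC, dry matter yield
DMY = FMY * DMC / 100, plant height PH) and normalized hyperspectral
reflectance on a 410-993 nm band grid measured on repeated flight
dates.  Every stochastic quantity has a recorded ground truth
(breeding values, band loadings, realized heritabilities) so that the
downstream adjustment, kernel and prediction stages can be tested
against known parameters.

The default configuration mirrors the emulated study: 10 founders,
264 RILs (plus founders: 274 genotypes), 8 environments (4 locations x
2 years), two alpha-lattice trials of two replicates per environment,
400 bands, two flight dates, entry-mean heritabilities of 0.5 (DMY)
and 0.8 (PH) and a DMY-PH genetic correlation of 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_population",
    "simulate_trial_design",
    "simulate_phenotypes",
    "simulate_spectra",
    "simulate_study",
]

N_CHROMOSOMES = 7  # rye karyotype

# fixed offsets deriving one independent RNG stream per operation
_STREAM = {"population": 11, "design": 23, "phenotypes": 37, "spectra": 53}


def _default_band_grid() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(410.0, 993.0, 400), 1))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study."""

    n_founders: int = 10
    n_lines: int = 264               # RILs; founders are appended as checks
    include_founders: bool = True
    n_markers: int = 2000
    n_envs: int = 8                  # n_locations x n_years
    n_locations: int = 4
    n_years: int = 2
    n_trials_per_env: int = 2
    n_reps: int = 2
    block_size: int = 10
    n_bands: int = 400
    band_grid: tuple[float, ...] = field(default_factory=_default_band_grid)
    n_dates: int = 2
    h2_dmy: float = 0.5
    h2_ph: float = 0.8
    rg_dmy_ph: float = 0.6
    cs_correlation: float = 0.5      # between-date error correlation per plot
    env_error_sds: tuple[float, ...] | None = None
    seed: int = 0

    # genome / QTL model
    n_selfing_gens: int = 4          # S4 lines
    crossovers_per_chrom: float = 1.5
    recomb_rate: float | None = None  # per marker interval; None -> derived
    frac_qtl: float = 0.10

    # trait scales (DMY in dt/ha, PH in cm)
    mu_dmy: float = 120.0
    sigma_g_dmy: float = 10.0
    mu_ph: float = 140.0
    sigma_g_ph: float = 8.0
    mu_dmc: float = 35.0
    sd_dmc: float = 1.5
    re_dmy_ph: float = 0.3           # residual plot-level correlation

    # environment / design effect SDs (per trait scale fraction of sigma_g)
    sd_loc_frac: float = 0.8
    sd_year_frac: float = 0.8
    sd_locyear_frac: float = 0.6
    sd_trial_frac: float = 0.3
    sd_rep_frac: float = 0.2
    sd_block_frac: float = 0.4
    gxe_split: tuple[float, float, float] = (0.3, 0.3, 0.4)  # LxG, YxG, LxYxG
    env_error_spread: float = 0.2    # relative spread of per-env error SDs
    decorrelated_envs: tuple[int, ...] = ()  # envs with independent GxE

    # spectral model (normalized-reflectance scale)
    band_peak_nm: float = 750.0
    band_peak_width_nm: float = 30.0
    band_loading_amp: float = 0.10
    band_latent_noise: float = 0.3   # latent score impurity vs DMY BV
    band_bg_sd: float = 0.04         # smooth genetic background per band
    band_bg_ncomp: int = 4           # smooth basis functions for background
    band_gxe_sd: float = 0.05        # genotype-by-environment deviation per band
    spectra_noise_sd: float = 0.06   # per plot x band, split by cs_correlation
    spectra_date_sd: float = 0.02
    spectra_design_sd: float = 0.01

    def __post_init__(self):
        if min(self.n_founders, self.n_lines, self.n_markers, self.n_envs,
               self.n_trials_per_env, self.n_reps, self.block_size,
               self.n_bands, self.n_dates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_founders < 3:
            raise ValueError("round-robin scheme needs >= 3 founders")
        for name in ("h2_dmy", "h2_ph"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not -1.0 <= self.rg_dmy_ph <= 1.0:
            raise ValueError("rg_dmy_ph must lie in [-1, 1]")
        if not 0.0 <= self.cs_correlation < 1.0:
            raise ValueError("cs_correlation must lie in [0, 1)")
        grid = np.asarray(self.band_grid, dtype=float)
        if grid.size != self.n_bands:
            raise ValueError("band_grid length must equal n_bands")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("band_grid must be strictly increasing")
        if self.env_error_sds is not None and len(self.env_error_sds) != self.n_envs:
            raise ValueError("env_error_sds must have one entry per environment")
        if self.n_locations * self.n_years != self.n_envs:
            raise ValueError("n_envs must equal n_locations * n_years")

    @property
    def n_genotypes(self) -> int:
        return self.n_lines + (self.n_founders if self.include_founders else 0)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAM[stream]])
        )


@dataclass
class TruthRecord:
    """Ground truth of one simulated study."""

    breeding_values: pd.DataFrame      # genotype, bv_dmy, bv_ph
    band_loadings: pd.DataFrame        # wavelength, loading
    realized_h2: dict[str, float]
    latent_score: np.ndarray | None = None


def _marker_map(cfg: SimulationConfig) -> tuple[np.ndarray, float]:
    """Chromosome assignment per marker and the per-interval recomb rate."""
    chrom = np.repeat(np.arange(N_CHROMOSOMES),
                      int(np.ceil(cfg.n_markers / N_CHROMOSOMES)))[: cfg.n_markers]
    if cfg.recomb_rate is not None:
        r = float(cfg.recomb_rate)
    else:
        per_chrom = max(np.bincount(chrom).max() - 1, 1)
        r = min(cfg.crossovers_per_chrom / per_chrom, 0.5)
    return chrom, r


def _gamete(h0: np.ndarray, h1: np.ndarray, chrom: np.ndarray, r: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a diploid (vectorised Markov path)."""
    m = h0.size
    new_chrom = np.empty(m, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    # crossover events between adjacent markers, none across chromosomes;
    # cumulative XOR of the events (reset per chromosome) picks the haplotype
    flips = (rng.random(m) < r) & ~new_chrom
    cum = np.cumsum(flips)
    base = np.zeros(m, dtype=np.int64)
    starts = np.nonzero(new_chrom)[0]
    base[starts] = cum[starts]
    base = np.maximum.accumulate(base)
    path = (cum - base) % 2
    seg = np.cumsum(new_chrom) - 1
    start = (rng.random(N_CHROMOSOMES) < 0.5).astype(int)
    hap = start[seg] ^ path
    return np.where(hap == 0, h0, h1)


def simulate_population(cfg: SimulationConfig):
    """Simulate RIL marker dosages and true breeding values.

    Returns ``(markers, truth)`` where ``markers`` is a genotype x marker
    DataFrame of dosages in {0, 1, 2} (monomorphic markers dropped) and
    ``truth`` records true breeding values and band loadings.
    """
    rng = cfg.rng("population")
    chrom, r = _marker_map(cfg)

    p_founder = rng.uniform(0.2, 0.8, cfg.n_markers)
    founders = (rng.random((cfg.n_founders, cfg.n_markers)) < p_founder).astype(np.int8)

    # round-robin chain: cross i x (i+1 mod F), lines spread over crosses
    cross_of_line = np.arange(cfg.n_lines) % cfg.n_founders
    haplotypes = np.empty((cfg.n_lines, 2, cfg.n_markers), dtype=np.int8)
    for i in range(cfg.n_lines):
        a = founders[cross_of_line[i]]
        b = founders[(cross_of_line[i] + 1) % cfg.n_founders]
        h0, h1 = a.copy(), b.copy()          # the F1
        for _ in range(cfg.n_selfing_gens):  # selfing with recombination
            g0 = _gamete(h0, h1, chrom, r, rng)
            g1 = _gamete(h0, h1, chrom, r, rng)
            h0, h1 = g0, g1
        haplotypes[i, 0], haplotypes[i, 1] = h0, h1

    dosages = haplotypes.sum(axis=1)
    if cfg.include_founders:
        dosages = np.vstack([dosages, 2 * founders])
    genotypes = [f"G{i + 1:04d}" for i in range(dosages.shape[0])]

    freq = dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.any():
        raise ValueError(
            "simulated markers are all monomorphic; increase n_lines or "
            "n_markers, or widen founder allele frequencies"
        )
    dosages = dosages[:, poly]
    marker_ids = [f"M{j + 1:05d}" for j in np.nonzero(poly)[0]]
    markers = pd.DataFrame(dosages, index=pd.Index(genotypes, name="genotype"),
                           columns=marker_ids)

    # additive bivariate QTL effects -> true breeding values, rescaled to
    # the configured genetic SDs (rescaling preserves the correlation)
    m_poly = dosages.shape[1]
    n_qtl = max(int(round(cfg.frac_qtl * m_poly)), 1)
    qtl = rng.choice(m_poly, size=n_qtl, replace=False)
    rho = cfg.rg_dmy_ph
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    eff = rng.standard_normal((n_qtl, 2)) @ L.T
    Zc = dosages[:, qtl] - dosages[:, qtl].mean(axis=0)
    bv = Zc @ eff
    bv -= bv.mean(axis=0)
    sd = bv.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    bv /= sd
    # linkage leaves few independent genome segments, so the realized BV
    # correlation would wander around rho; enforce it exactly by
    # Gram-Schmidt (both traits remain linear in the markers)
    if abs(rho) < 1.0 and bv.shape[0] > 2:
        z1 = bv[:, 0]
        r12 = float(np.corrcoef(z1, bv[:, 1])[0, 1])
        u = bv[:, 1] - r12 * z1
        usd = u.std(ddof=1)
        if usd > 0:
            bv[:, 1] = rho * z1 + np.sqrt(1.0 - rho ** 2) * u / usd
    bv = bv * np.array([cfg.sigma_g_dmy, cfg.sigma_g_ph])

    grid = np.asarray(cfg.band_grid, dtype=float)
    loadings = cfg.band_loading_amp * np.exp(
        -0.5 * ((grid - cfg.band_peak_nm) / cfg.band_peak_width_nm) ** 2
    )
    truth = TruthRecord(
        breeding_values=pd.DataFrame(
            {"genotype": genotypes, "bv_dmy": bv[:, 0], "bv_ph": bv[:, 1]}
        ),
        band_loadings=pd.DataFrame({"wavelength": grid, "loading": loadings}),
        realized_h2={},
    )
    return markers, truth


def simulate_trial_design(cfg: SimulationConfig,
                          genotypes: list[str] | None = None,
                          trial_sizes: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Alpha-lattice layout: env / trial / replicate / block / plot / genotype.

    Genotypes are split once into trials (shared split across
    environments, as in a testcross series); within each replicate the
    block composition is re-randomized.
    """
    rng = cfg.rng("design")
    if genotypes is None:
        genotypes = [f"G{i + 1:04d}" for i in range(cfg.n_genotypes)]
    n = len(genotypes)
    n_trials = cfg.n_trials_per_env
    if trial_sizes is not None:
        if sum(trial_sizes) != n or len(trial_sizes) != n_trials:
            raise ValueError("trial_sizes must partition the genotypes over "
                             "n_trials_per_env trials")
        sizes = list(trial_sizes)
    else:
        sizes = [n // n_trials + (1 if i < n % n_trials else 0)
                 for i in range(n_trials)]
    if cfg.block_size > max(sizes):
        raise ValueError(
            f"block_size {cfg.block_size} exceeds the largest trial size {max(sizes)}"
        )
    order = rng.permutation(n)
    trial_members: list[list[str]] = []
    k = 0
    for s in sizes:
        trial_members.append([genotypes[i] for i in order[k:k + s]])
        k += s

    rows = []
    plot = 0
    for env in range(cfg.n_envs):
        for t, members in enumerate(trial_members):
            for rep in range(cfg.n_reps):
                perm = rng.permutation(len(members))
                for pos, idx in enumerate(perm):
                    plot += 1
                    rows.append((
                        f"P{plot:06d}", f"E{env + 1}", f"T{t + 1}",
                        f"R{rep + 1}", f"B{pos // cfg.block_size + 1}",
                        members[idx],
                    ))
    df = pd.DataFrame(rows, columns=["plot_id", "env", "trial", "rep",
                                     "block", "genotype"])
    loc = (df["env"].str.slice(1).astype(int) - 1) % cfg.n_locations
    year = (df["env"].str.slice(1).astype(int) - 1) // cfg.n_locations
    df["location"] = "L" + (loc + 1).astype(str)
    df["year"] = "Y" + (year + 1).astype(str)
    return df


def _variance_targets(cfg: SimulationConfig, trait: str):
    """GxE and error variances implied by the target entry-mean h2.

    The GxE budget is split over LxG, YxG and LxYxG terms; a genotype
    mean averages them over L, Y and LY levels respectively, so the
    contribution to vbar/2 is s_ge2 * (f_LG/L + f_YG/Y + f_LYG/(LY)).
    Half the target vbar/2 is assigned to GxE, half to plot error.
    """
    if trait == "dmy":
        sg, h2 = cfg.sigma_g_dmy, cfg.h2_dmy
    else:
        sg, h2 = cfg.sigma_g_ph, cfg.h2_ph
    c = sg ** 2 * (1.0 - h2) / h2          # target vbar/2
    e = cfg.n_envs
    r = cfg.n_reps
    fr = cfg.gxe_split
    f = (fr[0] / cfg.n_locations + fr[1] / cfg.n_years
         + fr[2] / (cfg.n_locations * cfg.n_years))
    s_ge2 = c / (2.0 * f)                  # so mean-level GxE share = c/2
    s_e2 = c * e * r / 2.0                 # so s_e2/(Er) = c/2
    return sg ** 2, s_ge2, s_e2


def _env_error_sds(cfg: SimulationConfig, s_e2: float) -> np.ndarray:
    if cfg.env_error_sds is not None:
        return np.asarray(cfg.env_error_sds, dtype=float)
    mult = np.linspace(1.0 - cfg.env_error_spread, 1.0 + cfg.env_error_spread,
                       cfg.n_envs)
    mult /= np.sqrt(np.mean(mult ** 2))    # keep the mean variance on target
    return np.sqrt(s_e2) * mult


def simulate_phenotypes(markers: pd.DataFrame, design: pd.DataFrame,
                        cfg: SimulationConfig, truth: TruthRecord) -> pd.DataFrame:
    """Plot-level FMY / DMC / DMY / PH with the configured variance structure.

    DMY = genotype BV + location/year/interaction + trial/rep/block +
    env-specific error; FMY and DMC are generated so that
    DMY = FMY * DMC / 100 holds exactly on every plot.
    """
    rng = cfg.rng("phenotypes")
    bv = truth.breeding_values.set_index("genotype")
    missing = set(design["genotype"]) - set(bv.index)
    if missing:
        raise ValueError(f"design references unsimulated genotypes: {sorted(missing)[:5]}")

    out = design.copy()
    n_plots = len(out)
    geno_idx = bv.index.get_indexer(out["genotype"])
    loc_idx = out["location"].str.slice(1).astype(int).to_numpy() - 1
    year_idx = out["year"].str.slice(1).astype(int).to_numpy() - 1
    env_idx = out["env"].str.slice(1).astype(int).to_numpy() - 1
    n_g = len(bv)

    def trait_surface(trait: str, bvcol: np.ndarray):
        sg2, s_ge2, s_e2 = _variance_targets(cfg, trait)
        sg = np.sqrt(sg2)
        fr = cfg.gxe_split
        lg = rng.normal(0, np.sqrt(s_ge2 * fr[0]), (n_g, cfg.n_locations))
        yg = rng.normal(0, np.sqrt(s_ge2 * fr[1]), (n_g, cfg.n_years))
        lyg = rng.normal(0, np.sqrt(s_ge2 * fr[2]), (n_g, cfg.n_envs))
        gxe = (lg[geno_idx, loc_idx] + yg[geno_idx, year_idx]
               + lyg[geno_idx, env_idx])
        if cfg.decorrelated_envs:
            indep = rng.normal(0, np.sqrt(s_ge2), (n_g, cfg.n_envs))
            for e in cfg.decorrelated_envs:
                mask = env_idx == e
                gxe[mask] = indep[geno_idx[mask], e]
        lmain = rng.normal(0, cfg.sd_loc_frac * sg, cfg.n_locations)[loc_idx]
        ymain = rng.normal(0, cfg.sd_year_frac * sg, cfg.n_years)[year_idx]
        ly = rng.normal(0, cfg.sd_locyear_frac * sg, cfg.n_envs)[env_idx]

        design_eff = np.zeros(n_plots)
        for cols, frac in ((["env", "trial"], cfg.sd_trial_frac),
                           (["env", "trial", "rep"], cfg.sd_rep_frac),
                           (["env", "trial", "rep", "block"], cfg.sd_block_frac)):
            codes = pd.MultiIndex.from_frame(out[cols]).factorize()[0]
            design_eff += rng.normal(0, frac * sg, codes.max() + 1)[codes]

        err_sds = _env_error_sds(cfg, s_e2)
        err_z = rng.standard_normal(n_plots)
        return (bvcol[geno_idx] + gxe + lmain + ymain + ly + design_eff,
                err_z, err_sds[env_idx], sg2, s_ge2, s_e2)

    sfc_d, zd, sd_d, sg2_d, sge2_d, se2_d = trait_surface("dmy", bv["bv_dmy"].to_numpy())
    sfc_p, zp, sd_p, sg2_p, sge2_p, se2_p = trait_surface("ph", bv["bv_ph"].to_numpy())
    # correlated plot residuals between DMY and PH
    rho = cfg.re_dmy_ph
    zp = rho * zd + np.sqrt(max(1 - rho ** 2, 0.0)) * zp

    dmy = cfg.mu_dmy + sfc_d + zd * sd_d
    ph = cfg.mu_ph + sfc_p + zp * sd_p
    dmc = np.clip(cfg.mu_dmc + rng.normal(0, cfg.sd_dmc, n_plots), 5.0, 95.0)
    dmy = np.maximum(dmy, 1.0)             # yields are positive
    fmy = dmy * 100.0 / dmc

    out["FMY"] = fmy
    out["DMC"] = dmc
    out["DMY"] = fmy * dmc / 100.0         # identity holds by construction
    out["PH"] = ph

    fr = cfg.gxe_split
    f = (fr[0] / cfg.n_locations + fr[1] / cfg.n_years
         + fr[2] / (cfg.n_locations * cfg.n_years))
    for trait, sg2, sge2, se2 in (("DMY", sg2_d, sge2_d, se2_d),
                                  ("PH", sg2_p, sge2_p, se2_p)):
        vbar2 = sge2 * f + se2 / (cfg.n_envs * cfg.n_reps)
        truth.realized_h2[trait] = sg2 / (sg2 + vbar2)
    return out


def simulate_spectra(markers: pd.DataFrame, design: pd.DataFrame,
                     cfg: SimulationConfig, truth: TruthRecord) -> pd.DataFrame:
    """Per-plot, per-date reflectance spectra (wide table, band columns).

    Band value = smooth canopy profile + genetic loading x latent
    genotype score + date effect + design (illumination) offsets + a
    plot-level deviation shared across dates + per-date residual.  The
    shared plot deviation makes the between-date error correlation equal
    ``cs_correlation`` by construction.
    """
    rng = cfg.rng("spectra")
    bv = truth.breeding_values.set_index("genotype")
    grid = np.asarray(cfg.band_grid, dtype=float)
    loadings = truth.band_loadings["loading"].to_numpy()

    bvd = bv["bv_dmy"].to_numpy()
    z = (bvd - bvd.mean()) / (bvd.std() or 1.0)
    nu = cfg.band_latent_noise
    latent = np.sqrt(max(1 - nu ** 2, 0.0)) * z + nu * rng.standard_normal(len(bv))
    truth.latent_score = latent

    profile = 0.08 + 0.40 / (1.0 + np.exp(-(grid - 720.0) / 15.0))

    # smooth genotype-specific spectral deviations unrelated to DMY: every
    # band is heritable, with heritability varying along the spectrum
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    basis = np.stack([np.cos(np.pi * (c + 1) * x)
                      for c in range(cfg.band_bg_ncomp)], axis=1)
    # heritability envelope: strong genetic control in the visible range,
    # a dip just past the red edge, partial recovery in the near infrared
    envelope = (1.0
                - 0.25 * np.clip((grid - 410.0) / 340.0, 0.0, 1.0)
                - 0.65 * np.exp(-0.5 * ((grid - 770.0) / 30.0) ** 2)
                + 0.25 * np.clip((grid - 800.0) / 200.0, 0.0, 1.0))
    bg_coef = rng.normal(0, cfg.band_bg_sd, (len(bv), cfg.band_bg_ncomp))
    background = (bg_coef @ basis.T) * envelope[None, :]   # genotype x band

    # genotype-by-environment spectral deviations (smooth, shared across
    # dates within an environment): keeps entry-mean band h2 moderate
    gxe_coef = rng.normal(0, cfg.band_gxe_sd,
                          (cfg.n_envs, len(bv), cfg.band_bg_ncomp))

    n_plots = len(design)
    geno_idx = bv.index.get_indexer(design["genotype"])
    env_idx = design["env"].str.slice(1).astype(int).to_numpy() - 1

    # brightness offsets shared across bands (illumination per field unit)
    design_eff = np.zeros(n_plots)
    for cols in (["env", "trial"], ["env", "trial", "rep"],
                 ["env", "trial", "rep", "block"]):
        codes = pd.MultiIndex.from_frame(design[cols]).factorize()[0]
        design_eff += rng.normal(0, cfg.spectra_design_sd, codes.max() + 1)[codes]

    rho = cfg.cs_correlation
    sd_tot = cfg.spectra_noise_sd
    sd_plot = sd_tot * np.sqrt(rho)
    sd_res = sd_tot * np.sqrt(1.0 - rho)
    plot_dev = rng.normal(0, sd_plot, (n_plots, cfg.n_bands))
    date_eff = rng.normal(0, cfg.spectra_date_sd, (cfg.n_envs, cfg.n_dates))

    frames = []
    for d in range(cfg.n_dates):
        gxe_dev = np.einsum("pc,bc->pb", gxe_coef[env_idx, geno_idx], basis)
        vals = (profile[None, :]
                + np.outer(latent[geno_idx], loadings)
                + background[geno_idx]
                + gxe_dev
                + design_eff[:, None]
                + plot_dev
                + date_eff[env_idx, d][:, None]
                + rng.normal(0, sd_res, (n_plots, cfg.n_bands)))
        frame = pd.DataFrame(vals, columns=[_band_name(w) for w in grid])
        frame.insert(0, "date", f"D{d + 1}")
        frame.insert(0, "plot_id", design["plot_id"].to_numpy())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _band_name(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else f"{w:.1f}"


def simulate_study(cfg: SimulationConfig):
    """Run all four generator stages; returns (markers, truth, design, plots, spectra)."""
    markers, truth = simulate_population(cfg)
    design = simulate_trial_design(cfg, list(markers.index))
    plots = simulate_phenotypes(markers, design, cfg, truth)
    spectra = simulate_spectra(markers, design, cfg, truth)
    return markers, truth, design, plots, spectra
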