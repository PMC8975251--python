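"""Synthetic methylation-array studies with planted, recoverable structure.

The generator emulates the statistical structure of a mammalian
methylation-array aging study without requiring any download:

* a fraction of CpGs drift with (transformed) age on the logit scale,
  with promoter/island age-CpGs biased toward gaining methylation;
* tissue- and sex-specific constant offsets;
* species-specific baselines over a shared conserved probe set, with a
  configurable fraction of age-CpGs whose slopes are concordant across
  species on the relative-age scale;
* a breeding-status effect implemented as a multiplier on the aging
  slope of queens (rate difference, not a level shift);
* planted slopes are expressed as total logit drift over the configured
  age range (``effect_scale``), internally divided by the transformed-age
  span so drift magnitudes are comparable across transforms;
* Gaussian noise on the logit scale, inverse-logit back to beta values,
  clipped to [1e-6, 1-1e-6].

Every generated CpG's true slope is recorded in a SimulationTruth so
downstream estimators (clocks, EWAS, divergence screens, queen tests)
can be validated by round-trip recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .agetx import SpeciesParams, TransformSpec, apply_transform
from .core_io import BetaMatrix, CpGManifest, SampleSheet, ValidationError

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "simulate_methylation_study",
    "simulate_dual_species",
    "synthesize_at_transformed_age",
    "write_study",
]

BETA_CLIP = 1e-6


@dataclass
class SimConfig:
    """Parameters of a synthetic methylation study.

    Defaults emulate the NMR study design: multiple tissues, ages
    spanning 0-26 yr, ~10% of probes age-related, promoter/island age
    CpGs biased 80% toward hypermethylation, and queens (breeding
    females) aging at ``queen_rate_factor`` times the nonbreeder rate.
    ``effect_scale`` and ``noise_sd`` are in logit units (total drift
    over the configured age range, and per
    transformed-age unit, and per observation, respectively).
    """

    n_samples_per_tissue: int = 40
    tissues: tuple[str, ...] = ("blood", "liver", "skin")
    age_range_years: tuple[float, float] = (0.0, 26.0)
    n_cpgs: int = 2000
    frac_age_related: float = 0.10
    frac_island: float = 0.30
    promoter_hyper_bias: float = 0.80
    effect_scale: float = 2.0
    tissue_offset_sd: float = 0.30
    n_sex_cpgs: int = 20
    n_queen_cpgs: int = 0
    queen_offset_logit: float = 0.5
    sex_offset_logit: float = 2.0
    species_params: dict[str, SpeciesParams] = field(
        default_factory=lambda: {"naked_mole_rat": SpeciesParams(37.0, maturity_years=1.0)}
    )
    species_baseline_sd: float = 0.5
    frac_shared_probes: float = 0.5
    frac_divergent: float = 0.25
    queen_rate_factor: float = 1.0
    frac_queens: float = 0.0
    noise_sd: float = 0.15
    age_skew: bool = False
    transform: TransformSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_related",
            "frac_island",
            "promoter_hyper_bias",
            "frac_shared_probes",
            "frac_divergent",
            "frac_queens",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if not self.tissues:
            raise ValidationError("tissues must be non-empty")
        if self.queen_rate_factor <= 0:
            raise ValidationError("queen_rate_factor must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.age_range_years
        max_L = max(p.max_lifespan_years for p in self.species_params.values())
        if not (0 <= lo < hi <= max_L):
            raise ValidationError(
                f"age_range_years {self.age_range_years} must lie within [0, {max_L}]"
            )
        n_age = round(self.frac_age_related * self.n_cpgs)
        if self.n_cpgs < self.n_sex_cpgs + self.n_queen_cpgs + n_age:
            raise ValidationError("n_cpgs too small for the planted CpG counts")

    def default_transform(self, dual: bool) -> TransformSpec:
        if self.transform is not None:
            return self.transform
        kind = "relative" if dual else "identity"
        return TransformSpec(kind=kind, species=dict(self.species_params))


@dataclass
class SimulationTruth:
    """Planted structure of a simulated study (generative parameters)."""

    cpg_ids: list[str]
    baseline_logit: np.ndarray  # per CpG
    slopes: dict[str, np.ndarray]  # species -> per-CpG slope (0 for non-age CpGs)
    age_cpg_ids: list[str]
    sex_cpg_ids: list[str]
    queen_cpg_ids: list[str]
    divergent_cpg_ids: list[str]
    sample_groups: pd.DataFrame  # sample_id, tissue, sex, species, is_queen
    transform: TransformSpec

    def slope_for(self, species: str) -> np.ndarray:
        return self.slopes[species]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "age_cpg_ids": self.age_cpg_ids,
            "sex_cpg_ids": self.sex_cpg_ids,
            "queen_cpg_ids": self.queen_cpg_ids,
            "divergent_cpg_ids": self.divergent_cpg_ids,
            "slopes": {sp: dict(zip(self.cpg_ids, map(float, sl))) for sp, sl in self.slopes.items()},
            "sample_groups": self.sample_groups.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------
# manifest


def _make_manifest(cfg: SimConfig, rng: np.random.Generator) -> CpGManifest:
    n = cfg.n_cpgs
    cpg_ids = [f"cg{i:07d}" for i in range(n)]
    island = rng.random(n) < cfg.frac_island
    # islands sit in promoters far more often than background probes do
    classes = np.array(["promoter", "5'UTR", "exon", "intron", "3'UTR", "distal"])
    p_island = np.array([0.55, 0.10, 0.10, 0.10, 0.05, 0.10])
    p_open = np.array([0.10, 0.05, 0.15, 0.35, 0.05, 0.30])
    region = np.where(
        island,
        classes[rng.choice(6, size=n, p=p_island)],
        classes[rng.choice(6, size=n, p=p_open)],
    )
    tss = np.empty(n, dtype=int)
    for cls, lo, hi in (
        ("promoter", -1000, 200),
        ("5'UTR", 0, 2000),
        ("exon", 500, 50000),
        ("intron", 500, 50000),
        ("3'UTR", 2000, 80000),
        ("distal", -200000, 200000),
    ):
        mask = region == cls
        tss[mask] = rng.integers(lo, hi + 1, size=mask.sum())
    # distal probes must actually be distal
    distal = region == "distal"
    tss[distal] = np.sign(tss[distal] + 0.5).astype(int) * (np.abs(tss[distal]) + 10000)
    chroms = rng.integers(1, 23, size=n)
    start = rng.integers(0, 150_000_000, size=n)
    species = ",".join(sorted(cfg.species_params))
    frame = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chrom": [f"chr{c}" for c in chroms],
            "start": start,
            "end": start + 2,
            "gene": [f"GENE{i % max(1, n // 4):05d}" for i in range(n)],
            "signed_tss_distance": tss,
            "region_class": region,
            "island_flag": island,
            "species_mappable": species,
        }
    )
    return CpGManifest(frame)


def _sample_ages(cfg: SimConfig, n: int, L: float, L_ref: float, rng: np.random.Generator):
    lo, hi = cfg.age_range_years
    # dual-species: the configured range is for the reference (largest-L)
    # species; other species sample the same relative-age window
    rel_lo, rel_hi = lo / L_ref, hi / L_ref
    if cfg.age_skew:
        u = rng.beta(1.0, 3.0, size=n)  # right-skewed: mostly young
    else:
        u = rng.random(n)
    return (rel_lo + u * (rel_hi - rel_lo)) * L


def _make_sheet(cfg: SimConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    species = sorted(cfg.species_params)
    L_ref = max(p.max_lifespan_years for p in cfg.species_params.values())
    i = 0
    for sp in species:
        pars = cfg.species_params[sp]
        for tissue in cfg.tissues:
            ages = _sample_ages(cfg, cfg.n_samples_per_tissue, pars.max_lifespan_years, L_ref, rng)
            for a in ages:
                sex = "F" if rng.random() < 0.5 else "M"
                status = "nonbreeder"
                if sex == "F" and a >= pars.maturity_years and rng.random() < cfg.frac_queens:
                    status = "queen"
                rows.append(
                    {
                        "sample_id": f"S{i:05d}",
                        "age_years": float(a),
                        "tissue": tissue,
                        "sex": sex,
                        "species": sp,
                        "breeding_status": status,
                        "cell_type": "tissue",
                    }
                )
                i += 1
    return SampleSheet(pd.DataFrame(rows))


def _transformed_span(cfg: SimConfig, spec: TransformSpec) -> float:
    """f(hi) - f(lo) for the reference (longest-lived) species."""
    ref = max(cfg.species_params, key=lambda sp: cfg.species_params[sp].max_lifespan_years)
    frame = pd.DataFrame(
        {"age_years": list(cfg.age_range_years), "species": ref}
    )
    lo_t, hi_t = apply_transform(spec, frame)
    return float(hi_t - lo_t)


def _plant_slopes(
    cfg: SimConfig, manifest: CpGManifest, rng: np.random.Generator, dual: bool, span: float
) -> tuple[dict[str, np.ndarray], list[str], list[str]]:
    """Assign per-species aging slopes; returns slopes, age ids, divergent ids.

    ``effect_scale`` is the typical total logit drift of an age CpG over
    the configured age range; the per-transformed-unit slope is that
    drift divided by ``span``.
    """
    n = cfg.n_cpgs
    n_age = round(cfg.frac_age_related * n)
    idx_age = rng.choice(n, size=n_age, replace=False)
    man = manifest.frame
    promoterish = (
        man["region_class"].isin(["promoter", "5'UTR"]).to_numpy() | man["island_flag"].to_numpy()
    )

    def draw_slopes(idx, biased=True):
        # species-specific (non-conserved) slopes carry no promoter sign
        # bias: their direction is arbitrary per species
        p_pos = np.where(promoterish[idx], cfg.promoter_hyper_bias, 0.5) if biased else 0.5
        signs = np.where(rng.random(idx.size) < p_pos, 1.0, -1.0)
        mags = cfg.effect_scale / span * rng.uniform(0.5, 1.5, size=idx.size)
        return signs * mags

    species = sorted(cfg.species_params)
    slopes = {sp: np.zeros(n) for sp in species}
    divergent_ids: list[str] = []
    if not dual:
        slopes[species[0]][idx_age] = draw_slopes(idx_age)
    else:
        n_shared = round(cfg.frac_shared_probes * n_age)
        shared_idx = idx_age[:n_shared]
        own_idx = idx_age[n_shared:]
        shared_slopes = draw_slopes(shared_idx)
        for sp in species:
            slopes[sp][shared_idx] = shared_slopes
        # non-shared age CpGs: per-species independent slopes, half null
        for sp in species:
            active = rng.random(own_idx.size) < 0.5
            vals = draw_slopes(own_idx, biased=False)
            slopes[sp][own_idx[active]] = vals[active]
        if len(species) >= 3 and cfg.frac_divergent > 0 and n_shared > 0:
            short = min(species, key=lambda sp: cfg.species_params[sp].max_lifespan_years)
            n_div = round(cfg.frac_divergent * n_shared)
            div_idx = shared_idx[:n_div]
            slopes[short][div_idx] = 0.0
            divergent_ids = [manifest.cpg_ids[i] for i in sorted(div_idx)]
    age_ids = [manifest.cpg_ids[i] for i in sorted(idx_age)]
    return slopes, age_ids, divergent_ids


def _generate(cfg: SimConfig, dual: bool):
    rng = np.random.default_rng(cfg.seed)
    manifest = _make_manifest(cfg, rng)
    sheet = _make_sheet(cfg, rng)
    n = cfg.n_cpgs
    species = sorted(cfg.species_params)

    island = manifest.frame["island_flag"].to_numpy()
    baseline = np.where(
        island, rng.normal(-1.5, 0.5, size=n), rng.normal(1.0, 0.8, size=n)
    )

    spec = cfg.default_transform(dual)
    slopes, age_ids, divergent_ids = _plant_slopes(
        cfg, manifest, rng, dual, _transformed_span(cfg, spec)
    )

    # sex and queen marker CpGs from the non-age pool
    age_set = set(age_ids)
    free = np.array([i for i, c in enumerate(manifest.cpg_ids) if c not in age_set])
    rng.shuffle(free)
    sex_idx = np.array(free[: cfg.n_sex_cpgs], dtype=int)
    queen_idx = np.array(
        free[cfg.n_sex_cpgs : cfg.n_sex_cpgs + cfg.n_queen_cpgs], dtype=int
    )
    sex_sign = rng.choice([-1.0, 1.0], size=sex_idx.size)
    queen_sign = rng.choice([-1.0, 1.0], size=queen_idx.size)

    tissue_off = {
        t: rng.normal(0.0, cfg.tissue_offset_sd, size=n) for t in cfg.tissues
    }
    species_off = (
        {sp: rng.normal(0.0, cfg.species_baseline_sd, size=n) for sp in species}
        if dual
        else {species[0]: np.zeros(n)}
    )

    t = apply_transform(spec, sheet)
    df = sheet.frame
    is_queen = (df["breeding_status"] == "queen").to_numpy()
    is_female = (df["sex"] == "F").to_numpy()
    rate = np.where(is_queen, cfg.queen_rate_factor, 1.0)

    n_samples = len(df)
    M = np.empty((n_samples, n), dtype=float)
    for i in range(n_samples):
        sp = df.at[i, "species"]
        row = baseline + species_off[sp] + tissue_off[df.at[i, "tissue"]]
        row = row + slopes[sp] * (rate[i] * t[i])
        if is_female[i] and sex_idx.size:
            row[sex_idx] += cfg.sex_offset_logit * sex_sign
        if is_queen[i] and queen_idx.size:
            row[queen_idx] += cfg.queen_offset_logit * queen_sign
        M[i] = row
    if cfg.noise_sd > 0:
        M += rng.normal(0.0, cfg.noise_sd, size=M.shape)

    betas = np.clip(expit(M), BETA_CLIP, 1 - BETA_CLIP)
    matrix = BetaMatrix(
        pd.DataFrame(betas, index=df["sample_id"].tolist(), columns=manifest.cpg_ids)
    )
    truth = SimulationTruth(
        cpg_ids=manifest.cpg_ids,
        baseline_logit=baseline,
        slopes=slopes,
        age_cpg_ids=age_ids,
        sex_cpg_ids=[manifest.cpg_ids[i] for i in sorted(sex_idx)],
        queen_cpg_ids=[manifest.cpg_ids[i] for i in sorted(queen_idx)],
        divergent_cpg_ids=divergent_ids,
        sample_groups=df[["sample_id", "tissue", "sex", "species", "breeding_status"]].assign(
            is_queen=is_queen
        ),
        transform=spec,
    )
    return matrix, sheet, manifest, truth


def simulate_methylation_study(config: SimConfig):
    """Generate a single-species study: (BetaMatrix, SampleSheet, CpGManifest, SimulationTruth)."""
    if len(config.species_params) != 1:
        raise ValidationError(
            "simulate_methylation_study is single-species; use simulate_dual_species"
        )
    return _generate(config, dual=False)


def simulate_dual_species(config: SimConfig):
    """Generate a multi-species study over a shared conserved probe set.

    ``frac_shared_probes`` of age CpGs get slopes concordant across
    species on the (default relative-age) transformed scale; the rest
    have species-specific or null slopes. With >= 3 species,
    ``frac_divergent`` of the shared age CpGs are set to a null slope in
    the shortest-lived species (recoverable by the divergence screen).
    """
    if len(config.species_params) < 2:
        raise ValidationError(
            "simulate_dual_species needs >= 2 species; use simulate_methylation_study"
        )
    return _generate(config, dual=True)


def synthesize_at_transformed_age(
    truth: SimulationTruth,
    t_values,
    noise_sd: float = 0.0,
    species: str | None = None,
    seed: int = 0,
    prefix: str = "X",
) -> BetaMatrix:
    """Build new samples from a study's generative parameters at given
    transformed ages.

    Used e.g. to emulate reprogrammed (iPSC-like) samples at a
    prenatal-equivalent transformed age: pass a negative ``t`` for a
    loglinear-transform study and a clock trained on the ordinary
    samples will assign them a negative DNAm age.
    """
    rng = np.random.default_rng(seed)
    if species is None:
        species = sorted(truth.slopes)[0]
    sl = truth.slopes[species]
    t_values = np.asarray(t_values, dtype=float)
    M = truth.baseline_logit[None, :] + np.outer(t_values, sl)
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
    betas = np.clip(expit(M), BETA_CLIP, 1 - BETA_CLIP)
    ids = [f"{prefix}{i:04d}" for i in range(len(t_values))]
    return BetaMatrix(pd.DataFrame(betas, index=ids, columns=truth.cpg_ids))


def write_study(outdir: str | Path, matrix, sheet, manifest, truth) -> dict[str, str]:
    """Write the four study artifacts into ``outdir``; returns the paths."""
    from . import core_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": str(outdir / "betas.tsv"),
        "samples": str(outdir / "samples.csv"),
        "manifest": str(outdir / "manifest.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    core_io.write_beta_matrix(matrix, paths["betas"])
    core_io.write_sample_sheet(sheet, paths["samples"])
    core_io.write_manifest(manifest, paths["manifest"])
    truth.to_json(paths["truth"])
    return paths
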