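"""Synthetic co-divergence studies: sites, traits, landmarks, genotypes.

The generator emulates the statistical structure of a replicated
sulfide-spring study design: several clades, each containing paired
systems of one sulfidic spring plus one or more adjacent non-sulfidic
sites; life-history effects of the toxic habitat (larger but fewer
offspring) whose magnitude scales with the spring's H2S concentration;
allometry of fecundity with female standard length; sexual size
dimorphism; a head-enlargement shape effect on anterior landmarks; and
neutral genetic differentiation that increases with divergence strength.

Trait noise is Gaussian on the transformed scale (log10 / sqrt /
arcsine-sqrt), so back-transformed traits are positive and skewed, and
an offspring size-number trade-off is imposed through a shared latent
allocation variable.  Population allele frequencies follow the
Balding-Nichols beta model, whose differentiation parameter F is the
direct estimand of the Weir-Cockerham theta estimator.  H2S scaling of
effect sizes is linear by default; a saturating option is available.

All outputs are deterministic functions of the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometrics import ShapeData, write_tps
from .popgen import GenotypeTable, write_genepop

__all__ = [
    "StudyDesign",
    "EffectConfig",
    "MEAN_CONFIGURATION",
    "generate_sites",
    "generate_traits",
    "generate_landmarks",
    "generate_genotypes",
    "balding_nichols_frequencies",
    "write_study",
]


# 13-landmark mean configuration of a lateral poeciliid body outline:
# snout tip, dorsal head, nape, dorsal-fin origin, dorsal-fin insertion,
# dorsal caudal peduncle, caudal margin top, caudal midpoint, caudal
# margin bottom, ventral caudal peduncle, anal-fin origin, pelvic-fin
# origin, ventral head margin.
MEAN_CONFIGURATION: np.ndarray = np.array(
    [
        [0.00, 0.00],
        [0.10, 0.08],
        [0.28, 0.14],
        [0.48, 0.16],
        [0.62, 0.12],
        [0.80, 0.06],
        [0.92, 0.04],
        [1.00, 0.00],
        [0.92, -0.04],
        [0.80, -0.06],
        [0.55, -0.14],
        [0.35, -0.15],
        [0.12, -0.08],
    ]
)

# anterior (head) landmarks displaced by the sulfidic shape effect
HEAD_LANDMARKS: tuple[int, ...] = (0, 1, 2, 12)


@dataclass
class StudyDesign:
    """Shape of the sampling design.

    The default — five clades with two sulfide systems each and two
    non-sulfidic partner sites per system — yields the ten sulfidic
    systems of the cross-complex comparison.
    """

    n_clades: int = 5
    systems_per_clade: int = 2
    nonsulfidic_per_system: int = 2
    h2s_range: tuple[float, float] = (20.0, 200.0)
    latitude_origin: float = 20.0
    longitude_origin: float = -95.0

    def validate(self) -> None:
        if self.n_clades < 1 or self.systems_per_clade < 1:
            raise ValueError("need at least one clade and one system per clade")
        if self.nonsulfidic_per_system < 1:
            raise ValueError("each system needs at least one non-sulfidic site")
        lo, hi = self.h2s_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid H2S range")


@dataclass
class EffectConfig:
    """Effect sizes and noise scales of the generator.

    Habitat effects are stated at the reference H2S concentration
    (``h2s_reference``, µM) and scale with each spring's concentration:
    linearly in ``h2s_um`` by default, or saturating
    (``1 - exp(-h2s/h2s_reference)``) when ``h2s_saturating`` is set.
    ``embryo_mass_effect`` is the sulfidic-minus-non-sulfidic embryo
    lean-weight difference in mg at reference H2S; ``fecundity_effect``
    the offspring-count difference; ``head_shape_effect`` the anterior
    landmark displacement (in units of the unit-length mean
    configuration, i.e. approximately Procrustes units);
    ``divergence_F`` the Balding-Nichols differentiation parameter.
    Noise scales are standard deviations on the transformed scale.
    """

    embryo_mass_effect: float = 1.52
    fecundity_effect: float = -5.89
    head_shape_effect: float = 0.03
    allometry_r: float = 0.67
    tradeoff_r: float = -0.30
    divergence_F: float = 0.15
    effect_vs_h2s_slope: float = 1.0
    h2s_reference: float = 100.0
    h2s_saturating: bool = False
    scale_F_with_h2s: bool = True
    site_effect_sd: float = 0.05
    sl_sd: float = 0.04
    lean_sd: float = 0.05
    fat_sd: float = 0.05
    gsi_sd: float = 0.04
    fecundity_sd: float = 0.55
    embryo_lean_sd: float = 0.06
    embryo_fat_sd: float = 0.05
    landmark_noise_sd: float = 0.01

    # baseline (non-sulfidic) trait means
    fecundity_base: float = 14.98
    embryo_lean_base: float = 1.52

    def validate(self) -> None:
        if not (0.0 <= self.divergence_F < 1.0):
            raise ValueError("divergence_F must lie in [0, 1)")
        for name in (
            "site_effect_sd", "sl_sd", "lean_sd", "fat_sd", "gsi_sd",
            "fecundity_sd", "embryo_lean_sd", "embryo_fat_sd",
            "landmark_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative noise scale: {name}")
        if abs(self.allometry_r) ** 2 + abs(self.tradeoff_r) ** 2 >= 1.0:
            raise ValueError("allometry_r^2 + tradeoff_r^2 must be < 1")

    @classmethod
    def null(cls) -> "EffectConfig":
        """All habitat effects and between-site variation set to zero."""
        return cls(
            embryo_mass_effect=0.0,
            fecundity_effect=0.0,
            head_shape_effect=0.0,
            effect_vs_h2s_slope=0.0,
            site_effect_sd=0.0,
        )

    def h2s_scaling(self, h2s_um: np.ndarray | float) -> np.ndarray | float:
        """Multiplier applied to habitat effect sizes at a given H2S."""
        x = np.asarray(h2s_um, dtype=float) / self.h2s_reference
        if self.h2s_saturating:
            base = 1.0 - np.exp(-x)
        else:
            base = x
        return self.effect_vs_h2s_slope * base


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Sites


def generate_sites(design: StudyDesign | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the site table of a paired sulfidic/non-sulfidic design.

    Each system contains exactly one sulfidic spring (H2S drawn
    uniformly from the configured range) and the configured number of
    non-sulfidic partners (H2S = 0).  Coordinates are laid out on a
    small grid per clade so that "geographically closest" is
    well-defined downstream.
    """
    design = design or StudyDesign()
    design.validate()
    rng = _rng(seed, 0)
    rows = []
    lo, hi = design.h2s_range
    for ci in range(design.n_clades):
        clade = f"clade_{ci + 1}"
        for si in range(design.systems_per_clade):
            system = f"{clade}_sys{si + 1}"
            lat0 = design.latitude_origin + 2.0 * ci + 0.5 * si
            lon0 = design.longitude_origin + 1.5 * si
            h2s = float(rng.uniform(lo, hi))
            rows.append(
                {
                    "site_id": f"{system}_S",
                    "clade": clade,
                    "system_id": system,
                    "sulfidic": True,
                    "h2s_um": h2s,
                    "latitude": lat0,
                    "longitude": lon0,
                }
            )
            for ni in range(design.nonsulfidic_per_system):
                rows.append(
                    {
                        "site_id": f"{system}_N{ni + 1}",
                        "clade": clade,
                        "system_id": system,
                        "sulfidic": False,
                        "h2s_um": 0.0,
                        "latitude": lat0 + 0.02 * (ni + 1) + float(rng.uniform(0, 0.01)),
                        "longitude": lon0 + 0.02 * (ni + 1),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Traits


def generate_traits(
    sites: pd.DataFrame,
    effects: EffectConfig | None = None,
    n_per_site: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an individual trait table for every site.

    Half the individuals per site are female (all pregnant, carrying
    embryo traits), half male.  Standard length is drawn per sex with a
    clade offset; fecundity is generated on the square-root scale with
    the configured allometric correlation to log standard length and the
    offspring size-number trade-off through a shared latent allocation
    variable; habitat effects on embryo lean weight and fecundity scale
    with the spring's H2S concentration.  Means are bias-corrected so
    the back-transformed habitat means match the configured raw-scale
    targets.
    """
    effects = effects or EffectConfig()
    effects.validate()
    if n_per_site < 2:
        raise ValueError("n_per_site must be >= 2")
    clades = sorted(pd.unique(sites["clade"]))
    clade_rng = _rng(seed, 1)
    clade_offsets = {c: float(clade_rng.normal(0.0, 1.5)) for c in clades}
    ln10 = np.log(10.0)
    rows = []
    for site_idx, site in enumerate(sites.sort_values("site_id").itertuples()):
        rng = _rng(seed, 2, site_idx)
        sc = float(effects.h2s_scaling(site.h2s_um)) if site.sulfidic else 0.0
        site_eff = rng.normal(0.0, 1.0, size=6) * effects.site_effect_sd
        n_f = n_per_site // 2 + n_per_site % 2
        n_m = n_per_site - n_f
        for sex, n_sex in (("F", n_f), ("M", n_m)):
            base_sl = 27.5 if sex == "F" else 20.8
            mu_sl = np.log10(base_sl + clade_offsets[site.clade])
            z_sl = rng.normal(0.0, 1.0, n_sex)
            log_sl = mu_sl + site_eff[0] * 0.2 + effects.sl_sd * z_sl
            sl = 10.0**log_sl
            # adult composition
            mu_lean = -5.0 + 3.0 * log_sl
            lean = 10.0 ** (mu_lean + site_eff[1] * 0.3
                            + effects.lean_sd * rng.normal(0, 1, n_sex))
            fat = np.sin(
                np.arcsin(np.sqrt(0.10)) + site_eff[2] * 0.3
                + effects.fat_sd * rng.normal(0, 1, n_sex)
            ) ** 2
            gsi_base = 0.20 if sex == "F" else 0.03
            gsi = np.sin(
                np.arcsin(np.sqrt(gsi_base)) + site_eff[3] * 0.3
                + effects.gsi_sd * rng.normal(0, 1, n_sex)
            ) ** 2
            if sex == "F":
                u = rng.normal(0.0, 1.0, n_sex)  # latent allocation
                eps_f = rng.normal(0.0, 1.0, n_sex)
                fec_target = max(effects.fecundity_base + effects.fecundity_effect * sc, 1.0)
                mu_fec = np.sqrt(max(fec_target - effects.fecundity_sd**2, 0.25))
                w = abs(effects.tradeoff_r)
                rho = effects.allometry_r
                resid = np.sqrt(max(1.0 - rho**2 - w**2, 0.0))
                sqrt_fec = (
                    mu_fec + site_eff[4]
                    + effects.fecundity_sd * (rho * z_sl - w * u + resid * eps_f)
                )
                fecundity = np.round(np.clip(sqrt_fec, 0.0, None) ** 2).astype(int)
                emb_target = effects.embryo_lean_base + effects.embryo_mass_effect * sc
                mu_emb = (
                    np.log10(emb_target)
                    - (effects.embryo_lean_sd**2) * ln10 / 2.0
                )
                embryo_lean = 10.0 ** (
                    mu_emb + site_eff[5] * 0.5
                    + effects.embryo_lean_sd
                    * (w * u + np.sqrt(1.0 - w**2) * rng.normal(0, 1, n_sex))
                )
                embryo_fat = np.sin(
                    np.arcsin(np.sqrt(0.15))
                    + effects.embryo_fat_sd * rng.normal(0, 1, n_sex)
                ) ** 2
                stage = rng.integers(10, 45, n_sex)
            else:
                fecundity = np.full(n_sex, np.nan)
                embryo_lean = np.full(n_sex, np.nan)
                embryo_fat = np.full(n_sex, np.nan)
                stage = np.full(n_sex, np.nan)
            for i in range(n_sex):
                rows.append(
                    {
                        "individual_id": f"{site.site_id}_{sex}{i + 1}",
                        "site_id": site.site_id,
                        "clade": site.clade,
                        "system_id": site.system_id,
                        "sex": sex,
                        "sulfidic": bool(site.sulfidic),
                        "h2s_um": float(site.h2s_um),
                        "sl_mm": float(sl[i]),
                        "lean_weight_g": float(lean[i]),
                        "fat_content": float(fat[i]),
                        "gsi_or_ra": float(gsi[i]),
                        "fecundity": float(fecundity[i]),
                        "embryo_lean_weight_mg": float(embryo_lean[i]),
                        "embryo_fat": float(embryo_fat[i]),
                        "embryo_stage": float(stage[i]),
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["transform_state"] = "raw"
    return out


# ---------------------------------------------------------------------------
# Landmarks


def generate_landmarks(
    sites: pd.DataFrame,
    effects: EffectConfig | None = None,
    n_per_site: int = 24,
    seed: int = 0,
    mean_configuration: np.ndarray | None = None,
) -> ShapeData:
    """Generate raw landmark configurations for every site.

    Each specimen is the mean configuration plus the habitat deformation
    (anterior landmarks displaced away from the head centroid, magnitude
    scaling with H2S), a small sex effect on the anal-fin landmark,
    isotropic landmark noise, and nuisance rotation/translation/scaling
    that downstream alignment must remove.
    """
    effects = effects or EffectConfig()
    effects.validate()
    mean_cfg = (
        MEAN_CONFIGURATION if mean_configuration is None
        else np.asarray(mean_configuration, dtype=float)
    )
    if mean_cfg.shape != (13, 2):
        raise ValueError(f"mean configuration must be 13 x 2, got {mean_cfg.shape}")
    head = np.array(HEAD_LANDMARKS)
    head_centroid = mean_cfg[head].mean(axis=0)
    ids: list[str] = []
    meta_rows = []
    configs = []
    for site_idx, site in enumerate(sites.sort_values("site_id").itertuples()):
        rng = _rng(seed, 3, site_idx)
        sc = float(effects.h2s_scaling(site.h2s_um)) if site.sulfidic else 0.0
        n_f = n_per_site // 2 + n_per_site % 2
        for i in range(n_per_site):
            sex = "F" if i < n_f else "M"
            cfg = mean_cfg.copy()
            if sc != 0.0:
                d = cfg[head] - head_centroid
                norms = np.linalg.norm(d, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                cfg[head] = cfg[head] + effects.head_shape_effect * sc * d / norms
            if sex == "M":
                cfg[10, 0] -= 0.02  # anal-fin origin shifted anteriorly
            cfg = cfg + rng.normal(0.0, effects.landmark_noise_sd, cfg.shape)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = float(np.exp(rng.uniform(-0.5, 0.5))) * 30.0
            shift = rng.uniform(-50.0, 50.0, 2)
            configs.append(scale * cfg @ R.T + shift)
            sid = f"{site.site_id}_{sex}{i + 1 if sex == 'F' else i - n_f + 1}"
            ids.append(sid)
            meta_rows.append(
                {
                    "specimen_id": sid,
                    "site_id": site.site_id,
                    "clade": site.clade,
                    "system_id": site.system_id,
                    "sex": sex,
                    "sulfidic": bool(site.sulfidic),
                    "h2s_um": float(site.h2s_um),
                }
            )
    return ShapeData(
        specimen_ids=ids,
        coords=np.stack(configs),
        metadata=pd.DataFrame(meta_rows).set_index("specimen_id"),
    )


# ---------------------------------------------------------------------------
# Genotypes


def balding_nichols_frequencies(
    ancestral: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw population allele frequencies from the Balding-Nichols model.

    For a k-allele locus with ancestral frequencies ``p`` the population
    frequencies follow a Dirichlet with parameters ``p (1 - F) / F``;
    the variance of each frequency is ``F p (1 - p)``, making F the
    direct estimand of Weir-Cockerham theta.  ``F = 0`` returns the
    ancestral frequencies unchanged.
    """
    p = np.asarray(ancestral, dtype=float)
    if not (0.0 <= F < 1.0):
        raise ValueError("F must lie in [0, 1)")
    if F == 0.0:
        return p.copy()
    return rng.dirichlet(p * (1.0 - F) / F)


def generate_genotypes(
    sites: pd.DataFrame,
    effects: EffectConfig | None = None,
    n_per_site: int = 24,
    n_loci: int = 11,
    seed: int = 0,
    n_alleles: int = 6,
    ancestral: np.ndarray | None = None,
) -> GenotypeTable:
    """Generate diploid microsatellite genotypes for every site.

    Ancestral allele frequencies per locus are supplied or drawn from a
    flat Dirichlet (shared across sites of a clade); each site's
    frequencies are a Balding-Nichols draw with parameter
    ``divergence_F`` — scaled up with the H2S contrast for sulfidic
    sites when ``scale_F_with_h2s`` is set, so that stronger divergence
    brings stronger neutral differentiation — and genotypes are random
    unions of gametes.  Allele labels are microsatellite repeat sizes.
    """
    effects = effects or EffectConfig()
    effects.validate()
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    labels = 100 + 2 * np.arange(n_alleles)
    clades = sorted(pd.unique(sites["clade"]))
    anc: dict[str, np.ndarray] = {}
    for ci, clade in enumerate(clades):
        rng = _rng(seed, 4, ci)
        if ancestral is not None:
            anc[clade] = np.broadcast_to(
                np.asarray(ancestral, dtype=float), (n_loci, n_alleles)
            ).copy()
        else:
            anc[clade] = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    ids: list[str] = []
    site_ids: list[str] = []
    calls = []
    for site_idx, site in enumerate(sites.sort_values("site_id").itertuples()):
        rng = _rng(seed, 5, site_idx)
        F = effects.divergence_F
        if effects.scale_F_with_h2s and F > 0:
            if site.sulfidic:
                sc = float(effects.h2s_scaling(site.h2s_um))
                F = float(np.clip(F * (0.25 + 0.75 * sc), 0.0, 0.9))
            else:
                F = float(np.clip(F * 0.25, 0.0, 0.9))
        block = np.zeros((n_per_site, n_loci, 2), dtype=int)
        for j in range(n_loci):
            freqs = balding_nichols_frequencies(anc[site.clade][j], F, rng)
            draws = rng.choice(n_alleles, size=(n_per_site, 2), p=freqs)
            block[:, j, :] = labels[draws]
        for i in range(n_per_site):
            ids.append(f"{site.site_id}_g{i + 1}")
            site_ids.append(site.site_id)
        calls.append(block)
    return GenotypeTable(
        individual_ids=ids,
        site_ids=np.asarray(site_ids, dtype=object),
        loci=[f"locus_{j + 1}" for j in range(n_loci)],
        calls=np.concatenate(calls, axis=0),
    )


# ---------------------------------------------------------------------------
# Bundle writer


def write_study(
    outdir: str | Path,
    design: StudyDesign | None = None,
    effects: EffectConfig | None = None,
    n_per_site: int = 24,
    n_loci: int = 11,
    seed: int = 0,
) -> dict[str, str]:
    """Generate a full study and write it as a plain-text bundle.

    Writes the site table and trait table as CSV, landmarks as TPS,
    genotypes as GenePop, the configuration echo as YAML, and a JSON
    manifest logging every seed and parameter.  Returns the paths.
    """
    design = design or StudyDesign()
    effects = effects or EffectConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = generate_sites(design, seed=seed)
    traits = generate_traits(sites, effects, n_per_site=n_per_site, seed=seed)
    shapes = generate_landmarks(sites, effects, n_per_site=n_per_site, seed=seed)
    genotypes = generate_genotypes(
        sites, effects, n_per_site=n_per_site, n_loci=n_loci, seed=seed
    )
    paths = {
        "sites": str(outdir / "sites.csv"),
        "traits": str(outdir / "traits.csv"),
        "landmarks": str(outdir / "landmarks.tps"),
        "genotypes": str(outdir / "genotypes.gen"),
        "config": str(outdir / "config_echo.yaml"),
        "manifest": str(outdir / "manifest.json"),
    }
    sites.to_csv(paths["sites"], index=False)
    traits.to_csv(paths["traits"], index=False)
    write_tps(shapes, paths["landmarks"])
    shapes.metadata.reset_index().to_csv(outdir / "landmark_metadata.csv", index=False)
    paths["landmark_metadata"] = str(outdir / "landmark_metadata.csv")
    write_genepop(genotypes, paths["genotypes"])
    config_echo = {
        "design": asdict(design),
        "effects": asdict(effects),
        "n_per_site": n_per_site,
        "n_loci": n_loci,
        "seed": seed,
    }
    Path(paths["config"]).write_text(yaml.safe_dump(config_echo, sort_keys=True))
    Path(paths["manifest"]).write_text(
        json.dumps({"seed": seed, "parameters": config_echo, "files": paths},
                   indent=2, sort_keys=True)
        + "\n"
    )
    return paths
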