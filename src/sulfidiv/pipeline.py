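"""Config-driven orchestration of the full divergence analysis.

Runs generation (or loading) of a study, geometric morphometrics, the
nested MANCOVAs with divergence-vector extraction, microsatellite
differentiation with the partial Mantel test, and the system-level
integration statistics, writing every intermediate table plus a
machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import integration, models, morphometrics, popgen, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixture"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (generation parameters) or ``inputs``
    (paths to sites CSV, traits CSV, TPS landmarks + metadata CSV, and a
    GenePop file) must be given.
    """

    outdir: str = "sulfidiv_run"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    n_warps: int = 7
    n_perm: int = 999
    prune_alpha: float = 0.1
    prune: bool = True
    pairing: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' or 'inputs' must be configured"
            )
        if self.inputs is not None:
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {key!r}: {p} does not exist")


def _synthetic_objects(cfg: RunConfig):
    block = dict(cfg.synthetic or {})
    design = synthetic.StudyDesign(**block.get("design", {}))
    effects = synthetic.EffectConfig(**block.get("effects", {}))
    n_per_site = int(block.get("n_per_site", 24))
    n_loci = int(block.get("n_loci", 11))
    seed = int(block.get("seed", cfg.seed))
    sites = synthetic.generate_sites(design, seed=seed)
    traits = synthetic.generate_traits(sites, effects, n_per_site=n_per_site, seed=seed)
    shapes = synthetic.generate_landmarks(
        sites, effects, n_per_site=n_per_site, seed=seed
    )
    genotypes = synthetic.generate_genotypes(
        sites, effects, n_per_site=n_per_site, n_loci=n_loci, seed=seed
    )
    echo = {
        "design": dataclasses.asdict(design),
        "effects": dataclasses.asdict(effects),
        "n_per_site": n_per_site,
        "n_loci": n_loci,
        "seed": seed,
    }
    return sites, traits, shapes, genotypes, echo


def _load_inputs(cfg: RunConfig):
    inputs = cfg.inputs or {}
    sites = pd.read_csv(inputs["sites"])
    traits = pd.read_csv(inputs["traits"])
    traits.attrs["transform_state"] = "raw"
    shapes = morphometrics.read_tps(inputs["landmarks"])
    meta = pd.read_csv(inputs["landmark_metadata"]).set_index("specimen_id")
    shapes.metadata = meta.loc[shapes.specimen_ids]
    genotypes = popgen.read_genepop(inputs["genotypes"])
    return sites, traits, shapes, genotypes, {"inputs": dict(inputs)}


def _model_report(fit: models.MultivariateFit, site_tests: bool = True) -> dict:
    out = {"dependents": list(fit.spec.dependents),
           "terms": [r.as_dict() for r in fit.term_tests()]}
    for r in out["terms"]:
        r.pop("H", None)
    if site_tests and fit.spec.nested_random is not None:
        _, nest = fit.spec.nested_random
        site_rows = []
        names = list(nest) + ([":".join(nest)] if len(nest) > 1 else [])
        for term in names:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = models.site_level_test(fit, term)
                site_rows.append(res.as_dict() | {"H": None})
                site_rows[-1].pop("H")
            except (ValueError, np.linalg.LinAlgError) as exc:
                site_rows.append({"term": term, "error": str(exc)})
        out["site_level_tests"] = site_rows
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the JSON report.

    Stage failures raise :class:`PipelineError` naming the failing
    stage; intermediates written before the failure are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "load"
    try:
        if config.synthetic is not None:
            stage = "generate"
            sites, traits, shapes, genotypes, echo = _synthetic_objects(config)
        else:
            sites, traits, shapes, genotypes, echo = _load_inputs(config)
        report["config"] = echo | {
            "n_warps": config.n_warps,
            "n_perm": config.n_perm,
            "prune": config.prune,
            "prune_alpha": config.prune_alpha,
        }
        sites.to_csv(outdir / "sites.csv", index=False)
        traits.to_csv(outdir / "traits.csv", index=False)

        stage = "transform"
        transformed, record = models.transform_traits(traits)
        transformed.to_csv(outdir / "traits_transformed.csv", index=False)

        stage = "morphometrics"
        aligned = morphometrics.gpa(shapes)
        n_warps = min(
            config.n_warps,
            aligned.n_specimens - 1,
            2 * aligned.n_landmarks - 4,
        )
        warps = morphometrics.relative_warps(aligned, n_keep=n_warps)
        shape_df = warps.to_frame()
        shape_df["log_centroid_size"] = np.log10(aligned.centroid_sizes)
        shape_df = shape_df.join(aligned.metadata)
        shape_df.to_csv(outdir / "relative_warps.csv")
        report["relative_warps"] = {
            "n_retained": n_warps,
            "variance_fractions": warps.variance_fractions[:n_warps].tolist(),
            "cumulative_variance_pct": float(
                100.0 * warps.variance_fractions[:n_warps].sum()
            ),
        }

        stage = "models"
        nested = ("site_id", ("clade", "sulfidic"))
        warp_cols = [f"rw{i + 1}" for i in range(n_warps)]
        model_specs = {
            "sl_anova": models.ModelSpec(
                dependents=["sl_mm"],
                fixed_factors=["clade", "sex", "sulfidic"],
                nested_random=nested,
                interactions=models.all_interactions(["clade", "sex", "sulfidic"]),
            ),
            "adult_lh": models.ModelSpec(
                dependents=["lean_weight_g", "fat_content", "gsi_or_ra"],
                fixed_factors=["clade", "sex", "sulfidic"],
                covariates=["sl_mm"],
                nested_random=nested,
                interactions=models.all_interactions(
                    ["clade", "sex", "sulfidic", "sl_mm"]
                ),
            ),
            "offspring_lh": models.ModelSpec(
                dependents=["fecundity", "embryo_lean_weight_mg", "embryo_fat"],
                fixed_factors=["clade", "sulfidic"],
                covariates=["sl_mm", "embryo_stage"],
                nested_random=nested,
                interactions=models.all_interactions(
                    ["clade", "sulfidic", "sl_mm", "embryo_stage"]
                ),
            ),
            "body_shape": models.ModelSpec(
                dependents=warp_cols,
                fixed_factors=["clade", "sex", "sulfidic"],
                covariates=["log_centroid_size"],
                nested_random=nested,
                interactions=models.all_interactions(
                    ["clade", "sex", "sulfidic", "log_centroid_size"]
                ),
            ),
        }
        model_data = {
            "sl_anova": transformed,
            "adult_lh": transformed,
            "offspring_lh": transformed[transformed["sex"] == "F"],
            "body_shape": shape_df.reset_index(),
        }
        report["models"] = {}
        fits: dict[str, models.MultivariateFit] = {}
        for name, spec in model_specs.items():
            data = model_data[name]
            if config.prune:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    spec, fit = models.prune_model(data, spec, alpha=config.prune_alpha)
            else:
                fit = models.fit_mglm(data, spec)
            fits[name] = fit
            report["models"][name] = _model_report(fit)
            fit.summary_frame().to_csv(outdir / f"terms_{name}.csv", index=False)

        stage = "divergence_vectors"
        score_tables = {}
        for name in ("offspring_lh", "body_shape"):
            vec = models.divergence_vector(fits[name], term="sulfidic")
            fit = fits[name]
            tbl = pd.DataFrame(
                {
                    "individual_id": fit.data.get(
                        "individual_id", fit.data.get("specimen_id")
                    ),
                    "site_id": fit.data["site_id"],
                    "score": vec.scores,
                }
            )
            tbl.to_csv(outdir / f"divergence_scores_{name}.csv", index=False)
            score_tables[name] = tbl
            report["models"][name]["divergence_vector"] = {
                "coefficients": dict(
                    zip(vec.dependents, vec.coefficients.tolist())
                ),
                "orientation": vec.orientation,
            }

        stage = "popgen"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fst = popgen.fst_matrix(genotypes)
        fst.matrix.to_csv(outdir / "fst_matrix.csv")
        variability = popgen.genetic_variability(genotypes)
        variability.to_csv(outdir / "genetic_variability.csv", index=False)
        site_meta = sites.set_index("site_id").loc[fst.sites]
        habitat = popgen.binary_difference_matrix(site_meta["sulfidic"])
        clade = popgen.binary_difference_matrix(site_meta["clade"])
        pm = popgen.partial_mantel(
            fst.matrix, habitat, clade, n_perm=config.n_perm,
            seed=(config.seed * 7919 + 11) % (2**31),
        )
        report["popgen"] = {
            "n_sites": len(fst.sites),
            "mean_ho": float(variability["ho"].mean()),
            "mean_he": float(variability["he"].mean()),
            "partial_mantel": {
                "r": pm.r, "p": pm.p, "n_perm": pm.n_perm, "tails": pm.tails,
                "partial": pm.partial,
            },
        }

        stage = "integration"
        lh_sys = integration.system_divergence_scores(
            score_tables["offspring_lh"]["score"],
            score_tables["offspring_lh"]["site_id"],
            sites,
        )
        morph_sys = integration.system_divergence_scores(
            score_tables["body_shape"]["score"],
            score_tables["body_shape"]["site_id"],
            sites,
        )
        summary, corrs = integration.build_divergence_summary(
            lh_sys, morph_sys, sites, fst=fst.matrix, pairing=config.pairing
        )
        summary.to_csv(outdir / "divergence_summary.csv", index=False)
        report["integration"] = {
            "pc1_eigenvalue": summary.attrs["pc1_eigenvalue"],
            "pc1_variance_pct": 100.0 * summary.attrs["pc1_variance_fraction"],
            "correlations": {k: v.as_dict() for k, v in sorted(corrs.items())},
            "n_systems": int(len(summary)),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def make_fixture(outdir: str | Path, seed: int = 42) -> dict[str, str]:
    """Write a miniature study bundle for tests and examples.

    Four sulfide systems (two clades, two systems each, one non-sulfidic
    partner per system), 30 individuals per site, 8 microsatellite loci
    at a Balding-Nichols F of 0.25.
    """
    design = synthetic.StudyDesign(
        n_clades=2, systems_per_clade=2, nonsulfidic_per_system=1
    )
    effects = synthetic.EffectConfig(divergence_F=0.25, scale_F_with_h2s=False)
    return synthetic.write_study(
        outdir, design=design, effects=effects, n_per_site=30, n_loci=8, seed=seed
    )
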