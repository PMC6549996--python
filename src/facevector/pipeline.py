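"""End-to-end experiment orchestration.

Composes the full study: build the face space, sample and select distinctive
candidate faces per sex, simulate training ratings, estimate the
attractiveness vector, build the manipulated validation set, simulate
validation ratings per between-subject condition, and run the Bayesian
validation analysis.  Every stage gets its own seed derived by hashing the
master seed with the stage name, so stages are independently rerunnable and
the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import attractiveness, morphable, sampling
from .attractiveness import (
    AttractivenessVector,
    DEFAULT_DELTAS,
    MODES,
    ManipulationSpec,
    build_validation_set,
    fit_attractiveness_vector,
    manipulate,
    save_vector,
)
from .bayes import McmcSettings, validate_model
from .morphable import (
    FaceCoefficients,
    FaceSpaceModel,
    export_obj,
    export_texture_png,
    fit_face_space,
    make_template,
    sample_population,
    save_model,
    synthesize,
)
from .raters import (
    GroundTruthPreference,
    cronbach_alpha,
    mean_scores,
    rater_panel,
    simulate_ratings,
    standardize_ratings,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "render_gallery",
    "fixture_suite",
    "stage_seed",
]

SEXES = ("male", "female")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name)."""
    h = hashlib.blake2b(f"{master_seed}|{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


@dataclass
class ExperimentConfig:
    """All experiment parameters; defaults are the fast desk-scale design.

    ``paper_design()`` restores the full-scale constants: a 2043-vertex mesh
    with 256x256 textures and 50+50 PCs, 10 000 candidates per sex with the
    200 most distinctive selected and scaled by 0.5, 7 manipulation levels
    from -3 to +3 s.d., 10 validation faces per sex, and MCMC at 5000
    iterations / 500 burn-in / 4 chains.
    """

    # face space
    n_lat: int = 12
    n_lon: int = 12
    texture_size: int = 64
    k_shape: int = 20
    k_reflectance: int = 20
    population_size: int = 120
    # stimulus sampling
    n_candidates: int = 1000
    k_select: int = 200
    scale_factor: float = 0.5
    selection_method: str = "average_distance"
    # rating simulation
    n_raters_training: int = 20
    n_raters_validation: int = 16  # per between-subject condition
    noise_ratio: float = 1.0
    reflectance_weight: dict = field(
        default_factory=lambda: {"male": 0.0, "female": 0.5}
    )
    discretization: str = "per_rater_range"
    # validation design
    validation_faces: int = 10
    deltas: tuple = DEFAULT_DELTAS
    modes: tuple = MODES
    combined_normalization: str = "per_block"
    # analysis
    mcmc_iterations: int = 5000
    mcmc_burn_in: int = 500
    mcmc_chains: int = 4
    delta_rho_method: str = "joint"
    # run
    master_seed: int = 0
    outdir: str | None = None

    @classmethod
    def paper_design(cls, **overrides) -> "ExperimentConfig":
        base = dict(
            n_lat=13,
            n_lon=157,  # 13*157 + 2 poles = 2043 vertices
            texture_size=256,
            k_shape=50,
            k_reflectance=50,
            population_size=300,
            n_candidates=10_000,
            k_select=200,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        counts = (
            self.n_lat, self.n_lon, self.texture_size, self.k_shape,
            self.k_reflectance, self.population_size, self.n_candidates,
            self.k_select, self.n_raters_training, self.n_raters_validation,
            self.validation_faces, self.mcmc_iterations, self.mcmc_chains,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if self.mcmc_burn_in >= self.mcmc_iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if 0.0 not in tuple(self.deltas):
            raise ValueError("deltas must include the 0 (unmanipulated) level")
        if self.k_select > self.n_candidates:
            raise ValueError("k_select cannot exceed n_candidates")
        if self.population_size <= max(self.k_shape, self.k_reflectance):
            raise ValueError("population_size must exceed the PCA rank")
        for sex in SEXES:
            if sex not in self.reflectance_weight:
                raise ValueError(f"reflectance_weight missing sex {sex!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deltas"] = list(self.deltas)
        d["modes"] = list(self.modes)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # output location is not a design parameter
        return hashlib.sha1(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def mcmc_settings(self, seed: int) -> McmcSettings:
        return McmcSettings(
            iterations=self.mcmc_iterations,
            burn_in=self.mcmc_burn_in,
            chains=self.mcmc_chains,
            seed=seed,
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    model: FaceSpaceModel
    truths: dict  # sex -> GroundTruthPreference
    vectors: dict  # sex -> AttractivenessVector
    alphas: dict  # sex -> training Cronbach alpha
    cosines: dict  # sex -> cosine(joint t_hat, truth direction)
    analysis: dict  # validate_model output (report + fit objects)
    report: dict  # JSON-serializable run report
    outdir: Path | None = None


def _log(lines: list, stage: str, **info) -> None:
    payload = " ".join(f"{k}={v}" for k, v in info.items())
    lines.append(f"stage={stage} {payload}".rstrip())


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run every stage of the experiment under the master seed.

    Returns the in-memory result; when ``config.outdir`` is set, also writes
    the model container, candidate pools, rating tables, attractiveness
    vectors, the validation report and a stage log.
    """
    config.validate()
    seed = config.master_seed
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    chash = config.config_hash()
    _log(log, "config", hash=chash, master_seed=seed)

    template = make_template(
        config.n_lat, config.n_lon, config.texture_size,
        seed=stage_seed(seed, "template"),
    )
    population = sample_population(
        template, config.population_size, seed=stage_seed(seed, "population")
    )
    model = fit_face_space(population, config.k_shape, config.k_reflectance)
    model.metadata.update(
        model_ref=f"facespace-{chash}", seed=stage_seed(seed, "population")
    )
    _log(log, "face_space", n_vertices=model.n_vertices,
         k=f"{model.k_shape}+{model.k_reflectance}")
    if outdir:
        save_model(model, outdir / "model")

    truths, vectors, alphas, cosines = {}, {}, {}, {}
    training_pools, ratings_val = {}, {}
    for sex in SEXES:
        pool = sampling.sample_candidates(
            model, sex, config.n_candidates, stage_seed(seed, f"candidates_{sex}")
        )
        selected = sampling.select_distinct(
            pool, config.k_select, method=config.selection_method
        )
        training = sampling.scale_pool(selected, config.scale_factor)
        training_pools[sex] = training
        _log(log, f"sampling_{sex}", candidates=len(pool), selected=len(training))

        truth = GroundTruthPreference.random(
            config.k_shape,
            config.k_reflectance,
            config.reflectance_weight[sex],
            seed=stage_seed(seed, f"truth_{sex}"),
            sex=sex,
        )
        truths[sex] = truth
        latent_sd = float(truth.latent(training.candidates).std(ddof=1))

        panel = rater_panel(
            config.n_raters_training,
            latent_sd,
            noise_ratio=config.noise_ratio,
            seed=stage_seed(seed, f"raters_train_{sex}"),
        )
        half = config.n_raters_training // 2
        rater_sex = ["male"] * half + ["female"] * (config.n_raters_training - half)
        ratings = simulate_ratings(
            training.candidates,
            truth,
            panel,
            seed=stage_seed(seed, f"ratings_train_{sex}"),
            discretization=config.discretization,
            condition="training",
            rater_sex=rater_sex,
        )
        alphas[sex] = cronbach_alpha(ratings)
        r = mean_scores(standardize_ratings(ratings))
        vector = fit_attractiveness_vector(training.candidates, r.to_numpy(), sex)
        vector.model_ref = model.metadata["model_ref"]
        vector.metadata["combined_normalization"] = config.combined_normalization
        vectors[sex] = vector
        cosines[sex] = float(vector.t_hat_joint() @ truth.direction)
        _log(log, f"training_{sex}", alpha=round(alphas[sex], 4),
             cosine=round(cosines[sex], 4))

        records = build_validation_set(
            model,
            vector,
            n_faces=config.validation_faces,
            deltas=config.deltas,
            seed=stage_seed(seed, f"validation_faces_{sex}"),
            scale_factor=config.scale_factor,
            modes=config.modes,
            combined_normalization=config.combined_normalization,
        )
        for cond in config.modes:
            stim = [(fid, d, c) for fid, d, m, c in records if m == cond]
            item_ids = [f"{fid}@{d:+g}" for fid, d, _ in stim]
            deltas = np.array([d for _, d, _ in stim])
            val_panel = rater_panel(
                config.n_raters_validation,
                latent_sd,
                noise_ratio=config.noise_ratio,
                seed=stage_seed(seed, f"raters_val_{sex}_{cond}"),
            )
            ratings_val[(sex, cond)] = simulate_ratings(
                [c for _, _, c in stim],
                truth,
                val_panel,
                seed=stage_seed(seed, f"ratings_val_{sex}_{cond}"),
                discretization=config.discretization,
                face_ids=item_ids,
                condition=cond,
                delta_levels=deltas,
            )
        _log(log, f"validation_{sex}", stimuli=len(records),
             raters_per_condition=config.n_raters_validation)

        if outdir:
            pools_dir = outdir / "pools"
            pools_dir.mkdir(exist_ok=True)
            sampling.pool_to_csv(training, pools_dir / f"training_{sex}.csv")
            save_vector(vector, outdir / "vectors" / sex)
            (outdir / "vectors" / sex / "truth.json").write_text(
                json.dumps(truth.to_json())
            )
            ratings_dir = outdir / "ratings"
            ratings_dir.mkdir(exist_ok=True)
            ratings.to_long_frame().to_csv(
                ratings_dir / f"training_{sex}.csv", index=False
            )
            for cond in config.modes:
                ratings_val[(sex, cond)].to_long_frame().to_csv(
                    ratings_dir / f"validation_{sex}_{cond}.csv", index=False
                )

    analysis = validate_model(
        ratings_val,
        config.mcmc_settings(stage_seed(seed, "mcmc")),
        delta_rho_method=config.delta_rho_method,
    )
    _log(log, "analysis", sexes=len(SEXES), conditions=len(config.modes))

    report = {
        "config": config.to_dict(),
        "config_hash": chash,
        "master_seed": seed,
        "training": {
            sex: {
                "cronbach_alpha": alphas[sex],
                "direction_cosine": cosines[sex],
                "n_faces": config.k_select,
                "n_raters": config.n_raters_training,
            }
            for sex in SEXES
        },
        "validation": analysis["report"],
    }
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "log.txt").write_text("\n".join(log) + "\n")

    return ExperimentResult(
        config=config,
        model=model,
        truths=truths,
        vectors=vectors,
        alphas=alphas,
        cosines=cosines,
        analysis=analysis,
        report=report,
        outdir=outdir,
    )


def render_gallery(
    model: FaceSpaceModel,
    vector: AttractivenessVector,
    base: FaceCoefficients,
    outdir: str | Path,
    deltas=(-10.0, -3.0, 0.0, 3.0, 10.0),
    uv: np.ndarray | None = None,
) -> dict:
    """Export an OBJ + PNG grid of one face manipulated per mode and level.

    Rows are the three manipulation modes, columns the deltas (default
    -10, -3, 0, +3, +10 s.d.), plus a composite overview image of the
    texture maps.
    """
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tiles = []
    for mode in MODES:
        row = []
        for delta in deltas:
            spec = ManipulationSpec(delta=delta, mode=mode)
            geo = synthesize(model, manipulate(base, vector, spec))
            stem = f"{mode}_{delta:+g}"
            export_obj(geo, outdir / f"{stem}.obj", uv=uv)
            export_texture_png(geo, outdir / f"{stem}.png")
            paths[(mode, delta)] = outdir / stem
            row.append(np.round(geo.texture * 255).astype(np.uint8))
        tiles.append(np.concatenate(row, axis=1))
    overview = Image.fromarray(np.concatenate(tiles, axis=0), mode="RGB")
    overview.save(outdir / "overview.png")
    paths["overview"] = outdir / "overview.png"
    return paths


def fixture_suite(seed: int = 0) -> dict:
    """Deterministic miniature dataset for oracle tests.

    A 12-vertex head, a 2+2-PC face space fitted on 10 faces, a pool of 8
    male faces, 4 raters, their ratings, the mean standardized scores and
    the fitted attractiveness vector.
    """
    template = make_template(
        n_lat=2, n_lon=5, texture_size=4, n_idio_shape=8, n_idio_texture=8,
        seed=stage_seed(seed, "fixture_template"),
    )
    population = sample_population(
        template, 10, seed=stage_seed(seed, "fixture_population")
    )
    model = fit_face_space(population, k_shape=2, k_reflectance=2)
    pool = sampling.sample_candidates(
        model, "male", 8, stage_seed(seed, "fixture_pool")
    )
    truth = GroundTruthPreference.random(
        2, 2, 0.5, seed=stage_seed(seed, "fixture_truth"), sex="male"
    )
    latent_sd = float(truth.latent(pool.candidates).std(ddof=1))
    raters = rater_panel(
        4, latent_sd, noise_ratio=0.5, seed=stage_seed(seed, "fixture_raters")
    )
    ratings = simulate_ratings(
        pool.candidates, truth, raters, seed=stage_seed(seed, "fixture_ratings")
    )
    r = mean_scores(standardize_ratings(ratings))
    vector = fit_attractiveness_vector(pool.candidates, r.to_numpy(), "male")
    return {
        "template": template,
        "model": model,
        "pool": pool,
        "truth": truth,
        "raters": raters,
        "ratings": ratings,
        "r": r,
        "vector": vector,
    }
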