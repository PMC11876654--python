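"""End-to-end pipeline orchestration with caching and a run manifest.

Stages (oracle mode, no training required): simulate a labelled pool of
generated images, compute the treatment and size vectors from rater labels,
apply the treatment (and compensated composite) fractionally to produce the
image strips, and evaluate a realism report between a held-out simulator set
and an oracle-generated set.  Each stage records input/output hashes in a
manifest; a rerun with an unchanged configuration skips stages whose
recorded hashes still match.

The single ``global_seed`` fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed, stage_index)``, so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import directions, evaluate, gan, simulate

log = logging.getLogger("dermavec")

__all__ = ["PipelineConfig", "run_pipeline"]

_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class PipelineConfig:
    """Configuration of the oracle-mode end-to-end run."""

    output_root: str = "runs/pipeline"
    global_seed: int = 0
    resolution: int = 32
    n_pool: int = 600          # generated pool offered to the simulated raters
    n_eval: int = 200          # images per set in the realism report
    correlation: float = 0.3   # severity-size correlation of the data regime
    n_raters: int = 3
    n_strips: int = 3          # example images for the fraction strips
    fractions: tuple = _FRACTIONS
    n_source_images: int = 40  # simulator photographs feeding augmentation
    augment_count: int = 0     # >0 enables the augmentation stage
    train_kimg: int = 0        # >0 enables GAN training on the augmented set

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**(yaml.safe_load(fh) or {}))


def _stage_seed(global_seed: int, stage_index: int) -> int:
    return int(
        np.random.SeedSequence([int(global_seed), stage_index]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _sample_correlated_pool(cfg: PipelineConfig, seed: int):
    """w pool whose decoded severity and area carry the configured correlation."""
    factors = simulate.sample_factors(cfg.n_pool, correlation=cfg.correlation, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    w_pool = rng.standard_normal((cfg.n_pool, 512))
    for i, f in enumerate(factors):
        w_pool[i, :2] = gan.encode_factors(f.severity, f.area_fraction, [])[:2]
    return w_pool, factors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.json"
    old = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
    manifest: dict = {"config": asdict(config), "stages": {}}

    handler = logging.FileHandler(root / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    events = open(root / "events.jsonl", "a")

    def emit(stage: str, **kw):
        events.write(json.dumps({"stage": stage, "time": time.time(), **kw}) + "\n")
        events.flush()

    def run_stage(name: str, index: int, inputs_hash: str, outputs: list[Path], fn):
        rec_old = old.get("stages", {}).get(name)
        if (
            rec_old
            and rec_old.get("inputs_hash") == inputs_hash
            and all(Path(p).exists() for p in rec_old.get("outputs", {}))
            and all(_hash_file(Path(p)) == h for p, h in rec_old.get("outputs", {}).items())
        ):
            log.info("stage %s: cache hit", name)
            emit(name, cached=True)
            manifest["stages"][name] = {**rec_old, "cached": True}
            return False
        t0 = time.time()
        log.info("stage %s: running", name)
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            manifest_path.write_text(json.dumps(manifest, indent=2))
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "inputs_hash": inputs_hash,
            "seed": _stage_seed(config.global_seed, index),
            "outputs": {str(p): _hash_file(p) for p in outputs if p.exists()},
            "wall_time_s": round(time.time() - t0, 3),
            "cached": False,
        }
        emit(name, cached=False, wall_time_s=manifest["stages"][name]["wall_time_s"])
        return True

    cfg_hash = _hash_obj(asdict(config))

    # optional stages: source data -> augmentation -> GAN training --------
    if config.augment_count > 0:
        from .augment import AugmentConfig, augment_directory

        data_dir = root / "data"
        aug_dir = root / "augmented"
        seed_a = _stage_seed(config.global_seed, 10)

        def stage_data():
            pairs = simulate.sample_dataset(
                config.n_source_images, correlation=config.correlation,
                seed=seed_a, size=config.resolution,
            )
            simulate.save_dataset(pairs, data_dir)

        run_stage("data", 10, cfg_hash, [data_dir / "factors.csv"], stage_data)

        def stage_augment():
            augment_directory(
                data_dir, aug_dir,
                AugmentConfig(
                    target_count=config.augment_count,
                    output_size=config.resolution, seed=seed_a,
                ),
            )

        run_stage(
            "augment", 11, _hash_obj([cfg_hash, "aug"]),
            [aug_dir / "manifest.csv"], stage_augment,
        )

        if config.train_kimg > 0:
            ckpt = root / "generator.npz"
            train_log = root / "training_log.json"

            def stage_train():
                from PIL import Image as PILImage

                imgs = [
                    np.asarray(PILImage.open(p).convert("RGB"))
                    for p in sorted(aug_dir.glob("*.png"))
                ]
                tc = gan.TrainConfig(
                    resolution=config.resolution,
                    total_kimg=config.train_kimg,
                    seed=_stage_seed(config.global_seed, 12),
                )
                handle, tlog = gan.train(imgs, tc, n_eval=min(128, len(imgs)))
                gan.save_checkpoint(handle, ckpt)
                train_log.write_text(json.dumps(tlog))

            run_stage(
                "train", 12, _hash_obj([cfg_hash, "train"]),
                [ckpt, train_log], stage_train,
            )

    # stage 0: labelled oracle pool -------------------------------------
    pool_dir = root / "pool"
    seed0 = _stage_seed(config.global_seed, 0)
    w_csv = pool_dir / "w.csv"
    labels_csv = pool_dir / "labels.csv"

    def stage_pool():
        pool_dir.mkdir(parents=True, exist_ok=True)
        w_pool, factors = _sample_correlated_pool(config, seed0)
        ids = [f"img_{i:05d}" for i in range(len(w_pool))]
        pd.DataFrame(
            w_pool, index=pd.Index(ids, name="image_id"),
            columns=[f"w_{j}" for j in range(w_pool.shape[1])],
        ).to_csv(w_csv)
        decoded = [gan.decode_w(w) for w in w_pool]
        labels = simulate.simulate_labels(decoded, n_raters=config.n_raters, seed=seed0)
        labels.to_csv(labels_csv, index=False)

    run_stage("pool", 0, cfg_hash, [w_csv, labels_csv], stage_pool)

    # stage 1: directions -------------------------------------------------
    dir_dir = root / "directions"
    treat_csv = dir_dir / "treatment.csv"
    size_csv = dir_dir / "size.csv"

    def stage_directions():
        dir_dir.mkdir(parents=True, exist_ok=True)
        w_df = pd.read_csv(w_csv, index_col="image_id")
        labels = pd.read_csv(labels_csv)
        sev_pos, sev_neg = directions.select_label_groups(labels, "severity")
        treat = directions.compute_direction(
            [w_df.loc[i].to_numpy() for i in sev_neg],   # moderate = target
            [w_df.loc[i].to_numpy() for i in sev_pos],   # severe = source
            name="treatment",
        )
        directions.save_direction(treat, treat_csv)
        small, large = directions.select_label_groups(labels, "coverage")
        size_vec = directions.compute_direction(
            [w_df.loc[i].to_numpy() for i in small],
            [w_df.loc[i].to_numpy() for i in large],
            name="size",
        )
        directions.save_direction(size_vec, size_csv)

    run_stage("directions", 1, _hash_obj([cfg_hash, "dir"]), [treat_csv, size_csv], stage_directions)

    # stage 2: fraction strips --------------------------------------------
    strips_dir = root / "strips"
    strip_paths = [strips_dir / f"strip_{i}.png" for i in range(config.n_strips)]

    def stage_apply():
        strips_dir.mkdir(parents=True, exist_ok=True)
        gen = gan.oracle_generator(resolution=config.resolution, seed=seed0)
        treat = directions.load_direction(treat_csv)
        rng = np.random.default_rng(np.random.SeedSequence([seed0, 9]))
        for i in range(config.n_strips):
            w = rng.standard_normal(512)
            w[0] = rng.uniform(1.5, 2.5)  # severe regime
            imgs = [
                gen.synthesize(directions.apply_fraction(w, treat, f))
                for f in config.fractions
            ]
            strip = np.concatenate(imgs, axis=1)
            Image.fromarray(strip).save(strip_paths[i])

    run_stage("apply", 2, _hash_obj([cfg_hash, "apply"]), strip_paths, stage_apply)

    # stage 3: realism report ---------------------------------------------
    report_path = root / "realism_report.json"

    def stage_evaluate():
        seed3 = _stage_seed(config.global_seed, 3)
        gen = gan.oracle_generator(resolution=config.resolution, seed=seed3)
        set_a = [
            img for img, _ in simulate.sample_dataset(
                config.n_eval, correlation=config.correlation, seed=seed3,
                size=config.resolution,
            )
        ]
        rng = np.random.default_rng(np.random.SeedSequence([seed3, 13]))
        set_b = [gen.synthesize(rng.standard_normal(512)) for _ in range(config.n_eval)]
        report = evaluate.realism_report(set_a, set_b)
        report_path.write_text(json.dumps(report.to_json_dict(), indent=2))

    run_stage("evaluate", 3, _hash_obj([cfg_hash, "eval"]), [report_path], stage_evaluate)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    events.close()
    log.removeHandler(handler)
    handler.close()
    return manifest
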