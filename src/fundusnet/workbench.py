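"""Top-level orchestration: count reproduction, experiment runner, CLI.

``reproduce_counts`` tabulates the computed kernel-weight counts of the
published family members next to their printed values.  Four printed counts
(one-level, five-level, residual, dense) are not reproducible under the
counting convention that exactly matches the other nine and are emitted
with a ``not asserted`` flag.  ``run_experiment`` chains the full protocol:
preprocess -> weight maps -> splits -> repeated training -> threshold
selection -> per-image metrics -> two-stage aggregation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import click
import numpy as np
import pandas as pd
import tifffile

from . import evaluation as ev
from .data_pipeline import (
    REGISTRY,
    DatasetSpec,
    load_database,
    make_splits,
    prepare_samples,
    synthetic_dataset_spec,
)
from .model_family import (
    DEFAULT_SPEC,
    ArchitectureSpec,
    UnsupportedCountingError,
    build_network,
    kernel_weight_count,
)
from .preprocessing import FundusSample, erode_fov, preprocess
from .supervision import weight_map
from .synthetic_fundus import make_dataset, preset_a, preset_b
from .training import TrainConfig, repeat_runs, restore_model

__all__ = ["reproduce_counts", "run_experiment", "cli", "PRINTED_COUNTS"]


#: published family members: (label, spec or None, printed count, asserted)
PRINTED_COUNTS = [
    ("U (default)", DEFAULT_SPEC, 108_976, True),
    ("Udil", DEFAULT_SPEC.with_(block_variant="dilated_bottleneck"), 108_976, True),
    ("Uside", DEFAULT_SPEC.with_(block_variant="side_output"), 109_072, True),
    ("U-lin", DEFAULT_SPEC.with_(activation="linear"), 108_976, True),
    ("U-ns", DEFAULT_SPEC.with_(skip_connections=False), 97_456, True),
    ("U-1C", DEFAULT_SPEC.with_(convs_per_block=1), 49_072, True),
    ("8 filters", DEFAULT_SPEC.with_(init_filters=8), 27_352, True),
    ("4 filters", DEFAULT_SPEC.with_(init_filters=4), 6_892, True),
    ("2 filters", DEFAULT_SPEC.with_(init_filters=2), 1_750, True),
    ("1 filter", DEFAULT_SPEC.with_(init_filters=1), 451, True),
    ("2 levels", DEFAULT_SPEC.with_(levels=2), 23_984, True),
    ("1 level", DEFAULT_SPEC.with_(levels=1), 17_344, False),
    ("5 levels", DEFAULT_SPEC.with_(levels=5), 1_852_336, False),
    ("Ures", DEFAULT_SPEC.with_(block_variant="residual"), 154_768, False),
    ("Uden", DEFAULT_SPEC.with_(block_variant="dense_encoder"), 2_501_067, False),
]


def reproduce_counts() -> pd.DataFrame:
    """Computed vs printed kernel-weight counts for the published family."""
    rows = []
    for label, spec, printed, asserted in PRINTED_COUNTS:
        try:
            computed = kernel_weight_count(spec)
        except UnsupportedCountingError:
            computed = None
        rows.append({
            "model": label,
            "computed": computed,
            "printed": printed,
            "asserted": asserted,
            "match": (computed == printed) if computed is not None else False,
            "note": "" if asserted else "not asserted",
        })
    return pd.DataFrame(rows)


def _spec_from_dict(d: dict) -> ArchitectureSpec:
    return ArchitectureSpec(**d) if d else DEFAULT_SPEC


def _dataset_spec(manifest: dict, n_images: int) -> DatasetSpec:
    name = manifest.get("db", "synthetic")
    if name in REGISTRY:
        return REGISTRY[name]
    return synthetic_dataset_spec(
        n_images,
        image_size=manifest.get("image_size", 512),
        patch_size=manifest.get("patch_size", 96),
        batch_size=manifest.get("batch_size", 8),
        name=name,
    )


def run_experiment(manifest: dict):
    """Run one named experiment end to end.

    Manifest keys: ``db_dir`` (database directory), ``db`` (registry name or
    custom), ``spec`` (ArchitectureSpec fields), ``folds`` (list),
    ``n_repetitions``, ``train`` (TrainConfig fields), ``seed``.  Returns
    ``(records DataFrame, {fold: AggregateRow})``.
    """
    samples = load_database(manifest["db_dir"])
    db = _dataset_spec(manifest, len(samples))
    spec = _spec_from_dict(manifest.get("spec", {}))
    seed = int(manifest.get("seed", 0))
    n_rep = int(manifest.get("n_repetitions", 5))
    folds = manifest.get("folds", [0])
    cfg = TrainConfig(**manifest.get("train", {}), seed=seed) \
        if "seed" not in manifest.get("train", {}) \
        else TrainConfig(**manifest["train"])

    by_id = {s.image_id: s for s in samples}
    prepared = prepare_samples(samples, db)
    ids = sorted(by_id)
    all_records = []
    aggregates = {}
    for fold in folds:
        plan = make_splits(db, fold, seed, ids=ids)
        runs = repeat_runs(spec, prepared, plan, db, cfg, n=n_rep)
        for rollout, run in enumerate(runs):
            model = restore_model(run)
            val_preds = [ev.predict_sample(model, by_id[i], db.resample_factor)
                         for i in plan.validation]
            thr = ev.select_threshold(
                val_preds,
                [by_id[i].annotation for i in plan.validation],
                [erode_fov(by_id[i].fov) for i in plan.validation])
            for img_id in plan.test:
                s = by_id[img_id]
                pred = ev.predict_sample(model, s, db.resample_factor)
                rec = ev.image_metrics(pred, s.annotation, erode_fov(s.fov),
                                       thr, image_id=img_id,
                                       rollout_id=rollout)
                rec_d = rec.as_dict()
                rec_d["fold"] = fold
                all_records.append(rec_d)
        fold_records = [r for r in all_records if r["fold"] == fold]
        aggregates[fold] = ev.aggregate(
            [{k: v for k, v in r.items() if k != "fold"} for r in fold_records])
    return pd.DataFrame(all_records), aggregates


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """Few-parameter U-Net workbench for retinal vessel segmentation."""


def _load_spec_file(path: str | None) -> ArchitectureSpec:
    if path is None:
        return DEFAULT_SPEC
    text = Path(path).read_text()
    if path.endswith((".yaml", ".yml")):
        import yaml
        return ArchitectureSpec(**yaml.safe_load(text))
    return ArchitectureSpec(**json.loads(text))


@cli.command("count-params")
@click.option("--spec", "spec_path", type=click.Path(exists=True), default=None,
              help="YAML/JSON file with ArchitectureSpec fields (default spec if omitted)")
def cli_count_params(spec_path):
    """Print kernel and total trainable counts of a family member."""
    spec = _load_spec_file(spec_path)
    try:
        kw = kernel_weight_count(spec)
        click.echo(f"kernel_weight_count: {kw}")
    except UnsupportedCountingError as e:
        click.echo(f"kernel_weight_count: not covered ({e})")
    model = build_network(spec, seed=0)
    click.echo(f"introspected kernels: {model.kernel_weight_count}")
    click.echo(f"total trainable (incl. normalization): {model.total_trainable_count}")


@cli.command("reproduce-counts")
@click.option("--out", type=click.Path(), default=None, help="optional CSV path")
def cli_reproduce_counts(out):
    """Computed vs printed parameter counts of the published family."""
    df = reproduce_counts()
    if out:
        df.to_csv(out, index=False)
    click.echo(df.to_string(index=False))


@cli.command("synth")
@click.option("--n", default=12, show_default=True)
@click.option("--size", default=512, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--preset", default="a", type=click.Choice(["a", "b"]), show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_synth(n, size, seed, preset, out):
    """Generate a synthetic phantom database."""
    cfg = (preset_a if preset == "a" else preset_b)(image_size=size)
    path = make_dataset(n, cfg, seed, out)
    click.echo(f"wrote {n} phantoms to {path}")


@cli.command("preprocess")
@click.option("--image", required=True, type=click.Path(exists=True))
@click.option("--fov", "fov_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_preprocess(image, fov_path, out):
    """Preprocess one fundus image; writes a float TIFF plus the eroded FOV."""
    import imageio.v3 as iio
    rgb = np.asarray(iio.imread(image))[..., :3]
    fov = np.asarray(iio.imread(fov_path)) > 127
    pre = preprocess(FundusSample(rgb=rgb, fov=fov))
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out, pre.values.astype(np.float32))
    iio.imwrite(out.with_suffix(".fov.png"),
                erode_fov(fov).astype(np.uint8) * 255)
    click.echo(f"wrote {out}")


@cli.command("weight-map")
@click.option("--annotation", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_weight_map(annotation, out):
    """Inverse-diameter loss weight map of a binary vessel annotation."""
    import imageio.v3 as iio
    ann = np.asarray(iio.imread(annotation)) > 127
    wm = weight_map(ann)
    tifffile.imwrite(out, wm.W.astype(np.float32))
    click.echo(f"wrote {out} (max weight {wm.W.max():.3f})")


@cli.command("make-splits")
@click.option("--db", required=True)
@click.option("--fold", default=0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--n-images", default=None, type=int,
              help="image count for non-registry databases")
@click.option("--out", default=None, type=click.Path())
def cli_make_splits(db, fold, seed, n_images, out):
    """Write a train/validation/test plan as JSON."""
    spec = REGISTRY.get(db) or synthetic_dataset_spec(n_images or 12, name=db)
    plan = make_splits(spec, fold, seed)
    payload = dataclasses.asdict(plan)
    text = json.dumps(payload, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


@cli.command("train")
@click.option("--db-dir", required=True, type=click.Path(exists=True))
@click.option("--db", default="synthetic", show_default=True)
@click.option("--spec", "spec_path", type=click.Path(exists=True), default=None)
@click.option("--fold", default=0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--iterations", default=2000, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_train(db_dir, db, spec_path, fold, seed, iterations, out):
    """Train one model and store its run record (npz + JSON + CSV curves)."""
    from .training import restore_model, save_run, train as train_fn
    samples = load_database(db_dir)
    dbspec = REGISTRY.get(db) or synthetic_dataset_spec(len(samples), name=db)
    spec = _load_spec_file(spec_path)
    prepared = prepare_samples(samples, dbspec)
    plan = make_splits(dbspec, fold, seed, ids=sorted(prepared))
    cfg = TrainConfig(max_iterations=iterations, seed=seed)
    run = train_fn(spec, prepared, plan, dbspec, cfg)
    by_id = {s.image_id: s for s in samples}
    model = restore_model(run)
    val = [by_id[i] for i in plan.validation]
    thr = ev.select_threshold(
        [ev.predict_sample(model, s, dbspec.resample_factor) for s in val],
        [s.annotation for s in val], [erode_fov(s.fov) for s in val])
    save_run(run, out, threshold=thr)
    click.echo(f"best validation loss {run.best_val_loss:.5f} "
               f"at iteration {run.converged_iteration}; threshold {thr:.4f}")


@cli.command("evaluate")
@click.option("--run", "run_dir", required=True, type=click.Path(exists=True))
@click.option("--db-dir", required=True, type=click.Path(exists=True))
@click.option("--db", default="synthetic", show_default=True)
@click.option("--fold", default=0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", default=None, type=click.Path())
def cli_evaluate(run_dir, db_dir, db, fold, seed, out):
    """Evaluate a saved run on a database's test split (threshold reselected
    on that database's validation images)."""
    from .training import load_run
    model, _ = load_run(run_dir)
    samples = load_database(db_dir)
    dbspec = REGISTRY.get(db) or synthetic_dataset_spec(len(samples), name=db)
    by_id = {s.image_id: s for s in samples}
    plan = make_splits(dbspec, fold, seed, ids=sorted(by_id))
    val = [by_id[i] for i in plan.validation]
    thr = ev.select_threshold(
        [ev.predict_sample(model, s, dbspec.resample_factor) for s in val],
        [s.annotation for s in val], [erode_fov(s.fov) for s in val])
    records = []
    for tid in plan.test:
        s = by_id[tid]
        pred = ev.predict_sample(model, s, dbspec.resample_factor)
        records.append(ev.image_metrics(pred, s.annotation, erode_fov(s.fov),
                                        thr, image_id=tid))
    agg = ev.aggregate(records)
    _emit_metrics(records, agg, out)


@cli.command("transfer")
@click.option("--run", "run_dir", required=True, type=click.Path(exists=True))
@click.option("--target-db-dir", required=True, type=click.Path(exists=True))
@click.option("--target-db", default="synthetic", show_default=True)
@click.option("--out", default=None, type=click.Path())
def cli_transfer(run_dir, target_db_dir, target_db, out):
    """Apply a saved run to another database without retraining, carrying
    the source database's threshold."""
    from .training import load_run
    model, meta = load_run(run_dir)
    samples = load_database(target_db_dir)
    dbspec = REGISTRY.get(target_db) or synthetic_dataset_spec(
        len(samples), name=target_db)
    records, agg = ev.transfer_evaluate(model, samples,
                                        threshold=meta.get("threshold", 0.5),
                                        resample_factor=dbspec.resample_factor)
    _emit_metrics(records, agg, out)


def _emit_metrics(records, agg, out):
    if out:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([r.as_dict() for r in records]).to_csv(
            outdir / "records.csv", index=False)
        (outdir / "aggregate.json").write_text(
            json.dumps({"mean": agg.mean, "std": agg.std}, indent=2))
    click.echo("  ".join(f"{m}={agg.mean[m]:.4f}" for m in agg.mean))


@cli.command("run")
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
def cli_run(manifest, out):
    """Run a full experiment from a YAML/JSON manifest."""
    import yaml
    text = Path(manifest).read_text()
    man = yaml.safe_load(text)
    records, aggregates = run_experiment(man)
    if out:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "records.csv", index=False)
        agg = {str(f): {"mean": a.mean, "std": a.std} for f, a in aggregates.items()}
        (outdir / "aggregate.json").write_text(json.dumps(agg, indent=2))
    for fold, a in aggregates.items():
        click.echo(f"fold {fold}: " + "  ".join(
            f"{m}={a.mean[m]:.4f}±{a.std[m]:.4f}" for m in a.mean))


if __name__ == "__main__":
    cli()
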