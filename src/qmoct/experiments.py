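"""Reduced-scale in-silico studies.

Three scripted studies probe the behaviour of the dispersion-extraction
pipeline with a desk-scale (CPU, minutes) trained model standing in for a
full-scale one, so their outputs are trend indicators, not quantitative
reproductions:

* ``variability_grid`` — three-equal-layer objects whose layer thickness
  sweeps 4 -> 306 um over 138 profiles, for several GVD triples; larger
  within-object GVD contrast should predict better.
* ``snr_study`` — models trained at one noise level evaluated across
  noise levels (MAE matrix).
* ``resolution_sweep`` — a fixed three-interface object rendered at axial
  resolutions 2.72 -> 8.16 um and pushed through one model; predicted GVD
  scales with the resolution mismatch.

Also here: the high-contrast smoke-training setup used to exercise the
network end to end on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forward_model import (
    Layer,
    LayeredObject,
    NoiseConfig,
    SpectralGrid,
    add_noise,
    synthesize_spectrum,
)
from .network import QmRegressor, TrainConfig, build_model, predict_map, smoke_config, train
from .processing import fft_stack
from .profiles import DispersionMap, decode_gvd, profile_from_object

__all__ = [
    "StudyConfig",
    "high_contrast_objects",
    "epoch_pairs",
    "sign_recovery",
    "smoke_train",
    "variability_grid",
    "snr_study",
    "resolution_sweep",
]

#: GVD triples of the variability study rows (fs^2/mm), smallest to
#: largest within-object contrast.
DEFAULT_TRIPLES: tuple[tuple[float, float, float], ...] = (
    (1010.0, 1000.0, 1005.0),
    (1100.0, 1000.0, 1050.0),
    (1200.0, 1000.0, 1100.0),
    (1400.0, 1000.0, 1200.0),
    (2000.0, 1000.0, 1500.0),
)


@dataclass(frozen=True)
class StudyConfig:
    """Shared reduced-scale study settings."""

    study_id: str = "variability"
    snr_db: float | None = 30.0
    seed: int = 0
    n_profiles: int = 138
    thickness_range_um: tuple[float, float] = (4.0, 306.0)
    front_distance_um: float = 100.0
    resolutions_um: tuple[float, ...] = tuple(np.linspace(2.72, 8.16, 9).round(3))
    snr_levels: tuple[float | None, ...] = (None, 45.0, 35.0, 30.0, 25.0)


# ---------------------------------------------------------------------------
# smoke training
# ---------------------------------------------------------------------------

def high_contrast_objects(
    n: int,
    seed: int,
    *,
    gvd_magnitude: tuple[float, float] = (3000.0, 5000.0),
    thickness_um: tuple[float, float] = (220.0, 300.0),
    front_distance_um: tuple[float, float] = (150.0, 250.0),
) -> list[LayeredObject]:
    """Two-interface objects with one thick, strongly dispersive layer.

    The layer GVD magnitude is drawn uniformly from ``gvd_magnitude`` with
    a random sign — the regime where dispersion artefacts in the FFT stack
    are strongest and a lightly trained model can already read them.
    """
    rng = np.random.default_rng(seed)
    objs = []
    for _ in range(n):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        objs.append(
            LayeredObject(
                front_distance_um=float(rng.uniform(*front_distance_um)),
                layers=(
                    Layer(
                        thickness_um=float(rng.uniform(*thickness_um)),
                        gvd=sign * float(rng.uniform(*gvd_magnitude)),
                        reflectivity=float(rng.uniform(0.5, 1.0)),
                    ),
                ),
                front_reflectivity=float(rng.uniform(0.5, 1.0)),
            )
        )
    return objs


def epoch_pairs(
    objects: Sequence[LayeredObject],
    grid: SpectralGrid,
    snr_db: float | None,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(stack, profile) training pairs with fresh noise for one epoch.

    Object parameters stay fixed across epochs; the spectra (and their
    noise) are recomputed anew each time, mirroring on-the-fly dataset
    generation.
    """
    rng = np.random.default_rng(seed)
    noise = NoiseConfig(snr_db=snr_db, seed=seed)
    pairs = []
    for obj in objects:
        spec = add_noise(synthesize_spectrum(obj, grid), noise, rng=rng)
        pairs.append(
            (fft_stack(spec).values, profile_from_object(obj, grid).values)
        )
    return pairs


def sign_recovery(
    predicted: DispersionMap,
    truth: DispersionMap,
    min_abs_gvd: float = 1000.0,
) -> float:
    """Fraction of strongly dispersive pixels whose predicted GVD sign
    matches the ground truth.

    Only pixels whose true decoded |GVD| exceeds ``min_abs_gvd`` (layer
    interiors, not the neutral 0.5 background) are counted.
    """
    t = decode_gvd(truth.values)
    p = decode_gvd(np.clip(predicted.values, 0.0, 1.0))
    mask = np.abs(t) >= min_abs_gvd
    if not mask.any():
        raise ValueError("no pixels above the GVD magnitude threshold")
    return float(np.mean(np.sign(p[mask]) == np.sign(t[mask])))


def smoke_train(
    n_train: int = 200,
    n_test: int = 50,
    epochs: int = 10,
    snr_db: float | None = 30.0,
    seed: int = 0,
    grid: SpectralGrid | None = None,
) -> tuple[QmRegressor, dict[str, list[float]], dict[str, float]]:
    """Desk-scale end-to-end training run on high-contrast objects.

    Trains the small configuration for ``epochs`` epochs on ``n_train``
    two-interface objects at ``snr_db`` (data regenerated every epoch) and
    evaluates sign recovery on ``n_test`` held-out objects.  Returns
    ``(model, history, metrics)`` with metrics ``initial_mae``,
    ``final_mae``, ``test_mae`` and ``sign_recovery``.

    The learning rate is raised to 3e-3 for this short run; the full-scale
    rate of 1e-4 is tuned for hundreds of thousands of objects and makes
    no visible progress in ten desk-scale epochs.
    """
    grid = grid or SpectralGrid()
    train_objs = high_contrast_objects(n_train, seed)
    test_objs = high_contrast_objects(n_test, seed + 1)
    model = build_model(smoke_config(), seed=seed)
    cfg = TrainConfig(batch_size=16, learning_rate=3e-3, epochs=epochs, seed=seed)
    history = train(
        model,
        lambda epoch: epoch_pairs(train_objs, grid, snr_db, seed=1000 + epoch),
        None,
        cfg,
    )
    test_pairs = epoch_pairs(test_objs, grid, snr_db, seed=5000)
    stacks = np.stack([x for x, _ in test_pairs])
    truth = DispersionMap(np.stack([y for _, y in test_pairs]))
    pred = predict_map(model, stacks)
    metrics = {
        "initial_mae": history["initial_mae"][0] if history["initial_mae"] else float("nan"),
        "final_mae": history["train_mae"][-1] if history["train_mae"] else float("nan"),
        "test_mae": float(np.mean(np.abs(pred.values - truth.values))),
        "sign_recovery": sign_recovery(pred, truth, min_abs_gvd=1000.0),
    }
    return model, history, metrics


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def _three_layer_object(front_um: float, thickness_um: float,
                        triple: Sequence[float]) -> LayeredObject:
    return LayeredObject(
        front_distance_um=front_um,
        layers=tuple(Layer(thickness_um, g, 0.7) for g in triple),
        front_reflectivity=0.7,
    )


def variability_grid(
    model: QmRegressor,
    triples: Sequence[Sequence[float]] = DEFAULT_TRIPLES,
    config: StudyConfig | None = None,
    grid: SpectralGrid | None = None,
) -> dict:
    """Ground-truth and predicted maps over the thickness sweep.

    For each GVD triple, ``n_profiles`` three-equal-layer objects are
    generated with the layer thickness sweeping over
    ``thickness_range_um``; row i of a map is object i's profile.  Returns
    ``{"triples", "ground_truth", "predicted", "summary"}`` where summary
    is a per-triple DataFrame of mean absolute decoded-GVD error.
    """
    config = config or StudyConfig(study_id="variability")
    grid = grid or SpectralGrid()
    noise = NoiseConfig(snr_db=config.snr_db, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    thicknesses = np.linspace(*config.thickness_range_um, config.n_profiles)
    truth_maps, pred_maps, rows = [], [], []
    for triple in triples:
        truths, stacks = [], []
        for t in thicknesses:
            obj = _three_layer_object(config.front_distance_um, float(t), triple)
            truths.append(profile_from_object(obj, grid).values)
            spec = add_noise(synthesize_spectrum(obj, grid), noise, rng=rng)
            stacks.append(fft_stack(spec).values)
        truth = DispersionMap(np.stack(truths))
        pred = predict_map(model, np.stack(stacks))
        truth_maps.append(truth)
        pred_maps.append(pred)
        err = np.mean(np.abs(decode_gvd(pred.values) - decode_gvd(truth.values)))
        rows.append({"triple": tuple(triple), "mean_abs_gvd_error": float(err)})
    return {
        "triples": [tuple(t) for t in triples],
        "ground_truth": truth_maps,
        "predicted": pred_maps,
        "summary": pd.DataFrame(rows),
    }


def snr_study(
    config: StudyConfig | None = None,
    n_train: int = 60,
    n_test: int = 30,
    epochs: int = 3,
    grid: SpectralGrid | None = None,
) -> pd.DataFrame:
    """MAE matrix of models trained at one SNR, tested at every SNR.

    Heavily reduced scale: small high-contrast objects, few epochs.  The
    returned DataFrame is indexed by training SNR with one column per test
    SNR (None meaning noiseless).
    """
    config = config or StudyConfig(study_id="snr")
    grid = grid or SpectralGrid()
    train_objs = high_contrast_objects(n_train, config.seed)
    test_objs = high_contrast_objects(n_test, config.seed + 1)
    truth = np.stack([profile_from_object(o, grid).values for o in test_objs])
    test_stacks = {
        level: np.stack([
            x for x, _ in epoch_pairs(test_objs, grid, level,
                                      seed=config.seed + 7)
        ])
        for level in config.snr_levels
    }
    rows = {}
    for level in config.snr_levels:
        model = build_model(smoke_config(), seed=config.seed)
        train(
            model,
            lambda epoch, lv=level: epoch_pairs(
                train_objs, grid, lv, seed=config.seed + 100 + epoch
            ),
            None,
            TrainConfig(batch_size=16, learning_rate=3e-3, epochs=epochs,
                        seed=config.seed),
        )
        rows[_label(level)] = {
            _label(test_level): float(np.mean(np.abs(
                predict_map(model, test_stacks[test_level]).values - truth
            )))
            for test_level in config.snr_levels
        }
    df = pd.DataFrame(rows).T
    df.index.name = "train_snr_db"
    df.columns.name = "test_snr_db"
    return df


def resolution_sweep(
    model: QmRegressor,
    config: StudyConfig | None = None,
    layer_gvds: tuple[float, float] = (-1500.0, 1000.0),
    layer_thickness_um: float = 150.0,
    front_distance_um: float = 150.0,
) -> pd.DataFrame:
    """Predicted layer GVD of a fixed three-interface object versus the
    axial resolution used to render its spectrum.

    The object layout (two layers with GVD ``layer_gvds``) is held fixed;
    only the source envelope width changes.  Returns one row per
    resolution with the mean decoded GVD over each layer interior.
    """
    config = config or StudyConfig(study_id="resolution")
    noise = NoiseConfig(snr_db=config.snr_db, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    obj = LayeredObject(
        front_distance_um=front_distance_um,
        layers=tuple(Layer(layer_thickness_um, g, 0.7) for g in layer_gvds),
        front_reflectivity=0.7,
    )
    rows = []
    for res in config.resolutions_um:
        grid = SpectralGrid(axial_resolution_um=float(res))
        truth = profile_from_object(obj, grid)
        spec = add_noise(synthesize_spectrum(obj, grid), noise, rng=rng)
        pred = predict_map(model, fft_stack(spec)).values[0]
        row = {"resolution_um": float(res)}
        pix = np.rint(obj.interface_depths_um / truth.depth_pitch_um).astype(int)
        for i, g in enumerate(layer_gvds):
            interior = slice(pix[i] + 2, pix[i + 1] - 2)
            row[f"layer{i + 1}_true_gvd"] = g
            row[f"layer{i + 1}_pred_gvd"] = float(
                np.mean(decode_gvd(np.clip(pred[interior], 0, 1)))
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _label(level: float | None) -> str:
    return "noiseless" if level is None else f"{level:g}dB"
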