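"""End-to-end validation scenarios on synthetic phantoms with known truth.

Each benchmark builds labeled phantoms under the package's standard study
conditions, runs the corresponding pipeline and returns both the estimate
and the ground truth, so callers (tests, the acceptance script, examples)
can judge recovery quality. Problem sizes are desk-scale: logs of a few
centimetres radius and a few dozen slices, large enough for every structure
class to be resolved at >= 2 voxels tunnel radius.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ctvolume import normalize
from .decay import (
    TrainConfig,
    annotation_set_from_volume,
    predict_slice,
    predict_volume,
    quantify_decay,
    select_threshold,
    train_decay_model,
)
from .labels import Label
from .metrics import classification_metrics, confusion_counts, spearman
from .phantom import (
    ExperimentEffects,
    LogPhantomSpec,
    TreatmentDesign,
    generate_phantom,
    simulate_experiment,
    true_volume_summary,
)
from .tunnels import segment_log

#: standard desk-scale log geometry used by the benchmarks
BENCH_GEOMETRY = LogPhantomSpec(
    length_slices=40,
    radius_mm=30.0,
    bark_thickness_mm=4.0,
    pixel_spacing_mm=(0.5, 0.5),
    slice_thickness_mm=1.0,
    tunnel_radius_mm=(1.0, 1.8),  # >= 2 voxels: resolvable at this spacing
    tunnel_length_mm=(20.0, 40.0),
)


@dataclass
class TunnelBenchmarkResult:
    true_total_percent: float
    est_total_percent: float
    true_bark_percent: float
    est_bark_percent: float
    true_wood_percent: float
    est_wood_percent: float
    cavity_recall: float
    n_voxels: int


def tunnel_benchmark(seed: int = 1, noise_sigma_hu: float = 0.0) -> TunnelBenchmarkResult:
    """Full tunnel pipeline vs ground truth on one structured phantom."""
    spec = replace(
        BENCH_GEOMETRY,
        tunnel_count=3,
        bark_tunnel_count=1,
        crack_count=3,
        noise_sigma_hu=noise_sigma_hu,
        seed=seed,
    )
    vol, lab = generate_phantom(spec)
    seg = segment_log(normalize(vol))
    truth = true_volume_summary(lab, include_larvae=True)
    true_cav = lab.mask(Label.TUNNEL_BARK, Label.TUNNEL_WOOD)
    est_cav = seg.labels.mask(
        Label.TUNNEL_BARK, Label.TUNNEL_WOOD, Label.CRACK, Label.DRILLING
    )
    recall = float((true_cav & est_cav).sum() / max(true_cav.sum(), 1))
    return TunnelBenchmarkResult(
        true_total_percent=truth.tunnel_total_percent,
        est_total_percent=seg.summary.tunnel_total_percent,
        true_bark_percent=truth.tunnel_bark_percent,
        est_bark_percent=seg.summary.tunnel_bark_percent,
        true_wood_percent=truth.tunnel_wood_percent,
        est_wood_percent=seg.summary.tunnel_wood_percent,
        cavity_recall=recall,
        n_voxels=int(np.prod(vol.shape)),
    )


def control_false_positive_benchmark(seed: int = 1) -> tuple[float, int]:
    """Spurious tunnel volume [%] on a crack-only control phantom.

    Shrinkage cracks are the main false-positive source for tunnel
    detection; the geometry rules should keep the residual small.
    """
    spec = replace(BENCH_GEOMETRY, crack_count=4, noise_sigma_hu=0.0, seed=seed)
    vol, _ = generate_phantom(spec)
    seg = segment_log(normalize(vol))
    return seg.summary.tunnel_total_percent, int(np.prod(vol.shape))


#: decay benchmark geometry: smaller in-plane, textured brown-rot decay
_DECAY_GEOMETRY = LogPhantomSpec(
    length_slices=24,
    radius_mm=28.0,
    bark_thickness_mm=3.0,
    pixel_spacing_mm=(0.5, 0.5),
    slice_thickness_mm=1.0,
    decay_radius_mm=(6.0, 12.0),
    decay_crack_system=True,
)


@dataclass
class DecayTrainingResult:
    model: object
    threshold: float
    selection_f1: float
    heldout_f1: float
    heldout_accuracy: float
    final_loss: float
    history: list[float]
    n_pixels: int


def decay_training_benchmark(
    seed: int = 1, config: TrainConfig | None = None
) -> DecayTrainingResult:
    """Train the decay classifier on annotated phantom slices; evaluate held out.

    Two thirds of the slices train the model; the threshold is selected and
    the pixel F1 measured on the remaining held-out slices.
    """
    spec = replace(_DECAY_GEOMETRY, decay_patch_count=4, seed=seed)
    vol, lab = generate_phantom(spec)
    norm = normalize(vol)
    ann = annotation_set_from_volume(norm.values, lab.mask(Label.DECAY))
    n_train = (2 * len(ann)) // 3
    train = type(ann)(images=ann.images[:n_train], masks=ann.masks[:n_train])
    config = config or TrainConfig(seed=seed)
    model, history = train_decay_model(train, config)
    held_imgs = ann.images[n_train:]
    probs = np.stack([predict_slice(model, img) for img in held_imgs])
    truth = np.stack(ann.masks[n_train:])
    thr = select_threshold(probs, truth)
    m = classification_metrics(confusion_counts(probs >= thr.threshold, truth))
    return DecayTrainingResult(
        model=model,
        threshold=thr.threshold,
        selection_f1=thr.f1,
        heldout_f1=float(m.f1),
        heldout_accuracy=float(m.accuracy),
        final_loss=history[-1],
        history=history,
        n_pixels=int(truth.size),
    )


@dataclass
class DecayRecoveryResult:
    true_percent: list[float]
    est_percent: list[float]
    rho: float
    p_value: float
    n_logs: int


def decay_recovery_benchmark(
    model,
    threshold: float,
    seed: int = 1,
    n_logs: int = 20,
    smooth_sigma: float = 1.0,
) -> DecayRecoveryResult:
    """Per-log decay-fraction recovery across logs spanning ~5-40% decay.

    Renders ``n_logs`` phantoms with increasing decay load, predicts decay
    probability with the given trained model, quantifies the relative decay
    volume using the phantom's own wood and crack masks, and rank-correlates
    estimate against truth.
    """
    rng = np.random.default_rng(seed)
    truths, ests = [], []
    for i in range(n_logs):
        spec = replace(
            _DECAY_GEOMETRY,
            length_slices=16,
            radius_mm=24.0,
            decay_patch_count=1 + (2 * i) // n_logs,
            decay_radius_mm=(4.0, 6.0 + 6.0 * i / n_logs),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, lab = generate_phantom(spec)
        norm = normalize(vol)
        truth = true_volume_summary(lab)
        prob = predict_volume(model, norm)
        from .decay import smooth_longitudinal

        if smooth_sigma > 0:
            prob = smooth_longitudinal(prob, smooth_sigma)
        wood = lab.mask(Label.WOOD, Label.DECAY)
        crack = lab.mask(Label.CRACK)
        ests.append(quantify_decay(prob, threshold, wood, crack))
        truths.append(truth.decay_percent)
    corr = spearman(truths, ests)
    return DecayRecoveryResult(
        true_percent=truths, est_percent=ests, rho=corr.rho, p_value=corr.p_value,
        n_logs=n_logs,
    )


@dataclass
class GuildContrastResult:
    mean_est_total: dict[str, float]  # treatment -> mean estimated tunnel %
    mean_est_bark: dict[str, float]
    mean_est_wood: dict[str, float]
    logs_per_treatment: int


def guild_contrast_benchmark(seed: int = 1, logs_per_treatment: int = 4) -> GuildContrastResult:
    """Estimated tunnel volume per beetle guild on rendered experiment logs.

    Renders a subset of the simulated mesocosm experiment (shared crack
    load, guild-specific gallery effects) and runs the tunnel pipeline on
    each log. Wood-borers should show the largest excavated volume and the
    bark-beetle signal should sit in the bark compartment.
    """
    geometry = replace(
        BENCH_GEOMETRY,
        length_slices=30,
        radius_mm=25.0,
        bark_thickness_mm=3.5,
        crack_count=3,
        tunnel_length_mm=(15.0, 35.0),
    )
    exp = simulate_experiment(
        design=TreatmentDesign(logs_per_mesocosm=1),
        effects=ExperimentEffects(decay_percent_mean=0.0),
        seed=seed,
        geometry=geometry,
    )
    total: dict[str, list[float]] = {}
    bark: dict[str, list[float]] = {}
    wood: dict[str, list[float]] = {}
    for treatment in ("control", "bark_beetles", "wood_borers"):
        rows = exp.logs[exp.logs.treatment == treatment].head(logs_per_treatment)
        for log_id in rows.log_id:
            vol, _ = exp.render_log(log_id)
            seg = segment_log(normalize(vol))
            total.setdefault(treatment, []).append(seg.summary.tunnel_total_percent)
            bark.setdefault(treatment, []).append(seg.summary.tunnel_bark_percent)
            wood.setdefault(treatment, []).append(seg.summary.tunnel_wood_percent)
    return GuildContrastResult(
        mean_est_total={k: float(np.mean(v)) for k, v in total.items()},
        mean_est_bark={k: float(np.mean(v)) for k, v in bark.items()},
        mean_est_wood={k: float(np.mean(v)) for k, v in wood.items()},
        logs_per_treatment=logs_per_treatment,
    )
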