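"""End-to-end reproducible grip-strength experiment.

Runs the full pipeline at desk scale: generate labeled Hall windows and
ramp grip trials at the three wrist angles, train the angle CNN on a
stratified 4:1 split, fit per-angle Voigt parameters on the processed
training trials, estimate force on held-out trials with classifier-gated
parameters, and summarize accuracy, per-angle RMSE and the
force-deformation correlation.

All randomness flows from one top-level seed split into named sub-seeds
(window generation, split, training, trials) for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import preprocess, synth
from .angle_cnn import AngleCNNClassifier, evaluate_classifier
from .evaluate import EvalSummary, pearson_correlation, summarize_experiment
from .voigt import ANGLES, VoigtModel, estimate_derivative, estimate_grip

__all__ = ["ExperimentResult", "run_experiment", "reproduce"]


@dataclass
class ExperimentResult:
    summary: EvalSummary
    angle_accuracy_pct: float
    force_deformation_r: float
    classifier: AngleCNNClassifier
    params_bank: dict
    traces: dict

    def headline(self) -> dict:
        return {
            "angle_accuracy_pct": self.angle_accuracy_pct,
            "rmse_mean_N": self.summary.rmse_mean,
            "rmse_per_angle_N": {str(a): v for a, v in
                                 sorted(self.summary.rmse_per_angle.items())},
            "force_deformation_r": self.force_deformation_r,
        }


def _sub_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2 ** 31 for s in ss.generate_state(k)]


def _process_trial(trial: synth.GripTrial, maf_window: int = 6):
    """MAF-filter the measured voltages and estimate their derivative.

    The derivative uses a widened symmetric central-difference stencil
    (half-width 3): differentiation amplifies the ADC quantization steps,
    and the wide stencil attenuates them with no phase lag.  Must match
    the processing inside ``estimate_grip``.
    """
    dt = float(trial.t[1] - trial.t[0])
    Xf = preprocess.moving_average_filter(trial.volts_meas, w=maf_window)
    return Xf, estimate_derivative(Xf, dt, half_width=3)


def fit_params_bank(train_trials: dict[int, list[synth.GripTrial]],
                    maf_window: int = 6) -> dict:
    """Per-angle least-squares Voigt fits on pipeline-processed trials."""
    bank = {}
    for angle in ANGLES:
        X, Xd, y = [], [], []
        for trial in train_trials[angle]:
            Xf, Xdot = _process_trial(trial, maf_window)
            X.append(Xf)
            Xd.append(Xdot)
            y.append(trial.force_meas)
        model = VoigtModel(angle=angle).fit(np.vstack(X), np.concatenate(y),
                                            Xdot=np.vstack(Xd))
        bank[angle] = model.params_
    return bank


def run_experiment(seed: int = 42, cfg: synth.SynthConfig | None = None,
                   windows_per_angle: int = 333, n_train_trials: int = 4,
                   n_test_trials: int = 2,
                   cnn_kwargs: dict | None = None) -> ExperimentResult:
    cfg = cfg or synth.SynthConfig(seed=seed)
    seed_ds, seed_split, seed_train, seed_trial = _sub_seeds(seed, 4)

    # --- wrist-angle classifier on the Hall-window dataset
    windows = synth.make_angle_dataset(cfg, windows_per_angle,
                                       rng_seed=seed_ds)
    train_w, test_w = preprocess.split_dataset(windows, test_fraction=0.2,
                                               rng_seed=seed_split)
    Xtr, ytr = preprocess.windows_to_matrix(train_w)
    clf = AngleCNNClassifier(random_state=seed_train,
                             **(cnn_kwargs or {})).fit(Xtr, ytr)
    confusion, accuracy = evaluate_classifier(clf, test_w)

    # --- per-angle grip trials: fit on train, estimate on held-out
    trial_ss = np.random.SeedSequence(seed_trial)
    n_per_angle = n_train_trials + n_test_trials
    train_trials, test_trials = {}, {}
    for angle, sub in zip(ANGLES, trial_ss.spawn(3)):
        trials = [synth.generate_grip_trial(angle, cfg, rng_seed=s)
                  for s in sub.spawn(n_per_angle)]
        train_trials[angle] = trials[:n_train_trials]
        test_trials[angle] = trials[n_train_trials:]
    bank = fit_params_bank(train_trials)

    traces = {}
    for angle in ANGLES:
        traces[angle] = [
            estimate_grip(trial.to_frame(), clf, bank,
                          sampling_rate=cfg.sampling_rate)
            for trial in test_trials[angle]]

    # --- force vs mean filtered deformation correlation, one trial/angle
    corrs = []
    for angle in ANGLES:
        trial = test_trials[angle][0]
        Xf, _ = _process_trial(trial)
        corrs.append(pearson_correlation(trial.force_meas, Xf.mean(axis=1)))

    summary = summarize_experiment(traces, confusion=confusion,
                                   angle_accuracy=accuracy)
    return ExperimentResult(summary=summary,
                            angle_accuracy_pct=100.0 * accuracy,
                            force_deformation_r=float(np.mean(corrs)),
                            classifier=clf, params_bank=bank, traces=traces)


def reproduce(seed: int = 42, out_dir=None, make_plots: bool = True,
              **kwargs) -> ExperimentResult:
    """Run the full experiment and optionally write its artifacts."""
    result = run_experiment(seed=seed, **kwargs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.summary.to_json(out / "summary.json")
        with open(out / "headline.json", "w") as fh:
            json.dump(result.headline(), fh, indent=1, sort_keys=True)
        result.summary.confusion.to_frame().to_csv(out / "confusion.csv")
        from .voigt import save_params_bank
        save_params_bank(result.params_bank, out / "voigt_params.json")
        for angle, trs in result.traces.items():
            for i, tr in enumerate(trs):
                tr.to_frame().to_csv(out / f"trace_{angle}_{i}.csv",
                                     index=False)
        if make_plots:
            _write_plots(result, out)
    return result


def _write_plots(result: ExperimentResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3), sharey=True)
    for ax, angle in zip(axes, ANGLES):
        tr = result.traces[angle][0]
        ax.plot(tr.t, tr.Fm, label="measured", lw=0.8)
        ax.plot(tr.t, tr.Fp, label="estimated", lw=0.8)
        ax.set_title(f"{angle} deg")
        ax.set_xlabel("t (s)")
    axes[0].set_ylabel("grip force (N)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "grip_traces.png", dpi=120)
    plt.close(fig)

    cm = result.summary.confusion
    fig, ax = plt.subplots(figsize=(3.5, 3))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(3), cm.classes)
    ax.set_yticks(range(3), cm.classes)
    ax.set_xlabel("predicted angle")
    ax.set_ylabel("true angle")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, cm.counts[i, j], ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out / "confusion.png", dpi=120)
    plt.close(fig)
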