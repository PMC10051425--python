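"""Synthetic coincident-study generator: paired scripted / in-the-wild datasets.

Real lab-to-field context datasets are private, so this module synthesizes a
stand-in with the structural properties that matter to domain adaptation:

* two domains with a shared label space: a clean-labeled *source* (scripted)
  and a *target* (in-the-wild) whose labels can be noisy and whose marginal
  signal distribution is shifted;
* multi-label windows: one activity plus exactly one prioception (on-body
  phone placement) per window;
* activity-dependent waveforms (periodic bursts for locomotion, low-variance
  wander for sedentary states) on a 3-sensor x 3-axis x T grid;
* a per-prioception fixed linear transform (rotation + gain + bias) modelling
  placement diversity, and an additional *domain* transform scaled by
  ``shift_magnitude`` modelling lab-to-field covariate shift.  Labels are
  never changed by the shift, so the class-conditional distribution is
  preserved while the marginal moves.

Everything is deterministic given ``(config.seed, domain)``.
"""

from __future__ import annotations

import numpy as np

from .config import ACTIVITY_LABELS, PRIOCEPTION_LABELS, GeneratorConfig
from .datasets import DomainDataset, DomainSample

AUX_NAMES: tuple[str, ...] = (
    "speed_estimate", "screen_unlocked", "charging", "ringer_silent", "wifi_connected")

# kind: fundamental frequency (Hz), base amplitude, noise sd, typical speed (m/s)
_ACTIVITY_SIGNALS: dict[str, tuple[float, float, float, float]] = {
    "walking":          (2.0, 1.00, 0.15, 1.4),
    "jogging":          (2.7, 2.20, 0.25, 2.8),
    "running":          (3.2, 3.00, 0.30, 3.7),
    "stairs_up":        (1.7, 1.40, 0.20, 0.5),
    "stairs_down":      (1.9, 1.60, 0.22, 0.6),
    "typing":           (8.0, 0.15, 0.08, 0.0),
    "talking_on_phone": (0.5, 0.30, 0.10, 0.0),
    "bathroom":         (1.0, 0.50, 0.15, 0.1),
    "standing":         (0.0, 0.08, 0.05, 0.0),
    "sitting":          (0.0, 0.05, 0.03, 0.0),
    "lying_down":       (0.0, 0.03, 0.02, 0.0),
    "sleeping":         (0.0, 0.02, 0.01, 0.0),
}

# probability that each phone-state flag is on, per activity kind
_FLAG_TABLE = {
    "typing": (0.95, 0.15, 0.3, 0.7),
    "talking_on_phone": (0.9, 0.1, 0.1, 0.5),
    "sleeping": (0.02, 0.7, 0.8, 0.8),
    "_default": (0.2, 0.15, 0.3, 0.6),
}

# per-axis amplitude profile of each sensor relative to the activity amplitude
_SENSOR_AXIS_AMP = np.array([
    [1.00, 0.60, 0.80],   # accelerometer (m/s^2)
    [0.45, 0.55, 0.30],   # gyroscope (rad/s)
    [0.06, 0.08, 0.05],   # magnetometer (uT, motion-induced)
])
_SENSOR_NOISE_SCALE = np.array([1.0, 0.5, 0.3])
_GRAVITY = 9.81
_MAG_FIELD = np.array([22.0, 5.0, -14.0])  # ambient geomagnetic vector, uT

# fixed per-prioception transforms: (rotation axis, angle rad, per-axis gain, bias)
_PRIOCEPTION_TRANSFORMS: dict[str, tuple[np.ndarray, float, np.ndarray, np.ndarray]] = {
    "phone_in_hand":   (np.array([0.0, 0.0, 1.0]), 0.15,
                        np.array([1.00, 1.00, 1.00]), np.array([0.00, 0.00, 0.00])),
    "phone_in_pocket": (np.array([1.0, 0.3, 0.0]), 0.90,
                        np.array([1.15, 0.90, 1.05]), np.array([0.15, -0.10, 0.05])),
    "phone_in_bag":    (np.array([0.2, 1.0, 0.5]), 1.50,
                        np.array([0.85, 1.10, 0.95]), np.array([-0.10, 0.20, 0.10])),
}


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return np.eye(3)
    x, y, z = axis / norm
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _apply_linear(raw: np.ndarray, rot: np.ndarray, gain: np.ndarray,
                  bias: np.ndarray) -> np.ndarray:
    """Apply rotation + per-axis gain + bias to every sensor of raw [3,3,T].

    ``bias`` is either per-axis [3] (shared by sensors) or per-sensor-axis
    [3, 3].
    """
    out = np.einsum("ij,sjt->sit", rot, raw)
    out = out * gain[None, :, None]
    bias = np.asarray(bias)
    if bias.ndim == 1:
        out = out + bias[None, :, None]
    else:
        out = out + bias[:, :, None]
    return out


# per-sensor scales of the domain-shift bias and noise-floor components,
# relative to typical accel / gyro / magnetometer signal levels
_SHIFT_BIAS_SCALE = np.array([0.6, 0.25, 3.0])
_SHIFT_NOISE_SCALE = np.array([0.25, 0.12, 0.8])


def _draw_shift_params(rng: np.random.Generator, magnitude: float):
    """Device/person-specific lab-to-field transform, linear in ``magnitude``.

    Calibrated so magnitude 1 produces a substantial covariate shift: sensor
    re-orientation of tens of degrees, per-axis gain changes of tens of
    percent (device diversity), per-sensor offsets and a changed noise floor.
    """
    axis = rng.standard_normal(3)
    angle = magnitude * rng.normal(0.0, 0.6)
    gain = np.exp(magnitude * rng.normal(0.0, 0.25, size=3))
    bias = magnitude * rng.normal(0.0, 1.0, size=(3, 3)) * _SHIFT_BIAS_SCALE[:, None]
    return _rotation_matrix(axis, angle), gain, bias


def apply_domain_shift(sample: DomainSample, shift_magnitude: float,
                       rng: np.random.Generator) -> DomainSample:
    """Perturb a window's raw signal by a random linear domain transform.

    Rotation angle, per-axis log-gain and bias all scale linearly with
    ``shift_magnitude``; labels and auxiliary scalars are untouched, so only
    the marginal input distribution moves (covariate shift).
    """
    if shift_magnitude < 0:
        raise ValueError("shift_magnitude must be non-negative")
    if shift_magnitude == 0:
        return DomainSample(sample.raw.copy(), sample.aux.copy(),
                            None if sample.labels is None else sample.labels.copy(),
                            sample.subject_id, sample.domain)
    rot, gain, bias = _draw_shift_params(rng, shift_magnitude)
    raw = _apply_linear(sample.raw, rot, gain, bias)
    return DomainSample(raw, sample.aux.copy(),
                        None if sample.labels is None else sample.labels.copy(),
                        sample.subject_id, sample.domain)


def flip_labels(labels: np.ndarray, rate: float, rng: np.random.Generator,
                flippable: np.ndarray | None = None) -> np.ndarray:
    """Flip each activity bit independently with probability ``rate``.

    ``flippable`` is a boolean mask over label positions; prioception bits
    are excluded by the generator so the one-hot placement constraint holds
    even for noisy labels.  Works on a single vector or an [N, L] matrix.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("flip rate must lie in [0, 1]")
    labels = np.asarray(labels)
    out = labels.copy()
    flips = rng.random(labels.shape) < rate
    if flippable is not None:
        flips = flips & np.asarray(flippable, dtype=bool)
    out[flips] = 1 - out[flips]
    return out


def _synth_window(kind: str, T: int, fs: float, rng: np.random.Generator,
                  amp_scale: float) -> np.ndarray:
    """Raw [3 sensors, 3 axes, T] window for one activity, pre-transform."""
    f0, amp, noise_sd, _speed = _ACTIVITY_SIGNALS[kind]
    amp = amp * amp_scale
    t = np.arange(T) / fs
    raw = np.empty((3, 3, T))
    if f0 > 0:
        envelope = 1.0 + 0.25 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    else:
        envelope = np.ones(T)
    for s in range(3):
        for ax in range(3):
            a = amp * _SENSOR_AXIS_AMP[s, ax]
            if f0 > 0:
                phase = rng.uniform(0, 2 * np.pi)
                sig = a * (np.sin(2 * np.pi * f0 * t + phase)
                           + 0.35 * np.sin(2 * np.pi * 2 * f0 * t + 1.7 * phase))
                sig = sig * envelope
            else:
                # slow postural wander for sedentary states
                fr = rng.uniform(0.05, 0.3)
                sig = a * np.sin(2 * np.pi * fr * t + rng.uniform(0, 2 * np.pi))
            raw[s, ax] = sig
    raw += rng.standard_normal((3, 3, T)) * (noise_sd * _SENSOR_NOISE_SCALE)[:, None, None]
    raw[0, 2] += _GRAVITY                     # gravity along device z before rotation
    raw[2] += _MAG_FIELD[:, None]             # ambient magnetic field
    return raw


def _aux_scalars(kind: str, rng: np.random.Generator) -> np.ndarray:
    speed = max(0.0, _ACTIVITY_SIGNALS[kind][3] + rng.normal(0, 0.15))
    flags = _FLAG_TABLE.get(kind, _FLAG_TABLE["_default"])
    bits = (rng.random(4) < np.asarray(flags)).astype(float)
    return np.concatenate([[speed], bits])


def _categorical(priors: np.ndarray) -> np.ndarray:
    total = priors.sum()
    if total <= 0:
        raise ValueError("label priors must have positive mass")
    return priors / total


def generate_dataset(config: GeneratorConfig, domain: str, *,
                     identity_transforms: bool = False) -> DomainDataset:
    """Generate one domain of the simulated coincident study.

    Each window: draw (activity, prioception) from the domain's priors,
    synthesize the activity waveform, apply the prioception transform, then
    (target domain only) the subject's domain-shift transform scaled by
    ``config.shift_magnitude``, and attach activity-consistent aux scalars.
    ``identity_transforms=True`` skips both transforms, exposing the shared
    class-conditional core for testing.
    """
    if domain not in ("source", "target"):
        raise ValueError("domain must be 'source' or 'target'")
    dom_idx = 0 if domain == "source" else 1
    n = config.n_source if domain == "source" else config.n_target
    if n <= 0:
        raise ValueError("sample count must be positive")
    rng = np.random.default_rng([config.seed % (2**31), dom_idx])

    labels = config.label_names
    act_names = config.activity_names
    prio_names = config.prioception_names
    act_idx = [labels.index(a) for a in act_names]
    prio_idx = [labels.index(p) for p in prio_names]
    priors = np.asarray(config.label_priors_source if domain == "source"
                        else config.label_priors_target, dtype=float)
    p_act = _categorical(priors[act_idx])
    p_prio = _categorical(priors[prio_idx])

    T = config.window_samples
    n_subj = config.n_subjects_per_domain
    subj_offset = dom_idx * n_subj  # distinct people in the two studies

    # per-subject traits: amplitude scale, and (target only) the domain shift
    amp_scales = np.exp(rng.normal(0.0, 0.08, size=n_subj))
    shift_params = []
    noise_floors = []
    for _ in range(n_subj):
        if domain == "target" and config.shift_magnitude > 0 and not identity_transforms:
            shift_params.append(_draw_shift_params(rng, config.shift_magnitude))
            noise_floors.append(config.shift_magnitude * abs(rng.normal(0.0, 0.5))
                                * _SHIFT_NOISE_SCALE)
        else:
            shift_params.append(None)
            noise_floors.append(None)

    subjects = rng.integers(0, n_subj, size=n)
    acts = rng.choice(len(act_names), size=n, p=p_act)
    prios = rng.choice(len(prio_names), size=n, p=p_prio)

    raw = np.empty((n, 3, 3, T))
    aux = np.empty((n, len(AUX_NAMES)))
    lab = np.zeros((n, len(labels)), dtype=np.int8)
    for i in range(n):
        kind = act_names[acts[i]]
        window = _synth_window(kind, T, config.sample_rate, rng, amp_scales[subjects[i]])
        if not identity_transforms:
            axis, angle, gain, bias = _PRIOCEPTION_TRANSFORMS[prio_names[prios[i]]]
            window = _apply_linear(window, _rotation_matrix(axis, angle), gain, bias)
            sp = shift_params[subjects[i]]
            if sp is not None:
                window = _apply_linear(window, *sp)
                nf = noise_floors[subjects[i]]
                window = window + rng.standard_normal((3, 3, T)) * nf[:, None, None]
        raw[i] = window
        aux[i] = _aux_scalars(kind, rng)
        lab[i, act_idx[acts[i]]] = 1
        lab[i, prio_idx[prios[i]]] = 1

    if domain == "target" and config.target_label_noise > 0:
        flippable = np.zeros(len(labels), dtype=bool)
        flippable[act_idx] = True
        lab = flip_labels(lab, config.target_label_noise, rng,
                          flippable=np.broadcast_to(flippable, lab.shape))

    return DomainDataset(
        raw=raw, aux=aux, subject_ids=subjects + subj_offset, domain=domain,
        label_names=list(labels), _labels=lab)
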