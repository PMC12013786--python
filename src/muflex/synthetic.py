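"""Synthetic spike-train and toy-EMG generators with known ground truth.

These generators emulate the statistical structure assumed by the analysis
chain — populations of motor units whose smoothed rates are driven by a small
number of band-limited (<= 2.5 Hz) latent signals mixed homogeneously or
heterogeneously, plus independent noise — so every stage is testable without
the spiking simulator or any external data.

Spikes are drawn from a time-rescaled gamma-renewal process (shape 16, ISI
CoV 0.25), matching the firing regularity of voluntary motor units (ISI CoV
roughly 0.1-0.3) rather than the much noisier Poisson process.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spiketrain import PopulationRecording, SpikeTrain, write_spike_csv

__all__ = [
    "LatentPopulationSpec",
    "ToyEMGSpec",
    "lowpass_gaussian",
    "latent_population",
    "toy_emg",
    "write_fixtures",
]

GAMMA_SHAPE = 16.0  # renewal regularity; ISI CoV = 1/sqrt(shape) = 0.25


@dataclass(frozen=True)
class LatentPopulationSpec:
    """Recipe for a latent-driven motor-unit population.

    Defaults mirror the scale of the experimental recordings this package
    analyses: ~30 concurrently active units, 80 s of data (four 20 s plateaus
    worth), base rate 12 pps modulated by <= 2.5 Hz latents.
    """

    n_units: int = 30
    duration: float = 80.0
    k_true: int = 3
    mixing: str = "heterogeneous"  # or "homogeneous"
    base_rate: float = 12.0
    depth: float = 0.2
    noise_fraction: float = 0.1
    seed: int = 0
    fs: float = 2048.0

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.mixing not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown mixing {self.mixing!r}")


@dataclass(frozen=True)
class ToyEMGSpec:
    """Recipe for toy multichannel EMG built from known MUAP templates."""

    n_rows: int = 12          # differential rows
    n_cols: int = 5
    fs: float = 2048.0
    duration: float = 10.0
    template_dur: float = 0.015
    amplitude: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0


def lowpass_gaussian(
    n_samples: int,
    fs: float,
    cutoff: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Standardized low-pass-filtered Gaussian noise, shape (n_series, n).

    Band-limiting is done in the frequency domain (hard cutoff), which keeps
    the series exactly Gaussian and free of filter edge transients.
    """
    x = rng.standard_normal((n_series, n_samples))
    nyq = fs / 2.0
    if cutoff < nyq:
        spec = np.fft.rfft(x, axis=1)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        spec[:, freqs > cutoff] = 0.0
        x = np.fft.irfft(spec, n=n_samples, axis=1)
    out = x - x.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _softmax_weights(n: int, k: int, rng: np.random.Generator, temperature: float = 0.1) -> np.ndarray:
    """Heterogeneous mixing rows: softmax(T=0.1) of uniform(0,1) draws."""
    u = rng.uniform(0.0, 1.0, size=(n, k))
    z = u / temperature
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _gamma_renewal_times(
    rate: np.ndarray, fs: float, rng: np.random.Generator, shape: float = GAMMA_SHAPE
) -> np.ndarray:
    """Inhomogeneous gamma-renewal spike times by time rescaling.

    In rescaled (operational) time ``L(t) = integral of rate`` the process is
    a stationary renewal process with Gamma(shape, 1/shape) ISIs (unit mean),
    so spike counts track the rate integral while ISIs stay regular.
    """
    cum = np.concatenate(([0.0], np.cumsum(rate) / fs))  # L at sample edges
    total = cum[-1]
    # draw rescaled-time spike positions until total mass is exhausted
    n_guess = int(total + 10 * np.sqrt(total + 1)) + 10
    isis = rng.gamma(shape, 1.0 / shape, size=n_guess)
    s = np.cumsum(isis)
    while s.size and s[-1] < total:
        more = rng.gamma(shape, 1.0 / shape, size=n_guess)
        s = np.concatenate([s, s[-1] + np.cumsum(more)])
    s = s[s < total]
    # invert L by linear interpolation on the sample grid
    t_edges = np.arange(cum.size) / fs
    return np.interp(s, cum, t_edges)


def latent_population(
    spec: LatentPopulationSpec,
) -> tuple[PopulationRecording, dict]:
    """Generate a motor-unit population driven by band-limited latents.

    Per-unit rate is ``base_rate * (1 + depth * s_u(t))`` where ``s_u`` mixes
    the k latent signals (homogeneous: equal weights; heterogeneous: softmax
    weights) with independent noise in proportion
    ``(1 - noise_fraction) : noise_fraction`` (variance split).

    Returns the recording plus a ground-truth dict with ``latents`` (k x n at
    ``truth_fs``), ``weights`` (units x k) and ``rates``.
    """
    rng = np.random.default_rng(spec.seed)
    gen_fs = 256.0  # rate-generation grid; plenty for <= 2.5 Hz structure
    n = int(round(spec.duration * gen_fs))
    latents = lowpass_gaussian(n, gen_fs, 2.5, rng, n_series=spec.k_true)
    # orthogonalize so "k latents" really spans k directions
    if spec.k_true > 1:
        q, _ = np.linalg.qr(latents.T)
        latents = (q * np.sqrt(n)).T  # re-standardize to unit variance

    if spec.mixing == "homogeneous":
        weights = np.full((spec.n_units, spec.k_true), 1.0 / spec.k_true)
    else:
        weights = _softmax_weights(spec.n_units, spec.k_true, rng)

    common = weights @ latents
    csd = common.std(axis=1, keepdims=True)
    csd[csd == 0] = 1.0
    common /= csd
    noise = lowpass_gaussian(n, gen_fs, 2.5, rng, n_series=spec.n_units)
    mix = np.sqrt(1.0 - spec.noise_fraction) * common + np.sqrt(spec.noise_fraction) * noise

    rates = spec.base_rate * (1.0 + spec.depth * mix)
    if rates.min() < 0:
        raise ValueError(
            "instantaneous rate went negative; use a smaller modulation depth"
        )

    trains = []
    for u in range(spec.n_units):
        times = _gamma_renewal_times(rates[u], gen_fs, rng)
        trains.append(SpikeTrain(f"su{u:03d}", times))
    pop = PopulationRecording(tuple(trains), duration=spec.duration, fs=spec.fs)
    truth = {
        "latents": latents,
        "weights": weights,
        "rates": rates,
        "truth_fs": gen_fs,
        "k_true": spec.k_true,
    }
    return pop, truth


def _muap_shape(n_samp: int) -> np.ndarray:
    """Biphasic template: Gaussian-windowed sine, unit peak-to-peak."""
    t = np.linspace(-1, 1, n_samp)
    w = np.exp(-(t ** 2) / 0.18) * np.sin(2 * np.pi * 1.5 * t)
    return w / np.ptp(w)


def toy_emg(
    spec: ToyEMGSpec, trains: list[SpikeTrain]
) -> tuple[np.ndarray, dict]:
    """Multichannel toy EMG: per-unit MUAP templates at firing times + noise.

    Each unit gets a biphasic template centred on a seeded channel with a
    Gaussian spatial footprint over the grid. Returns the (channels x samples)
    signal and ground truth (per-unit template stacks and centre channels).
    """
    rng = np.random.default_rng(spec.seed)
    n_ch = spec.n_rows * spec.n_cols
    n_samp = int(round(spec.duration * spec.fs))
    w = int(round(spec.template_dur * spec.fs))
    if w % 2 == 0:
        w += 1
    shape = _muap_shape(w)
    emg = rng.standard_normal((n_ch, n_samp)) * spec.noise_sd

    centers: dict[str, tuple[int, int]] = {}
    templates: dict[str, np.ndarray] = {}
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    for tr in trains:
        r0 = int(rng.integers(1, spec.n_rows - 1))
        c0 = int(rng.integers(1, spec.n_cols - 1))
        footprint = spec.amplitude * np.exp(
            -((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * 1.2 ** 2)
        )
        tpl = footprint.reshape(n_ch, 1) * shape[None, :]
        templates[tr.unit_id] = tpl.reshape(spec.n_rows, spec.n_cols, w)
        centers[tr.unit_id] = (r0, c0)
        half = w // 2
        for t in tr.times:
            i = int(round(t * spec.fs))
            a, b = i - half, i + half + 1
            if a < 0 or b > n_samp:
                continue  # clipped at the recording edge
            emg[:, a:b] += tpl
    truth = {"templates": templates, "centers": centers, "window_samples": w}
    return emg, truth


def write_fixtures(out_dir) -> list[Path]:
    """Write the seeded fixture set (CSV + JSON manifests); deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {}
    for name, spec in {
        "pop_k1": LatentPopulationSpec(k_true=1, mixing="homogeneous", seed=11,
                                       duration=40.0, n_units=20),
        "pop_k3": LatentPopulationSpec(k_true=3, mixing="heterogeneous", seed=12,
                                       duration=40.0, n_units=20),
    }.items():
        pop, truth = latent_population(spec)
        path = out / f"{name}.csv"
        write_spike_csv(list(pop.trains), path)
        written.append(path)
        manifest[name] = {
            "k_true": spec.k_true,
            "mixing": spec.mixing,
            "n_units": spec.n_units,
            "duration_s": spec.duration,
            "seed": spec.seed,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    # duplicate pair: one train plus a 2 ms-shifted copy with a few drops
    rng = np.random.default_rng(7)
    base = np.cumsum(rng.gamma(GAMMA_SHAPE, 1.0 / (GAMMA_SHAPE * 10.0), size=200))
    keep = rng.random(base.size) > 0.1
    dup = [
        SpikeTrain("dupA", base),
        SpikeTrain("dupB", base[keep] + 0.002),
    ]
    dup_path = out / "duplicate_pair.csv"
    write_spike_csv(dup, dup_path)
    written.append(dup_path)
    manifest["duplicate_pair"] = {
        "shift_s": 0.002,
        "expected_duplicates": True,
        "sha256": hashlib.sha256(dup_path.read_bytes()).hexdigest(),
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)
    return written
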