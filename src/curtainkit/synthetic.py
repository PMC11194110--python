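"""Seeded Monte-Carlo generators for every analysis stage.

Each generator emulates the statistical structure of a DNA-curtains
measurement — exponential dissociation and photobleaching under a framed
illumination schedule, Bernoulli labeling of an N-site array, staircase
photobleaching of intensity traces, static versus 1-D-diffusing
molecules on a ~48.5 kb substrate, and transcription trajectories with
pauses, early stops and snapbacks — and returns a machine-readable truth
record sufficient to score the downstream estimators.

All generators are deterministic under a fixed seed; one root seed is
split into per-purpose streams via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kymo_positions import DNASubstrate, Feature
from .model_survival import FrameSchedule, KineticParams, SpotDataset, effective_lambda
from .bleach_steps import IntensityTrace
from .tracking import Kymogram, Trajectory
from .transcription import TranscriptionTrace

__all__ = [
    "SpotSimConfig",
    "KymoSimConfig",
    "TranscriptionSimConfig",
    "DEFAULT_DELAYS",
    "make_default_substrate",
    "simulate_spot_disappearance",
    "simulate_intensity_trace",
    "simulate_kymogram",
    "simulate_brownian_trajectory",
    "simulate_transcription_cohort",
    "simulate_binding_positions",
    "five_delay_design",
]

#: measurement frame delays used throughout (s), at 100 ms illumination
DEFAULT_DELAYS = (1.0, 4.0, 10.0, 40.0, 60.0)

_SUBSTRATE_SEED = 1202          # fixed: the default substrate is a constant
_SUBSTRATE_LENGTH = 48_502      # bp, lambda-like
_CBS_MOTIF = "CCACCAGGGGGCGCTAGTGG"
_T7_PROMOTER = "TAATACGACTCACTATAG"
_CASSETTE_STARTS = (15_000, 28_000)   # 13 kbp apart; each inside one 40-bin
_SITE_SPACING = 129                   # bp, start-to-start within a cassette


def make_default_substrate(
    kind: str = "4x",
    include_promoters: bool = False,
    n_bins: int = 40,
) -> DNASubstrate:
    """Deterministic 48,502 bp lambda-like substrate.

    ``kind="4x"``: two cassettes of four CBSs (129 bp spacing) in opposite
    orientation, 13 kbp apart; ``kind="1x"``: a single CBS.  The sequence
    has a GC-leaning left arm (~45% AT) and an AT-rich right arm (~62%
    AT) so that both AT classes exist.  Optional T7 promoters sit 150 bp
    upstream of each cassette.
    """
    if kind not in ("4x", "1x"):
        raise ValueError(f"kind must be '4x' or '1x', got {kind!r}")
    rng = np.random.default_rng(_SUBSTRATE_SEED)
    n = _SUBSTRATE_LENGTH
    bases = np.array(list("ATGC"))
    p_at = np.where(np.arange(n) < 22_000, 0.45, 0.62)
    probs = np.column_stack([p_at / 2, p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2])
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    seq = bases[idx]

    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    motif_fwd = _CBS_MOTIF
    motif_rev = "".join(comp[b] for b in reversed(_CBS_MOTIF))
    features: list[Feature] = []

    cassettes = (
        [(_CASSETTE_STARTS[0], "+"), (_CASSETTE_STARTS[1], "-")]
        if kind == "4x"
        else [(_CASSETTE_STARTS[0], "+")]
    )
    n_sites = 4 if kind == "4x" else 1
    for start, strand in cassettes:
        motif = motif_fwd if strand == "+" else motif_rev
        for s in range(n_sites):
            a = start + s * _SITE_SPACING
            seq[a : a + len(motif)] = list(motif)
            features.append(Feature(a, a + len(motif), strand, "CBS"))
        if include_promoters:
            p = start - 150
            seq[p : p + len(_T7_PROMOTER)] = list(_T7_PROMOTER)
            features.append(Feature(p, p + len(_T7_PROMOTER), strand, "promoter"))

    return DNASubstrate(
        length=n,
        sequence="".join(seq),
        features=tuple(features),
        n_bins=n_bins,
        name=f"default-{kind}",
    )


# ---------------------------------------------------------------------------
# spot disappearance (dwell-time) generator
# ---------------------------------------------------------------------------


@dataclass
class SpotSimConfig:
    """Ground truth and conditions for one dwell-time measurement."""

    seed: int
    schedule: FrameSchedule
    n_spots: int = 300
    tau: float = 3000.0             # dissociation lifetime (s); 50 min headline
    tau_nu: float = 30.0            # bleach lifetime at 100% illumination (s)
    N: int = 4
    l: float = 0.52
    c: float = 0.0
    recording_end: float = 3600.0   # s; inf disables censoring
    truncation: str = "component"   # "component" (matches model) or "reject"
    discrete_exposure: bool = False
    construct_id: str = "construct"
    dna_id: str = "dna"
    measurement_id: str = "measurement"


def _labeled_counts(rng: np.random.Generator, n: int, N: int, l: float) -> np.ndarray:
    """Binomial(N, l) conditioned on >= 1, by inverse CDF."""
    if not (0 < l <= 1):
        raise ValueError(f"l must lie in (0, 1], got {l}")
    i = np.arange(0, N + 1)
    pmf = np.array([math.comb(N, k) * l**k * (1 - l) ** (N - k) for k in i])
    pmf[0] = 0.0
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").clip(1, N)


def _max_exp_conditioned(
    rng: np.random.Generator, counts: np.ndarray, lam: float, c: float
) -> np.ndarray:
    """Disappearance time of the last of ``i`` fluorophores, conditioned on
    survival past ``c`` per component (inverse transform of C_i)."""
    ci_c = (-np.expm1(-c / lam)) ** counts
    u = ci_c + rng.random(counts.size) * (1.0 - ci_c)
    return -lam * np.log1p(-np.power(u, 1.0 / counts))


def _discrete_exposure_times(
    rng: np.random.Generator,
    counts: np.ndarray,
    cfg: SpotSimConfig,
) -> np.ndarray:
    """Per-frame exposure mode: bleaching advances only during the
    illuminated slices; dissociation runs on the wall clock."""
    t_on, t_int = cfg.schedule.illumination_time, cfg.schedule.frame_interval
    out = np.empty(counts.size)
    for j, k in enumerate(counts):
        bleach_illum = rng.exponential(cfg.tau_nu, int(k)) if math.isfinite(cfg.tau_nu) else np.full(int(k), np.inf)
        full = np.floor(bleach_illum / t_on)
        bleach_wall = full * t_int + (bleach_illum - full * t_on)
        diss_wall = rng.exponential(cfg.tau, int(k)) if math.isfinite(cfg.tau) else np.full(int(k), np.inf)
        out[j] = np.max(np.minimum(bleach_wall, diss_wall))
    return out


def simulate_spot_disappearance(cfg: SpotSimConfig) -> tuple[SpotDataset, dict]:
    """Monte-Carlo spot disappearance for one measurement.

    Each spot carries ``i ~ Binomial(N, l) | i >= 1`` labeled molecules;
    each fluorophore vanishes after an exponential time with the
    effective mean ``lambda`` (dissociation + duty-cycle-diluted
    bleaching); the spot disappears with the last fluorophore.  Events
    before the cut-off ``c`` are excluded by per-component truncation
    (default) or by whole-spot rejection; spots alive at
    ``recording_end`` are right-censored.
    """
    rng = np.random.default_rng(cfg.seed)
    lam = effective_lambda(cfg.tau, cfg.tau_nu, cfg.schedule.r_init if cfg.schedule.frame_delay > 0 else 1.0)
    counts = _labeled_counts(rng, cfg.n_spots, cfg.N, cfg.l)
    if cfg.discrete_exposure:
        times = _discrete_exposure_times(rng, counts, cfg)
        if cfg.c > 0:
            keep = times > cfg.c
            counts, times = counts[keep], times[keep]
    elif cfg.truncation == "component":
        times = _max_exp_conditioned(rng, counts, lam, cfg.c)
    elif cfg.truncation == "reject":
        times = _max_exp_conditioned(rng, counts, lam, 0.0)
        while True:
            bad = times <= cfg.c
            if not bad.any():
                break
            counts[bad] = _labeled_counts(rng, int(bad.sum()), cfg.N, cfg.l)
            times[bad] = _max_exp_conditioned(rng, counts[bad], lam, 0.0)
    else:
        raise ValueError(f"unknown truncation mode {cfg.truncation!r}")

    censored = times >= cfg.recording_end
    times = np.minimum(times, cfg.recording_end)
    dataset = SpotDataset(
        disappearance_times=times,
        censored=censored,
        schedule=cfg.schedule,
        construct_id=cfg.construct_id,
        dna_id=cfg.dna_id,
        measurement_id=cfg.measurement_id,
        c=cfg.c,
    )
    truth = {
        "seed": int(cfg.seed),
        "tau": cfg.tau,
        "tau_nu": cfg.tau_nu,
        "r": cfg.schedule.r_init,
        "lambda": lam,
        "N": cfg.N,
        "l": cfg.l,
        "c": cfg.c,
        "recording_end": cfg.recording_end,
        "labeled_counts": counts.tolist(),
        "n_censored": int(censored.sum()),
    }
    return dataset, truth


def five_delay_design(
    seed: int,
    n_spots: int = 300,
    tau: float = 3000.0,
    tau_nu: float = 30.0,
    N: int = 4,
    l: float = 0.52,
    delays: tuple[float, ...] = DEFAULT_DELAYS,
    illumination: float = 0.1,
    recording_end: float = 3600.0,
    construct_id: str = "wt",
    dna_id: str = "4x",
) -> tuple[list[SpotDataset], dict]:
    """The standard multi-frame-delay dwell-time design: one measurement
    per frame delay, shared kinetic truth.  Defaults are the study
    conditions (five delays at 100 ms illumination, 300 spots each,
    N = 4, l = 0.52, tau = 3000 s)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(delays)) % (2**31)
    datasets, truths = [], {}
    for d, s in zip(delays, seeds):
        cfg = SpotSimConfig(
            seed=int(s),
            schedule=FrameSchedule(illumination, d),
            n_spots=n_spots,
            tau=tau,
            tau_nu=tau_nu,
            N=N,
            l=l,
            recording_end=recording_end,
            construct_id=construct_id,
            dna_id=dna_id,
            measurement_id=f"{construct_id}-delay{d:g}",
        )
        ds, tr = simulate_spot_disappearance(cfg)
        datasets.append(ds)
        truths[ds.measurement_id] = tr
    truth = {
        "tau": tau,
        "tau_nu": tau_nu,
        "N": N,
        "l": l,
        "delays": list(delays),
        "per_measurement": truths,
    }
    return datasets, truth


# ---------------------------------------------------------------------------
# intensity staircases
# ---------------------------------------------------------------------------


def simulate_intensity_trace(
    n_steps: int,
    snr: float,
    seed: int,
    n_frames: int = 2600,
    frame_interval: float = 0.1,
    step_amplitude: float = 1.0,
    amplitude_cv: float = 0.1,
    mean_gap_frames: float = 200.0,
    min_gap_frames: int = 5,
    baseline: float = 0.0,
    trace_id: str = "trace",
) -> tuple[IntensityTrace, dict]:
    """Monotone bleaching staircase with Gaussian noise at the given SNR
    (step amplitude over noise sigma).

    Inter-step waits are exponential with a ``min_gap_frames``
    resolvability floor (two bleaching events inside the same camera
    frame are physically a single observable step; the floor keeps the
    ground-truth count well defined).  Steps whose waiting time runs past
    the recording are not realized; the truth record reports the realized
    step frames and the detector is scored against those.
    """
    if n_steps < 0:
        raise ValueError(f"n_steps must be >= 0, got {n_steps}")
    rng = np.random.default_rng(seed)
    gaps = min_gap_frames + rng.exponential(mean_gap_frames, n_steps)
    step_frames = (30 + np.cumsum(gaps)).astype(int)
    step_frames = step_frames[step_frames < n_frames - 20]
    amps = step_amplitude * np.clip(
        1.0 + amplitude_cv * rng.standard_normal(n_steps), 0.3, None
    )
    level = baseline + amps.sum()
    y = np.full(n_frames, level)
    for k, f in enumerate(step_frames):
        y[f:] -= amps[k]
    sigma = 0.0 if math.isinf(snr) else step_amplitude / snr
    noisy = y + sigma * rng.standard_normal(n_frames)
    times = np.arange(n_frames) * frame_interval
    trace = IntensityTrace(
        times=times, intensities=noisy, frame_interval=frame_interval, trace_id=trace_id
    )
    truth = {
        "seed": int(seed),
        "n_steps_programmed": int(n_steps),
        "n_steps_realized": int(step_frames.size),
        "step_frames": step_frames.tolist(),
        "amplitudes": amps[: step_frames.size].tolist(),
        "sigma": sigma,
        "snr": snr,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# kymograms and trajectories
# ---------------------------------------------------------------------------


@dataclass
class KymoSimConfig:
    seed: int
    substrate: DNASubstrate | None = None
    n_px: int = 128
    n_frames: int = 300
    frame_interval: float = 1.0     # s
    n_static: int = 2               # placed at CBS cassette centres
    n_diffusing: int = 1
    D: float = 1.0e4                # bp^2/s
    tau_static: float = math.inf
    tau_diffusing: float = math.inf
    amplitude: float = 150.0
    background: float = 20.0
    psf_sigma_px: float = 1.3


def simulate_brownian_trajectory(
    seed: int,
    D: float,
    n_frames: int = 500,
    frame_interval: float = 1.0,
    x0: float = 24_000.0,
    loc_sigma_bp: float = 0.0,
    bounds: tuple[float, float] | None = None,
) -> Trajectory:
    """Pure 1-D Brownian trajectory (optionally with localization noise
    and reflecting bounds); truth D is the argument."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * D * frame_interval), n_frames - 1)
    x = x0 + np.concatenate([[0.0], np.cumsum(steps)])
    if bounds is not None:
        lo, hi = bounds
        span = hi - lo
        x = lo + np.abs((x - lo) % (2 * span) - span)
    if loc_sigma_bp > 0:
        x = x + rng.normal(0.0, loc_sigma_bp, n_frames)
    return Trajectory(
        times=np.arange(n_frames) * frame_interval, positions=x, traj_id=int(seed)
    )


def simulate_kymogram(cfg: KymoSimConfig) -> tuple[Kymogram, list[dict]]:
    """Synthetic kymogram: static molecules parked on the CBS cassettes,
    diffusing molecules performing reflected Brownian motion, Gaussian
    point-spread in position and Poisson noise on top of a flat
    background.  Returns the image and per-molecule truth trajectories
    (frames, bp positions, kind)."""
    rng = np.random.default_rng(cfg.seed)
    sub = cfg.substrate or make_default_substrate()
    L = sub.length
    px_size = L / cfg.n_px
    truth: list[dict] = []

    cbs = sub.cbs_features()
    cassette_centres = []
    if cbs:
        starts = sorted(f.start for f in cbs)
        groups: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - groups[-1][-1] < 2000:
                groups[-1].append(s)
            else:
                groups.append([s])
        cassette_centres = [float(np.mean(g)) for g in groups]

    molecules = []
    for k in range(cfg.n_static):
        pos = (
            cassette_centres[k % len(cassette_centres)]
            if cassette_centres
            else rng.uniform(0.2 * L, 0.8 * L)
        )
        life = rng.exponential(cfg.tau_static) if math.isfinite(cfg.tau_static) else math.inf
        molecules.append({"kind": "static", "x": pos, "life": life})
    for _ in range(cfg.n_diffusing):
        pos = rng.uniform(0.15 * L, 0.85 * L)
        life = rng.exponential(cfg.tau_diffusing) if math.isfinite(cfg.tau_diffusing) else math.inf
        molecules.append({"kind": "diffusing", "x": pos, "life": life})

    img = np.zeros((cfg.n_px, cfg.n_frames))
    px_axis = np.arange(cfg.n_px)
    sigma_step = math.sqrt(2.0 * cfg.D * cfg.frame_interval)
    for m in molecules:
        frames, xs = [], []
        x = m["x"]
        for f in range(cfg.n_frames):
            t = f * cfg.frame_interval
            if t > m["life"]:
                break
            if m["kind"] == "diffusing" and f > 0:
                x = x + rng.normal(0.0, sigma_step)
                x = abs(x % (2 * L) - L) if (x < 0 or x > L) else x
            frames.append(f)
            xs.append(x)
            mu_px = x / px_size
            img[:, f] += cfg.amplitude * np.exp(
                -0.5 * ((px_axis - mu_px) / cfg.psf_sigma_px) ** 2
            )
        truth.append(
            {
                "kind": m["kind"],
                "frames": frames,
                "positions_bp": xs,
                "times_s": [f * cfg.frame_interval for f in frames],
            }
        )
    noisy = rng.poisson(img + cfg.background).astype(float)
    kymo = Kymogram(
        intensity=noisy, frame_interval=cfg.frame_interval, pixel_size=px_size
    )
    return kymo, truth


# ---------------------------------------------------------------------------
# transcription cohorts
# ---------------------------------------------------------------------------


@dataclass
class TranscriptionSimConfig:
    seed: int
    n_traces: int = 200
    proportions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    # (continuous, early_stop, snapback)
    velocity_mean: float = 230.0    # bp/s, saturating-NTP T7 regime
    velocity_sd: float = 25.0
    frame_interval: float = 1.0
    duration: float = 150.0         # s
    noise_bp: float = 30.0
    pause_prob: float = 0.3
    pause_len_s: tuple[float, float] = (5.0, 15.0)


def simulate_transcription_cohort(
    cfg: TranscriptionSimConfig,
) -> tuple[list[TranscriptionTrace], dict]:
    """Cohort of polymerase traces with programmed class proportions.

    Early stops terminate permanently strictly below 10 kb with a trailing
    dwell of at least 40 s; snapbacks contain one single-interval upstream
    jump of at least 600 bp; continuous traces advance past 10 kb
    (optionally with sub-30 s pauses) and never stop permanently below it.
    """
    props = np.asarray(cfg.proportions, dtype=float)
    if np.any(props < 0) or not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"proportions must be non-negative and sum to 1, got {props}")
    rng = np.random.default_rng(cfg.seed)
    classes = rng.choice(
        ["continuous", "early_stop", "snapback"], size=cfg.n_traces, p=props
    )
    n_frames = int(cfg.duration / cfg.frame_interval)
    traces: list[TranscriptionTrace] = []
    truth_classes: list[str] = []
    truth_net: list[float] = []
    for k, cls in enumerate(classes):
        v = max(rng.normal(cfg.velocity_mean, cfg.velocity_sd), 120.0)
        onset = int(rng.integers(2, 6))
        pos = np.zeros(n_frames)
        t = np.arange(n_frames) * cfg.frame_interval
        x = 0.0
        pause_until = -1.0
        if cls == "continuous" and rng.random() < cfg.pause_prob:
            p0 = rng.uniform(20, cfg.duration - 60)
            pause_until = p0 + rng.uniform(*cfg.pause_len_s)
            pause_from = p0
        else:
            pause_from = math.inf
        stop_pos = rng.uniform(2000, 9000) if cls == "early_stop" else math.inf
        jump_frame = (
            int(rng.uniform(0.25, 0.5) * n_frames) if cls == "snapback" else -1
        )
        jump_size = rng.uniform(600, 2500) if cls == "snapback" else 0.0
        for f in range(1, n_frames):
            if f < onset:
                pos[f] = x
                continue
            if f == jump_frame:
                x = max(x - jump_size, 0.0)
            elif pause_from <= t[f] <= pause_until:
                pass
            elif x < stop_pos:
                x = min(x + v * cfg.frame_interval, stop_pos)
            pos[f] = x
        noisy = np.clip(pos + cfg.noise_bp * rng.standard_normal(n_frames), 0.0, None)
        traces.append(
            TranscriptionTrace(
                times=t,
                positions=noisy,
                trace_id=f"t7-{k}",
                dna_id=f"dna-{k}",
                end_reason="stall" if cls == "early_stop" else "recording_end",
            )
        )
        truth_classes.append(str(cls))
        truth_net.append(float((pos[-1] - pos[onset]) / (t[-1] - t[onset])))
    truth = {
        "seed": int(cfg.seed),
        "classes": truth_classes,
        "proportions": props.tolist(),
        "net_rates": truth_net,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# binding positions
# ---------------------------------------------------------------------------


def simulate_binding_positions(
    seed: int,
    n: int,
    fold: float,
    substrate: DNASubstrate | None = None,
    condition: str = "",
):
    """Binding positions with a programmed ``fold``-times higher density
    per bp inside CBS bins than outside (fold = 1: uniform; fold = 0: no
    CBS-bin positions)."""
    from .kymo_positions import PositionSet

    if fold < 0:
        raise ValueError(f"fold must be >= 0, got {fold}")
    rng = np.random.default_rng(seed)
    sub = substrate or make_default_substrate()
    mask = sub.cbs_bin_mask()
    edges = sub.bin_edges
    widths = np.diff(edges)
    w_cbs = widths[mask].sum()
    w_other = widths[~mask].sum()
    p_cbs = fold * w_cbs / (fold * w_cbs + w_other)
    in_cbs = rng.random(n) < p_cbs
    pos = np.empty(n)
    for flag, m in ((True, mask), (False, ~mask)):
        sel = in_cbs == flag
        k = int(sel.sum())
        if k == 0:
            continue
        bins = np.flatnonzero(m)
        probs = widths[bins] / widths[bins].sum()
        chosen = rng.choice(bins, size=k, p=probs)
        pos[sel] = edges[chosen] + rng.random(k) * widths[chosen]
    return PositionSet(positions=pos, condition=condition)
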