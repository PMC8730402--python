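"""Synthetic data with exact ground truth for every pipeline stage.

Every input the analysis consumes can be generated here: damped-cosine
expression courses on the in vivo sampling design (48 h at 2-h
intervals), forward-simulated pre/mature mRNA pairs under the
first-order processing model, toy genomes with block-structured reads,
speckle images in droplet ("nucleation") and network ("spinodal")
regimes, and exponential FRAP recoveries.  Each generator is
deterministic under its seed and returns the generating parameters as
ground truth, so recovery accuracy can be measured exactly without any
external dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .frap import DEFAULT_FRAME_INTERVAL_S, DEFAULT_N_FRAMES, FrapTrace
from .genomic import GeneModel, ReadAlignment
from .kinetics import ExpressionTimecourse
from .morphometry import contour_measure, sphericity
from .timeseries import TimeSeries

__all__ = [
    "ComponentSpec",
    "SimScenario",
    "SignalSpec",
    "TrueSpeckle",
    "SpeckleImage",
    "FrapTruth",
    "gen_damped_sinusoid",
    "gen_expression_timecourse",
    "gen_speckle_image",
    "gen_frap_trace",
    "gen_read_set",
    "default_gene_models",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Parameters of one damped cosine used by the generators."""

    amplitude: float
    period: float
    decay_per_sample: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.decay_per_sample < 0:
            raise ValueError("decay_per_sample must be non-negative")


@dataclass(frozen=True)
class SimScenario:
    """Sampling design of a simulated time course.

    The default mirrors a two-day in vivo design: samples every 2 h for
    48 h starting at 0, i.e. 24 samples.  ``noise_sd`` is interpreted by
    each generator (additive Gaussian for plain series, log2-scale
    multiplicative for expression data).
    """

    t0: float = 0.0
    dt: float = 2.0
    n_samples: int = 24
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass(frozen=True)
class SignalSpec:
    """A baseline plus damped-cosine components defining a signal."""

    components: tuple[ComponentSpec, ...] = ()
    baseline: float = 0.0


def _eval_components(
    components, baseline: float, times: np.ndarray, dt: float, t0: float
) -> np.ndarray:
    """Continuous damped-cosine sum; decay exponent counts samples from t0."""
    k = (times - t0) / dt
    out = np.full_like(times, float(baseline))
    for c in components:
        out += c.amplitude * c.decay_per_sample**k * np.cos(
            2.0 * np.pi * times / c.period + c.phase
        )
    return out


def gen_damped_sinusoid(
    components: list[ComponentSpec] | tuple[ComponentSpec, ...],
    scenario: SimScenario,
    baseline: float = 0.0,
) -> TimeSeries:
    """Sample a sum of damped cosines plus additive Gaussian noise."""
    times = scenario.times
    vals = _eval_components(components, baseline, times, scenario.dt, scenario.t0)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        vals = vals + rng.normal(0.0, scenario.noise_sd, size=vals.shape)
    return TimeSeries(times, vals)


# --------------------------------------------------------------------------
# expression kinetics
# --------------------------------------------------------------------------

#: internal RK4 step bound for the forward model, hours
_ODE_STEP_H = 0.01


def gen_expression_timecourse(
    kp_spec: SignalSpec,
    p_spec: SignalSpec,
    kd: float,
    scenario: SimScenario,
    gene_id: str = "gene",
    m0: float | None = None,
    return_fine: bool = False,
) -> tuple[ExpressionTimecourse, TimeSeries] | tuple[
    ExpressionTimecourse, TimeSeries, dict[str, np.ndarray]
]:
    """Forward-simulate dm/dt = k_p(t) p(t) - k_d m and sample it.

    k_p(t) and p(t) are damped-cosine signals; negative excursions are
    clipped at zero with a warning.  The ODE is integrated with a
    fixed-step classical Runge-Kutta scheme at a step <= 0.01 h, then
    subsampled onto the scenario grid.  ``scenario.noise_sd`` applies
    multiplicative log-normal noise (sd on the log2 scale) to the
    observed p and m — not to the returned ground-truth k_p.

    ``m0`` defaults to the steady state k_p(t0) p(t0) / k_d.

    Returns the (noisy) observed time course and the true k_p series on
    the scenario grid; with ``return_fine`` also the noiseless fine-grid
    arrays (``t``, ``p``, ``m``, ``kp``) for diagnostics.
    """
    if kd < 0:
        raise ValueError("kd must be non-negative")
    times = scenario.times
    t0, t_end = times[0], times[-1]
    n_fine = int(math.ceil((t_end - t0) / _ODE_STEP_H)) + 1
    fine_t = np.linspace(t0, t_end, n_fine)
    h = fine_t[1] - fine_t[0]

    def kp_of(t):
        return _eval_components(kp_spec.components, kp_spec.baseline, t, scenario.dt, scenario.t0)

    def p_of(t):
        return _eval_components(p_spec.components, p_spec.baseline, t, scenario.dt, scenario.t0)

    kp_fine = kp_of(fine_t)
    p_fine = p_of(fine_t)
    if np.any(kp_fine < 0) or np.any(p_fine < 0):
        warnings.warn("k_p(t) or p(t) went negative; clipping at 0", stacklevel=2)
        kp_fine = np.clip(kp_fine, 0.0, None)
        p_fine = np.clip(p_fine, 0.0, None)

    drive_mid = kp_of(fine_t[:-1] + h / 2) * p_of(fine_t[:-1] + h / 2)
    drive_mid = np.clip(drive_mid, 0.0, None)
    drive = kp_fine * p_fine

    if m0 is None:
        m0 = drive[0] / kd if kd > 0 else 0.0
    m_fine = np.empty(n_fine)
    m_fine[0] = m0
    for i in range(n_fine - 1):
        m = m_fine[i]
        f = lambda mm, dd: dd - kd * mm
        k1 = f(m, drive[i])
        k2 = f(m + h / 2 * k1, drive_mid[i])
        k3 = f(m + h / 2 * k2, drive_mid[i])
        k4 = f(m + h * k3, drive[i + 1])
        m_fine[i + 1] = m + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    idx = np.rint((times - t0) / h).astype(int)
    p_obs = p_fine[idx].copy()
    m_obs = m_fine[idx].copy()
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        p_obs *= 2.0 ** rng.normal(0.0, scenario.noise_sd, p_obs.shape)
        m_obs *= 2.0 ** rng.normal(0.0, scenario.noise_sd, m_obs.shape)
    tc = ExpressionTimecourse(gene_id, TimeSeries(times, p_obs), TimeSeries(times, m_obs))
    kp_true = TimeSeries(times, kp_fine[idx])
    if return_fine:
        fine = {"t": fine_t, "p": p_fine, "m": m_fine, "kp": kp_fine}
        return tc, kp_true, fine
    return tc, kp_true


# --------------------------------------------------------------------------
# speckle images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueSpeckle:
    """Ground-truth geometry of one generated speckle."""

    nucleus_id: int
    area: float
    perimeter: float
    sphericity: float


@dataclass(frozen=True)
class SpeckleImage:
    """A rendered speckle image with its generating ground truth."""

    image: np.ndarray
    labels: np.ndarray  # per-speckle integer labels, 0 = background
    nucleus_mask: np.ndarray  # per-nucleus integer labels
    regions: tuple[TrueSpeckle, ...]
    mode: str


def gen_speckle_image(
    mode: str,
    n_nuclei: int = 3,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    nucleus_seed: int | None = None,
    speckles_per_nucleus: int = 6,
    radius_range: tuple[float, float] = (3.0, 9.0),
    nucleus_radius_frac: float = 0.16,
    field_sigma: float = 3.0,
    field_quantile: float = 0.75,
    intensity_noise_sd: float = 0.01,
    max_retries: int = 2000,
) -> SpeckleImage:
    """Render nuclei containing speckles in one of two LLPS regimes.

    ``nucleation`` places pairwise-disjoint anti-aliased disks inside
    elliptical nuclei; their ground-truth area/perimeter are analytic
    (pi r^2, 2 pi r, sphericity exactly 1).  ``spinodal`` thresholds a
    Gaussian random field (smoothing ``field_sigma``, threshold at
    ``field_quantile`` within the nucleus) into connected, branched
    shapes whose ground truth is measured on the generating binary mask
    contour.  Deterministic under ``seed``; ``nucleus_seed`` (defaulting
    to ``seed``) controls nucleus geometry separately so that a movie
    can keep its nuclei fixed while speckles vary per frame.
    """
    if mode not in ("nucleation", "spinodal"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("image must be at least 64x64")
    rng = np.random.default_rng(seed)
    nuc_rng = rng if nucleus_seed is None else np.random.default_rng(nucleus_seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    nucleus_mask = np.zeros(shape, dtype=np.int32)
    centers = _place_nuclei(nuc_rng, shape, n_nuclei, nucleus_radius_frac, max_retries)
    for nid, (cy, cx, ry, rx) in enumerate(centers, start=1):
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        nucleus_mask[inside] = nid

    image = np.full(shape, 0.05)
    image[nucleus_mask > 0] = 0.15
    labels = np.zeros(shape, dtype=np.int32)
    regions: list[TrueSpeckle] = []
    next_label = 1

    for nid, (cy, cx, ry, rx) in enumerate(centers, start=1):
        if mode == "nucleation":
            disks = _place_disks(
                rng, (cy, cx, ry, rx), speckles_per_nucleus, radius_range, max_retries
            )
            for dy, dx, r in disks:
                dist = np.hypot(yy - dy, xx - dx)
                cover = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
                image = np.maximum(image, cover)
                labels[dist <= r] = next_label
                regions.append(
                    TrueSpeckle(nid, math.pi * r**2, 2.0 * math.pi * r, 1.0)
                )
                next_label += 1
        else:
            inside = nucleus_mask == nid
            fld = gaussian_filter(rng.normal(size=shape), field_sigma)
            thr = np.quantile(fld[inside], field_quantile)
            binary = (fld > thr) & inside
            from skimage import measure as _measure

            comp = _measure.label(binary, connectivity=2)
            for props in _measure.regionprops(comp):
                if props.area < 4:
                    continue
                mask = comp == props.label
                try:
                    area, perim = contour_measure(mask)
                except ValueError:
                    continue
                if area <= 0:
                    continue
                labels[mask] = next_label
                regions.append(TrueSpeckle(nid, area, perim, sphericity(area, perim)))
                image[mask] = 1.0
                next_label += 1
            # soften edges by half a pixel for realistic anti-aliasing
            image = np.where(inside, gaussian_filter(image, 0.5), image)

    if intensity_noise_sd > 0:
        image = image + rng.normal(0.0, intensity_noise_sd, shape)
    return SpeckleImage(image, labels, nucleus_mask, tuple(regions), mode)


def _place_nuclei(rng, shape, n, radius_frac, max_retries):
    h, w = shape
    base_r = radius_frac * min(h, w)
    placed: list[tuple[float, float, float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_retries:
            raise RuntimeError("could not place disjoint nuclei; reduce n_nuclei")
        tries += 1
        if tries % 200 == 0:  # restart a placement that painted itself in
            placed.clear()
        ry = base_r * rng.uniform(0.85, 1.15)
        rx = base_r * rng.uniform(0.85, 1.15)
        cy = rng.uniform(ry + 2, h - ry - 2)
        cx = rng.uniform(rx + 2, w - rx - 2)
        if all(
            np.hypot(cy - py, cx - px) > 1.05 * (max(ry, rx) + max(pry, prx))
            for py, px, pry, prx in placed
        ):
            placed.append((cy, cx, ry, rx))
    return placed


def _place_disks(rng, nucleus, n, radius_range, max_retries):
    cy, cx, ry, rx = nucleus
    placed = []
    tries = 0
    while len(placed) < n:
        if tries > max_retries:
            raise RuntimeError(
                "could not place disjoint speckles; reduce speckles_per_nucleus or radii"
            )
        tries += 1
        r = rng.uniform(*radius_range)
        # sample inside the ellipse shrunk by the disk radius
        ang = rng.uniform(0, 2 * math.pi)
        rad = math.sqrt(rng.uniform())
        dy = cy + rad * (ry - r - 1.5) * math.sin(ang)
        dx = cx + rad * (rx - r - 1.5) * math.cos(ang)
        if ((dy - cy) / max(ry - r - 1.5, 1e-9)) ** 2 + (
            (dx - cx) / max(rx - r - 1.5, 1e-9)
        ) ** 2 > 1.0:
            continue
        if all(np.hypot(dy - py, dx - px) > r + pr + 2.0 for py, px, pr in placed):
            placed.append((dy, dx, r))
    return placed


def gen_speckle_movie(
    n_frames: int = 192,
    frame_interval_h: float = 0.25,
    period_h: float = 12.0,
    n_nuclei: int = 2,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    **image_kwargs,
) -> tuple[list[SpeckleImage], np.ndarray]:
    """A time-lapse alternating nucleation/spinodal regimes.

    The regime switches every half period (default: every 24 frames at
    15-min frames, a 12-h morphology square wave over 48 h).  Nucleus
    geometry is fixed across frames; speckle placement re-randomizes
    per frame.  Returns the frames and their times in hours.
    """
    frames_per_half = max(1, int(round(period_h / 2.0 / frame_interval_h)))
    image_kwargs.setdefault("nucleus_radius_frac", 0.22)
    image_kwargs.setdefault("radius_range", (2.0, 5.0))
    image_kwargs.setdefault("speckles_per_nucleus", 5)
    frames = []
    for f in range(n_frames):
        mode = "nucleation" if (f // frames_per_half) % 2 == 0 else "spinodal"
        frames.append(
            gen_speckle_image(
                mode,
                n_nuclei=n_nuclei,
                shape=shape,
                seed=seed + 1 + f,
                nucleus_seed=seed,
                **image_kwargs,
            )
        )
    times = frame_interval_h * np.arange(n_frames)
    return frames, times


# --------------------------------------------------------------------------
# FRAP traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapTruth:
    """Generating parameters of a synthetic FRAP trace."""

    model: str
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    offset: float
    half_life: float


def gen_frap_trace(
    model: str = "single",
    rates: tuple[float, ...] = (math.log(2.0) / 10.0,),
    amplitudes: tuple[float, ...] = (0.6,),
    offset: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S,
    reference_level: float = 1000.0,
    background_level: float = 50.0,
    reference_bleach_frac: float = 0.0,
) -> tuple[FrapTrace, FrapTruth]:
    """Generate a three-channel FRAP trace with known recovery kinetics.

    The underlying normalized recovery is ``offset + sum_i A_i (1 -
    exp(-k_i t))``; the bleached channel is rendered through the stated
    reference and background constants so that the normalization
    operation recovers the model exactly.  ``reference_bleach_frac``
    applies a linear acquisition-photobleaching decline to the reference
    (and bleached) channel over the trace.  Noise is additive Gaussian
    on the normalized scale.
    """
    if model not in ("single", "double"):
        raise ValueError(f"unknown model {model!r}")
    n_exp = 1 if model == "single" else 2
    if len(rates) != n_exp or len(amplitudes) != n_exp:
        raise ValueError(f"{model} model needs {n_exp} rate(s) and amplitude(s)")
    if any(k <= 0 for k in rates):
        raise ValueError("rates must be positive")
    if any(a < 0 for a in amplitudes):
        raise ValueError("amplitudes must be non-negative")
    t = frame_interval * np.arange(n_frames)
    f = np.full_like(t, offset)
    for a, k in zip(amplitudes, rates):
        f = f + a * (1.0 - np.exp(-k * t))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.shape)
    pb = 1.0 - reference_bleach_frac * (t / t[-1] if t[-1] > 0 else 0.0)
    reference = background_level + (reference_level - background_level) * pb
    bleached = background_level + (reference - background_level) * f
    background = np.full_like(t, background_level)
    trace = FrapTrace(t, bleached, reference, background)

    total = sum(amplitudes)
    if n_exp == 1:
        half = math.log(2.0) / rates[0]
    else:
        from .frap import _half_life_double

        half = _half_life_double(tuple(amplitudes), tuple(rates), float(t[-1]))
    return trace, FrapTruth(model, tuple(amplitudes), tuple(rates), offset, half)


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------


def default_gene_models() -> list[GeneModel]:
    """A small toy genome: three multi-exon genes on one chromosome."""
    return [
        GeneModel("geneA", "chr1", "+", ((0, 1000), (2000, 3000), (4000, 5000))),
        GeneModel("geneB", "chr1", "-", ((10_000, 10_800), (12_000, 13_000))),
        GeneModel("geneC", "chr1", "+", ((20_000, 21_500), (23_000, 23_800), (25_000, 26_000))),
    ]


def gen_read_set(
    gene_models: list[GeneModel],
    n_exon_reads: int = 5,
    n_junction_reads: int = 3,
    n_intron_reads: int = 2,
    n_split_reads: int = 2,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[ReadAlignment], dict[str, dict[str, int]]]:
    """Block reads of four known categories, per gene, with expected counts.

    Per gene: ``n_exon_reads`` single-block reads inside one exon,
    ``n_junction_reads`` straddling an exon/intron boundary (counted as
    intron), ``n_intron_reads`` inside an intron, and ``n_split_reads``
    spliced across two consecutive exons (counted once as exon).
    Expected counts per gene are therefore exon = exon + split reads and
    intron = junction + intron reads.  Raises when a requested category
    cannot fit (e.g. ``read_len`` longer than every exon, or junction
    reads requested for a single-exon gene).
    """
    if read_len < 2:
        raise ValueError("read_len must be >= 2")
    rng = np.random.default_rng(seed)
    reads: list[ReadAlignment] = []
    expected: dict[str, dict[str, int]] = {}
    for gene in gene_models:
        introns = gene.introns
        if (n_junction_reads or n_intron_reads or n_split_reads) and not introns:
            raise ValueError(f"{gene.gene_id}: intron-dependent reads need >= 2 exons")

        for _ in range(n_exon_reads):
            fits = [ex for ex in gene.exons if ex[1] - ex[0] >= read_len]
            if not fits:
                raise ValueError(f"{gene.gene_id}: read_len {read_len} exceeds every exon")
            s, e = fits[rng.integers(len(fits))]
            start = int(rng.integers(s, e - read_len + 1))
            reads.append(ReadAlignment(gene.chrom, ((start, start + read_len),)))

        for _ in range(n_junction_reads):
            # boundary between exon i end and intron i start (or intron->exon)
            i = int(rng.integers(len(introns)))
            boundary = introns[i][0] if rng.random() < 0.5 else introns[i][1]
            left = int(rng.integers(1, read_len))
            start = boundary - left
            reads.append(ReadAlignment(gene.chrom, ((start, start + read_len),)))

        for _ in range(n_intron_reads):
            fits = [iv for iv in introns if iv[1] - iv[0] >= read_len]
            if not fits:
                raise ValueError(f"{gene.gene_id}: read_len {read_len} exceeds every intron")
            s, e = fits[rng.integers(len(fits))]
            start = int(rng.integers(s, e - read_len + 1))
            reads.append(ReadAlignment(gene.chrom, ((start, start + read_len),)))

        for _ in range(n_split_reads):
            i = int(rng.integers(len(gene.exons) - 1))
            (s1, e1), (s2, e2) = gene.exons[i], gene.exons[i + 1]
            left = int(rng.integers(1, read_len))
            right = read_len - left
            left = min(left, e1 - s1)
            right = min(read_len - left, e2 - s2)
            reads.append(
                ReadAlignment(gene.chrom, ((e1 - left, e1), (s2, s2 + right)))
            )

        expected[gene.gene_id] = {
            "exon": n_exon_reads + n_split_reads,
            "intron": n_junction_reads + n_intron_reads,
        }
    return reads, expected
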