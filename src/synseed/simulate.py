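"""Synthetic-data generators with known ground truth.

Every input kind consumed by the analysis modules can be generated here:
sigmoidal ThT kinetic curves and whole plate runs, ordinal cohorts drawn
from a cumulative-logit model with known coefficients, rendered two-channel
fluorescence scenes with known inclusion counts / neurite lengths / nuclei
counts, and unimodal SEC fraction profiles.  Each generator records the
truth it used, so downstream estimators can be validated without any
external data.

All generators are deterministic under a fixed ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw as skdraw

__all__ = [
    "CurveSimSpec",
    "GroupPreset",
    "DEFAULT_PRESETS",
    "SyntheticCohortSpec",
    "ImageSceneSpec",
    "SceneTruth",
    "simulate_curve",
    "simulate_plate",
    "simulate_cohort",
    "render_scene",
    "random_fret_scene",
    "random_neurite_scene",
    "simulate_sec_profile",
    "logistic_crossing_time",
    "disk_pixels",
    "write_plate_csv",
]


# ---------------------------------------------------------------------------
# Kinetic curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSimSpec:
    """Parameters of one simulated ThT kinetic curve.

    The curve is a four-quantity logistic,

        F(t) = baseline + amplitude / (1 + exp(-rate_k * (t - midpoint_t50)))
               + Normal(0, noise_sd**2),

    sampled on the plate-reader grid ``t_i = i * cycle_period`` for
    ``i = 0 .. n_cycles - 1``.  Defaults mirror a 30-minute read cycle over
    60 h (120 cycles).

    Parameters
    ----------
    baseline : float
        Pre-aggregation fluorescence, arbitrary units (AU).
    amplitude : float
        Plateau rise above baseline, AU.  Zero gives a flat negative curve.
    rate_k : float
        Logistic growth rate, 1/h.
    midpoint_t50 : float
        Time of half-maximal rise, h.
    noise_sd : float
        SD of additive Gaussian read noise, AU.
    """

    baseline: float
    amplitude: float
    rate_k: float
    midpoint_t50: float
    noise_sd: float = 0.0
    n_cycles: int = 120
    cycle_period: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline", "amplitude", "rate_k", "midpoint_t50",
                     "noise_sd", "cycle_period"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"CurveSimSpec.{name} must be finite, got {v!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 20:
            raise ValueError("n_cycles must be >= 20 (threshold and plateau "
                             "statistics each need 10 cycles)")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_period


def simulate_curve(spec: CurveSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one kinetic curve.

    Returns
    -------
    (times, fluorescence) : two 1-D arrays of length ``spec.n_cycles``.
    """
    t = spec.times
    f = spec.baseline + spec.amplitude / (1.0 + np.exp(-spec.rate_k * (t - spec.midpoint_t50)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)
    return t, f


def logistic_crossing_time(spec: CurveSimSpec, threshold: float) -> float | None:
    """Analytic time at which the noiseless logistic reaches ``threshold``.

    Returns ``None`` when the plateau never reaches the threshold.  Used as
    an independent oracle for the on-grid crossing detector.
    """
    if threshold <= spec.baseline:
        return 0.0
    if spec.amplitude == 0 or threshold >= spec.baseline + spec.amplitude:
        return None
    frac = spec.amplitude / (threshold - spec.baseline) - 1.0
    return spec.midpoint_t50 - math.log(frac) / spec.rate_k


@dataclass(frozen=True)
class GroupPreset:
    """Per-group distribution of curve parameters.

    ``means``/``sds`` give the sampling distribution of each
    :class:`CurveSimSpec` field; per-sample parameters are drawn once and
    shared by the sample's replicate wells (each well gets independent read
    noise).  Draws for non-negative parameters are truncated at zero.
    """

    group_label: str
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)

    def mean_spec(self, **overrides) -> CurveSimSpec:
        """The noiseless spec at the preset means (noise_sd forced to 0)."""
        kw = dict(self.means)
        kw["noise_sd"] = 0.0
        kw.update(overrides)
        return CurveSimSpec(**kw)

    def draw_spec(self, rng: np.random.Generator, rng_seed: int = 0) -> CurveSimSpec:
        kw = {}
        for name, mu in self.means.items():
            sd = self.sds.get(name, 0.0)
            v = rng.normal(mu, sd) if sd > 0 else mu
            if name in ("amplitude", "noise_sd", "rate_k"):
                v = max(v, 0.0)
            kw[name] = v
        return CurveSimSpec(rng_seed=rng_seed, **kw)


def _preset(label: str, amplitude: float, t50: float, rate: float = 0.6,
            amp_sd: float = 0.0, t50_sd: float = 0.0) -> GroupPreset:
    return GroupPreset(
        group_label=label,
        means={"baseline": 10_000.0, "amplitude": amplitude, "rate_k": rate,
               "midpoint_t50": t50, "noise_sd": 400.0},
        sds={"amplitude": amp_sd, "midpoint_t50": t50_sd},
    )


#: Default presets encoding the qualitative group structure seen in brain
#: RT-QuIC: controls are flat; Lewy-body co-pathology gives earlier crossing
#: and a higher plateau than pure AD; APOE4 carriage raises the plateau
#: within the seeding-positive groups.
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "control/APOE4-": _preset("control/APOE4-", amplitude=0.0, t50=30.0),
    "control/APOE4+": _preset("control/APOE4+", amplitude=0.0, t50=30.0),
    "AD/APOE4-": _preset("AD/APOE4-", amplitude=80_000.0, t50=35.0,
                         rate=0.5, amp_sd=10_000.0, t50_sd=4.0),
    "AD/APOE4+": _preset("AD/APOE4+", amplitude=90_000.0, t50=34.0,
                         rate=0.5, amp_sd=10_000.0, t50_sd=4.0),
    "AD+LB/APOE4-": _preset("AD+LB/APOE4-", amplitude=150_000.0, t50=18.0,
                            rate=0.8, amp_sd=15_000.0, t50_sd=3.0),
    "AD+LB/APOE4+": _preset("AD+LB/APOE4+", amplitude=200_000.0, t50=16.0,
                            rate=0.8, amp_sd=15_000.0, t50_sd=3.0),
    "LBD/APOE4-": _preset("LBD/APOE4-", amplitude=140_000.0, t50=16.0,
                          rate=0.8, amp_sd=15_000.0, t50_sd=3.0),
    "LBD/APOE4+": _preset("LBD/APOE4+", amplitude=180_000.0, t50=14.0,
                          rate=0.8, amp_sd=15_000.0, t50_sd=3.0),
}

_ROWS = "ABCDEFGH"


def _well_ids(n: int, multi_plate: bool) -> tuple[list[str], list[int]]:
    if n > 96 and not multi_plate:
        raise ValueError(
            f"{n} wells exceed one 96-well plate; pass multi_plate=True")
    ids, plates = [], []
    for i in range(n):
        plate, pos = divmod(i, 96)
        row, col = divmod(pos, 12)
        wid = f"{_ROWS[row]}{col + 1}"
        ids.append(wid if plate == 0 else f"P{plate + 1}-{wid}")
        plates.append(plate + 1)
    return ids, plates


def simulate_plate(
    presets,
    replicates_per_sample: int = 3,
    samples_per_group: int = 3,
    rng_seed: int = 0,
    multi_plate: bool = False,
):
    """Simulate a plate run: groups x samples x replicate wells.

    Parameters
    ----------
    presets : list of GroupPreset, or mapping label -> GroupPreset, or a
        list of (preset, n_samples) pairs for unequal group sizes.
    replicates_per_sample : wells per biological sample (assay default 3).
    samples_per_group : samples per preset, ignored for (preset, n) pairs.

    Returns
    -------
    (plate, truth) : :class:`synseed.kinetics.PlateRun` and a DataFrame with
        one row per well recording the exact :class:`CurveSimSpec` used.
    """
    from synseed.kinetics import PlateRun

    if isinstance(presets, dict):
        presets = list(presets.values())
    if not presets:
        raise ValueError("at least one preset is required")
    norm: list[tuple[GroupPreset, int]] = []
    for p in presets:
        if isinstance(p, GroupPreset):
            norm.append((p, samples_per_group))
        else:
            preset, n = p
            norm.append((preset, int(n)))
    if replicates_per_sample < 1:
        raise ValueError("replicates_per_sample must be >= 1")

    n_wells = sum(n for _, n in norm) * replicates_per_sample
    well_ids, plates = _well_ids(n_wells, multi_plate)

    rng = np.random.default_rng(rng_seed)
    wells: dict[str, np.ndarray] = {}
    layout_rows, truth_rows = [], []
    times = None
    w = 0
    sample_counter = 0
    for preset, n_samples in norm:
        for _ in range(n_samples):
            sample_counter += 1
            sample_id = f"S{sample_counter:03d}"
            base_spec = preset.draw_spec(rng)
            for rep in range(1, replicates_per_sample + 1):
                well_seed = int(rng.integers(0, 2**31 - 1))
                spec = replace(base_spec, rng_seed=well_seed)
                t, f = simulate_curve(spec)
                if times is None:
                    times = t
                wid = well_ids[w]
                wells[wid] = f
                layout_rows.append({
                    "well": wid, "sample_id": sample_id,
                    "group": preset.group_label, "replicate": rep,
                    "batch": f"plate{plates[w]}",
                })
                truth_rows.append({
                    "well": wid, "sample_id": sample_id,
                    "group": preset.group_label,
                    **{k: getattr(spec, k) for k in (
                        "baseline", "amplitude", "rate_k", "midpoint_t50",
                        "noise_sd", "n_cycles", "cycle_period", "rng_seed")},
                })
                w += 1

    layout = pd.DataFrame(layout_rows).set_index("well")
    plate = PlateRun(times=times, wells=wells, layout=layout)
    return plate, pd.DataFrame(truth_rows)


def write_plate_csv(plate, curves_path, layout_path) -> None:
    """Write a plate run as the wide-CSV export + layout CSV pair."""
    cols = {f"t_{t:g}": [plate.wells[w][i] for w in plate.wells]
            for i, t in enumerate(plate.times)}
    df = pd.DataFrame({"well": list(plate.wells), **cols})
    df.to_csv(curves_path, index=False)
    plate.layout.reset_index().to_csv(layout_path, index=False)


# ---------------------------------------------------------------------------
# Ordinal cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a synthetic autopsy cohort with an ordinal outcome.

    The outcome is drawn from the cumulative-logit (proportional-odds) model

        P(Y <= j | x) = logistic(cutpoint_j - beta' x),

    so positive coefficients shift mass toward higher outcome levels.

    ``true_beta`` maps predictor names to coefficients.  Names matching a
    built-in covariate (``age``, ``sex``, ``caa``, ``braak``, ``thal``,
    ``apoe4_count``) use that covariate's distribution; any other name is
    drawn standard normal.
    """

    n_cases: int
    true_beta: dict[str, float]
    cutpoints: tuple[float, ...]
    rng_seed: int = 0
    include_covariates: tuple[str, ...] = (
        "age", "sex", "caa", "braak", "thal", "apoe4_count")

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        cp = np.asarray(self.cutpoints, dtype=float)
        if cp.size < 1 or np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must be strictly increasing")


def _draw_covariate(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    # Plausible autopsy-cohort marginals: elderly ages, advanced tau/amyloid
    # staging; not intended for inference about any real cohort.
    if name == "age":
        return rng.uniform(55.0, 100.0, n)
    if name == "sex":
        return rng.integers(0, 2, n).astype(float)
    if name == "caa":
        return rng.integers(0, 5, n).astype(float)
    if name == "braak":
        return rng.choice([3, 4, 5, 6], size=n, p=[0.1, 0.3, 0.3, 0.3]).astype(float)
    if name == "thal":
        return rng.choice([3, 4, 5], size=n, p=[0.2, 0.4, 0.4]).astype(float)
    if name == "apoe4_count":
        return rng.choice([0, 1, 2], size=n, p=[0.35, 0.5, 0.15]).astype(float)
    return rng.standard_normal(n)


def simulate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus the generating truth.

    Returns
    -------
    (table, truth) : the table has one row per case with all covariates,
        the predictors named in ``true_beta`` and the ordinal ``outcome``
        (levels 1..K); truth records ``beta`` and ``cutpoints``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_cases
    cols: dict[str, np.ndarray] = {}
    for name in spec.include_covariates:
        cols[name] = _draw_covariate(name, n, rng)
    for name in spec.true_beta:
        if name not in cols:
            cols[name] = _draw_covariate(name, n, rng)

    eta = np.zeros(n)
    for name, beta in spec.true_beta.items():
        eta += beta * cols[name]

    cp = np.asarray(spec.cutpoints, dtype=float)
    # P(Y <= j) for each cutpoint; invert via a uniform draw
    cum = 1.0 / (1.0 + np.exp(-(cp[None, :] - eta[:, None])))
    u = rng.uniform(size=n)
    outcome = 1 + (u[:, None] > cum).sum(axis=1)

    table = pd.DataFrame({"case_id": [f"C{i + 1:05d}" for i in range(n)], **cols,
                          "outcome": outcome})
    truth = {"beta": dict(spec.true_beta), "cutpoints": tuple(cp.tolist())}
    return table, truth


# ---------------------------------------------------------------------------
# Rendered microscopy scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneTruth:
    """Exact pre-noise ground truth of a rendered scene."""

    n_nuclei: int
    n_inclusions: int
    neurite_length: float        # summed Euclidean polyline length, px
    inclusion_centroids: tuple[tuple[float, float], ...]
    nuclei_centroids: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class ImageSceneSpec:
    """Geometry of a two-channel 8-bit fluorescence scene.

    ``nuclei``: list of ((row, col), radius) disks drawn in the blue channel.
    ``neurites``: list of polylines ([(r0, c0), (r1, c1), ...]) drawn 1 px
    wide (hard rasterization, no anti-aliasing) in the red channel.
    ``inclusions``: list of ((row, col), radius, peak_intensity) disks drawn
    in the red/FRET channel.
    """

    shape: tuple[int, int] = (256, 256)
    nuclei: tuple = ()
    neurites: tuple = ()
    inclusions: tuple = ()
    background: float = 10.0
    noise_sd: float = 0.0
    nucleus_intensity: float = 220.0
    neurite_intensity: float = 200.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for (r, c), rad in self.nuclei:
            if not (rad <= r <= h - 1 - rad and rad <= c <= w - 1 - rad):
                raise ValueError(f"nucleus at {(r, c)} radius {rad} exceeds canvas")
        for (r, c), rad, _ in self.inclusions:
            if not (rad <= r <= h - 1 - rad and rad <= c <= w - 1 - rad):
                raise ValueError(f"inclusion at {(r, c)} radius {rad} exceeds canvas")
        for poly in self.neurites:
            for r, c in poly:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(f"neurite vertex {(r, c)} exceeds canvas")
            if len(poly) < 2:
                raise ValueError("neurite polyline needs >= 2 vertices")


def _polyline_length(poly) -> float:
    pts = np.asarray(poly, dtype=float)
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def disk_pixels(center, radius, shape) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose center lies within Euclidean distance <= radius.

    Inclusive-boundary rasterization: a radius-5 disk covers 81 pixels
    (continuous area pi*25 ~ 78.5).  Exposed so tests can use the same
    predicate as an area oracle.
    """
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return np.nonzero(mask)


def render_scene(spec: ImageSceneSpec) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Rasterize a scene into (red, blue) 8-bit planes plus its truth.

    Noise is added before clipping to [0, 255], matching an 8-bit camera
    export.  Disks include pixels within Euclidean distance <= radius of the
    center; polylines are Bresenham lines, one pixel wide.
    """
    h, w = spec.shape
    red = np.full((h, w), spec.background, dtype=float)
    blue = np.full((h, w), spec.background, dtype=float)

    for (r, c), rad in spec.nuclei:
        rr, cc = disk_pixels((r, c), rad, (h, w))
        blue[rr, cc] = spec.nucleus_intensity
    for poly in spec.neurites:
        for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
            rr, cc = skdraw.line(int(r0), int(c0), int(r1), int(c1))
            red[rr, cc] = spec.neurite_intensity
    for (r, c), rad, peak in spec.inclusions:
        rr, cc = disk_pixels((r, c), rad, (h, w))
        red[rr, cc] = peak

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        red = red + rng.normal(0.0, spec.noise_sd, red.shape)
        blue = blue + rng.normal(0.0, spec.noise_sd, blue.shape)
    red = np.clip(red, 0, 255).astype(np.uint8)
    blue = np.clip(blue, 0, 255).astype(np.uint8)

    truth = SceneTruth(
        n_nuclei=len(spec.nuclei),
        n_inclusions=len(spec.inclusions),
        neurite_length=sum(_polyline_length(p) for p in spec.neurites),
        inclusion_centroids=tuple((float(r), float(c)) for (r, c), *_ in spec.inclusions),
        nuclei_centroids=tuple((float(r), float(c)) for (r, c), _ in spec.nuclei),
    )
    return red, blue, truth


def random_fret_scene(rng: np.random.Generator, shape=(300, 300),
                      n_disks=(1, 4), n_bars=(1, 3)) -> ImageSceneSpec:
    """Random FRET-channel scene: disk inclusions plus elongated bars.

    Disks are the true inclusions; 2-px-thick bars (drawn as paired
    polylines) emulate fiber-like artifacts that the downstream eccentricity
    filter must reject.  Objects are spaced so that a 10 px morphological
    closing cannot merge them, keeping the truth count exact.
    """
    h, w = shape
    margin = 25
    placed: list[tuple[float, float]] = []

    def place(min_sep=60.0):
        for _ in range(200):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2
                   for pr, pc in placed):
                placed.append((r, c))
                return r, c
        raise RuntimeError("could not place object; enlarge the canvas")

    inclusions = []
    for _ in range(rng.integers(*n_disks, endpoint=True)):
        r, c = place()
        rad = rng.uniform(2.0, 15.0)
        inclusions.append(((round(r), round(c)), rad, 250.0))
    bars = []
    for _ in range(rng.integers(*n_bars, endpoint=True)):
        r, c = place()
        r, c = int(r), int(c)
        length = int(rng.integers(25, 50))
        c0 = max(1, min(c - length // 2, w - length - 2))
        bars.append(((r, c0), (r, c0 + length)))
        bars.append(((r + 1, c0), (r + 1, c0 + length)))
    return ImageSceneSpec(
        shape=shape, inclusions=tuple(inclusions), neurites=tuple(bars),
        background=10.0, noise_sd=2.0, neurite_intensity=250.0,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def random_neurite_scene(rng: np.random.Generator,
                         shape=(300, 300)) -> ImageSceneSpec:
    """Random nuclei + neurite scene with tracks placed clear of the nuclei.

    Polylines are axis-aligned or at 45 degrees and kept in the right half
    of the canvas while nuclei sit in the left quarter, so the dilated
    nucleus mask never clips a neurite and the Euclidean truth length stays
    exact.
    """
    h, w = shape
    nuclei = []
    n_nuc = int(rng.integers(2, 5))
    rows = np.linspace(30, h - 30, n_nuc)
    for r in rows:
        nuclei.append(((int(r), int(rng.uniform(15, w // 4 - 15))), 8))

    neurites = []
    for _ in range(int(rng.integers(2, 5))):
        r0 = int(rng.uniform(20, h - 80))
        c0 = int(rng.uniform(w // 2, w - 80))
        kind = rng.integers(0, 3)
        length = int(rng.integers(40, 70))
        if kind == 0:       # horizontal
            c0 = min(c0, w - length - 2)
            neurites.append(((r0, c0), (r0, c0 + length)))
        elif kind == 1:     # vertical
            r0 = min(r0, h - length - 2)
            neurites.append(((r0, c0), (r0 + length, c0)))
        else:               # 45 degrees
            d = min(length, h - r0 - 2, w - c0 - 2)
            neurites.append(((r0, c0), (r0 + d, c0 + d)))
    return ImageSceneSpec(
        shape=shape, nuclei=tuple(nuclei), neurites=tuple(neurites),
        background=10.0, noise_sd=2.0,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# SEC profiles
# ---------------------------------------------------------------------------

def simulate_sec_profile(
    fractions=range(18, 57),
    peaks=((42, 1.0, 2.0),),
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> pd.Series:
    """A unimodal/multimodal Gaussian-mixture elution profile.

    ``peaks`` is a list of (center_fraction, height, width_fractions).
    Returns amounts indexed by fraction number (non-negative).
    """
    idx = np.asarray(list(fractions))
    y = np.zeros(idx.size, dtype=float)
    for center, height, width in peaks:
        y += height * np.exp(-0.5 * ((idx - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return pd.Series(np.clip(y, 0.0, None), index=idx, name="amount")
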