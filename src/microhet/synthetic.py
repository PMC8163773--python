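"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the study's assays: a flat-bed-scanner time-lapse of
bacterial colonies on an agar plate (Gompertz area growth plus linear
red-channel accumulation from a respiration-sensitive formazan dye),
per-colony area/red time series, a single-cell proteome summary table
with mean-dependent expression noise, an enzyme-abundance/flux panel
across growth conditions, and a grouped metabolome intensity matrix.

Every generator is a pure function of its configuration and seed and
returns its outputs together with a :class:`GroundTruth` record, so
downstream estimators can be scored by parameter recovery.

Default parameter dispersions mirror the colony populations the assay
was built for: growth-rate CV ~0.4, lag-time CV ~0.15 and
respiratory-rate CV ~0.25 across colonies of a clonal population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .growth import GompertzFit, gompertz_value, lag_time

__all__ = [
    "ParamDist",
    "PlateSimConfig",
    "GroundTruth",
    "PlacementError",
    "gen_plate_timelapse",
    "gen_colony_timeseries",
    "gen_protein_noise_table",
    "gen_annotation_sets",
    "gen_flux_protein_panel",
    "gen_metabolome_matrix",
]


class PlacementError(RuntimeError):
    """Raised when colonies cannot be packed on the plate without overlap."""


@dataclass(frozen=True)
class ParamDist:
    """A per-colony parameter distribution.

    ``dispersion`` is the coefficient of variation for the log-normal
    family and the standard deviation for the normal family.
    """

    mean: float
    dispersion: float
    family: str = "lognormal"  # or "normal"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dispersion == 0:
            return np.full(n, self.mean, dtype=float)
        if self.family == "lognormal":
            # parametrize so that E[X] = mean, CV = dispersion
            s2 = np.log1p(self.dispersion ** 2)
            mu = np.log(self.mean) - s2 / 2.0
            return rng.lognormal(mu, np.sqrt(s2), size=n)
        if self.family == "normal":
            return rng.normal(self.mean, self.dispersion, size=n)
        raise ValueError(f"unknown family {self.family!r}")


# Per-colony time-series defaults: a 24 h trace sampled every 10 min.
DEFAULT_COLONY_DISTS: dict[str, ParamDist] = {
    "a_min": ParamDist(20.0, 0.2, "lognormal"),
    "a_delta": ParamDist(2000.0, 0.3, "lognormal"),
    "k": ParamDist(0.5, 0.4, "lognormal"),
    "t_m": ParamDist(10.0, 1.5, "normal"),
}
DEFAULT_RESP_DIST = ParamDist(0.05, 0.25, "lognormal")

# Plate-rendering defaults: smaller colonies, shorter experiment, so the
# rendered plate holds 50 non-overlapping colonies.
PLATE_COLONY_DISTS: dict[str, ParamDist] = {
    "a_min": ParamDist(12.0, 0.2, "lognormal"),
    "a_delta": ParamDist(700.0, 0.25, "lognormal"),
    "k": ParamDist(0.6, 0.4, "lognormal"),
    "t_m": ParamDist(5.0, 0.75, "normal"),
}


@dataclass
class PlateSimConfig:
    """Configuration of the rendered plate time-lapse."""

    plate_diameter_px: int = 512
    n_colonies: int = 50
    frame_interval: float = 10.0  # minutes
    n_frames: int = 60
    growth_param_distributions: dict = field(
        default_factory=lambda: dict(PLATE_COLONY_DISTS))
    respiration_rate_distribution: ParamDist = DEFAULT_RESP_DIST
    illumination_gradient_amplitude: float = 0.1
    pixel_noise_sd: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """True simulated parameters, one record per generated entity."""

    colonies: pd.DataFrame | None = None
    proteins: pd.DataFrame | None = None
    enzymes: pd.DataFrame | None = None
    metabolites: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _sample_colony_params(n, dists, resp_dist, rng) -> pd.DataFrame:
    cols = {name: d.sample(n, rng) for name, d in dists.items()}
    cols["alpha"] = resp_dist.sample(n, rng)
    df = pd.DataFrame(cols)
    df.insert(0, "colony_id", np.arange(n))
    # red accumulation starts at the colony's lag time (tangent at A_min)
    df["red_onset_h"] = [
        max(lag_time(GompertzFit(r.a_min, r.a_delta, r.k, r.t_m)), 0.0)
        for r in df.itertuples()
    ]
    return df


def _place_colonies(truth: pd.DataFrame, plate_radius: float,
                    center: tuple[float, float], rng,
                    margin: float = 3.0, max_attempts: int = 10_000):
    """Rejection-sample non-overlapping colony centers inside the plate."""
    radii = np.sqrt((truth["a_min"] + truth["a_delta"]) / np.pi)
    rows, cols = [], []
    for r_i in radii:
        limit = plate_radius - r_i - margin
        if limit <= 0:
            raise PlacementError("colony larger than the plate")
        for attempt in range(max_attempts):
            ang = rng.uniform(0, 2 * np.pi)
            rad = limit * np.sqrt(rng.uniform())
            rr = center[0] + rad * np.sin(ang)
            cc = center[1] + rad * np.cos(ang)
            ok = all(
                np.hypot(rr - r0, cc - c0) >= r_i + radii[j] + margin
                for j, (r0, c0) in enumerate(zip(rows, cols))
            )
            if ok:
                rows.append(rr)
                cols.append(cc)
                break
        else:
            raise PlacementError(
                f"could not place colony {len(rows)} after {max_attempts} attempts")
    truth = truth.copy()
    truth["center_row"] = rows
    truth["center_col"] = cols
    return truth


def gen_plate_timelapse(cfg: PlateSimConfig):
    """Render an RGB plate time-lapse with Gompertz colony growth.

    Each colony is a disk whose area follows its true Gompertz curve and
    whose red channel increases linearly at rate alpha (AU/h) once the
    colony passes its lag time.  A smooth radial illumination gradient
    and i.i.d. Gaussian pixel noise are added.

    Returns
    -------
    (stack, truth) : stack is float32 of shape (n_frames, H, W, 3) in
    [0, 1]; truth.colonies holds one row per colony.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    size = cfg.plate_diameter_px + 12
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    plate_radius = cfg.plate_diameter_px / 2.0

    truth = _sample_colony_params(
        cfg.n_colonies, cfg.growth_param_distributions,
        cfg.respiration_rate_distribution, rng)
    if cfg.n_colonies > 0:
        truth = _place_colonies(truth, plate_radius, center, rng)
    else:
        truth = truth.assign(center_row=pd.Series(dtype=float),
                             center_col=pd.Series(dtype=float))

    times_h = np.arange(cfg.n_frames) * cfg.frame_interval / 60.0

    rr_idx, cc_idx = np.mgrid[0:size, 0:size]
    dist2 = (rr_idx - center[0]) ** 2 + (cc_idx - center[1]) ** 2
    plate = dist2 <= plate_radius ** 2
    # smooth radial vignette: brightest at the plate center
    gradient = cfg.illumination_gradient_amplitude * (1.0 - dist2 / plate_radius ** 2)

    bg_agar, bg_out = 0.15, 0.05
    colony_gb = 0.65

    stack = np.empty((cfg.n_frames, size, size, 3), dtype=np.float32)
    base = np.where(plate, bg_agar, bg_out).astype(np.float32)
    for f, t in enumerate(times_h):
        frame = np.repeat(base[:, :, None], 3, axis=2).copy()
        for row in truth.itertuples():
            fit = GompertzFit(row.a_min, row.a_delta, row.k, row.t_m)
            area = float(gompertz_value(fit, t))
            radius = np.sqrt(area / np.pi)
            if radius < 0.5:
                continue
            dd, cc = draw_disk((row.center_row, row.center_col), radius, shape=(size, size))
            red = colony_gb + row.alpha * max(t - row.red_onset_h, 0.0)
            frame[dd, cc, 0] = min(red, 1.0)
            frame[dd, cc, 1] = colony_gb
            frame[dd, cc, 2] = colony_gb
        frame += np.where(plate, gradient, 0.0)[:, :, None].astype(np.float32)
        if cfg.pixel_noise_sd > 0:
            frame += rng.normal(0.0, cfg.pixel_noise_sd, size=frame.shape).astype(np.float32)
        np.clip(frame, 0.0, 1.0, out=frame)
        stack[f] = frame

    gt = GroundTruth(colonies=truth, meta={
        "plate_center": center, "plate_radius": plate_radius,
        "frame_times_min": np.arange(cfg.n_frames) * cfg.frame_interval,
    })
    return stack, gt


def gen_colony_timeseries(n: int, param_dists=None, noise_sd: float = 0.05,
                          red_noise_sd: float = 0.005,
                          resp_dist: ParamDist = DEFAULT_RESP_DIST,
                          n_frames: int = 145, frame_interval: float = 10.0,
                          seed: int = 0):
    """Per-colony area and red-intensity traces with ground truth.

    ``noise_sd`` is the Gaussian noise standard deviation on area as a
    fraction of each colony's A_delta; 0 gives exact curves.
    ``red_noise_sd`` is the absolute noise (intensity units) on the mean
    red trace: because the trace is an average over the colony's pixel
    mask, per-pixel sensor noise shrinks by ~sqrt(mask size), leaving
    millinoise on the mean (default 0.005 AU).

    Returns a long-form table (colony_id, time_h, area, red) and truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0 or red_noise_sd < 0:
        raise ValueError("noise sds must be >= 0")
    dists = dict(DEFAULT_COLONY_DISTS if param_dists is None else param_dists)
    rng = np.random.default_rng(seed)
    truth = _sample_colony_params(n, dists, resp_dist, rng)
    t = np.arange(n_frames) * frame_interval / 60.0

    frames = []
    red_base = 0.65
    for row in truth.itertuples():
        fit = GompertzFit(row.a_min, row.a_delta, row.k, row.t_m)
        area = gompertz_value(fit, t)
        red = red_base + row.alpha * np.maximum(t - row.red_onset_h, 0.0)
        if noise_sd > 0:
            area = area + rng.normal(0.0, noise_sd * row.a_delta, size=t.size)
        if red_noise_sd > 0:
            red = red + rng.normal(0.0, red_noise_sd, size=t.size)
        frames.append(pd.DataFrame({
            "colony_id": row.colony_id, "time_h": t, "area": area, "red": red,
        }))
    table = pd.concat(frames, ignore_index=True)
    return table, GroundTruth(colonies=truth)


def gen_protein_noise_table(n_proteins: int = 1018,
                            mu_log10_mean: float = 1.2,
                            mu_log10_sd: float = 0.9,
                            intrinsic_coef: float = 1.0,
                            extrinsic_floor: float = 0.1,
                            deviation_sd: float = 0.5,
                            essential_fraction: float = 0.2,
                            seed: int = 0):
    """Single-cell proteome summary with mean-dependent noise.

    Noise follows eta_p = (a/mu_p + b) * eps*_p: an intrinsic 1/mu term
    (coefficient ``a``) dominating at low copy number plus an extrinsic
    floor ``b``, modulated by a per-protein log-normal deviation factor
    eps* with log-sd ``deviation_sd`` (median 1).  sigma_p = mu_p *
    sqrt(eta_p).  Essential proteins are biased toward high abundance
    and low deviation, as observed in single-cell proteome surveys.

    Returns (table, truth): table has protein_id, mu, sigma, essential.
    """
    if intrinsic_coef < 0 or extrinsic_floor < 0:
        raise ValueError("intrinsic_coef and extrinsic_floor must be >= 0")
    if deviation_sd < 0:
        raise ValueError("deviation_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = 10.0 ** rng.normal(mu_log10_mean, mu_log10_sd, size=n_proteins)
    eps_star = (np.exp(rng.normal(0.0, deviation_sd, size=n_proteins))
                if deviation_sd > 0 else np.ones(n_proteins))
    eta = (intrinsic_coef / mu + extrinsic_floor) * eps_star
    sigma = mu * np.sqrt(eta)

    # essentials: high-mu / low-deviation bias via a ranking score
    z_mu = (np.log10(mu) - np.log10(mu).mean()) / max(np.log10(mu).std(), 1e-12)
    z_eps = ((np.log(eps_star) - np.log(eps_star).mean())
             / max(np.log(eps_star).std(), 1e-12)) if deviation_sd > 0 else 0.0
    score = z_mu - 0.5 * z_eps + rng.normal(0, 0.8, size=n_proteins)
    n_ess = int(round(essential_fraction * n_proteins))
    essential = np.zeros(n_proteins, dtype=bool)
    if n_ess > 0:
        essential[np.argsort(score)[-n_ess:]] = True

    ids = np.array([f"P{i:04d}" for i in range(n_proteins)])
    table = pd.DataFrame({"protein_id": ids, "mu": mu, "sigma": sigma,
                          "essential": essential})
    truth = pd.DataFrame({"protein_id": ids, "mu": mu, "eps_star": eps_star,
                          "eta_true": eta, "essential": essential})
    return table, GroundTruth(proteins=truth)


def gen_annotation_sets(protein_ids, epsilon=None, n_sets: int = 20,
                        set_size: int = 25, eps_weight: float = 0.0,
                        seed: int = 0) -> dict[str, list]:
    """Random gene sets / TF-target sets over the given proteins.

    ``eps_weight`` > 0 biases membership toward high-deviation proteins
    (sampling weight exp(eps_weight * z(log eps))); 0 gives uniformly
    random sets.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(protein_ids)
    if epsilon is not None and eps_weight != 0.0:
        le = np.log(np.asarray(epsilon, dtype=float))
        z = (le - le.mean()) / max(le.std(), 1e-12)
        w = np.exp(eps_weight * z)
        p = w / w.sum()
    else:
        p = None
    return {
        f"SET{j:03d}": list(rng.choice(ids, size=set_size, replace=False, p=p))
        for j in range(n_sets)
    }


def gen_flux_protein_panel(n_enzymes: int = 40, n_conditions: int = 7,
                           slope_dist: ParamDist = ParamDist(1.0, 0.3),
                           noise_sd: float = 0.05,
                           null_fraction: float = 0.25, seed: int = 0):
    """Enzyme-abundance and flux matrices across growth conditions.

    flux[e, c] = s_e * protein[e, c] + noise; a ``null_fraction`` subset
    of enzymes has s_e = 0 (flux unrelated to abundance).  ``noise_sd``
    scales with each enzyme's flux dynamic range.  The default width of
    seven conditions matches the carbon-source panel the protein-flux
    proportionality was estimated on.
    """
    if n_conditions < 3:
        raise ValueError("n_conditions must be >= 3")
    rng = np.random.default_rng(seed)
    enz = np.array([f"E{i:03d}" for i in range(n_enzymes)])
    cond = np.array([f"cond{j}" for j in range(n_conditions)])
    base = rng.lognormal(np.log(500.0), 0.5, size=n_enzymes)
    protein = base[:, None] * rng.lognormal(0.0, 0.4, size=(n_enzymes, n_conditions))
    slopes = slope_dist.sample(n_enzymes, rng)
    n_null = int(round(null_fraction * n_enzymes))
    null_idx = rng.choice(n_enzymes, size=n_null, replace=False)
    slopes[null_idx] = 0.0
    flux = slopes[:, None] * protein
    scale = np.maximum(np.ptp(flux, axis=1), base * np.abs(slopes) + 1.0)
    flux = flux + rng.normal(0.0, 1.0, size=flux.shape) * (noise_sd * scale)[:, None]
    protein_df = pd.DataFrame(protein, index=enz, columns=cond)
    flux_df = pd.DataFrame(flux, index=enz, columns=cond)
    truth = pd.DataFrame({"enzyme_id": enz, "slope": slopes,
                          "is_null": np.isin(np.arange(n_enzymes), null_idx)})
    return protein_df, flux_df, GroundTruth(enzymes=truth)


def gen_metabolome_matrix(n_ions: int = 955,
                          groups: dict[str, int] | None = None,
                          n_pathways: int = 20, pathway_size: int = 40,
                          affected_pathway: str = "PW00",
                          effect_size: float = 1.0, rep_sd: float = 0.5,
                          seed: int = 0):
    """Grouped metabolome ion-intensity matrix with a planted pathway.

    Intensities are log-normal: per-ion baseline log2 ~ N(10, 2) with
    replicate noise sd ``rep_sd`` (log2 units).  Ions of
    ``affected_pathway`` are shifted by ``effect_size`` log2 units in
    the second group.  Groups default to two strains with three
    replicates each.  Each ion also carries a deprotonated-adduct m/z
    derived from a synthetic neutral mass (with 2 ppm jitter), plus the
    matching neutral-mass list for annotation tests.

    Returns (intensities, pathways, masses, truth): intensities is an
    ions x samples DataFrame with an ``mz`` column; pathways a GMT-style
    dict; masses a DataFrame (metabolite_id, mass).
    """
    if groups is None:
        groups = {"wildtype": 3, "mutant": 3}
    if any(n < 2 for n in groups.values()):
        raise ValueError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    ions = np.array([f"ion{i:04d}" for i in range(n_ions)])

    pathways = {}
    assigned = rng.permutation(n_ions)
    pos = 0
    for j in range(n_pathways):
        take = assigned[pos:pos + pathway_size]
        pathways[f"PW{j:02d}"] = list(ions[take])
        pos += pathway_size
        if pos >= n_ions:
            break
    affected = np.isin(ions, pathways.get(affected_pathway, []))

    group_names = list(groups)
    samples, labels = [], []
    for g in group_names:
        for r in range(groups[g]):
            samples.append(f"{g}_r{r+1}")
            labels.append(g)
    base = rng.normal(10.0, 2.0, size=n_ions)
    data = np.empty((n_ions, len(samples)))
    for s, g in enumerate(labels):
        shift = np.where(affected & (g == group_names[1]), effect_size, 0.0)
        data[:, s] = 2.0 ** (base + shift + rng.normal(0.0, rep_sd, size=n_ions))

    mass = rng.uniform(60.0, 1000.0, size=n_ions)
    mz = (mass - 1.007276) * (1.0 + rng.normal(0.0, 2e-6, size=n_ions))
    intens = pd.DataFrame(data, index=ions, columns=samples)
    intens.insert(0, "mz", mz)
    masses = pd.DataFrame({"metabolite_id": [f"M{i:04d}" for i in range(n_ions)],
                           "mass": mass, "ion_id": ions})
    truth = pd.DataFrame({"metabolite_id": ions, "affected": affected,
                          "effect_log2": np.where(affected, effect_size, 0.0)})
    return intens, pathways, masses, GroundTruth(
        metabolites=truth, meta={"sample_groups": dict(zip(samples, labels))})
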